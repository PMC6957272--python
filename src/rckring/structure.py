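"""Coordinate-file reading, assembly expansion and octameric-ring assembly.

The RCK regulatory rings analysed here are octamers: four dimers of a
Rossmann-fold domain arranged around a (pseudo) four-fold axis.  Depending
on the crystal form the deposited asymmetric unit holds 2, 8 or 16
protomers, so a ring may have to be generated by applying symmetry
operators, or extracted from a double-ring asymmetric unit by an explicit
chain selection.

Parsing and writing of PDB/mmCIF goes through :mod:`gemmi`; this module
exposes a small, author-numbered in-memory model sufficient for marker-atom
geometry and coordination-shell analysis.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .errors import MarkerMissingError, RingAssemblyError, StructureParseError, UsageError

STANDARD_AA3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "SEC", "PYL", "UNK",
}

_NONPROTEIN = {"HOH", "DOD", "ATP", "ADP", "AMP", "MG", "CA", "NA", "K", "CL", "ZN", "MN"}


@dataclass
class AtomRecord:
    """One atom with author residue numbering and crystallographic B/occupancy."""

    atom_name: str
    element: str
    residue_number: int
    residue_name: str
    chain_id: str
    position: np.ndarray  # (3,) Å
    b_factor: float = 0.0
    occupancy: float = 1.0
    is_hetero: bool = False

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise UsageError(f"atom {self.atom_name}: position must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise UsageError(f"atom {self.atom_name}: occupancy {self.occupancy} outside [0, 1]")


@dataclass
class Residue:
    number: int
    name: str
    atoms: dict[str, AtomRecord] = field(default_factory=dict)

    @property
    def is_protein(self) -> bool:
        if self.name in _NONPROTEIN:
            return False
        return self.name in STANDARD_AA3 or "CA" in self.atoms

    def atom_coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms.values()])


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def residue(self, number: int) -> Residue | None:
        for res in self.residues:
            if res.number == number:
                return res
        return None

    def iter_atoms(self):
        for res in self.residues:
            yield from res.atoms.values()

    @property
    def is_protein(self) -> bool:
        return any(res.is_protein for res in self.residues)

    def centroid(self) -> np.ndarray:
        """Cα centroid when Cα atoms exist, all-atom centroid otherwise."""
        ca = [r.atoms["CA"].position for r in self.residues if r.is_protein and "CA" in r.atoms]
        if ca:
            return np.mean(ca, axis=0)
        coords = np.array([a.position for a in self.iter_atoms()])
        return coords.mean(axis=0)

    def ca_map(self) -> dict[int, np.ndarray]:
        """Author residue number -> Cα position, protein residues only."""
        return {
            r.number: r.atoms["CA"].position
            for r in self.residues
            if r.is_protein and "CA" in r.atoms
        }


@dataclass
class StructureModel:
    chains: list[Chain]
    header: dict = field(default_factory=dict)
    # each operator is a (R, t) pair: 3x3 proper rotation and 3-vector translation
    assembly_operators: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)

    def chain(self, chain_id: str) -> Chain:
        for ch in self.chains:
            if ch.chain_id == chain_id:
                return ch
        raise UsageError(f"chain {chain_id!r} not present (have {[c.chain_id for c in self.chains]})")

    @property
    def protein_chains(self) -> list[Chain]:
        return [c for c in self.chains if c.is_protein]

    def iter_atoms(self):
        for ch in self.chains:
            yield from ch.iter_atoms()


@dataclass
class RingModel:
    """Eight subunits ordered by increasing angle about the ring axis.

    Ordering is deterministic: the subunit with the lexicographically
    smallest chain id sits first, the rest follow by increasing angle of
    their centroids about the principal (normal) axis of the ring.
    """

    subunits: list[Chain]
    axis: np.ndarray
    centroid: np.ndarray
    model: StructureModel | None = None

    def __post_init__(self):
        if len(self.subunits) != 8:
            raise RingAssemblyError(f"expected 8 subunits, found {len(self.subunits)}")
        self.axis = np.asarray(self.axis, dtype=float)
        norm = np.linalg.norm(self.axis)
        if not np.isclose(norm, 1.0, atol=1e-6):
            self.axis = self.axis / norm

    @property
    def chain_ids(self) -> list[str]:
        return [c.chain_id for c in self.subunits]


# ---------------------------------------------------------------------------
# Parsing


def _select_altloc(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep the highest-occupancy conformer per atom name; ties favour 'A'."""
    best: dict[str, gemmi.Atom] = {}
    for atom in residue:
        prev = best.get(atom.name)
        if prev is None:
            best[atom.name] = atom
            continue
        key = (atom.occ, -ord(atom.altloc or "A"))
        prev_key = (prev.occ, -ord(prev.altloc or "A"))
        if key > prev_key:
            best[atom.name] = atom
    return list(best.values())


def _from_gemmi(st: gemmi.Structure) -> StructureModel:
    if len(st) == 0:
        raise StructureParseError("structure contains no models")
    st.setup_entities()
    model = st[0]
    chains: list[Chain] = []
    for gch in model:
        ch = Chain(chain_id=gch.name)
        for gres in gch:
            res = Residue(number=gres.seqid.num, name=gres.name)
            for atom in _select_altloc(gres):
                occ = min(max(float(atom.occ), 0.0), 1.0)
                res.atoms[atom.name] = AtomRecord(
                    atom_name=atom.name,
                    element=atom.element.name,
                    residue_number=gres.seqid.num,
                    residue_name=gres.name,
                    chain_id=gch.name,
                    position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    b_factor=float(atom.b_iso),
                    occupancy=occ,
                    is_hetero=gres.het_flag == "H",
                )
            if res.atoms:
                ch.residues.append(res)
        if ch.residues:
            chains.append(ch)
    operators: list[tuple[np.ndarray, np.ndarray]] = []
    if st.assemblies:
        asm = st.assemblies[0]
        for gen in asm.generators:
            for oper in gen.operators:
                tr = oper.transform
                R = np.array(tr.mat.tolist(), dtype=float)
                t = np.array(tr.vec.tolist(), dtype=float)
                operators.append((R, t))
    header = {"id": st.name, "spacegroup": st.spacegroup_hm}
    return StructureModel(chains=chains, header=header, assembly_operators=operators)


def load_structure(source: str | Path, fmt: str | None = None) -> StructureModel:
    """Read a PDB or mmCIF file (or literal text) into a :class:`StructureModel`.

    ``fmt`` is ``"pdb"`` or ``"mmcif"``; when ``source`` is a path it may be
    omitted and is inferred from the suffix.  All ATOM/HETATM records are
    retained with author residue numbering; biological-assembly operators
    are captured when the file declares them.
    """
    text: str
    name = "structure"
    path = Path(source) if not (isinstance(source, str) and "\n" in source) else None
    if path is not None:
        if not path.exists():
            raise UsageError(f"no such file: {path}")
        text = path.read_text()
        name = path.stem
        if fmt is None:
            suffix = path.suffix.lower()
            fmt = "mmcif" if suffix in {".cif", ".mmcif"} else "pdb"
    else:
        text = str(source)
        if fmt is None:
            raise UsageError("format must be given explicitly for literal text input")
    fmt = fmt.lower()
    if fmt not in {"pdb", "mmcif"}:
        raise UsageError(f"unknown format {fmt!r}: expected 'pdb' or 'mmcif'")
    if not text.strip():
        raise StructureParseError("empty input: no coordinate records found")
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb_string(text)
        else:
            doc = gemmi.cif.read_string(text)
            st = gemmi.make_structure_from_block(doc.sole_block())
        st.name = st.name or name
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"could not parse {fmt} input: {exc}") from exc
    model = _from_gemmi(st)
    if not any(res.atoms for ch in model.chains for res in ch.residues):
        raise StructureParseError("no atoms found in input")
    return model


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write the model in fixed-column PDB format (synthetic fixtures, reports)."""
    st = gemmi.Structure()
    st.name = str(model.header.get("id", "rckring"))
    gm = gemmi.Model("1")
    for ch in model.chains:
        gch = gemmi.Chain(ch.chain_id)
        for res in ch.residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.number, " ")
            het = any(a.is_hetero for a in res.atoms.values())
            gres.het_flag = "H" if het else "A"
            for atom in res.atoms.values():
                ga = gemmi.Atom()
                ga.name = atom.atom_name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*atom.position)
                ga.occ = atom.occupancy
                ga.b_iso = atom.b_factor
                gres.add_atom(ga)
            gch.add_residue(gres)
        gm.add_chain(gch)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Assembly expansion and ring building


def _fresh_chain_ids(n: int, taken: set[str]) -> list[str]:
    pool = list(string.ascii_uppercase) + list(string.ascii_lowercase) + list(string.digits)
    pool += [a + b for a in string.ascii_uppercase for b in string.ascii_uppercase]
    out = []
    for cid in pool:
        if cid not in taken:
            out.append(cid)
            taken.add(cid)
        if len(out) == n:
            return out
    raise UsageError("exhausted chain-id pool")


def apply_assembly(
    model: StructureModel,
    operators: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> StructureModel:
    """Expand the model by rigid operators: one copy of each chain per operator.

    Operators default to the ones captured from the file.  Each must be a
    proper rigid transform (orthonormal rotation, det +1); copies receive
    fresh unique chain ids.
    """
    ops = operators if operators is not None else model.assembly_operators
    if not ops:
        raise UsageError("no assembly operators given and none present in the file")
    for i, (R, _t) in enumerate(ops):
        R = np.asarray(R, dtype=float)
        if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-3):
            raise UsageError(f"operator {i}: rotation matrix is not orthonormal within 1e-3")
        if np.linalg.det(R) < 0:
            raise UsageError(f"operator {i}: improper rotation (det < 0)")
    taken: set[str] = set()
    new_chains: list[Chain] = []
    ids = _fresh_chain_ids(len(ops) * len(model.chains), taken)
    k = 0
    for R, t in ops:
        R = np.asarray(R, dtype=float)
        t = np.asarray(t, dtype=float)
        for ch in model.chains:
            cid = ids[k]
            k += 1
            nch = Chain(chain_id=cid)
            for res in ch.residues:
                nres = Residue(number=res.number, name=res.name)
                for a in res.atoms.values():
                    nres.atoms[a.atom_name] = AtomRecord(
                        atom_name=a.atom_name,
                        element=a.element,
                        residue_number=a.residue_number,
                        residue_name=a.residue_name,
                        chain_id=cid,
                        position=R @ a.position + t,
                        b_factor=a.b_factor,
                        occupancy=a.occupancy,
                        is_hetero=a.is_hetero,
                    )
                nch.residues.append(nres)
            new_chains.append(nch)
    return StructureModel(chains=new_chains, header=dict(model.header), assembly_operators=[])


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Proper rotation matrix about ``axis`` by ``angle_deg`` (Rodrigues)."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    th = np.deg2rad(angle_deg)
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)


def fourfold_operators(axis=(0.0, 0.0, 1.0)) -> list[tuple[np.ndarray, np.ndarray]]:
    """The crystallographic 4-fold: identity plus 90/180/270 deg rotations."""
    zero = np.zeros(3)
    return [(rotation_about_axis(axis, a), zero) for a in (0.0, 90.0, 180.0, 270.0)]


def partition_rings(model: StructureModel, cutoff: float = 60.0) -> list[list[str]]:
    """Group protein chains into candidate rings by centroid proximity.

    Single-linkage connected components with inter-centroid distance below
    ``cutoff`` Å.  Used for asymmetric units holding two rings (16 protomers).
    """
    chains = model.protein_chains
    cents = np.array([c.centroid() for c in chains])
    n = len(chains)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(cents[i] - cents[j]) < cutoff:
                parent[find(i)] = find(j)
    groups: dict[int, list[str]] = {}
    for i, ch in enumerate(chains):
        groups.setdefault(find(i), []).append(ch.chain_id)
    return sorted((sorted(g) for g in groups.values()), key=lambda g: g[0])


def build_ring(model: StructureModel, chain_selection: list[str] | None = None) -> RingModel:
    """Assemble the ordered octameric ring from a chain selection.

    Without a selection all protein chains are used; they must number
    exactly eight.  The ring axis is the normal of the best-fit plane of
    the eight subunit centroids; subunits are ordered by increasing angle
    about that axis, starting from the smallest chain id.
    """
    if chain_selection is not None:
        chains = [model.chain(cid) for cid in chain_selection]
    else:
        chains = model.protein_chains
    if len(chains) != 8:
        raise RingAssemblyError(f"expected 8 subunits, found {len(chains)}")
    cents = np.array([c.centroid() for c in chains])
    center = cents.mean(axis=0)
    rel = cents - center
    # normal of the centroid plane = eigenvector of smallest covariance eigenvalue
    _w, v = np.linalg.eigh(rel.T @ rel)
    axis = v[:, 0]
    # deterministic sign
    for ref in (np.array([0.0, 0.0, 1.0]), np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0])):
        d = float(axis @ ref)
        if abs(d) > 1e-8:
            if d < 0:
                axis = -axis
            break
    start = min(range(8), key=lambda i: chains[i].chain_id)
    e1 = rel[start] - (rel[start] @ axis) * axis
    n1 = np.linalg.norm(e1)
    if n1 < 1e-9:
        raise RingAssemblyError("degenerate geometry: a subunit centroid lies on the ring axis")
    e1 /= n1
    e2 = np.cross(axis, e1)
    angles = np.mod(np.arctan2(rel @ e2, rel @ e1), 2 * np.pi)
    angles[start] = 0.0
    order = sorted(range(8), key=lambda i: (angles[i], chains[i].chain_id))
    return RingModel(subunits=[chains[i] for i in order], axis=axis, centroid=center, model=model)


def get_marker_coords(ring: RingModel, residue_number: int, atom_name: str = "CA") -> np.ndarray:
    """Positions of one marker atom in every subunit, in ring order.

    A missing residue or atom in any subunit (e.g. unmodelled domains in
    low-resolution entries) raises :class:`MarkerMissingError` naming the
    offending subunits — never a silent skip.
    """
    coords = []
    missing = []
    for ch in ring.subunits:
        res = ch.residue(residue_number)
        if res is None or atom_name not in res.atoms:
            missing.append(ch.chain_id)
        else:
            coords.append(res.atoms[atom_name].position)
    if missing:
        raise MarkerMissingError(
            f"marker {residue_number}:{atom_name} missing in subunit(s) {', '.join(missing)}"
        )
    return np.array(coords)
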