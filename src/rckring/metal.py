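"""Cation coordination-shell detection, geometry and ion-identity scoring.

The divalent-cation site at the RCK intra-dimer interface is characterized
by (i) the set of donor atoms (oxygens, occasionally guanidinium nitrogens)
within a cutoff of the metal center, (ii) the coordination polyhedron those
donors describe, and (iii) a declared, configurable scoring of candidate
ion identities.  Mg2+ is expected octahedral at ~2.07 Å Mg–O; Ca2+ prefers
CN 7 (pentagonal-bipyramidal) at ~2.39 Å Ca–O.  A metal modelled too heavy
for its electron density refines with an inflated B-factor relative to its
shell, so the center-B / donor-B ratio flags a lighter-ion candidate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np

from .errors import UsageError
from .structure import AtomRecord, StructureModel

# ---------------------------------------------------------------------------
# Ideal coordination polyhedra (unit vectors from the center)

_S3 = 1.0 / np.sqrt(3.0)

IDEAL_POLYHEDRA: dict[str, np.ndarray] = {
    "tetrahedral": np.array(
        [[_S3, _S3, _S3], [_S3, -_S3, -_S3], [-_S3, _S3, -_S3], [-_S3, -_S3, _S3]]
    ),
    "square-planar": np.array([[1, 0, 0], [0, 1, 0], [-1, 0, 0], [0, -1, 0]], dtype=float),
    "trigonal-bipyramidal": np.array(
        [[0, 0, 1], [0, 0, -1]]
        + [[np.cos(a), np.sin(a), 0.0] for a in 2 * np.pi * np.arange(3) / 3]
    ),
    "octahedral": np.array(
        [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]], dtype=float
    ),
    "pentagonal-bipyramidal": np.array(
        [[0, 0, 1], [0, 0, -1]]
        + [[np.cos(a), np.sin(a), 0.0] for a in 2 * np.pi * np.arange(5) / 5]
    ),
}

#: Angular RMSD (degrees) above which a shell is called irregular.
IRREGULAR_CUTOFF = 20.0


@dataclass
class IonProfile:
    """Expected coordination behaviour of one candidate ion.

    The ideal metal–oxygen distances (Mg–O 2.07 Å, Ca–O 2.39 Å) and the
    preferred coordination numbers/geometries are literature standards kept
    here as editable configuration, not hard-wired behaviour.
    """

    element: str
    ideal_donor_distance: float  # Å
    preferred_cn: frozenset[int]
    preferred_geometry: frozenset[str]

    def __post_init__(self):
        if self.ideal_donor_distance <= 0:
            raise UsageError("ideal_donor_distance must be positive")
        self.preferred_cn = frozenset(self.preferred_cn)
        self.preferred_geometry = frozenset(self.preferred_geometry)
        if not self.preferred_cn:
            raise UsageError("preferred_cn must be nonempty")


DEFAULT_ION_PROFILES: list[IonProfile] = [
    IonProfile("MG", 2.07, frozenset({6}), frozenset({"octahedral"})),
    IonProfile("CA", 2.39, frozenset({6, 7, 8}), frozenset({"octahedral", "pentagonal-bipyramidal"})),
]


@dataclass
class ScoreWeights:
    distance: float = 1.0   # per Å of |mean donor distance - ideal|
    cn: float = 0.5         # per unit distance of CN from the preferred set
    geometry: float = 0.5   # flat penalty for a non-preferred polyhedron
    b_ratio_flag: float = 1.2  # center-B / donor-B above this flags a lighter ion


@dataclass
class Donor:
    atom: AtomRecord
    element: str
    distance: float
    b_factor: float


@dataclass
class CoordinationShell:
    center: np.ndarray
    center_b_factor: float | None
    donors: list[Donor]

    @property
    def cn(self) -> int:
        return len(self.donors)

    @property
    def mean_distance(self) -> float:
        return float(np.mean([d.distance for d in self.donors])) if self.donors else float("nan")

    def donor_vectors(self) -> np.ndarray:
        vec = np.array([d.atom.position - self.center for d in self.donors])
        return vec / np.linalg.norm(vec, axis=1, keepdims=True)


@dataclass
class GeometryAssessment:
    best_polyhedron: str          # polyhedron label or "irregular"
    angular_rmsd: float | None    # degrees; None when CN < 3
    per_polyhedron: dict[str, float] = field(default_factory=dict)


@dataclass
class IdentityScore:
    terms: list[dict]             # per ion: element, distance/cn/geometry terms, total
    ranking: list[str]            # elements sorted by total, best (lowest) first
    b_ratio: float | None
    lighter_ion_suspected: bool
    geometry: GeometryAssessment | None = None


@dataclass
class InterfaceSite:
    center: np.ndarray
    donor_distances: dict[str, float]   # selector -> distance from candidate center
    missing: list[str]                  # selectors that could not be resolved


# ---------------------------------------------------------------------------
# Selectors


def resolve_selector(model: StructureModel, selector: str) -> AtomRecord:
    """Resolve a "chain:resnum:atom" selector to an atom record."""
    parts = selector.split(":")
    if len(parts) != 3:
        raise UsageError(f"bad selector {selector!r}: expected 'chain:resnum:atom'")
    chain_id, resnum_s, atom_name = parts
    try:
        resnum = int(resnum_s)
    except ValueError as exc:
        raise UsageError(f"bad selector {selector!r}: residue number not an integer") from exc
    chain = model.chain(chain_id)
    res = chain.residue(resnum)
    if res is None or atom_name not in res.atoms:
        raise UsageError(f"selector {selector!r} does not resolve to an atom")
    return res.atoms[atom_name]


# ---------------------------------------------------------------------------
# Shell detection


def find_shell(
    model: StructureModel,
    center,
    cutoff: float = 3.0,
    donor_elements: frozenset[str] = frozenset({"O", "N"}),
) -> CoordinationShell:
    """All donor-element atoms within ``cutoff`` Å of the center, by distance.

    ``center`` may be a position, an :class:`AtomRecord`, or a
    "chain:resnum:atom" selector.  Atoms of the center's own residue are
    excluded (covalently attached), as is anything closer than 0.8 Å
    (clash guard).  An empty shell is a CN-0 result, not an error.
    """
    if cutoff <= 0:
        raise UsageError("cutoff must be positive")
    center_atom: AtomRecord | None = None
    if isinstance(center, AtomRecord):
        center_atom = center
    elif isinstance(center, str):
        center_atom = resolve_selector(model, center)
    if center_atom is not None:
        pos = center_atom.position
        center_b: float | None = center_atom.b_factor
    else:
        pos = np.asarray(center, dtype=float)
        if pos.shape != (3,):
            raise UsageError("center must be a 3-vector, atom record, or selector")
        center_b = None
    donors: list[Donor] = []
    for atom in model.iter_atoms():
        if atom.element not in donor_elements:
            continue
        if center_atom is not None and (
            atom.chain_id == center_atom.chain_id
            and atom.residue_number == center_atom.residue_number
        ):
            continue
        dist = float(np.linalg.norm(atom.position - pos))
        if 0.8 < dist <= cutoff:
            donors.append(Donor(atom=atom, element=atom.element, distance=dist, b_factor=atom.b_factor))
    donors.sort(key=lambda d: d.distance)
    return CoordinationShell(center=pos, center_b_factor=center_b, donors=donors)


# ---------------------------------------------------------------------------
# Geometry assessment


def _best_fit_angular_rmsd(obs: np.ndarray, ideal: np.ndarray) -> float:
    """Minimum angular RMSD (deg) over all vertex assignments and rotations.

    For every permutation of ideal vertices the optimal rotation is the
    Kabsch solution on the unit vectors; the batched SVD keeps the exact
    enumeration fast up to CN 7 (5040 permutations).
    """
    n = obs.shape[0]
    perms = np.array(list(permutations(range(n))))
    X = ideal[perms]                      # (P, n, 3) permuted ideal vertices
    H = np.einsum("pnk,nl->pkl", X, obs)  # cross-covariance per permutation
    U, _S, Vt = np.linalg.svd(H)
    det = np.linalg.det(np.einsum("pij,pjk->pik", Vt.transpose(0, 2, 1), U.transpose(0, 2, 1)))
    D = np.repeat(np.eye(3)[None, :, :], len(perms), axis=0)
    D[:, 2, 2] = np.sign(det)
    R = np.einsum("pij,pjk,pkl->pil", Vt.transpose(0, 2, 1), D, U.transpose(0, 2, 1))
    rotated = np.einsum("pij,pnj->pni", R, X)
    cosang = np.clip(np.einsum("pni,ni->pn", rotated, obs), -1.0, 1.0)
    ang = np.degrees(np.arccos(cosang))
    rmsd = np.sqrt(np.mean(ang**2, axis=1))
    return float(rmsd.min())


def assess_geometry(shell: CoordinationShell) -> GeometryAssessment:
    """Match the shell's donor directions to ideal polyhedra of the same CN.

    The best polyhedron is the one with the lowest residual angular RMSD
    after optimal vertex assignment and rotation; a residual above 20°
    (or a CN with no catalogued polyhedron, or CN < 3) is "irregular".
    """
    if shell.cn < 3:
        return GeometryAssessment(best_polyhedron="irregular", angular_rmsd=None)
    obs = shell.donor_vectors()
    candidates = {name: v for name, v in IDEAL_POLYHEDRA.items() if v.shape[0] == shell.cn}
    if not candidates:
        return GeometryAssessment(best_polyhedron="irregular", angular_rmsd=None)
    residuals = {name: _best_fit_angular_rmsd(obs, v) for name, v in candidates.items()}
    best = min(residuals, key=residuals.get)
    if residuals[best] > IRREGULAR_CUTOFF:
        return GeometryAssessment(best_polyhedron="irregular", angular_rmsd=residuals[best],
                                  per_polyhedron=residuals)
    return GeometryAssessment(best_polyhedron=best, angular_rmsd=residuals[best],
                              per_polyhedron=residuals)


# ---------------------------------------------------------------------------
# Identity scoring


def score_identity(
    shell: CoordinationShell,
    profiles: list[IonProfile] | None = None,
    weights: ScoreWeights | None = None,
    geometry: GeometryAssessment | None = None,
) -> IdentityScore:
    """Rank candidate ions by a declared weighted sum of deviations.

    distance term: |mean donor distance - ideal| (Å); CN term: distance of
    the observed CN from the preferred set; geometry term: flat penalty when
    the best polyhedron is not a preferred one.  Lower total = better fit.
    The center-B / mean-donor-B ratio is reported and, above the configured
    threshold, flags that a lighter ion than modelled may occupy the site.
    """
    if shell.cn < 1:
        raise UsageError("cannot score an empty coordination shell")
    profiles = profiles if profiles is not None else DEFAULT_ION_PROFILES
    if not profiles:
        raise UsageError("at least one ion profile is required")
    weights = weights or ScoreWeights()
    if geometry is None:
        geometry = assess_geometry(shell)
    mean_dist = shell.mean_distance
    terms = []
    for prof in profiles:
        d_term = abs(mean_dist - prof.ideal_donor_distance)
        cn_term = 0.0 if shell.cn in prof.preferred_cn else float(
            min(abs(shell.cn - c) for c in prof.preferred_cn)
        )
        g_term = 0.0 if geometry.best_polyhedron in prof.preferred_geometry else 1.0
        total = weights.distance * d_term + weights.cn * cn_term + weights.geometry * g_term
        terms.append(
            {
                "element": prof.element,
                "distance_term": d_term,
                "cn_term": cn_term,
                "geometry_term": g_term,
                "total": total,
            }
        )
    ranking = [t["element"] for t in sorted(terms, key=lambda t: (t["total"], t["element"]))]
    b_ratio = None
    flagged = False
    donor_bs = [d.b_factor for d in shell.donors]
    if shell.center_b_factor is not None and donor_bs and np.mean(donor_bs) > 0:
        b_ratio = float(shell.center_b_factor / np.mean(donor_bs))
        flagged = b_ratio > weights.b_ratio_flag
    return IdentityScore(
        terms=terms, ranking=ranking, b_ratio=b_ratio,
        lighter_ion_suspected=flagged, geometry=geometry,
    )


def locate_interface_site(
    model: StructureModel,
    ligand_selectors: list[str],
    residue_selectors: list[str],
) -> InterfaceSite:
    """Screen the intra-dimer interface for a candidate cation position.

    The candidate center is the centroid of the named donor oxygens
    (γ-phosphate oxygens of the two nucleotides plus the carboxylate
    oxygens of the two interface glutamates).  Selectors that do not
    resolve — e.g. a mutated-away carboxylate — are reported as missing
    rather than silently dropped.  This is a screening aid, not a
    refinement.
    """
    positions: dict[str, np.ndarray] = {}
    missing: list[str] = []
    for sel in list(ligand_selectors) + list(residue_selectors):
        try:
            positions[sel] = resolve_selector(model, sel).position
        except UsageError:
            missing.append(sel)
    if not positions:
        raise UsageError("no interface selectors could be resolved")
    center = np.mean(list(positions.values()), axis=0)
    dists = {sel: float(np.linalg.norm(p - center)) for sel, p in positions.items()}
    return InterfaceSite(center=center, donor_distances=dists, missing=missing)
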