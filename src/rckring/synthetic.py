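"""Seeded generators emulating every input the analysis stages consume.

Each generator is deterministic given its arguments and seed (one
`numpy` Generator per call, never global state) and produces an object the
corresponding stage accepts directly: octameric rings with prescribed
diagonal distances, metal-site fragments with prescribed coordination,
ortholog-style alignments with prescribed column composition, ACMA-assay
quench traces (baseline / CCCP-triggered exponential decay / valinomycin
floor) and Hill-shaped titrations.

These are geometric/statistical stand-ins, not physically realistic
proteins: a subunit is a five-atom Cα stub (residues 34–38), which is the
minimum every consumer needs.
"""

from __future__ import annotations

import numpy as np

from .errors import UsageError
from .kinetics import FluxTrace, TitrationSeries, hill_equation
from .metal import IDEAL_POLYHEDRA
from .motifs import Alignment
from .structure import AtomRecord, Chain, Residue, RingModel, StructureModel, build_ring

#: Mg titration design: 0–2000 µM activator, as in the magnesium flux titration.
MG_GRID_UM = np.array([0.0, 25.0, 50.0, 100.0, 150.0, 250.0, 400.0, 700.0, 1200.0, 2000.0])
#: Choline titration design: 0–150 mM.
CHOLINE_GRID_MM = np.array([0.0, 2.0, 5.0, 10.0, 20.0, 40.0, 80.0, 150.0])

_CHAIN_IDS = "ABCDEFGH"
_AA20 = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# Rings


def make_ring(
    L1: float,
    L2: float,
    n_subunits: int = 8,
    dimer_D36: list[float] | None = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> RingModel:
    """Octameric ring whose (i, i+4) marker diagonals realize L1/L2 exactly.

    Marker (residue 38) Cα atoms sit on two interleaved diagonal pairs:
    even subunits at radius L1/2, odd subunits at L2/2, 45° apart, so the
    four cross-ring diagonals are (L1, L2, L1, L2).  Subunit centroids are
    pulled pairwise together so consecutive subunits (0,1), (2,3), ... form
    the compact dimers; the residue-36 markers of each dimer are placed at
    the requested intra-dimer separation (default 10 Å each).  Gaussian
    positional noise of ``noise_sigma`` Å is applied per atom coordinate.
    """
    if not (L1 >= L2 > 0):
        raise UsageError(f"need L1 >= L2 > 0, got L1={L1}, L2={L2}")
    if n_subunits != 8:
        raise UsageError("only 8-subunit rings are supported")
    d36 = list(dimer_D36) if dimer_D36 is not None else [10.0] * 4
    if len(d36) != 4 or any(d <= 0 for d in d36):
        raise UsageError("dimer_D36 must be 4 positive distances")
    rng = np.random.default_rng(seed)
    R_cent = max(L1, 30.0)  # centroid radius, keeps subunits well separated

    def polar(radius, angle_deg, z=0.0):
        a = np.deg2rad(angle_deg)
        return np.array([radius * np.cos(a), radius * np.sin(a), z])

    chains: list[Chain] = []
    for i in range(8):
        theta = 45.0 * i
        marker38 = polar(L1 / 2 if i % 2 == 0 else L2 / 2, theta)
        # pull dimer partners (2j, 2j+1) angularly together
        psi = theta + (10.0 if i % 2 == 0 else -10.0)
        cent = polar(R_cent, psi)
        j = i // 2
        mid_angle = 45.0 * (2 * j) + 22.5
        mid = polar(R_cent - 6.0, mid_angle)
        tangent = np.array([-np.sin(np.deg2rad(mid_angle)), np.cos(np.deg2rad(mid_angle)), 0.0])
        sign = -1.0 if i % 2 == 0 else 1.0
        marker36 = mid + sign * (d36[j] / 2) * tangent

        positions = {
            34: cent + np.array([0.0, 0.0, 3.0]),
            35: cent + np.array([0.0, 0.0, -3.0]),
            36: marker36,
            37: cent + np.array([1.5, 0.0, 0.0]),
            38: marker38,
        }
        names = {34: "ALA", 35: "ALA", 36: "ASP", 37: "ALA", 38: "ASN"}
        cid = _CHAIN_IDS[i]
        chain = Chain(chain_id=cid)
        for num, pos in positions.items():
            if noise_sigma > 0:
                pos = pos + rng.normal(0.0, noise_sigma, 3)
            res = Residue(number=num, name=names[num])
            res.atoms["CA"] = AtomRecord(
                atom_name="CA", element="C", residue_number=num, residue_name=names[num],
                chain_id=cid, position=pos, b_factor=30.0, occupancy=1.0,
            )
            chain.residues.append(res)
        chains.append(chain)
    model = StructureModel(chains=chains, header={"id": f"synthetic-ring-L1_{L1}-L2_{L2}"})
    return build_ring(model)


def make_dimer(hinge_separation: float = 10.0, seed: int = 0) -> StructureModel:
    """Mirror-symmetric two-subunit fragment for hinge-angle conventions."""
    ring = make_ring(30.0, 30.0, dimer_D36=[hinge_separation] * 4, seed=seed)
    sub = ring.subunits[:2]
    return StructureModel(chains=list(sub), header={"id": "synthetic-dimer"})


# ---------------------------------------------------------------------------
# Metal-site fragments


def make_metal_fragment(
    ion: str = "MG",
    cn: int = 6,
    distance: float = 2.07,
    geometry: str = "octahedral",
    jitter_dist: float = 0.0,
    jitter_ang: float = 0.0,
    b_center: float = 50.0,
    b_donors: float = 50.0,
    seed: int = 0,
) -> StructureModel:
    """Metal atom at the origin with donor oxygens at ideal polyhedron vertices.

    ``jitter_dist`` is a Gaussian σ (Å) on each donor distance and
    ``jitter_ang`` a Gaussian σ (degrees) on each donor direction (applied
    as tangent-plane noise calibrated so the RMS angular deviation equals
    the requested σ).  Donors are water oxygens in their own residues so
    shell detection sees them as non-bonded.
    """
    if geometry not in IDEAL_POLYHEDRA:
        raise UsageError(f"unknown geometry {geometry!r}")
    verts = IDEAL_POLYHEDRA[geometry]
    if verts.shape[0] != cn:
        raise UsageError(f"geometry {geometry} has {verts.shape[0]} vertices, not CN {cn}")
    rng = np.random.default_rng(seed)
    ion = ion.upper()
    element = ion.capitalize()

    metal_chain = Chain(chain_id="M")
    res_m = Residue(number=1, name=ion)
    res_m.atoms[ion] = AtomRecord(
        atom_name=ion, element=element, residue_number=1, residue_name=ion,
        chain_id="M", position=np.zeros(3), b_factor=b_center, occupancy=1.0, is_hetero=True,
    )
    metal_chain.residues.append(res_m)

    donor_chain = Chain(chain_id="W")
    sigma_t = np.deg2rad(jitter_ang) / np.sqrt(2.0)
    for k, v in enumerate(verts):
        direction = v.copy()
        if jitter_ang > 0:
            # tangent-plane Gaussian noise, renormalized
            t1 = np.cross(direction, [0.0, 0.0, 1.0])
            if np.linalg.norm(t1) < 1e-8:
                t1 = np.cross(direction, [1.0, 0.0, 0.0])
            t1 /= np.linalg.norm(t1)
            t2 = np.cross(direction, t1)
            direction = direction + rng.normal(0, sigma_t) * t1 + rng.normal(0, sigma_t) * t2
            direction /= np.linalg.norm(direction)
        r = distance + (rng.normal(0.0, jitter_dist) if jitter_dist > 0 else 0.0)
        res = Residue(number=101 + k, name="HOH")
        res.atoms["O"] = AtomRecord(
            atom_name="O", element="O", residue_number=101 + k, residue_name="HOH",
            chain_id="W", position=r * direction, b_factor=b_donors, occupancy=1.0,
            is_hetero=True,
        )
        donor_chain.residues.append(res)
    return StructureModel(
        chains=[metal_chain, donor_chain],
        header={"id": f"synthetic-{ion.lower()}-site-{geometry}"},
    )


# ---------------------------------------------------------------------------
# Alignments


def _apportion(freqs: dict[str, float], n: int) -> dict[str, int]:
    """Largest-remainder apportionment of column frequencies to exact counts."""
    raw = {r: f * n for r, f in freqs.items()}
    counts = {r: int(np.floor(v)) for r, v in raw.items()}
    short = n - sum(counts.values())
    order = sorted(raw, key=lambda r: (-(raw[r] - counts[r]), r))
    for r in order[:short]:
        counts[r] += 1
    return counts


def make_alignment(
    n_rows: int,
    length: int,
    column_spec: dict[int, dict[str, float]] | None = None,
    embed_nbs_motif: bool = False,
    motif_start: int = 1,
    exact_counts: bool = False,
    seed: int = 0,
) -> Alignment:
    """Alignment with per-column categorical composition (1-based columns).

    Unspecified columns are uniform over the 20 amino acids.  In exact-counts
    mode a column's residues are apportioned to rows deterministically
    (largest remainder, rows in order), so printed-count fixtures such as
    13 glutamates out of 15 are reproduced exactly.  With
    ``embed_nbs_motif`` the glycine-box pattern G-x-G-x-x-G-x{17}-E is
    written into every row starting at ``motif_start``.
    """
    if n_rows < 1 or length < 1:
        raise UsageError("n_rows and length must be positive")
    column_spec = column_spec or {}
    for col, freqs in column_spec.items():
        if not 1 <= col <= length:
            raise UsageError(f"column {col} outside 1..{length}")
        total = sum(freqs.values())
        if abs(total - 1.0) > 1e-6:
            raise UsageError(f"column {col}: frequencies sum to {total}, not 1")
    rng = np.random.default_rng(seed)
    rows = [list(rng.choice(list(_AA20), size=length)) for _ in range(n_rows)]
    for col, freqs in column_spec.items():
        residues = sorted(freqs)
        if exact_counts:
            counts = _apportion(freqs, n_rows)
            fill = [r for r in residues for _ in range(counts[r])]
        else:
            fill = list(rng.choice(residues, size=n_rows, p=[freqs[r] for r in residues]))
        for i in range(n_rows):
            rows[i][col - 1] = fill[i]
    if embed_nbs_motif:
        s = motif_start - 1
        if s < 0 or s + 24 > length:
            raise UsageError("motif does not fit at the requested start")
        for row in rows:
            row[s], row[s + 2], row[s + 5] = "G", "G", "G"
            # keep spacer free of accidental glycine-box starts
            row[s + 23] = "E"
    return Alignment(rows=[(f"seq{i + 1:02d}", "".join(r)) for i, r in enumerate(rows)])


def make_e125_column_alignment(seed: int = 0) -> tuple[Alignment, int]:
    """Fifteen-ortholog-style alignment with 13 E / 1 Q / 1 K at one column.

    Mirrors the conservation count at the interface-glutamate column of the
    KtrA ortholog set (13 of 15 -> 87%).  Returns (alignment, column).
    """
    column = 125
    aln = make_alignment(
        n_rows=15,
        length=150,
        column_spec={column: {"E": 13 / 15, "Q": 1 / 15, "K": 1 / 15}},
        exact_counts=True,
        seed=seed,
    )
    return aln, column


# ---------------------------------------------------------------------------
# Flux traces and titrations


def make_flux_trace(
    k_fast: float,
    k_slow: float | None = None,
    amp_fast: float = 1.0,
    floor: float = 0.0,
    noise_sigma: float = 0.0,
    baseline: float = 100.0,
    decay: float = 400.0,
    valinomycin_tail: float = 0.0,
    dt: float = 2.0,
    raw_scale: float = 1.0,
    raw_offset: float = 0.0,
    seed: int = 0,
) -> FluxTrace:
    """Assay-schedule quench trace: NF = 1 during the baseline, then
    floor + Σ A·exp(-k (t - t_CCCP)) with amplitudes summing to 1 - floor,
    plus an optional fast valinomycin tail decaying to 0.  Additive Gaussian
    noise acts on NF; the returned trace is raw_scale·NF + raw_offset.
    """
    if k_fast <= 0 or (k_slow is not None and k_slow <= 0):
        raise UsageError("rate constants must be positive")
    if not 0.0 <= amp_fast <= 1.0:
        raise UsageError("amp_fast must be a fraction in [0, 1]")
    if baseline <= 0 or decay <= 0 or dt <= 0:
        raise UsageError("invalid schedule: baseline, decay and dt must be positive")
    rng = np.random.default_rng(seed)
    total = baseline + decay + valinomycin_tail
    t = np.arange(0.0, total + dt / 2, dt)
    x0 = baseline
    nf = np.ones_like(t)
    post = t > x0
    amp_total = 1.0 - floor
    if k_slow is None:
        decay_part = amp_total * np.exp(-k_fast * (t[post] - x0))
    else:
        decay_part = amp_total * (
            amp_fast * np.exp(-k_fast * (t[post] - x0))
            + (1.0 - amp_fast) * np.exp(-k_slow * (t[post] - x0))
        )
    nf[post] = floor + decay_part
    val_time = None
    if valinomycin_tail > 0:
        val_time = baseline + decay
        tail = t >= val_time
        nf_at_val = float(np.interp(val_time, t, nf))
        nf[tail] = nf_at_val * np.exp(-0.2 * (t[tail] - val_time))
    if noise_sigma > 0:
        nf = nf + rng.normal(0.0, noise_sigma, nf.shape)
    f = raw_scale * nf + raw_offset
    return FluxTrace(
        time=t, fluorescence=f, cccp_time=x0, valinomycin_time=val_time,
        sampling_interval=dt, normalized=(raw_scale == 1.0 and raw_offset == 0.0),
    )


def make_titration(
    k_half: float,
    n_hill: float,
    start: float,
    end: float,
    conc_grid: np.ndarray,
    unit: str = "uM",
    replicate_noise_sigma: float = 0.05,
    n_replicates: int = 3,
    seed: int = 0,
) -> list[TitrationSeries]:
    """Replicate titration series from the Hill equation with multiplicative
    Gaussian rate noise, one :class:`TitrationSeries` per replicate."""
    conc = np.asarray(conc_grid, dtype=float)
    if conc.size == 0 or np.any(conc < 0):
        raise UsageError("concentration grid must be nonempty and nonnegative")
    if k_half <= 0 or n_hill <= 0:
        raise UsageError("k_half and n_hill must be positive")
    rng = np.random.default_rng(seed)
    ideal = hill_equation(conc, start, end, k_half, n_hill)
    out = []
    for _ in range(max(1, n_replicates)):
        noisy = ideal * (1.0 + rng.normal(0.0, replicate_noise_sigma, ideal.shape))
        out.append(TitrationSeries(concentrations=conc.copy(), rates=noisy, unit=unit))
    return out
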