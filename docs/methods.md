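# Methods

This note documents the models, conventions and numerical choices behind
`rckring`, in the order of the pipeline stages.

## Ring model and conformational metrics

A ring is exactly eight protein chains. The ring axis is the normal of the
best-fit plane of the eight subunit centroids (eigenvector of the smallest
covariance eigenvalue; sign fixed deterministically against +z, then +x,
then +y). Subunits are ordered by increasing angle about this axis starting
from the lexicographically smallest chain id, so the ordering is unique up
to the cyclic/reflective symmetry that is physically unavoidable for a
ring. Asymmetric units holding fewer than eight protomers are expanded with
`apply_assembly` (file-encoded operators or an explicit crystallographic
4-fold); units holding two rings are split by single-linkage connected
components of centroid distance (default cutoff 60 Å) or an explicit chain
list. Altloc conformers keep the highest occupancy, ties resolved to 'A'.
Waters and hetero groups (ATP, ADP, Mg, Ca) are retained and addressable by
residue name — the metal-site stage requires them.

**L1/L2.** The four (i, i+4) diagonals between marker Cα atoms (residue 38
by default, author numbering) are partitioned into the two symmetry-related
pairs {0, 2} and {1, 3}; L1 is the mean of the pair with the larger mean,
L2 the other. If all four diagonals agree within 0.2 Å the ring is treated
as four-fold symmetric and L1 = L2 = overall mean. This convention yields
exact equality for rings generated by a crystallographic 4-fold and two
distinct values for two-fold rings, and is insensitive to which ring face
the markers are read from since all eight markers enter.

**Square threshold (2.0 Å on L1 − L2).** All published square rings have
zero asymmetry and all published non-square rings have asymmetry ≥ 4 Å, so
2 Å splits the populations with margin on both sides. It is a CLI flag.

**Dimer pairing.** Consecutive subunits in angular order form the four
dimers, anchored so that the pair with the smallest inter-centroid distance
starts a dimer — RCK dimers are the compact units of the ring. The D36–D36
distance is reported per dimer in ring order.

**Clustering.** Non-square conformations are grouped by agglomerative
complete-linkage clustering on Euclidean distance in (L1, L2) space. The
default cut is 3.8 Å: on the published values the largest within-group
spread is |(34, 30) − (37, 28)| = 3.61 Å and the smallest between-group
complete-linkage distance is |(40.7, 30.7) − (42, 27)| = 3.92 Å, so any cut
in (3.61, 3.92) recovers the four observed conformational groups and 3.8 Å
is the midpoint choice. The cutoff is exposed on the estimator and the CLI.

**Superposition.** RMSD uses the closed-form Kabsch solution (SVD of the
cross-covariance, reflection corrected to a proper rotation). Whole-ring
Cα RMSD matches atoms by (subunit position in ring order, author residue
number) and drops unmodelled residues pairwise. Collinear point sets are
rejected as degenerate.

**Hinge angle.** The text source defines the intra-dimer hinge only
pictorially, so the package ships a *documented convention*: the vertex is
the centroid of the interface marker Cα atoms (residue 36 of both
subunits) and the angle is measured between the vectors to each subunit's
Cα centroid, in [0°, 180°]. Reports flag the value as
convention-dependent; it is not claimed to reproduce any drawn figure.

## Metal-site characterization

A coordination shell is every O/N atom within 3.0 Å of the center,
excluding the center's own residue and anything closer than 0.8 Å (clash
guard). Oxygen dominates real shells; N is included because guanidinium
nitrogens can complete the shell in the wild-type ATP ring. Geometry is
assessed by matching the unit donor directions to ideal polyhedra of the
same CN (tetrahedron, square plane, trigonal bipyramid, octahedron,
pentagonal bipyramid) under the best vertex assignment and rotation; the
assignment is solved exactly by enumerating permutations with a batched
Kabsch per permutation (≤ 5040 permutations at CN 7, vectorized SVD).
Residuals above 20° — which cleanly separates noisy-ideal from scrambled
fixtures — are "irregular".

Ion identity is a declared score, not a refinement: for each candidate ion
profile, `total = w_d·|mean donor distance − ideal| + w_cn·dist(CN,
preferred set) + w_g·[geometry not preferred]` with default weights
(1.0 /Å, 0.5 /unit, 0.5 flat) and default profiles Mg²⁺ (2.07 Å, CN {6},
octahedral) and Ca²⁺ (2.39 Å, CN {6, 7, 8}, octahedral or pentagonal-
bipyramidal) — literature coordination standards kept as editable
configuration. Lower total ranks first. When B-factors are present the
center-B / mean-donor-B ratio is reported; above 1.2 the report flags that
a lighter ion than modelled may occupy the site (a too-heavy ion refines
with an inflated displacement parameter relative to its shell). The
interface-site locator is a screening aid only: the candidate center is
the centroid of the named γ-phosphate and carboxylate oxygens, with
unresolvable selectors (e.g. a mutated-away glutamate) reported as missing.

## Motif scanning and conservation

The nucleotide-binding motif `GxGxxG[17-18]xE/D` is read as the glycine box
followed by a spacer of 17 or 18 arbitrary residues and then E or D,
implemented as the regex `G.G..G(.{17,18}?)([ED])`: non-greedy, so the
shorter spacer is preferred on overlap, and `finditer` yields
non-overlapping matches leftmost-first. The spacer range is an option for
users who read the bracket differently. Conservation at a column counts
gaps in the composition but never toward the target set; percent identity
is rounded half away from zero (13/15 → 87%). The default target set is
{E} — widen to {E, D} via `--target-residues ED`. Context motifs report the
(column−1, column) residue pair per row, with gap-containing rows counted
separately. Kef-family sequences are split purely by length at 580
residues. Alignment *computation* is out of scope: alignments are inputs
(FASTA or Clustal via Biopython).

## Flux-assay kinetics

The generator and the fitters share the assay schedule: 2-s sampling,
100 s of baseline, CCCP addition at t = 100 s, 400 s of monitored decay,
optionally a valinomycin tail. Normalization anchors follow the assay
definitions — F_ini is the last baseline point before CCCP, the floor is
either the post-valinomycin minimum or the steady-state mean of the final
50 s (450–500 s) — and NF = (F − floor)/(F_ini − floor) is affine-invariant
in the raw signal. Fits are performed on normalized traces; rate constants
are invariant under the affine normalization, so this choice is
inconsequential and merely standardizes amplitudes.

Exponential fits use nonlinear least squares (lmfit/MINPACK) on points with
t ≥ x0, where x0 is the CCCP-addition time; the single point immediately
after x0 is excluded (mixing artefact). Initial guesses come from a
log-linear regression restricted to the informative early decay
(normalized residual > 0.1 — the tail is noise-dominated and would corrupt
the slope). τ is bounded positive. The two-phase model has a degenerate
local minimum with a vanishing fast phase, so fits are multi-started from
a deterministic grid of (τ_fast, τ_slow) spreads and the best SSE kept;
one-phase fits stop early only when the SSE clearly beats a flat model.
Model selection uses the small-sample-corrected information criterion
AICc = n·ln(SSE/n) + 2k + 2k(k+1)/(n−k−1); the two-phase model must win by
ΔAICc > 2, ties go to one phase — the operational reading of "simplest
model that explains the data". For two-phase fits the reported rate is
always 1/τ_fast with an explicit dominance flag (|A_fast| > |A_slow|), so
the exceptional non-dominant cases are data, not silent behaviour changes.

Hill fits bound K½ > 0 and n ∈ (0, 10], initialize Start/End at the
min/max rate and K½ at the mid-response concentration, and are unweighted
by default (inverse-variance weighting available when replicate SDs are
supplied). Concentrations carry explicit units (µM/mM); internal math is in
µM and K½ is reported in the series' unit. Replicate handling is
per-curve fits followed by mean ± SD across replicates; there is no global
fit.

## Synthetic data: what it emulates, and what it does not

Rings are five-atom Cα stubs (residues 34–38) per subunit placed so the
(i, i+4) marker diagonals realize L1/L2 exactly and the dimer D36 spacings
are honoured, with optional per-coordinate Gaussian noise. Metal fragments
put donor oxygens at ideal polyhedron vertices with Gaussian distance
jitter and tangent-plane angular jitter calibrated so the RMS angular
deviation equals the requested σ. Alignments draw per-column categorical
compositions (exact-counts mode apportions by largest remainder so printed
counts like 13/15 reproduce deterministically). Traces follow the assay
schedule with additive Gaussian noise on NF and an affine map to raw AU;
titrations apply multiplicative Gaussian noise to Hill-equation rates.
Every generator takes a seed and owns its random stream, so outputs are
bit-identical across runs.

These generators are statistical stand-ins, not physical models: there are
no side chains, no liposome-orientation mixtures, no H⁺ electro-diffusion,
and real deposited coordinates carry correlated errors the isotropic noise
model does not. Passing recovery tests therefore demonstrates correctness
of the *estimators* under the stated noise models — it does not certify
rates or distances re-derived from real traces or maps.

## Problem sizes used in the recovery experiments

Rate-constant recovery uses 200 replicate traces per rate (≈ 250 points
each); Hill recovery uses 3 replicate titrations of 10 (µM grid) or 8 (mM
grid) concentrations with 5% multiplicative noise; ion-identity ranking
uses 500 jittered shells per ion (σ_dist = 0.05 Å, σ_ang = 5°); motif-scan
validation uses 1000 random length-300 sequences. These sizes give
comfortably stable statistics for the tolerances tested while keeping the
default suite fast.

## Known limitations

* The hinge angle is a convention, not a reproduction of any published
  per-structure value.
* Identity scoring ranks candidate ions heuristically with declared
  weights; it is not an occupancy/B refinement and does not evaluate
  electron density or anomalous signal.
* Which deposited chains constitute "the" biological ring is entry-specific
  knowledge; the CLI accepts explicit chain lists and assembly operators
  rather than guessing beyond the documented defaults.
* The percent-identity breakdowns of specific ortholog sets (e.g. the
  RE/TE vs PE context split) depend on the exact sequence selection and are
  exercised here only through synthetic alignments.
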