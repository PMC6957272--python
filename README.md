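# rckring

Analysis toolkit for nucleotide-dependent RCK-domain octameric rings —
conformational metrics, divalent-cation site characterization, binding-motif
conservation, and liposome flux-assay kinetics.

RCK ("regulator of conductance of K⁺") domains gate bacterial potassium
channels and transporters such as *B. subtilis* KtrAB, where the cytosolic
KtrA protein forms an octameric ring of four dimers. ATP binding drives the
ring into a four-fold-symmetric **square** (active) conformation; ADP-bound
rings relax into two-fold **non-square** (inactive) states. Activation
additionally requires a cation cofactor — Mg²⁺ (or Ca²⁺) chelated at the
intra-dimer interface by a conserved glutamate (E125) and the γ-phosphates
of the two bound ATP molecules. `rckring` packages the computational side of
this analysis for structural biologists and channel biophysicists:

* **Ring conformation** — the ring state is summarized by the cross-ring
  diagonals L1 and L2 between Cα atoms of residue N38 in opposite subunits
  (square ⇔ L1 ≈ L2; e.g. 30.0/30.0 Å for the ATP state vs 40.7/30.7 Å for
  ADP), the intra-dimer D36–D36 Cα distances, whole-ring Cα RMSD after
  Kabsch superposition, and complete-linkage clustering of (L1, L2)
  conformations.
* **Metal site** — coordination-shell detection around a cation center,
  matching of donor directions to ideal polyhedra (octahedral for Mg²⁺,
  pentagonal-bipyramidal for CN-7 Ca²⁺), and a declared, configurable
  ion-identity score using donor distances (Mg–O 2.07 Å, Ca–O 2.39 Å),
  coordination number, geometry, and the center-to-shell B-factor ratio.
* **Motif & conservation** — scanning for the Rossmann nucleotide-binding
  motif `GxGxxG[17-18]xE/D`, alignment-column conservation at the
  E125-equivalent position, two-residue context motifs (PE/RE/TE/GE), and
  the 580-residue KefC vs KefC-like length split.
* **Flux kinetics** — ACMA quench traces are normalized to
  NF = (F − F_floor)/(F_ini − F_floor), fitted with one- or two-phase
  exponentials `y = y0 + Σ Aᵢ·exp(−(x − x0)/τᵢ)` (the first post-CCCP point
  is excluded; the simpler model is kept unless the corrected information
  criterion favours two phases by > 2), and the flux rate constant is
  k = 1/τ (fast component for biphasic fits, with a dominance flag).
  Titrations of k against activator concentration are fitted with the Hill
  equation `y = Start + (End − Start)·xⁿ/(K½ⁿ + xⁿ)`.
* **Synthetic data** — seeded generators for rings with prescribed
  diagonals, ideal/jittered metal sites, alignments with prescribed column
  composition, assay-schedule quench traces and Hill titrations, so every
  stage is testable offline.

The curve fitters are scikit-learn-style estimators
(`ExponentialDecayModel`, `HillModel`, `ConformationClusterer`) and compose
with sklearn tooling; `fit_exponential`, `fit_hill` and
`cluster_conformations` are thin functional wrappers.

## Worked example

```sh
$ rckring simulate-ring --l1 40.7 --l2 30.7 --out adp_ring.pdb
$ rckring ring-metrics adp_ring.pdb --out out
adp_ring        L1=40.70        L2=30.70        non-square
```

The ring's four (i, i+4) marker diagonals average to L1 = 40.7 Å and
L2 = 30.7 Å; the 10 Å asymmetry exceeds the 2 Å square threshold, so the
ring is called non-square (the ADP-like state).

```sh
$ rckring simulate-trace --k 0.096 --noise 0.01 --valinomycin-tail 100 \
    --raw-scale 700 --raw-offset 80 --seed 5 --out trace.csv
$ rckring flux-fit trace.csv --mode valinomycin --model auto
order=1 k=0.09514 s^-1  component=single
```

A quench trace generated at k = 0.096 s⁻¹ (the Mg²⁺-activated ATP-state
rate) with 0.01 NF noise is normalized against its valinomycin floor; model
selection keeps the one-phase fit and recovers k = 0.095 s⁻¹, i.e. within
about 1% of the generating rate.

```sh
$ rckring simulate-titration --k-half 155 --n-hill 1.8 --seed 2 --out titr.csv
$ rckring titrate titr.csv --unit uM
K1/2=145.4 uM   n=2.21
```

Three replicate titrations generated at (K½ = 155 µM, n = 1.8) with 5%
rate noise are pooled into one Hill fit: the half-activation concentration
comes back within ~6% and the cooperativity coefficient within the scatter
expected from three noisy replicates.

Every subcommand writes a JSON report (with the effective configuration and
library version embedded) plus a TSV twin into `--out`.

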