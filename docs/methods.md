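# Methods

This note documents the models, estimators, calibrations and numerical
choices behind aquabridge, and what the synthetic-data validation does
and does not demonstrate about real simulation data.

## Contact model

All contact criteria operate on heavy-atom geometry with inclusive
(`<=`) boundary comparisons, so results are deterministic and
reproducible to the byte.  Distances use the minimum-image convention
whenever the frame carries a periodic box (fractional-coordinate
rounding; exact for orthorhombic and mildly skewed triclinic boxes).

* **Hydrogen bond** — donor–acceptor heavy-atom distance ≤ 3.5 Å.  When
  the topology contains hydrogens, a donor's covalent hydrogens are
  located by a ≤ 1.25 Å search within the donor's residue, and the
  straightest D–H···A angle must additionally be ≥ 120°.  Without
  hydrogens (crystal structures, coarse synthetic scenes) the distance
  criterion alone applies.  These are common MD-analysis conventions,
  not universal constants; every report row carries the criteria used.
* **Salt bridge** — formal-cation heavy atom (Lys NZ, Arg NE/NH1/NH2,
  declared ligand cations) to formal-anion heavy atom (Asp OD1/OD2,
  Glu OE1/OE2, C-terminal OXT) ≤ 4.0 Å.
* **Water bridge** — order 1 only: a single water oxygen whose hydrogen
  bonds to ≥ 1 ligand atom and ≥ 1 pocket-residue atom are both
  satisfied in the same frame.  One record per (ligand atom, water
  residue, target atom) triple.  Chains of two or more waters are out
  of scope.
* **Hydrophobic contact** — minimal carbon–carbon distance between
  ligand and residue ≤ 4.5 Å.  Every carbon atom carries the
  hydrophobic role; aromatic stacking is *not* detected as a distinct
  geometry, so π–π partners appear only as hydrophobic contacts.

Polar roles of the twenty standard amino acids and water are built-in
lookup tables; roles of any other residue must be declared in the run
configuration and are never inferred — novel ligands are not in any
dictionary, and silent guessing would corrupt every downstream count.

### Per-frame classification

For a configured focal residue (default BW 2.50) and pocket residue set
(default BW 2.50, 3.35, 3.39, 7.45, 7.46 — the sodium-pocket polar
cluster), each frame receives exactly one category:

1. `DIRECT_INTERACTION` — ≥ 1 direct H-bond or salt bridge between
   ligand and the focal residue (water bridges may also be present);
2. `WATER_MEDIATED_ONLY` — no direct focal contact, but ≥ 1 water
   bridge from ligand to any pocket residue;
3. `NO_POLAR_CONTACT` — neither.

The categories are exhaustive and mutually exclusive by construction;
their counts sum to the number of analysed frames, and a DIRECT frame's
category is invariant to adding or removing waters (tested).

## Lifetime estimation

The presence indicator h(t) of an interaction feeds the intermittent
(history-independent) autocorrelation

    C(t) = ⟨h(s) h(s+t)⟩_s / ⟨h(s)²⟩_s ,

with both averages over the same valid origins s ∈ [0, n−t).  This
windowed normalisation keeps the finite-sample estimate within [0, 1]
for binary h and pins C(0) = 1 exactly; a full-series denominator can
exceed 1 when events cluster late in a series.  The lag grid equals the
frame spacing; the maximum lag is half the series duration (longer lags
have too few origins).

The intermittent definition (rather than continuous/first-passage
lifetimes) is deliberate: water bridges break and reform constantly as
bridging waters exchange with bulk, and correlation times comparable to
the trajectory length are only meaningful if reformation counts.  The
water-mediated indicator is identity-agnostic for the same reason, and
equals the logical OR of per-water indicators (tested).

**Plateau.**  Both τ estimators first remove a plateau C∞.  The default
is the indicator's mean occupancy — the exact stationary plateau of
this estimator for a binary process, since ⟨h(0)h(∞)⟩/⟨h²⟩ = ⟨h⟩²/⟨h⟩ =
⟨h⟩.  A tail-window mean (last 10 % of lags) is available as a config
option but is markedly noisier on single replicas: the long-lag part of
an ACF estimated from ~10²ρ events wanders by ±0.1, and any plateau
error is amplified by the integration length.

**Integral estimator.**  τ = trapezoid integral of (C−C∞)/(1−C∞),
truncated at the first zero crossing of the corrected curve or at the
self-consistent window t ≥ 6·τ (Sokal-style), whichever comes first.
Beyond the decay the integrand is pure noise whose contribution grows
linearly with the upper limit; truncation is what makes the estimator
usable at realistic series lengths.  On a noiseless exp(−t/5 ns) curve
sampled at 0.1 ns over 0–50 ns the recovered τ is 4.988 ns (−0.24 %).

**Exponential fit.**  Least squares of C(t) = C∞ + (1−C∞)exp(−t/τ) with
C∞ fixed at the plateau estimate, fitted over the adaptive window
[0, 10·τ₀] where τ₀ is the corrected curve's 1/e crossing.  Long lags
carry no decay information and would otherwise dominate the residual.

**Censoring.**  A curve that never decays below (1 − 0.02) is flagged
censored and τ is reported as the maximum usable lag — a lower bound,
never a point estimate.

**Aggregation.**  Replicas are the independent unit.  The package
reports per-replica τ values, their mean ± SEM (sample SD/√n; undefined
and reported as NaN for n = 1), and the τ of the replica-pooled C(t)
curve.  Pooling before estimation suppresses per-replica plateau wander
and is the preferred aggregate; with 8 replicas of 100 relaxation times
each, the pooled estimate recovers a known relaxation time to well
within 20 % (mean error ~8 % over many seeds), while individual-replica
estimates scatter several-fold more.

**Water exchange.**  Over frame-ordered bridge records: the number of
bridge-containing frames, the number of identity switches (successive
bridge frames whose bridging-water sets are disjoint), and the count of
distinct waters observed.  The switch fraction (switches per pair of
successive bridge frames) recovers a configured per-frame swap
probability when bridges are uninterrupted; across gaps the generator
draws a fresh water, as a new bridge would in solution.

## Statistics

Category fractions are reported per replica (each triple sums to 1) and
pooled frame-weighted over replicas; whether one averages replicas or
pools frames changes the numbers whenever replica lengths differ, so
both are always emitted and labelled.  Conditional contact distances
average per replica over the frames where the contact exists; replicas
with no qualifying frames are excluded and listed.  Between-ligand
comparisons use Welch's unequal-variance two-sample t-test on
per-replica summaries (fractions, τ, mean distances), two-sided.  No
multiple-testing correction is applied by default — the planned
comparison table is small — with Holm adjustment available in config.

## Static-structure geometry

Superposition is the Kabsch SVD solution with determinant correction
(proper rotation, det = +1, verified to 1e-6), RMSD computed over the
selection after transform; it is cross-checked in the tests against an
independent quaternion-free implementation
(`scipy.spatial.transform.Rotation.align_vectors`).  Residue
displacements (Cα, heavy-sidechain centroid, or max shared sidechain
atom) assume the caller has already superposed the models on a stated
reference selection; when measuring a moving element (e.g. the
intracellular end of TM6) the alignment selection should exclude it,
else the moving part biases the frame.  Measurements are always
reported together with the atom specs that produced them, because
"the" TM6 displacement depends on that choice.

## Linker design

The reach model is pure arithmetic: `reach(n) = anchor_offset + n ×
per_methylene`.  Defaults (shipped in `defaults.yaml`, not in code):
`per_methylene = 1.25 Å` — the per-carbon axial projection of an
extended all-anti chain; `anchor_offset = 4.3 Å` — the anchor-nitrogen
bond into the chain plus the reach of a guanidinium-class warhead to
its salt-bridge partner; `tolerance = 0.7 Å`.  The offset and tolerance
were calibrated once against the known outcome that an 11.2 Å
amine-to-carboxylate distance selects 5- and 6-carbon linkers, and are
deliberately configuration values: a different warhead chemistry needs
a different offset.  No conformational modelling of the linker is
attempted.

The worked design measurement ships with a **synthetic stand-in**
structure (`synthetic_4n6h_pocket`): a minimal pocket model whose
NTI-like tertiary amine sits exactly 11.2 Å (the published
inactive-state value) from the nearest D95 carboxylate oxygen.  It
exercises BW resolution, atom-spec parsing and group-minimum distances,
but it carries no experimental coordinates — measurements on it
validate the machinery, not the crystallography.

## Synthetic data: what it shows and what it does not

The generator emits a rigid ~17-atom scene — focal aspartate, pocket
serine, a valine for hydrophobic profiling, a 3-atom ligand warhead,
five single-oxygen waters — with three placements (bound at 3.0 Å,
bridged at 2×2.8 Å legs, free at 12 Å) driven by an exactly-discretised
two-state Markov chain, plus configurable bridge insertion and
bridging-water identity swaps.  Per-atom jitter (±0.1 Å uniform) is
bounded so placements never cross cutoffs spuriously
(`SceneLayout.validate` enforces the margins).  Replica r draws from
`default_rng(base_seed + r)`; identical parameters give byte-identical
outputs.

Passing the recovery tests therefore demonstrates that the detectors,
classifier, estimators and report plumbing are correct and unbiased
under known ground truth.  It does **not** demonstrate robustness to
force-field physics the scene lacks: no realistic water geometry or
hydrogens (the hydrogen/angle code path is exercised by constructed
cases and randomized oracle frames instead), no multi-exponential
kinetics, no conformational coupling between contacts, no wrapped or
triclinic production boxes.  Applying the pipeline to real trajectories
leaves the choice of cutoffs, stride and frame interval to the user's
config, and those choices move contact percentages by several points.

## Problem sizes and defaults

Default study conditions used throughout tests and the acceptance
script: 8 replicas, 0.1 ns frame interval; 5 000 frames/replica for
lifetime recovery (500 ns ≈ 100 relaxation times of the τ = 5 ns
reference chain); 2 000 frames/replica for the 84/14/2 category-mixture
study (16 000 frames; with per-frame autocorrelation e⁻¹, the effective
sample is ~7 000, giving ~0.4 percentage-point binomial SD on the
direct fraction); 500 always-bridged frames for water-swap recovery;
1 000 random ≤ 50-atom frames for detector–oracle equivalence.  These
sizes make every stage a desk-scale computation while keeping the
statistical targets (20 % on τ, ~4–5σ bands on fractions) meaningful.

## Known limitations

* Order-2+ water bridges, π-stacking geometry, and per-atom energy
  decomposition are out of scope by design.
* The minimum-image reduction is exact only for orthorhombic (and
  near-orthorhombic) boxes; heavily skewed triclinic boxes would need
  pre-wrapping.
* Trajectory time stamps are not trusted (DCD headers are unit-
  ambiguous); the frame interval is always taken from configuration.
* Censored correlation times are lower bounds, and τ of order the
  trajectory length cannot be distinguished from non-decay.
* The Welch test on ≤ 8 replicas has limited power; "not significant"
  on such n is weak evidence of equality.
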