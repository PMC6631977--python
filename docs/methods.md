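# Methods

This note documents the models and procedures implemented in `nirdx`, the
parameter choices that matter, what the synthetic-data generator does and
does not emulate, and the package's known limitations.

## Problem setting

A tissue section's NIR transflectance spectrum (12,000–4,000 cm⁻¹) is an
overlapping sum of X–H overtone and combination bands. The BRAF V600E
mutation swaps a valine side chain ((CH₃)₂CH–) for glutamic acid's
–(CH₂)₂COOH, shifting intensity between CH₃-, CH₂- and COOH-associated
bands. Individual bands are not resolvable, so classification proceeds by
chemometrics: preprocess, compress to PCA scores, and classify with a
counter-propagation ANN. Each sample is measured at three tissue locations
(the mutation can be spatially heterogeneous), and the per-sample call
aggregates the three per-spectrum predictions.

## Preprocessing

Strategies are ordered operator compositions written `"SNV+NDS(5,5)+FD+MC"`.
Semantics that matter:

* **Calibration state.** Only two operators carry state fitted on the
  calibration set: MC (per-variable means) and MSC (the reference = the
  calibration mean spectrum *at that point in the chain*). Validation and
  test spectra are transformed with the stored state, never refit — the test
  suite asserts this leakage guard directly.
* **Order.** Operators apply left to right; MC, when present, is always the
  final step. Composition order is significant (e.g. `SGS+FD+MC` smooths
  then differentiates).
* **Conventions.** SNV uses the sample (n−1) standard deviation. FD/SD are
  finite differences on the point index (central, with one-sided endpoint
  handling). The Norris derivative is a centered moving average over
  `segment` points followed by a gap difference; order 1 is the forward
  difference `s[i+gap] − s[i]`, chosen so that segment 1 / gap 1 reduces to
  the plain first difference. Savitzky–Golay uses polynomial edge handling
  (`scipy.signal.savgol_filter`, mode `interp`).
* **Defaults.** SGS window 11, polyorder 3; NDS segment 5, gap 5. Commercial
  packages do not publish their kernels, so these are explicit, configurable
  stand-ins, recorded in every run's provenance.
* **Where preprocessing happens.** The strategy is fitted and applied on the
  full shared grid and the modeling subranges are extracted afterwards.
  Rationale: the derivative and smoothing filters require a uniformly spaced
  axis, which the concatenation of two disjoint subranges is not; MC
  commutes with extraction, so for the winning strategy the order is
  immaterial.

## PCA feature selection

PCA is a mean-centered SVD of the preprocessed calibration matrix only.
Explained-variance ratios are computed against the total centered variance.
The score dimensionality is the smallest k whose cumulative ratio reaches
**85.0%** (read inclusively, ≥); if 20 components cannot reach the
threshold the model is flagged **NA** and downstream classification refuses
to run, mirroring how scatter- and derivative-heavy strategies can wash the
signal into many small components. Both threshold and cap are configurable.
Loading signs are fixed (largest-magnitude element positive) for
reproducibility.

## Counter-propagation ANN

A square, non-toroidal S×S Kohonen layer (weights `w_j ∈ R^d` on the PCA
scores) coupled to an output layer (`u_j ∈ R^C`, class weights). Training,
per epoch and per input in seed-controlled shuffled order:

1. winner `c = argmin_j ‖w_j − x‖²`, ties broken toward the lowest
   (row, col) in lexicographic order;
2. both layers update for all neurons within the current radius `r`:
   `w_j += η·h·(x − w_j)`, `u_j += η·h·(y − u_j)`, with triangular
   neighborhood `h = max(0, (r + 1 − d_jc)/(r + 1))` on the Chebyshev
   topological distance `d_jc`;
3. `η` decays linearly from 0.5 to 0.01 over epochs (default 100); `r`
   shrinks linearly from S/2 to 0.

Kohonen weights initialize uniformly within the per-dimension score range
(drawn in [0,1] at `init_map`, rescaled when training starts); output
weights start at 1/C. Because every update is a convex combination, output
weights remain in [0,1] and sum to 1 per neuron — asserted in tests.
Prediction assigns the argmax class of the winning neuron's output weights
(ties toward the lower class index, i.e. mutant). Everything is a
deterministic function of (seed, data, config).

Map sizes 10, 12 and 15 per side are the candidate structures; 12×12 is the
default. Cross-validation (CACV) is 5-fold, grouped by sample (all three
replicate spectra share a fold — per-spectrum CV would leak replicates) and
stratified by class. The fold scheme for the original clinical work is not
recoverable, so grouped stratified k-fold is this package's documented
choice.

## Model selection and diagnosis

The grid runs every strategy × subrange × map-side combination under one
shared seed. Ranking is lexicographic on (CAV, CAC) descending — validation
accuracy is the generalization claim — with ties broken by higher CACV,
then smaller map, then fewer components; NA rows are excluded.

Sample diagnosis uses the OR rule with mutant as the positive class: wild
type only if all three replicate predictions are wild type. The rule can
only convert samples toward "mutant", so sample-level sensitivity dominates
per-spectrum sensitivity and specificity is traded away — the right bias
for a screening assay, and a property the tests assert. Metrics are
sensitivity TP/(TP+FN), specificity TN/(TN+FP), accuracy (TP+TN)/total;
display values round half-up to one decimal, full precision is kept
internally.

## Synthetic data generator

Real clinical spectra for this task are not publicly deposited, so the
generator produces datasets with the statistical structure the pipeline
assumes (defaults frozen in `SyntheticConfig`):

* grid 12,000→4,000 cm⁻¹ at 4 cm⁻¹ (2001 points), a plausible digitization
  of 8 cm⁻¹ instrument resolution;
* 52 samples per class (40 calibration + 12 validation, the 30% validation
  proportion), 3 replicate spectra each, mutant/wild-type alternating in
  storage order;
* spectra = smooth polynomial baseline + Gaussian bands (σ ≈ 35–60 cm⁻¹,
  broad NIR overtones) at the diagnostic C–H/O–H positions (8480, 8163,
  7355, 7263, 7186, 7080, 6944, 5905, 5872, 5680, 5600, 4520, 4395,
  4250 cm⁻¹);
* class effect: mutant raises CH₂/COOH-associated amplitudes and lowers
  CH₃-associated ones. No published quantification of this difference
  exists, so the delta magnitudes (±0.014–0.049 AU on base amplitudes of
  0.05–0.12 AU) are free parameters of the generator; they were calibrated
  once so the default pipeline reproduces the intended headline performance
  band, then frozen;
* nuisance structure per replicate: relative band-amplitude jitter (sd 0.10,
  replicate heterogeneity of the mutation), multiplicative/additive scatter
  a·x+b (a ~ N(1, 0.05), b ~ N(0, 0.02)), white noise (sd 0.01 AU), plus a
  per-sample relative amplitude draw (sd 0.05) for between-sample biology;
* a fixed additive interference profile per preparation class: paraffin
  (CH₂ alkane bands, moderate) or hematoxylin–eosin (broad offset + dye
  bands, stronger).

What it deliberately does **not** emulate: Beer–Lambert/radiative-transfer
tissue physics, absolute absorbance levels, wavelength-dependent noise,
instrument drift, water bands, or batch effects. Consequences worth knowing:

* The interference profile is identical across spectra (varied only through
  the scatter transform), so mean centering removes most of it; on real
  data interference varies per section and degrades stained samples more.
* After MC the synthetic variance concentrates in 2 components (scatter,
  offset + class direction), so the variance rule selects ~2 PCs where
  clinical data yielded ~6; and scatter-correcting or derivative strategies
  (MSC/SNV/FD/SD) strip so much structured variance that the 85% rule
  becomes unreachable at the 20-PC cap — the grid then shows NA rows where
  the clinical grid had valid (if weaker) models. The qualitative ordering
  (plain MC wins) is preserved; the full Table-style grid is not
  numerically reproducible from synthetic data.
* Passing tests demonstrate the pipeline's correctness and its behavior
  under the generator's assumptions, not clinical performance.

The class-separability of the defaults is also a step function of effect
size: below the level where the class direction enters the selected PCs the
pipeline is at chance, above it near-perfect. The monotonicity test
therefore compares mean validation accuracies with a 3-point sampling
allowance, since both low-effect levels sit at chance.

## Numerical and testing choices

* Degenerate inputs raise typed errors rather than returning NaNs (constant
  spectrum in SNV, |slope| < 1e−12 in MSC, zero-variance PCA input, NA PCA
  model in `project`).
* Problem sizes: the test suite runs the full-size default dataset
  (240 + 72 spectra, 2001 points) for end-to-end checks — one pipeline fit
  takes well under a second — and reduced sizes (tiny grids, 4-neuron maps,
  5–30 epochs) for unit and property tests. The null-control check pools 20
  seeds; its binomial band is computed on the number of independent
  samples, not spectra, because replicates are correlated.
* Reproduction script: `scripts/acceptance.py` reruns the frozen default
  pipeline for five consecutive seeds and reports across-seed medians of
  calibration sensitivity, CAC, CAV and calibration specificity.

## Known limitations

* JCAMP-DX support covers single-block AFFN `(X++(Y..Y))` tables only (no
  compressed DIFDUP forms, no multi-block files).
* The CP-ANN is the classic variant: no toroidal topology, batch-SOM, or
  XY-fused supervised SOM variants.
* CACV's fold scheme and the commercial software's exact derivative kernels
  are reconstructions by documented convention, not reverse engineering.
* Model archives (`.npz`) are runtime artifacts, not a long-term
  interchange format.
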