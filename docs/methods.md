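# Methods

## The measurement model

One e-nose breath measurement is a 3-way array of conductivity values with
modes *temperature step* (64), *measurement cycle* (36) and *sensor* (3).
The temperature program ramps the micro-hotplates from 260 °C to 340 °C in
32 evenly spaced steps and back down through the mirrored 32 steps; the
package fixes the ascending half to `linspace(260, 340, 32)` since only the
endpoints and the step count are physically specified. Conductivities are
strictly positive and carry arbitrary units — every downstream step is
invariant to the overall gain of a device, which is why per-device
multipliers are a nuisance parameter rather than signal.

## Preprocessing (scaling options)

Model selection searches over named scaling options:

| name | action | fitted on |
|---|---|---|
| `none` | identity | — |
| `baseline_ratio` | divide each sensor trace by that sensor's mean over cycle 0 | per measurement |
| `log_baseline_ratio` | natural log of the baseline ratio | per measurement |
| `per_sensor_zscore` | center/scale each sensor by training-set statistics | training fold |
| `per_measurement_minmax` | map the measurement's tensor to [0, 1] | per measurement |

`log_baseline_ratio` is the default: log-conductance ratios are the standard
transform for metal-oxide sensors (positive data, multiplicative noise,
device gain cancels exactly). `none` and `baseline_ratio` are idempotent
(applying the fitted option to its own output changes nothing);
`log_baseline_ratio` is not, because its output leaves the positive cone and
a second application is outside the transform's domain — callers apply each
option exactly once, and `apply_scaling` rejects non-positive inputs to the
log.

## Tucker3 compression

A measurement tensor is compressed by projecting onto orthonormal factor
matrices fitted per training fold: the training tensors are stacked along an
augmented sample mode and higher-order orthogonal iteration (HOOI,
initialized by truncated HOSVD) runs on the three measurement modes with the
sample mode untouched. Held-out tensors are projected onto the fitted
factors, so test data never influence the basis. The vectorized coefficient
core is the feature vector (default ranks (4, 3, 2) → 24 features, small
relative to cohort sizes of ~130).

Numerical choices: factor-sign convention makes each column's
largest-magnitude entry positive (reproducible across SVD backends);
convergence when the relative fit improvement drops below `tol = 1e-7`
(`max_iter = 200`, non-convergence flagged, model still returned);
reconstruction error is computed from the explicit residual rather than the
`‖X‖² − ‖G‖²` identity, which loses half the significant digits to
cancellation near an exact fit. Feature vectors are standardized per fold
(training mean/sd) before network training, since the leading Tucker
coefficient is an order of magnitude larger than the rest and would saturate
tanh units.

## Classifier networks and the judge ensemble

Candidate classifiers are single-hidden-layer tanh networks (hidden size
h ∈ {4, 8} by default) trained by deterministic full-batch gradient descent
on mean squared error against −1/+1 labels (learning rate 0.01, 2000 epochs,
no early stopping — a fixed epoch count keeps nested cross-validation exactly
reproducible). The tanh output makes 0.00 the natural decision threshold;
ties at the threshold classify as positive.

The ensemble ("judge") is a gating network plus two committees of three
networks. At inference the gate's output routes the sample: gate ≥ 0 → mean
of the positive committee's three outputs, otherwise the negative
committee's. Selection is by brute force: every pool member can be the gate;
committees are drawn from the top-m pool members (default m = 8) of the same
feature configuration ranked by individual inner-CV MCC; all
gate × C(m,3)² assemblies are scored by the mean per-inner-fold MCC of the
assembled judge's out-of-fold predictions, with ties broken toward the
lexicographically earliest provenance tag. Members may be reused between
gate and committees; the three members within one committee are distinct
(an `allow_reuse` switch relaxes this for very small pools). Candidate
out-of-fold predictions come from retraining each candidate configuration on
every inner-training split — the trained pool itself is fitted on the full
outer-training features and only supplies the final weights of the selected
assembly. The gated-inference reading (one gate applied at prediction time)
was chosen over a train-time partition of the data into two groups; the
config-exposed alternative was considered but the gated form is the one the
ensemble's inference rule actually defines.

## Double cross-validation

Outer 10-fold / inner 5-fold, both stratified by class and seeded. Per outer
fold, everything — scaling statistics, Tucker factors, feature
standardization, candidate pool, judge assembly — is fitted on outer-training
data; inner folds refit scaling and factors per split, so no selection step
ever sees an outer-test tensor. Pooled out-of-fold records (exactly one per
patient) yield sensitivity, specificity, accuracy, MCC (0 when a denominator
factor vanishes), a tie-grouped trapezoidal ROC/AUC, and percentile bootstrap
confidence intervals stratified by class (B = 500–1000). The smaller class
is "positive" by default. The three pairwise comparisons are reported
separately without multiplicity adjustment, matching how such feasibility
studies present them. A single master seed drives fold assignment, weight
initialization (per-fold, per-configuration seeds derived via
`numpy.random.SeedSequence` with CRC-tagged keys), simulation and bootstrap,
so a full run is bit-reproducible.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes, not
sensor chemistry:

- **Baseline surface** — per sensor, a separable product of a low-order
  sinusoid in temperature step and a slow exponential-plus-cosine drift in
  cycle, at sensor-specific gain (order 10 in arbitrary conductance units).
  Smooth, strictly positive, shared by all classes.
- **Class effect** — one random multilinear perturbation pattern of the
  configured `signature_ranks` (default (1, 1, 1)), normalized to unit peak
  magnitude and shared by all classes; class k adds it with a deterministic
  coefficient evenly spaced on [+1, −1] times `effect_amplitude` × baseline
  mean. Pairwise template differences therefore have multilinear rank at
  most `signature_ranks` and a guaranteed peak of
  2/(K−1) × amplitude × baseline mean. Deterministic coefficients make the
  amplitude a calibrated effect size rather than a random draw (a per-class
  random rescaled core would reduce a rank-1 effect to a coin-flip sign, so
  two classes could coincide exactly), and peak normalization makes template
  positivity seed-independent: the baseline is deterministic, so any
  amplitude below min(baseline)/mean(baseline) ≈ 0.4 is valid for every
  seed. Amplitude 0 makes all classes identical. Default amplitude
  0.15 = 3× the default noise CV — a clearly separable regime.
- **Device effects** — one log-normal gain per serial (sd 0.10 of log gain);
  the five serials are allocated to patients by largest-remainder rounding of
  the configured proportions, so stated allocation counts are reproduced
  exactly.
- **Noise** — element-wise log-normal with unit mean
  (σ² = ln(1 + CV²), μ = −σ²/2), default CV 0.05: conductance is positive
  and relative errors dominate in metal-oxide sensors.
- **Metadata** — age (normal), sex/smoking/food intake (Bernoulli),
  pack-years (exponential) and tumor stage (categorical) per class.

What the generator does **not** emulate: real between-device and
between-session variance magnitudes (unknown; config-exposed, not claimed
realistic), VOC-specific adsorption kinetics, temporal drift within a
measurement beyond the smooth cycle trend, or confounding between smoking
status and the breath signal. Passing tests therefore demonstrate that the
pipeline recovers low-rank class structure of a stated size under
multiplicative noise and device gain variation — they do not certify
performance on clinical breath data, whose class effects may be weaker,
higher-rank, and confounded.

## Problem sizes used by the tests and the acceptance script

Study-sized synthetic cohorts (100/40/28 per class) with outer 10-fold /
inner 5-fold nested CV are used for the end-to-end checks; smaller cohorts
(around 50–64 patients, outer 5 / inner 3) exercise scale-free properties
such as the leakage sentinel, and the default search grid is two scaling
options × ranks (4,3,2) × hidden sizes {4,8} × 2 weight seeds — sizes chosen
so a full double-CV run completes in about a minute on one CPU while still
exercising every selection stage.

## Known limitations

- The judge enumeration is exhaustive only within the declared candidate set
  (gate from the whole pool, committees from the top-m members); m trades
  completeness against cost as C(m,3)² grows quickly.
- Fisher's two-sided p uses the probability method (sum of tables no more
  likely than observed, with a 1+1e−7 relative slack on ties); other
  two-sided conventions (doubling, mid-p) give different values on asymmetric
  margins.
- MCC's zero-denominator convention (0) makes the inner-selection score
  conservative for degenerate assemblies that predict one class only.
- No missing-data handling in Tucker fitting; measurement files must be
  complete 64×36×3 grids.
- Binary pairwise comparisons only; no three-class classification or
  calibration analysis.
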