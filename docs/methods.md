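# Methods

This note records the model, the numerical choices, the synthetic-data
design, and the limitations of the `epicog` pipeline.

## Signal model and feature definition

A recording is a 19-channel scalp EEG in the fixed 10–20 montage
(Fp1, Fp2, Fz, Cz, Pz, C3, C4, T3, T4, T5, T6, F3, F4, F7, F8, O1, O2,
P3, P4), nominally 256 Hz, in microvolts. The analysis path is:

1. **Broadband filter** 0.5–30 Hz: 4th-order Butterworth band-pass applied
   forward–backward (`sosfiltfilt`), so the filter contributes zero phase
   delay. Phase estimation downstream would otherwise be biased by the
   filter's group delay. The continuous recording is filtered before
   epoching (standard practice; a per-epoch order is not meaningful for a
   0.5 Hz edge whose transient outlasts an epoch).
2. **Epoching**: contiguous, non-overlapping 6-s windows from the start of
   the recording; the trailing remainder is discarded. A 20-min recording
   yields exactly 200 epochs. An optional amplitude-threshold epoch
   rejector (configurable threshold, typically 100 µV; off by default) removes epochs
   with gross transients; it is a deliberately simple cleaning stage, not
   an ICA substitute, and synthetic data does not need it.
3. **Band split**: each epoch is band-passed (same zero-phase Butterworth
   design) into δ 1–4, θ 4–7, α 8–13, β 14–30 Hz. The 7–8 Hz gap in this
   band table is intentional and kept; the band table is configurable.
4. **Instantaneous phase**: angle of the Hilbert analytic signal per
   channel per epoch. This is only a valid phase estimator for narrowband
   signals, which is why the band split precedes it.
5. **PLV**: for channels a, b the phase difference Δθ(t, n) is pooled
   across the N epochs at each retained time point,
   PLV(t) = (1/N)|Σ_n exp(i Δθ(t, n))|, and the scalar feature is the mean
   of PLV(t) over the epoch interior. The first and last 0.5 s of each
   epoch are excluded (`edge_trim_s`) because the Hilbert transform and
   the per-epoch filtering distort phase near epoch edges; trimming beats
   tapering here because a taper would reweight, not remove, the corrupted
   samples. The diagonal of the 19×19 matrix is fixed at 1 and never
   exported as a feature.

The per-pair reduction over time (mean of PLV(t) over the interior) is a
design choice: the estimator is defined per time point, and a single
number per pair per band is what the feature tables require. Averaging
over the interior uses all retained samples and is invariant to where
within the epoch the locking occurs.

`max_epochs` optionally restricts the estimator to the first k epochs
(deterministically). The default uses all available epochs, which is the
more data-efficient convention; the knob exists because clinical practice
sometimes scores a fixed number of artifact-free segments (e.g. 80).

Vectorization takes the upper triangle of each band matrix in canonical
pair order: 171 features per band, 684 total, named `theta_T5-T6` style.
The canonical channel order above is part of the public contract.

## Clinical encoding

23 items: three continuous (age, age at first onset, years since onset),
fifteen binary (0/1; female = 1), five ordinal encoded 0-based in clinical
order (seizure type generalized/focal/both; seizure frequency
rare/occasional/frequent; anxiety none→definitely-obvious; depression
none→definitely; education ≤6y/7–9y/10–12y/≥13y). Ordinal rather than
one-hot encoding: both Fisher scoring and tree ensembles operate naturally
on ordered codes, and it keeps one column — and one score — per clinical
item. Missing values are an input error; the pipeline does not impute.

## Fisher screening

F_j = Σ_k n_k (μ_jk − μ_j)² / (Σ_k n_k σ²_jk + ε) with population
variances, class-size weighting in both numerator and denominator, and
ε = 1e−12 guarding features constant within both classes. The score is
invariant to per-feature rescaling, so ranking is identical on raw and
standardized tables. Ties are broken by original column order (stable
sort) for determinism.

By default screening is fitted once on the full table before
cross-validation, mirroring the screening-then-modeling sequence of the
clinical workflow this package reproduces. **This leaks ranking
information across folds**: with many candidate features and few
subjects, the held-out metrics of the default protocol are optimistic.
The effect is large enough to matter — on label-permuted data the default
protocol's AUC rises to roughly 0.78 with 150-of-684 screening at n = 80,
while the leakage-free mode sits at chance. `select_per_fold=True`
re-ranks inside every training fold and is what the permutation-null test
uses; users estimating generalization error should prefer it.

## Classifiers and cross-validation

Two ensembles, chosen for their complementary inductive biases on
small-n/wide-p tables:

* **AdaBoost (SAMME.R)** over RBF-kernel SVCs with probability
  calibration. SAMME.R requires class-probability estimates from the base
  learner, hence the calibrated SVC. The real-valued boosting update is
  implemented in `epicog.boosting` as an sklearn-compatible estimator
  (scikit-learn ≥1.6 no longer ships this variant); tests cross-check it
  against scikit-learn's discrete AdaBoost on separable data.
* **GBDT**: `GradientBoostingClassifier` (CART base learners) with
  subsampling.

Evaluation is stratified five-fold cross-validation (class imbalance at
clinical group sizes makes unstratified folds noisy), with an inner
stratified five-fold grid search on each training split maximizing mean
accuracy — i.e. nested CV; hyperparameters are never chosen on a test
fold. AUC is computed per held-out fold and averaged. CI is the positive
class throughout; undefined precision (no positive predictions) is
reported as 0 with a flag.

Search spaces (`default_grid`): AdaBoost n_estimators {50…150},
learning rate {0.1…1.0}, C at powers of 4 in [2⁻¹⁰, 2¹⁰], γ decades
{1e−4…10}; GBDT n_estimators {50…150}, learning rate {0.1…1.0}, subsample
{0.5…0.8}, max_depth {8, 10, 12, 15}, max_leaf_nodes {10…30}. Learning
rate 0 is degenerate and excluded. The full product is expensive
(thousands of nested-CV fits of calibrated SVC ensembles), so `small_grid`
provides a compact representative corner — single n_estimators, a
low/high learning-rate pair, and two values on the most influential
capacity axis per algorithm — used by the test suite, the pipeline
default, and the examples. Grids are plain dicts and fully configurable.

All randomness flows from explicit integer seeds; a fixed (data, seed)
pair reproduces every report byte-identically.

## Statistics

Continuous features: Shapiro–Wilk per group at α = 0.05; both groups
normal → independent-samples t-test, otherwise Mann–Whitney U (two-sided
throughout; SciPy uses the exact null for small samples without ties). A
`method` argument can force either test. Categorical features: Pearson χ²
without continuity correction; 2×2 tables with any expected cell count
below 5 fall back to Fisher's exact test; larger sparse tables keep χ²
with a warning. FDR control is Benjamini–Hochberg, applied over one
analysis batch as a single family. Features constant in both groups
report p = 1 with a flag rather than erroring.

## Synthetic cohorts

The generator defines the conditions under which the pipeline is
validated.

**Coupling model.** A coupling (band, pair, κ_CON, κ_CI) injects a shared
narrowband carrier into both channels of the pair: carrier frequency
wanders smoothly within the band (low-pass-filtered frequency modulation,
excursion ≤ ±0.5× the half-bandwidth), and the *first* channel's copy is
offset by a von Mises(0, κ) phase drawn once per 6-s epoch. The pair's
across-epoch phase difference is therefore exactly von Mises(κ), and the
expected PLV is the mean resultant length I₁(κ)/I₀(κ). Jittering one
channel rather than both is deliberate: jitter on both sides would make
the expected PLV the *square* of the Bessel ratio and break the one-line
calibration law. Per-epoch (not per-sample) redraws make the across-epoch
PLV estimator the exact estimand of the law.

**Background.** Each channel carries 1/f noise (exponent 1, 10 µV RMS
over 0.3–45 Hz) plus an independent narrowband oscillation per band
(δ/θ/α/β RMS 8/6/8/5 µV) — except that a coupled channel's independent
component in the coupled band is replaced by the shared carrier
(amplitude 80 µV). The carrier-to-in-band-background ratio keeps the
additive-noise dilution of measured PLV below ~0.01, small against the
test tolerances; uncoupled pairs remain phase-independent by
construction, with E[PLV] ≈ √(π/4N) ≈ 0.063 at N = 200.

**Two levels.** `generate_eeg` synthesizes full waveforms and is used
wherever filtering and Hilbert phase must themselves be exercised
(calibration law: 20 replicate subjects per κ ∈ {0.5, 2, 8}, 20-min
recordings, tolerance ±0.03 on the replicate mean). For cohort-scale
experiments, `simulate_plv_features` draws the per-epoch phase differences
directly and applies the same PLV estimator — identical distributional
model, no waveform cost — producing 684-column tables for hundreds of
subjects in seconds. Selection-recovery and classification experiments
run at n = 40 + 40 with N = 200 epochs.

**Default contrast.** Five disjoint θ-band pairs with κ_CON = 4
(PLV ≈ 0.86) vs κ_CI = 1 (PLV ≈ 0.45). For classification experiments a
per-subject lognormal spread on κ (σ = 0.5) adds biological heterogeneity
so the groups overlap rather than separate trivially; with five informative
features the achievable accuracy stays high (mid-0.9s) while single
features remain imperfect predictors. Couplings use disjoint channel
pairs because two couplings sharing a channel would mix their carriers in
that channel's band phase.

**Clinical tables** are drawn per group from category frequencies and
continuous moments configured in `DEFAULT_CLINICAL_SPEC` (defaults follow
a 55/76 two-group epilepsy cohort: e.g. education skewed low and frequent
seizures over-represented in the impaired group). Age is generated as
onset age + disease duration so the bookkeeping invariant
`years_since_onset ≤ age` holds by construction; its SD is therefore the
convolution of the two components rather than an independently set value.

**What passing does not show.** The generator produces stationary,
artifact-free, reference-clean signals with literal band-limited phase
coupling. Real EEG adds volume conduction (which inflates zero-lag PLV
between neighboring electrodes), ocular/muscle artifacts, non-stationary
state changes, and label noise in the MoCA split. Recovery of implanted
couplings here validates the estimator and the pipeline plumbing, not
clinical performance; clinical metrics reported on synthetic cohorts
reflect the implanted contrast, not any real-world effect size.

## EDF round trip

Fixtures are written as minimal 16-bit EDF (1-s records, physical range
±3276.8 µV → quantization step exactly 0.1 µV) and read back through
MNE's EDF reader with alias normalization ("EEG Fp1-A1" → "Fp1"),
reference-lead dropping (A1/A2) and canonical reordering. Round-trip
error is bounded by half a quantization step.

## Problem sizes and runtime choices

Test and example runs use reduced problem sizes chosen to keep the
package's own validation loop fast: cohorts of 40 + 40 (recovery,
classification), 12 + 12 (pipeline artifacts), 20 replicate subjects per
κ for signal-level calibration, and `small_grid` search spaces. The full
131-subject configuration and the full grids remain the defaults of
`CohortConfig` and `default_grid` and run unchanged, just longer.

## Known limitations

* No ICA or channel interpolation; the amplitude rejector only catches
  gross artifacts.
* PLV is sensitive to volume conduction; no leakage-robust variant
  (imaginary coherence, wPLI) is provided — out of scope by design.
* The default screening protocol leaks selection information across folds
  (see above); it is retained as the default for fidelity to the clinical
  workflow being reproduced, with the leakage-free mode one flag away.
* The phase-level generator shares its model with the waveform generator
  but bypasses filtering; any defect confined to the filtering/Hilbert
  stages is caught only by the signal-level tests.
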