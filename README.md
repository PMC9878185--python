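# epicog

EEG phase-locking connectivity and clinical features for classifying
cognitive impairment in people with epilepsy.

Roughly half of adults with epilepsy develop measurable cognitive deficits,
but screening instruments such as the MoCA are time-consuming and
examiner-dependent. This package implements a diagnostic pipeline that
works from data already collected in routine epilepsy care: a resting
scalp EEG and the clinical history. It targets a two-group problem —
cognitively normal (CON) vs cognitively impaired (CI) — and provides every
stage as a tested, reusable library: connectivity feature extraction,
feature screening, ensemble classification, group statistics, and a
synthetic cohort generator with known ground truth.

## The method

**Connectivity features.** A 19-lead 10–20 recording (Fp1 … P4, 256 Hz) is
band-passed to 0.5–30 Hz, cut into non-overlapping 6-s epochs, and split
into the four clinical bands δ (1–4 Hz), θ (4–7 Hz), α (8–13 Hz) and
β (14–30 Hz). Per band, each channel's instantaneous phase θ(t) is the
angle of its Hilbert analytic signal, and for every channel pair the
phase-locking value pools the phase difference Δθ(t, n) across the N
epochs:

```
PLV(t) = (1/N) | Σ_{n=1..N} exp( i · Δθ(t, n) ) |
```

PLV = 1 means the pair's phase difference is identical in every epoch;
PLV = 0 means it is uniformly spread on the circle. The scalar feature per
pair is the mean of PLV(t) over the epoch interior. With 19 channels this
gives C(19,2) = 171 features per band, 684 across the four bands; adding
23 encoded clinical items (demographics, epilepsy history, imaging,
medication, psychometric screens) yields a 707-column subject table.

**Screening and classification.** Features are ranked by the two-class
Fisher score F_j = Σ_k n_k (μ_jk − μ_j)² / Σ_k n_k σ²_jk and the top-k are
fed to one of two ensembles under stratified five-fold cross-validation
with nested grid search: AdaBoost (SAMME.R) over probability-calibrated
RBF-SVC base learners, or gradient-boosted CART trees (GBDT). Reports
carry per-fold and mean accuracy, precision, recall, F1 and ROC-AUC with
CI as the positive class. Group statistics (Shapiro–Wilk-gated t /
Mann–Whitney, χ² / Fisher exact, Benjamini–Hochberg FDR) reproduce the
standard clinical comparison tables.

**Synthetic cohorts.** No patient data ships with the package. The
`synthetic` module generates two-group cohorts with implanted pairwise
phase couplings: a coupled pair's phase difference is von Mises(κ)
distributed across epochs, so its expected PLV is the Bessel ratio
I₁(κ)/I₀(κ) — an analytic calibration law the whole pipeline is tested
against. Clinical tables are drawn from configurable per-group category
frequencies and moments.

## Worked example

```python
from epicog import CohortConfig, CognitionClassifier, simulate_plv_features
from epicog.model import small_grid

cfg = CohortConfig(seed=7, n_con=40, n_ci=40, kappa_spread=0.5)
features, labels, truth = simulate_plv_features(cfg)
clf = CognitionClassifier(features, labels, algorithm="gbdt", top_k=150,
                          param_grid=small_grid("gbdt"), seed=0)
res = clf.fit()
print(res.summary())
```

prints

```
Cognition classification — gbdt
features used: 150   outer folds: 5   seed: 0

            accuracy  precision  recall     f1    auc
Fold 1        0.8750     1.0000  0.7500 0.8571 1.0000
Fold 2        0.8125     1.0000  0.6250 0.7692 0.9531
Fold 3        1.0000     1.0000  1.0000 1.0000 1.0000
Fold 4        1.0000     1.0000  1.0000 1.0000 1.0000
Fold 5        0.9375     0.8889  1.0000 0.9412 1.0000
Mean-value    0.9250     0.9778  0.8750 0.9135 0.9906
```

The cohort has five θ-band couplings implanted with concentration
κ = 4 (CON) vs κ = 1 (CI) — an expected PLV gap of about 0.42 per coupled
pair. The classifier recovers the group difference (mean accuracy 0.925,
AUC 0.99 over the five held-out folds), and the Fisher ranking places all
five implanted features first:

```
implanted features: ['theta_Fp1-Fz', 'theta_T5-T6', 'theta_F4-P3', 'theta_Fp2-T4', 'theta_Pz-C3']
Fisher top 5      : ['theta_F4-P3', 'theta_Pz-C3', 'theta_Fp2-T4', 'theta_T5-T6', 'theta_Fp1-Fz']
```

The command line mirrors the library: `epicog simulate` writes a cohort as
EDF files + clinical CSV, `epicog extract` turns an EDF directory into the
684-column feature table, and `epicog run-all` runs the six-model
experiment (three feature views × two algorithms).

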