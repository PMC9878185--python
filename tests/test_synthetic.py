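"""Generator ground truth: calibration law, specificity, clinical tables, EDF."""

import json

import numpy as np
import pytest

from epicog.connectivity import instantaneous_phase, plv_matrix
from epicog.io import segment_epochs
from epicog.montage import channel_index
from epicog.preprocess import DEFAULT_BANDS, band_decompose, broadband_filter
from epicog.synthetic import (
    DEFAULT_CLINICAL_SPEC,
    CohortConfig,
    CouplingSpec,
    expected_plv,
    generate_clinical,
    generate_eeg,
    simulate_plv_features,
)

THETA = DEFAULT_BANDS[1]


def pipeline_plv_matrix(rec, band=THETA):
    """Full analysis path: broadband filter -> epochs -> band -> phase -> PLV."""
    es = segment_epochs(broadband_filter(rec))
    bes = band_decompose(es, (band,))[band.name]
    return plv_matrix(instantaneous_phase(bes)).values


def pipeline_pair_plv(cfg, subject_index, pair, band=THETA):
    m = pipeline_plv_matrix(generate_eeg(cfg, subject_index), band)
    return m[channel_index(pair[0]), channel_index(pair[1])]


@pytest.fixture(scope="module")
def coupled_run():
    cfg = CohortConfig(
        seed=42, n_con=1, n_ci=1, duration_s=1200.0,
        couplings=(CouplingSpec("theta", ("Fp1", "Fz"), 1e6, 1e6),),
    )
    rec = generate_eeg(cfg, 0)
    return {band.name: pipeline_plv_matrix(rec, band) for band in DEFAULT_BANDS[:3]}


class TestSignalLevel:
    def test_jitter_free_coupling_near_perfect(self, coupled_run):
        i, j = channel_index("Fp1"), channel_index("Fz")
        assert coupled_run["theta"][i, j] >= 0.99

    def test_uncoupled_pairs_stay_at_independence_null(self, coupled_run):
        m = coupled_run["theta"].copy()
        i, j = channel_index("Fp1"), channel_index("Fz")
        m[i, j] = m[j, i] = np.nan
        off = m[np.triu_indices(19, 1)]
        assert np.nanmean(off) < 0.12

    def test_coupling_is_band_specific(self, coupled_run):
        # the implanted theta coupling must not leak into delta or alpha
        i, j = channel_index("Fp1"), channel_index("Fz")
        assert coupled_run["delta"][i, j] < 0.12
        assert coupled_run["alpha"][i, j] < 0.12

    def test_calibration_matches_bessel_ratio(self):
        """Mean pipeline PLV over replicate subjects follows I1(k)/I0(k)."""
        n_reps = 20
        for kappa in (0.5, 2.0, 8.0):
            vals = [
                pipeline_pair_plv(
                    CohortConfig(
                        seed=300 + rep, n_con=1, n_ci=1, duration_s=1200.0,
                        couplings=(CouplingSpec("theta", ("Fp1", "Fz"), kappa, kappa),),
                    ),
                    0,
                    ("Fp1", "Fz"),
                )
                for rep in range(n_reps)
            ]
            assert np.mean(vals) == pytest.approx(expected_plv(kappa), abs=0.03)


class TestExpectedPlv:
    def test_bessel_ratio_values(self):
        assert expected_plv(2.0) == pytest.approx(0.6978, abs=1e-4)
        assert expected_plv(0.0) == 0.0
        assert 0.999 < expected_plv(1e6) < 1.0

    def test_monotone_in_kappa(self):
        ks = [0.1, 0.5, 1, 2, 4, 8, 50, 1000]
        vals = [expected_plv(k) for k in ks]
        assert all(a < b for a, b in zip(vals, vals[1:]))


class TestSimulatedFeatures:
    def test_shapes_labels_and_determinism(self):
        cfg = CohortConfig(seed=5, n_con=6, n_ci=9, duration_s=120.0)
        f1, l1, truth = simulate_plv_features(cfg)
        f2, l2, _ = simulate_plv_features(cfg)
        assert f1.shape == (15, 684)
        assert (l1 == 0).sum() == 6 and (l1 == 1).sum() == 9
        assert f1.equals(f2) and l1.equals(l2)
        assert len(truth["couplings"]) == len(cfg.couplings)

    def test_coupled_features_match_bessel_law(self):
        cfg = CohortConfig(seed=31, n_con=60, n_ci=60, duration_s=1200.0)
        feats, labels, truth = simulate_plv_features(cfg)
        for c in truth["couplings"]:
            con_mean = feats.loc[labels == 0, c["feature"]].mean()
            ci_mean = feats.loc[labels == 1, c["feature"]].mean()
            assert con_mean == pytest.approx(c["expected_plv_con"], abs=0.03)
            # kappa=1 group carries larger finite-N bias; still near the law
            assert ci_mean == pytest.approx(c["expected_plv_ci"], abs=0.05)

    def test_uncoupled_features_near_null(self):
        cfg = CohortConfig(seed=8, n_con=10, n_ci=10, duration_s=1200.0)
        feats, _, truth = simulate_plv_features(cfg)
        coupled = {c["feature"] for c in truth["couplings"]}
        rest = feats.drop(columns=list(coupled))
        assert rest.to_numpy().mean() == pytest.approx(np.sqrt(np.pi / 800), abs=0.01)


class TestGenerateClinical:
    def test_group_sizes_and_labels(self):
        cfg = CohortConfig(seed=2)
        recs = generate_clinical(cfg)
        assert len(recs) == 131
        assert sum(r.label == "CON" for r in recs) == 55

    def test_same_seed_identical_tables(self):
        cfg = CohortConfig(seed=2, n_con=5, n_ci=5)
        r1 = generate_clinical(cfg)
        r2 = generate_clinical(cfg)
        assert [vars(a) for a in r1] == [vars(b) for b in r2]

    def test_degenerate_probability_gives_constant_column(self):
        spec = dict(DEFAULT_CLINICAL_SPEC)
        spec["education"] = {
            "kind": "categorical",
            "categories": ("<=6y", "7-9y", "10-12y", ">=13y"),
            "CON": (0.0, 0.0, 0.0, 1.0),
            "CI": (0.0, 0.0, 0.0, 1.0),
        }
        cfg = CohortConfig(seed=3, n_con=10, n_ci=10, clinical_spec=spec)
        assert {r.education for r in generate_clinical(cfg)} == {">=13y"}

    def test_invalid_probabilities_error(self):
        spec = dict(DEFAULT_CLINICAL_SPEC)
        spec["education"] = {
            "kind": "categorical",
            "categories": ("a", "b"),
            "CON": (0.7, 0.7),
            "CI": (0.5, 0.5),
        }
        with pytest.raises(ValueError):
            CohortConfig(seed=1, clinical_spec=spec)

    def test_category_frequencies_track_spec(self):
        cfg = CohortConfig(seed=17, n_con=400, n_ci=400)
        recs = generate_clinical(cfg)
        freq = np.mean([r.education == "<=6y" for r in recs if r.label == "CI"])
        assert freq == pytest.approx(23 / 76, abs=0.06)

    def test_onset_plus_duration_equals_age(self):
        for r in generate_clinical(CohortConfig(seed=4, n_con=20, n_ci=20)):
            assert r.age_y == pytest.approx(r.age_first_onset_y + r.years_since_onset)


class TestCouplingSpec:
    def test_unknown_channel_rejected(self):
        with pytest.raises(KeyError):
            CouplingSpec("theta", ("Fp1", "XX"), 1.0, 1.0)

    def test_unknown_band_rejected(self):
        with pytest.raises(ValueError):
            CouplingSpec("gamma", ("Fp1", "Fz"), 1.0, 1.0)

    def test_feature_name_canonical(self):
        assert CouplingSpec("theta", ("T6", "T5"), 1, 1).feature_name == "theta_T5-T6"
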