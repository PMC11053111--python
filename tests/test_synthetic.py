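"""Synthetic cohort generator: reproducibility, calibration, defect structure."""

import json

import numpy as np
import pytest

from polarmace.errors import ConfigurationError
from polarmace.polar import load_cohort
from polarmace.signals import derive_signal
from polarmace.synthetic import (
    DEFAULT_CLINICAL_SCHEMA,
    GeneratorConfig,
    GroundTruth,
    simulate_clinical,
    simulate_cohort,
    simulate_outcomes,
    simulate_polar_study,
    write_cohort,
)


class TestReproducibility:
    def test_same_seed_gives_identical_cohort(self):
        cfg = GeneratorConfig(n_patients=12, seed=5)
        a, _ = simulate_cohort(cfg)
        b, _ = simulate_cohort(cfg)
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.study.s_mbf.values, rb.study.s_mbf.values)
            assert ra.outcome == rb.outcome
            assert ra.clinical == rb.clinical

    def test_different_seed_differs(self):
        a, _ = simulate_cohort(GeneratorConfig(n_patients=5, seed=1))
        b, _ = simulate_cohort(GeneratorConfig(n_patients=5, seed=2))
        assert not np.array_equal(a[0].study.s_mbf.values, b[0].study.s_mbf.values)


class TestPolarStudy:
    def test_noiseless_defect_free_study_has_constant_reserve(self):
        cfg = GeneratorConfig(defect_probability=0.0, noise_sd_fraction=0.0, seed=3)
        rng = np.random.default_rng(3)
        study, truth = simulate_polar_study(cfg, rng, "p")
        ratio = study.s_mbf.values / study.r_mbf.values
        assert np.allclose(ratio, ratio[0, 0])
        assert truth.defect_burden == 0.0

    def test_defect_reduces_stress_flow_inside_mask(self):
        cfg = GeneratorConfig(defect_probability=1.0, seed=0)
        rng = np.random.default_rng(11)
        ratios = []
        for i in range(50):
            study, truth = simulate_polar_study(cfg, rng, f"p{i}")
            if truth.defect_mask.sum() == 0 or truth.defect_mask.all():
                continue
            mfr = study.s_mbf.values / study.r_mbf.values
            ratios.append(mfr[truth.defect_mask].mean() / mfr[~truth.defect_mask].mean())
        # average in-mask reserve should track the severity range (0.3-0.8)
        assert 0.2 < np.mean(ratios) < 0.9

    def test_cohort_median_flows_near_reference_values(self):
        records, _ = simulate_cohort(GeneratorConfig(n_patients=1000, seed=42))
        smbf = np.median([r.study.s_mbf.values.mean() for r in records])
        rmbf = np.median([r.study.r_mbf.values.mean() for r in records])
        assert abs(smbf - 1.96) / 1.96 < 0.15
        assert abs(rmbf - 0.82) / 0.82 < 0.15
        mfr = np.median([derive_signal(r.study, "mfr").values.mean() for r in records])
        assert 1.9 < mfr < 3.1

    def test_rpp_spans_reference_value(self):
        records, _ = simulate_cohort(GeneratorConfig(n_patients=200, seed=9))
        rpp = np.array([r.study.rest_hr * r.study.rest_sbp for r in records])
        assert rpp.min() < 8500.0 < rpp.max()


class TestOutcomes:
    def test_null_coefficients_hit_target_rate(self):
        cfg = GeneratorConfig(
            n_patients=10000, beta_global=0.0, beta_defect=0.0, beta_clinical=0.0, seed=1
        )
        records, _ = simulate_cohort(cfg)
        rate = np.mean([r.outcome.event for r in records])
        assert rate == pytest.approx(0.20, abs=0.01)

    def test_lower_stress_flow_means_more_events(self):
        cfg = GeneratorConfig(n_patients=2000, beta_global=-2.5, beta_defect=0.0,
                              beta_clinical=0.0, defect_probability=0.0, seed=2)
        records, truths = simulate_cohort(cfg)
        smbf = np.array([t.global_smbf for t in truths])
        events = np.array([r.outcome.event for r in records])
        low, high = smbf < np.median(smbf), smbf >= np.median(smbf)
        assert events[low].mean() > events[high].mean()

    def test_median_followup_in_window(self):
        records, _ = simulate_cohort(GeneratorConfig(n_patients=500, seed=4))
        med = np.median([r.outcome.time_days for r in records])
        assert 500 < med < 800

    def test_degenerate_followup_window_rejected(self):
        with pytest.raises(ConfigurationError):
            GeneratorConfig(followup_window_days=(0.0, 0.0))

    def test_unattainable_rate_is_an_error(self):
        truths = [
            GroundTruth("p", np.zeros((16, 36), bool), (), 0.0, 2.0, 0.0) for _ in range(10)
        ]
        cfg = GeneratorConfig(event_rate=1.0)  # censoring makes rate 1 impossible
        with pytest.raises(ConfigurationError):
            simulate_outcomes(truths, cfg, np.random.default_rng(0))


class TestClinical:
    def test_prevalence_one_variable_is_all_ones(self):
        cfg = GeneratorConfig(clinical_prevalences={"always": 1.0})
        rng = np.random.default_rng(0)
        rows = [simulate_clinical(cfg, rng, 0.0) for _ in range(20)]
        assert all(r["always"] == 1 for r in rows)

    def test_binomial_prevalence_calibration(self):
        cfg = GeneratorConfig()
        rng = np.random.default_rng(1)
        rows = [simulate_clinical(cfg, rng, 0.0) for _ in range(10000)]
        freq = np.mean([r["hypertension"] for r in rows])
        assert freq == pytest.approx(0.73, abs=0.01)

    def test_rows_match_default_schema(self):
        cfg = GeneratorConfig()
        rng = np.random.default_rng(2)
        row = simulate_clinical(cfg, rng, 0.3)
        assert set(row) == set(DEFAULT_CLINICAL_SCHEMA)
        assert len(row) == 19

    def test_invalid_prevalence_rejected(self):
        with pytest.raises(ConfigurationError):
            GeneratorConfig(clinical_prevalences={"bad": 1.2})


class TestWriteCohort:
    def test_roundtrip_through_manifest(self, tmp_path):
        records, truths = simulate_cohort(GeneratorConfig(n_patients=4, seed=6))
        manifest = write_cohort(records, truths, tmp_path)
        loaded = load_cohort(manifest)
        assert len(loaded) == 4
        for orig, back in zip(records, loaded):
            np.testing.assert_allclose(
                back.study.s_mbf.values, orig.study.s_mbf.values, rtol=1e-9
            )
            assert back.outcome.event == orig.outcome.event
        truth_payload = json.loads((tmp_path / "ground_truth.json").read_text())
        assert len(truth_payload) == 4
        assert {t["patient_id"] for t in truth_payload} == {r.study.patient_id for r in records}

    def test_file_counts(self, tmp_path):
        records, truths = simulate_cohort(GeneratorConfig(n_patients=5, seed=8))
        write_cohort(records, truths, tmp_path)
        assert len(list((tmp_path / "matrices").glob("*.csv"))) == 10
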