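"""Generator determinism, eGFR inversion, calibration, and latent-structure
fidelity of the synthetic cohorts."""

import numpy as np
import pytest

from akdscreen.cohort_analysis import evaluate_score
from akdscreen.errors import CalibrationError, DomainError, ValidationError
from akdscreen.io import RunConfig
from akdscreen.kidney_function import Demographics, egfr
from akdscreen.pipeline import run_pipeline
from akdscreen.risk_scoring import SYMPTOM_COLUMNS, ScoreWeights
from akdscreen.synthetic import (
    CalibrationTargets,
    CohortConfig,
    calibrate_symptom_probs,
    exact_operating_characteristics,
    generate_cohort,
    scr_from_egfr,
    simulated_operating_characteristics,
)


def scores_and_labels(cohort):
    w = ScoreWeights()
    p = cohort.patients
    score = sum(p[SYMPTOM_COLUMNS[f]] * w.points[f] for f in w.points)
    labels = p["latent_category"].isin(["AKD_with_AKI", "AKD_without_AKI"])
    return score.to_numpy(), labels.to_numpy()


class TestScrFromEgfr:
    @pytest.mark.parametrize("target", [15, 60, 90, 120])
    @pytest.mark.parametrize("sex", ["female", "male"])
    def test_round_trip_identity(self, target, sex):
        demo = Demographics(50, sex)
        scr = scr_from_egfr(target, demo)
        assert egfr(scr, demo) == pytest.approx(target, abs=1e-6)

    def test_inverse_of_worked_example(self):
        assert scr_from_egfr(105.3, Demographics(50, "female")) == pytest.approx(0.7, abs=1e-3)

    def test_monotone_in_target(self):
        demo = Demographics(60, "male")
        scrs = [scr_from_egfr(g, demo) for g in (20, 50, 80, 110)]
        assert all(b < a for a, b in zip(scrs, scrs[1:]))

    def test_out_of_domain_rejected(self):
        with pytest.raises(DomainError):
            scr_from_egfr(0.5, Demographics(50, "male"))
        with pytest.raises(DomainError):
            scr_from_egfr(199.9, Demographics(95, "male"))


class TestGenerateCohort:
    def test_empty_cohort(self):
        c = generate_cohort(CohortConfig(n_patients=0, seed=1))
        assert len(c) == 0
        assert len(c.measurements) == 0

    def test_seeded_determinism_byte_identical_csv(self):
        cfg = dict(n_patients=400, seed=42)
        a = generate_cohort(CohortConfig(**cfg))
        b = generate_cohort(CohortConfig(**cfg))
        assert a.patients.to_csv(index=False) == b.patients.to_csv(index=False)
        assert a.measurements.to_csv(index=False) == b.measurements.to_csv(index=False)
        c = generate_cohort(CohortConfig(n_patients=400, seed=43))
        assert a.measurements.to_csv(index=False) != c.measurements.to_csv(index=False)

    def test_noiseless_observed_equals_true(self):
        c = generate_cohort(CohortConfig(n_patients=300, seed=5, poc_cv=0.0, lab_cv=0.0))
        m = c.measurements
        assert (m["scr_value"] == m["scr_value_true"]).all()

    def test_degenerate_all_stage3_config_recovers_stage3(self):
        cfg = CohortConfig(
            n_patients=150,
            seed=9,
            poc_cv=0.0,
            lab_cv=0.0,
            pre_admission_prob=1.0,
            scr_decimals=None,  # exact values: stage bands recover exactly
            category_prevalence={
                "AKD_with_AKI": 1.0, "AKD_without_AKI": 0.0, "CKD": 0.0, "NKD": 0.0
            },
            stage_mix={1: 0.0, 2: 0.0, 3: 1.0},
        )
        c = generate_cohort(cfg)
        assert (c.patients["latent_stage"] == 3).all()
        res = run_pipeline(c.patients, c.measurements, RunConfig())
        assert (res.frame["category"] == "AKD_with_AKI").all()
        assert (res.frame["aki_stage"] == 3).all()

    def test_invalid_prevalence_rejected(self):
        cfg = CohortConfig(
            category_prevalence={
                "AKD_with_AKI": 0.5, "AKD_without_AKI": 0.5, "CKD": 0.2, "NKD": 0.0
            }
        )
        with pytest.raises(ValidationError):
            cfg.validate()

    def test_age_distribution_order_statistics(self):
        c = generate_cohort(CohortConfig(n_patients=20000, seed=13))
        age = c.patients["age"]
        assert (age >= 18).all() and (age <= 100).all()
        med, q1, q3 = np.percentile(age, [50, 25, 75])
        assert med == pytest.approx(57, abs=2.5)
        assert q1 == pytest.approx(42, abs=3.5)
        assert q3 == pytest.approx(70, abs=3.0)

    def test_prevalence_conservation_large_n(self):
        """Empirical latent fractions converge to the config prevalences."""
        cfg = CohortConfig(n_patients=20000, seed=21)
        c = generate_cohort(cfg)
        frac = c.patients["latent_category"].value_counts(normalize=True)
        for cat, p in cfg.category_prevalence.items():
            assert frac.get(cat, 0.0) == pytest.approx(p, abs=0.015)

    def test_noise_model_mean_absolute_relative_deviation(self):
        """Proportional Gaussian noise: E|obs-true|/true ~ CV * sqrt(2/pi)."""
        c = generate_cohort(CohortConfig(n_patients=8000, seed=17))
        m = c.measurements
        for source, cv in (("poc", 0.07), ("lab", 0.03)):
            sub = m[m["scr_source"] == source]
            rel = (sub["scr_value"] - sub["scr_value_true"]).abs() / sub["scr_value_true"]
            expected = cv * np.sqrt(2 / np.pi)
            assert rel.mean() == pytest.approx(expected, rel=0.10)

    def test_to_records_round_trip_fields(self):
        c = generate_cohort(CohortConfig(n_patients=25, seed=2))
        recs = c.to_records()
        assert len(recs) == 25
        r = recs[0]
        row = c.patients.iloc[0]
        assert r.patient_id == row["patient_id"]
        assert r.latent_category == row["latent_category"]
        assert set(r.symptoms) == set(SYMPTOM_COLUMNS)


class TestOperatingCharacteristics:
    def test_exact_matches_simulation(self):
        cfg = CohortConfig()
        ex = exact_operating_characteristics(cfg.symptom_probs, cfg.category_prevalence)
        sim = simulated_operating_characteristics(
            cfg.symptom_probs, cfg.category_prevalence, n_sim=40000, seed=4
        )
        for k in ex:
            assert sim[k] == pytest.approx(ex[k], abs=0.02)

    def test_shipped_defaults_hit_published_targets_exactly(self):
        cfg = CohortConfig()
        ex = exact_operating_characteristics(cfg.symptom_probs, cfg.category_prevalence)
        assert ex["auroc"] == pytest.approx(0.824, abs=0.005)
        assert ex["sensitivity"] == pytest.approx(0.929, abs=0.005)
        assert ex["specificity"] == pytest.approx(0.589, abs=0.005)

    def test_generated_cohort_reproduces_targets(self):
        c = generate_cohort(CohortConfig(n_patients=20000, seed=1))
        scores, labels = scores_and_labels(c)
        perf = evaluate_score(scores, labels, cutoff=10)
        assert perf.auroc == pytest.approx(0.824, abs=0.02)
        assert perf.sensitivity_at_cutoff == pytest.approx(0.929, abs=0.03)
        assert perf.specificity_at_cutoff == pytest.approx(0.589, abs=0.03)


class TestCalibration:
    def test_vacuous_tolerance_returns_immediately(self):
        t = CalibrationTargets(tolerance={"auroc": 1.0, "sensitivity": 1.0, "specificity": 1.0})
        sol = calibrate_symptom_probs(t, CohortConfig(), n_sim=5000, seed=0, max_rounds=1)
        assert set(sol) == {"AKD_with_AKI", "AKD_without_AKI", "CKD", "NKD"}

    def test_default_targets_satisfied_from_shipped_start(self):
        sol = calibrate_symptom_probs(n_sim=20000, seed=0, max_rounds=2)
        ex = exact_operating_characteristics(sol, CohortConfig().category_prevalence)
        assert ex["auroc"] == pytest.approx(0.824, abs=0.02)

    def test_degenerate_targets_raise_calibration_error(self):
        t = CalibrationTargets(
            auroc=0.824, sensitivity_at_cutoff=1.0, specificity_at_cutoff=1.0,
            tolerance={"auroc": 0.005, "sensitivity": 0.005, "specificity": 0.005},
        )
        with pytest.raises(CalibrationError) as exc:
            calibrate_symptom_probs(t, CohortConfig(), n_sim=5000, seed=0, max_rounds=2)
        assert "auroc" in exc.value.best

    def test_n_sim_floor_enforced(self):
        with pytest.raises(ValidationError):
            calibrate_symptom_probs(n_sim=100, seed=0)


class TestParameterRecovery:
    def test_noiseless_pipeline_recovers_latent_structure(self, noiseless_cohort_2k):
        res = run_pipeline(
            noiseless_cohort_2k.patients, noiseless_cohort_2k.measurements, RunConfig()
        )
        f = res.frame
        cat_conc = (f["category"] == f["latent_category"]).mean()
        aki = f[f["latent_category"] == "AKD_with_AKI"]
        stage_conc = (aki["aki_stage"] == aki["latent_stage"]).mean()
        assert cat_conc >= 0.95
        assert stage_conc >= 0.90
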