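"""Generator contracts: determinism, calibrated marginals, survival mechanics."""

import numpy as np
import pandas as pd
import pytest

from dietrisk.synthetic_cohort import (
    DEFAULT_COVARIATE_EFFECTS,
    FLOWCHART_COUNTS,
    ScenarioConfig,
    build_flowchart_fixture,
    build_linear_predictor,
    calibrate_baseline_hazard,
    generate_cohort,
    generate_genotypes,
    simulate_survival,
    _admin_years,
)


class TestConfig:
    def test_invalid_maf_rejected(self):
        with pytest.raises(ValueError, match="maf_range"):
            ScenarioConfig(maf_range=(0.0, 0.6))

    def test_recruitment_precedes_censor(self):
        with pytest.raises(ValueError, match="censor"):
            ScenarioConfig(recruitment_window=("2023-01-01", "2024-01-01"))

    def test_negative_n_rejected(self):
        with pytest.raises(ValueError):
            ScenarioConfig(n_participants=-1)


class TestGenerateCohort:
    def test_empty_cohort_schema_intact(self):
        raw = generate_cohort(ScenarioConfig(n_participants=0))
        assert raw.n == 0
        assert {"participant_id", "age", "sex", "energy_mean"} <= set(raw.participants.columns)

    def test_determinism(self):
        cfg = ScenarioConfig(n_participants=500, seed=123)
        a, b = generate_cohort(cfg), generate_cohort(cfg)
        pd.testing.assert_frame_equal(a.participants, b.participants)
        pd.testing.assert_frame_equal(a.diet, b.diet)

    def test_vegetable_median_calibration(self):
        raw = generate_cohort(ScenarioConfig(n_participants=50_000, seed=1))
        med = raw.diet.groupby("participant_id")["vegetables"].mean().median()
        assert abs(med - 284.75) / 284.75 < 0.10

    def test_categorical_levels_declared(self):
        raw = generate_cohort(ScenarioConfig(n_participants=2000, seed=5))
        from dietrisk.cohort_pipeline import CATEGORICAL_LEVELS

        for col, levels in CATEGORICAL_LEVELS.items():
            assert set(raw.participants[col].unique()) <= set(levels)

    def test_entry_dates_within_window(self):
        cfg = ScenarioConfig(n_participants=1000, seed=2)
        raw = generate_cohort(cfg)
        entries = pd.to_datetime(raw.participants["entry_date"])
        assert entries.min() >= pd.Timestamp(cfg.recruitment_window[0])
        assert entries.max() <= pd.Timestamp(cfg.recruitment_window[1])


class TestGenotypes:
    def test_mean_dosage_tracks_maf(self):
        cfg = ScenarioConfig(n_participants=10_000, seed=3, maf_range=(0.25, 0.25),
                             n_sites=2, variants_per_site=3)
        dosages, weights = generate_genotypes(cfg)
        se = np.sqrt(2 * 0.25 * 0.75 / 10_000)
        assert np.abs(dosages.mean().to_numpy() - 0.5).max() < 3 * se

    def test_near_zero_maf_all_zero(self):
        cfg = ScenarioConfig(n_participants=200, seed=4, maf_range=(1e-9, 1e-9),
                             n_sites=1, variants_per_site=1)
        dosages, _ = generate_genotypes(cfg)
        assert (dosages.to_numpy() == 0).all()

    def test_determinism(self):
        cfg = ScenarioConfig(n_participants=300, seed=9, n_sites=3, variants_per_site=2)
        a, _ = generate_genotypes(cfg)
        b, _ = generate_genotypes(cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_weights_cover_all_sites(self):
        cfg = ScenarioConfig(n_participants=10, seed=1, n_sites=4, variants_per_site=5)
        _, weights = generate_genotypes(cfg)
        assert weights["site"].nunique() == 4
        assert (weights.groupby("site").size() == 5).all()


class TestSurvival:
    def _frame(self, n, seed=0):
        cfg = ScenarioConfig(n_participants=n, seed=seed)
        raw = generate_cohort(cfg)
        return cfg, raw.participants

    def test_null_hazard_no_events(self):
        cfg, part = self._frame(300)
        out = simulate_survival(part, np.zeros(len(part)), cfg, baseline_hazard=0.0)
        assert out["event"].sum() == 0
        admin = _admin_years(part["entry_date"], cfg.censor_date)
        assert np.allclose(out["follow_up_years"], admin)

    def test_closed_form_incidence(self):
        # eta = 0, h0 * tbar ~ 0.09: empirical incidence matches
        # mean(1 - exp(-h0 * A)) within 3 binomial SE
        cfg, part = self._frame(20_000, seed=8)
        admin = _admin_years(part["entry_date"], cfg.censor_date)
        h0 = 0.09 / admin.mean()
        out = simulate_survival(part, np.zeros(len(part)), cfg, baseline_hazard=h0)
        expected = float(np.mean(-np.expm1(-h0 * admin)))
        se = np.sqrt(expected * (1 - expected) / len(part))
        assert abs(out["event"].mean() - expected) < 3 * se

    def test_incidence_monotone_in_hazard(self):
        cfg, part = self._frame(5000, seed=6)
        eta = np.zeros(len(part))
        inc = [
            simulate_survival(part, eta, cfg, baseline_hazard=h)["event"].mean()
            for h in (0.004, 0.008)
        ]
        assert inc[1] > inc[0]

    def test_event_before_censor_date(self):
        cfg, part = self._frame(2000, seed=10)
        out = simulate_survival(part, np.zeros(len(part)), cfg, baseline_hazard=0.01)
        ev = out[out["event"] == 1]
        assert (pd.to_datetime(ev["exit_date"]) <= pd.Timestamp(cfg.censor_date)).all()


class TestCalibration:
    def test_small_target_small_hazard(self):
        eta = np.zeros(1000)
        admin = np.full(1000, 13.0)
        h_small = calibrate_baseline_hazard(1e-4, eta, admin)
        h_large = calibrate_baseline_hazard(0.1, eta, admin)
        assert 0 < h_small < 1e-4 and h_small < h_large

    def test_monotone_in_target(self):
        rng = np.random.default_rng(0)
        eta = rng.normal(0, 0.5, 2000)
        admin = rng.uniform(11, 16, 2000)
        h = [calibrate_baseline_hazard(t, eta, admin) for t in (0.02, 0.05, 0.10)]
        assert h[0] < h[1] < h[2]

    def test_closed_form_inverse(self):
        # with eta = 0 and constant A: h0 = -log(1 - p)/A exactly
        admin = np.full(500, 12.0)
        h = calibrate_baseline_hazard(0.0872, np.zeros(500), admin)
        assert h == pytest.approx(-np.log(1 - 0.0872) / 12.0, rel=1e-8)

    def test_unattainable_target_rejected(self):
        with pytest.raises(ValueError):
            calibrate_baseline_hazard(1.0, np.zeros(10), np.full(10, 13.0))


class TestLinearPredictor:
    def test_recognized_names_and_centering(self):
        raw = generate_cohort(ScenarioConfig(n_participants=1000, seed=13))
        part = raw.participants
        eta = build_linear_predictor(part, DEFAULT_COVARIATE_EFFECTS)
        assert abs(eta.mean()) < 1e-10
        older = part["age"] > part["age"].median()
        assert eta[older.to_numpy()].mean() > eta[~older.to_numpy()].mean()

    def test_unknown_name_rejected(self):
        raw = generate_cohort(ScenarioConfig(n_participants=10, seed=13))
        with pytest.raises(ValueError, match="mystery"):
            build_linear_predictor(raw.participants, {"mystery": 0.1})


class TestFlowchartFixture:
    def test_fixture_size_and_arithmetic(self):
        raw = build_flowchart_fixture()
        assert len(raw.participants) == 502_411
        removed = sum(
            v for k, v in FLOWCHART_COUNTS.items() if k not in ("initial", "final")
        )
        assert FLOWCHART_COUNTS["initial"] - removed == FLOWCHART_COUNTS["final"] == 177_441

    def test_flags_mutually_exclusive(self):
        part = build_flowchart_fixture().participants
        flags = np.column_stack(
            [
                part["baseline_cancer"].to_numpy(),
                (part["n_assessments"] == 0).to_numpy(),
                (~part["european_ancestry"]).to_numpy(),
                (~part["has_prs_data"]).to_numpy(),
                part["lost_to_followup"].to_numpy(),
                ((part["sex"] == "men") & (part["energy_mean"] < 800)).to_numpy(),
            ]
        )
        assert flags.sum(axis=1).max() <= 1


class TestEndToEndRecovery:
    def test_generating_model_recovered(self):
        # fitting the generating Cox model recovers the injected per-SD
        # effect within 3 SE (single replicate; the acceptance suite does
        # this at scale)
        from dietrisk import run_scenario
        from dietrisk.cohort_pipeline import build_design, model_covariates
        from dietrisk.survival_models import fit_cox

        eff = dict(DEFAULT_COVARIATE_EFFECTS)
        eff["phd_per_sd"] = np.log(0.85)
        res = run_scenario(ScenarioConfig(n_participants=12_000, seed=77, true_effects=eff))
        ds = res.dataset
        design = build_design(ds, model_covariates("model2"))
        design["phd_z"] = ds["phd_z"]
        design["follow_up_years"] = ds["follow_up_years"]
        design["event"] = ds["event"]
        fit = fit_cox(design, ["phd_z"] + [c for c in design.columns
                                           if c not in ("phd_z", "follow_up_years", "event")])
        assert abs(fit.params["phd_z"] - np.log(0.85)) < 3 * fit.se["phd_z"]
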