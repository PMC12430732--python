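"""Cox engine against analytic and library oracles; spline, trend, PH tests."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter
from lifelines.statistics import proportional_hazard_test

from dietrisk.survival_models import (
    fit_cox,
    rcs_basis,
    rcs_dose_response,
    rcs_knots,
    run_joint_suite,
    run_main_suite,
    run_sensitivity_suite,
    run_subgroup_suite,
    schoenfeld_test,
    trend_test,
    washout_mask,
)

LIFELINES_TIGHT = {"precision": 1e-12}


def random_survival(rng, n=120, p=3, beta=None, ties=True):
    beta = np.zeros(p) if beta is None else np.asarray(beta)
    X = rng.normal(size=(n, p))
    t = rng.exponential(1.0 / np.exp(X @ beta))
    if ties:
        t = np.ceil(t * 8) / 8
    c = rng.exponential(2.0, size=n)
    df = pd.DataFrame(X, columns=[f"x{j+1}" for j in range(p)])
    df["follow_up_years"] = np.minimum(t, c)
    df["event"] = (t <= c).astype(int)
    return df


class TestFitCox:
    def test_three_subject_analytic_example(self):
        # binary covariate (1,0,1), event times (1,2,3), all events:
        # the partial likelihood maximizes at beta = -log(2)/2
        df = pd.DataFrame(
            {"x": [1.0, 0.0, 1.0], "follow_up_years": [1.0, 2.0, 3.0], "event": 1}
        )
        fit = fit_cox(df, ["x"])
        assert fit.converged
        assert fit.params["x"] == pytest.approx(-0.5 * np.log(2.0), abs=1e-9)

    def test_null_covariate_near_one(self):
        rng = np.random.default_rng(11)
        df = random_survival(rng, n=20_000, p=1, ties=False)
        fit = fit_cox(df, ["x1"])
        assert abs(fit.params["x1"]) < 3 * fit.se["x1"]

    def test_oracle_equivalence_many_datasets(self):
        # 50 random datasets incl. tied times: coefficients within 1e-6
        rng = np.random.default_rng(5)
        worst = 0.0
        for rep in range(50):
            df = random_survival(rng, n=rng.integers(60, 200), p=3,
                                 beta=[0.5, -0.3, 0.1], ties=bool(rep % 2))
            if df["event"].sum() < 10:
                continue
            fit = fit_cox(df, ["x1", "x2", "x3"])
            cph = CoxPHFitter().fit(
                df, "follow_up_years", "event", fit_options=LIFELINES_TIGHT
            )
            worst = max(worst, np.abs(fit.params.to_numpy() - cph.params_.to_numpy()).max())
            worst = max(worst, np.abs(fit.se.to_numpy() - cph.standard_errors_.to_numpy()).max())
        assert worst < 1e-6

    def test_no_events_rejected(self):
        df = pd.DataFrame({"x": [1.0, 0.0], "follow_up_years": [1.0, 2.0], "event": 0})
        with pytest.raises(ValueError, match="no events"):
            fit_cox(df, ["x"])

    def test_collinear_columns_named(self):
        rng = np.random.default_rng(2)
        df = random_survival(rng, n=100, p=2)
        df["x_dup"] = 2 * df["x1"] + 1
        with pytest.raises(ValueError, match="x_dup|x1"):
            fit_cox(df, ["x1", "x2", "x_dup"])

    def test_monotone_likelihood_flagged(self):
        # perfectly separating covariate -> divergent coefficient, not silent
        df = pd.DataFrame(
            {
                "x": [1.0, 1.0, 1.0, 0.0, 0.0, 0.0],
                "follow_up_years": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
                "event": [1, 1, 1, 1, 1, 1],
            }
        )
        with pytest.warns(RuntimeWarning, match="monotone"):
            fit = fit_cox(df, ["x"])
        assert not fit.converged

    def test_ci_brackets_hr(self, survival_frame):
        fit = fit_cox(survival_frame, ["x1", "x2", "x3"])
        s = fit.summary
        assert ((s["ci_low"] <= s["hr"]) & (s["hr"] <= s["ci_high"])).all()
        cov = fit.cov.to_numpy()
        assert np.allclose(cov, cov.T)
        assert np.all(np.linalg.eigvalsh(cov) > -1e-12)


class TestSchoenfeld:
    def test_oracle_p_values(self, survival_frame):
        fit = fit_cox(survival_frame, ["x1", "x2", "x3"])
        cph = CoxPHFitter().fit(
            survival_frame, "follow_up_years", "event", fit_options=LIFELINES_TIGHT
        )
        mine = schoenfeld_test(fit, "km")
        theirs = proportional_hazard_test(cph, survival_frame, time_transform="km")
        assert np.abs(mine.p_values.to_numpy() - np.asarray(theirs.p_value)).max() < 1e-4

    def test_detects_time_varying_effect(self):
        # effect sign flip over time -> strong violation at n=5000
        rng = np.random.default_rng(17)
        n = 5000
        x = rng.normal(size=n)
        early = rng.exponential(1 / np.exp(1.2 * x))
        late = 1.0 + rng.exponential(1 / np.exp(-1.2 * x))
        t = np.where(early < 1.0, early, late)
        df = pd.DataFrame({"x": x, "follow_up_years": np.minimum(t, 3.0),
                           "event": (t < 3.0).astype(int)})
        fit = fit_cox(df, ["x"])
        assert schoenfeld_test(fit).p_values["x"] < 0.05

    def test_too_few_events_rejected(self):
        df = pd.DataFrame({"x": [1.0, 0.0, 1.0], "follow_up_years": [1, 2, 3],
                           "event": [1, 0, 0]})
        fit = fit_cox(df, ["x"])
        with pytest.raises(ValueError, match="events"):
            schoenfeld_test(fit)


class TestRCS:
    def test_linear_tails(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 10, 500)
        knots = rcs_knots(x, 4)
        grid = np.linspace(knots[-1] + 0.5, knots[-1] + 5.0, 50)
        B = rcs_basis(grid, knots)
        # beyond the boundary knot every column is affine in x: second
        # differences vanish
        d2 = np.diff(B, n=2, axis=0)
        assert np.abs(d2).max() < 1e-8

    def test_nonlinearity_power_on_quadratic(self):
        rng = np.random.default_rng(21)
        n = 10_000
        x = rng.normal(size=n)
        eta = 0.35 * x**2
        t = rng.exponential(1 / (0.05 * np.exp(eta - eta.mean())))
        df = pd.DataFrame({"x": x, "follow_up_years": np.minimum(t, 12.0),
                           "event": (t < 12.0).astype(int)})
        sp = rcs_dose_response(df, "x")
        assert sp.p_nonlinearity < 0.05

    def test_curve_zero_at_reference(self):
        rng = np.random.default_rng(4)
        df = random_survival(rng, n=800, p=1, beta=[0.3], ties=False)
        sp = rcs_dose_response(df, "x1", reference=0.0)
        i0 = np.argmin(np.abs(sp.curve["exposure"]))
        # curve passes through ~0 at the reference by construction
        ref_val = (rcs_basis(np.array([0.0]), sp.knots)
                   - rcs_basis(np.array([sp.reference]), sp.knots)) @ sp.params.to_numpy()
        assert abs(ref_val[0]) < 1e-12

    def test_coincident_knots_rejected(self):
        x = np.array([1.0] * 96 + [2.0, 3.0, 4.0, 5.0])
        with pytest.raises(ValueError, match="knots"):
            rcs_knots(x, 4)


class TestTrend:
    def test_power_on_monotone_groups(self):
        rng = np.random.default_rng(9)
        n = 20_000
        g = rng.integers(0, 3, n)
        t = rng.exponential(1 / (0.05 * np.exp(0.2 * g)))
        df = pd.DataFrame({"grp": g, "follow_up_years": np.minimum(t, 10.0),
                           "event": (t < 10.0).astype(int)})
        assert trend_test(df, "grp", [0, 1, 2]) < 0.001

    def test_reversal_symmetry(self, survival_frame):
        df = survival_frame.copy()
        df["grp"] = (df["x1"] > 0).astype(int) + (df["x1"] > 1).astype(int)
        p_fwd = trend_test(df, "grp", [0, 1, 2])
        p_rev = trend_test(df, "grp", [2, 1, 0])
        assert p_fwd == pytest.approx(p_rev, rel=1e-9)

    def test_single_group_rejected(self, survival_frame):
        df = survival_frame.assign(grp=1)
        with pytest.raises(ValueError, match="2 ordered groups"):
            trend_test(df, "grp", [1])


@pytest.fixture(scope="module")
def scenario_dataset():
    from dietrisk import ScenarioConfig, run_scenario
    from dietrisk.synthetic_cohort import DEFAULT_COVARIATE_EFFECTS

    eff = dict(DEFAULT_COVARIATE_EFFECTS)
    eff["phd_per_sd"] = np.log(0.90)
    cfg = ScenarioConfig(n_participants=6000, seed=42, true_effects=eff)
    return run_scenario(cfg).dataset


class TestSuites:
    def test_main_suite_reference_convention(self, scenario_dataset):
        rep = run_main_suite(scenario_dataset, "all", "model1")
        qrows = rep[rep.term.str.startswith("phd_q")]
        assert len(qrows) == 5
        q1 = qrows[qrows.term == "phd_q1"].iloc[0]
        assert q1.hr == 1.0 and q1.ci_low == 1.0 and q1.ci_high == 1.0
        assert rep[rep.term == "phd_per_sd"].iloc[0].hr < 1.0

    def test_joint_suite_15_rows(self, scenario_dataset):
        rep = run_joint_suite(scenario_dataset, "men", "model1")
        assert len(rep) == 15
        ref = rep[rep.term == "q1_high"].iloc[0]
        assert ref.hr == 1.0

    def test_subgroup_bins_partition(self, scenario_dataset):
        rep = run_subgroup_suite(scenario_dataset, stratifiers=("bmi",), model="model1")
        assert rep["n"].sum() == len(scenario_dataset)
        # stratifier dropped inside its own strata: fits succeeded (hr finite)
        assert rep["hr"].notna().all()

    def test_sensitivity_washout_and_min2(self, scenario_dataset):
        rep = run_sensitivity_suite(scenario_dataset, model="model1")
        assert list(rep["stratum"]) == ["washout_2y", "min_2_assessments", "alternative_score"]
        full_n = len(scenario_dataset)
        assert rep[rep.stratum == "washout_2y"].iloc[0]["n"] <= full_n
        assert rep[rep.stratum == "min_2_assessments"].iloc[0]["n"] == int(
            (scenario_dataset["n_assessments"] >= 2).sum()
        )
        # identity re-run (c) matches the full-sample per-SD fit
        alt = rep[rep.stratum == "alternative_score"].iloc[0]
        assert alt["n"] == full_n

    def test_washout_removes_exactly_recent_events(self, scenario_dataset):
        ds = scenario_dataset
        mask = washout_mask(ds, 2.0)
        event_date = pd.to_datetime(ds["entry_date"]) + pd.to_timedelta(
            ds["follow_up_years"] * 365.25, unit="D"
        )
        gap = (event_date - pd.to_datetime(ds["last_recall_date"])).dt.days / 365.25
        expected = ds["event"].astype(bool) & (gap < 2.0)
        assert (mask == expected).all()
        assert mask.sum() > 0  # scenario produces some early events
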