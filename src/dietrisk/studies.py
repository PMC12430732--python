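"""Headline study scenarios: effect-injection and parameter-recovery runners.

Each runner builds a synthetic cohort whose generating Cox model carries a
caller-supplied set of true hazard ratios, pushes it through the full
pipeline (scoring, genetic risk, exclusions, outcome simulation), fits the
corresponding analysis model, and returns the recovered estimate with its
standard error.  Because the generating and fitted models coincide, the
estimate is consistent for the injected truth; the runners are the basis of
the package's end-to-end validation.
"""

from __future__ import annotations

import numpy as np

from .cohort_pipeline import build_design, model_covariates
from .scenario import run_scenario
from .survival_models import fit_cox, run_joint_suite
from .synthetic_cohort import DEFAULT_COVARIATE_EFFECTS, ScenarioConfig

__all__ = [
    "make_joint_effects",
    "recover_per_sd_hr",
    "recover_cprs_group_hr",
    "recover_joint_extreme_hr",
    "calibrated_incidence_pct",
]


def _model2_design(ds, stratified: bool):
    design = build_design(ds, model_covariates("model2", stratified_by_sex=stratified))
    design["follow_up_years"] = ds["follow_up_years"].astype(float)
    design["event"] = ds["event"].astype(int)
    return design


def recover_per_sd_hr(n: int, seed: int, true_hr: float) -> dict:
    """Inject a per-SD diet-score HR, refit the adjusted model, recover it."""
    effects = dict(DEFAULT_COVARIATE_EFFECTS)
    effects["phd_per_sd"] = np.log(true_hr)
    res = run_scenario(ScenarioConfig(n_participants=n, seed=seed, true_effects=effects))
    ds = res.dataset
    design = _model2_design(ds, stratified=False)
    design["phd_z"] = ds["phd_z"].to_numpy(dtype=float)
    adj = [c for c in design.columns if c not in ("phd_z", "follow_up_years", "event")]
    fit = fit_cox(design, ["phd_z"] + adj)
    beta, se = float(fit.params["phd_z"]), float(fit.se["phd_z"])
    return {
        "hr": float(np.exp(beta)),
        "beta": beta,
        "se": se,
        "true_hr": true_hr,
        "n": len(ds),
        "events": fit.n_events,
    }


def recover_cprs_group_hr(
    n: int, seed: int, hr_intermediate: float, hr_high: float, sex: str = "men"
) -> dict:
    """Single-sex cohort with genetic-risk group effects; report high vs low."""
    effects = dict(DEFAULT_COVARIATE_EFFECTS)
    effects.pop("sex_male", None)
    effects["cprs_intermediate"] = np.log(hr_intermediate)
    effects["cprs_high"] = np.log(hr_high)
    cfg = ScenarioConfig(
        n_participants=n, seed=seed, sex_ratio=1.0 if sex == "men" else 0.0,
        true_effects=effects,
    )
    res = run_scenario(cfg)
    ds = res.dataset
    design = _model2_design(ds, stratified=True)
    design["grp_intermediate"] = (ds["risk_group"].astype(str) == "intermediate").astype(float)
    design["grp_high"] = (ds["risk_group"].astype(str) == "high").astype(float)
    adj = [
        c
        for c in design.columns
        if c not in ("grp_intermediate", "grp_high", "follow_up_years", "event")
    ]
    fit = fit_cox(design, ["grp_intermediate", "grp_high"] + adj)
    beta, se = float(fit.params["grp_high"]), float(fit.se["grp_high"])
    return {
        "hr": float(np.exp(beta)),
        "beta": beta,
        "se": se,
        "true_hr": hr_high,
        "hr_intermediate": float(np.exp(fit.params["grp_intermediate"])),
        "n": len(ds),
        "events": fit.n_events,
    }


def make_joint_effects(
    hr_extreme: float, hr_intermediate_vs_low: float, hr_high_vs_low: float
) -> dict[str, float]:
    """True log-HR surface for the 15 joint groups vs the (Q1, high) reference.

    Additive in the log: a linear diet-quintile trend plus genetic-group
    offsets, anchored so the (Q5, low) contrast equals ``hr_extreme``.
    """
    b_low = -np.log(hr_high_vs_low)
    b_int = b_low + np.log(hr_intermediate_vs_low)
    slope = (np.log(hr_extreme) - b_low) / 4.0
    effects = {}
    for q in range(1, 6):
        for g, bg in (("low", b_low), ("intermediate", b_int), ("high", 0.0)):
            if q == 1 and g == "high":
                continue  # reference group
            effects[f"joint:q{q}_{g}"] = slope * (q - 1) + bg
    return effects


def recover_joint_extreme_hr(
    n: int,
    seed: int,
    sex: str,
    hr_extreme: float,
    hr_intermediate_vs_low: float,
    hr_high_vs_low: float,
    replicates: int = 1,
) -> dict:
    """Single-sex joint-analysis recovery of the (Q5, low) vs (Q1, high) HR.

    The extreme joint cell holds only ~4% of the cohort, so a single
    replicate carries substantial Monte-Carlo error; with ``replicates > 1``
    independent cohorts are simulated and the log-HR estimates combined by
    inverse-variance weighting, shrinking the Monte-Carlo SE by ~1/sqrt(K)
    without touching the estimator itself.
    """
    effects = dict(DEFAULT_COVARIATE_EFFECTS)
    effects.pop("sex_male", None)
    effects.update(make_joint_effects(hr_extreme, hr_intermediate_vs_low, hr_high_vs_low))

    betas, variances, n_total, ev_total = [], [], 0, 0
    report = None
    for k in range(replicates):
        cfg = ScenarioConfig(
            n_participants=n, seed=seed + 1_000_003 * k,
            sex_ratio=1.0 if sex == "men" else 0.0,
            true_effects=effects,
        )
        res = run_scenario(cfg)
        report = run_joint_suite(res.dataset, sex)
        row = report.loc[report["term"] == "q5_low"].iloc[0]
        b = float(np.log(row["hr"]))
        s = (np.log(row["ci_high"]) - np.log(row["ci_low"])) / (2 * 1.959963984540054)
        betas.append(b)
        variances.append(float(s) ** 2)
        n_total += len(res.dataset)
        ev_total += int(res.dataset["event"].sum())
    w = 1.0 / np.asarray(variances)
    beta = float(np.sum(w * np.asarray(betas)) / w.sum())
    se = float(np.sqrt(1.0 / w.sum()))
    return {
        "hr": float(np.exp(beta)),
        "beta": beta,
        "se": se,
        "true_hr": hr_extreme,
        "n": n_total,
        "events": ev_total,
        "report": report,
    }


def calibrated_incidence_pct(n: int, seed: int, target_incidence: float) -> dict:
    """Calibrate the baseline hazard to a target cumulative incidence and
    report the simulated percentage of participants with an event."""
    cfg = ScenarioConfig(
        n_participants=n, seed=seed, target_incidence=target_incidence,
    )
    res = run_scenario(cfg)
    inc = res.incidence
    se = float(np.sqrt(target_incidence * (1 - target_incidence) / len(res.dataset)))
    return {
        "incidence_pct": 100.0 * inc,
        "target_pct": 100.0 * target_incidence,
        "se_pct": 100.0 * se,
        "baseline_hazard": res.baseline_hazard,
        "n": len(res.dataset),
        "events": int(res.dataset["event"].sum()),
    }
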