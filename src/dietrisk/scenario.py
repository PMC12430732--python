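"""End-to-end scenario runner: generate, score, weight, filter, simulate, fit.

Glues the generator to the analysis stages in the order a real study would
run them: draw the cohort and genotypes, score the diet, build the
incidence-weighted genetic risk score and its groups, apply the exclusion
cascade, inject the configured true effects into an exponential
proportional-hazards model, and assemble the analysis dataset.  The result
carries everything the survival suites and the recovery checks need.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort_pipeline import (
    apply_exclusions,
    assign_quintiles,
    build_analysis_dataset,
    standardize_exposure,
    ExclusionAudit,
)
from .genetic_risk import IncidenceWeights, cprs_pipeline, default_incidence_weights
from .phd_scoring import score_cohort
from .synthetic_cohort import (
    RawCohort,
    ScenarioConfig,
    _admin_years,
    build_linear_predictor,
    calibrate_baseline_hazard,
    generate_cohort,
    generate_genotypes,
    simulate_survival,
)

__all__ = ["ScenarioResult", "run_scenario"]


@dataclass
class ScenarioResult:
    config: ScenarioConfig
    raw: RawCohort
    dosages: pd.DataFrame
    weights: pd.DataFrame
    phd: pd.DataFrame
    cprs: pd.DataFrame
    audit: ExclusionAudit
    eta: np.ndarray
    baseline_hazard: float
    outcomes: pd.DataFrame
    dataset: pd.DataFrame

    @property
    def incidence(self) -> float:
        return float(self.dataset["event"].mean())


def run_scenario(
    config: ScenarioConfig,
    model: str = "model2",
    incidence_weights: IncidenceWeights | None = None,
    stratified_by_sex: bool = False,
) -> ScenarioResult:
    """Run one simulated study end to end and return all intermediates."""
    raw = generate_cohort(config)
    dosages, weights = generate_genotypes(config)
    incidence_weights = incidence_weights or default_incidence_weights(config.n_sites)

    survivors, audit = apply_exclusions(raw.participants)
    surv = survivors.set_index("participant_id")

    phd = score_cohort(raw.diet[raw.diet["participant_id"].isin(surv.index)])
    sex = surv["sex"]
    cprs = cprs_pipeline(dosages.loc[surv.index], weights, incidence_weights, sex)
    cprs.index.name = "participant_id"

    # realized exposures on the analysis sample, used for effect injection
    expo = surv.copy()
    expo["phd_total"] = phd.set_index("participant_id")["phd_total"]
    expo["phd_z"], _ = standardize_exposure(expo["phd_total"])
    expo["risk_group"] = cprs["risk_group"].astype(str)
    q_sex, _ = assign_quintiles(expo["phd_total"], strata=expo["sex"])
    expo["joint_group"] = "q" + q_sex.astype(str) + "_" + expo["risk_group"]
    expo = expo.reset_index()

    eta = build_linear_predictor(expo, config.true_effects)
    if config.baseline_hazard is not None:
        h0 = config.baseline_hazard
    else:
        admin = _admin_years(expo["entry_date"], config.censor_date)
        h0 = calibrate_baseline_hazard(config.target_incidence, eta, admin)

    outcomes = simulate_survival(expo, eta, config, baseline_hazard=h0)

    dataset = build_analysis_dataset(
        survivors,
        phd,
        cprs.reset_index(),
        outcomes,
        model=model,
        stratified_by_sex=stratified_by_sex,
    )
    return ScenarioResult(
        config=config,
        raw=raw,
        dosages=dosages,
        weights=weights,
        phd=phd,
        cprs=cprs,
        audit=audit,
        eta=eta,
        baseline_hazard=h0,
        outcomes=outcomes,
        dataset=dataset,
    )
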