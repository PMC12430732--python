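"""Exclusion cascade, exposure derivation and analysis-dataset assembly.

The cohort enters as a raw participant table carrying exclusion flags and is
filtered through a fixed sequence of rules (baseline cancer, no dietary
questionnaire, non-European ancestry, missing polygenic-score inputs, loss
to follow-up, implausible energy intake), with a per-step audit trail in the
style of a study flowchart.  Attribution is sequential: a participant
removed by an earlier rule is never counted again by a later one, so the
per-step removal counts sum with the survivors to the initial n.

Downstream, continuous exposures are standardized (per-SD) and cut into
quintiles (Q1 = lowest fifth, reference), and the merged analysis dataset
is assembled for one of three covariate specifications:

* crude  -- exposure only;
* model1 -- + age, sex, BMI, total energy, first 10 genetic principal
  components;
* model2 -- model1 + income, education, Townsend deprivation index,
  alcohol status, smoking status, family history of cancer.

Categorical covariates keep an explicit "unknown" level (no imputation, no
listwise deletion) and are dummy-encoded against a declared reference level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ENERGY_BOUNDS",
    "CATEGORICAL_LEVELS",
    "ExclusionRule",
    "ExclusionAudit",
    "default_exclusion_rules",
    "apply_exclusions",
    "assign_quintiles",
    "standardize_exposure",
    "model_covariates",
    "build_design",
    "build_analysis_dataset",
]

# Sex-specific plausibility bounds on mean daily energy intake (kcal/day).
ENERGY_BOUNDS = {"men": (800.0, 4000.0), "women": (500.0, 3500.0)}

# Declared levels per categorical covariate; first level is the dummy
# reference.  "unknown" is a real level, mirroring explicit unknown/missing
# questionnaire responses.
CATEGORICAL_LEVELS: dict[str, tuple[str, ...]] = {
    "income": ("lt_18k", "18k_30k", "30k_52k", "52k_100k", "gt_100k", "unknown"),
    "education": ("high", "middle", "none", "unknown"),
    "smoking": ("never", "previous", "current", "unknown"),
    "alcohol": ("never", "previous", "current", "unknown"),
    "family_history": ("no", "yes", "unknown"),
}

MODEL_SPECS = ("crude", "model1", "model2")


@dataclass(frozen=True)
class ExclusionRule:
    name: str
    position: int
    description: str
    predicate: Callable[[pd.DataFrame], pd.Series]

    def mask(self, df: pd.DataFrame) -> pd.Series:
        return self.predicate(df).astype(bool)


@dataclass
class ExclusionAudit:
    """Per-rule entering / removed / remaining counts."""

    steps: list[dict] = field(default_factory=list)

    def add(self, rule: ExclusionRule, entering: int, removed: int) -> None:
        self.steps.append(
            {
                "position": rule.position,
                "rule": rule.name,
                "entering": entering,
                "removed": removed,
                "remaining": entering - removed,
            }
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps)

    def removed_by(self, rule_name: str) -> int:
        for s in self.steps:
            if s["rule"] == rule_name:
                return s["removed"]
        raise KeyError(rule_name)

    @property
    def final_n(self) -> int:
        return self.steps[-1]["remaining"] if self.steps else 0


def _need(df: pd.DataFrame, cols: Sequence[str], rule: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(
            f"exclusion rule {rule!r} needs missing field(s): {', '.join(missing)}"
        )


def _implausible_energy(df: pd.DataFrame) -> pd.Series:
    _need(df, ["sex", "energy_mean"], "implausible_energy")
    e = df["energy_mean"].to_numpy(dtype=float)
    men = (df["sex"] == "men").to_numpy()
    lo = np.where(men, ENERGY_BOUNDS["men"][0], ENERGY_BOUNDS["women"][0])
    hi = np.where(men, ENERGY_BOUNDS["men"][1], ENERGY_BOUNDS["women"][1])
    return pd.Series((e < lo) | (e > hi), index=df.index)


def default_exclusion_rules() -> list[ExclusionRule]:
    """The flowchart sequence, in order."""

    def flag(col):
        def pred(df, col=col):
            _need(df, [col], col)
            return df[col].astype(bool)

        return pred

    def no_diet(df):
        _need(df, ["n_assessments"], "no_dietary_questionnaire")
        return df["n_assessments"].fillna(0).astype(int) == 0

    def non_euro(df):
        _need(df, ["european_ancestry"], "not_european_ancestry")
        return ~df["european_ancestry"].astype(bool)

    def no_prs(df):
        _need(df, ["has_prs_data"], "missing_prs_data")
        return ~df["has_prs_data"].astype(bool)

    return [
        ExclusionRule("baseline_cancer", 1, "cancer diagnosis at baseline", flag("baseline_cancer")),
        ExclusionRule("no_dietary_questionnaire", 2, "no completed dietary assessment", no_diet),
        ExclusionRule("not_european_ancestry", 3, "not white European ancestry", non_euro),
        ExclusionRule("missing_prs_data", 4, "missing inputs for polygenic scores", no_prs),
        ExclusionRule("lost_to_followup", 5, "withdrawn or lost to follow-up", flag("lost_to_followup")),
        ExclusionRule(
            "implausible_energy",
            6,
            "mean energy outside sex-specific bounds "
            "(men <800 or >4000, women <500 or >3500 kcal/day)",
            _implausible_energy,
        ),
    ]


def apply_exclusions(
    participants: pd.DataFrame,
    rules: Sequence[ExclusionRule] | None = None,
) -> tuple[pd.DataFrame, ExclusionAudit]:
    """Apply the exclusion cascade sequentially, returning survivors + audit."""
    rules = default_exclusion_rules() if rules is None else rules
    audit = ExclusionAudit()
    current = participants
    for rule in rules:
        entering = len(current)
        drop = rule.mask(current)
        audit.add(rule, entering, int(drop.sum()))
        current = current.loc[~drop]
    return current.copy(), audit


def assign_quintiles(
    values: pd.Series, strata: pd.Series | None = None
) -> tuple[pd.Series, dict]:
    """Quintile labels 1..5 from empirical 20/40/60/80 percentile cut points.

    Boundary ties go to the lower quintile.  With ``strata`` given, cut
    points are computed within each stratum.  Returns (labels, cut points).
    """
    values = pd.Series(values)

    def _cuts_and_labels(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        if len(np.unique(v)) < 5:
            raise ValueError("need >= 5 distinct values to form quintiles")
        cuts = np.quantile(v, [0.2, 0.4, 0.6, 0.8])
        # searchsorted 'left' counts cuts strictly below v, so v == cut
        # lands in the lower quintile.
        return cuts, np.searchsorted(cuts, v, side="left") + 1

    labels = pd.Series(0, index=values.index, dtype=int, name="quintile")
    cutpoints: dict = {}
    if strata is None:
        cuts, lab = _cuts_and_labels(values.to_numpy(dtype=float))
        labels[:] = lab
        cutpoints["all"] = cuts
    else:
        strata = pd.Series(strata).reindex(values.index)
        for level, idx in values.groupby(strata).groups.items():
            cuts, lab = _cuts_and_labels(values.loc[idx].to_numpy(dtype=float))
            labels.loc[idx] = lab
            cutpoints[level] = cuts
    return labels, cutpoints


def standardize_exposure(values: pd.Series) -> tuple[pd.Series, float]:
    """(x - mean)/SD with the sample SD (n-1).  Returns (z, SD used)."""
    values = pd.Series(values).astype(float)
    if len(values) < 2:
        raise ValueError("need >= 2 values to standardize")
    sd = float(values.std(ddof=1))
    if sd == 0:
        raise ValueError("zero variance; cannot standardize")
    return (values - values.mean()) / sd, sd


def model_covariates(model: str, stratified_by_sex: bool = False) -> list[str]:
    """Covariate (pre-encoding) names for a model spec."""
    if model not in MODEL_SPECS:
        raise ValueError(f"unknown model spec {model!r}; expected one of {MODEL_SPECS}")
    if model == "crude":
        return []
    cols = ["age", "bmi", "energy_mean"] + [f"pc{i}" for i in range(1, 11)]
    if not stratified_by_sex:
        cols.insert(1, "sex")
    if model == "model2":
        cols += ["income", "education", "townsend", "alcohol", "smoking", "family_history"]
    return cols


def build_design(
    df: pd.DataFrame,
    columns: Sequence[str],
) -> pd.DataFrame:
    """Numeric design matrix: continuous columns as-is, categoricals dummy-coded.

    Categorical covariates use the declared level sets (unknown retained as
    an explicit level) with the first level as reference; ``sex`` is coded
    as an indicator for men.
    """
    out = {}
    for col in columns:
        if col not in df.columns:
            raise ValueError(f"design needs missing column {col!r}")
        if col == "sex":
            bad = set(df[col].unique()) - {"men", "women"}
            if bad:
                raise ValueError(f"unknown sex level(s): {sorted(bad)}")
            out["sex_men"] = (df[col] == "men").astype(float)
        elif col in CATEGORICAL_LEVELS:
            levels = CATEGORICAL_LEVELS[col]
            bad = set(df[col].unique()) - set(levels)
            if bad:
                raise ValueError(f"unknown level(s) for {col!r}: {sorted(bad)}")
            for lv in levels[1:]:
                dummy = (df[col] == lv).astype(float)
                if dummy.sum() > 0:
                    out[f"{col}_{lv}"] = dummy
        else:
            out[col] = df[col].astype(float)
    return pd.DataFrame(out, index=df.index)


def build_analysis_dataset(
    filtered: pd.DataFrame,
    phd: pd.DataFrame,
    cprs: pd.DataFrame,
    outcomes: pd.DataFrame,
    model: str = "model2",
    stratified_by_sex: bool = False,
) -> pd.DataFrame:
    """Join covariates, diet score, genetic risk and outcomes by participant.

    Inputs are keyed by ``participant_id`` (column or index).  The result
    carries the exposures (``phd_total``, ``phd_z``, ``phd_quintile``,
    ``cprs``, ``risk_group``), the model's covariates, ``follow_up_years``
    and ``event``; the chosen model spec is recorded in ``attrs``.
    """

    def keyed(df: pd.DataFrame, what: str) -> pd.DataFrame:
        if "participant_id" in df.columns:
            df = df.set_index("participant_id")
        if df.index.has_duplicates:
            raise ValueError(f"duplicate participant ids in {what} table")
        return df

    base = keyed(filtered, "cohort")
    for name, tab in (("phd", phd), ("cprs", cprs), ("outcomes", outcomes)):
        tab = keyed(tab, name)
        unmatched = base.index.difference(tab.index)
        if len(unmatched):
            raise ValueError(
                f"{len(unmatched)} participant(s) unmatched in {name} table "
                f"(e.g. {list(unmatched[:3])})"
            )
        cols = [c for c in tab.columns if c not in base.columns]
        base = base.join(tab[cols], how="left")

    covs = model_covariates(model, stratified_by_sex)
    needed = set(covs) | {"phd_total", "cprs", "risk_group", "follow_up_years", "event"}
    missing = [c for c in needed if c not in base.columns]
    if missing:
        raise ValueError(f"analysis dataset missing column(s): {', '.join(sorted(missing))}")
    for col in covs:
        if col in CATEGORICAL_LEVELS:
            bad = set(base[col].unique()) - set(CATEGORICAL_LEVELS[col])
            if bad:
                raise ValueError(f"unknown level(s) for {col!r}: {sorted(bad)}")

    ds = base.copy()
    ds["phd_z"], phd_sd = standardize_exposure(ds["phd_total"])
    strata = ds["sex"] if stratified_by_sex else None
    ds["phd_quintile"], qcuts = assign_quintiles(ds["phd_total"], strata=strata)
    ds.attrs.update(
        model=model,
        covariates=covs,
        phd_sd=phd_sd,
        phd_quintile_cuts=qcuts,
        stratified_by_sex=stratified_by_sex,
    )
    return ds
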