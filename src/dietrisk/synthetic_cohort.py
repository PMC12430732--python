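"""Synthetic prospective-cohort generator.

Emulates the statistical structure of a biobank-style prospective
diet/genetics cohort so the whole analysis pipeline can be exercised and validated
without data access: covariates calibrated to the study's baseline table,
right-skewed dietary intakes with a shared diet-quality latent factor,
binomial genotype dosages with per-site effect weights, exponential
proportional-hazards event times with uniform recruitment over 2006-2010
and administrative censoring on 2022-05-31, and the exclusion flags the
cohort pipeline consumes.

Effects are injected through a named map of true log hazard ratios
(per-SD diet score, genetic-risk group contrasts, joint-group contrasts,
covariate effects), so fitting the generating Cox model recovers known
truth.  All randomness flows through named sub-streams of a single seed
(covariates / diet / genotypes / survival), so perturbing one scenario
block leaves the others untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .phd_scoring import COMPONENTS

__all__ = [
    "DEFAULT_COVARIATE_EFFECTS",
    "DEFAULT_DIET_MEDIANS",
    "ScenarioConfig",
    "RawCohort",
    "generate_cohort",
    "generate_genotypes",
    "build_linear_predictor",
    "simulate_survival",
    "calibrate_baseline_hazard",
    "build_flowchart_fixture",
    "FLOWCHART_COUNTS",
]

DAYS_PER_YEAR = 365.25

# Realistic cancer-hazard covariate effects (log HR) used as generator
# defaults: hazard roughly doubles per decade of age, is higher in men,
# rises with adiposity, smoking and family history.
DEFAULT_COVARIATE_EFFECTS: dict[str, float] = {
    "age": 0.07,  # per year
    "sex_male": 0.25,
    "bmi": 0.015,  # per kg/m^2
    "smoking_previous": 0.15,
    "smoking_current": 0.45,
    "family_history_yes": 0.25,
}

# Median habitual intakes (g/day); zero-median items in the source cohort
# are given small positive medians because intakes here are log-normal.
DEFAULT_DIET_MEDIANS: dict[str, float] = {
    "vegetables": 284.75,
    "fruits": 280.0,
    "nuts": 12.0,
    "fish": 60.0,
    "legumes": 32.5,
    "unsaturated_fats": 13.17,
    "whole_grains": 150.0,
    "dairy": 95.0,
    "eggs": 20.0,
    "potatoes": 175.0,
    "poultry": 35.0,
    "saturated_fats": 28.2,
    "red_meat": 92.0,
    "added_sugars": 3.0,
}

# Loading of each component on the shared diet-quality latent factor:
# plant/adequacy foods rise together, moderation foods fall.
_DIET_LOADINGS: dict[str, float] = {
    **{c: 0.35 for c in ("vegetables", "fruits", "nuts", "fish", "legumes", "unsaturated_fats")},
    **{c: 0.12 for c in ("whole_grains", "dairy", "eggs", "potatoes", "poultry")},
    **{c: -0.18 for c in ("saturated_fats", "red_meat", "added_sugars")},
}

_DIET_SIGMA = 0.55  # between-person log-scale dispersion per component
_ASSESS_SIGMA = 0.25  # within-person recall noise (log scale)

_CATEGORICAL_PROBS = {
    # calibrated to the baseline characteristics table
    "income": {
        "lt_18k": 0.1344,
        "18k_30k": 0.2166,
        "30k_52k": 0.2586,
        "52k_100k": 0.2251,
        "gt_100k": 0.0663,
        "unknown": 0.0990,
    },
    "education": {"high": 0.4243, "middle": 0.4869, "none": 0.0850, "unknown": 0.0038},
    "smoking": {"never": 0.5642, "previous": 0.3571, "current": 0.0766, "unknown": 0.0021},
    "alcohol": {"current": 0.9451, "never": 0.0256, "previous": 0.0289, "unknown": 0.0004},
    "family_history": {"no": 0.5628, "yes": 0.3535, "unknown": 0.0837},
}


@dataclass(frozen=True)
class ScenarioConfig:
    """All knobs of one simulated study scenario.

    ``true_effects`` maps named effects to log hazard ratios; see
    :func:`build_linear_predictor` for the recognized names.
    ``baseline_hazard`` is events per person-year for a reference
    participant; when ``None`` it is calibrated so the expected cumulative
    incidence equals ``target_incidence``.
    """

    n_participants: int = 50_000
    seed: int = 0
    sex_ratio: float = 0.4629  # fraction of men
    true_effects: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS)
    )
    baseline_hazard: float | None = None
    recruitment_window: tuple[str, str] = ("2006-01-01", "2010-12-31")
    censor_date: str = "2022-05-31"
    n_sites: int = 20
    variants_per_site: int = 10
    maf_range: tuple[float, float] = (0.05, 0.45)
    target_incidence: float = 0.0872
    diet_medians: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DIET_MEDIANS)
    )
    assessment_probs: tuple[float, ...] = (0.45, 0.25, 0.15, 0.10, 0.05)
    exclusion_rates: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_participants < 0:
            raise ValueError("n_participants must be >= 0")
        if not 0 <= self.sex_ratio <= 1:
            raise ValueError("sex_ratio must lie in [0, 1]")
        if self.baseline_hazard is not None and self.baseline_hazard < 0:
            raise ValueError("baseline_hazard must be >= 0")
        lo, hi = self.maf_range
        if not (0 < lo <= hi < 0.5):
            raise ValueError("maf_range must lie within (0, 0.5)")
        if pd.Timestamp(self.recruitment_window[1]) >= pd.Timestamp(self.censor_date):
            raise ValueError("recruitment window must precede the censor date")
        if not 0 < self.target_incidence < 1:
            raise ValueError("target_incidence must lie in (0, 1)")
        if abs(sum(self.assessment_probs) - 1) > 1e-9:
            raise ValueError("assessment_probs must sum to 1")

    def with_(self, **kwargs) -> "ScenarioConfig":
        return replace(self, **kwargs)


@dataclass
class RawCohort:
    """Participant covariate table plus long-format dietary assessments."""

    participants: pd.DataFrame  # one row per participant, participant_id column
    diet: pd.DataFrame  # one row per (participant, assessment)

    @property
    def n(self) -> int:
        return len(self.participants)


def _streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(4)
    names = ("covariates", "diet", "genotypes", "survival")
    return {nm: np.random.default_rng(ss) for nm, ss in zip(names, children)}


def _categorical(rng, probs: Mapping[str, float], n: int) -> np.ndarray:
    levels = list(probs)
    p = np.array([probs[lv] for lv in levels], dtype=float)
    return rng.choice(levels, size=n, p=p / p.sum())


def generate_cohort(config: ScenarioConfig) -> RawCohort:
    """Draw covariates, exclusion flags and dietary assessments."""
    n = config.n_participants
    rngs = _streams(config.seed)
    rng = rngs["covariates"]

    part = pd.DataFrame({"participant_id": np.arange(1, n + 1)})
    a, b = (37 - 56.5) / 8.1, (73 - 56.5) / 8.1
    part["age"] = stats.truncnorm.rvs(a, b, loc=56.5, scale=8.1, size=n, random_state=rng)
    part["sex"] = np.where(rng.random(n) < config.sex_ratio, "men", "women")
    part["bmi"] = np.exp(rng.normal(np.log(26.25), 0.155, size=n))
    part["townsend"] = np.clip(rng.normal(-2.2, 2.7, size=n), -6.5, 11.0)
    energy_true = np.exp(rng.normal(np.log(2008.0), 0.257, size=n))
    for i in range(1, 11):
        part[f"pc{i}"] = rng.normal(size=n)
    for col, probs in _CATEGORICAL_PROBS.items():
        part[col] = _categorical(rng, probs, n)

    rates = dict(config.exclusion_rates)
    part["baseline_cancer"] = rng.random(n) < rates.get("baseline_cancer", 0.0)
    part["european_ancestry"] = ~(rng.random(n) < rates.get("not_european_ancestry", 0.0))
    part["has_prs_data"] = ~(rng.random(n) < rates.get("missing_prs_data", 0.0))
    part["lost_to_followup"] = rng.random(n) < rates.get("lost_to_followup", 0.0)

    start = pd.Timestamp(config.recruitment_window[0])
    end = pd.Timestamp(config.recruitment_window[1])
    span_days = (end - start).days
    part["entry_date"] = start + pd.to_timedelta(
        rng.integers(0, span_days + 1, size=n), unit="D"
    )

    # number of completed 24-h recalls (0 only via the exclusion rate)
    k_max = len(config.assessment_probs)
    n_assess = 1 + rng.choice(k_max, size=n, p=np.asarray(config.assessment_probs))
    no_diet = rng.random(n) < rates.get("no_dietary_questionnaire", 0.0)
    n_assess = np.where(no_diet, 0, n_assess)
    part["n_assessments"] = n_assess

    # shared diet-quality latent factor, mildly confounded with covariates
    drng = rngs["diet"]
    z_diet = (
        drng.normal(size=n)
        + 0.15 * (part["age"].to_numpy() - 57.0) / 8.1
        - 0.20 * (part["bmi"].to_numpy() - 26.25) / 4.0
        - 0.40 * (part["smoking"] == "current").to_numpy()
    )
    truth = {}
    for c in COMPONENTS:
        med = config.diet_medians[c]
        lam = _DIET_LOADINGS[c]
        truth[c] = med * np.exp(lam * z_diet + _DIET_SIGMA * drng.normal(size=n))

    rep = np.repeat(np.arange(n), n_assess)
    m = len(rep)
    assess_idx = np.concatenate([np.arange(k) for k in n_assess]) if m else np.array([], int)
    diet = pd.DataFrame(
        {
            "participant_id": part["participant_id"].to_numpy()[rep],
            "assessment": assess_idx + 1,
        }
    )
    for c in COMPONENTS:
        diet[c] = truth[c][rep] * np.exp(_ASSESS_SIGMA * drng.normal(size=m))
    diet["energy"] = energy_true[rep] * np.exp(0.12 * drng.normal(size=m))
    offsets = np.where(assess_idx == 0, 0.0, assess_idx * 0.4 + drng.uniform(0, 0.3, size=m))
    diet["date"] = part["entry_date"].to_numpy()[rep] + pd.to_timedelta(
        offsets * DAYS_PER_YEAR, unit="D"
    )

    if m:
        by = diet.groupby("participant_id")
        e_mean = by["energy"].mean()
        last = by["date"].max()
        part["energy_mean"] = (
            part["participant_id"].map(e_mean).fillna(pd.Series(energy_true, index=part.index))
        )
        part["last_recall_date"] = part["participant_id"].map(last).fillna(part["entry_date"])
    else:
        part["energy_mean"] = energy_true
        part["last_recall_date"] = part["entry_date"]
    return RawCohort(participants=part, diet=diet)


def generate_genotypes(config: ScenarioConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Binomial dosages (participants x variants) plus the per-site weight table."""
    if config.n_sites < 1 or config.variants_per_site < 1:
        raise ValueError("need n_sites >= 1 and variants_per_site >= 1")
    rng = _streams(config.seed)["genotypes"]
    n = config.n_participants
    m = config.n_sites * config.variants_per_site
    lo, hi = config.maf_range
    maf = rng.uniform(lo, hi, size=m)
    dose = rng.binomial(2, maf, size=(n, m)).astype(np.int8)
    variant_ids = [f"v{j + 1:05d}" for j in range(m)]
    dosages = pd.DataFrame(dose, columns=variant_ids)
    dosages.index = pd.Index(np.arange(1, n + 1), name="participant_id")
    weights = pd.DataFrame(
        {
            "variant_id": variant_ids,
            "effect_allele": ["A"] * m,
            "beta": rng.normal(0.0, 0.1, size=m),
            "site": [f"site_{j // config.variants_per_site + 1}" for j in range(m)],
            "maf": maf,
        }
    )
    return dosages, weights


def build_linear_predictor(df: pd.DataFrame, effects: Mapping[str, float]) -> np.ndarray:
    """Compose the true log-hazard linear predictor from named effects.

    Recognized names: ``phd_per_sd`` (needs ``phd_z``), ``cprs_intermediate``
    / ``cprs_high`` (needs ``risk_group``), ``joint:<label>`` (needs
    ``joint_group``), ``age`` (per year, centered), ``sex_male``, ``bmi``
    (per unit, centered), ``townsend`` (centered), ``<categorical>_<level>``
    indicators for smoking / alcohol / education / income / family_history.
    The result is mean-centered so the baseline hazard keeps its reference
    interpretation.
    """
    eta = np.zeros(len(df))
    for name, beta in effects.items():
        if name == "phd_per_sd":
            eta += beta * df["phd_z"].to_numpy(dtype=float)
        elif name in ("cprs_intermediate", "cprs_high"):
            level = name.split("_", 1)[1]
            eta += beta * (df["risk_group"].astype(str) == level).to_numpy(dtype=float)
        elif name.startswith("joint:"):
            label = name.split(":", 1)[1]
            eta += beta * (df["joint_group"].astype(str) == label).to_numpy(dtype=float)
        elif name == "age":
            eta += beta * (df["age"].to_numpy(dtype=float) - 57.0)
        elif name == "sex_male":
            eta += beta * (df["sex"] == "men").to_numpy(dtype=float)
        elif name == "bmi":
            eta += beta * (df["bmi"].to_numpy(dtype=float) - 26.25)
        elif name == "townsend":
            eta += beta * (df["townsend"].to_numpy(dtype=float) + 2.4)
        else:
            for col in ("smoking", "alcohol", "education", "income", "family_history"):
                if name.startswith(col + "_"):
                    level = name[len(col) + 1 :]
                    eta += beta * (df[col] == level).to_numpy(dtype=float)
                    break
            else:
                raise ValueError(f"unrecognized effect name {name!r}")
    return eta - eta.mean() if len(eta) else eta


def _admin_years(entry_date: pd.Series, censor_date: str) -> np.ndarray:
    return (
        (pd.Timestamp(censor_date) - pd.to_datetime(entry_date)).dt.days.to_numpy()
        / DAYS_PER_YEAR
    )


def simulate_survival(
    df: pd.DataFrame,
    eta: np.ndarray,
    config: ScenarioConfig,
    baseline_hazard: float | None = None,
) -> pd.DataFrame:
    """Exponential proportional-hazards event times with admin censoring.

    ``T ~ Exp(h0 * exp(eta))``; follow-up ends at the event or at the
    censor date, whichever comes first.
    """
    eta = np.asarray(eta, dtype=float)
    if not np.isfinite(eta).all():
        raise ValueError("linear predictor must be finite")
    h0 = config.baseline_hazard if baseline_hazard is None else baseline_hazard
    if h0 is None:
        raise ValueError("baseline hazard not set; calibrate or configure it")
    if h0 < 0:
        raise ValueError("baseline_hazard must be >= 0")
    rng = _streams(config.seed)["survival"]
    admin = _admin_years(df["entry_date"], config.censor_date)
    rate = h0 * np.exp(eta)
    with np.errstate(divide="ignore"):
        t_event = np.where(rate > 0, rng.exponential(1.0, size=len(df)) / np.where(rate > 0, rate, 1.0), np.inf)
    event = t_event < admin
    follow = np.minimum(t_event, admin)
    out = pd.DataFrame(
        {
            "participant_id": df["participant_id"].to_numpy(),
            "follow_up_years": follow,
            "event": event.astype(int),
            "entry_date": pd.to_datetime(df["entry_date"]).to_numpy(),
        }
    )
    out["exit_date"] = out["entry_date"] + pd.to_timedelta(follow * DAYS_PER_YEAR, unit="D")
    return out


def calibrate_baseline_hazard(
    target_incidence: float,
    eta: np.ndarray,
    admin_years: np.ndarray,
    tol: float = 1e-4,
) -> float:
    """Root-find h0 so expected cumulative incidence hits the target.

    The incidence map ``h0 -> mean(1 - exp(-h0 exp(eta) A))`` is strictly
    increasing, so bisection on a bracketed interval converges; tolerance is
    on the incidence scale.
    """
    if not 0 < target_incidence < 1:
        raise ValueError("target incidence must lie in (0, 1)")
    eta = np.asarray(eta, dtype=float)
    admin = np.asarray(admin_years, dtype=float)

    def expected(h0: float) -> float:
        return float(np.mean(-np.expm1(-h0 * np.exp(eta) * admin)))

    hi = 1e-3
    while expected(hi) < target_incidence:
        hi *= 4.0
        if hi > 1e6:
            raise ValueError("target incidence unattainable")
    h0 = optimize.brentq(
        lambda h: expected(h) - target_incidence, 0.0, hi, xtol=1e-14, rtol=1e-12
    )
    assert abs(expected(h0) - target_incidence) < tol
    return float(h0)


# Printed flowchart counts: initial cohort and sequential removals.
FLOWCHART_COUNTS = {
    "initial": 502_411,
    "baseline_cancer": 44_825,
    "no_dietary_questionnaire": 265_106,
    "not_european_ancestry": 9_169,
    "missing_prs_data": 3_611,
    "lost_to_followup": 11,
    "implausible_energy": 2_248,
    "final": 177_441,
}


def build_flowchart_fixture() -> RawCohort:
    """Deterministic cohort reproducing the selection flowchart exactly.

    Exclusion flags are assigned to sequential, mutually exclusive blocks
    of participants so each cascade step removes the printed count.
    """
    n = FLOWCHART_COUNTS["initial"]
    part = pd.DataFrame({"participant_id": np.arange(1, n + 1)})
    part["sex"] = np.where(part["participant_id"] % 2 == 0, "women", "men")
    part["baseline_cancer"] = False
    part["n_assessments"] = 1
    part["european_ancestry"] = True
    part["has_prs_data"] = True
    part["lost_to_followup"] = False
    part["energy_mean"] = 2000.0

    pos = 0
    blocks = [
        ("baseline_cancer", FLOWCHART_COUNTS["baseline_cancer"]),
        ("no_dietary_questionnaire", FLOWCHART_COUNTS["no_dietary_questionnaire"]),
        ("not_european_ancestry", FLOWCHART_COUNTS["not_european_ancestry"]),
        ("missing_prs_data", FLOWCHART_COUNTS["missing_prs_data"]),
        ("lost_to_followup", FLOWCHART_COUNTS["lost_to_followup"]),
        ("implausible_energy", FLOWCHART_COUNTS["implausible_energy"]),
    ]
    for name, count in blocks:
        sl = slice(pos, pos + count)
        if name == "baseline_cancer":
            part.loc[part.index[sl], "baseline_cancer"] = True
        elif name == "no_dietary_questionnaire":
            part.loc[part.index[sl], "n_assessments"] = 0
        elif name == "not_european_ancestry":
            part.loc[part.index[sl], "european_ancestry"] = False
        elif name == "missing_prs_data":
            part.loc[part.index[sl], "has_prs_data"] = False
        elif name == "lost_to_followup":
            part.loc[part.index[sl], "lost_to_followup"] = True
        elif name == "implausible_energy":
            # men below the male lower bound -> excluded; same value would
            # be retained for women (bounds are sex-specific)
            part.loc[part.index[sl], "sex"] = "men"
            part.loc[part.index[sl], "energy_mean"] = 700.0
        pos += count
    return RawCohort(participants=part, diet=pd.DataFrame(columns=["participant_id"]))
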