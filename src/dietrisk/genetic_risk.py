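"""Site-specific polygenic risk scores and the incidence-weighted composite.

A per-site polygenic risk score (PRS) is the additive weighted sum of risk
allele dosages: ``PRS[i, k] = sum_j dosage[i, j] * beta[j, k]`` over the
variants assigned to cancer site ``k``.  Site PRS are z-standardized within
sex so that sites with different panel sizes are on a common scale, then
combined into a single cancer polygenic risk score

    CPRS[i] = sum_k h[k] * PRS_z[i, k]

where ``h[k]`` is the age-standardized population incidence of site ``k``
(cases per 100 000 person-years, optionally sex-specific).  Sites that do
not apply to a participant's sex (e.g. prostate in women) are excluded via
the incidence-weight configuration.  Participants are finally grouped by
within-sex CPRS quintiles into low (lowest quintile), intermediate
(quintiles 2-4) and high (highest quintile) genetic risk.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "IncidenceWeights",
    "default_incidence_weights",
    "compute_site_prs",
    "compute_all_site_prs",
    "standardize_site_prs",
    "compute_cprs",
    "assign_risk_groups",
    "cprs_pipeline",
]

RISK_GROUPS = ("low", "intermediate", "high")

WEIGHT_COLUMNS = ("variant_id", "effect_allele", "beta", "site")


@dataclass(frozen=True)
class IncidenceWeights:
    """Per-site incidence weights, optionally sex-specific.

    ``rates`` maps site -> cases per 100 000 person-years.  ``sex_sites``
    maps each sex label to the list of sites that apply to that sex; a site
    absent from a sex's list contributes nothing to that sex's CPRS.
    """

    rates: dict[str, float]
    sex_sites: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for site, h in self.rates.items():
            if h < 0:
                raise ValueError(f"negative incidence weight for site {site!r}: {h}")
        for sex in self.sites_by_sex_labels():
            if not any(self.rates.get(s, 0.0) > 0 for s in self.sites_for(sex)):
                raise ValueError(f"no positive incidence weight for sex {sex!r}")

    def sites_by_sex_labels(self) -> tuple[str, ...]:
        return tuple(self.sex_sites) if self.sex_sites else ("men", "women")

    def sites_for(self, sex: str) -> tuple[str, ...]:
        if self.sex_sites:
            return tuple(self.sex_sites.get(sex, tuple(self.rates)))
        return tuple(self.rates)

    @classmethod
    def from_yaml(cls, path) -> "IncidenceWeights":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            rates={str(k): float(v) for k, v in raw["rates"].items()},
            sex_sites={
                sex: tuple(sites) for sex, sites in (raw.get("sex_sites") or {}).items()
            },
        )


def default_incidence_weights(n_sites: int = 20) -> IncidenceWeights:
    """Synthetic age-standardized rates: a smoothly decaying schedule.

    Real UK rates are not hard-coded; these defaults give the composite a
    realistic dominance structure (a few common sites, a long tail).
    """
    rates = {f"site_{k + 1}": 120.0 * 0.85**k + 5.0 for k in range(n_sites)}
    return IncidenceWeights(rates=rates)


def _check_weights(weights: pd.DataFrame) -> None:
    missing = [c for c in WEIGHT_COLUMNS if c not in weights.columns]
    if missing:
        raise ValueError(f"weight table missing column(s): {', '.join(missing)}")
    dup = weights.duplicated(subset=["variant_id", "site"])
    if dup.any():
        raise ValueError("duplicate (variant, site) pairs in weight table")


def compute_site_prs(
    dosages: pd.DataFrame, weights: pd.DataFrame, site: str
) -> pd.Series:
    """Raw additive PRS for one site: dose-weighted sum of effect sizes.

    ``dosages`` is participants x variants (values in [0, 2]); ``weights``
    has columns variant_id / effect_allele / beta / site.
    """
    _check_weights(weights)
    w = weights.loc[weights["site"] == site]
    if w.empty:
        raise ValueError(f"no variants assigned to site {site!r}")
    missing = [v for v in w["variant_id"] if v not in dosages.columns]
    if missing:
        raise ValueError(
            f"variant(s) missing from dosage matrix: {', '.join(map(str, missing))}"
        )
    sub = dosages[list(w["variant_id"])]
    if sub.isna().any().any():
        bad = sub.columns[sub.isna().any()].tolist()
        raise ValueError(
            "missing dosage entries (no silent imputation) in variant(s): "
            + ", ".join(map(str, bad))
        )
    vals = sub.to_numpy(dtype=float)
    if len(vals) and (vals.min() < 0 or vals.max() > 2):
        raise ValueError("dosages must lie in [0, 2]")
    # accumulate variant-by-variant in weight-table order: deterministic
    # summation order, so a per-participant loop reproduces it bit-exactly
    betas = w["beta"].to_numpy(dtype=float)
    prs = np.zeros(len(vals))
    for j in range(vals.shape[1]):
        prs += vals[:, j] * betas[j]
    return pd.Series(prs, index=dosages.index, name=site)


def compute_all_site_prs(dosages: pd.DataFrame, weights: pd.DataFrame) -> pd.DataFrame:
    """Raw PRS for every site in the weight table (participants x sites)."""
    _check_weights(weights)
    sites = list(dict.fromkeys(weights["site"]))
    return pd.DataFrame(
        {site: compute_site_prs(dosages, weights, site) for site in sites}
    )


def standardize_site_prs(raw: pd.DataFrame, sex: pd.Series) -> pd.DataFrame:
    """z-transform each site PRS within sex stratum (mean 0, SD 1 per site)."""
    sex = sex.reindex(raw.index)
    out = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for label, idx in raw.groupby(sex).groups.items():
        if len(idx) < 2:
            raise ValueError(f"need >= 2 participants in sex stratum {label!r}")
        block = raw.loc[idx]
        sd = block.std(ddof=1)
        degenerate = sd[sd == 0].index.tolist()
        if degenerate:
            raise ValueError(
                f"zero PRS variance in stratum {label!r} for site(s): "
                + ", ".join(map(str, degenerate))
            )
        out.loc[idx] = (block - block.mean()) / sd
    return out


def compute_cprs(
    site_prs_z: pd.DataFrame, weights: IncidenceWeights, sex: pd.Series
) -> pd.Series:
    """Incidence-weighted composite across the participant's sex-specific sites."""
    sex = sex.reindex(site_prs_z.index)
    cprs = pd.Series(0.0, index=site_prs_z.index, name="cprs")
    for label, idx in site_prs_z.groupby(sex).groups.items():
        sites = [s for s in weights.sites_for(str(label)) if weights.rates.get(s, 0) > 0]
        missing = [s for s in sites if s not in site_prs_z.columns]
        if missing:
            raise ValueError(
                f"site(s) in incidence weights but absent from PRS table: "
                + ", ".join(missing)
            )
        if sites:
            h = np.array([weights.rates[s] for s in sites])
            cprs.loc[idx] = site_prs_z.loc[idx, sites].to_numpy() @ h
    return cprs


def assign_risk_groups(cprs: pd.Series, sex: pd.Series) -> pd.Series:
    """Low / intermediate / high genetic risk from within-sex CPRS quintiles.

    Quintile cut points are the empirical 20/40/60/80 percentiles within each
    sex; boundary ties go to the lower group.
    """
    from .cohort_pipeline import assign_quintiles

    sex = sex.reindex(cprs.index)
    q, _ = assign_quintiles(cprs, strata=sex)
    group = pd.Series("intermediate", index=cprs.index, dtype=object)
    group[q == 1] = "low"
    group[q == 5] = "high"
    return pd.Series(
        pd.Categorical(group, categories=list(RISK_GROUPS), ordered=True),
        index=cprs.index,
        name="risk_group",
    )


def cprs_pipeline(
    dosages: pd.DataFrame,
    weights: pd.DataFrame,
    incidence: IncidenceWeights,
    sex: pd.Series,
) -> pd.DataFrame:
    """dosages -> per-site PRS -> within-sex z -> CPRS -> risk group."""
    raw = compute_all_site_prs(dosages, weights)
    z = standardize_site_prs(raw, sex)
    cprs = compute_cprs(z, incidence, sex)
    group = assign_risk_groups(cprs, sex)
    out = pd.DataFrame({"cprs": cprs, "risk_group": group})
    for site in raw.columns:
        out[f"prs_{site}"] = raw[site]
        out[f"prs_z_{site}"] = z[site]
    return out
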