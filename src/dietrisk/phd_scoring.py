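"""Planetary health diet (PHD) score: 14 components, 0-10 points each.

The PHD operationalizes the EAT-Lancet reference diet as an adherence score.
Each of 14 food components is scored on a 0-10 scale after normalizing the
intake to a 2500 kcal/day reference energy, and the component scores are
summed to a 0-140 total. Three scoring-rule classes are used:

* adequacy -- plant foods whose consumption is encouraged (vegetables,
  fruits, nuts, fish, legumes, unsaturated fats): score rises linearly from
  0 at zero intake to 10 at the recommended amount ``T`` and stays at 10
  above it.
* moderation -- foods to limit (saturated fats, red meat, added sugars):
  score falls linearly from 10 at zero intake to 0 at the upper limit ``L``
  and stays at 0 above it.
* balanced -- foods with a target window (whole grains, dairy, eggs,
  potatoes, poultry): a tent function peaking at 10 exactly at the target
  ``T`` and declining proportionally on both sides, so intakes of 50% or
  150% of the target score 5 points, and 0% or 200% score 0.

Reference amounts ship as an editable table of defaults drawn from the
EAT-Lancet 2500-kcal reference diet; every value can be overridden, and all
scoring logic is independent of the particular numbers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "COMPONENTS",
    "ComponentRule",
    "DietaryAssessment",
    "PHDResult",
    "default_rules",
    "load_rules",
    "average_assessments",
    "energy_adjust",
    "score_component",
    "compute_phd",
    "score_cohort",
]

#: The 14 PHD components, in canonical order.
COMPONENTS: tuple[str, ...] = (
    "vegetables",
    "fruits",
    "nuts",
    "fish",
    "legumes",
    "unsaturated_fats",
    "whole_grains",
    "dairy",
    "eggs",
    "potatoes",
    "poultry",
    "saturated_fats",
    "red_meat",
    "added_sugars",
)

_RULE_CLASSES = ("adequacy", "moderation", "balanced")

REFERENCE_ENERGY_KCAL = 2500.0


@dataclass(frozen=True)
class ComponentRule:
    """Scoring rule for one component.

    ``reference_amount`` is in g/day at the 2500 kcal reference energy and
    plays the role of the recommended maximum (adequacy), the upper limit
    (moderation) or the exact target (balanced).
    """

    component: str
    rule_class: str
    reference_amount: float

    def __post_init__(self) -> None:
        if self.rule_class not in _RULE_CLASSES:
            raise ValueError(
                f"unknown rule class {self.rule_class!r} for component "
                f"{self.component!r}; expected one of {_RULE_CLASSES}"
            )
        if not self.reference_amount > 0:
            raise ValueError(
                f"reference_amount must be > 0, got {self.reference_amount!r} "
                f"for component {self.component!r}"
            )


@dataclass(frozen=True)
class DietaryAssessment:
    """One 24-hour dietary recall: component intakes (g/day) plus energy."""

    participant_id: object
    intakes: Mapping[str, float]
    energy_kcal: float
    assessment_index: int = 0

    def __post_init__(self) -> None:
        missing = [c for c in COMPONENTS if c not in self.intakes]
        if missing:
            raise ValueError(f"missing component intake(s): {', '.join(missing)}")
        for c in COMPONENTS:
            if self.intakes[c] < 0:
                raise ValueError(f"negative intake for {c}: {self.intakes[c]}")
        if not self.energy_kcal > 0:
            raise ValueError(f"energy must be > 0 kcal/day, got {self.energy_kcal}")


@dataclass(frozen=True)
class PHDResult:
    participant_id: object
    component_scores: Mapping[str, float]
    total: float
    adjusted_intakes: Mapping[str, float]


# EAT-Lancet 2500-kcal reference diet amounts (g/day).  Overridable.
_DEFAULT_AMOUNTS: dict[str, tuple[str, float]] = {
    "vegetables": ("adequacy", 300.0),
    "fruits": ("adequacy", 200.0),
    "nuts": ("adequacy", 50.0),
    "fish": ("adequacy", 28.0),
    "legumes": ("adequacy", 75.0),
    "unsaturated_fats": ("adequacy", 40.0),
    "whole_grains": ("balanced", 232.0),
    "dairy": ("balanced", 250.0),
    "eggs": ("balanced", 13.0),
    "potatoes": ("balanced", 50.0),
    "poultry": ("balanced", 29.0),
    "saturated_fats": ("moderation", 11.8),
    "red_meat": ("moderation", 14.0),
    "added_sugars": ("moderation", 31.0),
}


def default_rules() -> dict[str, ComponentRule]:
    """The 14 default component rules keyed by component name."""
    return {
        c: ComponentRule(c, cls, amt) for c, (cls, amt) in _DEFAULT_AMOUNTS.items()
    }


def load_rules(path) -> dict[str, ComponentRule]:
    """Load component rules from a YAML/JSON table.

    The file maps component name to ``{class: ..., reference_amount: ...}``
    or is a list of ``{component, class, reference_amount}`` records.
    Components not mentioned fall back to the defaults.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    rules = default_rules()
    if isinstance(raw, list):
        raw = {rec["component"]: rec for rec in raw}
    for comp, rec in (raw or {}).items():
        if comp not in COMPONENTS:
            raise ValueError(f"unknown component in rules file: {comp!r}")
        rules[comp] = ComponentRule(
            comp,
            rec.get("class", rec.get("rule_class", rules[comp].rule_class)),
            float(rec.get("reference_amount", rules[comp].reference_amount)),
        )
    return rules


def average_assessments(
    assessments: Sequence[DietaryAssessment],
) -> DietaryAssessment:
    """Arithmetic mean of a participant's recalls, component-wise and for energy.

    Participants with repeated 24-hour recalls are summarized by the average
    intake of each item across all completed assessments.
    """
    if len(assessments) == 0:
        raise ValueError(
            "cannot average zero assessments; participants without dietary "
            "data should have been excluded upstream"
        )
    pids = {a.participant_id for a in assessments}
    if len(pids) > 1:
        raise ValueError(f"assessments belong to multiple participants: {pids}")
    mean_intakes = {
        c: float(np.mean([a.intakes[c] for a in assessments])) for c in COMPONENTS
    }
    mean_energy = float(np.mean([a.energy_kcal for a in assessments]))
    return DietaryAssessment(assessments[0].participant_id, mean_intakes, mean_energy)


def energy_adjust(intake, energy_kcal):
    """Rescale an intake (g/day) to the 2500 kcal/day reference energy."""
    intake = np.asarray(intake, dtype=float)
    energy = np.asarray(energy_kcal, dtype=float)
    if np.any(energy <= 0):
        raise ValueError("energy must be > 0 kcal/day")
    out = intake * (REFERENCE_ENERGY_KCAL / energy)
    return float(out) if out.ndim == 0 else out


def score_component(adjusted_intake, rule: ComponentRule):
    """Score one component (0-10) from its energy-adjusted intake.

    adequacy:   10 * min(1, x / T)
    moderation: 10 * max(0, 1 - x / L)
    balanced:   10 * max(0, 1 - |x - T| / T)
    """
    x = np.asarray(adjusted_intake, dtype=float)
    if np.any(x < 0):
        raise ValueError(f"adjusted intake must be >= 0 for {rule.component!r}")
    T = rule.reference_amount
    if rule.rule_class == "adequacy":
        s = 10.0 * np.minimum(1.0, x / T)
    elif rule.rule_class == "moderation":
        s = 10.0 * np.maximum(0.0, 1.0 - x / T)
    elif rule.rule_class == "balanced":
        s = 10.0 * np.maximum(0.0, 1.0 - np.abs(x - T) / T)
    else:  # pragma: no cover - blocked by ComponentRule validation
        raise ValueError(f"unknown rule class {rule.rule_class!r}")
    return float(s) if s.ndim == 0 else s


def compute_phd(
    assessment: DietaryAssessment,
    rules: Mapping[str, ComponentRule] | None = None,
) -> PHDResult:
    """Score one (averaged) assessment: energy-adjust, score, and sum."""
    rules = default_rules() if rules is None else rules
    missing = [c for c in COMPONENTS if c not in rules]
    if missing:
        raise ValueError(f"missing scoring rule(s) for: {', '.join(missing)}")
    adjusted = {
        c: energy_adjust(assessment.intakes[c], assessment.energy_kcal)
        for c in COMPONENTS
    }
    scores = {c: score_component(adjusted[c], rules[c]) for c in COMPONENTS}
    return PHDResult(
        participant_id=assessment.participant_id,
        component_scores=scores,
        total=float(sum(scores.values())),
        adjusted_intakes=adjusted,
    )


def score_cohort(
    diet: pd.DataFrame,
    rules: Mapping[str, ComponentRule] | None = None,
) -> pd.DataFrame:
    """Vectorized PHD scoring for a long-format assessment table.

    ``diet`` has one row per (participant, assessment) with columns
    ``participant_id``, the 14 component columns (g/day) and ``energy``
    (kcal/day).  Intakes are first averaged across each participant's
    assessments, then scored.  Returns one row per participant with
    ``n_assessments``, ``score_<component>`` columns, ``energy_mean`` and
    ``phd_total``.
    """
    rules = default_rules() if rules is None else rules
    missing = [c for c in COMPONENTS if c not in diet.columns]
    if missing:
        raise ValueError(f"diet table missing component column(s): {', '.join(missing)}")
    if "energy" not in diet.columns:
        raise ValueError("diet table missing 'energy' column")

    grouped = diet.groupby("participant_id", sort=True)
    means = grouped[list(COMPONENTS) + ["energy"]].mean()
    n_assess = grouped.size()
    if np.any(means["energy"].to_numpy() <= 0):
        raise ValueError("non-positive mean energy encountered")

    out = pd.DataFrame(index=means.index)
    out["n_assessments"] = n_assess
    out["energy_mean"] = means["energy"]
    total = np.zeros(len(means))
    for c in COMPONENTS:
        adj = energy_adjust(means[c].to_numpy(), means["energy"].to_numpy())
        s = score_component(adj, rules[c])
        out[f"score_{c}"] = s
        total += s
    out["phd_total"] = total
    return out.reset_index()
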