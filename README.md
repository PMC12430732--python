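# dietrisk

Diet quality, inherited risk, and cancer incidence in a prospective cohort:
a tested, end-to-end analysis pipeline with a synthetic-cohort generator.

## The problem

Large biobank studies ask whether adherence to the EAT-Lancet *planetary
health diet* (PHD) is associated with lower overall cancer incidence, whether
the association differs by sex, and how it combines with inherited
susceptibility summarized by polygenic risk scores. Answering this requires a
chain of non-trivial components:

1. **PHD scoring** — 14 dietary components, each scored 0–10 after
   normalizing intakes to a 2500 kcal/day reference energy
   (`adjusted = intake × 2500 / energy`), summed to a 0–140 score.
   Three rule classes: *adequacy* (score `10·min(1, x/T)`), *moderation*
   (`10·max(0, 1 − x/L)`), and *balanced* (tent function
   `10·max(0, 1 − |x − T|/T)`, so 50% or 150% of the target halves the
   score). Repeated 24-h recalls are averaged before scoring.
2. **Composite genetic risk (CPRS)** — per cancer site *k*, an additive
   polygenic score `PRS_ik = Σ_j dosage_ij · β_jk`, z-standardized within
   sex, then combined with age-standardized population incidence weights:
   `CPRS_i = Σ_k h_k · PRS_ik`. Participants are grouped by within-sex CPRS
   quintiles into low (Q1) / intermediate (Q2–4) / high (Q5) genetic risk.
3. **Cohort pipeline** — a six-step exclusion cascade with a flowchart-style
   audit (baseline cancer → no dietary questionnaire → non-European ancestry
   → missing PRS inputs → loss to follow-up → implausible energy intake with
   sex-specific bounds), exposure quintiles and per-SD standardization, and
   covariate encodings for three nested Cox models (crude / Model 1 /
   Model 2).
4. **Survival analysis** — Cox proportional hazards fitted by
   Newton–Raphson on the Efron-corrected partial likelihood (implemented
   here from first principles and cross-checked against `lifelines`),
   Schoenfeld-residual proportional-hazards tests, restricted-cubic-spline
   dose–response with a likelihood-ratio nonlinearity test, ordinal trend
   tests, and reporting suites: main (quintile + per-SD), joint 15-group
   (PHD quintile × genetic-risk group, reference = lowest diet quintile with
   high genetic risk), subgroup, and sensitivity re-fits.
5. **Synthetic cohort generator** — because individual-level biobank data
   cannot be redistributed, the package ships a generator that reproduces
   the statistical structure the analysis assumes: covariates calibrated to
   the study's baseline table, right-skewed correlated dietary intakes,
   binomial genotype dosages, exponential proportional-hazards event times
   with uniform 2006–2010 recruitment and administrative censoring on
   2022-05-31, and a named map of true log hazard ratios injected into the
   generating model so that every estimate the pipeline produces can be
   checked against known truth.

## Worked example

```python
import numpy as np
from dietrisk import ScenarioConfig, run_scenario
from dietrisk.survival_models import run_main_suite
from dietrisk.synthetic_cohort import DEFAULT_COVARIATE_EFFECTS

effects = dict(DEFAULT_COVARIATE_EFFECTS, phd_per_sd=np.log(0.95))
res = run_scenario(ScenarioConfig(n_participants=40_000, seed=20251002,
                                  true_effects=effects))
report = run_main_suite(res.dataset, sex="all", model="model2")
print(report[report.term == "phd_per_sd"])
```

With a true per-SD hazard ratio of 0.95 injected, the run above prints
(`analysis/05_survival_suites.py` is the full script):

```
analysis set: 39377 participants, 3514 events
per-SD HR 0.958 (0.926-0.991), p-trend 0.021, p-nonlinearity 0.13, PH global p 0.31  [truth 0.95]
```

The fitted hazard ratio per standard deviation of PHD score (0.958) recovers
the generating value within its confidence interval; the spline finds no
spurious nonlinearity and the Schoenfeld test no proportional-hazards
violation, as expected under this generating model. The numbered scripts
under `analysis/` walk the pipeline stage by stage (simulation, scoring,
genetic risk, flowchart, suites, recovery checks) and write their tables
under `results/`.

The exclusion-cascade driver reproduces the selection flowchart exactly:

```
 position                     rule  entering  removed  remaining
        1          baseline_cancer    502411    44825     457586
        2 no_dietary_questionnaire    457586   265106     192480
        ...
        6       implausible_energy    179689     2248     177441
```

## Layout

```
src/dietrisk/          library: phd_scoring, genetic_risk, cohort_pipeline,
                       survival_models, synthetic_cohort, scenario, studies, cli
analysis/              numbered narrative drivers over the library
tests/                 pytest suite (unit, property and end-to-end recovery)
scripts/acceptance.py  from-scratch recomputation of the headline quantities
docs/methods.md        models, assumptions, parameter choices, limitations
```
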