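# Methods

This note documents the models, the parameter choices that matter, what the
synthetic data do and do not emulate, and the numerical conventions. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Diet score

The planetary health diet score sums 14 component scores, each on a 0–10
scale, for a 0–140 total. Intakes (g/day) are first averaged across a
participant's repeated 24-hour recalls (arithmetic mean, component-wise and
for energy), then rescaled to a 2500 kcal/day reference energy
(`x_adj = x · 2500 / E`), so the score reflects dietary composition rather
than total consumption; multiplying all intakes and energy by a common
factor leaves every score unchanged (a tested invariant).

Rule classes and their shapes:

| class | components | score |
|---|---|---|
| adequacy | vegetables, fruits, nuts, fish, legumes, unsaturated fats | `10·min(1, x/T)` |
| balanced | whole grains, dairy, eggs, potatoes, poultry | `10·max(0, 1 − |x−T|/T)` |
| moderation | saturated fats, red meat, added sugars | `10·max(0, 1 − x/L)` |

Conventions that were genuinely open and are fixed here: adequacy passes
through the origin (zero intake = 0 points, full non-adherence); moderation
declines linearly from the first gram with no tolerance band; the
"optimum"-type components use the tent rule, the only shape under which
deviations below and above the target are penalized proportionally and 50%
or 150% of the target halves the score (implying 0 points at 0% and 200%).
The default reference amounts are the EAT-Lancet 2500-kcal reference diet
values (e.g. vegetables 300 g/d, red meat 14 g/d); they ship as an editable
table (`rules.yaml` accepted by the CLI) because the analysis logic must not
depend on any particular cut-off set, and all rule tests are written against
symbolic T/L.

Out of scope: the crosswalk from questionnaire food items to the 14
components (consumed as pre-aggregated g/day columns), and alternative
scoring systems (a pluggable-rules hook exists in the sensitivity suite).

## Composite genetic risk

Per-site polygenic scores are plain additive dosage-weighted sums. Raw PRS
scales depend arbitrarily on panel size and effect-size units, so site
scores are z-standardized **within sex** before combination; the
age-standardized incidence weight `h_k` is then the sole determinant of a
site's influence on the composite `CPRS = Σ_k h_k · PRS_z,k`. Incidence
weights are an editable config (site, rate per 100 000 person-years,
optional sex-specific site lists, e.g. prostate male-only); the shipped
defaults are a synthetic decaying schedule, not real national rates.
Genetic-risk groups are within-sex CPRS quintiles: low (Q1), intermediate
(Q2–4), high (Q5). Group assignment is invariant to any increasing
transform of CPRS, so the weight scale (per 100 000 vs proportion) cannot
affect it.

## Cohort pipeline

Exclusions run strictly in flowchart order with first-match attribution:
each participant is counted against the first rule that removes them, so
per-step counts depend on rule order but the surviving set does not
(set-difference semantics, asserted on crafted overlapping fixtures).
Energy plausibility uses the sex-specific bounds (men 800–4000, women
500–3500 kcal/day) applied to the mean energy across assessments.

Quintiles use empirical 20/40/60/80 percentile cut points (linear
interpolation) with boundary ties assigned to the lower quintile; on
177 441 distinct values this yields group sizes 35 489 / 35 488 ×4. The
main analysis computes quintiles on the pooled analysis sample; the joint
15-group analysis recomputes them within sex, matching the sex-separated
design of that analysis. Per-SD exposures use the sample SD (n−1).

Categorical covariates (income, education, smoking, alcohol, family
history) retain an explicit `unknown` level — no imputation and no listwise
deletion — and are dummy-coded against a declared reference level. Model 1
adjusts for age, sex, BMI, total energy and 10 genetic principal
components; Model 2 adds income, education, Townsend index, alcohol,
smoking and family history. Sex-stratified fits drop the sex indicator.

## Cox engine and diagnostics

The partial likelihood uses the Efron tie correction and is maximized by
Newton–Raphson with step-halving on an internally standardized design
(columns centered and scaled; estimates and covariance transformed back).
Convergence: max |score| < 1e-8 or relative log-likelihood change < 1e-10;
rank-deficient designs are rejected naming the collinear columns (QR with
pivoting); coefficients whose original-scale magnitude exceeds 15 at
termination are flagged as monotone-likelihood divergence and the fit is
marked non-converged rather than silently returned. A rare dummy level
with no events in its carriers is the typical benign trigger: its CI is
infinite, other coefficients are unaffected. Wald CIs are
`exp(β̂ ± 1.96·SE)` from the inverse observed information. Follow-up time
(years since recruitment) is the time scale, with age as a covariate.

The proportional-hazards check is the Grambsch–Therneau score test:
Efron-consistent Schoenfeld residuals, scaled by `d·V̂`, correlated with
Kaplan-Meier-transformed event times (`g(t) = 1 − KM(t)`); per-covariate
χ²(1) statistics plus a global quadratic form on χ²(p). The per-covariate
p-values are test-verified to 1e-4 against `lifelines`'
`proportional_hazard_test`, and both the PH and the spline nonlinearity
test hold 5% ± 2% type-I error over 500 null replicates in the acceptance
suite.

Restricted cubic splines use Harrell's basis (normalized by
`(t_K − t_1)²`, linear beyond the boundary knots) with 4 knots at the
5/35/65/95 percentiles by default (3 or 5 knots configurable);
nonlinearity is the likelihood-ratio test of the K−2 nonlinear terms.
The dose–response curve reports the log-HR relative to the exposure median
with pointwise Wald bands. Trend tests use integer-coded ordinal groups
(the median-per-quintile alternative coding was not adopted; the choice
only affects the trend statistic, not the group contrasts). BMI subgroup
bins are <24 / 24–28 (boundaries inclusive) / >28 kg/m².

## Synthetic cohort

The generator emulates the *structure* the analysis assumes, at desk scale:

- **Covariates** calibrated to the study's baseline table: age truncated
  normal 37–73 (median ≈ 57), 46.29% men, log-normal BMI (median 26.25)
  and energy (median 2008 kcal/d), Townsend ≈ N(−2.2, 2.7), categorical
  distributions matching the published percentages including their
  `unknown` shares, 10 standard-normal principal components.
- **Diet**: per-component log-normal intakes with configurable medians
  (Table-level defaults, e.g. vegetables 284.75 g/d) sharing a latent
  diet-quality factor (loadings +0.35 plant/adequacy, +0.12 balanced,
  −0.18 moderation; dispersion 0.55) that is mildly confounded with age,
  BMI and current smoking — so crude and adjusted estimates genuinely
  differ and Model-2 adjustment is exercised. 1–5 recalls per participant
  (probabilities 0.45/0.25/0.15/0.10/0.05) with 0.25 log-scale recall
  noise.
- **Genotypes**: per-variant MAF ~ U(0.05, 0.45), Hardy–Weinberg binomial
  dosages, N(0, 0.1) effect sizes, 20 sites × 10 variants by default. No
  linkage disequilibrium or ancestry structure — group assignment, not
  genetic architecture, is what the analysis consumes.
- **Survival**: exponential event times `T ~ Exp(h0·e^η)` (constant
  baseline hazard — Cox estimation is invariant to the baseline shape and
  the exponential gives closed forms for calibration tests), entry uniform
  over 2006-01-01..2010-12-31, administrative censoring 2022-05-31, no
  competing risks. The linear predictor η is assembled from a named map of
  true log hazard ratios over *realized* exposures (per-SD diet score,
  genetic-risk groups, joint groups, covariates), so the generating model
  and the fitted model coincide and every estimate has a known truth.
  Default covariate effects: age +0.07/yr, male +0.25, BMI +0.015/unit,
  smoking +0.45/+0.15 (current/previous), family history +0.25.
- **Calibration**: `h0` is root-found (Brent) so the expected cumulative
  incidence `mean(1 − exp(−h0·e^η·A_i))` hits a target (default 8.72%)
  to 1e-4; the map is strictly increasing in `h0`.
- Exclusion-flag rates default to zero: the generator produces an
  analysis-ready population, while the deterministic flowchart fixture
  (502 411 records, block-assigned flags) exercises the full cascade with
  the exact published counts.

Randomness flows through four named sub-streams of one seed (covariates /
diet / genotypes / survival), so reconfiguring one block does not perturb
the draws of the others; identical configs give byte-identical cohorts.

**What passing tests do not show about real data.** Intakes are continuous
log-normals: the heavy zero-inflation of real recall data (many true zero
consumers of nuts, fish, added sugar) is not modeled, and components with
published zero medians were given small positive default medians. Diet is
measured with independent multiplicative noise, not the correlated,
systematic misreporting of real questionnaires. There is no death as a
competing risk, no loss to follow-up during the study, no LD, and no
population stratification. Recovery of an injected effect therefore
validates the estimator chain, not the causal interpretability of the
real-world estimates.

## Problem sizes

The test suite runs its end-to-end recovery checks at n = 50 000 (one
replicate each) and the type-I calibrations at 500 replicates of n = 2 000;
`scripts/acceptance.py` uses n = 200 000 (per-SD), 80 000 (men's genetic
risk and joint), 95 000 (women's joint) and 100 000 (incidence
calibration). The joint extreme cell holds only ~4% of a cohort, so its
log-HR carries ~0.09 Monte-Carlo SE per replicate; the acceptance script
averages four independent replicates by inverse-variance weighting
(SE ≈ 0.045) — a variance reduction of an unbiased estimator, with each
replicate at the full per-cohort size.

## Known limitations

- The pluggable alternative-scoring hook re-runs the default rules unless
  an alternative score vector is supplied; no second scoring system ships.
- The Wald trend test and ordinal coding are one of several defensible
  conventions; likewise the 4-knot RCS default.
- Quintile cut points use linear-interpolated percentiles; other quantile
  definitions shift boundary membership by at most one participant.
- The CLI reads whole TSVs into memory; it is sized for cohorts of a few
  hundred thousand rows, not millions.
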