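# Methods

## Model structure and assumptions

The engine (`chfcea.markov_engine`) is a deterministic two-state Markov
cohort model with monthly cycles over a lifetime horizon (480 cycles, which
takes the default 60-year-old cohort to age 100). The alive fraction at the
start of cycle *m* is the product of two independent survival processes:

* **CV mortality** — Gompertz proportional hazards, `h(t) = λ·e^{γt}`, with
  cumulative hazard `H(t) = (λ/γ)(e^{γt}−1)` computed via `expm1` (the
  γ→0 limit reduces exactly to the exponential). The treatment hazard ratio
  enters as `S^HR`. Exponential, Weibull and Kaplan–Meier (step function,
  extended beyond its support at its average within-support hazard) are
  alternative baselines for structural sensitivity analysis.
* **Non-CV mortality** — annual life-table probabilities converted to a
  constant monthly factor `(1−qx)^{1/12}` within each attained year of age;
  the cohort is a mixture of the two sexes (mixture of survival curves).
  Identical across arms; no cause-deletion adjustment is applied to the
  all-cause table, matching the original model's use of national rates as a
  proxy for non-CV mortality.

NYHA occupancy and hospital admissions are overlays on the alive state (not
separate states): occupancy weights utilities; the admission rate (constant
per patient-month, unaffected by ageing) accrues episode costs and a
one-cycle utility decrement per expected admission — the one-month duration
mirrors the ±30-day window used when the utility regression was estimated.
Membership for accrual is the alive fraction at cycle start (deaths at cycle
boundaries); a half-cycle correction is available as a flag but off in the
base case, where calibration absorbs the difference. Discounting is
`(1+r)^{−m/12}` with r = 3.5%/year for both costs and effects.

With a finite treatment duration the drug cost always stops at
discontinuation. Whether the clinical effects (HR, RR) persist afterwards is
genuinely undetermined; the published 5-year-duration scenario *lowers* the
ICER, which is only possible when effects outlast the drug cost, so
`discontinuation='persist'` is the scenario default and `'revert'`
(hazards return to baseline, the accrued survival advantage is kept) is a
config option.

## Key parameters

| parameter | default | units | source/rationale |
|---|---|---|---|
| hr_cv | 0.90 (0.80–1.03) | hazard ratio | published treatment effect on CV death |
| rr_hosp | 0.83 (0.78–0.93) | rate ratio | published effect on all-cause admissions |
| gompertz_shape γ | 0.01 | /month | package-wide default baseline shape (see calibration) |
| gompertz_rate λ | calibrated (≈0.0060) | /month | matched to SoC discounted LY 5.61 |
| hosp_rate_soc | calibrated (≈0.0405) | admissions/patient-month | matched to SoC hospitalization cost €1,781 |
| NYHA mix | calibrated (≈0.05/0.68/0.26/0.01) | occupancy | matched to SoC QALY 3.99 via one severity shift |
| utilities | 0.82/0.74/0.64/0.46 | EQ-5D utility | published per-class values |
| admission decrements | 0.04/0.07/0.10/0.29 | utility, 1 cycle | published per-class hospitalization offsets |
| costs | 40.52/35.26/26.05/3.44 € | per month / one-off | published 2013 tariffs, used as given (whether pre- or post-rebate is unstated) |
| per-diems, LoS | 200/110 €, 7/4/5 d | — | published; HF episodes: 30% ICU (3 d) + ward (4 d) |
| cause_mix | 0.45/0.30/0.25 | proportion | chosen so the mixture LoS ≈ the stated 5-day all-cause average |
| discount | 0.035 | /year | published |
| threshold | 36,000 | €/QALY | ≈2× GDP per capita (18,000 €); 1× and 3× reported via the CEAC grid |

Rebates (9% positive-list + 5% volume, both on the ex-factory base) are
applied additively in `net_price`; sequential compounding is a flag (the
difference is 0.45 points at 9%+5%). Non-CV admissions are costed at the
5-day all-cause stay in a cardiac ward because no separate non-CV per-diem
exists.

## Calibration

The published model's fitted coefficients are unavailable, so
`chfcea.calibration` matches the SoC arm to the three published SoC outputs
(discounted LY 5.61, QALY 3.99, hospitalization cost €1,781) by
least-squares on relative errors with Latin-hypercube multi-start. Three
free parameters keep the problem exactly identified: log λ, log admission
rate, and a single severity shift on the cumulative logits of a reference
NYHA mix (2/50/45/3%). The Gompertz shape γ is **not identified** by these
targets — every (λ, γ) pair on an iso-LY curve fits them equally — so it is
fixed at 0.01/month, the same shape used as the synthetic-trial ground
truth, giving one coherent baseline hazard across the package. The published
SoC total cost (€5,873) is reported as a consistency residual only: it is
€35 below what its own printed components sum to, an inconsistency of the
source table that calibration does not try to resolve.

Round-trip recovery (targets produced by the engine at known parameters are
recovered within 1%) is the primary correctness property of this stage.

## What replication can and cannot reproduce

Applying only the published effects (HR, RR, drug cost, ECG) to the
calibrated SoC arm yields ΔLY ≈ 0.29, ΔQALY ≈ 0.21, ΔCost ≈ €2,862 and an
ICER ≈ €13,600/QALY, versus the published 0.25 / 0.28 / €2,792 / €9,986.
The gap is structural, not numerical: the published ΔQALY (0.28) *exceeds*
ΔLY (0.25), which is impossible when both arms share the same NYHA/utility
structure — mean utility per life-year is ≈0.71, so arm-identical weights
give ΔQALY ≈ 0.71·ΔLY ≤ 0.21 for any ΔLY ≤ 0.29. The original risk
equations predicted NYHA class and quality of life *by treatment
allocation*, and that arm-specific benefit (≈ +0.017 utility per alive
month in the ivabradine arm, by back-calculation) was never published. We
deliberately do not back-fit it from the ivabradine arm's own printed
outputs — that would make the replication circular — so the model here
understates ΔQALY and overstates the ICER by roughly a third, while the
ivabradine arm's absolute QALYs (4.20 vs 4.27) and the SoC-side quantities
reproduce closely. The engine supports arm-specific NYHA models
(`nyha=NYHAModel`, fitted per arm) for users with patient-level data.

Published cost components are also internally inconsistent with flat
monthly costing (HF management lower, hospitalization cost higher in the
ivabradine arm than person-month arithmetic allows); with the flat €26.05
management cost and rate-ratio-scaled admissions used here, the component
discrepancies nearly cancel and the total incremental cost agrees within 3%.

## Synthetic trial generator

`chfcea.synthetic_trial` emulates the kind of individual patient data the
original risk equations were fitted on: baseline covariates (age N(60,10),
25% female, NYHA 2/50/45/3%, LVEF, HF duration, beta-blocker use, diabetes,
prior CAD — all documented assumptions, since the trial's baseline table is
not reproduced here), CV death times from the Gompertz PH process by
inverse transform, life-table non-CV deaths, Poisson admissions with cause
tags, proportional-odds NYHA observations and mixed-model EQ-5D utilities
(random intercept SD 0.10, residual SD 0.08, truncated to the tariff range
[−0.594, 1]) at visits every 4 months to month 28. Administrative censoring
only.

What it does **not** emulate: loss to follow-up, covariate-dependent
hazards by default (supported via `covariate_betas` but defaulting to a
treatment-only linear predictor), informative visit schedules, adverse
events, or EQ-5D's discrete tariff support. Passing recovery tests
therefore demonstrates the estimators and engine are correct under the
assumed data-generating process, not that the original trial's estimates
would be reproduced from real data.

## Sensitivity analyses

* **Tornado** (`one_way_sa`): each parameter set to its bounds (95% CI where
  published, ±20% otherwise) with a full two-arm re-run; entries sorted by
  ICER span, dominance mapped to the ends of the ordering scale.
* **Structural scenarios** (`run_scenario`): alternative survival baselines
  re-matched to the SoC discounted LY (Weibull shape 1.2 assumed;
  exponential; Kaplan–Meier built from the within-trial calibrated curve),
  5-year treatment duration, HF-only mortality effect (HR 0.74 on the HF
  share of CV deaths, default share 0.55 — an assumption, the split is
  unpublished — blended as `f·0.74 + (1−f)`), titration-cost exclusion, and
  age-adjusted utilities (multiplicative decrement 2×10⁻⁴ per year of
  ageing; magnitude unpublished, configurable).
* **Subgroups** (`run_subgroups`): profiles act through CV-hazard and
  admission-rate multipliers, an NYHA occupancy severity shift, and starting
  age. Severity multipliers follow the roughly threefold mortality gradient
  of NYHA IV vs II seen in CHF cohorts; occupancy is shifted, not pinned at
  the baseline class, because NYHA status is dynamic over a lifetime.
* **PSA** (`chfcea.psa`): lognormal HR/RR from their CIs, beta utilities
  (SE = 10% of mean), gamma costs (SE = 20%) and gamma admission rate
  (SE = 10%) — the original analysis reported none of its distributions, so
  these are documented assumptions. Dependence via a Gaussian copula whose
  correlation matrix is Cholesky-factored; multivariate-normal coefficient
  blocks (from a fitted model's covariance) are supported the same way.
  Invalid draws are rejected and counted, not truncated. 5,000 draws by
  default; under these assumptions the acceptability at €36,000/QALY is
  ≈0.86 (the published 0.95 is not strictly reproducible).

## Numerical choices

Survival MLE: L-BFGS-B on (log λ, shape, β) with analytic gradients;
covariance from the finite-difference Hessian of the gradient; AIC = −2ℓ+2k,
BIC with log n. Degenerate inputs raise (`no events`, zero exposure,
classes outside 1–4); Poisson separation (an arm with zero events) is
flagged non-estimable rather than silently returning a divergent
coefficient. Noise-free utility data fall back to exact cell means with
zero variance components, flagged. Calibration: `least_squares` (trust
region reflective) in log space for rates, ≥6 LHS starts, convergence
declared below 10⁻⁴ on the summed squared relative error. Ties in the
AIC ranking keep input order. Problem sizes in the test suite (8,000–50,000
patients for recovery checks, 200,000 for the microsimulation oracle,
400–1,000 PSA draws) were chosen so each check has Monte-Carlo error well
below its tolerance.

## Known limitations

* The base-case ivabradine arm omits the unpublished arm-specific
  NYHA/utility benefit (quantified above), biasing the ICER upward.
* Plain Poisson admissions (no overdispersion); the original analysis does
  not state whether overdispersion was handled.
* Gompertz shape fixed rather than identified; users with survival data can
  refit it via `risk_equations` and pass it through.
* The bundled life table is synthetic (Gompertz–Makeham, calibrated to
  plausible southern-European magnitudes), not a national registry table.
* Subgroup multipliers are assumptions; subgroup results are directional.
* No frailty or time-varying hazard ratios; no adverse-event states; no
  budget-impact or value-of-information analysis.
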