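# chfcea — cost-utility model of ivabradine in chronic heart failure

`chfcea` is a lifetime cost-utility (Markov cohort) model comparing
**ivabradine plus standard care (SoC)** with **SoC alone** in chronic heart
failure patients in sinus rhythm with elevated heart rate, from a third-party
payer perspective (2013 €, Greek tariffs). It is aimed at health-economic
modellers who want a tested, scriptable replication of this class of
two-state decision model — including the statistical machinery that feeds it
— rather than a spreadsheet.

## The model

A two-state (alive/dead) cohort model with monthly cycles:

* **CV mortality** follows a Gompertz proportional-hazards baseline,
  `h(t) = λ·e^{γt}`, so `S(t) = exp(−(λ/γ)(e^{γt}−1)·e^{x′β})`; the treatment
  effect is the hazard ratio **HR = 0.90** (95% CI 0.80–1.03), applied as
  `S^HR`. Exponential, Weibull and Kaplan–Meier baselines are sensitivity
  options.
* **Non-CV mortality** comes from an age/sex life table, identical across
  arms and independent of the CV process (a synthetic Gompertz–Makeham table
  is bundled; supply a national table via `life_table_path`).
* **Hospital admissions** occur at a constant Poisson rate per patient-month
  with treatment rate ratio **RR = 0.83** (0.78–0.93), split HF / other-CV /
  non-CV and costed per episode (HF: 30% pass through ICU at €200/day).
* **Quality of life**: alive patients are distributed over NYHA classes
  I–IV with utilities 0.82 / 0.74 / 0.64 / 0.46 and per-admission decrements
  0.04 / 0.07 / 0.10 / 0.29 applied for one cycle.
* **Costs**: drug acquisition (€40.52/month ivabradine + €35.26/month SoC),
  HF management €26.05/month, admission episodes, and a one-off titration
  ECG (€3.44). Costs and effects are discounted at 3.5%/year; the
  willingness-to-pay threshold is €36,000/QALY (≈2× GDP per capita).

Because the trial-fitted coefficients behind the published model were never
printed, the SoC arm is **calibrated** (Gompertz rate, admission rate, NYHA
mix) to the published SoC outputs, and the ivabradine arm is generated by
applying only the published effects. A synthetic trial generator
(`chfcea.synthetic_trial`) produces SHIFT-like individual patient data with
known ground truth so every fitting stage — parametric survival MLE, Poisson
rates, proportional-odds NYHA, mixed-model EQ-5D utilities — is testable
end-to-end.

## Worked example

```python
from chfcea import (StrategyInputs, CalibrationTargets, calibrate_soc,
                    replicate_base_case, load_bundled_life_table)

base = StrategyInputs(life_table=load_bundled_life_table())
calib = calibrate_soc(CalibrationTargets(), base)   # match published SoC outputs
soc, iva, inc = replicate_base_case(calib, base)
print(f"SoC: {soc.qaly:.2f} QALYs, EUR {soc.total_cost:,.0f}")
print(f"iva: {iva.qaly:.2f} QALYs, EUR {iva.total_cost:,.0f}")
print(f"ICER: EUR {inc.icer_per_qaly:,.0f}/QALY")
```

prints

```
SoC: 3.99 QALYs, EUR 5,908
iva: 4.20 QALYs, EUR 8,770
ICER: EUR 13,581/QALY
```

The SoC arm reproduces the published SoC outputs (5.61 LY, 3.99 QALYs,
€1,781 hospitalization cost) by construction. The ivabradine arm then gains
0.29 LY and 0.21 QALYs for €2,862 — cost-effective at the €36,000/QALY
threshold. The QALY gain is smaller than the published 0.28 because the
original model also gave ivabradine an arm-specific NYHA/quality-of-life
benefit whose magnitude was never published; `docs/methods.md` quantifies
exactly what that omission changes.

The same pipeline is scripted in `analysis/01…07` (simulate → fit →
calibrate → base case → tornado/scenarios → subgroups → PSA), each step
writing its tables under `results/`, or via the CLI:

```bash
chfcea calibrate && chfcea base-case && chfcea psa --n-sims 5000
```

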