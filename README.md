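# jointpsa

Joint modelling of longitudinal PSA trajectories and prostate-cancer
recurrence risk after radiation therapy.

Serum PSA is measured repeatedly during follow-up after radiotherapy; a
rising level or steep slope signals recurrence.  Relating such an
*internal*, error-prone, irregularly-measured biomarker to a censored
event time is exactly what shared-random-effects joint models are for.
`jointpsa` is for biostatisticians who want a tested, seedable
implementation of that model — fit, simulate, and validate — without a
clinical dataset attached: the package ships a synthetic-cohort generator
whose defaults mirror a published post-radiotherapy cohort (314 patients,
~4 PSA measures each, ~25% recurrence, median follow-up under a year).

## The model

Longitudinal sub-model (on transformed PSA, `y* = ln(PSA + 0.1)` by
default):

    y_ij = m_i(t_ij) + e_ij,           e_ij ~ N(0, sigma^2)
    m_i(t) = x_i(t)' beta + b_i0 + b_i1 t,   b_i ~ N(0, D)

Proportional-hazards sub-model with current-value and slope association:

    h_i(t) = h0(t) exp( gamma' w_i + alpha * m_i(t) + alpha_s * m_i'(t) )

where `w_i` holds hormone therapy, stage, dose band, Gleason band and
age, and `h0` is Weibull, piecewise-constant or B-spline (chosen by AIC).
Estimation is EM with adaptive Gauss-Hermite quadrature over `b_i`,
finished by a quasi-Newton step on the marginal likelihood with the
analytic score; standard errors come from the observed information.
`exp(alpha)` is the recurrence hazard ratio per transformed-PSA unit;
`exp(alpha_s)` per unit/year of slope.  See `docs/methods.md` for the
estimation details and all simulator defaults.

## Worked example

```python
from jointpsa import (SimConfig, generate_cohort, em_fit,
                      standard_errors, rr_table, kaplan_meier)

cohort = generate_cohort(SimConfig(n_subjects=314, seed=1))
fit = standard_errors(em_fit(cohort), cohort)
print(fit.loglik, fit.aic, fit.converged)
print(rr_table(fit)[["parameter", "coef", "rr", "rr_ci_low", "rr_ci_high"]])
```

prints (seed 1; 314 subjects, 1177 PSA measurements, 85 events):

```
loglik = -1580.80   AIC = 3209.60   converged = True
            parameter   coef    rr  rr_ci_low  rr_ci_high  p_value
gamma_hormone_therapy -0.904 0.405      0.192       0.853    0.017
      gamma_stage_3_4  2.092 8.103      4.938      13.295    0.000
     gamma_dose_51_69 -0.241 0.785      0.318       1.943    0.601
      gamma_dose_ge70 -1.252 0.286      0.120       0.682    0.005
      gamma_gleason_6 -0.821 0.440      0.191       1.014    0.054
      gamma_gleason_7 -0.859 0.424      0.193       0.931    0.033
   gamma_gleason_8_10 -0.605 0.546      0.243       1.229    0.144
            gamma_age  0.018 1.018      1.004       1.033    0.014
                alpha  0.461 1.586      1.283       1.959    0.000
              alpha_s  0.063 1.065      0.399       2.839    0.900
```

Reading it: this synthetic cohort was generated with `alpha = 0.33`
(each transformed-PSA unit multiplies the recurrence hazard by ~1.39)
and a stage III-IV log-RR of `ln 5.79`; the fit recovers a significant
current-value association (`alpha = 0.46 +- 0.11`, RR 1.59) and stage
effect (RR 8.1, CI 4.9-13.3) on this single replicate, while the slope
association — weakly identified at sub-year follow-up — is estimated
with a wide interval (RR 1.07, CI 0.40-2.84).  The Kaplan-Meier median
recurrence-free time on the same cohort is 2.43 years (95% CI
1.45-3.35):

```python
km = kaplan_meier([s.event_time for s in cohort.subjects],
                  [s.event for s in cohort.subjects])
print(km.median, km.median_ci)
```

The same pipeline is scriptable:

```sh
jointpsa simulate --n 314 --seed 1 --out data/
jointpsa fit --longitudinal data/longitudinal.csv --survival data/survival.csv \
             --shift 0.0 --out results/        # fit.json, rr_table.tsv, trace.tsv
jointpsa km --survival data/survival.csv --out results/
jointpsa compare --longitudinal data/longitudinal.csv --survival data/survival.csv \
                 --out results/                # AIC across baseline families
jointpsa recover --replicates 10 --seed 1 --n 300 --out results/
```

## Acceptance harness

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch at run time: the relative-risk arithmetic of
the reported association coefficients through the reporting layer, and a
10-replicate recovery experiment (cohorts of n=300 simulated from the
default generative truth with seeds `seed..seed+9`, each refit by EM)
whose mean recovered current-value association, slope association,
longitudinal intercept and time slope, and stage relative risk are
written to the JSON.  Runtime is a few minutes on one CPU.
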