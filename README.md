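# centime

Discrete-time survival analysis with an **event-conditional censoring
model**, for biostatisticians and ML researchers who need actual
time-to-event estimates — not just risk rankings — from heavily censored
cohorts.

## The problem

In clinical survival data most subjects are right-censored: the record says
only that the subject was alive at month *c*, not when the event happened.
Cox-style models use censored rows solely to populate risk sets and are
untrainable without uncensored examples; classification-style models
(DeepHit) treat censored rows through the classical independent-censoring
likelihood, whose censored term `log Σ_{t>c} p(D=t|x)` is maximised by
pushing all probability mass past the horizon — so with few uncensored rows
the estimates of the event-time distribution drift upward without bound.

The event-conditional model (CenTime) assumes the censoring time is drawn
*given* the event time: *t* ~ p(D=t|x) first, then *c* uniform on
{1..t−1}. Marginalising gives the censored-time likelihood

```
p(C=c|x) = Σ_{t=c+1}^{Tmax}  p(D=t|x) / (t−1)
```

and the mixture objective

```
L(θ) = Σ_{n uncensored} log p(D=t_n|x_n)  +  Σ_{n censored} log Σ_{t>c_n} p(D=t|x_n)/(t−1).
```

The only difference from the classical censored term is the `1/(t−1)`
weight — but that weight makes each censored term a proper likelihood for
the event-model parameters θ, so the MLE stays **consistent even with
purely censored data**. The event distribution is a discretised Gaussian on
the month grid `1..Tmax`: `p(D=t|x) ∝ exp(−(t−μ_θ(x))²/2σ²)`, with μ linear
in the covariates here and σ fixed (12 months by default) or learned.

The package also implements, for comparison under identical conditions: the
classical censoring likelihood, the Cox partial likelihood (full-batch,
minibatch with the all-censored skip rule, and a memory-bank variant that
keeps training signal alive in small or all-censored batches), DeepHit-style
losses, the standard metrics (Harrell C-index, MAE, RAE over uncensored
subjects), and seeded generators for both censoring mechanisms plus a
fixed-proportion sampler that can produce exactly 100%-censored cohorts.

## Worked example: recovering a model from 100% censored data

```python
from centime import CohortConfig, sample_cohort, fit_event_model

truth = CohortConfig(
    n_subjects=1500, t_max=60, covariate_dim=2,
    intercept=30.0, weights=(4.0, -2.0), sigma=12.0,
    mechanism="fixed_proportion", censored_fraction=1.0, seed=42,
)
cohort = sample_cohort(truth)          # 1500 subjects, every record censored
fit = fit_event_model(cohort, likelihood="centime", t_max=60, sigma=12.0)
print(fit.summary())
```

```
Discrete-time event model (centime likelihood)
n=1500 (uncensored 0), Tmax=60, sigma=12.000 (fixed)
log-likelihood -5354.199 (per obs -3.569466), converged=True, iterations=7
                coef   std err          z
intercept  28.675341  0.596126  48.102854
x1          3.582950  0.598545   5.986097
x2         -1.244141  0.583322  -2.132852
```

Despite never observing a single death time, the fit lands near the truth
(intercept 30, weights +4/−2) with honest standard errors from the observed
information — the consistency property in action. The same call with
`likelihood="classical"` drives the intercept far past the horizon, which
is exactly the failure mode the event-conditional term repairs. Evaluating
on an independent fully-observed test cohort:

```python
test = sample_cohort(CohortConfig(
    n_subjects=500, t_max=60, covariate_dim=2, intercept=30.0,
    weights=(4.0, -2.0), sigma=12.0, mechanism="event_conditional",
    censoring_prob=0.0, seed=7,
))
print(fit.evaluate(test))
```

```
C-Index 0.5857  MAE 9.121 months  RAE 0.4595  (n_uncensored=500, pairs=121855)
```

MAE ≈ 9 months is close to the floor set by the σ = 12 event noise itself;
the C-index reflects the modest signal-to-noise of the simulated covariate
effects, not estimation error.

The same workflow is available from the shell:

```sh
centime simulate --mechanism fixed_proportion --n 1500 --tmax 60 \
    --intercept 30 --weights 4,-2 --sigma 12 --censored-frac 1.0 \
    --seed 42 --out cohort.csv
centime fit --likelihood centime --data cohort.csv --tmax 60 --sigma 12 --out model.json
centime evaluate --model model.json --data test.csv
```

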