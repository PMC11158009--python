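# Methods

## Data model

Time is discrete: integer months `t ∈ {1, …, Tmax}`. A subject contributes
either an uncensored record `(δ=1, x, t)` — the death time is observed — or
a right-censored record `(δ=0, x, c)` — the subject was alive at month `c`
and the true death time exceeds `c`. `Tmax` defaults to 156 months, a
typical maximum follow-up for a clinical cohort; all grids are configurable.

## Event distribution

The event-time model is a discretised Gaussian:

```
p(D=t|x) = exp(−(t−μ(x))²/(2σ²)) / Z,    Z = Σ_{t=1}^{Tmax} exp(−(t−μ(x))²/(2σ²)).
```

`μ(x) = β₀ + β·x` is linear in this reference implementation (the predictor
is an ordinary design-matrix map, so richer models can substitute); `σ` is
fixed at 12 months by default and shared across subjects — fixing the scale
stabilises fitting and matches how such models are used in practice — or
learned through `log σ` so positivity is structural. `μ` is deliberately
unconstrained: values outside the grid are legal and simply shift mass
toward an edge, with `Z` absorbing the truncation; nothing is clamped. All
pmf computation happens in log space with max-subtraction, so extreme
`(μ, σ)` never produce invalid logs. The quadratic penalty in `t` encodes
that a near-miss in predicted death time is better than a distant one —
the property a softmax-over-categories model lacks.

The predicted death time reported by `predict_time`/metrics defaults to the
distribution **mean** (smooth, uses the full shape); the mode is available
behind a flag, with ties broken to the smallest time index for
reproducibility.

## The two censoring likelihoods

**Event-conditional (CenTime).** Censoring is generated *given* the event:
`t ~ p(D|x)` first, then `c` uniform on `{1..t−1}`. Marginalising over the
unknown death time gives `p(C=c|x) = Σ_{t=c+1}^{Tmax} p(D=t|x)/(t−1)`, and
the training objective is the exact mixture log-likelihood of uncensored
and censored terms. Because each censored term is itself a proper
likelihood in the event-model parameters, the MLE remains consistent when
*every* record is censored — the package's central claim, exercised
directly by the parameter-recovery experiments. Identity worth knowing:
`Σ_c p(C=c|x) = 1 − p(D=1|x)`, since a subject dying in month 1 admits no
censoring time. Consequently a censored record with `c = Tmax` has an empty
admissible-event sum; dataset validation rejects such records with advice
to raise `Tmax`, because a silent `−inf` would corrupt optimisation.

**Classical.** `t` and `c` are independent, `c` uniform on `{1..Tmax}`, and
the smaller value is observed. Censored records contribute
`(1/Tmax) Σ_{t>c} p(D=t|x)`; uncensored ones `((Tmax−t+1)/Tmax)·p(D=t|x)`.
The training objective drops the additive constants (both forms are
exposed; the normalised form is what the joint-mass identity
`Σ_c p(0,c|x) + Σ_t p(1,t|x) = 1` tests). The sole structural difference
from the event-conditional censored term is the missing `1/(t−1)` weight —
and that difference is what makes the classical censored term improper as a
stand-alone likelihood: on purely censored data it is maximised by pushing
all event mass beyond every observed `c`, so the fitted intercept diverges
toward and past the horizon. The recovery experiments show this directly
(classical intercept overshoots the truth by hundreds of months at
n = 2000, 100% censored, while the event-conditional fit sits within a
fraction of a month in median).

A printed-formula note: the censored sums are implemented as
`Σ_{t>c} p(D=t|x)` with `t` the summation variable — the only reading
consistent with the marginalisation they come from.

## Cox-family baselines

Risk scores are linear, `g(x) = β·x`. The partial log-likelihood is the
uncensored-mean form `L = (1/|U|) Σ_{n∈U} [g_n − log Σ_{m∈R_n} e^{g_m}]`
with risk sets `R_n = {m : time_m ≥ time_n}` over observed times — the
Breslow convention for ties, chosen for determinism and because the
discrete month grid produces many ties. The implementation sorts by time
and uses one reverse cumulative log-sum-exp sweep (risk sets are nested);
tests pin it to the naive per-subject evaluation and, on tie-free data
(where Breslow and Efron coincide), to lifelines' independent Cox fitter.
The objective is shift-invariant in the scores; gradients are analytic.

**Minibatch and memory bank.** The within-batch objective is undefined for
a batch with no uncensored subject; such batches return an explicit
skip-signal sentinel (never zero, which would silently be a valid loss).
The memory-bank variant (CoxMB) keeps the latest score of every training
subject; the per-batch objective pools fresh batch scores with stored
scores (constants, no gradient), takes as anchors the uncensored subjects
of the pool, and samples a fraction `K` (default 1.0) of eligible stored
scores per anchor without replacement, without staleness decay — the
simplest bookkeeping consistent with the memory-bank literature, and an
explicit reconstruction rather than a published recipe. Limiting cases are
exact and tested: `K=1` with the full dataset as the batch reproduces the
full partial likelihood; `K=0` reproduces minibatch semantics including the
skip-signal; an all-censored batch remains trainable through bank anchors —
the property that motivates the variant. Death times from a fitted Cox
model use the Breslow cumulative baseline hazard and the first grid time
where `S(t|x) = exp(−H₀(t)e^g)` crosses 0.5 (`Tmax` if never; restricted
mean survival time available behind a flag).

**DeepHit-style losses.** A softmax over `Tmax` logits (linear in x per
time bin) trained with the classical likelihood plus a pairwise rank term
`Σ exp(−(F_i(t_i) − F_j(t_i))/s)`, `s = 0.1`, summed over pairs with
subject *i* uncensored and `t_i < t_j` (a censored `t_i` is only a lower
bound, so such pairs are unverifiable; ties in time are excluded). The
exponent is implemented as a division by `s`, matching the reference
DeepHit formulation — the printed form is ambiguous between `·s` and `/s`.
Sum over pairs is the default; a mean reduction is exposed. `rank_weight=0`
gives the likelihood-only ablation.

## Metrics

Harrell's C-index over comparable pairs (`t_i < t_j` with subject *i*
uncensored; tied times excluded), with tied predictions earning 0.5 — so an
uninformative constant predictor scores 0.5 instead of being undefined.
`direction="risk"` (larger score = earlier death) serves Cox-style outputs;
`direction="time"` serves time predictions. MAE and RAE average `|t̂−t|`
and `|t̂−t|/t` over uncensored subjects only. All three raise a defined
error when no comparable pair or uncensored subject exists.

## Synthetic cohorts

One covariate-linked ground truth (standard-normal covariates, linear μ,
shared σ) feeds three mechanisms: event-conditional (per-subject censoring
probability, default 0.65 to mirror a typical clinical censoring rate;
`c` uniform on `{1..t−1}`; subjects with `t=1` are emitted uncensored by
default since no censoring time exists, with a resample-t policy behind a
flag), classical (independent `c` uniform on `{1..Tmax}`), and
fixed-proportion (exactly `round(N·pc)` censored records drawn from the
event-conditional censoring marginal — the sampler that makes 100%-censored
cohorts constructible, which the classical mechanism cannot guarantee).
Generators are pure functions of their config; one seed, one cohort,
byte-identical on repetition. Chi-square fidelity tests compare empirical
(status, time) frequencies with the closed-form model probabilities on a
small grid.

What the generators deliberately do not emulate: covariate-dependent
(informative) censoring, non-linear covariate effects, measurement error,
or anything image-like. Passing tests therefore demonstrate correctness of
the estimators under their own assumptions — identifiability, consistency,
the contrast between censoring models — not robustness to misspecification
on real clinical data.

## Fitting and numerics

Full-batch fits maximise the mean per-observation log-likelihood with
L-BFGS and analytic gradients (closed-form score of the discretised
Gaussian under both censored terms; verified against finite differences).
Accepted iterates never decrease the objective; the recorded trace is
checked for that invariant. Initialisation is deterministic: intercept at
the grid midpoint `(Tmax+1)/2`, weights zero, `log σ` at its configured
value. Convergence is declared when the objective moves less than 1e-7
over five successive accepted iterates or at 2000 iterations. Standard
errors come from the observed information (central finite differences of
the analytic score), reported as NaN when the Hessian is singular — e.g.
for the divergent classical fit on purely censored data. Minibatch
objectives (cox_minibatch, coxmb) use seeded shuffled gradient ascent with
a 1/(1+0.05·epoch) step decay; they report no standard errors.

Experiment sizes are chosen for desk-scale replication: recovery studies
use n = 2000, d = 2, σ = 12, Tmax = 60 over 20 seeded replicates; the
bias-versus-n ladder uses nested cohorts (one n = 4000 draw per replicate,
fitting its first 250/1000/4000 rows) so errors are paired across n and
the median comparison has high power at 20 replicates; the
uncensored-fraction sweep uses n_train = 800, n_test = 300 over 10
replicates.

## Known limitations

- Left- and interval-censoring variants of the event-conditional likelihood
  are not implemented.
- The censoring conditional is fixed uniform; a learned `p(C|D,x)` is not.
- Linear predictors only; the model classes define the interface a neural
  predictor would plug into, but no deep variants ship here.
- Efron tie handling, stratification and time-varying covariates are out of
  scope for the Cox baselines.
- The memory-bank bookkeeping is a documented reconstruction; other
  refresh/sampling policies are plausible.
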