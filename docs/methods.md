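# Methods

## The behavioural models

All models concern binary intertemporal choices between an immediate reward
`R0` and a delayed reward `RD` after `D` days, valued hyperbolically,
`V = RD / (1 + K·D)`, with the log discount rate `k = ln K` as the taste
parameter (larger `k` = more impulsive). Choices are coded 1 = delayed.

**KT (softmax / trembling hand).** Deterministic valuation plus softmax
response noise: `pi_D = 1 / (1 + exp((Q0 − QD) / T))` with `Q0 = R0`,
`QD = RD / (1 + e^k D)`. Noise (`T`, in value units) is independent of taste.

**KU (random preference).** The agent holds a Gaussian belief `N(m, u)` over
its own `k`, samples a taste on each trial and chooses deterministically.
The policy is a probit in the pair's indifference point
`theta = ln[(RD/R0 − 1)/D]`: `pi_D = Phi((theta − m)/sqrt(u))`. `u` is a
**variance** throughout the package (the CDF width is `sqrt(u)`); the
alternative reading as an SD is noted as an open interpretation, but one
convention is fixed for consistency with the preference-shift model, where
the self-belief variance and `u` must be the same object.

**PS (uncertainty–relevance preference shift).** The agent assumes its own
taste `k_s` and the Other's taste `k_o` are drawn with variance `sigma_r²`
around a latent reference mean carrying a flat prior. Integrating the latent
mean out, the posterior over `k_s` is the product of the self likelihood
`N(m_s, u_s)` with the other-likelihood widened by `2·sigma_r²`; the posterior
over `k_o` is the mirror image. Self-choices use the self-posterior through
the KU policy plus a lapse mixture `pi(1 − xi) + xi/2`; choices made on
behalf of the Other use the other-posterior through the KU policy, relaxed by
a power temperature `tau_o` (these choices are unincentivised, hence noisier).
Five parameters per participant: `m_s, u_s, sigma_r, tau_o, xi`.

Structural consequences used as tests: the posterior self-mean always lies
between `m_s` and the other-likelihood mode (no overtaking); the shift is
strictly increasing in `u_s` and strictly decreasing in `sigma_r`; posterior
variance never exceeds prior variance. The closed forms are verified against
brute-force numerical integration of the three-variable generative model
(tolerance 1e−3 on mean and variance over a 100-point parameter sweep), and
the KU policy against Monte-Carlo taste sampling (3 SE at 10⁶ samples).

**Filtering the other-likelihood.** The Gaussian summary of the Other enters
the posteriors in filtered form: before each trial it summarises the Other's
choices observed so far (through veridical feedback), evaluated as a product
of unit-temperature softmax Bernoulli terms on a grid over
`k ∈ [−12, 2]` (601 nodes), normalised and moment-matched. The finite grid
acts as a uniform prior over its span, which keeps the summary proper when
all observed choices are one-sided. The participant's own *guesses* are not
evidence about `k_o`; only revealed Other choices update the filter, and
phase-3 other-trials keep updating it. The Other's own small lapse is ignored
in the inversion model. Because the filter depends only on the observed
choice sequence (never on the fitted parameters), it is precomputed once per
dataset, which makes the five-parameter likelihood a cheap vectorised
function.

## The task simulator

The simulator is the package's stand-in for raw data and reproduces the
three-phase protocol: 60 phase-1 self-choices (30 standard + 30 adaptive,
interleaved); partner selection `k_o = k_b ± 2.3` with the move toward the
population mean −4.5 taken with probability 2/3 (`k_b` is the mode of the
experimenter's grid posterior at assumed `T = 1`, deliberately the same
rough in-task procedure as the protocol, not the final fit); phase 2
guess-the-Other trials with veridical feedback until 8-of-the-last-10
correct (full window required) or 60 trials; phase 3 with (by default) three
10-trial mini-blocks per role. The Other's actual choices are simulated from
the softmax at `T = 1`. Adaptive pairs minimise the expected entropy of the
grid posterior over a pool of 200 random candidates per trial, with
deterministic tie-breaking.

Stimulus menus are not uniquely determined by the protocol; the defaults are
immediate rewards of 1–10 currency units, delayed/immediate ratios in
(1, 5], delays of 1–365 days, and standard-set indifference points evenly
spaced over `k ∈ [−9, 0]`. One structural consequence worth noting: with
delays capped at a year, pairs probing very patient tastes necessarily carry
reward ratios close to 1, so their value differences are compressed — this
is what produces the spurious positive correlation between fitted `k` and
`ln T` when softmax fits are applied to random-preference agents, and the
package's tests reproduce exactly that mechanism.

Population defaults for synthetic agents: `m ~ N(−4.5, 2.3²)` (the stated
community-sample distribution), `ln u ~ N(−0.1, 0.8²)` (mean taste
uncertainty ≈ 1.2, matching reported group means near 1.1–1.3),
`ln sigma_r ~ N(0, 0.6²)` (mean ≈ 1.2, near the reported fitted mean of
1.13), `ln tau_o ~ N(0, 0.3²)`, `xi ~ Beta(2, 100)` (median ≈ 0.017, near
the reported median lapse of 0.015). A `ku` population kind fixes
`sigma_r = ∞, tau_o = 1` (no social coupling, uncorrelated `m` and `u`); a
`kt` kind draws softmax agents for phase-1-only studies.

What the generator does **not** emulate: individual differences in the
discounting functional form, sequential effects beyond the modelled
filtering, reaction times, menu discreteness of a real stimulus table, and
any instrumental or normative motives for conformity. Passing recovery tests
therefore show that the estimation stack is correct and well calibrated
*under the model*, not that the model is correct for any given human
sample.

## Fitting

Fitting works on unconstrained scales: `(k, ln T)`, `(m, ln u)`,
`(m1, m3, ln u)` for the phase-perturbation comparator, and
`(m_s, ln u_s, ln sigma_r, ln tau_o, logit xi)`. Policy probabilities are
clipped to `[1e−12, 1 − 1e−12]` inside log-likelihoods. `map_fit` runs
multi-start Nelder–Mead (a data-driven start from the choice-fraction
quantile of the indifference points, plus jittered restarts) inside a soft
parameter box, and reports a Laplace covariance from the numerical Hessian.
Estimates pinned to the box edge on identifiability-critical parameters
(taste modes, log-uncertainty) are flagged as boundary fits — e.g. a
participant who always waited — and excluded from prior construction; a
lapse rate at zero is benign and is not flagged.

`mcmc_fit` is a component-wise adaptive random-walk Metropolis sampler
(per-component proposal scales tuned toward 0.44 acceptance during warm-up,
then frozen), a deliberately simple stand-in for component-wise hit-and-run
sampling with the same target. Point estimates are posterior medians.
Convergence requires bulk-ESS ≥ 100 on every parameter (arviz estimator)
and a split-chain stationarity z below 3 with autocorrelation-adjusted
standard errors; failures are flagged, never raised. Defaults (20 000
iterations, 2 000 warm-up, thin 10) are a desk-scale budget; the sampler is
validated against the conjugate closed form on a Gaussian toy target.

**Empirical Bayes.** The five-parameter model is fitted in stages: (i)
individual flat-prior fits; (ii) a Gaussian estimate, on the transformed
scale, of the sample distribution of each parameter, built from the
converged non-boundary fits only (SDs floored at 0.05); (iii) a refit of
*every* participant under those priors. Stage (iii) uses MAP by default;
MCMC refits are available but changed desk-scale recovery rank correlations
by less than 0.02 at roughly 30× the cost.

**Model comparison** reports per-participant log-likelihood and BIC
differences (`BIC = −2·LL + p·ln n`), the fraction favouring each model
(ties counted half, binomial SEM), a Wilcoxon signed-rank test, and the
fractions beyond the conventional BIC margins of 2 and 6. The
phase-perturbation model (`m1`, `m3`, shared `u`, self-trials only) is
compared against a static single-`m` variant fitted to the same trials.

## Population analysis

All statistics are pure functions of a one-row-per-participant table, so
reports reproduce bit-for-bit from the serialized CSV. The signed shift is
`(m3 − m1)·sign(k_o − m1)` (positive = toward the Other) using the
perturbation-model taste modes. Partial correlations use double
residualization (OLS on controls, Pearson on residuals; cross-checked
against pingouin in the tests), with t-based p-values at `n − 2 − #controls`
degrees of freedom. Mediation is read in partial-correlation terms: an
age effect on shifting is called fully mediated by `u` when the raw age
association is significant, vanishes given `u`, and `u` retains its own
association. Near-deterministic responders are flagged at `u < 0.01`
(configurable).

## Known limitations and numerical choices

* Desk-scale problem sizes are used throughout the tests and the acceptance
  script (populations of 50–100 agents, MAP-based staging); these are the
  package's default study sizes, configurable upward.
* Recovery of the taste-uncertainty parameter `u_s` is noise-limited: with
  ~90 self-trials per participant and the adaptive arm concentrating pairs
  at the taste mode (where trials carry no width information), the sampling
  SD of `ln u` is about 1.0 — comparable to the population spread — so
  true-vs-recovered rank correlations plateau near 0.65 for `u_s` while
  `m_s` (≈ 0.99) and `sigma_r` (≈ 0.77) recover well. Both MAP and
  MCMC-median estimators hit the same ceiling.
* The relaxation `tau_o` and lapse `xi` are weakly identified per
  participant and are deliberately not used as analysis endpoints.
* Flat beliefs are represented by precision 0 (variance ∞) and all posterior
  algebra is done in precision form; belief variances are floored at 1e−12.
* Degenerate inputs (empty datasets, missing phase-2 feedback, improper
  posteriors from two flat beliefs, zero-variance analysis columns) raise
  `ValueError` with the participant/row named.
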