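# Methods

## Observer model

All tasks share one generative core.  A stimulus pair presented at a
signed asynchrony `SOA` (ms; positive = second-named stimulus trails the
first, e.g. beep after flash) produces an internal arrival-time difference

    dt ~ N(SOA + mu, sigma^2)

`mu` is the observer-specific asynchrony offset contributed by differential
sensory delays; `sigma` is the latency noise, the SD of the difference in
central arrival times.  The SOA that minimises E|dt| is `-mu`, so the
reported point of subjective simultaneity is `pss = -mu`; `ObserverParams`
stores the internal `mu` and exposes `pss` as a property.  Noise is
constant across SOA (no scalar/Weber component) and the objective-to-
subjective mapping is affine; both are deliberate simplifications.

### Task decision rules

* **TOJ.**  One criterion at dt = 0: the positive-direction order response
  has probability `Phi((SOA + mu)/sigma)`, a cumulative Gaussian crossing
  1/2 at the PSS.
* **SJ (3-parameter).**  Two criteria on the SOA axis, `crit_low <=
  crit_high` (they absorb `mu`, which is not separately identifiable):
  P("simultaneous") = `Phi((SOA-crit_low)/sigma) -
  Phi((SOA-crit_high)/sigma)`.  A single PSS requires the equidistance
  assumption: the midpoint of the two criteria.
* **SJ (4-parameter).**  The two flanks carry separate SDs `sigma_low`,
  `sigma_high`, the classical way to capture asymmetric simultaneity
  curves via noisy criteria.  The reported precision is
  `min(sigma_low, sigma_high)` (an upper bound on the latency noise).  The
  raw difference of Gaussians can turn infinitesimally negative in the far
  tails when the flank SDs differ (the noisy criteria may cross); it is
  clipped at zero before the lapse mix.
* **Ternary.**  The same two-criterion partition expressed for three
  response categories under a multinomial likelihood; the "simultaneous"
  component equals the SJ prediction pre-lapse.
* **Dual presentation (2xSJ).**  Two pairs per trial; the pair with the
  larger |dt| is judged less simultaneous.  With the standard defined as
  the SOA nearer zero (ties: interval 1), the probability of choosing the
  standard for an unbiased observer is
  `P(dt_std^2 / dt_test^2 < 1)` — the CDF of a doubly non-central
  F(1,1) ratio whose numerator non-centrality comes from the standard pair
  and denominator from the test pair (an assignment verified against
  direct Monte-Carlo simulation of the decision rule).  Interval bias
  takes one of two forms: *proportional* (threshold `beta` on the squared
  ratio, applied as `beta` when the standard leads and `1/beta` when it
  trails; the equivalent threshold on |dt| is `c = sqrt(beta)`), or
  *constant* (choose interval 1 when `|dt_1| - |dt_2| < c`, with the sign
  of `c` flipped for the reversed order).  Both forms are fitted and the
  higher likelihood retained; the two are non-nested with equal parameter
  counts, so raw log-likelihood decides.

### Lapse

Every model carries a fixed 1% keyboard-error/lapse rate, implemented as a
uniform mixture: `p' = (1 - lambda) p + lambda / K` with K the number of
response options.  This bounds every predicted probability inside
`[lambda/K, 1 - lambda (K-1)/K]`, keeps likelihoods finite, and preserves
the nesting of guessing models.  Lapse is never free.

## Numerics

The dual-presentation probability reduces to `P(|X1| - |X2| < c)` for
independent Gaussians with possibly unequal scales (the proportional form
via `|sqrt(x) dt_test|`).  Conditioning on X2 leaves one-dimensional
integrals of `Phi(a + b u) phi(u)`, each of which equals a bivariate
normal CDF evaluated through Owen's T function — an exact, vectorised
closed form (verified against scipy's bivariate normal, adaptive
quadrature, and 10^6-draw Monte Carlo; agreement ~1e-9 or 3 MC standard
errors).  Arguments of the bivariate CDF are nudged 1e-10 away from zero
to keep Owen's delta-term bookkeeping well conditioned; the induced error
is below 1e-9.

The doubly non-central F(1,1) CDF is exposed with four methods:
`closed_form` (the folded-normal route, exact), `series` (double Poisson
mixture of incomplete beta functions), `quadrature` (adaptive 1-D
integration), and `saddlepoint` (second-order Lugannani-Rice on the
indefinite quadratic form `N1^2 - x N2^2`).  The saddlepoint scheme loses
absolute accuracy (up to ~1.6e-2) when either non-centrality is small —
the chi-square(1) density is unbounded at zero — so the public method
certifies each evaluation against the exact closed form and falls back,
with a logged note, beyond 1e-3 disagreement.  Model fits use the exact
closed form throughout and never depend on the approximation.

## Fitting

Maximum likelihood on grouped data (trials pooled by unique stimulus
condition; for dual data the condition key includes the presentation
order, because interval bias makes order informative).  Grouping leaves
the trial-wise log-likelihood unchanged.  Optimisation is Nelder-Mead
seeded from the factorial combination of per-parameter starts — defaults:
mu in {-100, 0, 100} ms, sigma in {20, 60, 150, 400} ms, beta in
{0.5, 1, 2}, c in {-50, 0, 50} ms, SJ criteria from response-weighted SOA
quantiles — with a 1e-6 function tolerance and 2000 iterations per seed;
the winning start is recorded.  Scale parameters (sigma, the criterion
gap, beta) are fitted on a log scale to stay positive.  Guessing nulls
have closed-form MLEs (category proportions) and are computed analytically.

Deviance is `-2 x` the log-likelihood shortfall against the saturated
model (empirical category proportions per condition).  Nested model pairs
are compared by the deviance improvement against an upper-tail chi-square
with df equal to the parameter difference, one-tailed at p < 0.05.
Ladders: TOJ null -> observer; SJ 2-parameter cumulative Gaussian (signed
slope, so it covers guessing and one-sided data) -> 3-parameter ->
4-parameter; ternary 2-parameter guessing -> 3 -> 4; dual null ->
bias-free -> best bias form.  Complex models are additionally seeded with
the simpler model's optimum, which enforces monotone deviance down each
ladder.

## Validation

*Goodness of fit* is parametric Monte Carlo: keep every stimulus value the
observer actually received (adaptive designs are treated as fixed),
resample responses from the fitted model, refit, and collect the refit
deviances; the observed deviance is ranked two-tailed,
`p = min(1, 2 (min(n_at_or_below, n_at_or_above) + 1) / (n_sims + 1))`.
Failed replicates are retried once from the full grid and otherwise
recorded as missing, never dropped silently.

*Bootstrap intervals* are non-parametric BCa: trials resampled with
replacement, refit warm-started at the full-data optimum; bias correction
from the fraction of replicate estimates below the point estimate;
acceleration from a leave-one-trial-out jackknife (identical trials
deduplicated and weighted — the exchangeable unit is the trial, not the
condition); endpoints are order statistics.  Degenerate resamples are
skipped and logged; more than 5% flags the result.

## Adaptive stimulus selection

Two count-based samplers, both deliberately simple because only their
qualitative behaviour is constrained:

* **Roving distribution** (dual task): 20-ms grid, initially uniform over
  -60..+60 ms with hard bounds at +/-300 ms (25-ms/+/-75/+/-375 in the
  wide variant).  After each trial every grid point within +/-40 ms of the
  asynchrony judged most simultaneous gains one count; a boosted boundary
  point extends the support one step (never past the hard bounds).  Driven
  by a simulated observer this concentrates near the PSS without pinning
  to zero.
* **Generalized Polya urn** (single-presentation tasks): the urn starts
  uniform (one design variant boosts the two extreme SOAs ninefold) and
  each accepted trial adds k balls (k = 32 or 8 by design) one grid step
  from the tested SOA on the side the response indicates, expanding within
  hard bounds.  This steers sampling toward the response-flip region; the
  displacement kernel is a documented interpretation, not a reconstruction
  of the original urn scheme, and its stationary mean approaches the flip
  point only slowly.

Design presets reproduce the published schedules: 19 constant-stimuli SOAs
x 4 repetitions x 2 intervals = 152 dual trials per block (15 blocks =
2280), the combined variant adding two SJ responses per dual trial (304
per block), 100-trial TOJ blocks, and the wide-range variants.  The
detection-target trials of the attention experiment are not scheduled
(only their hit/false-alarm summary enters, via d-prime), so its TOJ
preset counts the 152 temporal-judgment trials of a 190-trial block while
its dual preset enumerates the 19 x 5 x 2 stimulus schedule.

## Synthetic observers

`simulate_response` draws dt per pair and applies the task's literal
decision rule, then a uniform lapse channel, so simulated response
frequencies match the analytic models by construction (law-of-large-
numbers tests at 10^5 draws).  For the 4-parameter SJ variant the criteria
are drawn per trial with SD `sqrt(sigma_flank^2 - sigma^2)`; the analytic
difference-of-Gaussians ignores the (rare) event that the noisy criteria
cross, so generative/analytic agreement is exact only when the criterion
separation is large relative to the criterion noise — tests use that
regime.  Combined sessions reuse the same dt draw for the SJ response and
the dual comparison, as a single presentation would.  Reaction times are
Gaussian per modality truncated at zero — the analysis only consumes
trimmed means and variances, so no ex-Gaussian machinery is warranted.
Simulated trial cancellation (repeat at end of block, excluded from
likelihoods) exercises the exclusion path with default probability zero.

## RT analysis and group statistics

Simple-RT trials are trimmed per modality in a single pass (drop RT < 100
ms or above the pre-trim mean + 2.5 SD).  The RT-based PSS is
trimmed-mean RT(light) - trimmed-mean RT(sound); the RT-based sigma sums
the two trimmed variances and takes the square root.  Group comparisons
use sign-flip permutation paired t-tests (10^4 flips, two-tailed, add-one
p), with a max-|t| reference across comparison families for multiple
comparisons; associations use Pearson r with BCa bootstrap significance.
d-prime applies a 1/(2N) correction to degenerate rates when trial counts
are supplied.  Wilson score intervals come from scipy's binomial test
machinery.

## Problem sizes used in the test suite

Stochastic checks run at sizes chosen to keep the full suite routine:
kernel certification on a 5x5x3x3 parameter grid (quadrature to 1e-6,
10^6-draw Monte Carlo to 3 SE) and a 7x5x5 box for the saddlepoint;
generative/analytic agreement at 10^5 draws per point; full-scale
parameter recovery at 2280 trials; bootstrap coverage via 12 seeded
152-trial dual replicates (99 resamples) plus 100 single-presentation
replicates; calibration of the nested tests at 500 replicates and of the
goodness-of-fit p-values at 200 meta-replicates of 199 simulations.
Calibration replicates use 40-80 trials per condition: below that, the
likelihood-ratio gate inflates (~7.5% at 20/condition) and the two-tailed
goodness-of-fit rank shows a central-tendency bias — finite-sample
properties of the statistics that the asymptotic 5%/uniformity claims do
not cover.
Production analyses should use the full 1000-simulation / 1999-resample
settings, which the API defaults to.

## Known limitations

* Constant latency noise: no scalar-timing (Weber) component, no
  exponential-tail latency models, no low-threshold "guessing zone"
  variants.
* The 4-parameter SJ analytic form is an approximation to its generative
  rule when criterion noise is large relative to criterion separation.
* The urn displacement kernel is an interpretation; designs that depend on
  the exact published urn dynamics should treat it as qualitative.
* Asymptotic chi-square gates are mildly anticonservative below ~30 trials
  per condition (measured ~7.5% at 20/condition for the SJ flank-SD gate).
* Stimulus delivery, timing hardware and response-box I/O are out of
  scope; the package consumes trial CSVs.
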