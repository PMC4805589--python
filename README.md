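# rovingsj

Detection-theoretic observer models for temporal judgments: estimate the
**point of subjective simultaneity (PSS)** and **latency noise (σ)** from
temporal order judgments (TOJ), simultaneity judgments (SJ), ternary
judgments, and **roving dual-presentation simultaneity judgments (2xSJ)**.

## Who this is for

Psychophysicists studying multisensory (or within-modality) timing need to
know at what physical stimulus onset asynchrony (SOA) an observer perceives
two events as maximally synchronous, and how noisy that percept is.  The
classic TOJ and SJ tasks answer this, but each with caveats: the TOJ
confounds perceptual and decisional bias, and the SJ yields a *region* of
reported synchrony whose midpoint depends on criterion placement.  The
dual-presentation task shows two stimulus pairs per trial and asks which
was *more* simultaneous; in the roving design neither pair is guaranteed
synchronous, so observers cannot learn true synchrony.  This package
implements the observer models, maximum-likelihood fitting, model
selection, resampling validation and adaptive stimulus-selection machinery
for all four tasks, plus a synthetic-observer simulator so every component
is testable without human data.

## The model

Each stimulus pair presented at asynchrony `SOA` produces an internal
arrival-time difference

    Δt ~ N(SOA + μ, σ²)

where μ is the observer-specific asynchrony offset (reported
PSS = −μ) and σ is the latency noise ("precision").  Task decision rules:

* **TOJ** — one criterion on Δt: a cumulative Gaussian psychometric
  function crossing ½ at the PSS.
* **SJ / ternary** — two criteria B_low < B_high: P("simultaneous") is a
  difference of cumulative Gaussians; a four-parameter variant gives the
  flanks separate SDs (noisy criteria).  The equidistance assumption
  (PSS = midpoint of the criteria) converts boundaries to a point estimate.
* **2xSJ** — the pair with the larger |Δt| is judged *less* simultaneous.
  The probability of choosing the standard (the SOA nearer zero) is
  P(Δt²_std / Δt²_test < 1), the CDF of a doubly non-central F ratio with
  (1, 1) degrees of freedom evaluated at 1 — or at β (proportional
  interval bias) or via P(|Δt₁| − |Δt₂| < c) (constant interval bias).
  Both bias forms are fitted and the better likelihood retained.

All models carry a fixed 1% lapse rate mixed uniformly over the response
options.  Fits are grid-seeded Nelder-Mead maximum likelihood; model
ladders are compared by deviance against one-tailed χ² gates; fits are
validated by Monte-Carlo goodness of fit (simulated-deviance reference
distributions) and bracketed by BCa bootstrap confidence intervals.

The dual-presentation probabilities are evaluated through an exact closed
form for P(|X₁| − |X₂| < c) built on Owen's T function; a saddlepoint
approximation to the doubly non-central F CDF is provided and certified
against quadrature and Monte-Carlo oracles.

## Worked example

`examples/fit_dual_presentation.py` simulates one 152-trial roving 2xSJ
block from a known observer and fits the model ladder:

```
simulated 152 dual-presentation trials
winning model      : 2xsj_constant
PSS                :     4.1 ms   (true 0)
latency noise sigma:    41.9 ms   (true 50)
interval bias      : constant = 33.0   (true constant = 30)
  observer_vs_guessing: delta deviance  118.5, df 2, one-tailed p 1.9e-26
      bias_vs_biasfree: delta deviance   19.2, df 1, one-tailed p 1.2e-05
```

The fitted PSS is the test SOA at which a pair is most likely to be called
"more simultaneous" than any standard; σ is the SD of the internal
arrival-time difference; the interval bias captures the preference for
reporting one presentation interval over the other — ignoring it would
inflate σ.  The nested tests show the observer model beats a
guessing-only account and that the bias parameter earns its keep.

Other examples: `compare_tasks.py` (one observer through all four tasks),
`adaptive_sampling_demo.py` (roving distribution and Pólya-urn sampler),
`goodness_of_fit_and_bootstrap.py`, `rt_and_group_stats.py`.

A thin CLI mirrors the library:

```bash
rovingsj simulate --design exp1b_2xsj --seed 7 --out block.csv
rovingsj fit --task 2xsj --input block.csv --out report.json --seed 7
```

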