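# Methods

This note documents the models, estimation rules and design choices behind
`gaitspc`, in the spirit of a model-description appendix: what is assumed,
what is tunable, and what the synthetic experiments do and do not show.

## Transfer-time model

A person's transfer times (seconds) are modelled as log-logistic: if X is a
transfer time, log X follows a logistic distribution with location μ
(log-seconds) and scale σ. The density is

    p(x | μ, σ) = (1/σ) (1/x) e^z / (1 + e^z)²,   z = (log x − μ)/σ,  x > 0.

The distribution is right-skewed with median e^μ; heavier tails than a
log-normal make occasional very slow crossings (hesitations, detours,
walking-aid changes) part of the model rather than outliers. Four named
parameterizations are built in:

| label | μ | σ | median | interpretation |
|-------|------|------|--------|----------------|
| SGM | 1.504 | 0.155 | 4.50 s | stable gait: fast, consistent |
| TGM1 | 1.504 | 0.206 | 4.50 s | theoretical: stable level, unstable spread |
| TGM2 | 2.097 | 0.155 | 8.14 s | theoretical: unstable level, stable spread |
| UGM | 2.097 | 0.206 | 8.14 s | unstable gait: slow, variable |

Sampling uses the inverse CDF, x = exp(μ + σ·logit(U)); `fit_loglogistic`
is the logistic MLE on log-times (delegated to `scipy.stats.logistic.fit`),
and `scipy.stats.fisk` provides an independent parameterization used for
cross-checks in the tests.

Daily measurement counts are Poisson with mean λ=5; draws above a cap of 2λ
are redrawn, reproducing observed per-day counts of 0–10 (the redraw lowers
the effective mean to ≈4.91). The "halved rate" variant uses λ=2.5, cap 5.
Days with zero measurements carry no median and are skipped by the charts.

A health transition from model A to model B over T days assigns day d of
the transition the interpolated parameters A + (d/(T+1))·(B − A), applied
to μ and σ separately, so every transition day lies strictly between the
endpoint models. T=0 is an abrupt switch with no intermediate days.

### Scenario catalog

Training scenarios use 12-week segments joined by 4-week transitions
(totals 12/28/44 weeks for zero/one/two trends). Validation scenarios total
52 weeks; the catalog fixes the first segment at 12 weeks, the segment
between two transitions at 12 weeks, and lets the final segment absorb the
remainder — the one allocation consistent with all catalog durations, since
the sources of the catalog do not state transition start days. Ground-truth
windows equal the transition periods; an abrupt switch gets a 4-day window
starting on the switch day, within which an alarm counts as correct.

## Baseline estimation

The charts monitor the daily median series. From the first 14 usable days
(a trade-off confirmed by the initialization-length sweep: detection rate
saturates after a few days, false alarms stop improving beyond ~two weeks):

* **μ₀** is the mean of the daily medians — the centre of the monitored
  series. Using the pooled raw mean instead would sit ≈0.1σ above it
  (skewness), biasing the chart toward downward alarms and measurably
  slowing stable→unstable detection relative to unstable→stable, the
  opposite of the asymmetry the method should show (an upward median shift
  of 3.6 s is ≈2.6 baseline SDs from a stable start but only ≈1.0 from an
  unstable one).
* **σ₀** is the sample standard deviation (ddof=1) of *all raw
  measurements* in the window — a per-measurement dispersion. This is what
  makes rational subgroups meaningful: σ₀/√n_i approximates the sampling
  dispersion of a median built from n_i measurements (the standard
  variable-subgroup-size scaling), so days backed by many measurements get
  tight limits and sparse days get wide ones. Estimating σ₀ from the 14
  daily medians instead would make the √n_i division over-narrow the limits
  and *raise* the false-alarm rate, inverting the purpose of the subgroup
  correction.

For medians-only input (e.g. a pre-aggregated export) each day contributes
its median once, and σ₀ degrades to the dispersion of the median series;
rational subgroups should then be used with care.

## Chart mechanics

Defaults: k=0.5, h=3 (CUSUM), λ=0.15, L=3 (EWMA) — the textbook
small-shift rule of thumb; optimized operating points k=0.42, h=2.08
(tabular CUSUM + reinitialization) and λ=0.18, L=2 (EWMA + rational
subgroups + reinitialization).

* Flags use strict inequality; a value exactly on a limit is in control.
* The standardized CUSUM works on y_i = (x_i − μ₀)/σ₀ with slack k/2 and
  limit h (the working scale already has unit dispersion). Note that this
  makes it *exactly* scale-equivalent to the tabular chart — dividing the
  tabular recursion by σ₀ maps one onto the other, with or without the
  √n_i subgroup scaling — a property the test suite asserts flag-for-flag.
* The EWMA limit factor 1−(1−λ)^{2i} counts i in usable days since the
  chart (re)started, giving narrow startup limits that widen monotonically
  to the steady state Lσ₀√(λ/(2−λ)); at λ=1 the chart degenerates to
  plotting raw medians against fixed limits.
* An **alarm event** is a maximal run of ≥2 consecutive usable flagged days
  (a two-in-a-row zone rule); its *trigger day* is the second flagged day.
  Empty days neither break nor extend runs. No flags are raised during the
  initialization window.
* **Reinitialization**: after 3 consecutive alarm days the baseline is
  re-estimated from the 14 usable days strictly before the last alarm day
  (days of the triggering run inside that span are not excluded), chart
  state resets (C± = 0, z = new μ₀, EWMA day counter back to 1), and
  monitoring continues. This is what keeps a second trend detectable after
  a first one has moved the process to a new level.

## Evaluation rules

* An alarm event is **correct** when it starts inside a ground-truth
  window or exactly one day before it (the run that confirms inside the
  window may begin a day early); it is **false** when it starts two or more
  days before a window or any time after it.
* **Detection Rate**: percentage of windows with at least one correct
  event, averaged per transition and across replicates; scenarios without
  transitions report no DR.
* **Run length**: days from the window start to the first day of the
  earliest correct event, counted inclusively and clamped at 1. Counting to
  the event's first day rather than its confirmation day matches the
  intuitive "days until the chart reacted" and is what makes sub-2-day
  means possible for abrupt switches. ARL is averaged over detected
  windows only; for two-trend scenarios the per-transition means are
  averaged and the scenario SD is taken over the pooled run lengths.
* **FPR**: false events per week of eligible time — days outside truth
  windows and outside the initialization window (alarms are suppressed
  there, so counting those days would deflate the rate).
* Pooling across scenarios is an unweighted mean of per-scenario metrics.

Replicate RNG streams are derived from (master seed, scenario id,
replicate), independent of the chart configuration, so different
configurations and all grid nodes see **common random numbers**; grid
results are exactly reproducible for a given master seed.

## Optimization

The grid spans k ∈ [0, 1] and h ∈ [2, 4] for CUSUM, λ ∈ (0, 1] and
L ∈ [2, 4] for EWMA (λ=0 is a degenerate chart and excluded), with default
steps of 0.02 for k/λ and 0.04 for h/L — fine enough to express the
operating points above exactly. The published-style choice of an operating
point from a trade-off plot is replaced by a deterministic lexicographic
policy: maximize DR (ties within 0.5 pp), then minimize ARL, then FPR,
with a final deterministic tie-break toward smaller limit width, then
smaller weight. A custom policy callable can be supplied.

## Problem sizes

Monte-Carlo summaries in the tests and the acceptance script use 20
replicates per scenario (the catalog's replication depth); the
initialization sweep uses 10 replicates per length over the two one-trend
training scenarios. Distributional checks use 10⁵ draws (10⁴ for MLE
recovery). A full default-resolution grid search (≈2 500 nodes × 120
series) is supported but intended as an offline run; tests exercise the
machinery on coarse grids.

## What the simulations do and do not show

The generator reproduces the statistical skeleton of real home-monitoring
data — skewed per-measurement times, sparse and variable daily counts,
gradual or abrupt model changes — but not its failure modes: measurement
noise from imperfect tracking, walking-aid changes, visitors, multi-day
gaps, or seasonal routines. Passing the synthetic benchmarks therefore
shows the detector reacts correctly to the modelled kinds of change at
realistic noise levels; it does not bound the false-alarm rate on real
data, where non-health-related disruptions can and do trigger plausible
alarms. Two further limitations are worth stating:

* σ-only changes (spread without level shift) are detected only about half
  the time at the optimized settings — the EWMA tracks the level, and a
  spread change moves the median little;
* with limits scaled by √n_i, halving the measurement rate widens the
  per-day limits (σ₀/√n_i grows) and low-count days interrupt
  consecutive-flag runs, so detection is a few days slower at λ=2.5 than
  at λ=5; the detection *rate* is unaffected.
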