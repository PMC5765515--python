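# Methods

## Model and decision rule

`uifscan` screens monthly counts of spontaneous suspected-adverse-reaction
reports per drug–event combination for unexpected increases in frequency.
The unit of counting is one (case, drug, PT) report row with a receive
date; study-module reports are excluded throughout, and a month with no
reports is an explicit zero, never missing — the sparse-history rule below
is defined on zero months.

For a monitored month `t0`, the preceding `w` counts (default `w = 6`)
are fitted by maximum likelihood with an NB2 log-linear trend:

    y_t ~ NegBin(mu_t, alpha),  log mu_t = b0 + b1 t,  Var(y) = mu + alpha mu^2,

time coded `t = -w, …, -1`.  Centering the forecast month at `t = 0`
makes the forecast linear predictor the intercept, so `y_hat = exp(b0)`
and its standard error is read directly from the parameter covariance —
numerically stabler than extrapolating a mid-centred fit.  The intercept
plus slope form is the smallest regression that can capture drift in six
points; no seasonal or spatial terms are included (six months cannot
identify them, and requiring years of history would delay screening of
newly marketed products).

Decision rule at threshold `tau`:

1. `y0 < tau`: nothing is evaluated and no model is fitted.
2. Otherwise, if the history has `>= w - 2` zero months (for `w = 6`:
   four or more), the regression is not run and the month is flagged by
   the *heuristic branch* (`y0 >= tau` suffices).  The `w - 2` rule
   generalises the six-month convention so that the two-parameter fit
   always has at least three informative points.
3. Otherwise the *regression branch* flags iff `y0 >` the forecast's
   upper bound.  Threshold comparison is attainment (`>=`, a minimum
   count); bound comparison is strict exceedance.

### Upper bounds

Two bound flavours are provided (`bound_type`):

* `ci_mean` (default): the Wald upper confidence bound of the expected
  count, `exp(b0 + z se(b0))`, `z = Phi^{-1}(1 - (1-level)/2)`, default
  level 0.95.  This is a bound on the *mean*, not on the count, and is
  the default because the decision rule is framed as comparing `y0` with
  the upper bound of the `y_hat` estimate.
* `prediction`: the smallest integer `q` whose NB/Poisson CDF — evaluated
  at the upper mean bound and the fitted dispersion — reaches the level.
  It accounts for outcome-level variability and is markedly more
  conservative.

### Fitting and the Poisson boundary

Standard model machinery comes from statsmodels.  Histories whose sample
variance (ddof = 1) does not exceed their mean are fitted directly as a
Poisson trend GLM (`alpha = 0`): the NB2 dispersion MLE lies on the zero
boundary there and six points cannot identify it.  Otherwise the joint
(b0, b1, alpha) likelihood is maximised (BFGS, Nelder–Mead fallback,
started from the Poisson fit plus a moment estimate of alpha), followed
by a short Nelder–Mead polish in (b0, b1, log alpha) — short count
samples occasionally stall quasi-Newton optimizers, and the polish
guarantees the returned likelihood is at least the best iterate seen.
A dispersion below 1e-6, a fit that fails to improve on the Poisson
likelihood, or an unusable Hessian all fall back to the Poisson fit
rather than dropping the series.  `se(b0)` comes from the inverse
observed information of the joint fit (dispersion-conditional GLM
covariance as fallback).  Tests cross-check the fitted likelihood against
an independent dense grid search written directly from the NB2 density.

## Counting conventions

Counts are per calendar month of the receive date.  Configuration axes:
drug level (substance vs commercial product; rows without a product name
are excluded from product-level screens), event level (single PT, all PTs
pooled, or grouping terms — each unit counts once under every HLT/SMQ
whose expansion contains its PT, so grouping counts are unit counts and
PT-level conservation is exact), literature in/out, and IME/DME
restriction (default on, mirroring routine practice of screening only
clinically serious terms).  Multi-drug/multi-event cases are counted once
per distinct (case, drug, PT) triple — the reporting conventions give no
basis for case-level deduplication across terms, and unit counting keeps
pooled series provably equal to sums of PT series.

## Evaluation

A detection is labelled against a concern register: *out of universe* if
its drug matches no registered concern's scope (abuse/misuse concerns are
substance-wide; product-level screens skip them since abuse is not
product-specific); *true positive* if some matching concern's case
definition contains the detected event and the detection month lies in
`[index month - 12, index month + 6]`, inclusive, at month granularity;
*false positive* otherwise.  Quality-defect case definitions exclude PTs
that name the quality issue itself: the algorithm's premise is that
defects are detectable from the reported harms.  PPV is the pooled ratio
TP / (TP + FP) over in-universe detections, reported overall and per
branch (branch PPVs restrict numerator and denominator alike); zero
denominators yield an explicit undefined marker (JSON null), never 0.
Ties (one detection matching several concerns) resolve to the first
concern in id order.

## Synthetic data

The generator emulates a spontaneous-report database with known ground
truth.  Background: for each substance a random subset of PTs, each
pair–month count drawn NB2 with mean `baseline_mu * trend^m` and
dispersion `alpha` via the gamma–Poisson mixture — identical
parameterisation to the detector's, so calibration experiments are exact.
Concern episodes append extra Poisson reports to every PT of a grouping
term so episode months run at `fold_increase` times baseline in
expectation; injected PTs are added to the substance's background
assignment so the fold target is exact.  Packaged defaults: 15
substances, 24 PTs each, `baseline_mu = 2` reports/month (a realistic
rate for a single drug–event pair), `alpha = 0.3`, stationary trend, 10%
literature reports, 90 months (2008-01 to 2015-06), and 13 injected
concerns (5 QD / 5 ME / 3 A/M, fold 6, three-month episodes) mirroring
the structure of the packaged historical register.  A synthetic
single-axial hierarchy (4 SOCs × 2 HLGTs × 3 HLTs × 4 PTs, six SMQs of 8
PTs, 75% IME, plus a quality-issue branch) stands in for the licensed
terminology.

What the generator does **not** emulate: duplicate reports, stimulated
reporting waves, country strata, exposure trends tied to sales, or
multi-axial term assignment.  Passing tests therefore demonstrate the
algorithm's behaviour under its own statistical assumptions, not its
operating characteristics on real regulatory data, whose PPVs are far
lower because the screening universe is orders of magnitude larger.

## Measured operating characteristics

All numbers below are recomputed by the test suite and
`scripts/acceptance.py` at run time; sizes were chosen to keep the whole
suite to a few minutes.  Null calibration (stationary NB(10, 0.3), 10,000
reps, prediction bound, level 0.95, tau = 3): the regression branch's
false-alarm rate stays below the nominal 5% plus Monte-Carlo error.
Power against a deterministic 5× spike under the same null (own 1000-rep
simulation): ≈ 0.89 with the `ci_mean` bound and ≈ 0.62 with the
`prediction` bound — the prediction bound pays for its null conservatism,
because a dispersion overestimated from six points inflates the count
quantile; the test suite asserts floors of 0.84/0.55 set from that
simulation.  End-to-end, the packaged 13-concern scenario is screened
monthly and every injected concern is recovered, with pipeline outputs
byte-for-byte reproducible for a fixed seed.

## Numerical and design notes

* Dates are ISO-8601 everywhere; month keys are `YYYY-MM`; substance and
  product names are matched after case-folding and whitespace collapse
  only (no fuzzy matching).
* The hierarchy is single-axial by construction; the algorithm only needs
  PT-to-grouping membership.
* The screening universe at `t0` is every combination with `y0 >= 1`;
  zero observed count is never a candidate.
* No multiplicity correction is applied across the screened universe; PPV
  against a concern register is the operating metric.
* Per-series fit failures during a screen are logged and skipped, never
  aborting the run.
* Grouping-level screens default to using every HLT and SMQ as keys; a
  narrower key list can be supplied.
* The CLI is a thin layer over the library; `run-all` writes a manifest
  (seed, config snapshot, input digests, row counts) sufficient to
  reproduce its artifact directory byte for byte.

## Known limitations

Six-point fits identify the dispersion poorly; the Poisson fallback is
frequent and intentional.  The `ci_mean` bound understates total
forecast uncertainty (it ignores outcome variance); the `prediction`
bound overstates it when the dispersion estimate is inflated.  The
evaluation window (−12/+6 months) is a pragmatic convention for
retrospectively registered concerns, not an estimate of detection delay.
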