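# Methods

`greyshap` forecasts an annual road-traffic death toll with two member
models — a grey Verhulst trend model and a six-covariate linear
regression — and fuses them into a convex-weighted combined predictor
whose weights come from a Shapley-value apportionment of the members'
forecast errors. This note records the models, the conventions that
matter for reproducing the bundled study tables, the numerical choices,
and the known limitations.

## Grey Verhulst model

The Verhulst (logistic) differential equation

    dx1/dt + a x1 = mu x1^2

describes a quantity decaying (a > 0) toward extinction or saturating
toward the level a/mu. Its grey discretisation replaces the derivative
by a first difference and the state by the consecutive-neighbour mean
z1(k) = (x1(k) + x1(k-1))/2:

    x0(k) + a z1(k) = mu z1(k)^2,   k = 2..n,

where x0 is the first-difference (IAGO) sequence of the accumulated
series x1. The two parameters are estimated by ordinary least squares on
the design [-z1, z1^2] (solved by QR via `numpy.linalg.lstsq`, never by
explicit normal-equation inversion). Fitted and forecast values come
from the whitened time response

    x1_hat(k+1) = a x1(0) / (mu x1(0) + (a - mu x1(0)) e^{a k}),

which returns the anchor x1(0) exactly at k = 0.

**Orientation.** Two conventions are exposed:

- `observed_as_accumulated` (default): the observed series itself plays
  the role of x1. This is the right reading for a series that is already
  S-shaped in level, like the national fatality count, and it is the
  convention the bundled study tables were produced with.
- `classic_ago`: the observed series is cumulated (AGO) first; fitted
  values are recovered by differencing (IAGO). Offered for generality.

**Forecast indexing.** The out-of-sample year `first_year + n + j - 1`
(j = 1..horizon) is evaluated at index k = n + j - 1, the unique
continuation of the in-sample index map. With the bundled series this
gives 56936 for the first hold-out year. The bundled hold-out table's
standalone trend-model entries correspond to shifted indices (its second
year matches k = 12 exactly rather than k = 11) and cannot be reproduced
under any single consistent convention, so they are treated as inputs
where needed (the combined column) and never as forecast oracles.

**Validation.** Observed input series must have at least 4 consecutive
years and strictly positive values (Verhulst dynamics assume positive
states); a constant series makes the 2-column design rank-1 and raises a
degenerate-fit error.

## Linear regression member

Fatalities are regressed with intercept on six macroscopic exposure
covariates: vehicle population (1e4 vehicles), population (1e4 persons),
GDP (1e8 yuan), road freight volume (1e4 t), road passenger volume
(1e4 persons) and road mileage (km). With 10 training years and 7
parameters the residual degrees of freedom are 3, so every reported
diagnostic is small-sample: per-coefficient t values and two-sided
p-values at df = 3, R^2 = 1 - SSE/SST, R = sqrt(R^2), and
F = (R^2/6) / ((1-R^2)/3). Fitting goes through statsmodels' QR-based
OLS; the covariates are strongly collinear (pairwise correlations with
the response all exceed 0.89 in magnitude), which is why the individual
t statistics are all insignificant while F is large. A rank-deficient
design is rejected with the collinear columns named (pivoted QR).

Predictions always use the full-precision refit coefficients. The
display-rounded published equation is matched only at printed precision:
rounding the road-mileage coefficient alone (0.00324 -> 0.003) moves a
prediction by roughly a thousand persons, which is also why the
full-precision hold-out prediction for the first hold-out year (61893)
differs from the published 62402 by about 0.8%.

The printed determination statistic 0.996 is arithmetically inconsistent
with F = 67.431 at df (6, 3), which implies R^2 = 0.9926 and R = 0.9963;
both R and R^2 are reported and neither is asserted against 0.996.

## Error evaluation

Per-year relative error is |observed - predicted| / observed x 100; the
*comprehensive error* is the arithmetic mean of the per-year relative
errors. Inclusion convention: the grey Verhulst fit is exact at its
anchor year by construction, so its comprehensive error averages the
remaining years (9 of 10 here, giving 2.700%); the regression and the
combined model average all years (1.534% and 2.025%). The flag
`exclude_anchor` drops the first year of a report; defaults follow this
rule (`RunConfig.exclude_verhulst_anchor = True`).

## Shapley combination

With member comprehensive errors E_i, the coalition error of any subset
is the arithmetic mean of its members' errors (no joint refitting), so
the grand-coalition error is E = mean(E_i). Each member's Shapley share
is its average marginal contribution over join orders,

    share_i = sum_{s : i in s} (n-|s|)!(|s|-1)!/n! * (E(s) - E(s\{i})),

and efficiency (shares sum to E, asserted to 1e-9) converts shares to
weights omega_i = (E - share_i)/((n-1) E), which sum to 1 identically.

Two conventions matter for bit-compatibility with the bundled tables:

- **Reported-precision inputs.** The allocation consumes the member
  comprehensive errors *as reported*, rounded to 3 decimals (2.700 and
  1.534). This reproduces the shares (0.4755, 1.6415) and weights
  (0.7754, 0.2246) to 4 decimals exactly; full-precision errors are also
  carried on the reproduction bundle.
- **Weight-to-model mapping.** The published combination applies the
  weight derived from the *regression's* error share to the *Verhulst*
  member and vice versa. `mapping="paper"` (default) reproduces this by
  swapping the two weights and is defined only for two members;
  `mapping="consistent"` applies each weight to the model whose error
  produced it and works for any n. The consistent mapping gives a
  visibly different combined column (documented divergence).

**Negative weights.** omega_i < 0 occurs exactly when a member's share
exceeds E; for two members this happens when one error exceeds three
times the other. Negative weights are emitted with a warning and never
clamped, since clamping would silently break the unit sum.

## Synthetic data generator

`generate_logistic` samples the continuous Verhulst solution at integer
years (defaults: the fitted study parameters a = 0.12238288,
mu = 6.89477e-7, x0 = 109381, n = 10). Noise is multiplicative Gaussian
(relative), matching the relative-error evaluation currency; noise 0
returns the exact trajectory. `generate_panel` builds covariates as
geometric trends (per-column start and annual growth, defaults echoing
the real panel's 2002 levels and growth rates) and a response that is
exactly linear in them plus additive Gaussian noise (default sd 500
persons, the scale of the regression's residuals).

What the generator does *not* emulate: policy shocks and regime changes
(such as the collapse of road passenger volume in the second hold-out
year), measurement revisions, and cross-sectional correlation of
covariate innovations. Passing tests therefore demonstrate estimator
correctness under the models' own assumptions, not robustness of the
forecasts to structural breaks — the hold-out years themselves show the
regression failing under a regime change.

## Numerical notes and test design

- The geometric-trend panel is realistically collinear: the default
  design's condition number (~1e9) bounds float64 slope recovery near
  1e-6 relative even with zero noise. Noise-free recovery is asserted at
  1e-5 for the default panel and 1e-8 for a deliberately
  well-conditioned one; exact 10-digit agreement is asserted between the
  QR solve and the closed-form normal equations on the same data, where
  conditioning cancels out.
- Monte-Carlo calibration of the slope estimator (500 seeded replicates)
  uses a 40-year well-conditioned panel so that residual df = 33 makes
  the 3-SE band hold at the 99% level per coefficient; at the study's
  own n = 10 (df = 3) the t tails make 3-SE coverage ~94% per
  coefficient, which is a property of small samples, not a defect.
- Discretisation bias of the grey fit: for noise-free logistic input the
  refit parameters are within 1% of truth for decay rates up to ~0.15
  /year and per-year fitted errors stay below 1% for rates up to 0.3
  /year (both tested on grids).
- Reported predictions are rounded to the nearest person (deaths are
  counts); the pipeline keeps full precision internally, and all printed
  comparisons are made at printed precision only.

## Limitations

- Point forecasts only; no interval or probabilistic output.
- The grey Verhulst member can only describe monotone saturating decline;
  the regression member requires future covariate values to be supplied.
- Only the Shapley weighting scheme is implemented; alternative
  combination weightings (arithmetic average, variance-based, AHP,
  optimal weighting) are out of scope.
- The combination weight formula is the standard error-apportionment
  rule for a fixed member set; adding or removing a member changes every
  weight.
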