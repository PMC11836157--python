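# Methods

## The single-patch MVT model

The package analyses central-place foraging trips to one patch. The gain
curve is the two-parameter saturating form `g(T) = A(1 − e^(−kT))`:
strictly increasing, strictly concave, `g(0) = 0`, bounded by the asymptote
`A`. `A` is the maximum attainable gain in the patch (Euro when gain is
operationalized as money spent, a count when operationalized as number of
products); `k` (1/min) sets the initial rate, `g′(0) = A·k`. Diminishing
returns here need not come from depletion of the shelf: a shopper's list
makes each additional item less valuable, which produces the same concave
shape. A piecewise linear-plateau curve (`slope·min(T, T_plateau)`) is
available in the generator as an alternative truth for robustness checks;
its tangent optimum sits at the plateau corner for every travel time.

Travel time is signed negative throughout the model layer: the tangent
from `(t, 0)` to the curve gives the optimal residence time, so
`t = T − g(T)/g′(T) < 0` for every `T > 0`, and the net gain rate
`g(T)/(T − t)` equals the marginal rate `g′(T)` exactly at the optimum.
Survey files store travel time as the positive number people report; the
I/O layer negates at the model boundary.

The inverse problem — the optimal `T` for a given `t` — solves
`e^(kT) = k(T − t) + 1`. `f(T) = e^(kT) − kT + kt − 1` has `f(0) = kt ≤ 0`
and `f′ > 0` for `T > 0`, so the positive root is unique; it is bracketed
from the closed-form hint `ln(1 + k|t|)/k`, expanded geometrically until
the sign changes, solved by Brent's method and polished by Newton steps to
an absolute residual below 1e-10 (configurable in `model.SOLVER_TOL`).
`T = 0` arises only for `t = 0`; records with zero residence time are
excluded upstream.

## Synthetic surveys

`simulate_foragers` emulates what an intercept survey at a supermarket
records, under the exact assumptions the analysis makes:

* one shared gain curve (defaults `A = 60` Euro, `k = 0.08`/min);
* true round-trip travel times from a log-normal distribution truncated to
  [2, 20] min (μ_log = 2.1, σ_log = 0.55, median ≈ 8 min) — a stand-in for
  an urban on-foot shopping population, not an empirical claim;
* true residence times set to the MVT optimum for each travel time, so the
  model is correctly specified;
* reported values = true values + independent Gaussian reporting error
  (σ_T = σ_t = 2 min, σ_g = 5 Euro), rounded to 1 min / 0.50 Euro and
  floored at 1 min (no zero-minute reports);
* filter attributes and demographics from independent mixtures
  (P(main patch) = 0.70, P(home round trip) = 0.70, P(on foot) = 0.65,
  expected subset fraction ≈ 0.32 of the sample; gender, age, work status,
  household and group size calibrated to a German urban intercept sample);
* each of the three key fields (gain, travel time, residence time) blanked
  independently with probability 0.02 to exercise the exclusion rule.

What the generator does *not* emulate: within-store movement, correlated
reporting errors (people who misjudge travel probably also misjudge
residence time), heaping on "nice" numbers beyond uniform rounding,
context-dependent gain curves, or any dependence of the filter attributes
on times and gains. Passing tests therefore show the pipeline is correct
and calibrated *under its own assumptions*; they do not validate those
assumptions for real surveys.

## Preprocessing

A record is excluded iff gain, travel time or residence time is missing.
The analysable subset then keeps records with main-patch = true, trip type
= home round trip, transport = on foot; filters are applied in that fixed
order purely so attrition counts are reproducible (the subset itself is a
conjunction and order-independent). Shopping-frequency free text is parsed
to times-per-week ("3 or 4 times a week" → 3.5) and binned to
{<1/wk, 1–2/wk, 3–4/wk, 5+/wk}; household size to {1, 2, >2}; age to
{18–29, 30–49, 50+}. These cut-points are package defaults — the source
surveys in this field do not standardize them — and exist for dummy coding
only; inferential group comparisons use a median split (ties to "low").
An estimated-distance column, if present, is dropped on read.

## Orthogonal-distance regression

Both axes carry error, so the fit minimizes Σ‖D_i‖², the squared Euclidean
point-to-curve distances. The footpoint of `(T_obs, g_obs)` minimizes
`(T − T_obs)² + (g(T) − g_obs)²` over `T ≥ 0`; because the vertical
distance at `T_obs` bounds the horizontal excursion of the minimizer, the
bracket `[T_obs − d0, T_obs + d0]` with `d0 = |g(T_obs) − g_obs|` always
contains it, and a coarse scan plus vectorized golden-section resolves it
essentially exactly. The outer search over `(log A, log k)` is Nelder–Mead
from two starts — a heuristic (`A0 = 1.1·max g`,
`k0 = mean g / (A0 · mean T)` clipped to [1e-4, 10]) and the vertical
least-squares estimate — followed by a polish stage with high-accuracy
footpoints; convergence is a relative objective change below 1e-10 or 500
iterations. Starting from the vertical-LS fit mirrors standard orthogonal
nonlinear least-squares practice, and guarantees the fitted orthogonal
objective never exceeds the OLS estimate's.

**Axis scaling.** Orthogonal distances mix minutes and Euro, so the
criterion depends on axis units. In raw units this is not a cosmetic
issue: with reporting errors of a few Euro against a few minutes and curve
slopes of 1–3 Euro/min, a near-linear fit (`A → ∞`, `k → 0`, `A·k` fixed)
rotates its residual direction against the dominant gain-axis error and
*deflates* every residual by `1/√(1 + slope²)`. Whenever the observed
residence-time window shows little curvature — exactly the situation when
travel times cap at ~20 min — the raw-unit objective loses its interior
minimum entirely and descends monotonically along that ridge (ODRPACK
reproduces the same divergence). The default therefore standardizes both
axes to unit variance, where the reporting errors are close to isotropic
and the estimator is well-posed, and maps the estimates back
(`A → A·s_g`, `k → k/s_T`; the model family is closed under axis
scaling). `standardize=False` restores the raw-unit criterion for
sensitivity analysis; a regression test pins its scale dependence.

Residual statistics use `s² = Σ‖D‖²/(n − 2)` and `SE = √s²`, with the two
fitted parameters as model degrees of freedom. Footpoints, residual
lengths and signs (positive above the curve) are always reported in raw
units.

Known limitation: with the default noise levels and a [2, 20] min travel
window the optimal residence times span only ≈ 6–18 min, and `k` is
attenuated toward zero by the errors-in-variables geometry — replicate
studies at n = 61 recover `A` with a median relative error around 20% but
`k` only around 25–30%. This is a property of the estimator under these
conditions, not an optimizer artifact (fits match an exhaustive zoomed
grid search), and it propagates into travel-time predictions, which depend
on `k` alone.

## Diagnostics and tests

* **Paired t-test** of observed vs predicted values, two-tailed,
  `df = n − 1`; exactly constant differences are reported as `t = 0, p = 1`
  (all zero) or flagged degenerate (infinite t).
* **Welch t-test** with Satterthwaite df for group comparisons (gender;
  age via median split).
* **Bias regression**: OLS of observed on predicted; intercept 0 and slope
  1 indicate no systematic bias; identity-line endpoints are returned for
  plotting.
* **Q–Q against chi-square(2)**: squared orthogonal residuals are compared
  to the chi-square(2) reference (the exponential with mean 2; quantiles
  `−2·ln(1 − p)` at plotting positions `(i − ½)/n`, Blom optional).
  Because squared orthogonal residuals carry arbitrary squared-data units,
  they are rescaled by `mean/2` so their mean matches the reference's; an
  unscaled variant is available. Whether a 2-df reference is theoretically
  right for squared distances to a smooth curve is debatable (locally the
  distance is one-dimensional); the package implements the 2-df comparison
  as the field uses it and leaves the question open.
* **Histogram bins**: Freedman–Diaconis, falling back to the square-root
  rule for near-constant inputs.

**Null calibration.** The paired-test stage is calibrated by simulating
correctly specified surveys and testing observed values against
predictions from the *generating* curve. Predicting from parameters fitted
to the same records is not a usable null — the fit absorbs the mean
difference and the rejection rate collapses to zero. Even against the true
curve the test runs slightly hot (≈ 5–8% at the 5% level across seed
streams) because time-axis noise propagates through the concave curve: the
differences acquire a small mean of order ½|g″|σ_T². This is a real,
documented property of the observed-vs-predicted construction, inherited
by any study using it.

## Travel-time evaluation

Predictions use `t = T − (e^(kT) − 1)/k` with the fitted `k` at each
record's observed residence time (the asymptote cancels). Residuals are
vertical in the travel direction — the prediction target — not orthogonal,
`s²` again uses `n − 2`, and a paired t-test compares signed observed and
predicted times (an absolute-value switch exists; signed is the default
because the model's sign convention is part of the prediction).

## Clustering

Two exploratory analyses: Jaccard distance on the socioeconomic dummy
variables and Euclidean distance on the three raw-unit metric variables
(travel time, residence time, gain), both agglomerated with complete
linkage (scipy). Numeric variables are deliberately *not* standardized
before the Euclidean analysis (raw units are the documented convention
here; a caller can standardize upstream). The cluster count is suggested
by the maximum second difference of the merge-height scree series
`h(κ)` (the cost of going below κ+1 clusters), ties to the smallest κ; a
perfectly linear series is flagged `no_elbow`. The full series is always
emitted so a human can overrule the automatic choice. Identical all-zero
dummy rows get Jaccard distance 0 by convention (logged).

## Pipeline, seeds, outputs

`run_pipeline` executes exclusion → subset → clustering (on all complete
records) → ODR fit → diagnostics → travel evaluation, writing each stage's
artifact plus a single `summary.json`. One master seed drives everything;
the generator receives a derived stream (recorded in the summary), and
identical config + seed give a byte-identical summary. An empty subset or
a fit failure aborts gracefully with the error recorded in the summary and
the attrition report still written.

Problem sizes used by the test suite and `scripts/acceptance.py` — 1,000
random parameter pairs for the identity checks, 20 small instances against
the exhaustive grid oracle, 200 replicate fits at n = 61 for parameter
recovery, 1,000 replicates for test calibration, 10,000 draws for the Q–Q
check — are the package's chosen defaults for a laptop-scale run.
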