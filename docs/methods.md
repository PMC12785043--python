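# Methods

`tlbtools` automates two steps of thermal liquid biopsy (TLB) data
processing: baseline correction of differential scanning calorimetry
(DSC) thermograms, and screening of noise-dominated profiles before any
correction is attempted. A thermogram here is an ordered series of
(temperature, excess heat capacity) points for one biofluid sample,
already corrected for the instrument baseline and normalized to protein
concentration upstream; heat-capacity units are carried through
unchanged.

## Baseline correction

DSC baselines — the slowly varying heat-capacity background between the
native and unfolded states — are not uniquely defined, and manual
selection is slow and operator-dependent. The automated procedure:

1. **Trimming.** Points outside the analysis range (default 45–90 °C)
   are dropped. Edge artifacts (heater activation at the start,
   aggregation/precipitation at the end) are removed by a robust fence
   on absolute first differences: leading points are discarded while the
   first |Δ value| exceeds `median(|Δ|) + k·MAD(|Δ|)` (default k = 10),
   and trailing points symmetrically. The median term makes the fence
   well-behaved on noiseless profiles, where the MAD alone collapses to
   ~0; only genuine outlying jumps at the edges are stripped, and a
   clean profile passes through unchanged.

2. **Endpoint detection.** The user supplies an exclusion region — the
   temperature interval housing the transitions (presets: plasma
   48–81 °C, covering the fibrinogen transition near 50–55 °C and the
   main transitions at 60–80 °C; urine 60–80 °C). The pre-transition
   segment is everything strictly below it, the post-transition segment
   strictly above (boundary-equal points belong to the exclusion
   region). On each segment one cubic smoothing spline is fit with its
   penalty chosen by generalized cross-validation (GCV), and a window of
   `window_size` points (default 90, matching a typical acquisition rate
   of ~90 points per minute) slides one point at a time over the spline
   residuals. The window with the smallest sample SD (ddof = 1) of
   residuals is the most stable baseline region. The spline is fit once
   per segment, not per window: refitting per window would cost
   quadratically more and overfit short windows, and a single residual
   trace is also the natural diagnostic to plot. Ties in the SD trace
   (which occur only in degenerate noiseless inputs) are broken toward
   the exclusion region, maximizing the baseline span feeding the
   baseline splines. The endpoint is then the window's innermost point
   (nearest the exclusion region — the default, which agreed best with
   expert manual selection), its midpoint (index `start + (w−1)//2`), or
   its outermost point.

3. **Baseline model and subtraction.** Smoothing splines are fit to the
   data at `T ≤ T_low` and `T ≥ T_high`; between the endpoints the
   baseline is the straight line joining the two *spline-predicted*
   endpoint values (not the raw observations, which would inject point
   noise into the connector), so the model is continuous by
   construction. The baseline is subtracted and the corrected profile is
   resampled onto the uniform 45–90 °C grid in 0.1 °C steps (451 points)
   through one more GCV spline. Grid cells outside the observed
   temperature span are left as NaN — spline extrapolation is unbounded
   and is never performed. Alternative transition-region models
   (sigmoidal, cubic) and adaptive per-profile exclusion regions are
   deliberately out of scope: a fixed region and linear connector keep
   the correction standardized and reproducible across a cohort.

Everything in this path is deterministic: the same input and parameters
give bit-identical output.

Numerical details: the GCV spline requires ≥ 5 points; a segment of
exactly 4 points (the minimum accepted) falls back to the exact cubic
through them. Profiles must retain at least `2·window_size + 10` points
after trimming, and each baseline segment must contain at least
`window_size` points — with the plasma preset this means the 45–48 °C
pre-transition segment needs instrument-grade sampling density (≳ 30
points/°C) for the default window.

## Signal detection

Some biofluids (urine especially) yield profiles with little or no
thermal signal. The screen classifies each profile before baseline
correction so that downstream analysis sees only interpretable data.

The profile is first differenced once (`x[i+1] − x[i]`), which removes
linear instrument drift up to an additive constant. The differenced
series then enters an iterative unit-root search: a KPSS test of level
stationarity (constant regression) is run with the short Bartlett lag
truncation `trunc(4·(n/100)^0.25)`; while the stationarity null is
rejected at `alpha` (default 0.05) the series is differenced again, up
to 2 extra differences. The number of extra differences beyond the
initial one is `d_extra`, and the label is **Signal** exactly when
`d_extra ≥ 1`. Only the differencing-order selection of the auto-ARIMA
machinery is used; AR/MA orders are never fit. A zero-variance series
short-circuits to `d_extra = 0` (NoSignal), since stationarity tests are
undefined on constants.

Why this works: the KPSS statistic is built from partial sums of the
demeaned series. Partial sums of a first-differenced profile
reconstruct the profile itself minus its chord, so a transition's
footprint re-accumulates in the statistic's numerator while the chord
removes drift. Pure white noise, once differenced, has partial sums of
order one noise SD — far below any rejection threshold — which is why
the screen is extremely specific on independent noise.

Properties (verified by tests): the label is invariant to positive
rescaling (the statistic is scale-free) and essentially invariant to
added linear trends; the KPSS rejection rate on true noise sits near the
test's nominal 5% level (a 1–2 point finite-sample size distortion is
expected).

Raw, native-resolution input is the default classifier input. The
baseline-corrected mode exists for comparison, but correction artifacts
on low-signal profiles — inaccurate endpoints distorting the spline —
can flatten subtle transitions and push the classifier toward NoSignal,
so raw mode is the recommended and default choice. Grid cells outside
the observed span are dropped, not imputed, before differencing.

### Detection power on synthetic profiles

An important and deliberate honesty note. For a smooth Gaussian-shaped
transition of amplitude `A·σ` (σ = the i.i.d. noise SD) and width `σ_T`
riding on independent point noise sampled at `ppd` points/°C, the KPSS
statistic of the differenced series **saturates** as `A` grows: the
transition inflates the Bartlett long-run-variance estimate at the same
`A²` rate as the partial-sum numerator. The saturated ceiling is
approximately `2·ppd·σ_T² / (45·(2q+1))` with `q` the lag truncation.
At the generator's default density (10 points/°C) and a realistic
transition width compact enough to sit inside the 60–80 °C exclusion
region (σ_T ≈ 2 °C), that ceiling is ≈ 0.30 — below the 5% critical
value of 0.463 — so *no* amplitude of such a peak is ever called
Signal. Real high-signal thermograms are detected because their
amplitude-to-point-noise ratios run in the hundreds and their noise is
autocorrelated (instrument wander), which the partial sums accumulate.
Consequently, on this package's synthetic strata the classifier is
near-perfectly specific (≈ 100% of pure-noise profiles called NoSignal)
but insensitive to compact peaks at 20·σ amplitude; the acceptance
suite records this honestly (one sensitivity check fails by design of
the conditions), and the evaluation harness prints the measured rates
rather than aspirational ones. Broad transitions (σ_T ≳ 4 °C) at large
amplitude are detected reliably and are what the examples and pipeline
tests use for the Signal path.

## Synthetic data generator

Generated profiles are `drift(T) + Σ Gaussians + iid Normal(0, σ)` on a
uniform temperature grid (default 45–90 °C at 10 points/°C). Gaussian
peaks are a simplification of van 't Hoff two-state unfolding shapes,
chosen because the algorithms are shape-agnostic and Gaussians give
closed-form heights (`A`), areas (`A·σ_T·√(2π)`) and widths
(`2.3548·σ_T`) for oracle tests. The default drift (0.2 − 0.002·T) is a
gentle linear decline of the kind first differencing should annihilate.

Presets: `plasma_like` places four transitions (52.5, 63, 70, 77 °C)
echoing a fibrinogen peak plus a main multi-protein envelope;
`urine_high/moderate/low/nosignal` place a main transition at 68.5 °C
with a 72.5 °C shoulder, at peak amplitudes of 20, 5, 1.5 and 0 times
the noise SD (default σ = 0.01, arbitrary units). Widths (σ_T ≈ 2 °C)
are chosen so the transitions' footprint — defined as where the
noise-free peak curve exceeds 10⁻³ of the tallest amplitude — stays
strictly inside the 60–80 °C exclusion region, which is what makes the
endpoint-placement ground truth well-defined.

What the generator does **not** emulate: autocorrelated instrument
noise, exothermic aggregation dips, scan-rate artifacts, or the
amplitude distributions of real cohorts. Passing tests on this data
demonstrate algorithmic correctness (endpoint search optimality, exact
grid conformance, quantitative recovery of injected transitions,
classifier invariances and specificity), not clinical performance on
real biofluids.

## Problem sizes

Tests and the acceptance script use profiles of ~451 points (45–90 °C
at 10 points/°C), cohorts of 100 profiles per condition, 20 random
segments for the window-search oracle, and 100 paired trials for the
invariance checks — sizes at which every Monte Carlo rate in the suite
is stable to a couple of percentage points.

## Known limitations

- The exclusion region is global per run (with optional per-sample
  overrides), not adaptive; profiles whose transitions leak outside it
  get biased baselines.
- The classifier returns a hard label, not a confidence; borderline
  (low signal-to-noise) profiles are intrinsically unstable under it.
- The plasma preset's narrow pre-transition range (45–48 °C) requires
  dense sampling or a smaller window.
- Excel round-trips are exact for values but not for column order of
  duplicate-named samples; sample ids should be unique.
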