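# tlbtools

Automated processing of **thermal liquid biopsy (TLB)** data:
differential scanning calorimetry (DSC) thermograms of biofluids such as
blood plasma and urine. A thermogram is an ordered series of
(temperature, excess heat capacity) points whose unfolding transitions
carry diagnostic information; before any transition metric can be read
off, the slowly varying heat-capacity baseline must be subtracted, and
profiles with no discernable signal (common in urine, where protein
concentration varies widely) must be screened out. Both steps are
traditionally manual bottlenecks; `tlbtools` automates them for batch
workflows, for researchers processing DSC cohorts from Python or the
shell.

## What it does

**Baseline correction** (`auto_baseline`). Given an exclusion region
[L, U] housing the transitions (presets: plasma 48–81 °C, urine
60–80 °C), the algorithm fits one GCV smoothing spline per outer
segment, slides a `w`-point window (default `w = 90`) over the spline
residuals, and takes the window with the lowest residual SD as the most
stable baseline region; the endpoint is that window's innermost point
(nearest the exclusion region) by default. The baseline is then

    b(T) = s_pre(T)            for T ≤ T_low
           linear connector    for T_low < T < T_high
           s_post(T)           for T ≥ T_high

with the connector anchored at the spline values `s_pre(T_low)` and
`s_post(T_high)`, so `b` is continuous. After subtraction the corrected
profile is resampled onto the uniform 45–90 °C grid (0.1 °C steps, 451
points) for cross-sample comparability; nothing is extrapolated.

**Signal detection** (`detect_signal`). The profile is first
differenced (removing linear drift), then an iterative KPSS
level-stationarity search counts how many *extra* differences the
series needs: `d_extra ≥ 1` ⇒ **Signal**, `d_extra = 0` ⇒ **NoSignal**
(white noise). Raw native-resolution input is the default; corrected
input is available for comparison.

Around these sit a synthetic thermogram generator with ground truth
(drift + Gaussian transitions + i.i.d. noise, plasma/urine presets at
four signal-to-noise strata), CSV/Excel I/O for single-sample,
paired-wide and long layouts, four summary metrics (peak height, T_max,
area, width at half height), a screening-first batch pipeline with
multi-sheet Excel export and metadata capture, and a per-stratum
classifier evaluation harness.

## Worked example

```python
from tlbtools import (EXCLUSION_PRESETS, auto_baseline, basic_metrics,
                      from_preset, generate)

profile, truth = generate(
    from_preset("plasma_like", seed=11, points_per_degree=40))
gridded = auto_baseline(profile, EXCLUSION_PRESETS["plasma"])
fit = gridded.fit_metadata
print(fit.lower_endpoint, fit.upper_endpoint)
print(basic_metrics(gridded))
```

prints (see `examples/01_baseline_correction.py` for the narrated
version):

```
baseline endpoints: 47.2 degC / 82.3 degC (method: innermost)
peak height:       0.2531 at T_max = 63.1 degC
area:              3.6545
width @ half max:  12.49 degC

truth: tallest injected peak 0.2542 at 63.1 degC
```

The detected endpoints bracket the 48–81 °C exclusion region from
within the stable baseline segments, and the corrected curve recovers
the injected main transition's height (0.2531 vs 0.2542 true) and
position exactly at the grid resolution. The other examples cover
signal detection (`02`), the batch pipeline with Excel export (`03`)
and the per-stratum classifier evaluation (`04`).

The same functionality is available from the shell:

```sh
tlbtools simulate --preset urine_high --n 8 --seed 1 --output batch.csv
tlbtools process --input batch.csv --output out.xlsx --format xlsx --preset urine
tlbtools evaluate --n-per-stratum 25 --seed 1
```

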