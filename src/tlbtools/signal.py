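"""Signal detection: is there a discernable thermal transition?

Biofluids with variable protein concentration (urine especially) produce
thermograms ranging from strong, well-defined unfolding transitions down
to pure instrument noise. Baseline-correcting a noise-dominated profile
is meaningless, so profiles are screened first.

The screen is a two-step time-series procedure. The profile is first
differenced once, which annihilates linear background drift up to a
constant. The differenced series is then run through an iterative
unit-root search in the style of the forecast package's ``ndiffs``: a
KPSS level-stationarity test (constant regression, short Bartlett lag
truncation ``trunc(4 * (n/100)**0.25)``) is applied; while the null of
stationarity is rejected at ``alpha`` the series is differenced again,
up to ``max_d`` extra differences. A profile whose first-differenced
series already looks stationary is white noise ("NoSignal"); one that
needs extra differencing contains accumulated low-frequency structure —
a transition — and is labeled "Signal". Only the differencing-order
machinery of auto-ARIMA is used; no AR/MA orders are fit.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
from statsmodels.tools.sm_exceptions import InterpolationWarning
from statsmodels.tsa.stattools import kpss

from .exceptions import ThermogramError
from .profiles import GriddedProfile, SignalClassification, ThermogramProfile

__all__ = ["first_difference", "required_differences", "detect_signal"]

#: Minimum series length for the stationarity search, and minimum number
#: of finite profile points for classification (one point is consumed by
#: the initial first difference).
MIN_SERIES = 20
MIN_PROFILE_POINTS = 22


def first_difference(values: Sequence[float]) -> np.ndarray:
    """Successive differences ``out[i] = values[i+1] - values[i]``."""
    v = np.asarray(values, float)
    if v.size < 2:
        raise ThermogramError("first difference needs at least 2 values")
    return np.diff(v)


def _kpss_short(values: np.ndarray) -> tuple[float, float]:
    """KPSS level-stationarity test with the short lag truncation.

    Returns (statistic, p-value). The p-value is table-interpolated and
    clamped to [0.01, 0.10] as usual for this test.
    """
    nlags = int(4 * (values.size / 100.0) ** 0.25)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", InterpolationWarning)
        stat, pvalue, _, _ = kpss(values, regression="c", nlags=nlags)
    return float(stat), float(pvalue)


def required_differences(
    values: Sequence[float],
    alpha: float = 0.05,
    max_d: int = 2,
    record: list[float] | None = None,
) -> int:
    """Number of differencing steps needed for level stationarity.

    Iteratively applies the KPSS test and differences while the null of
    stationarity is rejected at ``alpha``, up to ``max_d`` differences.
    A zero-variance (constant) series at any stage returns immediately
    without testing, since stationarity tests are undefined on
    constants. Stage p-values are appended to ``record`` if given.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    x = np.asarray(values, float)
    d = 0
    while True:
        if x.size < MIN_SERIES:
            raise ThermogramError(
                f"series of {x.size} values is too short for the "
                f"stationarity search (need {MIN_SERIES})"
            )
        if np.ptp(x) == 0:
            return d
        _, pvalue = _kpss_short(x)
        if record is not None:
            record.append(pvalue)
        if pvalue >= alpha or d >= max_d:
            return d
        x = np.diff(x)
        d += 1


def detect_signal(
    profile: ThermogramProfile | GriddedProfile,
    input_mode: str = "raw",
    alpha: float = 0.05,
) -> SignalClassification:
    """Classify a thermogram as Signal or NoSignal.

    ``raw`` mode consumes a native-resolution :class:`ThermogramProfile`
    (recommended: baseline-correction artifacts on low-signal profiles
    can mask subtle transitions); ``baseline_corrected`` mode consumes
    the grid values of a :class:`GriddedProfile`. NaN grid cells are
    dropped, never imputed. The label is Signal exactly when the
    first-differenced series needs at least one further difference to
    reach stationarity.
    """
    if input_mode not in ("raw", "baseline_corrected"):
        raise ValueError(f"unknown input_mode {input_mode!r}")
    if isinstance(profile, GriddedProfile):
        values = profile.corrected_values
    else:
        values = profile.heat_capacity
    values = np.asarray(values, float)
    values = values[np.isfinite(values)]
    if values.size < MIN_PROFILE_POINTS:
        raise ThermogramError(
            f"[{profile.sample_id}] {values.size} finite points; signal "
            f"detection needs at least {MIN_PROFILE_POINTS}"
        )
    d1 = first_difference(values)
    pvalues: list[float] = []
    d_extra = required_differences(d1, alpha=alpha, record=pvalues)
    return SignalClassification(
        sample_id=profile.sample_id,
        d_extra=d_extra,
        test_name="kpss",
        test_pvalues=tuple(pvalues),
        input_mode=input_mode,
    )
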