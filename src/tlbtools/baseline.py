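"""Automated baseline correction for TLB thermograms.

The procedure has three steps:

1. **Endpoint detection.** The trimmed profile is split into a
   pre-transition segment (strictly below the exclusion region), the
   exclusion region itself, and a post-transition segment (strictly
   above). One smoothing spline with a generalized-cross-validation
   (GCV) penalty is fit to each outer segment; a window of fixed size is
   slid one point at a time across the segment and the sample standard
   deviation of the spline residuals in each window is computed. The
   window with the lowest residual SD is the most stable baseline
   region, and the endpoint is taken at its innermost point (nearest the
   exclusion region), its midpoint, or its outermost point.

2. **Baseline model.** Smoothing splines are fit to the data below the
   lower endpoint and above the upper endpoint; the two spline values at
   the endpoints are joined by a straight line across the exclusion
   region, giving a continuous baseline over the whole profile.

3. **Subtraction and gridding.** The baseline is subtracted and the
   corrected profile is resampled onto the uniform 45-90 degC grid
   (0.1 degC steps) through one more smoothing-spline fit. Grid cells
   outside the observed temperature span stay NaN.

Everything here is deterministic: identical input and parameters give
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.interpolate import make_smoothing_spline

from .exceptions import ThermogramError, UnprocessableProfileError
from .profiles import (
    BaselineFit,
    EndpointParams,
    ExclusionRegion,
    GriddedProfile,
    GridSpec,
    ThermogramProfile,
)

__all__ = [
    "trim_profile",
    "find_stable_window",
    "select_endpoint",
    "fit_baseline",
    "auto_baseline",
    "multiple_auto_baseline",
    "BaselineFailure",
]


def _smooth_spline(x: np.ndarray, y: np.ndarray) -> Callable[[np.ndarray], np.ndarray]:
    """Smoothing spline with GCV-chosen penalty.

    scipy's GCV spline needs at least 5 points; a segment of exactly 4
    points falls back to the exact cubic through them.
    """
    if x.size >= 5:
        return make_smoothing_spline(x, y)
    # degree n-1 polynomial interpolates exactly; centre x for conditioning
    x0 = x.mean()
    coef = np.polynomial.polynomial.polyfit(x - x0, y, deg=x.size - 1)
    return lambda t: np.polynomial.polynomial.polyval(np.asarray(t) - x0, coef)


def trim_profile(
    profile: ThermogramProfile,
    trim_low: float = 45.0,
    trim_high: float = 90.0,
    spike_k: float = 10.0,
    window_size: int = 90,
) -> ThermogramProfile:
    """Restrict to [trim_low, trim_high] and strip edge artifacts.

    Thermograms often carry large excursions at the very start (heater
    activation) or end (protein aggregation/precipitation). After the
    range filter, leading points are removed while the first absolute
    first-difference exceeds a robust outlier fence,
    ``median(|d|) + spike_k * MAD(|d|)`` over all absolute first
    differences, and trailing points are removed symmetrically.

    Raises
    ------
    UnprocessableProfileError
        If fewer than ``2 * window_size + 10`` points remain.
    """
    if spike_k <= 0:
        raise ValueError("spike_k must be positive")
    t, v = profile.temperatures, profile.heat_capacity
    keep = (t >= trim_low) & (t <= trim_high)
    t, v = t[keep], v[keep]

    def fence() -> float:
        d = np.abs(np.diff(v))
        med = np.median(d)
        mad = np.median(np.abs(d - med))
        return med + spike_k * mad

    while t.size > 2 and abs(v[1] - v[0]) > fence():
        t, v = t[1:], v[1:]
    while t.size > 2 and abs(v[-1] - v[-2]) > fence():
        t, v = t[:-1], v[:-1]

    if t.size < 2 * window_size + 10:
        raise UnprocessableProfileError(
            f"only {t.size} points remain after trimming to "
            f"[{trim_low}, {trim_high}]; need {2 * window_size + 10}",
            sample_id=profile.sample_id,
        )
    return ThermogramProfile(profile.sample_id, t, v, source=profile.source)


def find_stable_window(
    segment_temps: Sequence[float],
    segment_values: Sequence[float],
    window_size: int,
    side: Literal["pre", "post"] = "pre",
) -> tuple[int, np.ndarray]:
    """Locate the most stable baseline window within one segment.

    Fits a single GCV smoothing spline to the whole segment, then scans
    a window of ``window_size`` points with stride one over the spline
    residuals and returns ``(start_index, sds)`` where ``sds[k]`` is the
    sample SD (ddof=1) of the residuals in the window starting at ``k``
    and ``start_index`` is the argmin. Ties are broken toward the
    exclusion region: the highest start index on the pre side, the
    lowest on the post side, so the retained baseline span is maximal.
    """
    t = np.asarray(segment_temps, float)
    v = np.asarray(segment_values, float)
    n = t.size
    if n < window_size:
        raise ThermogramError(
            f"segment of {n} points is shorter than window_size={window_size}"
        )
    spline = _smooth_spline(t, v)
    resid = v - spline(t)
    windows = sliding_window_view(resid, window_size)
    sds = windows.std(axis=1, ddof=1)
    best = sds.min()
    candidates = np.flatnonzero(sds == best)
    start = int(candidates[-1] if side == "pre" else candidates[0])
    return start, sds


def select_endpoint(
    segment_temps: Sequence[float],
    window_start: int,
    window_size: int,
    side: Literal["pre", "post"],
    method: str = "innermost",
) -> float:
    """Pick the endpoint temperature from the most stable window.

    On the pre-transition side the innermost point is the
    highest-temperature point of the window and the outermost the
    lowest; the post-transition side mirrors this. The midpoint is the
    point at ``window_start + (window_size - 1) // 2`` on both sides.
    """
    t = np.asarray(segment_temps, float)
    last = window_start + window_size - 1
    if window_start < 0 or last >= t.size:
        raise ThermogramError("window does not fit inside the segment")
    if method == "midpoint":
        idx = window_start + (window_size - 1) // 2
    elif method == "innermost":
        idx = last if side == "pre" else window_start
    elif method == "outermost":
        idx = window_start if side == "pre" else last
    else:
        raise ValueError(f"unknown endpoint method {method!r}")
    return float(t[idx])


def fit_baseline(
    profile: ThermogramProfile,
    lower_endpoint: float,
    upper_endpoint: float,
) -> BaselineFit:
    """Model the baseline given the two endpoints.

    Smoothing splines are fit to the points at ``T <= lower_endpoint``
    and ``T >= upper_endpoint``; between the endpoints the baseline is
    the straight line joining the two spline values at the endpoints, so
    the model is continuous by construction.
    """
    if not lower_endpoint < upper_endpoint:
        raise ThermogramError(
            f"lower endpoint {lower_endpoint} must be below upper endpoint "
            f"{upper_endpoint}"
        )
    t, v = profile.temperatures, profile.heat_capacity
    pre = t <= lower_endpoint
    post = t >= upper_endpoint
    if pre.sum() < 4:
        raise ThermogramError(
            f"[{profile.sample_id}] pre-transition side has {int(pre.sum())} "
            f"points below {lower_endpoint}; need at least 4"
        )
    if post.sum() < 4:
        raise ThermogramError(
            f"[{profile.sample_id}] post-transition side has "
            f"{int(post.sum())} points above {upper_endpoint}; need at least 4"
        )
    pre_spline = _smooth_spline(t[pre], v[pre])
    post_spline = _smooth_spline(t[post], v[post])

    y_low = float(pre_spline(np.asarray(lower_endpoint)))
    y_high = float(post_spline(np.asarray(upper_endpoint)))

    baseline = np.empty_like(v)
    baseline[pre] = pre_spline(t[pre])
    baseline[post] = post_spline(t[post])
    mid = ~pre & ~post
    slope = (y_high - y_low) / (upper_endpoint - lower_endpoint)
    baseline[mid] = y_low + slope * (t[mid] - lower_endpoint)
    if not np.all(np.isfinite(baseline)):
        raise ThermogramError(
            f"[{profile.sample_id}] baseline model produced non-finite values"
        )
    return BaselineFit(lower_endpoint, upper_endpoint, baseline)


def auto_baseline(
    profile: ThermogramProfile,
    exclusion: ExclusionRegion,
    params: EndpointParams = EndpointParams(),
    grid: GridSpec = GridSpec(),
    trim: bool = True,
) -> GriddedProfile:
    """Full automated baseline correction of one thermogram.

    Pipeline: trim -> moving-window endpoint detection independently on
    the pre- and post-transition segments -> spline + linear baseline ->
    subtraction -> smoothing-spline resampling onto the uniform grid.
    The detected endpoints and residual-SD traces are recorded in
    ``fit_metadata``. Grid cells outside the observed span are NaN.
    """
    w = params.window_size
    if trim:
        profile = trim_profile(profile, grid.start, grid.end, window_size=w)
    else:
        profile.require_processable(w)
    t, v = profile.temperatures, profile.heat_capacity

    pre = t < exclusion.lower
    post = t > exclusion.upper
    for side, mask in (("pre", pre), ("post", post)):
        if mask.sum() < w:
            raise UnprocessableProfileError(
                f"{side}-transition segment has {int(mask.sum())} points "
                f"outside exclusion ({exclusion.lower}, {exclusion.upper}); "
                f"window_size={w} requires at least {w}",
                sample_id=profile.sample_id,
            )

    pre_start, pre_sds = find_stable_window(t[pre], v[pre], w, side="pre")
    post_start, post_sds = find_stable_window(t[post], v[post], w, side="post")
    t_low = select_endpoint(t[pre], pre_start, w, "pre", params.method)
    t_high = select_endpoint(t[post], post_start, w, "post", params.method)

    fit = fit_baseline(profile, t_low, t_high)
    fit.pre_window_sds = pre_sds
    fit.post_window_sds = post_sds
    fit.method = params.method

    corrected = v - fit.baseline_values
    grid_t = grid.temperatures()
    grid_v = np.full(grid_t.shape, np.nan)
    inside = (grid_t >= t[0]) & (grid_t <= t[-1])
    spline = _smooth_spline(t, corrected)
    grid_v[inside] = spline(grid_t[inside])
    return GriddedProfile(profile.sample_id, grid_t, grid_v, fit_metadata=fit)


@dataclass
class BaselineFailure:
    """Record of a per-sample failure during batch baseline correction."""

    sample_id: str
    error: str


def multiple_auto_baseline(
    profiles: Sequence[ThermogramProfile],
    exclusion: ExclusionRegion,
    params: EndpointParams = EndpointParams(),
    grid: GridSpec = GridSpec(),
    overrides: dict[str, ExclusionRegion] | None = None,
) -> tuple[list[GriddedProfile], list[BaselineFailure]]:
    """Batch baseline correction with per-sample failure isolation.

    Applies :func:`auto_baseline` to each profile independently;
    failures are collected as :class:`BaselineFailure` records instead
    of being raised, and output order matches input order. ``overrides``
    maps sample ids to per-sample exclusion regions.
    """
    overrides = overrides or {}
    out: list[GriddedProfile] = []
    failures: list[BaselineFailure] = []
    for p in profiles:
        try:
            excl = overrides.get(p.sample_id, exclusion)
            out.append(auto_baseline(p, excl, params, grid))
        except Exception as exc:  # isolation is the contract
            failures.append(BaselineFailure(p.sample_id, str(exc)))
    return out, failures
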