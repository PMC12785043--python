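"""Core domain types for thermal liquid biopsy (TLB) thermograms.

A thermogram is an ordered series of (temperature, excess heat capacity)
points recorded by differential scanning calorimetry of a biofluid. The
types here carry a profile through the processing pipeline: raw profile ->
baseline fit -> baseline-corrected values on a uniform temperature grid ->
binary Signal / No-Signal classification.

Heat-capacity units are deliberately not interpreted: values are carried
through unchanged (e.g. cal per degC per g after upstream concentration
normalization).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .exceptions import UnprocessableProfileError

EndpointMethod = Literal["innermost", "midpoint", "outermost"]

#: Uniform output grid: 45.0, 45.1, ..., 90.0 degC (451 points).
GRID_START = 45.0
GRID_END = 90.0
GRID_STEP = 0.1


@dataclass(frozen=True)
class GridSpec:
    """Uniform temperature grid for cross-sample comparability.

    Defaults to 45-90 degC in 0.1 degC increments (451 points).
    """

    start: float = GRID_START
    end: float = GRID_END
    step: float = GRID_STEP

    def __post_init__(self):
        if not (self.start < self.end and self.step > 0):
            raise ValueError("grid requires start < end and step > 0")
        span = self.end - self.start
        n = span / self.step
        if abs(n - round(n)) > 1e-9 * max(1.0, n):
            raise ValueError(
                f"grid step {self.step} does not divide span {span} evenly"
            )

    @property
    def n_points(self) -> int:
        return int(round((self.end - self.start) / self.step)) + 1

    def temperatures(self) -> np.ndarray:
        return np.linspace(self.start, self.end, self.n_points)


@dataclass(frozen=True)
class ExclusionRegion:
    """Temperature interval excluded from baseline fitting.

    The exclusion region houses the unfolding transitions; baseline
    endpoints are searched strictly below ``lower`` and strictly above
    ``upper``. Published presets: plasma 48-81 degC (covers the fibrinogen
    transition near 50-55 degC and the main transitions at 60-80 degC),
    urine 60-80 degC.
    """

    lower: float
    upper: float

    def __post_init__(self):
        if not self.lower < self.upper:
            raise ValueError(
                f"exclusion region requires lower < upper, got "
                f"({self.lower}, {self.upper})"
            )


#: Named exclusion-region presets by sample type.
EXCLUSION_PRESETS: dict[str, ExclusionRegion] = {
    "plasma": ExclusionRegion(48.0, 81.0),
    "urine": ExclusionRegion(60.0, 80.0),
}

#: Default exclusion region when none is given.
DEFAULT_EXCLUSION = EXCLUSION_PRESETS["urine"]


@dataclass(frozen=True)
class EndpointParams:
    """Parameters of the moving-window baseline endpoint search.

    window_size
        Number of consecutive points per window; typically matched to the
        instrument acquisition rate (~90 points per minute), default 90.
    method
        Which point of the most stable window becomes the endpoint:
        ``innermost`` (nearest the exclusion region, the default, which
        agreed best with expert manual selection), ``midpoint`` or
        ``outermost``.
    """

    window_size: int = 90
    method: EndpointMethod = "innermost"

    def __post_init__(self):
        if self.window_size < 5:
            raise ValueError("window_size must be >= 5")
        if self.method not in ("innermost", "midpoint", "outermost"):
            raise ValueError(f"unknown endpoint method {self.method!r}")


@dataclass
class ThermogramProfile:
    """One sample's ordered (temperature, heat capacity) series.

    Temperatures must be strictly increasing with no missing values; the
    loader enforces this (sorting, duplicate averaging, NaN-row dropping).
    """

    sample_id: str
    temperatures: np.ndarray
    heat_capacity: np.ndarray
    source: str | None = None

    def __post_init__(self):
        t = np.asarray(self.temperatures, dtype=float)
        v = np.asarray(self.heat_capacity, dtype=float)
        if t.ndim != 1 or v.ndim != 1 or t.size != v.size:
            raise ValueError(
                f"[{self.sample_id}] temperatures and heat_capacity must be "
                f"1-D and of equal length"
            )
        if t.size < 2:
            raise ValueError(f"[{self.sample_id}] need at least 2 points")
        if np.isnan(t).any() or np.isnan(v).any():
            raise ValueError(f"[{self.sample_id}] NaN values are not allowed")
        if not np.all(np.diff(t) > 0):
            raise ValueError(
                f"[{self.sample_id}] temperatures must be strictly increasing"
            )
        self.temperatures = t
        self.heat_capacity = v

    @property
    def n_points(self) -> int:
        return int(self.temperatures.size)

    def is_processable(self, window_size: int = 90) -> bool:
        """Whether the profile is long enough for endpoint detection."""
        return self.n_points >= 2 * window_size + 10

    def require_processable(self, window_size: int = 90) -> None:
        if not self.is_processable(window_size):
            raise UnprocessableProfileError(
                f"profile has {self.n_points} points; endpoint detection with "
                f"window_size={window_size} requires at least "
                f"{2 * window_size + 10}",
                sample_id=self.sample_id,
            )


@dataclass
class BaselineFit:
    """Result of baseline endpoint detection and baseline modeling.

    ``baseline_values`` is the modeled baseline evaluated on the profile's
    own temperatures: the pre-transition spline below ``lower_endpoint``,
    the post-transition spline above ``upper_endpoint`` and the linear
    connector in between. The per-window residual standard deviation
    traces are kept as diagnostics of the moving-window search.
    """

    lower_endpoint: float
    upper_endpoint: float
    baseline_values: np.ndarray
    pre_window_sds: np.ndarray | None = None
    post_window_sds: np.ndarray | None = None
    method: EndpointMethod = "innermost"


@dataclass
class GriddedProfile:
    """Baseline-corrected values on the uniform temperature grid.

    Grid cells outside the observed temperature span are NaN (no
    extrapolation is ever performed).
    """

    sample_id: str
    grid_temperatures: np.ndarray
    corrected_values: np.ndarray
    fit_metadata: BaselineFit | None = None

    def __post_init__(self):
        self.grid_temperatures = np.asarray(self.grid_temperatures, float)
        self.corrected_values = np.asarray(self.corrected_values, float)
        if self.grid_temperatures.shape != self.corrected_values.shape:
            raise ValueError(
                f"[{self.sample_id}] grid and values must align"
            )


@dataclass
class SignalClassification:
    """Binary Signal / No-Signal call with its stationarity evidence.

    ``d_extra`` is the number of differencing steps the stationarity
    search applied beyond the initial first difference; the profile is
    labeled Signal exactly when at least one extra difference was needed.
    """

    sample_id: str
    d_extra: int
    test_name: str = "kpss"
    test_pvalues: tuple[float, ...] = field(default_factory=tuple)
    input_mode: Literal["raw", "baseline_corrected"] = "raw"

    def __post_init__(self):
        if self.d_extra not in (0, 1, 2):
            raise ValueError("d_extra must be in {0, 1, 2}")

    @property
    def label(self) -> str:
        return "Signal" if self.d_extra >= 1 else "NoSignal"

    @property
    def is_signal(self) -> bool:
        return self.d_extra >= 1
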