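"""Synthetic thermogram generator.

The study's plasma and urine datasets are not public, so every algorithm
in this package is exercised on generated profiles:

    value(T) = drift(T) + sum_j A_j * exp(-(T - c_j)^2 / (2 s_j^2)) + eps,
    eps ~ iid Normal(0, noise_sigma)

i.e. a polynomial background drift (degree <= 2), Gaussian-shaped
unfolding transitions, and white measurement noise. Gaussian peaks are a
deliberate simplification of two-state unfolding thermodynamics: the
algorithms under test are shape-agnostic and Gaussians have closed-form
heights, areas and widths for oracle tests.

Presets emulate the profile families seen in biofluid TLB data: a
plasma-like multi-transition profile (main transitions at 60-80 degC and
a smaller fibrinogen-like transition near 50-55 degC) and four urine
signal-to-noise strata (high / moderate / low / no signal) whose peak
amplitudes are 20, 5, 1.5 and 0 times the noise SD. The strata are
analogs of expert-adjudicated classes, not reproductions.

Every generated profile comes with a ground-truth record (noise-free
drift and peak curves, the exact noise draw, and a signal-free mask) so
tests can check conservation and endpoint placement against truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .profiles import ThermogramProfile

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "generate",
    "generate_cohort",
    "CohortMember",
    "PRESETS",
    "STRATUM_AMPLITUDES",
    "from_preset",
]

#: Peak amplitude as a multiple of noise_sigma, per signal-to-noise stratum.
STRATUM_AMPLITUDES: dict[str, float] = {
    "high": 20.0,
    "moderate": 5.0,
    "low": 1.5,
    "nosignal": 0.0,
}

#: Default measurement-noise SD (heat-capacity units are arbitrary).
_NOISE = 0.01

#: Relative urine peak geometry: a main transition and a shoulder, both
#: compact within the 60-80 degC urine exclusion region.
_URINE_PEAKS = ((68.5, 2.0, 1.0), (72.5, 1.8, 0.6))

#: Relative plasma peak geometry: fibrinogen-like transition near 52 degC
#: plus the main multi-protein envelope at 60-80 degC.
_PLASMA_PEAKS = (
    (52.5, 1.5, 0.35),
    (63.0, 2.5, 1.0),
    (70.0, 2.5, 0.8),
    (77.0, 2.0, 0.45),
)

_PRESET_TABLE: dict[str, tuple[tuple, float]] = {
    # name -> (relative peaks, amplitude multiple of noise_sigma)
    "plasma_like": (_PLASMA_PEAKS, 25.0),
    "urine_high": (_URINE_PEAKS, STRATUM_AMPLITUDES["high"]),
    "urine_moderate": (_URINE_PEAKS, STRATUM_AMPLITUDES["moderate"]),
    "urine_low": (_URINE_PEAKS, STRATUM_AMPLITUDES["low"]),
    "urine_nosignal": ((), STRATUM_AMPLITUDES["nosignal"]),
}

PRESETS = tuple(_PRESET_TABLE)


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic thermogram.

    drift holds ascending polynomial coefficients (c0, c1, c2); peaks
    are (center degC, width sigma degC, amplitude) triples.
    """

    temp_range: tuple[float, float] = (45.0, 90.0)
    points_per_degree: int = 10
    drift: tuple[float, ...] = (0.0,)
    peaks: tuple[tuple[float, float, float], ...] = ()
    noise_sigma: float = 0.0
    seed: int = 0
    preset: str | None = None

    def __post_init__(self):
        lo, hi = self.temp_range
        if not lo < hi:
            raise ValueError("temp_range must satisfy start < end")
        if self.points_per_degree < 1:
            raise ValueError("points_per_degree must be >= 1")
        if len(self.drift) > 3:
            raise ValueError("drift polynomial degree must be <= 2")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        for center, width, _ in self.peaks:
            if not lo <= center <= hi:
                raise ValueError(
                    f"peak center {center} outside temp_range {self.temp_range}"
                )
            if width <= 0:
                raise ValueError("peak width must be positive")
        if self.preset == "plasma_like":
            centers = sorted(c for c, _, _ in self.peaks)
            if not any(50 <= c <= 55 for c in centers) or not all(
                (50 <= c <= 55) or (60 <= c <= 80) for c in centers
            ):
                raise ValueError(
                    "plasma_like preset requires peak centers in [60, 80] "
                    "plus one additional peak in [50, 55]"
                )


def from_preset(name: str, seed: int = 0, noise_sigma: float = _NOISE,
                **overrides) -> SyntheticSpec:
    """Build a :class:`SyntheticSpec` from a named preset.

    Peak amplitudes scale with ``noise_sigma`` through the stratum
    multipliers so signal-to-noise ratio is preserved under rescaling.
    """
    if name not in _PRESET_TABLE:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESETS}")
    rel_peaks, multiple = _PRESET_TABLE[name]
    amp = multiple * noise_sigma
    peaks = tuple((c, w, a * amp) for c, w, a in rel_peaks)
    spec = SyntheticSpec(
        drift=(0.2, -0.002),
        peaks=peaks,
        noise_sigma=noise_sigma,
        seed=seed,
        preset=name,
    )
    return replace(spec, **overrides) if overrides else spec


@dataclass
class GroundTruth:
    """Noise-free decomposition of a generated profile."""

    temperatures: np.ndarray
    drift_curve: np.ndarray
    peak_curve: np.ndarray
    noise: np.ndarray
    #: True where the noise-free peak contribution is negligible
    #: (< 1e-3 of the largest peak amplitude); everywhere if no peaks.
    signal_free_mask: np.ndarray
    has_signal: bool
    peaks: tuple[tuple[float, float, float], ...] = field(default_factory=tuple)


def _curves(spec: SyntheticSpec, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    drift = np.polynomial.polynomial.polyval(t, np.asarray(spec.drift, float))
    peak = np.zeros_like(t)
    for center, width, amp in spec.peaks:
        peak += amp * np.exp(-((t - center) ** 2) / (2.0 * width**2))
    return drift, peak


def generate(spec: SyntheticSpec) -> tuple[ThermogramProfile, GroundTruth]:
    """Generate one profile plus its ground truth, deterministically."""
    lo, hi = spec.temp_range
    n = int(round((hi - lo) * spec.points_per_degree)) + 1
    t = np.linspace(lo, hi, n)
    drift, peak = _curves(spec, t)
    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(0.0, spec.noise_sigma, n) if spec.noise_sigma > 0 else np.zeros(n)
    values = drift + peak + noise
    # store the realized residual so value - drift - peak == noise exactly
    noise = values - drift - peak

    max_amp = max((abs(a) for _, _, a in spec.peaks), default=0.0)
    if max_amp > 0:
        signal_free = np.abs(peak) < 1e-3 * max_amp
    else:
        signal_free = np.ones(n, dtype=bool)

    name = spec.preset or "synthetic"
    profile = ThermogramProfile(
        sample_id=f"{name}_seed{spec.seed}",
        temperatures=t,
        heat_capacity=values,
        source="synthetic",
    )
    truth = GroundTruth(
        temperatures=t,
        drift_curve=drift,
        peak_curve=peak,
        noise=noise,
        signal_free_mask=signal_free,
        has_signal=max_amp > 0,
        peaks=spec.peaks,
    )
    return profile, truth


@dataclass
class CohortMember:
    profile: ThermogramProfile
    stratum: str
    truth: GroundTruth


def generate_cohort(
    n_per_stratum: int,
    strata: Sequence[str],
    base_seed: int = 0,
    noise_sigma: float = _NOISE,
) -> list[CohortMember]:
    """Reproducible cohort of profiles across signal-to-noise strata.

    Per-profile seeds are drawn once from ``base_seed`` so the cohort is
    stable across runs; sample ids are made unique per member.
    """
    if n_per_stratum < 1:
        raise ValueError("n_per_stratum must be >= 1")
    strata = list(strata)
    rng = np.random.default_rng(base_seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_per_stratum * len(strata))
    out: list[CohortMember] = []
    k = 0
    for stratum in strata:
        for i in range(n_per_stratum):
            spec = from_preset(stratum, seed=int(seeds[k]), noise_sigma=noise_sigma)
            profile, truth = generate(spec)
            profile.sample_id = f"{stratum}_{i:03d}"
            out.append(CohortMember(profile, stratum, truth))
            k += 1
    return out
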