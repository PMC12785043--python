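import numpy as np
import pytest

from tlbtools import ExclusionRegion, ThermogramProfile, SyntheticSpec, generate

URINE = ExclusionRegion(60.0, 80.0)


def make_profile(sample_id="s", start=45.0, end=90.0, ppd=10,
                 fn=lambda t: np.zeros_like(t)):
    t = np.linspace(start, end, int(round((end - start) * ppd)) + 1)
    return ThermogramProfile(sample_id, t, fn(t))


def gaussian(center, width, amplitude):
    return lambda t: amplitude * np.exp(-((t - center) ** 2) / (2 * width**2))


@pytest.fixture
def urine_high():
    """One reproducible high signal-to-noise urine-like profile."""
    spec = SyntheticSpec(
        drift=(0.2, -0.002),
        peaks=((68.5, 2.0, 0.2), (72.5, 1.8, 0.12)),
        noise_sigma=0.01,
        seed=7,
    )
    return generate(spec)
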