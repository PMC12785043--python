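"""Baseline-correct one synthetic plasma-like thermogram.

Generates a multi-transition profile (fibrinogen-like peak near 52 degC,
main transitions at 60-80 degC) on a drifting background, runs the
automated endpoint detection + spline/linear baseline model with the
plasma exclusion preset (48-81 degC), and prints the detected endpoints
and summary metrics of the corrected curve.
"""

import numpy as np

from tlbtools import (
    EXCLUSION_PRESETS,
    auto_baseline,
    basic_metrics,
    from_preset,
    generate,
)

# The plasma exclusion region (48-81 degC) leaves only 45-48 degC of
# pre-transition baseline, so the 90-point window needs instrument-like
# sampling density (tens of points per degC) to fit.
profile, truth = generate(
    from_preset("plasma_like", seed=11, points_per_degree=40))
gridded = auto_baseline(profile, EXCLUSION_PRESETS["plasma"])

fit = gridded.fit_metadata
print(f"sample:            {profile.sample_id} ({profile.n_points} points)")
print(f"baseline endpoints: {fit.lower_endpoint:.1f} degC / "
      f"{fit.upper_endpoint:.1f} degC (method: {fit.method})")
print(f"grid:              {gridded.grid_temperatures.size} points, "
      f"{gridded.grid_temperatures[0]:.1f}-{gridded.grid_temperatures[-1]:.1f} degC")

m = basic_metrics(gridded)
print(f"peak height:       {m['peak_height']:.4f} at "
      f"T_max = {m['t_max']:.1f} degC")
print(f"area:              {m['area']:.4f}")
print(f"width @ half max:  {m['width_at_half_height']:.2f} degC")

# compare against the injected ground truth
i_max = int(np.argmax(truth.peak_curve))
print(f"\ntruth: tallest injected peak {truth.peak_curve[i_max]:.4f} "
      f"at {truth.temperatures[i_max]:.1f} degC")
print("The endpoints bracket the 48-81 degC exclusion region and the "
      "corrected maximum sits on the main transition; height differs from "
      "truth only by noise and overlap of neighbouring transitions.")
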