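"""Fit the furrow-closure sigmoid and extract the division window.

Builds the short-axis (furrow width) time series of one dividing cell
from a noiseless simulation, fits the falling logistic
w(t) = w_end + (w_start - w_end) / (1 + exp((t - t0)/tau)), and reports
the window between the two knee points t0 ± ln(2+sqrt(3))·tau — the
period of division-associated morphological change.
"""

import numpy as np

from sulfodiv import (
    MW001,
    RunConfig,
    division_window,
    fit_sigmoid,
    link_tracks,
    simulate_movie,
)
from sulfodiv.pipeline import measure_movie

movie, truth = simulate_movie(
    MW001, n_cells=12, n_frames=50, frame_interval_s=30.0, seed=2,
    field_shape=(200, 200), noise=False, drift_step_sd_px=0.0,
)
observations = measure_movie(movie, RunConfig(preset="MW001", noise=False))
tracks = link_tracks(observations)

parent = next(t for t in tracks if len(t.child_ids) == 2)
times = np.array([o.frame * movie.frame_interval_s
                  for o in parent.observations])
widths = np.array([o.furrow_width_px for o in parent.observations])

fit = fit_sigmoid(times, widths)
lo, hi = division_window(fit)
print(f"w_start = {fit.w_start:.2f} px, w_end = {fit.w_end:.2f} px")
print(f"t0 = {fit.t0:.0f} s, tau = {fit.tau:.0f} s")
print(f"division window: {lo:.0f} s to {hi:.0f} s "
      f"(length {hi - lo:.0f} s = 2·ln(2+sqrt(3))·tau)")
# The window brackets the visible transition of the sigmoid: before it the
# cell is essentially unconstricted, after it the furrow is nearly closed.
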