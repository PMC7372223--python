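"""Measure division-ring positions in synthetic fixed-cell images.

Renders immunofluorescence-style images (cell outline + ring band),
recovers each ring's fractional position along the cell axis and converts
it to the ring-position statistic rho = min/max pole distance (1 = exactly
central, 0 = at a pole), then compares centred vs mispositioned rings.
"""

import numpy as np

from sulfodiv import mann_whitney_u, measure_ring_images, simulate_ring_images

im_central, _ = simulate_ring_images(
    60, {"kind": "gaussian", "mean": 0.5, "sd": 0.03}, seed=5
)
im_offset, _ = simulate_ring_images(
    60, {"kind": "uniform", "lo": 0.1, "hi": 0.45}, seed=6
)

rho_c = [m.position_stat for m in measure_ring_images(im_central,
                                                      stage="pre")]
rho_o = [m.position_stat for m in measure_ring_images(im_offset,
                                                      stage="pre")]
u, p = mann_whitney_u(rho_c, rho_o)
print(f"central rings   (n={len(rho_c)}): median rho = "
      f"{np.median(rho_c):.3f}")
print(f"offset rings    (n={len(rho_o)}): median rho = "
      f"{np.median(rho_o):.3f}")
print(f"Mann-Whitney two-sided p = {p:.2e}")
# Central rings score near 1 by definition; rings that slip along the axis
# score well below it, and the two populations separate at p << 1e-4.
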