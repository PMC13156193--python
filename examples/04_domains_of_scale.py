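"""Domains of scale from derivative transitions of an extent-extent smooth.

Builds a synthetic scale-of-effect relationship with a known breakpoint
(landscape extent rises with response extent up to 12 ha, then is flat),
smooths it with a penalized spline, estimates the first derivative by 1 ha
finite differences with simulation CIs, and calls domain boundaries where
the derivative's significance state changes.
"""

import numpy as np

from scalescape.domains import (
    assemble_domains,
    derivative_with_ci,
    detect_boundaries,
    fit_extent_smooth,
)

response_ha = np.pi * np.arange(50.0, 351.0, 25.0) ** 2 / 1e4  # 13 extents
rng = np.random.default_rng(2)
landscape_ha = np.where(response_ha < 12.0, 3.0 * response_ha, 36.0)
landscape_ha = landscape_ha + rng.normal(0.0, 2.0, len(response_ha))

fit = fit_extent_smooth(response_ha, landscape_ha)
series = derivative_with_ci(fit, metric="edge_density", nsim=1000, seed=0)
partition = assemble_domains(
    detect_boundaries(series), fit.x_range, metric="edge_density"
)

for b in partition.boundaries:
    print(
        f"boundary at {b.response_extent_ha:5.1f} ha  kind={b.kind:13s}"
        f"  CI before=({b.ci_before[0]:+.2f},{b.ci_before[1]:+.2f})"
        f"  selected={b.selected}"
    )
print(f"domains: {[(round(a, 1), round(b, 1)) for a, b in partition.domains]}")
print(
    "\nThe first derivative of landscape extent on response extent is"
    "\nsignificantly positive below the breakpoint and indistinguishable from"
    "\nzero above it; the called boundary should sit near the implanted 12 ha."
)
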