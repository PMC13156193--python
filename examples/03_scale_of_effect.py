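"""Scale-of-effect scan: at which landscape extent does a metric matter most?

Simulates a study whose richness responds to edge density measured at 15 ha,
fits the global count model (metric + uplands + GDD + spatial autocovariate)
at every landscape extent from the response extent upward, and selects the
scale of effect by the tiered rule (significant tier first, then marginal,
then fallback; highest marginal R-squared within the tier).
"""

import numpy as np
import pandas as pd

from scalescape import metric_scan, richness_from_detections
from scalescape.models import scan_landscape_extents, select_scale_of_effect
from scalescape.synthetic import LandscapeParams, StudyConfig, generate_study
from scalescape.synthetic.community import surveys_to_frames

config = StudyConfig(
    landscape=LandscapeParams(shape=(1500, 1500), n_blocks=150),
    n_sites=60,
)
study = generate_study(config, seed=3)
sites, detections = surveys_to_frames(study.surveys)

response_radius = 150.0  # 7.1 ha response extent
richness = richness_from_detections(detections, sites, [response_radius])
radii = np.arange(50.0, 501.0, 50.0)
metrics = pd.concat(
    [
        metric_scan(study.raster, (r.x, r.y), radii, table=study.class_table,
                    site=r.site, metrics=("edge_density",))
        for r in sites.itertuples(index=False)
    ],
    ignore_index=True,
)

fits = scan_landscape_extents(
    richness, metrics, sites, "edge_density", response_radius, family="auto"
)
print(fits[["landscape_extent_ha", "beta", "se", "p_value", "marginal_r2"]]
      .to_string(index=False, float_format=lambda v: f"{v:0.4f}"))

record = select_scale_of_effect(fits)
print(
    f"\nSelected scale of effect: {record.landscape_extent_ha:.1f} ha"
    f" (tier '{record.tier}', beta = {record.estimate:.3f}"
    f" +- {record.std_error:.3f}, p = {record.p_value:.4f})"
    f"\nImplanted effect extent:  {study.truth.effects[0]['extent_ha']:.1f} ha"
    "\nbeta is the standardized coefficient of edge density; the selected"
    "\nextent should sit near the implanted one (extent grid permitting)."
)
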