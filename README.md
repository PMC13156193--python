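# scalescape

Multi-scale analysis of how landscape configurational heterogeneity relates
to songbird species richness in managed-forest mosaics.

Point-based bird surveys (autonomous recording units in harvest blocks) pose
a double scale problem: richness can be counted within any truncation radius
around the recorder (the **response extent**), and a landscape configuration
metric can be measured within any buffer radius (the **landscape extent**).
Conclusions about which aspects of mosaic structure drive local diversity
depend on both choices. `scalescape` implements a two-step, multiple
uniscale regression framework for parsing this dependence:

1. **Configuration metrics in circular buffers.** Five FRAGSTATS-style
   landscape-level indices on a categorical land-cover raster — edge density
   (m/ha), Shannon diversity SHDI = −Σᵢ Pᵢ ln Pᵢ, contagion
   CONTAG = 100·[1 + Σᵢₖ q᷈ᵢₖ ln q᷈ᵢₖ / (2 ln m)], perimeter–area fractal
   dimension PAFRAC = 2/slope of ln A on ln P across patches, and the
   coefficient of variation of the per-patch core area index (CAI CV) —
   evaluated over a schedule of buffer radii around each site. Buffers where
   a metric is incomputable (e.g. PAFRAC with fewer than 10 patches) are
   reported as undefined values, not errors.
2. **Nested richness responses.** Distance-truncated species richness at 13
   nested extents (50–350 m radius every 25 m; 0.79–38 ha).
3. **Scale-of-effect scan.** At each response extent *i*, the global model
   `log E[richness_i] = β₀ + β_metric·metric_j + β_upl·uplands_j + β_GDD·GDD
   + β_auto·autocov + α_year`, with Poisson or negative-binomial family by
   dispersion and α_year a survey-year random intercept (Laplace
   approximation), is fit at every landscape extent *j ≥ i*; the scale of
   effect is the extent with the highest Nakagawa–Schielzeth marginal R²
   among significant metric coefficients (then marginal, then all). Fixed
   effect structures (additive / interaction / quadratic) are compared by
   likelihood-ratio tests.
4. **Domains of scale.** Selected landscape extents are smoothed against
   response extents with an independent penalized spline per metric; the
   first derivative (1 ha finite differences, CIs from 1000 posterior
   coefficient draws) flags domain boundaries wherever its significance
   state changes, and a persistence rule groups weakly supported
   oscillations into single domains.

The proprietary inputs of real studies (vegetation inventory rasters,
acoustic recordings) are replaced by a first-class synthetic-data generator:
5 m-grain mosaics of mature forest, harvest blocks in 10-year age classes
with retention islands and irregular boundaries, wide linear features and
lowlands, plus bird communities whose richness responds to configuration
metrics at *implanted* effect extents — so every stage can be tested against
known truth.

## Worked example

```python
import numpy as np, pandas as pd
from scalescape import metric_scan, richness_from_detections
from scalescape.models import scan_landscape_extents, select_scale_of_effect
from scalescape.synthetic import LandscapeParams, StudyConfig, generate_study
from scalescape.synthetic.community import surveys_to_frames

study = generate_study(
    StudyConfig(landscape=LandscapeParams(shape=(1500, 1500), n_blocks=150),
                n_sites=60),
    seed=3,
)
sites, detections = surveys_to_frames(study.surveys)
richness = richness_from_detections(detections, sites, [150.0])
metrics = pd.concat(
    [metric_scan(study.raster, (r.x, r.y), np.arange(50.0, 501.0, 50.0),
                 table=study.class_table, site=r.site,
                 metrics=("edge_density",))
     for r in sites.itertuples(index=False)], ignore_index=True)
fits = scan_landscape_extents(richness, metrics, sites,
                              "edge_density", 150.0, family="auto")
rec = select_scale_of_effect(fits)
print(rec.landscape_extent_ha, rec.estimate, rec.p_value, rec.tier)
```

prints

```
12.566370614359172 0.21160253...  0.01482... significant
```

i.e. with richness counted within 150 m (7.1 ha) and the community's true
edge-density effect implanted at 15 ha, the scan selects a 12.6 ha scale of
effect (the schedule extent nearest the truth) with a standardized
coefficient of 0.21 (p = 0.015): a one-SD increase in edge density at that
extent multiplies expected richness by e^0.21 ≈ 1.24.

The `examples/` scripts walk one capability each (metrics in buffers,
synthetic studies, the scale-of-effect scan, domain detection), and the
`scalescape` command runs the file-based pipeline stagewise:

```bash
scalescape all --seed 7 --out run/     # simulate -> metrics -> richness -> scan -> domains
```

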