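"""Recovery experiments on synthetic data with implanted ground truth.

Each experiment regenerates its data from scratch, runs the package's own
estimation machinery, and measures how well a known quantity is recovered:
Wald CI coverage of the count-model fixed effects, scale-of-effect recovery
against an implanted effect extent, and domain-boundary recovery against an
implanted two-regime extent relationship (plus its 1:1 null). These back the
package's correctness claims and are reused by the acceptance script.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .domains import (
    assemble_domains,
    derivative_with_ci,
    detect_boundaries,
    fit_extent_smooth,
)
from .metrics import metric_scan
from .models import ModelSpec, fit_model, scan_landscape_extents, select_scale_of_effect
from .richness import richness_from_detections
from .synthetic import (
    CommunityParams,
    LandscapeParams,
    generate_landscape,
    place_sites,
    simulate_community,
    surveys_to_frames,
)
from .synthetic.community import simulate_direct_glm, site_metric_values

__all__ = [
    "glm_coverage",
    "soe_recovery",
    "domain_breakpoint_recovery",
    "domain_null_rate",
    "RESPONSE_EXTENTS_HA",
]

# the 13 reference response extents (50-350 m radius every 25 m), in hectares
RESPONSE_EXTENTS_HA = np.pi * np.arange(50.0, 351.0, 25.0) ** 2 / 1e4


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(n)]


def glm_coverage(
    n_reps: int = 200,
    n: int = 400,
    seed: int = 0,
    family: str = "poisson",
    theta: float | None = None,
    beta: dict[str, float] | None = None,
) -> dict:
    """95% Wald CI coverage of every fixed effect over direct-GLM simulations.

    Counts are drawn straight from the log-linear model (no mechanistic
    community layer), so nominal coverage is the correct benchmark.
    """
    beta = beta or {"intercept": 1.2, "metric": 0.3, "uplands": 0.1, "gdd": 0.2}
    seeds = _child_seeds(seed, n_reps)
    covered = 0
    total = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s in seeds:
            data = simulate_direct_glm(n, beta, family=family, theta=theta, seed=s)
            fit = fit_model(
                data, ModelSpec(family=family, standardize=False, use_autocov=False)
            )
            ci = fit.conf_int()
            for term, truth in beta.items():
                covered += bool(
                    ci.loc[term, "lower"] <= truth <= ci.loc[term, "upper"]
                )
                total += 1
    return {"coverage": covered / total, "n_reps": n_reps, "n": n, "family": family}


def soe_recovery(
    n_reps: int = 20,
    seed: int = 0,
    n_sites: int = 100,
    effect_extent_ha: float = 15.0,
    response_radius_m: float = 150.0,
    metric: str = "edge_density",
    landscape_radii_m: np.ndarray | None = None,
    landscape_params: LandscapeParams | None = None,
    community_params: CommunityParams | None = None,
) -> dict:
    """Recover an implanted scale of effect from full synthetic replicates.

    Each replicate generates a fresh mosaic, places sites, simulates the
    community whose richness responds to the metric at ``effect_extent_ha``,
    scans landscape extents at one response extent, and selects the scale of
    effect by the tiered rule. Returns the selected extents and the median
    absolute error in hectares.
    """
    if landscape_radii_m is None:
        landscape_radii_m = np.arange(50.0, 501.0, 25.0)
    if landscape_params is None:
        landscape_params = LandscapeParams(shape=(2300, 2300), n_blocks=300)
    if community_params is None:
        community_params = CommunityParams()
    seeds = _child_seeds(seed, n_reps)
    selected = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s in seeds:
            s_land, s_site, s_comm = _child_seeds(s, 3)
            raster, table = generate_landscape(landscape_params, s_land)
            sites_xy = place_sites(raster, n_sites, seed=s_site)
            pre = {
                (metric, effect_extent_ha): site_metric_values(
                    raster, sites_xy, metric, effect_extent_ha, table
                )
            }
            surveys, _ = simulate_community(
                raster, sites_xy, community_params, s_comm, table=table,
                metric_values=pre,
            )
            sites, det = surveys_to_frames(surveys)
            rich = richness_from_detections(det, sites, [response_radius_m])
            mets = pd.concat(
                [
                    metric_scan(
                        raster, (r.x, r.y), landscape_radii_m, table=table,
                        site=r.site, metrics=(metric,),
                    )
                    for r in sites.itertuples(index=False)
                ],
                ignore_index=True,
            )
            fits = scan_landscape_extents(
                rich, mets, sites, metric, response_radius_m, family="auto"
            )
            selected.append(select_scale_of_effect(fits).landscape_extent_ha)
    selected = np.asarray(selected)
    errors = np.abs(selected - effect_extent_ha)
    return {
        "selected_extents_ha": selected.tolist(),
        "median_abs_error_ha": float(np.median(errors)),
        "effect_extent_ha": effect_extent_ha,
        "n_reps": n_reps,
        "n_sites": n_sites,
    }


def _boundary_replicate(y: np.ndarray, x: np.ndarray, seed: int) -> list[float]:
    fit = fit_extent_smooth(x, y)
    series = derivative_with_ci(fit, nsim=1000, seed=seed)
    part = assemble_domains(detect_boundaries(series), fit.x_range)
    return [b.response_extent_ha for b in part.boundaries if b.selected]


def domain_breakpoint_recovery(
    n_reps: int = 20,
    seed: int = 0,
    threshold_ha: float = 12.0,
    slope: float = 3.0,
    noise_sd_ha: float = 2.0,
    x: np.ndarray | None = None,
) -> dict:
    """Recovery of an implanted two-regime breakpoint in the extent relation.

    Landscape extent rises at ``slope`` below the threshold and is flat
    above, with Gaussian noise; a replicate scores a hit when its first
    selected boundary falls within ±3 ha of the threshold.
    """
    if x is None:
        x = RESPONSE_EXTENTS_HA
    rng_seeds = _child_seeds(seed, n_reps)
    locations = []
    hits = 0
    for s in rng_seeds:
        rng = np.random.default_rng(s)
        y = np.where(x < threshold_ha, slope * x, slope * threshold_ha)
        y = y + rng.normal(0, noise_sd_ha, len(x))
        kept = _boundary_replicate(y, x, seed=s)
        if kept:
            locations.append(kept[0])
            hits += abs(kept[0] - threshold_ha) <= 3.0
    return {
        "hit_rate": hits / n_reps,
        "boundaries_ha": locations,
        "threshold_ha": threshold_ha,
        "n_reps": n_reps,
    }


def domain_null_rate(
    n_reps: int = 50,
    seed: int = 0,
    noise_sd_ha: float = 2.0,
    x: np.ndarray | None = None,
) -> dict:
    """Fraction of 1:1 (no-domain-structure) scans with no selected boundary."""
    if x is None:
        x = RESPONSE_EXTENTS_HA
    rng_seeds = _child_seeds(seed, n_reps)
    clean = 0
    for s in rng_seeds:
        rng = np.random.default_rng(s)
        y = x + rng.normal(0, noise_sd_ha, len(x))
        kept = _boundary_replicate(y, x, seed=s)
        clean += len(kept) == 0
    return {"no_boundary_rate": clean / n_reps, "n_reps": n_reps}
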