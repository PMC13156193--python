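"""Nested species-richness responses by detection-distance truncation.

Species richness at a *response extent* is the number of distinct species
with at least one detection within the truncation radius of the recorder.
Because smaller radii retain subsets of the detections at larger radii, the
per-site series is monotone non-decreasing by construction. The default
schedule spans 50–350 m every 25 m (13 extents), 350 m being the maximum
detection distance of many songbirds on modern recording units.

Richness here is naive — no detection-probability correction — and the
species list is whatever the detections table carries; any taxonomic
filtering is the caller's responsibility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic.community import SiteSurvey

__all__ = [
    "DEFAULT_RESPONSE_RADII",
    "RichnessSeries",
    "richness_at",
    "richness_series",
    "richness_table",
    "accumulation_summary",
]

DEFAULT_RESPONSE_RADII: tuple[float, ...] = tuple(float(r) for r in range(50, 351, 25))


def _extent_ha(radius_m: float) -> float:
    return np.pi * radius_m**2 / 10_000.0


@dataclass
class RichnessSeries:
    """Per-site richness counts at an ordered schedule of truncation radii."""

    site: str
    radii_m: np.ndarray
    richness: np.ndarray

    def __post_init__(self) -> None:
        self.radii_m = np.asarray(self.radii_m, dtype=float)
        self.richness = np.asarray(self.richness, dtype=int)
        if np.any(np.diff(self.radii_m) <= 0):
            raise ValueError("radii must be strictly increasing")
        if np.any(self.richness < 0) or np.any(np.diff(self.richness) < 0):
            raise ValueError("richness counts must be non-negative and non-decreasing")

    @property
    def extents_ha(self) -> np.ndarray:
        return _extent_ha(self.radii_m)


def richness_at(survey: SiteSurvey, radius: float) -> int:
    """Distinct species with >= 1 detection at distance <= radius (ties included)."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    return len({sp for sp, d in survey.detections if d <= radius})


def richness_series(
    survey: SiteSurvey, radii: np.ndarray | list[float] = DEFAULT_RESPONSE_RADII
) -> RichnessSeries:
    """Richness at every radius of a strictly increasing truncation schedule."""
    radii = np.asarray(radii, dtype=float)
    if radii.size == 0:
        raise ValueError("radius schedule is empty")
    counts = [richness_at(survey, float(r)) for r in radii]
    return RichnessSeries(site=survey.site, radii_m=radii, richness=np.array(counts))


def richness_table(
    surveys: list[SiteSurvey],
    radii: np.ndarray | list[float] = DEFAULT_RESPONSE_RADII,
) -> pd.DataFrame:
    """Long-format richness per (site, radius): site, radius_m, extent_ha, richness."""
    rows = []
    for survey in surveys:
        series = richness_series(survey, radii)
        for r, e, k in zip(series.radii_m, series.extents_ha, series.richness):
            rows.append(
                {"site": series.site, "radius_m": r, "extent_ha": e, "richness": int(k)}
            )
    return pd.DataFrame(rows)


def richness_from_detections(
    detections: pd.DataFrame,
    sites: pd.DataFrame,
    radii: np.ndarray | list[float] = DEFAULT_RESPONSE_RADII,
) -> pd.DataFrame:
    """Richness table from file-schema frames (site,species,distance_m / site,...).

    Sites with no detections get zero counts at every radius.
    """
    radii = np.asarray(radii, dtype=float)
    if np.any(np.diff(radii) <= 0):
        raise ValueError("radii must be strictly increasing")
    rows = []
    grouped = dict(tuple(detections.groupby("site"))) if len(detections) else {}
    for site in sites["site"]:
        det = grouped.get(site)
        for r in radii:
            if det is None:
                k = 0
            else:
                k = det.loc[det["distance_m"] <= r, "species"].nunique()
            rows.append(
                {
                    "site": site,
                    "radius_m": float(r),
                    "extent_ha": _extent_ha(float(r)),
                    "richness": int(k),
                }
            )
    return pd.DataFrame(rows)


def accumulation_summary(richness: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD of richness per response extent (species-accumulation curve)."""
    if len(richness) == 0:
        raise ValueError("richness table is empty")
    out = (
        richness.groupby(["radius_m", "extent_ha"])["richness"]
        .agg(mean_richness="mean", sd_richness=lambda v: v.std(ddof=0))
        .reset_index()
        .sort_values("radius_m")
        .reset_index(drop=True)
    )
    return out
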