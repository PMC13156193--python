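"""Assemble a full synthetic study: landscape + sites + surveys + truth.

The bundle round-trips through the package's external file formats (ASCII
grid or GeoTIFF raster, class-table CSV, ``sites.csv``, ``detections.csv``,
``truth.json``) so every downstream stage can also be exercised from files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ..raster import ClassRaster, ClassTable, write_class_raster, write_class_table
from .community import (
    CommunityParams,
    SiteSurvey,
    SyntheticTruth,
    simulate_community,
    surveys_to_frames,
)
from .landscape import LandscapeParams, generate_landscape, place_sites

__all__ = ["StudyConfig", "StudyBundle", "generate_study"]


@dataclass
class StudyConfig:
    """Everything needed to regenerate a synthetic study from one seed."""

    landscape: LandscapeParams = field(default_factory=LandscapeParams)
    community: CommunityParams = field(default_factory=CommunityParams)
    n_sites: int = 60
    min_spacing_m: float = 300.0
    edge_clearance_m: float = 150.0


@dataclass
class StudyBundle:
    """A generated study: raster, class table, site table, surveys, truth."""

    raster: ClassRaster
    class_table: ClassTable
    sites: pd.DataFrame  # site, x, y, year, gdd
    surveys: list[SiteSurvey]
    truth: SyntheticTruth

    def write(self, outdir: str | Path, raster_format: str = "asc") -> dict[str, Path]:
        """Write the bundle in the external-interface formats; returns paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "raster": outdir / f"landscape.{raster_format}",
            "class_table": outdir / "classes.csv",
            "sites": outdir / "sites.csv",
            "detections": outdir / "detections.csv",
            "truth": outdir / "truth.json",
        }
        write_class_raster(self.raster, paths["raster"])
        write_class_table(self.class_table, paths["class_table"])
        sites_df, det_df = surveys_to_frames(self.surveys)
        sites_df.to_csv(paths["sites"], index=False, float_format="%.17g")
        det_df.to_csv(paths["detections"], index=False, float_format="%.17g")
        self.truth.to_json(paths["truth"])
        return paths


def generate_study(config: StudyConfig, seed: int) -> StudyBundle:
    """Generate a complete synthetic study, deterministic given config + seed.

    The master seed spawns independent child seeds for the landscape, site
    placement, and community stages, so changing (say) community parameters
    never reshuffles the landscape.
    """
    ss = np.random.SeedSequence(seed)
    s_land, s_sites, s_comm = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(3)]

    raster, table = generate_landscape(config.landscape, s_land)
    site_xy = place_sites(
        raster,
        n=config.n_sites,
        min_spacing=config.min_spacing_m,
        edge_clearance=config.edge_clearance_m,
        seed=s_sites,
    )
    surveys, truth = simulate_community(
        raster, site_xy, config.community, s_comm, table=table
    )
    truth.seed = int(seed)
    sites_df, _ = surveys_to_frames(surveys)
    return StudyBundle(
        raster=raster, class_table=table, sites=sites_df, surveys=surveys, truth=truth
    )
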