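"""The scale-of-effect scan: fit the global model across landscape extents,
select the scale of effect by the tiered rule, and settle the fixed-effect
structure by likelihood-ratio tests.

For a response extent *i*, the candidate landscape extents *j* run from *i*
upward (the minimum landscape extent always matches the response extent), and
proportion uplands is measured at the same extent *j* as the metric. Buffers
where a metric is undefined are skipped, not imputed: the fit at each extent
uses the sites where the metric exists, provided enough remain.

The tiered selection rule: among extents where the metric coefficient is
significant (p <= 0.05), take the highest marginal R²; failing that, among
marginal extents (0.05 < p <= 0.1); failing that, over all remaining extents.
Ties on R² break toward the smaller extent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .autocov import build_autocovariate
from .glm import ModelFit, ModelSpec, choose_family, fit_model, marginal_r2

__all__ = [
    "ScaleOfEffectRecord",
    "assemble_model_data",
    "scan_landscape_extents",
    "select_scale_of_effect",
    "compare_structures",
]


@dataclass
class ScaleOfEffectRecord:
    """Selected landscape extent for one (metric, response extent) pair."""

    metric: str
    response_radius_m: float
    response_extent_ha: float
    landscape_radius_m: float
    landscape_extent_ha: float
    estimate: float
    std_error: float
    p_value: float
    marginal_r2: float
    tier: str  # 'significant' | 'marginal' | 'fallback'
    family: str
    n_sites: int


def assemble_model_data(
    richness: pd.DataFrame,
    metrics: pd.DataFrame,
    sites: pd.DataFrame,
    metric: str,
    response_radius_m: float,
    landscape_radius_m: float,
) -> pd.DataFrame:
    """Merge one (i, j) modelling dataset: response, metric, uplands, covariates.

    Sites where the metric is undefined at extent *j* are dropped. Returns
    columns ``site, x, y, year, gdd, richness, metric, uplands``.
    """
    resp = richness.loc[
        np.isclose(richness["radius_m"], response_radius_m),
        ["site", "richness"],
    ]
    mvals = metrics.loc[
        (metrics["metric"] == metric)
        & np.isclose(metrics["radius_m"], landscape_radius_m)
        & metrics["defined"],
        ["site", "value"],
    ].rename(columns={"value": "metric"})
    upl = metrics.loc[
        (metrics["metric"] == "prop_upland")
        & np.isclose(metrics["radius_m"], landscape_radius_m),
        ["site", "value"],
    ].rename(columns={"value": "uplands"})
    df = sites.merge(resp, on="site").merge(mvals, on="site").merge(upl, on="site")
    return df.reset_index(drop=True)


def _fit_one_extent(
    data: pd.DataFrame,
    family: str,
    random_effect: bool,
    use_autocov: bool,
    structure: str = "additive",
) -> tuple[ModelFit, str]:
    """Fit the global model on one (i, j) dataset, resolving family='auto'."""
    data = data.copy()
    if use_autocov:
        data["autocov"] = build_autocovariate(
            data, data[["x", "y"]].to_numpy(dtype=float)
        )
    if family == "auto":
        from .glm import build_design

        probe = ModelSpec(family="poisson", structure=structure,
                          random_effect=False, use_autocov=use_autocov)
        X, y, _, _ = build_design(data, probe)
        family = choose_family(y, X)
    spec = ModelSpec(family=family, structure=structure,
                     random_effect=random_effect, use_autocov=use_autocov)
    return fit_model(data, spec), family


def scan_landscape_extents(
    richness: pd.DataFrame,
    metrics: pd.DataFrame,
    sites: pd.DataFrame,
    metric: str,
    response_radius_m: float,
    landscape_radii: list[float] | np.ndarray | None = None,
    family: str = "auto",
    random_effect: bool = False,
    use_autocov: bool = True,
    min_sites: int = 30,
) -> pd.DataFrame:
    """One global-model fit per landscape extent j >= response extent i.

    Returns the effect-surface rows for this (metric, i): landscape extent,
    standardized metric coefficient, SE, Wald p, marginal R², family, the
    number of sites with a defined metric, and a skip reason where no model
    could be fit.
    """
    all_radii = np.sort(metrics["radius_m"].unique())
    if landscape_radii is None:
        landscape_radii = all_radii
    landscape_radii = np.asarray(landscape_radii, dtype=float)
    landscape_radii = landscape_radii[landscape_radii >= response_radius_m - 1e-9]
    if landscape_radii.size == 0:
        raise ValueError(
            "no landscape radii at or above the response radius "
            f"{response_radius_m} m"
        )
    rows = []
    for j in landscape_radii:
        row = {
            "metric": metric,
            "response_radius_m": float(response_radius_m),
            "response_extent_ha": np.pi * response_radius_m**2 / 10_000.0,
            "landscape_radius_m": float(j),
            "landscape_extent_ha": np.pi * j**2 / 10_000.0,
        }
        data = assemble_model_data(
            richness, metrics, sites, metric, response_radius_m, j
        )
        if len(data) < min_sites:
            row.update(
                n_sites=len(data), beta=np.nan, se=np.nan, p_value=np.nan,
                marginal_r2=np.nan, family=None, converged=False,
                skipped=f"only {len(data)} sites with defined {metric}",
            )
            rows.append(row)
            continue
        try:
            fit, fam = _fit_one_extent(data, family, random_effect, use_autocov)
        except (ValueError, np.linalg.LinAlgError) as exc:
            row.update(
                n_sites=len(data), beta=np.nan, se=np.nan, p_value=np.nan,
                marginal_r2=np.nan, family=None, converged=False,
                skipped=str(exc),
            )
            rows.append(row)
            continue
        r2 = marginal_r2(fit) if fit.converged else np.nan
        row.update(
            n_sites=len(data),
            beta=float(fit.params["metric"]),
            se=float(fit.bse["metric"]),
            p_value=float(fit.pvalues["metric"]),
            marginal_r2=r2,
            family=fam,
            converged=fit.converged,
            skipped=None,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def select_scale_of_effect(fits: pd.DataFrame) -> ScaleOfEffectRecord:
    """Tiered scale-of-effect selection over one scan table.

    Tier 'significant': p <= 0.05, highest marginal R²; tier 'marginal':
    0.05 < p <= 0.1; tier 'fallback': all remaining converged fits. R² ties
    break toward the smaller landscape extent.
    """
    ok = fits.loc[fits["converged"] & fits["marginal_r2"].notna()].copy()
    if len(ok) == 0:
        raise ValueError("no converged fits to select a scale of effect from")
    tiers = (
        ("significant", ok["p_value"] <= 0.05),
        ("marginal", (ok["p_value"] > 0.05) & (ok["p_value"] <= 0.1)),
        ("fallback", ok["p_value"] > 0.1),
    )
    for tier, mask in tiers:
        subset = ok.loc[mask]
        if len(subset) == 0:
            continue
        subset = subset.sort_values(
            ["marginal_r2", "landscape_radius_m"], ascending=[False, True]
        )
        best = subset.iloc[0]
        return ScaleOfEffectRecord(
            metric=str(best["metric"]),
            response_radius_m=float(best["response_radius_m"]),
            response_extent_ha=float(best["response_extent_ha"]),
            landscape_radius_m=float(best["landscape_radius_m"]),
            landscape_extent_ha=float(best["landscape_extent_ha"]),
            estimate=float(best["beta"]),
            std_error=float(best["se"]),
            p_value=float(best["p_value"]),
            marginal_r2=float(best["marginal_r2"]),
            tier=tier,
            family=str(best["family"]),
            n_sites=int(best["n_sites"]),
        )
    raise ValueError("unreachable: tiers cover all p-values")


def compare_structures(
    data: pd.DataFrame,
    family: str,
    random_effect: bool = False,
    use_autocov: bool = True,
    alpha: float = 0.05,
) -> tuple[str, ModelFit, pd.DataFrame]:
    """Pairwise LRTs among additive, interaction and polynomial structures.

    The additive model is nested in each alternative with one extra term, so
    each test statistic is 2·Δll against chi-square(1). When no alternative
    improves significantly the additive model is kept (parsimony); when both
    do, the higher log-likelihood wins (equal complexity). A non-convergent
    polynomial fit is excluded with a warning.
    """
    fits: dict[str, ModelFit] = {}
    for structure in ("additive", "interaction", "polynomial"):
        try:
            fit, _ = _fit_one_extent(
                data, family, random_effect, use_autocov, structure=structure
            )
        except (ValueError, np.linalg.LinAlgError) as exc:
            warnings.warn(f"{structure} fit failed: {exc}")
            continue
        if not fit.converged:
            warnings.warn(f"{structure} fit did not converge; excluded")
            continue
        fits[structure] = fit
    if "additive" not in fits:
        raise ValueError("additive model failed to fit; cannot compare structures")
    lrt_rows = []
    winners = []
    for alt in ("interaction", "polynomial"):
        if alt not in fits:
            continue
        stat = 2.0 * (fits[alt].llf - fits["additive"].llf)
        p = float(stats.chi2.sf(max(stat, 0.0), df=1))
        lrt_rows.append(
            {"comparison": f"additive_vs_{alt}", "lr_stat": stat, "df": 1, "p": p}
        )
        if p <= alpha:
            winners.append(alt)
    if len(winners) == 0:
        choice = "additive"
    elif len(winners) == 1:
        choice = winners[0]
    else:
        choice = max(winners, key=lambda s: fits[s].llf)
    return choice, fits[choice], pd.DataFrame(lrt_rows)
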