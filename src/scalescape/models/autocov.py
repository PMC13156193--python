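"""Spatial autocovariate: fitted values of a 2-D smooth on model residuals.

Residual spatial correlation is absorbed by a covariate built in two steps:
fit the global model *without* any spatial term, then smooth its deviance
residuals over site coordinates with a low-rank thin-plate-type penalized
spline (radial basis r² log r at a deterministic knot subset, unpenalized
linear null space, ridge penalty on the radial coefficients chosen by GCV).
The smooth's fitted values, standardised, enter the final model as the
``autocov`` predictor.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["build_autocovariate", "tps_smooth_2d"]


def _tps_eta(r: np.ndarray) -> np.ndarray:
    out = np.zeros_like(r)
    pos = r > 0
    out[pos] = r[pos] ** 2 * np.log(r[pos])
    return out


def tps_smooth_2d(
    values: np.ndarray,
    coords: np.ndarray,
    basis_dim: int = 30,
    lambdas: np.ndarray | None = None,
    gamma: float = 1.4,
    return_hat: bool = False,
) -> tuple[np.ndarray, float, float]:
    """Penalized thin-plate-style smooth of scattered values on (x, y).

    Knots are a deterministic evenly-spaced subset (in coordinate sort order)
    of the data points, so the smooth is reproducible without any random
    state. ``gamma`` inflates the effective-df cost in the GCV score (the
    usual guard against GCV undersmoothing on noisy inputs). Returns
    (fitted values, chosen lambda, effective df).
    """
    values = np.asarray(values, dtype=float)
    coords = np.asarray(coords, dtype=float)
    n = len(values)
    if coords.shape != (n, 2):
        raise ValueError("coords must be (n, 2)")
    # scale coordinates to the unit square for conditioning
    span = coords.max(axis=0) - coords.min(axis=0)
    span[span <= 0] = 1.0
    sc = (coords - coords.min(axis=0)) / span
    k = min(basis_dim, n)
    order = np.lexsort((sc[:, 1], sc[:, 0]))
    knot_idx = order[np.linspace(0, n - 1, k).round().astype(int)]
    knots = sc[knot_idx]
    # radial part + unpenalized affine null space
    d = np.sqrt(((sc[:, None, :] - knots[None, :, :]) ** 2).sum(-1))
    E = _tps_eta(d)
    T = np.column_stack([np.ones(n), sc])
    B = np.column_stack([T, E])
    pen = np.zeros(B.shape[1])
    pen[T.shape[1]:] = 1.0
    P = np.diag(pen)
    BtB = B.T @ B
    Bty = B.T @ values
    if lambdas is None:
        lambdas = np.logspace(-6, 4, 25)
    best = None
    for lam in lambdas:
        try:
            A = BtB + lam * P
            Ainv_Bt = np.linalg.solve(A, B.T)
            coef = np.linalg.solve(A, Bty)
            hat_diag = np.einsum("ij,ji->i", B, Ainv_Bt)
            edf = float(hat_diag.sum())
        except np.linalg.LinAlgError:
            continue
        fitted = B @ coef
        rss = float(((values - fitted) ** 2).sum())
        denom = max(n - gamma * edf, 1e-6)
        gcv = n * rss / denom**2
        if best is None or gcv < best[0]:
            best = (gcv, lam, fitted, edf, hat_diag)
    if best is None:
        raise np.linalg.LinAlgError("smooth basis is singular at every lambda")
    _, lam, fitted, edf, hat_diag = best
    if return_hat:
        return fitted, float(lam), edf, hat_diag
    return fitted, float(lam), edf


def build_autocovariate(
    data: pd.DataFrame,
    coords: np.ndarray | pd.DataFrame,
    family: str = "poisson",
    theta: float | None = None,
    basis_dim: int = 30,
    min_sites: int = 30,
    standardize: bool = True,
) -> np.ndarray:
    """Autocovariate from a non-spatial fit's deviance residuals.

    ``data`` must carry the global-model columns (``richness, metric,
    uplands, gdd``); the non-spatial model is fit with the requested family
    (NB uses the supplied size, or Poisson deviance residuals as a fallback
    when none is given). Raises when sites are too few or coordinates are
    coincident (the basis collapses) — jitter duplicate locations upstream.
    """
    if isinstance(coords, pd.DataFrame):
        coords = coords[["x", "y"]].to_numpy(dtype=float)
    coords = np.asarray(coords, dtype=float)
    n = len(data)
    if n < min_sites:
        raise ValueError(f"autocovariate needs >= {min_sites} sites, got {n}")
    if len(np.unique(coords, axis=0)) < n:
        raise ValueError(
            "coincident site coordinates collapse the spatial basis; "
            "jitter duplicate locations before building the autocovariate"
        )
    from .glm import ModelSpec, build_design

    spec = ModelSpec(family="poisson", structure="additive",
                     random_effect=False, use_autocov=False)
    X, y, _, _ = build_design(data, spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if family == "nb" and theta is not None:
            fam = sm.families.NegativeBinomial(alpha=1.0 / theta)
        else:
            fam = sm.families.Poisson()
        res = sm.GLM(y, X, family=fam).fit()
    resid = np.asarray(res.resid_deviance, dtype=float)
    fitted, _, _, hat = tps_smooth_2d(
        resid, coords, basis_dim=basis_dim, return_hat=True
    )
    # A smooth of the model's own residuals fed straight back as a covariate
    # is circular: its in-sample fit carries ~edf degrees of spurious signal.
    # Two guards keep the autocovariate honest under spatially white
    # residuals: (1) use leave-one-out predictions of the smooth, and
    # (2) include it only when those predictions have out-of-sample skill,
    # i.e. beat the intercept-only predictor of the residuals. Without skill
    # the autocovariate is identically zero and drops out of the design.
    h = np.clip(hat, None, 0.95)
    loo = (fitted - h * resid) / (1.0 - h)
    loo_rss = float(((resid - loo) ** 2).sum())
    null_pred = (resid.sum() - resid) / (n - 1)  # leave-one-out mean
    null_rss = float(((resid - null_pred) ** 2).sum())
    if loo_rss >= null_rss:
        return np.zeros(n)
    if standardize:
        sd = loo.std()
        if sd < 1e-12:
            return np.zeros(n)
        return (loo - loo.mean()) / sd
    return loo
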