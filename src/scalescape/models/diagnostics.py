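"""Simulation-based residual diagnostics and the random-effect decision.

Residuals are randomized-quantile (PIT) residuals against simulations from
the fitted model (the DHARMa approach): with a well-specified model they are
uniform on (0, 1). Three checks are run — overdispersion (observed Pearson
statistic against its simulated distribution), residual spatial
autocorrelation (Moran's I with inverse-distance weights, normal
approximation), and uniformity (Kolmogorov–Smirnov). The survey-year random
intercept is retained when it resolves a detected violation or when its
estimated variance is non-negligible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .glm import ModelFit, ModelSpec, fit_model

__all__ = [
    "quantile_residuals",
    "dispersion_test",
    "morans_i",
    "uniformity_test",
    "DiagnosticsReport",
    "residual_diagnostics",
    "decide_random_effect",
]


def quantile_residuals(
    fit: ModelFit, nsim: int = 250, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Randomized PIT residuals of the observations against model simulations."""
    rng = np.random.default_rng(seed)
    sims = fit.simulate(rng, nsim)  # (nsim, n)
    y = fit.y
    below = (sims < y[None, :]).sum(axis=0)
    equal = (sims == y[None, :]).sum(axis=0)
    u = (below + rng.random(fit.n) * (equal + 1)) / (nsim + 1)
    return u


def dispersion_test(
    fit: ModelFit, nsim: int = 250, seed: int | np.random.Generator = 0
) -> tuple[float, float]:
    """(ratio, p) — observed Pearson statistic vs its simulated distribution.

    Ratio > 1 signals overdispersion relative to the fitted family; the
    p-value is two-sided with the usual +1 small-sample correction.
    """
    rng = np.random.default_rng(seed)
    mu = fit.fitted
    var = mu if fit.family == "poisson" else mu + mu**2 / fit.theta
    d_obs = float(((fit.y - mu) ** 2 / var).sum())
    sims = fit.simulate(rng, nsim)
    d_sim = ((sims - mu[None, :]) ** 2 / var[None, :]).sum(axis=1)
    p_hi = (np.sum(d_sim >= d_obs) + 1) / (nsim + 1)
    p_lo = (np.sum(d_sim <= d_obs) + 1) / (nsim + 1)
    ratio = d_obs / float(d_sim.mean())
    return ratio, min(1.0, 2.0 * min(p_hi, p_lo))


def morans_i(values: np.ndarray, coords: np.ndarray) -> tuple[float, float]:
    """Moran's I with inverse-distance weights; (I, two-sided normal-approx p)."""
    z = np.asarray(values, dtype=float)
    z = z - z.mean()
    coords = np.asarray(coords, dtype=float)
    n = len(z)
    if n < 4:
        raise ValueError("Moran's I needs at least 4 observations")
    d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    with np.errstate(divide="ignore"):
        w = 1.0 / d
    np.fill_diagonal(w, 0.0)
    w[~np.isfinite(w)] = 0.0
    W = w.sum()
    denom = float((z**2).sum())
    if denom < 1e-300 or W <= 0:
        return 0.0, 1.0
    I = n / W * float(z @ w @ z) / denom
    # moments under the normality assumption
    EI = -1.0 / (n - 1)
    s1 = 0.5 * ((w + w.T) ** 2).sum()
    s2 = ((w.sum(axis=0) + w.sum(axis=1)) ** 2).sum()
    b2 = n * (z**4).sum() / denom**2
    num = n * ((n**2 - 3 * n + 3) * s1 - n * s2 + 3 * W**2) - b2 * (
        (n**2 - n) * s1 - 2 * n * s2 + 6 * W**2
    )
    var = num / ((n - 1) * (n - 2) * (n - 3) * W**2) - EI**2
    if var <= 0:
        return I, 1.0
    zstat = (I - EI) / np.sqrt(var)
    return I, float(2 * stats.norm.sf(abs(zstat)))


def uniformity_test(u: np.ndarray) -> float:
    """KS p-value of PIT residuals against the uniform distribution."""
    return float(stats.kstest(u, "uniform").pvalue)


@dataclass
class DiagnosticsReport:
    """All residual test statistics for one fitted model."""

    dispersion_ratio: float
    dispersion_p: float
    morans_i: float
    morans_p: float
    ks_p: float
    sigma2_alpha: float | None = None
    n_sim: int = 250
    violations: list[str] = field(default_factory=list)

    def any_violation(self) -> bool:
        return len(self.violations) > 0


def residual_diagnostics(
    fit: ModelFit,
    coords: np.ndarray,
    nsim: int = 250,
    alpha: float = 0.05,
    seed: int = 0,
) -> DiagnosticsReport:
    rng = np.random.default_rng(seed)
    u = quantile_residuals(fit, nsim=nsim, seed=rng)
    ratio, disp_p = dispersion_test(fit, nsim=nsim, seed=rng)
    I, moran_p = morans_i(u - 0.5, coords)
    ks_p = uniformity_test(u)
    violations = []
    if disp_p < alpha:
        violations.append("overdispersion")
    if moran_p < alpha:
        violations.append("spatial_autocorrelation")
    if ks_p < alpha:
        violations.append("non_uniform_residuals")
    return DiagnosticsReport(
        dispersion_ratio=ratio,
        dispersion_p=disp_p,
        morans_i=I,
        morans_p=moran_p,
        ks_p=ks_p,
        sigma2_alpha=fit.sigma2_alpha,
        n_sim=nsim,
        violations=violations,
    )


def decide_random_effect(
    data: pd.DataFrame,
    coords: np.ndarray | pd.DataFrame,
    family: str = "poisson",
    alpha: float = 0.05,
    sigma2_floor: float = 0.05,
    nsim: int = 250,
    seed: int = 0,
) -> tuple[bool, dict]:
    """Decide whether the survey-year random intercept stays in the model.

    Fits the additive model with and without the intercept, runs the residual
    diagnostics on both, and includes the intercept iff it resolves a
    violation detected without it, or its estimated variance exceeds
    ``sigma2_floor``. With a single year level the intercept is excluded
    outright. Returns (include, report dict with both diagnostics).
    """
    if isinstance(coords, pd.DataFrame):
        coords = coords[["x", "y"]].to_numpy(dtype=float)
    if "year" not in data.columns or data["year"].nunique() < 2:
        return False, {"reason": "fewer than 2 survey-year levels"}
    base_spec = ModelSpec(family=family, structure="additive",
                          random_effect=False,
                          use_autocov="autocov" in data.columns)
    re_spec = ModelSpec(family=family, structure="additive",
                        random_effect=True,
                        use_autocov="autocov" in data.columns)
    fit0 = fit_model(data, base_spec)
    fit1 = fit_model(data, re_spec)
    diag0 = residual_diagnostics(fit0, coords, nsim=nsim, alpha=alpha, seed=seed)
    diag1 = residual_diagnostics(fit1, coords, nsim=nsim, alpha=alpha, seed=seed + 1)
    resolves = diag0.any_violation() and not diag1.any_violation()
    big_sigma = (fit1.sigma2_alpha or 0.0) > sigma2_floor
    include = bool(fit1.converged and (resolves or big_sigma))
    report = {
        "without_re": diag0,
        "with_re": diag1,
        "sigma2_alpha": fit1.sigma2_alpha,
        "resolves_violation": resolves,
        "sigma2_above_floor": big_sigma,
        "include": include,
    }
    return include, report
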