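"""Count regressions: Poisson / negative-binomial GLMs, optionally with a
single survey-year random intercept integrated by Laplace approximation.

Fixed-effect-only fits delegate to statsmodels (GLM for Poisson, the discrete
NB2 model with ML-estimated dispersion for the negative binomial). The mixed
model — one Gaussian random intercept over survey years — is fit here by
maximising the Laplace-approximated marginal likelihood: the per-group
conditional modes are found by Newton steps (the inner problem separates by
group), and the outer parameters (fixed effects, log SD of the intercept,
and log size for the NB) go through L-BFGS-B with numerical derivatives.

Predictors are z-scored before fitting ("scaled and centred coefficients"),
so effect sizes are comparable across metrics and extents.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special, stats
from statsmodels.discrete.discrete_model import NegativeBinomial
from statsmodels.tools.numdiff import approx_hess1

__all__ = ["ModelSpec", "ModelFit", "fit_model", "choose_family", "marginal_r2"]

STRUCTURES = ("additive", "interaction", "polynomial")


@dataclass(frozen=True)
class ModelSpec:
    """Family, fixed-effect structure and random-effect switch of one fit."""

    family: str = "poisson"  # 'poisson' | 'nb'
    structure: str = "additive"  # 'additive' | 'interaction' | 'polynomial'
    random_effect: bool = False
    use_autocov: bool = True
    standardize: bool = True
    fixed_theta: float | None = None  # hold the NB size fixed instead of ML

    def __post_init__(self) -> None:
        if self.family not in ("poisson", "nb"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.structure not in STRUCTURES:
            raise ValueError(f"unknown structure {self.structure!r}")


@dataclass
class ModelFit:
    """A fitted count model: estimates, SEs, Wald p-values, likelihood, extras."""

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    llf: float
    family: str
    spec: ModelSpec
    n: int
    df_model: int
    converged: bool
    theta: float | None = None  # NB size; None for Poisson
    sigma2_alpha: float | None = None  # random-intercept variance, if present
    X: np.ndarray = field(default=None, repr=False)
    y: np.ndarray = field(default=None, repr=False)
    groups: np.ndarray = field(default=None, repr=False)  # year codes, if RE
    group_modes: np.ndarray = field(default=None, repr=False)
    exog_names: list[str] = field(default_factory=list)

    @property
    def fitted(self) -> np.ndarray:
        """Conditional mean (includes the estimated year intercepts if present)."""
        eta = self.X @ self.params.to_numpy()
        if self.groups is not None and self.group_modes is not None:
            eta = eta + self.group_modes[self.groups]
        return np.exp(eta)

    @property
    def fixed_linpred(self) -> np.ndarray:
        return self.X @ self.params.to_numpy()

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2)
        lo = self.params - z * self.bse
        hi = self.params + z * self.bse
        return pd.DataFrame({"lower": lo, "upper": hi})

    def simulate(self, rng: np.random.Generator, nsim: int = 250) -> np.ndarray:
        """Simulate (nsim, n) responses from the fitted model.

        Random effects, when present, are re-drawn from N(0, sigma2_alpha) per
        simulation, so the simulations reflect the marginal model.
        """
        eta_fix = self.fixed_linpred
        out = np.empty((nsim, self.n), dtype=np.int64)
        for s in range(nsim):
            eta = eta_fix.copy()
            if self.groups is not None and self.sigma2_alpha is not None:
                u = rng.normal(0, np.sqrt(self.sigma2_alpha), self.groups.max() + 1)
                eta = eta + u[self.groups]
            mu = np.exp(eta)
            if self.family == "poisson":
                out[s] = rng.poisson(mu)
            else:
                lam = rng.gamma(self.theta, mu / self.theta)
                out[s] = rng.poisson(lam)
        return out


def _zscore_cols(df: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    out = df.copy()
    for c in cols:
        v = out[c].to_numpy(dtype=float)
        sd = v.std()
        out[c] = (v - v.mean()) / sd if sd > 1e-12 else 0.0
    return out


def build_design(
    data: pd.DataFrame, spec: ModelSpec
) -> tuple[np.ndarray, np.ndarray, list[str], np.ndarray | None]:
    """Design matrix for the global model under a fixed-effect structure.

    Expects columns ``richness, metric, uplands, gdd`` and optionally
    ``autocov`` and ``year``. Continuous predictors are z-scored (per fitted
    dataset) when the spec requests standardisation; interaction / quadratic
    terms are formed from the standardised columns.
    """
    required = ["richness", "metric", "uplands", "gdd"]
    missing = [c for c in required if c not in data.columns]
    if missing:
        raise ValueError(f"model data missing columns: {missing}")
    cont = ["metric", "uplands", "gdd"]
    if spec.use_autocov and "autocov" in data.columns:
        cont.append("autocov")
    if data["metric"].to_numpy(dtype=float).std() < 1e-12:
        raise ValueError("metric has zero variance at this extent")
    # constant nuisance covariates (e.g. uplands = 1 everywhere at fine
    # extents inside harvest blocks) carry no information and are dropped
    cont = [c for c in cont
            if c == "metric" or data[c].to_numpy(dtype=float).std() > 1e-12]
    df = _zscore_cols(data, cont) if spec.standardize else data.copy()
    cols = {"intercept": np.ones(len(df))}
    for c in cont:
        cols[c] = df[c].to_numpy(dtype=float)
    if spec.structure == "interaction":
        if "uplands" not in cols:
            raise ValueError(
                "interaction structure needs non-constant proportion uplands"
            )
        cols["metric:uplands"] = cols["metric"] * cols["uplands"]
    elif spec.structure == "polynomial":
        cols["metric^2"] = cols["metric"] ** 2
    names = list(cols)
    X = np.column_stack([cols[c] for c in names])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the collinear terms: columns whose removal restores full rank
        bad = []
        for k in range(X.shape[1] - 1, 0, -1):
            Xk = np.delete(X, k, axis=1)
            if np.linalg.matrix_rank(Xk) == rank:
                bad.append(names[k])
        raise ValueError(f"rank-deficient design; collinear terms: {bad}")
    y = df["richness"].to_numpy(dtype=float)
    groups = None
    if spec.random_effect:
        if "year" not in df.columns:
            raise ValueError("random_effect requested but no 'year' column")
        groups = pd.Categorical(df["year"]).codes.astype(int)
        if len(np.unique(groups)) < 2:
            raise ValueError("random intercept needs >= 2 year levels")
    return X, y, names, groups


# ---------------------------------------------------------------------------
# Fixed-effects fits (statsmodels)
# ---------------------------------------------------------------------------

def _fit_fixed(y: np.ndarray, X: np.ndarray, family: str,
               fixed_theta: float | None = None):
    """Return (params, bse, pvalues, llf, theta, converged)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if family == "poisson":
            res = sm.GLM(y, X, family=sm.families.Poisson()).fit()
            return (
                res.params, res.bse, res.pvalues, float(res.llf), None, True,
            )
        if fixed_theta is not None:
            fam = sm.families.NegativeBinomial(alpha=1.0 / fixed_theta)
            res = sm.GLM(y, X, family=fam).fit()
            return (
                res.params, res.bse, res.pvalues, float(res.llf),
                float(fixed_theta), True,
            )
        mod = NegativeBinomial(y, X)
        res = mod.fit(disp=0, maxiter=500, method="bfgs")
        converged = bool(res.mle_retvals.get("converged", True))
        alpha = max(float(res.params[-1]), 1e-10)
        theta = 1.0 / alpha
        return (
            res.params[:-1], res.bse[:-1], res.pvalues[:-1],
            float(res.llf), theta, converged,
        )


# ---------------------------------------------------------------------------
# Laplace-approximated mixed model (single categorical random intercept)
# ---------------------------------------------------------------------------

def _count_ll_derivs(y, eta, family, theta):
    """Pointwise log-likelihood and its first/second derivatives in eta."""
    mu = np.exp(eta)
    if family == "poisson":
        ll = y * eta - mu - special.gammaln(y + 1)
        d1 = y - mu
        d2 = -mu
    else:
        ll = (
            special.gammaln(y + theta)
            - special.gammaln(theta)
            - special.gammaln(y + 1)
            + theta * np.log(theta)
            + y * eta
            - (y + theta) * np.log(theta + mu)
        )
        d1 = y - (y + theta) * mu / (theta + mu)
        d2 = -(y + theta) * theta * mu / (theta + mu) ** 2
    return ll, d1, d2


def _inner_modes(y, eta_fix, groups, n_groups, sigma2, family, theta, u0=None):
    """Newton solve for the per-group conditional modes of the random intercepts."""
    u = np.zeros(n_groups) if u0 is None else u0.copy()
    for _ in range(50):
        eta = eta_fix + u[groups]
        _, d1, d2 = _count_ll_derivs(y, eta, family, theta)
        g = np.bincount(groups, weights=d1, minlength=n_groups) - u / sigma2
        h = np.bincount(groups, weights=d2, minlength=n_groups) - 1.0 / sigma2
        step = g / h
        # dampen large Newton steps for stability at extreme starting points
        step = np.clip(step, -5.0, 5.0)
        u = u - step
        if np.max(np.abs(step)) < 1e-10:
            break
    return u


def _laplace_loglik(psi, y, X, groups, n_groups, family, u_cache):
    p = X.shape[1]
    beta = psi[:p]
    sigma2 = np.exp(2.0 * psi[p])
    theta = np.exp(psi[p + 1]) if family == "nb" else None
    eta_fix = X @ beta
    u = _inner_modes(y, eta_fix, groups, n_groups, sigma2, family, theta,
                     u0=u_cache.get("u"))
    u_cache["u"] = u
    eta = eta_fix + u[groups]
    ll, _, d2 = _count_ll_derivs(y, eta, family, theta)
    joint = (
        ll.sum()
        - 0.5 * np.sum(u**2) / sigma2
        - 0.5 * n_groups * np.log(2 * np.pi * sigma2)
    )
    h = -(np.bincount(groups, weights=d2, minlength=n_groups) - 1.0 / sigma2)
    return joint + 0.5 * n_groups * np.log(2 * np.pi) - 0.5 * np.sum(np.log(h))


def _fit_mixed(y, X, groups, family: str):
    """Laplace ML fit; returns (params, bse, pvalues, llf, theta, sigma2, modes, ok)."""
    n_groups = int(groups.max()) + 1
    p = X.shape[1]
    # starting values from the fixed-effects fit
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        start_res = sm.GLM(y, X, family=sm.families.Poisson()).fit()
    beta0 = np.asarray(start_res.params, dtype=float)
    psi0 = np.concatenate([beta0, [np.log(0.3)]])
    bounds = [(None, None)] * p + [(np.log(1e-4), np.log(10.0))]
    if family == "nb":
        psi0 = np.concatenate([psi0, [np.log(1.0)]])
        bounds = bounds + [(np.log(1e-3), np.log(1e6))]
    u_cache: dict = {}

    def nll(psi):
        val = _laplace_loglik(psi, y, X, groups, n_groups, family, u_cache)
        return -val if np.isfinite(val) else 1e12

    res = optimize.minimize(
        nll, psi0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-11},
    )
    psi = res.x
    sigma2 = float(np.exp(2.0 * psi[p]))
    theta = float(np.exp(psi[p + 1])) if family == "nb" else None
    llf = -float(res.fun)
    eta_fix = X @ psi[:p]
    modes = _inner_modes(y, eta_fix, groups, n_groups, sigma2, family, theta)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        H = approx_hess1(psi, nll)
    bse = np.full(len(psi), np.nan)
    try:
        cov = np.linalg.inv(H)
        diag = np.diag(cov)
        ok_var = diag > 0
        bse[ok_var] = np.sqrt(diag[ok_var])
    except np.linalg.LinAlgError:
        pass
    beta = psi[:p]
    beta_se = bse[:p]
    zvals = np.divide(beta, beta_se, out=np.full(p, np.nan), where=beta_se > 0)
    pvals = 2 * stats.norm.sf(np.abs(zvals))
    return beta, beta_se, pvals, llf, theta, sigma2, modes, bool(res.success)


# ---------------------------------------------------------------------------
# Public interface
# ---------------------------------------------------------------------------

def fit_model(data: pd.DataFrame, spec: ModelSpec) -> ModelFit:
    """Maximum-likelihood fit of the global richness model.

    Non-convergence is flagged on the returned fit, not raised; a
    rank-deficient design raises naming the collinear terms.
    """
    X, y, names, groups = build_design(data, spec)
    if groups is None:
        params, bse, pvals, llf, theta, converged = _fit_fixed(
            y, X, spec.family, fixed_theta=spec.fixed_theta
        )
        sigma2 = None
        modes = None
    else:
        params, bse, pvals, llf, theta, sigma2, modes, converged = _fit_mixed(
            y, X, groups, spec.family
        )
    return ModelFit(
        params=pd.Series(np.asarray(params, dtype=float), index=names),
        bse=pd.Series(np.asarray(bse, dtype=float), index=names),
        pvalues=pd.Series(np.asarray(pvals, dtype=float), index=names),
        llf=llf,
        family=spec.family,
        spec=spec,
        n=len(y),
        df_model=X.shape[1] - 1,
        converged=converged,
        theta=theta,
        sigma2_alpha=sigma2,
        X=X,
        y=y,
        groups=groups,
        group_modes=modes,
        exog_names=names,
    )


def choose_family(
    y: np.ndarray | pd.Series,
    X: np.ndarray | None = None,
    threshold: float = 1.5,
) -> str:
    """Pick 'poisson' or 'nb' from the Pearson dispersion of a Poisson fit.

    Fits a Poisson GLM (intercept-only unless a design is given) and returns
    the negative binomial when Pearson chi-square / residual df exceeds the
    threshold (default 1.5). A failed Poisson fit falls back to 'nb'.
    """
    y = np.asarray(y, dtype=float)
    if len(y) < 20:
        raise ValueError("need at least 20 observations to judge dispersion")
    if X is None:
        X = np.ones((len(y), 1))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        dispersion = float(res.pearson_chi2) / res.df_resid
    except Exception:
        warnings.warn("Poisson fit failed while judging dispersion; using NB")
        return "nb"
    return "nb" if dispersion > threshold else "poisson"


def marginal_r2(fit: ModelFit, method: str = "lognormal") -> float:
    """Nakagawa–Schielzeth marginal R²: fixed-effect variance share on the link.

    R²m = s²_f / (s²_f + s²_alpha + s²_dist) with s²_f the variance of the
    fixed linear predictor and the distribution-specific variance s²_dist by
    the lognormal approximation (default), the delta method, or the trigamma
    function. The rate entering s²_dist is estimated by the mean response.
    """
    if not fit.converged:
        raise ValueError("marginal R² requires a converged fit")
    if method not in ("lognormal", "delta", "trigamma"):
        raise ValueError(f"unknown method {method!r}")
    beta = fit.params.to_numpy()
    # fixed-effect variance excludes the intercept column
    nonint = [i for i, nm in enumerate(fit.exog_names) if nm != "intercept"]
    var_f = float(np.var(fit.X[:, nonint] @ beta[nonint])) if nonint else 0.0
    var_alpha = fit.sigma2_alpha or 0.0
    lam = float(np.mean(fit.y))
    if lam <= 0:
        return 0.0
    inv = 1.0 / lam + (1.0 / fit.theta if fit.family == "nb" else 0.0)
    if method == "lognormal":
        var_dist = np.log1p(inv)
    elif method == "delta":
        var_dist = inv
    else:
        var_dist = float(special.polygamma(1, 1.0 / inv))
    denom = var_f + var_alpha + var_dist
    return var_f / denom if denom > 0 else 0.0
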