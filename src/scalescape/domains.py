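"""Domains of scale from derivative transitions of extent–extent smooths.

For each configuration metric, the selected landscape extent is smoothed
against response extent with an independent penalized regression spline (own
shape and own wiggliness per metric — no shared global smooth). The smooth's
first derivative is estimated by central finite differences with a 1 ha step,
with pointwise 95% CIs propagated through the posterior coefficient
covariance by simulation (1000 coefficient draws by default). A domain
boundary is called wherever the derivative's significance state changes —
significantly positive to non-significant, significantly negative to
non-significant, or a sign reversal — i.e. wherever the CI on the significant
side of the transition excludes zero. A persistence rule then collapses
later, weakly-supported boundaries into a single domain for parsimony.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

__all__ = [
    "PSplineFit",
    "DerivativeSeries",
    "DomainBoundary",
    "fit_extent_smooth",
    "fit_extent_smooths",
    "derivative_with_ci",
    "detect_boundaries",
    "assemble_domains",
    "boundaries_table",
]

MIN_POINTS = 5


@dataclass
class PSplineFit:
    """A penalized cubic B-spline fit y ~ f(x) with posterior covariance.

    A P-spline in the rich-basis tradition: ``basis_dim`` cubic B-splines over
    the data range (deliberately more than the data could support unpenalized)
    with a second-order difference penalty, the smoothing parameter chosen by
    restricted maximum likelihood. ``cov`` is the Bayesian posterior
    covariance sigma² (B'B + λD'D)⁻¹ used for simulation-based derivative CIs;
    ``sigma2`` is the REML variance (RSS + λ·penalty)/(n − penalty nullity),
    which is stable at the small n typical of extent scans.
    """

    knots: np.ndarray
    coef: np.ndarray
    cov: np.ndarray
    lam: float
    sigma2: float
    edf: float
    x_range: tuple[float, float]
    degree: int = 3
    x_data: np.ndarray | None = None

    def basis(self, x: np.ndarray) -> np.ndarray:
        x = np.clip(np.asarray(x, dtype=float), *self.x_range)
        return BSpline.design_matrix(
            x, self.knots, self.degree, extrapolate=False
        ).toarray()

    def predict(self, x: np.ndarray, coef: np.ndarray | None = None) -> np.ndarray:
        c = self.coef if coef is None else coef
        return self.basis(x) @ c


def _bspline_knots(x: np.ndarray, basis_dim: int, degree: int = 3) -> np.ndarray:
    """Clamped knot vector giving exactly ``basis_dim`` B-splines on [min, max]."""
    n_interior = basis_dim - degree - 1
    if n_interior < 0:
        raise ValueError(f"basis_dim must be >= {degree + 1}")
    lo, hi = float(x.min()), float(x.max())
    interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
    return np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])


def _divided_difference_matrix(
    knots: np.ndarray, k: int, degree: int, order: int
) -> np.ndarray:
    """Difference penalty in divided-difference form at the Greville sites.

    With clamped (repeated-end) knots the Greville abscissae are nonuniform,
    so plain index-wise coefficient differences penalize linear functions near
    the boundary; divided differences keep polynomials of degree < order in
    the penalty nullspace exactly.
    """
    greville = np.array(
        [knots[j + 1 : j + degree + 1].mean() for j in range(k)]
    )
    D = np.eye(k)
    sites = greville
    for _ in range(order):
        h = np.diff(sites)
        h[h <= 0] = np.min(h[h > 0]) if (h > 0).any() else 1.0
        D = (D[1:] - D[:-1]) / h[:, None]
        sites = 0.5 * (sites[1:] + sites[:-1])
    # scale back to O(1) rows so lambda magnitudes stay comparable
    return D * np.median(np.abs(np.diff(greville))) ** order


def fit_extent_smooth(
    x: np.ndarray,
    y: np.ndarray,
    basis_dim: int = 30,
    lambdas: np.ndarray | None = None,
    pen_order: int = 2,
) -> PSplineFit:
    """Fit one penalized-spline smooth of landscape extent on response extent.

    The basis is deliberately generous (default 30 cubic B-splines for ~13
    points): a coarse basis smears sharp regime changes over its knot spacing
    and dislocates derivative transitions, whereas a rich basis with the
    second-order difference penalty resolves a kink to about the data spacing
    while REML keeps the effective degrees of freedom small. Needs >= 5
    points.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    order = np.argsort(x)
    x, y = x[order], y[order]
    if len(x) < MIN_POINTS:
        raise ValueError(f"need >= {MIN_POINTS} points per metric, got {len(x)}")
    degree = 3
    knots = _bspline_knots(x, basis_dim, degree)
    B = BSpline.design_matrix(x, knots, degree, extrapolate=False).toarray()
    k = B.shape[1]
    D = _divided_difference_matrix(knots, k, degree, pen_order)
    P = D.T @ D
    BtB = B.T @ B
    Bty = B.T @ y
    n = len(x)
    if lambdas is None:
        lambdas = np.logspace(-4, 8, 61)
    # variance floor keeps the restricted likelihood well-defined on exactly
    # interpolable (noise-free) inputs, where every lambda gives zero residual
    var_floor = 1e-8 * float(y.var()) + 1e-30
    best = None
    for lam in lambdas:
        A = BtB + lam * P
        try:
            Ainv = np.linalg.inv(A)
        except np.linalg.LinAlgError:
            continue
        coef = Ainv @ Bty
        rss = float(((y - B @ coef) ** 2).sum())
        pen = float(coef @ P @ coef)
        sig2r = max((rss + lam * pen) / (n - pen_order), var_floor)
        # restricted likelihood, dropping lambda-free constants
        sign, logdetA = np.linalg.slogdet(A)
        if sign <= 0:
            continue
        score = (
            (n - pen_order) * np.log(sig2r)
            + logdetA
            - (k - pen_order) * np.log(lam)
        )
        if best is None or score < best[0]:
            edf = float(np.trace(Ainv @ BtB))
            best = (score, lam, coef, Ainv, edf, sig2r)
    if best is None:
        raise np.linalg.LinAlgError("singular spline system at every lambda")
    _, lam, coef, Ainv, edf, sigma2 = best
    cov = sigma2 * Ainv
    return PSplineFit(
        knots=knots,
        coef=coef,
        cov=cov,
        lam=float(lam),
        sigma2=float(sigma2),
        edf=edf,
        x_range=(float(x.min()), float(x.max())),
        degree=degree,
        x_data=x.copy(),
    )


def fit_extent_smooths(
    records: pd.DataFrame, basis_dim: int = 30
) -> dict[str, PSplineFit]:
    """Independent smooth per metric from a scale-of-effect table.

    Expects columns ``metric, response_extent_ha, landscape_extent_ha``.
    Metrics with fewer than 5 points are skipped with a warning.
    """
    fits: dict[str, PSplineFit] = {}
    for metric, grp in records.groupby("metric"):
        if len(grp) < MIN_POINTS:
            warnings.warn(
                f"{metric}: only {len(grp)} points (< {MIN_POINTS}); skipped"
            )
            continue
        fits[metric] = fit_extent_smooth(
            grp["response_extent_ha"].to_numpy(),
            grp["landscape_extent_ha"].to_numpy(),
            basis_dim=basis_dim,
        )
    return fits


@dataclass
class DerivativeSeries:
    """First-derivative estimates of one smooth with pointwise simulation CIs."""

    metric: str
    grid: np.ndarray  # response extents (ha)
    derivative: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    step_ha: float
    nsim: int

    def states(self) -> np.ndarray:
        """Significance state per grid point: +1 pos, -1 neg, 0 ns (CI vs zero)."""
        out = np.zeros(len(self.grid), dtype=int)
        out[self.ci_lower > 0] = 1
        out[self.ci_upper < 0] = -1
        return out


def derivative_with_ci(
    fit: PSplineFit,
    metric: str = "",
    step_ha: float = 1.0,
    nsim: int = 1000,
    seed: int = 0,
    grid: np.ndarray | None = None,
) -> DerivativeSeries:
    """Central finite-difference derivative with simulation-based 95% CIs.

    The derivative at x is (f(x + s/2) − f(x − s/2)) / s with s = 1 ha by
    default, evaluated on a 1 ha grid across the fitted range but trimmed by
    half the median data spacing at each end: at the extreme ends the CI
    widens for want of data, and the resulting significance flips are edge
    artifacts, not domain transitions. Uncertainty is propagated by drawing
    ``nsim`` coefficient vectors from the posterior normal and taking
    pointwise 2.5/97.5 percentiles.
    """
    lo, hi = fit.x_range
    if grid is None:
        trim = 0.0
        if fit.x_data is not None and len(fit.x_data) > 1:
            trim = 0.5 * float(np.median(np.diff(np.sort(fit.x_data))))
        glo, ghi = lo + trim, hi - trim
        grid = np.arange(glo, ghi + 1e-9, step_ha)
        if grid[-1] < ghi - 1e-9:
            grid = np.append(grid, ghi)
    grid = np.asarray(grid, dtype=float)
    x_hi = np.minimum(grid + step_ha / 2.0, hi)
    x_lo = np.maximum(grid - step_ha / 2.0, lo)
    span = x_hi - x_lo  # shrinks at the range ends where the stencil is clipped
    B_hi = fit.basis(x_hi)
    B_lo = fit.basis(x_lo)
    Bdiff = (B_hi - B_lo) / span[:, None]
    deriv = Bdiff @ fit.coef
    rng = np.random.default_rng(seed)
    # draw coefficients from the posterior normal; jitter scaled to the
    # covariance magnitude, with an eigenvalue-clip fallback
    scale = max(float(np.abs(np.diag(fit.cov)).max()), 1e-30)
    cov = fit.cov + 1e-10 * scale * np.eye(len(fit.coef))
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(cov)
        L = V * np.sqrt(np.clip(w, 0.0, None))
    draws = fit.coef[None, :] + rng.standard_normal((nsim, len(fit.coef))) @ L.T
    sims = draws @ Bdiff.T  # (nsim, grid)
    ci_lo = np.percentile(sims, 2.5, axis=0)
    ci_hi = np.percentile(sims, 97.5, axis=0)
    return DerivativeSeries(
        metric=metric,
        grid=grid,
        derivative=deriv,
        ci_lower=ci_lo,
        ci_upper=ci_hi,
        step_ha=step_ha,
        nsim=nsim,
    )


@dataclass
class DomainBoundary:
    """One derivative-state transition: location, flanking CIs, selection flag."""

    metric: str
    response_extent_ha: float  # midpoint of the transition interval
    kind: str  # 'pos->ns' | 'neg->ns' | 'ns->pos' | 'ns->neg' | 'sign_reversal'
    ci_before: tuple[float, float]
    ci_after: tuple[float, float]
    selected: bool = True


_KIND = {
    (1, 0): "pos->ns",
    (-1, 0): "neg->ns",
    (0, 1): "ns->pos",
    (0, -1): "ns->neg",
    (1, -1): "sign_reversal",
    (-1, 1): "sign_reversal",
}


def detect_boundaries(series: DerivativeSeries) -> list[DomainBoundary]:
    """Call a boundary at every adjacent change of derivative significance state.

    Every transition involves at least one significant flank whose CI excludes
    zero (that is what makes the state significant), which is exactly the
    filter for a domain change; both flanking CIs are recorded since either
    side may be the one reported.
    """
    if len(series.grid) < 3:
        raise ValueError("derivative series needs >= 3 grid points")
    states = series.states()
    out: list[DomainBoundary] = []
    for k in range(len(states) - 1):
        a, b = int(states[k]), int(states[k + 1])
        if a == b:
            continue
        out.append(
            DomainBoundary(
                metric=series.metric,
                response_extent_ha=float((series.grid[k] + series.grid[k + 1]) / 2.0),
                kind=_KIND[(a, b)],
                ci_before=(float(series.ci_lower[k]), float(series.ci_upper[k])),
                ci_after=(float(series.ci_lower[k + 1]), float(series.ci_upper[k + 1])),
            )
        )
    return out


@dataclass
class DomainPartition:
    """Domains of scale for one metric: intervals between selected boundaries."""

    metric: str
    boundaries: list[DomainBoundary]
    domains: list[tuple[float, float]]


def _significant_margin(b: DomainBoundary) -> float:
    """|CI bound nearest zero| on the significant flank(s) of a transition."""
    margins = []
    for lo, hi in (b.ci_before, b.ci_after):
        if lo > 0 or hi < 0:  # this flank is significant
            margins.append(min(abs(lo), abs(hi)))
    return max(margins) if margins else 0.0


def assemble_domains(
    boundaries: list[DomainBoundary],
    x_range: tuple[float, float],
    metric: str = "",
    margin_threshold: float = 0.1,
) -> DomainPartition:
    """Apply the persistence rule and cut the extent range into domains.

    The first boundary is always kept. Each later boundary is kept only when
    its significant flank is convincingly away from zero — the CI bound
    nearest zero exceeds ``margin_threshold`` (in derivative units, ha per
    ha); transitions whose CIs merely graze zero are oscillations and are
    grouped into the surrounding domain for parsimony (selected=False).
    """
    boundaries = sorted(boundaries, key=lambda b: b.response_extent_ha)
    for rank, b in enumerate(boundaries):
        b.selected = rank == 0 or _significant_margin(b) > margin_threshold
    if metric == "" and boundaries:
        metric = boundaries[0].metric
    cuts = [b.response_extent_ha for b in boundaries if b.selected]
    edges = [x_range[0], *cuts, x_range[1]]
    domains = [(edges[i], edges[i + 1]) for i in range(len(edges) - 1)]
    return DomainPartition(metric=metric, boundaries=boundaries, domains=domains)


def boundaries_table(partitions: list[DomainPartition]) -> pd.DataFrame:
    """Long-format boundary table: one row per detected transition.

    Columns mirror the reporting schema: metric, response extent (ha), the
    flanking derivative CIs, the transition kind, whether the transition is a
    domain change, and whether the persistence rule kept it.
    """
    rows = []
    for part in partitions:
        if not part.boundaries:
            rows.append(
                {
                    "metric": part.metric,
                    "response_extent_ha": np.nan,
                    "deriv_ci_lower_before": np.nan,
                    "deriv_ci_upper_before": np.nan,
                    "deriv_ci_lower_after": np.nan,
                    "deriv_ci_upper_after": np.nan,
                    "kind": "none",
                    "domain_change": False,
                    "selected": False,
                }
            )
            continue
        for b in part.boundaries:
            rows.append(
                {
                    "metric": b.metric,
                    "response_extent_ha": b.response_extent_ha,
                    "deriv_ci_lower_before": b.ci_before[0],
                    "deriv_ci_upper_before": b.ci_before[1],
                    "deriv_ci_lower_after": b.ci_after[0],
                    "deriv_ci_upper_after": b.ci_after[1],
                    "kind": b.kind,
                    "domain_change": True,
                    "selected": b.selected,
                }
            )
    return pd.DataFrame(rows)
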