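"""Extent-extent smooths, derivative CIs, boundary calling, domain assembly."""

import numpy as np
import pandas as pd
import pytest

from scalescape.domains import (
    DerivativeSeries,
    assemble_domains,
    boundaries_table,
    derivative_with_ci,
    detect_boundaries,
    fit_extent_smooth,
    fit_extent_smooths,
)

RESPONSE_EXTENTS = np.pi * np.arange(50.0, 351.0, 25.0) ** 2 / 1e4  # 13 points


def two_regime(x, threshold=12.0, slope=3.0):
    """Landscape extent rising at `slope` below the threshold, flat above."""
    return np.where(x < threshold, slope * x, slope * threshold)


class TestFitExtentSmooth:
    def test_reproduces_linear_relationship(self):
        x = RESPONSE_EXTENTS
        fit = fit_extent_smooth(x, x)
        grid = np.linspace(x.min(), x.max(), 40)
        np.testing.assert_allclose(fit.predict(grid), grid, atol=0.5)

    def test_constant_data_flat_with_zero_derivative(self):
        x = RESPONSE_EXTENTS
        fit = fit_extent_smooth(x, np.full_like(x, 20.0))
        series = derivative_with_ci(fit, nsim=400, seed=0)
        assert np.abs(series.derivative).max() < 1e-6

    def test_noisy_piecewise_fit_beats_noise(self):
        rng = np.random.default_rng(3)
        x = RESPONSE_EXTENTS
        y = two_regime(x) + rng.normal(0, 2.0, len(x))
        fit = fit_extent_smooth(x, y)
        resid_sd = np.std(y - fit.predict(x))
        assert resid_sd < np.std(y)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="5"):
            fit_extent_smooth(np.arange(4.0), np.arange(4.0))

    def test_grouped_fit_skips_sparse_metric_with_warning(self):
        records = pd.DataFrame(
            {
                "metric": ["a"] * 13 + ["b"] * 3,
                "response_extent_ha": np.r_[RESPONSE_EXTENTS, [1.0, 2.0, 3.0]],
                "landscape_extent_ha": np.r_[RESPONSE_EXTENTS, [1.0, 2.0, 3.0]],
            }
        )
        with pytest.warns(UserWarning, match="b"):
            fits = fit_extent_smooths(records)
        assert set(fits) == {"a"}


class TestDerivativeWithCI:
    def test_linear_one_to_one_derivative_is_one_everywhere(self):
        x = RESPONSE_EXTENTS
        rng = np.random.default_rng(1)
        fit = fit_extent_smooth(x, x + rng.normal(0, 0.3, len(x)))
        series = derivative_with_ci(fit, nsim=1000, seed=5)
        assert np.allclose(series.derivative, 1.0, atol=0.2)
        assert (series.ci_lower > 0).all()  # CI excludes 0 throughout

    def test_less_noise_narrower_ci(self):
        x = RESPONSE_EXTENTS
        rng = np.random.default_rng(2)
        noise = rng.normal(0, 1.0, len(x))
        wide = derivative_with_ci(
            fit_extent_smooth(x, x + 2.0 * noise), nsim=600, seed=7
        )
        narrow = derivative_with_ci(
            fit_extent_smooth(x, x + 1.0 * noise), nsim=600, seed=7
        )
        assert (narrow.ci_upper - narrow.ci_lower).mean() < (
            wide.ci_upper - wide.ci_lower
        ).mean()

    def test_fixed_seed_reproducible(self):
        x = RESPONSE_EXTENTS
        fit = fit_extent_smooth(x, two_regime(x))
        a = derivative_with_ci(fit, nsim=300, seed=9)
        b = derivative_with_ci(fit, nsim=300, seed=9)
        np.testing.assert_array_equal(a.ci_lower, b.ci_lower)
        np.testing.assert_array_equal(a.ci_upper, b.ci_upper)

    def test_grid_spacing_is_one_hectare(self):
        x = RESPONSE_EXTENTS
        fit = fit_extent_smooth(x, x)
        series = derivative_with_ci(fit, seed=0, nsim=100)
        steps = np.diff(series.grid)
        assert np.allclose(steps[:-1], 1.0)

    def test_derivative_integrates_back_to_curve(self):
        """Trapezoid integral of the derivative reconstructs the smooth."""
        rng = np.random.default_rng(4)
        x = RESPONSE_EXTENTS
        fit = fit_extent_smooth(x, two_regime(x) + rng.normal(0, 1.0, len(x)))
        series = derivative_with_ci(fit, nsim=100, seed=0)
        curve = fit.predict(series.grid)
        recon = curve[0] + np.concatenate(
            [[0.0], np.cumsum(
                0.5 * (series.derivative[1:] + series.derivative[:-1])
                * np.diff(series.grid)
            )]
        )
        err = np.abs(recon - curve).max()
        assert err < 0.01 * (curve.max() - curve.min())


def make_series(states, values=None):
    """Hand-built DerivativeSeries: states +1/0/-1 per grid point."""
    n = len(states)
    grid = np.arange(1.0, n + 1.0)
    deriv = np.zeros(n)
    lo = np.empty(n)
    hi = np.empty(n)
    for i, s in enumerate(states):
        if s == 1:
            lo[i], hi[i], deriv[i] = 0.2, 0.9, 0.5
        elif s == -1:
            lo[i], hi[i], deriv[i] = -0.9, -0.2, -0.5
        else:
            lo[i], hi[i], deriv[i] = -0.3, 0.3, 0.0
    if values is not None:
        for i, (a, b) in values.items():
            lo[i], hi[i] = a, b
    return DerivativeSeries(
        metric="m", grid=grid, derivative=deriv, ci_lower=lo, ci_upper=hi,
        step_ha=1.0, nsim=100,
    )


class TestDetectBoundaries:
    def test_uniformly_significant_positive_no_boundary(self):
        series = make_series([1] * 10)
        assert detect_boundaries(series) == []

    def test_pos_to_ns_transition_detected(self):
        series = make_series([1, 1, 1, 0, 0], values={2: (0.2, 0.9)})
        bounds = detect_boundaries(series)
        assert len(bounds) == 1
        b = bounds[0]
        assert b.kind == "pos->ns"
        assert b.response_extent_ha == pytest.approx(3.5)
        assert b.ci_before == (0.2, 0.9)

    def test_pos_ns_pos_two_transitions(self):
        series = make_series([1, 1, 0, 1, 1])
        bounds = detect_boundaries(series)
        assert [b.kind for b in bounds] == ["pos->ns", "ns->pos"]

    def test_sign_reversal_detected(self):
        series = make_series([1, 1, -1, -1])
        bounds = detect_boundaries(series)
        assert [b.kind for b in bounds] == ["sign_reversal"]

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            detect_boundaries(make_series([1, 0]))


class TestAssembleDomains:
    def test_single_boundary_two_domains(self):
        series = make_series([1, 1, 1, 0, 0, 0])
        part = assemble_domains(detect_boundaries(series), (1.0, 6.0))
        assert len(part.domains) == 2
        assert part.domains[0][1] == part.domains[1][0]

    def test_no_boundaries_single_domain(self):
        part = assemble_domains([], (1.0, 40.0), metric="edge_density")
        assert part.domains == [(1.0, 40.0)]

    def test_oscillating_weak_transitions_grouped_for_parsimony(self):
        """One strong early transition plus later CI-grazing oscillations:
        only the first boundary is kept."""
        states = [1, 1, 1, 1, 0, 0, -1, 0, -1, 0]
        series = make_series(
            states,
            values={3: (0.8, 2.5), 6: (-0.9, -0.01), 8: (-0.8, -0.02)},
        )
        part = assemble_domains(detect_boundaries(series), (1.0, 10.0))
        kept = [b for b in part.boundaries if b.selected]
        assert len(kept) == 1
        assert kept[0].response_extent_ha == pytest.approx(4.5)
        assert all(not b.selected for b in part.boundaries[1:])
        assert len(part.domains) == 2

    def test_boundaries_table_schema(self):
        series = make_series([1, 1, 0, 0])
        part = assemble_domains(detect_boundaries(series), (1.0, 4.0))
        empty = assemble_domains([], (1.0, 4.0), metric="edge_density")
        table = boundaries_table([part, empty])
        assert {"metric", "response_extent_ha", "domain_change", "selected"}.issubset(
            table.columns
        )
        ed = table[table.metric == "edge_density"]
        assert not ed.domain_change.iloc[0]


class TestRecovery:
    def test_null_one_to_one_scan_selects_no_boundary(self):
        """1:1 extent scans (pure spatial autocorrelation) should yield a
        single domain in nearly every replicate (quick 15-replicate check;
        the 50-replicate version runs in the acceptance suite)."""
        rng = np.random.default_rng(10)
        x = RESPONSE_EXTENTS
        false_pos = 0
        for _ in range(15):
            y = x + rng.normal(0, 2.0, len(x))
            fit = fit_extent_smooth(x, y)
            series = derivative_with_ci(fit, nsim=500, seed=int(rng.integers(2**31)))
            part = assemble_domains(detect_boundaries(series), fit.x_range)
            false_pos += sum(b.selected for b in part.boundaries) > 0
        assert false_pos <= 2

    def test_breakpoint_recovered_within_tolerance(self):
        """Two-regime truth (slope 3 below 12 ha, flat above, noise SD 2):
        the first selected boundary lands near the breakpoint."""
        rng = np.random.default_rng(11)
        x = RESPONSE_EXTENTS
        hits = 0
        for _ in range(10):
            y = two_regime(x, threshold=12.0, slope=3.0) + rng.normal(0, 2.0, len(x))
            fit = fit_extent_smooth(x, y)
            series = derivative_with_ci(fit, nsim=500, seed=int(rng.integers(2**31)))
            part = assemble_domains(detect_boundaries(series), fit.x_range)
            kept = [b.response_extent_ha for b in part.boundaries if b.selected]
            hits += bool(kept) and abs(kept[0] - 12.0) <= 3.0
        assert hits >= 8

    def test_derivative_ci_calibrated_on_known_truth(self):
        """Pointwise 95% CI covers the true derivative of a smooth truth at
        roughly nominal rate."""
        rng = np.random.default_rng(12)
        x = np.linspace(1.0, 38.0, 13)
        truth = lambda t: 20.0 + 8.0 * np.sin(t / 12.0)
        dtruth = lambda t: (truth(t + 0.5) - truth(t - 0.5)) / 1.0
        covered = total = 0
        for _ in range(60):
            y = truth(x) + rng.normal(0, 1.0, len(x))
            fit = fit_extent_smooth(x, y)
            series = derivative_with_ci(fit, nsim=400, seed=int(rng.integers(2**31)))
            inner = (series.grid > x.min() + 2) & (series.grid < x.max() - 2)
            d = dtruth(series.grid[inner])
            covered += ((series.ci_lower[inner] <= d) & (d <= series.ci_upper[inner])).sum()
            total += inner.sum()
        assert 0.88 <= covered / total <= 0.995
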