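"""Count models: family choice, GLM/GLMM fitting, marginal R², autocovariate,
residual diagnostics, structure comparison, and scale-of-effect selection."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from scalescape.models import (
    ModelSpec,
    build_autocovariate,
    choose_family,
    compare_structures,
    decide_random_effect,
    fit_model,
    marginal_r2,
    select_scale_of_effect,
)
from scalescape.models.autocov import tps_smooth_2d
from scalescape.models.diagnostics import morans_i
from scalescape.synthetic import simulate_direct_glm


def model_frame(n, rng, beta_metric=0.3, family="poisson", theta=None,
                year_sd=0.0, n_years=5, beta=None):
    """A direct-GLM dataset shaped like the global-model input frame."""
    beta = beta or {"intercept": 1.2, "metric": beta_metric,
                    "uplands": 0.1, "gdd": 0.2}
    seed = int(rng.integers(2**31))
    return simulate_direct_glm(400 if n is None else n, beta, family=family,
                               theta=theta, seed=seed, year_sd=year_sd,
                               n_years=n_years)


class TestChooseFamily:
    def test_poisson_data_chooses_poisson(self):
        rng = np.random.default_rng(0)
        hits = 0
        for _ in range(50):
            y = rng.poisson(5.0, size=500)
            hits += choose_family(y) == "poisson"
        assert hits >= 45

    def test_nb_data_chooses_nb(self):
        rng = np.random.default_rng(1)
        hits = 0
        for _ in range(50):
            lam = rng.gamma(0.8, 5.0 / 0.8, size=500)
            y = rng.poisson(lam)
            hits += choose_family(y) == "nb"
        assert hits >= 45

    def test_constant_counts_are_equidispersed(self):
        assert choose_family(np.full(100, 4)) == "poisson"

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            choose_family(np.arange(10))


class TestFitModel:
    def test_recovers_known_coefficients(self):
        rng = np.random.default_rng(7)
        data = model_frame(2000, rng)
        fit = fit_model(data, ModelSpec(family="poisson", standardize=False))
        for term, truth in (("metric", 0.3), ("uplands", 0.1), ("gdd", 0.2)):
            assert abs(fit.params[term] - truth) < 3 * fit.bse[term]

    def test_nb_with_large_theta_matches_poisson(self):
        """In the theta -> infinity limit the NB fit degenerates to Poisson."""
        rng = np.random.default_rng(8)
        data = model_frame(800, rng)
        pois = fit_model(data, ModelSpec(family="poisson"))
        nb = fit_model(data, ModelSpec(family="nb", fixed_theta=1e8))
        np.testing.assert_allclose(
            nb.params.to_numpy(), pois.params.to_numpy(), atol=1e-4
        )
        # ML-estimated dispersion on equidispersed data lands near the limit
        nb_ml = fit_model(data, ModelSpec(family="nb"))
        np.testing.assert_allclose(
            nb_ml.params.to_numpy(), pois.params.to_numpy(), atol=5e-3
        )

    def test_rank_deficient_design_names_terms(self):
        rng = np.random.default_rng(9)
        data = model_frame(100, rng)
        data["gdd"] = data["metric"]  # perfectly collinear after z-scoring
        with pytest.raises(ValueError, match="collinear"):
            fit_model(data, ModelSpec())

    def test_zero_variance_metric_rejected(self):
        rng = np.random.default_rng(10)
        data = model_frame(100, rng)
        data["metric"] = 3.0
        with pytest.raises(ValueError, match="zero variance"):
            fit_model(data, ModelSpec())

    def test_mixed_fit_recovers_year_variance(self):
        rng = np.random.default_rng(11)
        data = model_frame(1500, rng, year_sd=0.5, n_years=8)
        fit = fit_model(data, ModelSpec(family="poisson", random_effect=True))
        assert fit.converged
        assert 0.1 < fit.sigma2_alpha < 0.6  # truth 0.25
        assert abs(fit.params["metric"] - 0.3) < 4 * fit.bse["metric"]

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
    def test_mixed_poisson_matches_lme4_laplace(self, tmp_path):
        """Independent oracle: lme4::glmer (Laplace) on the same data."""
        rng = np.random.default_rng(12)
        data = model_frame(600, rng, year_sd=0.4, n_years=6)
        fit = fit_model(data, ModelSpec(family="poisson", random_effect=True,
                                        standardize=False))
        csv = tmp_path / "d.csv"
        data.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            m <- glmer(richness ~ metric + uplands + gdd + (1 | year), data = d,
                       family = poisson)
            cat(fixef(m), sqrt(unlist(VarCorr(m))), logLik(m), sep = "\\n")
            """
        )
        out = subprocess.run(
            ["Rscript", "--vanilla", str(script)],
            capture_output=True, text=True, timeout=300,
        )
        assert out.returncode == 0, out.stderr
        vals = [float(v) for v in out.stdout.split()]
        r_beta, r_sd, r_llf = vals[:4], vals[4], vals[5]
        ours = [fit.params[t] for t in ("intercept", "metric", "uplands", "gdd")]
        np.testing.assert_allclose(ours, r_beta, atol=2e-3)
        assert abs(np.sqrt(fit.sigma2_alpha) - r_sd) < 0.02
        assert abs(fit.llf - r_llf) < 0.5

    def test_coverage_of_fixed_effect_cis(self):
        """95% Wald CIs cover the truth at roughly nominal rate (quick check;
        the full 200-replicate calibration runs in the acceptance suite)."""
        rng = np.random.default_rng(13)
        beta = {"intercept": 1.2, "metric": 0.3, "uplands": 0.1, "gdd": 0.2}
        covered = 0
        total = 0
        for _ in range(60):
            data = model_frame(400, rng)
            fit = fit_model(data, ModelSpec(family="poisson", standardize=False))
            ci = fit.conf_int()
            for term, truth in beta.items():
                covered += ci.loc[term, "lower"] <= truth <= ci.loc[term, "upper"]
                total += 1
        assert 0.88 <= covered / total <= 0.99

    def test_null_metric_gives_uniform_pvalues(self):
        rng = np.random.default_rng(14)
        pvals = []
        for _ in range(100):
            data = model_frame(300, rng, beta_metric=0.0)
            fit = fit_model(data, ModelSpec(family="poisson"))
            pvals.append(fit.pvalues["metric"])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestMarginalR2:
    def test_intercept_only_is_zero(self):
        rng = np.random.default_rng(15)
        data = model_frame(300, rng, beta={"intercept": 1.0})
        data["metric"] = rng.standard_normal(300)
        data["uplands"] = rng.standard_normal(300)
        data["gdd"] = rng.standard_normal(300)
        fit = fit_model(data, ModelSpec(family="poisson"))
        fit.params[:] = [fit.params["intercept"], 0.0, 0.0, 0.0]
        assert marginal_r2(fit) == pytest.approx(0.0, abs=1e-12)

    def test_stronger_effect_larger_r2(self):
        rng = np.random.default_rng(16)
        weak = fit_model(model_frame(600, np.random.default_rng(1), beta_metric=0.1),
                         ModelSpec(family="poisson"))
        strong = fit_model(model_frame(600, np.random.default_rng(1), beta_metric=0.8),
                           ModelSpec(family="poisson"))
        assert marginal_r2(strong) > marginal_r2(weak)

    @pytest.mark.parametrize("method", ["lognormal", "delta", "trigamma"])
    def test_always_in_unit_interval(self, method):
        rng = np.random.default_rng(17)
        for family, theta in (("poisson", None), ("nb", 2.0)):
            data = model_frame(300, rng, family=family, theta=theta)
            fit = fit_model(data, ModelSpec(family=family))
            r2 = marginal_r2(fit, method=method)
            assert 0.0 <= r2 < 1.0


class TestAutocovariate:
    @staticmethod
    def _coords(n, rng):
        return rng.uniform(0, 5000, size=(n, 2))

    def test_white_noise_residuals_autocov_covers_zero(self):
        """With no spatial signal the downstream autocovariate coefficient
        should be null: its 95% CI covers 0 in most replicates."""
        rng = np.random.default_rng(18)
        covered = 0
        for _ in range(50):
            data = model_frame(60, rng)
            coords = self._coords(60, rng)
            data["autocov"] = build_autocovariate(data, coords)
            fit = fit_model(data, ModelSpec(family="poisson"))
            if "autocov" in fit.params.index:
                ci = fit.conf_int().loc["autocov"]
                covered += ci.lower <= 0.0 <= ci.upper
            else:
                # skill gate zeroed the autocovariate: effectively a null effect
                covered += 1
        assert covered >= 45

    def test_recovers_implanted_spatial_trend(self):
        rng = np.random.default_rng(19)
        hits = 0
        for _ in range(20):
            n = 80
            coords = self._coords(n, rng)
            trend = np.sin(coords[:, 0] / 1500.0) + coords[:, 1] / 5000.0
            data = model_frame(n, rng, beta_metric=0.2)
            eta = 1.0 + 0.2 * data["metric"] + trend
            data["richness"] = rng.poisson(np.exp(eta))
            auto = build_autocovariate(data, coords)
            hits += np.corrcoef(auto, trend)[0, 1] > 0.7
        assert hits >= 16

    def test_deterministic_on_fixed_inputs(self):
        rng = np.random.default_rng(20)
        data = model_frame(50, rng)
        coords = self._coords(50, np.random.default_rng(4))
        a = build_autocovariate(data, coords)
        b = build_autocovariate(data, coords)
        np.testing.assert_array_equal(a, b)

    def test_coincident_coordinates_rejected_with_guidance(self):
        rng = np.random.default_rng(21)
        data = model_frame(40, rng)
        coords = self._coords(40, rng)
        coords[1] = coords[0]
        with pytest.raises(ValueError, match="jitter"):
            build_autocovariate(data, coords)

    def test_smooth_interpolates_smooth_surface(self):
        rng = np.random.default_rng(22)
        coords = self._coords(150, rng)
        z = np.cos(coords[:, 0] / 2000.0) + 0.5 * np.sin(coords[:, 1] / 1500.0)
        fitted, lam, edf = tps_smooth_2d(z + rng.normal(0, 0.05, 150), coords)
        assert np.corrcoef(fitted, z)[0, 1] > 0.95


class TestDiagnosticsAndRandomEffect:
    def test_morans_i_detects_gradient(self):
        rng = np.random.default_rng(23)
        coords = rng.uniform(0, 1000, size=(80, 2))
        gradient = coords[:, 0] / 1000.0
        I, p = morans_i(gradient + rng.normal(0, 0.05, 80), coords)
        assert I > 0 and p < 0.01
        I0, p0 = morans_i(rng.standard_normal(80), coords)
        assert p0 > 0.01

    def test_strong_year_effects_include_random_intercept(self):
        rng = np.random.default_rng(24)
        include = 0
        for rep in range(30):
            data = model_frame(250, rng, year_sd=0.5, n_years=6)
            coords = rng.uniform(0, 5000, size=(250, 2))
            inc, _ = decide_random_effect(data, coords, seed=rep)
            include += inc
        assert include >= 24

    def test_zero_year_variance_excludes_random_intercept(self):
        rng = np.random.default_rng(25)
        exclude = 0
        for rep in range(30):
            data = model_frame(250, rng, year_sd=0.0, n_years=6)
            coords = rng.uniform(0, 5000, size=(250, 2))
            inc, _ = decide_random_effect(data, coords, seed=rep)
            exclude += not inc
        assert exclude >= 24

    def test_single_year_level_forced_exclusion(self):
        rng = np.random.default_rng(26)
        data = model_frame(100, rng, n_years=1)
        inc, report = decide_random_effect(data, rng.uniform(0, 1, (100, 2)))
        assert not inc and "levels" in report["reason"]


class TestStructureComparison:
    def test_additive_truth_keeps_additive(self):
        rng = np.random.default_rng(27)
        wins = 0
        for _ in range(50):
            data = model_frame(400, rng)
            choice, _, _ = compare_structures(data, family="poisson",
                                              use_autocov=False)
            wins += choice == "additive"
        assert wins >= 40

    def test_quadratic_truth_selects_polynomial(self):
        rng = np.random.default_rng(28)
        wins = 0
        for _ in range(50):
            data = model_frame(400, rng)
            x = data["metric"].to_numpy()
            zx = (x - x.mean()) / x.std()
            data["richness"] = rng.poisson(np.exp(1.0 + 0.2 * zx - 0.3 * zx**2))
            choice, _, _ = compare_structures(data, family="poisson",
                                              use_autocov=False)
            wins += choice == "polynomial"
        assert wins >= 40

    def test_null_interaction_lrt_is_chi2_one(self):
        """2·Δll between additive and interaction fits on additive truth
        follows chi-square(1)."""
        rng = np.random.default_rng(29)
        stats_ = []
        for _ in range(120):
            data = model_frame(300, rng)
            _, _, lrt = compare_structures(data, family="poisson",
                                           use_autocov=False)
            row = lrt[lrt.comparison == "additive_vs_interaction"]
            stats_.append(max(float(row.lr_stat.iloc[0]), 0.0))
        ks = stats.kstest(stats_, stats.chi2(df=1).cdf)
        assert ks.pvalue > 0.005


class TestScaleOfEffectSelection:
    @staticmethod
    def _table(rows):
        base = {
            "metric": "edge_density",
            "response_radius_m": 150.0,
            "response_extent_ha": 7.07,
            "n_sites": 60,
            "beta": 0.1,
            "se": 0.05,
            "family": "poisson",
            "converged": True,
        }
        recs = []
        for i, (p, r2) in enumerate(rows):
            rec = dict(base)
            rec.update(
                p_value=p, marginal_r2=r2,
                landscape_radius_m=150.0 + 50 * i,
                landscape_extent_ha=np.pi * (150 + 50 * i) ** 2 / 1e4,
            )
            recs.append(rec)
        return pd.DataFrame(recs)

    def test_significant_tier_highest_r2_wins(self):
        fits = self._table([(0.01, 0.10), (0.04, 0.20), (0.20, 0.50)])
        rec = select_scale_of_effect(fits)
        assert rec.tier == "significant"
        assert rec.marginal_r2 == 0.20 and rec.p_value == 0.04

    def test_marginal_tier_when_no_significant(self):
        fits = self._table([(0.07, 0.30), (0.30, 0.60)])
        rec = select_scale_of_effect(fits)
        assert rec.tier == "marginal" and rec.p_value == 0.07

    def test_fallback_highest_r2_overall(self):
        fits = self._table([(0.20, 0.10), (0.50, 0.40), (0.30, 0.25)])
        rec = select_scale_of_effect(fits)
        assert rec.tier == "fallback" and rec.marginal_r2 == 0.40

    def test_r2_ties_break_to_smaller_extent(self):
        fits = self._table([(0.01, 0.30), (0.02, 0.30)])
        rec = select_scale_of_effect(fits)
        assert rec.landscape_radius_m == 150.0
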