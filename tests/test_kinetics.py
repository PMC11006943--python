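import math

import numpy as np
import pytest

from mztkin import kinetics
from mztkin.binning import BinSpec

T = BinSpec().centers()


class TestModelCurves:
    def test_half_life_identity(self):
        # one 20-min half-life after onset: half the expression remains
        val = kinetics.evaluate_maternal(1.0, math.log(2) / 20, 240.0, 260.0)
        assert val == pytest.approx(-1.0)

    def test_onset_continuity_and_preonset_plateau(self):
        x0 = 8.0
        assert kinetics.evaluate_maternal(x0, 0.1, 250.0, 250.0) == pytest.approx(math.log2(x0))
        assert kinetics.evaluate_maternal(x0, 0.1, 250.0, 245.0) == pytest.approx(math.log2(x0))

    def test_linear_accumulation_reference_point(self):
        # alpha * (t - d) = 0.01 * 100 = 1 -> log2 = 0
        assert kinetics.evaluate_zygotic(0.01, 240.0, 340.0) == pytest.approx(0.0)

    def test_saturating_asymptote(self):
        alpha, beta_z = 0.01, 0.05
        val = kinetics.evaluate_zygotic(alpha, 240.0, 1e7, beta_z=beta_z)
        assert val == pytest.approx(math.log2(alpha / beta_z))

    def test_just_after_onset_clamped_at_floor(self):
        assert kinetics.evaluate_zygotic(0.01, 240.0, 240.0 + 1e-9) == -4.0


class TestFitting:
    def test_noiseless_decay_recovery_vs_grid_oracle(self):
        x0, beta, d = 2.0 ** 7, math.log(2) / 35, 255.0
        y = kinetics.evaluate_maternal(x0, beta, d, T)
        fit = kinetics.fit_kinetic_model(T, y, "M_decay", rng_seed=0)
        # independent dense grid-search oracle over the bounded box
        best = (np.inf, None)
        for lx in np.linspace(3, 11, 33):
            for lb in np.linspace(-9, -3, 49):
                for dd in np.linspace(240, 280, 41):
                    pred = lx - 2.0 ** lb * np.maximum(T - dd, 0) * np.log2(np.e)
                    rss = float(np.sum((pred - y) ** 2))
                    if rss < best[0]:
                        best = (rss, (2.0 ** lx, 2.0 ** lb, dd))
        assert fit.rss <= best[0] + 1e-12
        assert fit.params["x0"] == pytest.approx(x0, rel=1e-3)
        assert fit.params["beta"] == pytest.approx(beta, rel=1e-3)
        assert fit.params["d"] == pytest.approx(d, abs=0.1)

    def test_noiseless_saturating_recovery(self):
        alpha, beta_z, d = 5e-3, 0.03, 245.0
        y = kinetics.evaluate_zygotic(alpha, d, T, beta_z=beta_z)
        fit = kinetics.fit_kinetic_model(T, y, "Z_sat", rng_seed=0)
        assert fit.params["alpha"] == pytest.approx(alpha, rel=1e-2)
        assert fit.params["beta_z"] == pytest.approx(beta_z, rel=1e-2)

    def test_flat_profile_constant_fit_has_zero_rss(self):
        y = np.full(len(T), 3.0)
        fit = kinetics.fit_kinetic_model(T, y, "M_const")
        assert fit.rss == pytest.approx(0.0, abs=1e-20)
        assert fit.r_squared == 1.0  # zero-variance convention
        assert fit.params["x0"] == pytest.approx(8.0)

    def test_determinism_under_fixed_seed(self):
        rng = np.random.default_rng(4)
        y = kinetics.evaluate_maternal(16.0, 0.02, 250.0, T) + rng.normal(0, 0.3, len(T))
        a = kinetics.fit_kinetic_model(T, y, "M_decay", rng_seed=42)
        b = kinetics.fit_kinetic_model(T, y, "M_decay", rng_seed=42)
        assert a.params == b.params and a.rss == b.rss

    def test_too_few_observations_is_unfit(self):
        assert kinetics.fit_kinetic_model(T[:3], np.ones(3), "M_decay") is None

    def test_sigma_ml_and_halflife_reciprocity(self):
        rng = np.random.default_rng(5)
        y = kinetics.evaluate_maternal(64.0, 0.03, 250.0, T) + rng.normal(0, 0.2, len(T))
        fit = kinetics.fit_kinetic_model(T, y, "M_decay", rng_seed=1)
        assert fit.sigma_ml == pytest.approx(math.sqrt(fit.rss / fit.n))
        half_life = math.log(2) / fit.params["beta"]
        assert half_life * fit.params["beta"] == pytest.approx(math.log(2))


class TestLikelihoodRatio:
    def _fit_pair(self, rss_null, rss_alt, n=11, p_null=1, p_alt=3):
        mk = lambda rss, p, mid: kinetics.ModelFit(
            model_id=mid, params={}, n=n, p=p, rss=rss,
            sigma_ml=math.sqrt(rss / n), loglik=0.0, r_squared=0.0)
        return mk(rss_null, p_null, "M_const"), mk(rss_alt, p_alt, "M_decay")

    def test_identical_rss_gives_p_one(self):
        stat, p = kinetics.likelihood_ratio_test(*self._fit_pair(2.0, 2.0))
        assert stat == 0.0 and p == 1.0

    def test_halved_rss_reference_value(self):
        # n=11, rss halved, df=1: statistic 11 ln 2 = 7.625, p = 0.00576
        null, alt = self._fit_pair(2.0, 1.0, p_alt=2)
        stat, p = kinetics.likelihood_ratio_test(null, alt)
        assert stat == pytest.approx(11 * math.log(2), rel=1e-12)
        assert p == pytest.approx(0.005758, abs=2e-6)

    def test_zero_statistic_with_two_df(self):
        stat, p = kinetics.likelihood_ratio_test(*self._fit_pair(2.0, 2.0, p_alt=3))
        assert p == 1.0

    def test_non_nested_rejected(self):
        null, alt = self._fit_pair(2.0, 1.0)
        with pytest.raises(ValueError):
            kinetics.likelihood_ratio_test(alt, null)


class TestSelection:
    def test_low_expression_rule_forces_null(self):
        y = np.full(len(T), -3.5)
        y[:6] = 1.0  # 5 of 11 bins below -3
        sel = kinetics.select_nested_model(T, y, "maternal", rng_seed=0)
        assert sel.selected.model_id == "M_null"

    def test_strong_decay_selects_decay_model(self):
        rng = np.random.default_rng(8)
        y = kinetics.evaluate_maternal(64.0, math.log(2) / 20, 250.0, T) \
            + rng.normal(0, 0.1, len(T))
        sel = kinetics.select_nested_model(T, y, "maternal", rng_seed=0)
        assert sel.selected.model_id == "M_decay"

    def test_saturating_curvature_selects_saturating_model(self):
        rng = np.random.default_rng(9)
        y = kinetics.evaluate_zygotic(0.05, 245.0, T, beta_z=0.08) + rng.normal(0, 0.05, len(T))
        sel = kinetics.select_nested_model(T, y, "zygotic", rng_seed=0)
        assert sel.selected.model_id == "Z_sat"

    def test_null_pvalues_are_conservative(self):
        # the flat null lies on the boundary of the decay model's parameter
        # space (onset at the window end / vanishing rate), so decay-vs-const
        # p-values are stochastically larger than uniform: P(p < a) <= a
        rng = np.random.default_rng(17)
        pvals = []
        for i in range(300):
            y = 2.0 + rng.normal(0, 0.2, len(T))
            sel = kinetics.select_nested_model(T, y, "maternal", rng_seed=i)
            if "M_decay" in sel.p_values:
                pvals.append(sel.p_values["M_decay"])
        pvals = np.asarray(pvals)
        assert len(pvals) > 250
        for a in (0.01, 0.05, 0.10, 0.25):
            # allow three binomial SDs of Monte-Carlo slack above nominal
            slack = 3 * math.sqrt(a * (1 - a) / len(pvals))
            assert (pvals < a).mean() <= a + slack

    def test_nesting_guarantee_on_noisy_profiles(self):
        rng = np.random.default_rng(10)
        for i in range(20):
            y = rng.normal(1.0, 0.5, len(T))
            sel = kinetics.select_nested_model(T, y, "maternal", rng_seed=i)
            fits = sel.fits
            if fits.get("M_decay") is not None and fits.get("M_const") is not None:
                assert fits["M_decay"].rss <= fits["M_const"].rss + 1e-9
                assert fits["M_const"].rss <= fits["M_null"].rss + 1e-9


class TestClassification:
    def _selection(self, model_id, params, component="maternal"):
        fit = kinetics.ModelFit(model_id=model_id, params=params, n=11,
                                p=kinetics.n_params(model_id), rss=0.1,
                                sigma_ml=0.1, loglik=0.0, r_squared=0.9)
        return kinetics.SelectionResult(selected=fit, fits={}, p_values={})

    def _mz(self, half_life, log2_alpha):
        m = self._selection("M_decay", {"x0": 10.0, "beta": math.log(2) / half_life, "d": 250.0})
        z = self._selection("Z_linear", {"alpha": 2.0 ** log2_alpha, "d": 250.0}, "zygotic")
        return kinetics.classify_and_group("g", m, z)

    def test_fast_replacement_group_a(self):
        gk = self._mz(15.0, -10.5)
        assert gk.gene_class == "maternal_zygotic"
        assert gk.group == "A"
        assert gk.half_life == pytest.approx(15.0)

    def test_slow_decay_fast_accumulation_group_d(self):
        assert self._mz(60.0, -10.5).group == "D"

    def test_groups_b_and_c(self):
        assert self._mz(15.0, -12.5).group == "B"
        assert self._mz(60.0, -12.5).group == "C"

    def test_excluded_middle_band_unassigned(self):
        assert self._mz(30.0, -10.5).group == "unassigned"
        assert self._mz(60.0, -11.5).group == "unassigned"

    def test_single_component_classes(self):
        m = self._selection("M_decay", {"x0": 10.0, "beta": 0.02, "d": 250.0})
        z_null = self._selection("Z_null", {}, "zygotic")
        gk = kinetics.classify_and_group("g", m, z_null)
        assert gk.gene_class == "maternal_only"
        m_null = self._selection("M_null", {})
        z = self._selection("Z_linear", {"alpha": 1e-3, "d": 250.0}, "zygotic")
        assert kinetics.classify_and_group("g", m_null, z).gene_class == "zygotic_only"
        assert kinetics.classify_and_group("g", m_null, z_null).gene_class == "unfit"
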