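"""Growth-trajectory fitting, AICc comparison, AMGR, and sensitivity refits."""

import math
import warnings

import numpy as np
import pytest

from troutstock.growth import (
    GrowthFamily,
    GrowthModel,
    ImplausibleAsymptoteWarning,
    aicc_weights,
    amgr,
    compare_models_aicc,
    predict_length,
    sensitivity_refit,
)
from troutstock.simulate import GrowthParams

PARAMS = (105.0, 0.216, 3.99)


class TestMeanFunctions:
    def test_von_bertalanffy_vanishes_at_t0(self):
        assert predict_length("von_bertalanffy", (100.0, 0.3, -0.5), -0.5) == 0.0

    def test_gompertz_inflection_value_is_tlinf_over_e(self):
        assert predict_length("gompertz", PARAMS, 3.99) == pytest.approx(
            105.0 / math.e, abs=1e-12
        )

    def test_logistic_midpoint_is_half_asymptote(self):
        assert predict_length("logistic", (80.0, 0.5, 2.0), 2.0) == pytest.approx(40.0)

    @pytest.mark.parametrize("family", list(GrowthFamily))
    def test_strictly_increasing_and_asymptotic(self, family):
        t = np.linspace(0.1, 40, 500)
        y = predict_length(family, (100.0, 0.25, 3.0), t)
        assert np.all(np.diff(y) > 0)
        assert predict_length(family, (100.0, 0.25, 3.0), 300.0) == pytest.approx(
            100.0, rel=1e-9
        )

    def test_gompertz_growth_rate_peaks_at_t0_with_amgr_slope(self):
        # finite-difference oracle for dTL/dt: maximum at t0, value G*TL_inf/e
        t = np.linspace(0.0, 12.0, 24001)
        y = predict_length("gompertz", PARAMS, t)
        rate = np.gradient(y, t)
        i = int(np.argmax(rate))
        assert t[i] == pytest.approx(3.99, abs=0.01)
        assert rate[i] == pytest.approx(0.216 * 105.0 / math.e, rel=1e-5)


class TestFitting:
    @pytest.mark.parametrize("family", list(GrowthFamily))
    def test_noiseless_recovery_is_exact(self, family):
        rng = np.random.default_rng(0)
        t = rng.uniform(0.3, 10.7, 300)
        true = (105.0, 0.216, 3.99) if family is not GrowthFamily.VON_BERTALANFFY else (105.0, 0.216, -0.3)
        TL = predict_length(family, true, t)
        fit = GrowthModel.from_arrays(t, TL, family).fit()
        assert fit.converged
        assert fit.params == pytest.approx(true, abs=1e-6)
        assert fit.rss == pytest.approx(0.0, abs=1e-9)

    def test_noisy_fit_brackets_truth_with_its_ci(self):
        rng = np.random.default_rng(1)
        t = rng.uniform(0.3, 10.7, 2000)
        TL = predict_length("gompertz", PARAMS, t) + rng.normal(0, 3.0, 2000)
        fit = GrowthModel.from_arrays(t, TL, "gompertz").fit()
        for truth, ci in zip(PARAMS, fit.ci):
            assert ci[0] < truth < ci[1]

    def test_ci_coverage_near_nominal(self):
        # 95% CIs should cover the generating parameters in ~95% of replicates
        rng = np.random.default_rng(2)
        reps, cover = 200, np.zeros(3)
        for _ in range(reps):
            t = rng.uniform(0.3, 10.7, 400)
            TL = predict_length("gompertz", PARAMS, t) + rng.normal(0, 3.0, 400)
            fit = GrowthModel.from_arrays(t, TL, "gompertz").fit()
            for j, (truth, ci) in enumerate(zip(PARAMS, fit.ci)):
                cover[j] += ci[0] < truth < ci[1]
        assert np.all(cover / reps > 0.90)
        assert np.all(cover / reps <= 1.0)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            GrowthModel.from_arrays([1, 2, 3, 4], [10, 20, 30, 35], "gompertz").fit()

    def test_implausible_asymptote_warns(self):
        t = np.linspace(0.5, 6.0, 60)
        TL = predict_length("gompertz", (200.0, 0.2, 4.0), t)
        with pytest.warns(ImplausibleAsymptoteWarning):
            GrowthModel.from_arrays(t, TL, "gompertz").fit()


class TestModelComparison:
    def _fits(self):
        rng = np.random.default_rng(3)
        t = rng.uniform(0.3, 10.7, 500)
        TL = predict_length("gompertz", PARAMS, t) + rng.normal(0, 4.0, 500)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return [GrowthModel.from_arrays(t, TL, fam).fit() for fam in GrowthFamily]

    def test_generating_family_wins_aicc(self):
        cmp = compare_models_aicc(self._fits())
        assert cmp.best is GrowthFamily.GOMPERTZ
        assert cmp.table["weight"].sum() == pytest.approx(1.0)
        assert cmp.table["delta_AICc"].min() == 0.0

    def test_equal_fits_split_weight_evenly(self):
        w = aicc_weights(np.array([123.4, 123.4]))
        assert w == pytest.approx([0.5, 0.5])

    def test_handset_aicc_weights(self):
        # direct evaluation of exp(-delta/2) normalisation
        w = aicc_weights(np.array([100.0, 102.0, 110.0]))
        assert w == pytest.approx([0.7275, 0.2676, 0.0049], abs=5e-4)

    def test_weights_invariant_to_common_shift(self):
        a = np.array([100.0, 102.0, 110.0])
        assert aicc_weights(a) == pytest.approx(aicc_weights(a + 57.3))

    def test_mismatched_samples_rejected(self):
        fits = self._fits()
        other = fits[0].__class__(**{**fits[0].__dict__, "n": fits[0].n + 1})
        with pytest.raises(ValueError):
            compare_models_aicc([fits[0], other])


class TestAmgrAndSensitivity:
    def _gompertz_fit(self, TL_inf=105.0, G=0.216):
        rng = np.random.default_rng(4)
        t = rng.uniform(0.3, 10.7, 300)
        TL = predict_length("gompertz", (TL_inf, G, 3.99), t)
        return GrowthModel.from_arrays(t, TL, "gompertz"), None

    @staticmethod
    def _results_with(TL_inf, G):
        from troutstock.growth import GrowthResults

        return GrowthResults(
            family=GrowthFamily.GOMPERTZ,
            params=(TL_inf, G, 3.0),
            se=(0.0, 0.0, 0.0),
            ci=((TL_inf, TL_inf), (G, G), (3.0, 3.0)),
            rss=0.0,
            sigma_hat=0.0,
            n=10,
            aicc=0.0,
            loglik=0.0,
            converged=True,
        )

    def test_amgr_unit_case(self):
        assert amgr(self._results_with(1.0, math.e)) == pytest.approx(1.0, abs=1e-15)

    def test_amgr_published_parameters(self):
        model, _ = self._gompertz_fit()
        fit = model.fit()
        assert amgr(fit) == pytest.approx(0.216 * 105.0 / math.e, abs=1e-6)
        assert amgr(fit) == pytest.approx(8.34, abs=0.005)

    def test_amgr_linear_in_asymptote(self):
        f1 = self._gompertz_fit(TL_inf=50.0)[0].fit()
        f2 = self._gompertz_fit(TL_inf=100.0)[0].fit()
        assert amgr(f2) == pytest.approx(2 * amgr(f1), rel=1e-6)

    def test_amgr_requires_gompertz(self):
        rng = np.random.default_rng(5)
        t = rng.uniform(0.3, 8.0, 100)
        TL = predict_length("logistic", (90.0, 0.4, 3.0), t)
        fit = GrowthModel.from_arrays(t, TL, "logistic").fit()
        with pytest.raises(ValueError):
            amgr(fit)

    def test_sensitivity_drop_zero_is_identity(self):
        model, _ = self._gompertz_fit()
        fit = model.fit()
        refit, change, ok = sensitivity_refit(model, fit, 0)
        assert refit is fit and change == 0.0 and ok

    def test_sensitivity_without_outliers_changes_little(self):
        rng = np.random.default_rng(6)
        t = rng.uniform(0.3, 10.7, 500)
        TL = predict_length("gompertz", PARAMS, t) + rng.normal(0, 3.0, 500)
        model = GrowthModel.from_arrays(t, TL, "gompertz")
        fit = model.fit()
        _, change, ok = sensitivity_refit(model, fit, 3)
        assert ok
        assert change < 0.05
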