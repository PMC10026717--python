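"""Catch-curve construction and Chapman–Robson mortality estimation."""

import math

import numpy as np
import pandas as pd
import pytest

from troutstock.data import Dataset
from troutstock.mortality import (
    CatchCurve,
    DegenerateCurveError,
    DescendingLimb,
    annual_rate,
    build_catch_curve,
    chapman_robson,
    natural_mortality_tmax,
    partition_mortality,
    select_descending_limb,
)
from troutstock.simulate import SyntheticConfig, simulate_ages, simulate_population


def _limb_from_counts(counts: dict[int, int]) -> DescendingLimb:
    s = pd.Series(counts).sort_index()
    return DescendingLimb(
        counts=s,
        first_included_class=0,
        n=int(s.sum()),
        T=int((s.index.to_numpy() * s.values).sum()),
    )


def _ds_from_ages(ages) -> Dataset:
    return Dataset(
        pd.DataFrame({"id": [f"f{i}" for i in range(len(ages))], "TL_cm": 20.0, "age_yr": ages})
    )


class TestCatchCurve:
    def test_hand_counted_toy(self):
        curve = build_catch_curve(_ds_from_ages([0.5, 1.5, 1.6, 2.5]))
        assert curve.counts.to_dict() == {0: 1, 1: 2, 2: 1}
        assert curve.peak_class == 1

    def test_geometric_sample_peaks_at_class_zero(self):
        cfg = SyntheticConfig(n=5000, seed=9, full_recruit_age=0, ascending_catchability=())
        curve = build_catch_curve(simulate_population(cfg))
        assert curve.peak_class == 0

    def test_single_class_is_degenerate(self):
        with pytest.raises(DegenerateCurveError):
            build_catch_curve(_ds_from_ages([1.2, 1.5, 1.9]))

    def test_empty_interior_classes_kept_as_zeros(self):
        curve = build_catch_curve(_ds_from_ages([0.5, 0.6, 3.5]))
        assert curve.counts.to_dict() == {0: 2, 1: 0, 2: 0, 3: 1}


class TestDescendingLimb:
    def test_exclude_peak_recodes_from_zero(self):
        curve = CatchCurve(counts=pd.Series({0: 5, 1: 9, 2: 4, 3: 2}), peak_class=1)
        limb = select_descending_limb(curve, "exclude_peak")
        assert limb.counts.to_dict() == {0: 4, 1: 2}
        assert limb.n == 6 and limb.T == 2
        assert limb.first_included_class == 2

    def test_include_peak_keeps_modal_class(self):
        curve = CatchCurve(counts=pd.Series({0: 5, 1: 9, 2: 4, 3: 2}), peak_class=1)
        limb = select_descending_limb(curve, "include_peak")
        assert limb.counts.to_dict() == {0: 9, 1: 4, 2: 2}
        assert limb.n == 15

    def test_gap_truncates_limb(self):
        counts = pd.Series({2: 50, 3: 30, 4: 12, 5: 6, 6: 2, 7: 0, 8: 0, 9: 2, 10: 1})
        limb = select_descending_limb(CatchCurve(counts=counts, peak_class=2))
        assert list(limb.counts.index) == [0, 1, 2, 3]  # classes 3-6 only
        assert limb.n == 50

    def test_max_class_truncates(self):
        counts = pd.Series({2: 50, 3: 30, 4: 12, 5: 6, 6: 2})
        limb = select_descending_limb(CatchCurve(counts=counts, peak_class=2), max_class=4)
        assert list(limb.counts.index) == [0, 1]

    def test_too_short_limb_rejected(self):
        curve = CatchCurve(counts=pd.Series({0: 5, 1: 9, 2: 4}), peak_class=1)
        with pytest.raises(DegenerateCurveError):
            select_descending_limb(curve, "exclude_peak", max_class=2)


class TestChapmanRobson:
    def test_hand_evaluated_small_instance(self):
        # counts {0:4, 1:2, 2:1}: n=7, T=4 -> S = 4/10; corrected
        # Z = -ln(0.4) - (6*5)/(7*5*10) = 0.91629 - 0.08571 = 0.83058
        res = chapman_robson(_limb_from_counts({0: 4, 1: 2, 2: 1}))
        assert res.S_hat == pytest.approx(0.4)
        assert res.Z == pytest.approx(0.83058, abs=5e-6)
        uncorr = chapman_robson(_limb_from_counts({0: 4, 1: 2, 2: 1}), corrected=False)
        assert uncorr.Z == pytest.approx(-math.log(0.4), abs=1e-12)

    def test_bias_correction_always_shrinks_z(self):
        for counts in ({0: 4, 1: 2, 2: 1}, {0: 40, 1: 25, 2: 12, 3: 3}, {0: 3, 1: 3}):
            limb = _limb_from_counts(counts)
            assert chapman_robson(limb).Z < chapman_robson(limb, corrected=False).Z

    def test_survival_estimate_close_to_geometric_mle_at_large_n(self):
        # S_hat = T/(n+T-1) and the MLE T/(n+T) agree asymptotically
        rng = np.random.default_rng(10)
        x = rng.geometric(1 - math.exp(-0.9), size=5000) - 1
        limb = _limb_from_counts(pd.Series(x).value_counts().to_dict())
        grid = np.linspace(1e-4, 1 - 1e-4, 20000)
        loglik = limb.n * np.log(1 - grid) + limb.T * np.log(grid)
        s_mle = grid[np.argmax(loglik)]
        assert s_mle == pytest.approx(limb.T / (limb.n + limb.T), abs=1e-4)
        assert chapman_robson(limb).S_hat == pytest.approx(s_mle, abs=1e-4)

    def test_small_sample_mle_is_t_over_n_plus_t(self):
        # exact small-sample relationship: the grid MLE maximises at T/(n+T),
        # one fish-equivalent away from the unbiased Chapman-Robson T/(n+T-1)
        limb = _limb_from_counts({0: 4, 1: 2, 2: 1})
        grid = np.linspace(1e-6, 1 - 1e-6, 2_000_000)
        loglik = limb.n * np.log(1 - grid) + limb.T * np.log(grid)
        s_mle = grid[np.argmax(loglik)]
        assert s_mle == pytest.approx(limb.T / (limb.n + limb.T), abs=1e-5)
        assert limb.T / (limb.n + limb.T) != pytest.approx(chapman_robson(limb).S_hat, abs=1e-3)

    def test_recovers_generator_mortality(self):
        cfg = SyntheticConfig(
            n=100_000, seed=12, Z_true=0.9, t_max=25, full_recruit_age=0, ascending_catchability=()
        )
        ds = simulate_population(cfg)
        curve = build_catch_curve(ds)
        limb = select_descending_limb(curve, "include_peak")
        assert chapman_robson(limb).Z == pytest.approx(0.9, abs=0.01)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DegenerateCurveError):
            chapman_robson(_limb_from_counts({0: 10, 1: 0}))


class TestRatesAndPartition:
    @pytest.mark.parametrize(
        "R,expected", [(0.0, 0.0), (math.log(2), 0.5), (0.924, 0.603)]
    )
    def test_annual_rate_values(self, R, expected):
        assert annual_rate(R) == pytest.approx(expected, abs=5e-4)

    def test_annual_rate_monotone_into_unit_interval(self):
        R = np.linspace(0, 20, 500)
        A = annual_rate(R)
        assert np.all(np.diff(A) > 0)
        assert A[0] == 0.0 and A[-1] < 1.0

    def test_annual_rate_rejects_negative(self):
        with pytest.raises(ValueError):
            annual_rate(-0.1)

    @pytest.mark.parametrize("t_max,expected", [(5.109, 1.0), (11, 0.4645), (10, 0.5109)])
    def test_longevity_mortality(self, t_max, expected):
        assert natural_mortality_tmax(t_max) == pytest.approx(expected, abs=5e-5)

    def test_longevity_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            natural_mortality_tmax(0)

    def test_partition_when_f_equals_m(self):
        p = partition_mortality(0.8, 0.4)
        assert p.F == pytest.approx(0.4)
        assert p.E == pytest.approx(0.5)

    def test_partition_zero_fishing(self):
        p = partition_mortality(0.5, 0.5)
        assert p.F == 0.0 and p.E == 0.0

    def test_partition_published_chain(self):
        p = partition_mortality(0.924, 5.109 / 11)
        assert p.F == pytest.approx(0.460, abs=5e-4)
        assert p.A_M == pytest.approx(0.372, abs=5e-4)
        assert p.E == pytest.approx(0.497, abs=5e-4)

    def test_m_exceeding_z_floors_f_with_warning(self):
        with pytest.warns(UserWarning, match="floored"):
            p = partition_mortality(0.3, 0.5)
        assert p.F == 0.0 and p.F_floored and p.E == 0.0

    def test_annual_ordering_follows_instantaneous(self):
        assert annual_rate(0.9) >= annual_rate(0.4)
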