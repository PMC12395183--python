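import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ecostoich import (
    community_resorption, control_strategy, nure, resorbed_np,
    simulate_power_law,
)
from ecostoich.community_traits import CommunitySample
from ecostoich.io_tables import POOLED_TOKEN
from ecostoich.resorption import (
    InsufficientDataError, JOINT, NUTRIENT_LIMITATION, STOICHIOMETRIC,
)


class TestNure:
    @pytest.mark.parametrize("green,senesced,mlcf,expected", [
        (20.0, 10.0, 0.762, 61.9),
        (20.0, 20.0, 0.762, 23.8),  # ratio 1 forces (1 - MLCF) * 100
        (20.0, 0.0, 0.762, 100.0),
    ])
    def test_hand_computed(self, green, senesced, mlcf, expected):
        assert nure(green, senesced, mlcf) == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_green_rejected(self):
        with pytest.raises(ValueError):
            nure(0.0, 1.0)

    @given(g=st.floats(0.1, 100), s=st.floats(0.0, 100),
           m=st.floats(0.01, 1.0))
    @settings(deadline=None)
    def test_decreasing_in_senesced_and_mlcf(self, g, s, m):
        assert nure(g, s + 0.1, m) < nure(g, s, m)
        assert nure(g, s, m) <= nure(g, s, m * 0.9) if s > 0 else True
        assert nure(g, s, 1.0) == pytest.approx((1 - s / g) * 100, rel=1e-9)


class TestResorbedNP:
    def test_simple_difference_ratio_with_unit_mlcf(self):
        assert resorbed_np(20, 2, 10, 1, mlcf=1.0) == pytest.approx(10.0, rel=1e-12)

    def test_hand_computed_with_default_mlcf(self):
        # (20 - 7.62) / (2 - 0.762) = 12.38 / 1.238
        assert resorbed_np(20, 2, 10, 1, mlcf=0.762) == pytest.approx(10.0, rel=1e-10)

    def test_phosphorus_accretion_is_undefined(self):
        assert math.isnan(resorbed_np(20, 2, 10, 3, mlcf=0.762))

    @given(ltn=st.floats(5, 50), ltp=st.floats(0.5, 5),
           fn=st.floats(0.05, 0.9), fp=st.floats(0.05, 0.9),
           k=st.floats(0.1, 10))
    @settings(deadline=None)
    def test_scale_invariance(self, ltn, ltp, fn, fp, k):
        """Multiplying all four concentrations by k > 0 leaves the ratio fixed."""
        v = resorbed_np(ltn, ltp, ltn * fn, ltp * fp)
        vk = resorbed_np(ltn * k, ltp * k, ltn * fn * k, ltp * fp * k)
        assert vk == pytest.approx(v, rel=1e-9)


def _green(plot_id="P1", ltn=20.0, ltp=2.0):
    return CommunitySample(
        plot_id=plot_id, LTC=440.0, LTN=ltn, LTP=ltp,
        ratio_CN=440 / ltn, ratio_CP=440 / ltp, ratio_NP=ltn / ltp,
        shannon=1.0, pielou=0.9, richness=3, total_biomass=100.0)


class TestCommunityResorption:
    def test_pooled_litter(self):
        litter = pd.DataFrame([{"plot_id": "P1", "species": POOLED_TOKEN,
                                "senesced_N": 5.0, "senesced_P": 0.5}])
        res = community_resorption(_green(), litter, mlcf=0.762)
        assert res.NRE == pytest.approx(80.95, abs=0.005)

    def test_biomass_weighted_species_litter(self):
        litter = pd.DataFrame([
            {"plot_id": "P1", "species": "a", "senesced_N": 5.0, "senesced_P": 0.4},
            {"plot_id": "P1", "species": "b", "senesced_N": 5.0, "senesced_P": 0.6},
        ])
        res = community_resorption(
            _green(), litter, mlcf=0.762, pooling="weighted",
            biomass_shares={"a": 2.0, "b": 2.0})
        # equal-biomass mean senesced P = 0.5 -> PRE = (1 - 0.762 * 0.25) * 100
        assert res.PRE == pytest.approx((1 - 0.762 * 0.25) * 100, rel=1e-10)

    def test_litter_identical_to_green(self):
        litter = pd.DataFrame([{"plot_id": "P1", "species": POOLED_TOKEN,
                                "senesced_N": 20.0, "senesced_P": 2.0}])
        res = community_resorption(_green(), litter, mlcf=0.762)
        assert res.NRE == pytest.approx(23.8, rel=1e-10)
        assert res.PRE == pytest.approx(23.8, rel=1e-10)
        assert res.ratio_NRE_PRE == pytest.approx(1.0, rel=1e-10)

    def test_unknown_litter_species_falls_back_unweighted(self, caplog):
        litter = pd.DataFrame([
            {"plot_id": "P1", "species": "mystery", "senesced_N": 5.0,
             "senesced_P": 0.5}])
        with caplog.at_level("WARNING"):
            res = community_resorption(_green(), litter, pooling="weighted",
                                       biomass_shares={"a": 1.0})
        assert "unweighted-litter-mean" in res.flags
        assert "mystery" in caplog.text


class TestControlStrategy:
    def test_exact_proportionality_recovers_unit_slopes(self):
        x = np.linspace(10, 20, 10)
        res = control_strategy(x, x)
        assert res.lambda_hat == pytest.approx(1.0, abs=1e-10)
        assert res.linear_slope == pytest.approx(1.0, abs=1e-10)
        assert res.omega == pytest.approx(1.0, rel=1e-9)
        assert res.label == STOICHIOMETRIC

    def test_known_exponent_detected_as_nutrient_limitation(self):
        x, y = simulate_power_law(0.5, 1.0, 60, 0.05, rng=7)
        res = control_strategy(x, y)
        assert 0.45 <= res.lambda_hat <= 0.55
        assert res.lambda_CI[1] < 1.0
        assert res.label == NUTRIENT_LIMITATION

    def test_joint_regulation_when_only_linear_slope_deviates(self):
        # curvature strong enough to pull the linear slope off 1 while the
        # log-log exponent CI still straddles 1 is rare; construct directly
        rng = np.random.default_rng(3)
        x = np.exp(rng.uniform(np.log(5), np.log(40), 200))
        y = 3.0 + 0.55 * x  # affine, not power law
        res = control_strategy(x, y)
        assert res.linear_slope_CI[1] < 1.0
        if res.lambda_CI[0] <= 1.0 <= res.lambda_CI[1]:
            assert res.label == JOINT

    def test_nonpositive_points_excluded_and_counted(self):
        x = np.array([10.0, 12, 14, 16, 18, 20])
        y = x.copy()
        y[2] = -1.0
        res = control_strategy(x, y)
        assert res.n_used == 5 and res.n_excluded == 1

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            control_strategy([10, 20], [10, 20])

    def test_ci_contains_point_estimate(self):
        x, y = simulate_power_law(0.912, 1.25, 24, 0.1, rng=11)
        res = control_strategy(x, y)
        assert res.lambda_CI[0] <= res.lambda_hat <= res.lambda_CI[1]
        assert res.linear_slope_CI[0] <= res.linear_slope <= res.linear_slope_CI[1]
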