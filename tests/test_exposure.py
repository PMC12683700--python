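import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stressorweave.core_data import StudyFrame
from stressorweave.exposure import (annualize_and_standardize,
                                    backcast_entanglement_scalars, backcast_prey,
                                    entanglement_probability,
                                    extrapolate_canadian_entanglement,
                                    individual_prey_index,
                                    individual_strike_probability,
                                    regional_strike_probability)


class TestEntanglementProbability:
    def test_zero_risk_region(self):
        assert entanglement_probability([1.0, 0.0], [0.0, 0.9], [1, 1], 0.5) == 0.0

    def test_hand_arithmetic(self):
        p = entanglement_probability([0.5, 0.5], [0.2, 0.4], [1.0, 1.0], 0.1)
        assert p == pytest.approx(0.03, abs=1e-15)

    def test_linear_in_backcast_scalar(self, rng):
        z = rng.dirichlet([1, 1, 1])
        G = rng.random(3)
        e = rng.random(3) + 0.1
        assert entanglement_probability(z, G, 2 * e, 0.05) == pytest.approx(
            2 * entanglement_probability(z, G, e, 0.05))

    def test_rejects_probability_above_one(self):
        with pytest.raises(ValueError, match="> 1"):
            entanglement_probability([1.0], [1.0], [3.0], 0.5)


class TestStrikeProbability:
    def test_reference_year_identity(self):
        ais = np.array([0.1, 0.5, 1.0 - 1e-9])
        p = regional_strike_probability(ais, 0.3, 0.7, 2019)
        np.testing.assert_allclose(p, 0.3 * ais, rtol=1e-9)

    def test_logit_trend_oracle(self):
        p = regional_strike_probability(np.array([0.5]), 0.2, 0.05, 1999)
        assert p[0] == pytest.approx(0.231969316684074, abs=1e-9)

    def test_zero_trend_constant_over_years(self):
        ais = np.array([0.2, 0.6])
        for year in (1970, 1990, 2019):
            np.testing.assert_allclose(
                regional_strike_probability(ais, 0.1, 0.0, year), 0.1 * ais)

    def test_zero_ais_maps_to_zero(self):
        p = regional_strike_probability(np.array([0.0, 0.4]), 0.2, -0.1, 1980)
        assert p[0] == 0.0

    def test_saturated_logit_rejected(self):
        with pytest.raises(ValueError, match="logit"):
            regional_strike_probability(np.array([1.0]), 1.0, 0.0, 2000)

    def test_individual_strike_weighting(self):
        assert individual_strike_probability([1.0, 0.0], [0.7, 0.1]) == 0.7
        assert individual_strike_probability([0.5, 0.5], [0.02, 0.04]) == pytest.approx(0.03)
        z = np.random.default_rng(0).dirichlet(np.ones(5))
        assert individual_strike_probability(z, np.full(5, 0.3)) == pytest.approx(0.3)


class TestPreyIndex:
    def test_degenerate_occupancy(self):
        assert individual_prey_index([1.0, 0.0], [3.2, 9.9]) == pytest.approx(3.2)

    def test_standardisation_oracle(self):
        frame = StudyFrame(regions=("A", "B"), start_year=2000, end_year=2002,
                           era_break_year=2002)
        steps = np.repeat([1.0, 2.0, 3.0], 4)  # annual means 1, 2, 3
        std, (mean, sd) = annualize_and_standardize(steps, frame)
        assert (mean, sd) == (2.0, 1.0)  # sample SD over annual means
        np.testing.assert_allclose(std, [-1.0, 0.0, 1.0])

    def test_degenerate_sd_rejected(self):
        frame = StudyFrame(regions=("A", "B"), start_year=2000, end_year=2001,
                           era_break_year=2001)
        with pytest.raises(ValueError, match="SD"):
            annualize_and_standardize(np.ones(frame.T), frame)


class TestBackcasts:
    def test_entanglement_scalar_baseline_is_one(self, small_frame):
        landings = {"trap": {y: 100.0 for y in range(1990, 2016)}}
        landings["trap"][2000] = 50.0
        e = backcast_entanglement_scalars(
            landings, {r: "trap" for r in small_frame.regions},
            baseline_years=(2010, 2015), frame=small_frame)
        t_base = small_frame.step(2003, 0)
        assert e[0, t_base] == pytest.approx(1.0)
        assert e[0, small_frame.step(2000, 0)] == pytest.approx(0.5)

    def test_constant_landings_give_unit_scalars(self, small_frame):
        landings = {"trap": {y: 70.0 for y in range(1990, 2020)}}
        e = backcast_entanglement_scalars(
            landings, {r: "trap" for r in small_frame.regions},
            baseline_years=(2000, 2004), frame=small_frame)
        np.testing.assert_allclose(e, 1.0)

    def test_canadian_extrapolation_ratios(self, small_frame):
        G = np.ones((3, small_frame.T))
        G[2] = 0.0  # the 'Canadian' region starts empty
        years = range(small_frame.start_year, small_frame.end_year + 1)
        out = extrapolate_canadian_entanglement(
            G, small_frame, {"NORTH": {y: 10.0 for y in years}},
            {y: 100.0 for y in years}, ["NORTH"], ["SOUTH", "MID"])
        np.testing.assert_allclose(out[2], 0.1 * 2.0)  # 10% of summed US risk
        out_eq = extrapolate_canadian_entanglement(
            G, small_frame, {"NORTH": {y: 100.0 for y in years}},
            {y: 100.0 for y in years}, ["NORTH"], ["SOUTH", "MID"])
        np.testing.assert_allclose(out_eq[2], 2.0)
        out_zero = extrapolate_canadian_entanglement(
            G, small_frame, {"NORTH": {y: 0.0 for y in years}},
            {y: 100.0 for y in years}, ["NORTH"], ["SOUTH", "MID"])
        np.testing.assert_allclose(out_zero[2], 0.0)

    def test_prey_backcast_exact_on_noiseless_data(self):
        years = np.arange(1999, 2020)
        anomalies = {int(y): np.sin(y / 3.0) for y in range(1970, 2020)}
        index = np.exp(1.0 + 0.5 * np.array([anomalies[int(y)] for y in years]))
        preds, fit = backcast_prey(years, index, anomalies, np.arange(1970, 1999))
        assert fit["intercept"] == pytest.approx(1.0, abs=1e-6)
        assert fit["slope"] == pytest.approx(0.5, abs=1e-6)
        assert fit["r2"] == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(
            preds, np.exp(1.0 + 0.5 * np.array([anomalies[int(y)]
                                                for y in range(1970, 1999)])),
            rtol=1e-6)

    def test_prediction_at_mean_anomaly_equals_fitted_geometric_level(self):
        years = np.arange(1999, 2010)
        rng = np.random.default_rng(1)
        anomalies = {int(y): float(a) for y, a in zip(years, rng.normal(size=len(years)))}
        overlap_mean = np.mean([anomalies[int(y)] for y in years])
        anomalies[1990] = overlap_mean
        index = np.exp(0.3 - 0.8 * np.array([anomalies[int(y)] for y in years]))
        preds, fit = backcast_prey(years, index, anomalies, np.array([1990]))
        assert preds[0] == pytest.approx(
            np.exp(fit["intercept"] + fit["slope"] * overlap_mean))

    def test_constant_anomaly_unidentifiable(self):
        years = np.arange(1999, 2010)
        anomalies = {int(y): 0.5 for y in years}
        with pytest.raises(ValueError, match="constant"):
            backcast_prey(years, np.ones(len(years)) + 1, anomalies, np.array([]))

    def test_nonpositive_index_rejected(self):
        years = np.arange(1999, 2010)
        anomalies = {int(y): float(y) for y in years}
        with pytest.raises(ValueError, match="positive"):
            backcast_prey(years, np.zeros(len(years)), anomalies, np.array([]))


@settings(deadline=None, max_examples=100, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_weighted_quantities_are_convex_combinations(seed):
    rng = np.random.default_rng(seed)
    R = int(rng.integers(2, 8))
    z = rng.dirichlet(np.ones(R) * rng.uniform(0.2, 3))
    p_r = rng.uniform(0, 1, R)
    prey = rng.uniform(0, 5, R)
    assert p_r.min() - 1e-12 <= individual_strike_probability(z, p_r) <= p_r.max() + 1e-12
    assert prey.min() - 1e-12 <= individual_prey_index(z, prey) <= prey.max() + 1e-12


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_entanglement_probability_monotone_in_risk(seed):
    rng = np.random.default_rng(seed)
    z = rng.dirichlet(np.ones(3))
    G = rng.uniform(0, 1, 3)
    e = rng.uniform(0, 2, 3)
    base = entanglement_probability(z, G, e, 0.1)
    G2 = np.minimum(G + rng.uniform(0, 1 - G), 1.0)
    assert entanglement_probability(z, G2, e, 0.1) >= base - 1e-15
    assert entanglement_probability(z, G, e * 1.5, 0.1) >= base - 1e-15
    assert entanglement_probability(z, G, e, 0.12) >= base - 1e-15
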