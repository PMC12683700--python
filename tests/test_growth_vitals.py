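import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stressorweave.core_data import IndividualRecord, StudyFrame
from stressorweave.growth import (GrowthParameters, asymptote_predictor,
                                  expected_length, growth_covariate_windows)
from stressorweave.vital_rates import (VitalRateParameters, annual_hazard,
                                       calving_probability, demographic_transition,
                                       hazard_rate, is_available,
                                       survival_probability)


class TestGrowthCurve:
    def test_intercept_at_age_zero(self):
        assert expected_length(0.0, 14.0, 0.3, 4.5) == pytest.approx(4.5)

    def test_asymptote_at_large_age(self):
        assert expected_length(80.0, 14.0, 0.3, 4.5) == pytest.approx(14.0, abs=1e-6)

    def test_curve_value_oracle(self):
        assert expected_length(5.0, 14.0, 0.3, 4.0) == pytest.approx(11.768698, abs=1e-5)

    def test_monotone_in_age(self, rng):
        for _ in range(50):
            A = rng.uniform(10, 16)
            k = rng.uniform(0.05, 1.0)
            ages = np.sort(rng.uniform(0, 40, 10))
            L = expected_length(ages, A, k, 4.5)
            assert np.all(np.diff(L) >= -1e-12)


class TestAsymptotePredictor:
    def test_reference_covariates_give_intercept(self):
        p = GrowthParameters(A0=13.5, birth_year_trend=0.0)
        assert asymptote_predictor({}, p, 1990) == 13.5

    def test_covariate_sum(self):
        p = GrowthParameters(A0=13.5, beta_A={"prey": 0.3, "ent": -0.5, "prey_ent": 0.1})
        assert asymptote_predictor({"prey": 1.0, "ent": 1.0, "prey_ent": 1.0},
                                   p, p.birth_year_ref) == pytest.approx(13.5 - 0.1)

    def test_birth_year_trend_linearity(self):
        p = GrowthParameters(A0=13.5, birth_year_trend=-0.02)
        a = asymptote_predictor({}, p, 1990)
        b = asymptote_predictor({}, p, 2000)
        assert a - b == pytest.approx(0.2)

    def test_unknown_covariate_fails_closed(self):
        with pytest.raises(KeyError):
            asymptote_predictor({"typo": 1.0}, GrowthParameters(), 1990)


class TestCovariateWindows:
    def test_never_entangled(self):
        out = growth_covariate_windows(np.full(8, 80.0), np.zeros(8), np.zeros(8), 2)
        assert out["mean_entanglement"] == 0.0
        assert out["coverage"] == 1.0

    def test_entangled_half_of_first_two_years(self):
        gear = np.array([1, 1, 1, 1, 0, 0, 0, 0], dtype=float)
        out = growth_covariate_windows(np.full(8, 80.0), np.zeros(8), gear, 2)
        assert out["mean_entanglement"] == 0.5

    def test_window_longer_than_life_flags_coverage(self):
        out = growth_covariate_windows(np.full(6, 80.0), np.zeros(6), np.zeros(6), 5)
        assert out["coverage"] == pytest.approx(6 / 20)


class TestSurvival:
    def test_hazard_probability_identity(self, rng):
        p = VitalRateParameters(a_s=-1.2, b_s=0.04)
        h = rng.uniform(1, 100, 200)
        np.testing.assert_allclose(np.exp(-hazard_rate(h, p)),
                                   survival_probability(h, p), rtol=0, atol=1e-12)

    def test_value_oracle(self):
        p = VitalRateParameters(a_s=0.0, b_s=0.05)
        assert hazard_rate(100.0, p) == pytest.approx(np.exp(-5), rel=1e-12)
        assert survival_probability(100.0, p) == pytest.approx(0.993285, abs=1e-6)

    def test_monotone_in_health(self, rng):
        p = VitalRateParameters(a_s=-1.0, b_s=0.03)
        h = np.sort(rng.uniform(1, 100, 100))
        s = survival_probability(h, p)
        assert np.all(np.diff(s) >= 0)

    def test_null_slope_constant(self):
        p = VitalRateParameters(a_s=-2.0, b_s=0.0)
        np.testing.assert_allclose(survival_probability(np.array([10.0, 90.0]), p),
                                   survival_probability(np.array([50.0, 50.0]), p))

    def test_annual_hazard_sums_quarters(self):
        p = VitalRateParameters(a_s=-1.5, b_s=0.05)
        h = np.array([80.0, 75.0, 70.0, 85.0])
        assert annual_hazard(h, p) == pytest.approx(float(hazard_rate(h, p).sum()))

    def test_nonadditivity_of_simultaneous_insults(self):
        # additive health insults are non-additive on the survival scale:
        # frozen worked instance (a_s = -1.5, b_s = 0.05, h = 80, insults 10 & 15)
        p = VitalRateParameters(a_s=-1.5, b_s=0.05)
        theta = lambda h: float(survival_probability(h, p))
        joint = theta(80.0) - theta(80.0 - 10 - 15)
        separate = (theta(80.0) - theta(70.0)) + (theta(80.0) - theta(65.0))
        assert joint - separate == pytest.approx(0.002911738757133575, abs=1e-12)
        assert joint > separate


class TestCalving:
    def test_unavailable_year_gives_zero(self):
        p = VitalRateParameters()
        assert calving_probability(80.0, 13.5, False, p) == 0.0

    def test_intercept_oracle(self):
        p = VitalRateParameters(c0=-1.5, c1=0.04, c2=0.8)
        assert calving_probability(p.h_ref, p.L_ref, True, p) == pytest.approx(
            0.18242552, abs=1e-7)

    def test_length_linearity_on_logit_scale(self):
        from scipy.special import logit
        p = VitalRateParameters(c0=-1.0, c1=0.0, c2=0.5)
        d = (logit(calving_probability(p.h_ref, p.L_ref + 1.0, True, p))
             - logit(calving_probability(p.h_ref, p.L_ref, True, p)))
        assert d == pytest.approx(0.5, abs=1e-9)

    def test_availability_rule(self):
        frame = StudyFrame(regions=("A", "B"), start_year=1990, end_year=2010,
                           era_break_year=2005)
        p = VitalRateParameters(min_calving_interval=2, maturity_age=9)
        rec = IndividualRecord(id="w", sex="F", birth_year=1990, first_step=0,
                               last_step=frame.T - 1, calving_years=[2003])
        assert not is_available(rec, 2004, frame, p)   # resting
        assert not is_available(rec, 2005, frame, p)   # still inside interval
        assert is_available(rec, 2006, frame, p)
        young = IndividualRecord(id="y", sex="F", birth_year=1998, first_step=0,
                                 last_step=frame.T - 1)
        assert not is_available(young, 2005, frame, p)  # age 7 < maturity
        assert is_available(young, 2008, frame, p)      # age 10, never calved
        male = IndividualRecord(id="m", sex="M", birth_year=1990, first_step=0,
                                last_step=frame.T - 1)
        assert not is_available(male, 2005, frame, p)


class TestDemographicTransition:
    def test_calf_becomes_juvenile_at_age_one(self):
        assert demographic_transition("calf", 0.75, "F", True) == "juvenile"
        assert demographic_transition("calf", 0.5, "F", True) == "calf"

    def test_death_absorbing(self):
        assert demographic_transition("dead", 5.0, "M", True) == "dead"
        assert demographic_transition("juvenile", 5.0, "M", False) == "dead"

    def test_maturity(self):
        assert demographic_transition("juvenile", 8.75, "F", True) == "adult female"
        assert demographic_transition("juvenile", 8.0, "M", True) == "juvenile"


@settings(deadline=None, max_examples=100, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_hazard_consistency_property(seed):
    rng = np.random.default_rng(seed)
    p = VitalRateParameters(a_s=float(rng.uniform(-4, 0)), b_s=float(rng.uniform(0, 0.2)))
    h = rng.uniform(0.5, 100, 20)
    assert np.allclose(np.exp(-hazard_rate(h, p)), survival_probability(h, p),
                       atol=1e-12, rtol=0)
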