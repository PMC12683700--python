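import numpy as np
import pytest

from stressorweave import ObservationSet
from stressorweave import health as health_mod
from stressorweave import observation as obs_mod
from stressorweave.health import HealthParameters
from stressorweave.inference import (GibbsSampler, ModelSpec, build_joint_model,
                                     default_params, run_mcmc,
                                     summarize_interactions, summarize_parameters)


@pytest.fixture(scope="module")
def joint_model(default_dataset):
    spec = ModelSpec(formulation="v1", hypothesis="health:gear_prey")
    return build_joint_model(spec, default_dataset["records"],
                             default_dataset["observations"],
                             default_dataset["surfaces"],
                             default_dataset["config"].frame)


class TestModelSpecValidation:
    def test_exposure_hypothesis_requires_spatial_formulation(self):
        with pytest.raises(ValueError, match="spatial"):
            ModelSpec(formulation="v3", hypothesis="exposure:prey_ent_risk")
        ModelSpec(formulation="v1", hypothesis="exposure:prey_ent_risk")

    def test_prolonged_health_length_hypothesis_is_nonspatial_only(self):
        with pytest.raises(ValueError, match="non-spatial"):
            ModelSpec(formulation="v1", hypothesis="length:prolonged_health_15")
        ModelSpec(formulation="v3", hypothesis="length:prolonged_health_15")

    def test_unknown_hypothesis_rejected(self):
        with pytest.raises(ValueError, match="hypothesis"):
            ModelSpec(hypothesis="health:moon_phase")


class TestJointModelComposition:
    def test_drift_design_matches_health_module(self, joint_model, default_dataset):
        """The vectorised drift design reproduces the health module's drift."""
        m = joint_model
        hp = HealthParameters(active_interaction="gear_prey", gamma_gear_prey=1.2,
                              beta_prey=2.5)
        theta = []
        for name in m.drift_names:
            if name.startswith("delta_sev_"):
                theta.append(hp.delta_sev[name.rsplit("_", 1)[1]])
            elif name.startswith("delta_inj_"):
                theta.append(hp.delta_inj[name.rsplit("_", 1)[1]])
            elif name == "delta_transition":
                theta.append(hp.delta_transition)
            elif name == "delta_lactation":
                theta.append(hp.delta_lactation)
            elif name == "delta_gear":
                theta.append(hp.delta_gear)
            elif name == "beta_prey":
                theta.append(hp.beta_prey)
            elif name == "gamma_gear_prey":
                theta.append(hp.gamma_gear_prey)
        theta = np.array(theta)
        D = m.X @ theta
        checked = 0
        for i, rec in enumerate(m.records):
            if not rec.entanglements or rec.birth_year is None:
                continue
            d_ref = health_mod.health_drift(rec, m.frame, m.prey_std[i], hp,
                                            m.t0[i], m.t1[i])
            np.testing.assert_allclose(D[i, m.t0[i] + 1:m.t1[i] + 1], d_ref,
                                       atol=1e-10)
            checked += 1
            if checked >= 5:
                break
        assert checked >= 3

    def test_vha_component_matches_observation_module(self, joint_model, rng):
        m = joint_model
        h = np.clip(rng.normal(75, 10, size=(m.n, m.T)), 1, 100)
        ref = obs_mod.vha_loglik(m.vha_s, h[m.vha_i, m.vha_t], m.vha_x,
                                 m.spec.obs_params)
        assert m.loglik_vha(h) == pytest.approx(ref, rel=1e-12)

    def test_health_component_matches_truncated_normal_oracle(self, joint_model, rng):
        from scipy.stats import truncnorm
        m = joint_model
        h = np.clip(rng.normal(75, 8, size=(m.n, m.T)), 1, 100)
        theta = rng.normal(0, 1, size=len(m.drift_names))
        sigma = 2.5
        got = m.loglik_health(h, theta, sigma)
        D = m.X @ theta
        total = 0.0
        for i in range(m.n):
            for t in range(m.t0[i] + 1, m.t1[i] + 1):
                mu = h[i, t - 1] + D[i, t]
                a, b = (m.spec.floor - mu) / sigma, (m.spec.ceiling - mu) / sigma
                total += truncnorm.logpdf(h[i, t], a, b, loc=mu, scale=sigma)
            h0 = h[i, m.t0[i]]
            total += (-0.5 * ((h0 - m.spec.h0_mean) / m.spec.h0_sd) ** 2
                      - np.log(m.spec.h0_sd) - 0.5 * np.log(2 * np.pi))
        assert got == pytest.approx(total, rel=1e-9)

    def test_empty_data_posterior_equals_prior(self, default_dataset):
        frame = default_dataset["config"].frame
        model = build_joint_model(ModelSpec(formulation="v3", hypothesis=None),
                                  [], ObservationSet.empty(),
                                  default_dataset["surfaces"], frame)
        params = default_params(model)
        state = {p.name: p.init for p in params}
        state["h"] = np.zeros((0, frame.T))
        state["A"] = np.zeros(0)
        lp = model.log_posterior(state, priors=params)
        assert lp == pytest.approx(sum(p.log_prior(state[p.name]) for p in params))

    def test_v1_and_v2_exposure_covariates_agree(self, default_dataset):
        d = default_dataset
        frame = d["config"].frame
        m1 = build_joint_model(ModelSpec(formulation="v1"), d["records"],
                               d["observations"], d["surfaces"], frame)
        m2 = build_joint_model(ModelSpec(formulation="v2"), d["records"],
                               d["observations"], d["surfaces"], frame)
        a, b = m1.base_ent[m1.mask], m2.base_ent[m2.mask]
        assert np.corrcoef(a, b)[0, 1] > 0.8


class TestSampler:
    def test_same_seed_reproduces_draws(self, joint_model):
        d1 = GibbsSampler(joint_model, seed=42).run(12, 4)
        d2 = GibbsSampler(joint_model, seed=42).run(12, 4)
        for k in d1:
            np.testing.assert_array_equal(d1[k], d2[k])

    def test_run_mcmc_reports_diagnostics(self, joint_model):
        out = run_mcmc(joint_model, n_iter=16, warmup=8, chains=2, seed=1)
        assert out["draws"]["b_s"].shape == (2, 8)
        assert "rhat" in out["meta"]
        assert isinstance(out["meta"]["converged"], (bool, np.bool_))

    def test_posterior_invariant_to_record_order(self, default_dataset):
        d = default_dataset
        frame = d["config"].frame
        spec = ModelSpec(formulation="v1", hypothesis="health:gear_prey")
        m_fwd = build_joint_model(spec, d["records"], d["observations"],
                                  d["surfaces"], frame)
        m_rev = build_joint_model(spec, list(reversed(d["records"])),
                                  d["observations"], d["surfaces"], frame)
        s1, s2 = GibbsSampler(m_fwd, seed=0), GibbsSampler(m_rev, seed=0)
        t1 = np.array([s1.state[p.name] for p in s1.params])
        for c in ("health", "ent", "strike", "surv"):
            assert s1._component(c) == pytest.approx(s2._component(c), rel=1e-9)


class TestSummaries:
    def test_quantile_oracle(self, rng):
        draws = {"x": rng.normal(0.5, 0.1, size=4000)}
        table = summarize_parameters(draws)
        row = table.iloc[0]
        assert row["ci_low"] == pytest.approx(0.304, abs=0.02)
        assert row["ci_high"] == pytest.approx(0.696, abs=0.02)
        assert not row["ci_overlaps_zero"]
        assert row["sign"] == 1

    def test_symmetric_draws_overlap_zero(self, rng):
        draws = {"x": rng.normal(0.0, 1.0, size=2000)}
        row = summarize_parameters(draws).iloc[0]
        assert abs(row["median"]) < 0.1
        assert row["ci_overlaps_zero"]

    def test_interaction_table_lists_active_hypothesis(self, joint_model):
        out = {"draws": {"gamma_gear_prey": np.random.default_rng(0).normal(
            1.0, 0.1, 100)}}
        table = summarize_interactions(out, joint_model)
        assert list(table["parameter"]) == ["gamma_gear_prey"]
        assert table.iloc[0]["hypothesis"] == "health:gear_prey"
        assert not table.iloc[0]["ci_overlaps_zero"]
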