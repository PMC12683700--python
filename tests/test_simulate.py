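import numpy as np
import pytest

from stressorweave.core_data import StudyFrame, read_individuals, read_surfaces, write_surfaces
from stressorweave.exposure import ExposureParameters
from stressorweave.simulate import (SimulationConfig, generate_dataset,
                                    generate_observations, generate_population,
                                    generate_surfaces, write_dataset)
from stressorweave.vital_rates import VitalRateParameters


class TestSurfaces:
    def test_seeded_rerun_is_bit_identical(self):
        cfg = SimulationConfig()
        a = generate_surfaces(cfg.frame, cfg, seed=9)
        b = generate_surfaces(cfg.frame, cfg, seed=9)
        for var in ("G", "ent_scalar", "ais", "prey", "dsm"):
            np.testing.assert_array_equal(a.array(var), b.array(var))

    def test_zero_regime_shift_equalises_prey_eras(self):
        frame = StudyFrame(regions=("A", "B", "C"), start_year=1995, end_year=2044,
                           era_break_year=2020)
        cfg = SimulationConfig(frame=frame, prey_regime_shift=0.0, prey_noise_sd=0.2)
        means = []
        for seed in range(10):
            s = generate_surfaces(frame, cfg, seed=seed)
            years = frame.year_of_step(np.arange(frame.T))
            means.append([s.prey[:, years < 2020].mean(), s.prey[:, years >= 2020].mean()])
        means = np.array(means)
        # pre/post means equal in expectation within Monte-Carlo tolerance
        assert abs(means[:, 0].mean() - means[:, 1].mean()) < 0.05 * means.mean()

    def test_configured_traffic_trend_recovered_by_regression(self):
        frame = StudyFrame(regions=("A", "B", "C"), start_year=1970, end_year=2019,
                           era_break_year=2010)
        cfg = SimulationConfig(frame=frame, traffic_trend=0.02)
        s = generate_surfaces(frame, cfg, seed=4)
        years = frame.year_of_step(np.arange(frame.T)).astype(float)
        slope = np.polyfit(years, np.log(s.ais.mean(axis=0) + 1e-12), 1)[0]
        assert slope == pytest.approx(0.02, abs=0.004)


class TestPopulation:
    def test_frozen_dynamics(self):
        cfg = SimulationConfig(
            exposure=ExposureParameters(iota1=0.0, iota2=0.0, v_trend=0.0),
            vitals=VitalRateParameters(a_s=-40.0, b_s=0.0, c0=-40.0))
        surfaces = generate_surfaces(cfg.frame, cfg, seed=1)
        truth = generate_population(cfg.frame, surfaces, cfg, seed=2)
        assert len(truth.records) == cfg.n_initial
        assert all(r.death_step is None for r in truth.records)
        assert all(not r.entanglements and not r.strikes for r in truth.records)
        assert all(not r.calving_years for r in truth.records)

    def test_doubling_iota1_doubles_event_rate(self):
        """Realized event counts match the simulator's own Poisson-binomial
        expectation, and the per-step event rate doubles with iota1."""
        from stressorweave.core_data import rescale_unit
        rates = []
        for iota1 in (0.08, 0.16):
            cfg = SimulationConfig(exposure=ExposureParameters(
                iota1=iota1, iota2=0.012, v_trend=-0.02))
            observed = expected = var = steps = 0.0
            for seed in (11, 12, 13):
                surfaces = generate_surfaces(cfg.frame, cfg, seed=seed)
                truth = generate_population(cfg.frame, surfaces, cfg, seed=seed + 100)
                G01 = rescale_unit(surfaces.G)
                w = G01 * surfaces.ent_scalar
                p = iota1 * np.einsum("ntr,rt->nt", truth.z, w)
                alive = truth.alive
                observed += sum(len(r.entanglements) for r in truth.records)
                expected += p[alive].sum()
                var += (p[alive] * (1 - p[alive])).sum()
                steps += alive.sum()
            assert expected >= 200
            assert abs(observed - expected) <= 4 * np.sqrt(var)
            rates.append(observed / steps)
        assert 1.7 <= rates[1] / rates[0] <= 2.3

    def test_maternal_entanglement_lowers_calf_asymptote(self):
        # strong effect + high entanglement rate so exposed calves exist
        from stressorweave.growth import GrowthParameters
        cfg = SimulationConfig(
            exposure=ExposureParameters(iota1=0.25, iota2=0.012, v_trend=-0.02),
            growth=GrowthParameters(birth_year_trend=0.0,
                                    beta_A={"mother_entangled": -1.0}))
        exposed, unexposed = [], []
        for seed in range(6):
            surfaces = generate_surfaces(cfg.frame, cfg, seed=seed)
            truth = generate_population(cfg.frame, surfaces, cfg, seed=seed + 50)
            idx = {r.id: i for i, r in enumerate(truth.records)}
            for calf_id, mother_id in truth.mother.items():
                i = idx[calf_id]
                # reconstruct exposure flag from the mother's gear record
                mrec = truth.records[idx[mother_id]]
                rec = truth.records[i]
                birth = rec.first_step
                flag = any(e.step <= birth - k < e.step + e.gear_steps
                           for e in mrec.entanglements for k in range(0, 5))
                (exposed if flag else unexposed).append(truth.asymptote[i])
        assert len(exposed) >= 10
        diff = np.mean(exposed) - np.mean(unexposed)
        se = np.sqrt(np.var(exposed) / len(exposed) + np.var(unexposed) / len(unexposed))
        assert diff == pytest.approx(-1.0, abs=max(3 * se, 0.3))


class TestObservations:
    def test_perfect_detection_sights_every_alive_step(self):
        from stressorweave.observation import ObservationParameters
        cfg = SimulationConfig(obs=ObservationParameters(p_det=1.0, p_vha=0.0,
                                                         p_length=0.0))
        surfaces = generate_surfaces(cfg.frame, cfg, seed=1)
        truth = generate_population(cfg.frame, surfaces, cfg, seed=2)
        records, obs = generate_observations(truth, cfg.obs, seed=3)
        n_alive = int(truth.alive.sum())
        assert len(obs.sightings) == n_alive

    def test_zero_measurement_noise_returns_latent_lengths(self):
        from stressorweave.observation import ObservationParameters
        cfg = SimulationConfig(obs=ObservationParameters(
            sigma_P={"aircraft": 1e-9, "drone": 1e-9}, p_length=0.5))
        surfaces = generate_surfaces(cfg.frame, cfg, seed=1)
        truth = generate_population(cfg.frame, surfaces, cfg, seed=2)
        records, obs = generate_observations(truth, cfg.obs, seed=3)
        idx = {r.id: i for i, r in enumerate(truth.records)}
        for _, row in obs.lengths.head(50).iterrows():
            i = idx[row["id"]]
            assert row["length_m"] == pytest.approx(
                truth.length[i, int(row["t"])], abs=1e-6)

    def test_event_detection_thinning(self):
        from stressorweave.observation import ObservationParameters
        cfg = SimulationConfig(obs=ObservationParameters(p_ent_detect=0.5))
        n_true = n_obs = 0
        for seed in (21, 22, 23):
            surfaces = generate_surfaces(cfg.frame, cfg, seed=seed)
            truth = generate_population(cfg.frame, surfaces, cfg, seed=seed + 7)
            records, obs = generate_observations(truth, cfg.obs, seed=seed + 14)
            n_true += sum(len(r.entanglements) for r in truth.records)
            n_obs += len(obs.entanglements)
        assert n_true >= 100
        assert n_obs / n_true == pytest.approx(0.5, abs=3 * 0.5 / np.sqrt(n_true))


class TestEndToEnd:
    def test_written_dataset_passes_validation(self, default_dataset, tmp_path):
        write_dataset(default_dataset, tmp_path)
        frame = default_dataset["config"].frame
        surfaces = read_surfaces(tmp_path / "surfaces.csv", frame)
        records, obs = read_individuals(tmp_path, frame)
        assert surfaces.G.shape == (frame.R, frame.T)
        assert len(records) == len(default_dataset["records"])
        obs.validate_against(records)

    def test_dataset_generation_deterministic(self, default_dataset):
        again = generate_dataset(SimulationConfig(), seed=3)
        assert [r.id for r in again["records"]] == \
            [r.id for r in default_dataset["records"]]
        np.testing.assert_array_equal(again["truth"].health,
                                      default_dataset["truth"].health)
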