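"""Forward simulation of the full generative model with known truth.

The generator emulates the structure of a photo-identification database for a
long-lived, wide-ranging whale population exposed to three interacting
stressors, at a configurable desk scale (default 3 regions x 30 years x ~40
founding individuals, growing by births).  It produces:

* smooth regional stressor surfaces (entanglement risk elevated in northern
  regions, vessel traffic with a configurable temporal trend, prey with a
  post-era regime shift and inter-annual noise);
* an individual-based population: birth via the calving process, movement via
  a true Dirichlet occupancy, entanglement/strike events via the exposure
  equations, health via the bounded random walk, length via the growth curve,
  death via the health-dependent hazard;
* observation tables produced by masking the truth through detection, ordinal
  health scoring, photogrammetry, event detection and carcass recovery.

Every stochastic operation takes an explicit seed; the truth (parameters,
latent trajectories, complete event log) is kept alongside the observed
dataset so estimation code can be scored against it.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_data import (CLASSES, INJURIES, SEVERITIES,
                        EntanglementEvent, IndividualRecord, ObservationSet,
                        RegionalSurfaceSet, StrikeEvent, StudyFrame,
                        rescale_unit, write_individuals, write_surfaces)
from .exposure import (ExposureParameters, entanglement_probability,
                       individual_strike_probability, regional_strike_probability)
from .growth import GrowthParameters, expected_length, sample_asymptote
from .health import HealthParameters, health_drift
from .observation import ObservationParameters, vha_category_probs
from .vital_rates import VitalRateParameters, hazard_rate, is_available, calving_probability

DEFAULT_SIM_REGIONS = ("SEUS", "NEUS", "GSL")


def default_sim_frame() -> StudyFrame:
    return StudyFrame(regions=DEFAULT_SIM_REGIONS, start_year=1990, end_year=2019,
                      era_break_year=2010)


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic experiment (the truth)."""

    frame: StudyFrame = field(default_factory=default_sim_frame)
    n_initial: int = 40
    # surfaces
    traffic_trend: float = 0.0        # log-linear trend per year on the traffic field
    prey_regime_shift: float = 0.3    # fractional post-era prey decline in northern regions
    prey_noise_sd: float = 0.2        # lognormal inter-annual noise
    # truth parameters
    health: HealthParameters = field(default_factory=lambda: HealthParameters(
        active_interaction="gear_prey", gamma_gear_prey=1.5))
    growth: GrowthParameters = field(default_factory=lambda: GrowthParameters(
        birth_year_trend=-0.03, beta_A={"mother_entangled": -0.4}))
    vitals: VitalRateParameters = field(default_factory=VitalRateParameters)
    exposure: ExposureParameters = field(default_factory=lambda: ExposureParameters(
        iota1=0.08, iota2=0.012, v_trend=-0.02))
    obs: ObservationParameters = field(default_factory=ObservationParameters)
    # initial state / demography
    h_birth_mean: float = 80.0
    h_birth_sd: float = 5.0
    severity_probs: tuple = (0.5, 0.35, 0.15)
    injury_probs: tuple = (0.35, 0.3, 0.2, 0.15)
    mean_gear_steps: dict = field(default_factory=lambda: {
        "minor": 1.0, "moderate": 2.0, "severe": 4.0})


# ---------------------------------------------------------------------------
# surfaces

def generate_surfaces(frame: StudyFrame, config: SimulationConfig,
                      seed: int) -> RegionalSurfaceSet:
    """Seasonal regional surfaces with the configured trends and regime shift.

    Regions are treated as ordered south -> north; entanglement risk and
    summer prey are elevated in the north, vessel traffic in the south.
    """
    rng = np.random.default_rng(seed)
    R, T = frame.R, frame.T
    lat = np.linspace(0.1, 1.0, R)                       # south -> north score
    years = frame.year_of_step(np.arange(T)).astype(float)
    quarters = frame.quarter_of_step(np.arange(T))
    season = np.sin(np.pi * (quarters + 0.5) / 4.0)      # peaks mid-year

    G = np.outer(lat, 0.4 + 0.6 * season) * rng.lognormal(0.0, 0.1, size=(R, T))

    # landings-derived backcast scalar: rises toward 1 at the cutoff year
    cutoff = 2015
    frac = np.clip((years - (frame.start_year - 20)) / (cutoff - (frame.start_year - 20)), 0, 1)
    ent_scalar = np.tile(0.5 + 0.5 * frac, (R, 1))
    ent_scalar[:, years >= cutoff] = 1.0

    traffic = np.outer(1.2 - lat, 0.5 + 0.5 * season)
    traffic = traffic * np.exp(config.traffic_trend * (years - frame.start_year))
    traffic = traffic * rng.lognormal(0.0, 0.05, size=(R, T))
    ais = rescale_unit(traffic)

    prey = np.outer(0.3 + 0.7 * lat, 0.5 + 1.5 * season) + 0.2
    year_noise = rng.lognormal(0.0, config.prey_noise_sd, size=frame.n_years)
    prey = prey * year_noise[((np.arange(T)) // 4)][None, :]
    post = years >= frame.era_break_year
    northern = lat >= 0.5
    prey[np.ix_(northern, post)] *= (1.0 - config.prey_regime_shift)

    dsm = np.outer(0.5 + lat, 0.6 + 0.4 * season) * rng.lognormal(0.0, 0.05, size=(R, T))

    return RegionalSurfaceSet(frame=frame, G=G, ent_scalar=ent_scalar, ais=ais,
                              prey=prey, dsm=dsm,
                              metadata={"generator_seed": int(seed)})


# ---------------------------------------------------------------------------
# true occupancy concentrations

def default_true_alpha(frame: StudyFrame) -> dict:
    """Class x quarter x era Dirichlet concentrations with a post-era northward shift."""
    R = frame.R
    lat = np.linspace(0.1, 1.0, R)
    alpha = {}
    for ci, cls in enumerate(CLASSES):
        for q in range(4):
            # winter south (esp. calving females), summer north
            south_weight = max(0.0, 1.0 - q / 1.5) if q <= 1 else 0.0
            base = 1.0 + 4.0 * ((1 - lat) * south_weight + lat * (1 - south_weight))
            if cls in ("calf", "adult female") and q == 0:
                base = base + 2.0 * (1 - lat)
            alpha[(cls, q, "pre")] = base
            shift = base + 2.5 * lat * (1 if q >= 1 else 0.3)   # post-era northward shift
            alpha[(cls, q, "post")] = shift
    return alpha


# ---------------------------------------------------------------------------
# population forward simulation

@dataclass
class SimulationTruth:
    config: SimulationConfig
    surfaces: RegionalSurfaceSet
    alpha: dict
    records: list                      # true IndividualRecord (complete event log)
    health: np.ndarray                 # (n, T), NaN outside life
    length: np.ndarray                 # (n, T)
    z: np.ndarray                      # (n, T, R)
    prey_std: np.ndarray               # (n, n_years)
    asymptote: np.ndarray              # (n,)
    alive: np.ndarray                  # (n, T) bool
    mother: dict                       # calf id -> mother id
    prey_constants: tuple              # (mean, sd) used for standardisation


class _Individual:
    __slots__ = ("id", "sex", "birth_year", "birth_step", "h", "A", "alive",
                 "entanglements", "strikes", "calving_years", "death_step",
                 "death_cause", "mother", "mother_entangled")

    def __init__(self, iid, sex, birth_year, birth_step, h0, A, mother=None,
                 mother_entangled=0.0):
        self.id = iid
        self.sex = sex
        self.birth_year = birth_year
        self.birth_step = birth_step
        self.h = h0
        self.A = A
        self.alive = True
        self.entanglements = []
        self.strikes = []
        self.calving_years = []
        self.death_step = None
        self.death_cause = None
        self.mother = mother
        self.mother_entangled = mother_entangled

    def age_years(self, t):
        return (t - self.birth_step) / 4.0

    def class_at(self, t, maturity_age=9):
        age = self.age_years(t)
        if age < 1:
            return "calf"
        if age < maturity_age:
            return "juvenile"
        return "adult female" if self.sex == "F" else "adult male"

    def carrying_gear(self, t):
        return any(ev.step <= t < ev.step + ev.gear_steps for ev in self.entanglements)


def _surface_prey_constants(surfaces: RegionalSurfaceSet) -> tuple:
    """Population-level prey standardisation constants from the density-weighted
    average individual's annual prey means."""
    frame = surfaces.frame
    w = surfaces.dsm / surfaces.dsm.sum(axis=0, keepdims=True)
    step_prey = np.sum(w * surfaces.prey, axis=0)          # (T,)
    annual = step_prey.reshape(frame.n_years, 4).mean(axis=1)
    return float(annual.mean()), float(annual.std(ddof=1))


def generate_population(frame: StudyFrame, surfaces: RegionalSurfaceSet,
                        config: SimulationConfig, seed: int) -> SimulationTruth:
    """Forward-simulate the individual-based population over the study frame."""
    rng = np.random.default_rng(seed)
    alpha = default_true_alpha(frame)
    G01 = rescale_unit(surfaces.G)
    prey_mean, prey_sd = _surface_prey_constants(surfaces)
    hp, gp, vp, xp = config.health, config.growth, config.vitals, config.exposure

    # pre-compute the regional strike field once
    years = frame.year_of_step(np.arange(frame.T))
    p_r = np.column_stack([
        regional_strike_probability(surfaces.ais[:, t], xp.iota2, xp.v_trend,
                                    int(years[t]), xp.reference_year)
        for t in range(frame.T)])                           # (R, T)

    population: list[_Individual] = []
    counter = [0]

    def new_id():
        counter[0] += 1
        return f"EG{counter[0]:04d}"

    # founding individuals with a realistic standing age structure
    for _ in range(config.n_initial):
        age = int(rng.integers(1, 31))
        sex = "F" if rng.random() < 0.5 else "M"
        birth_year = frame.start_year - age
        A_mean = gp.A0 + gp.birth_year_trend * (birth_year - gp.birth_year_ref)
        ind = _Individual(new_id(), sex, birth_year, birth_step=-4 * age,
                          h0=float(np.clip(rng.normal(config.h_birth_mean,
                                                      config.h_birth_sd), 40, 100)),
                          A=sample_asymptote(A_mean, gp, rng))
        population.append(ind)

    # per-individual per-year storage (grown dynamically)
    z_store: dict = {}
    h_store: dict = {}
    prey_step_store: dict = {}

    mother_of = {}

    for t in range(frame.T):
        year = int(years[t])
        quarter = int(frame.quarter_of_step(t))
        era = frame.era_of_step(t)
        year_idx = year - frame.start_year

        # annual bookkeeping at the start of each year: calving decisions
        if quarter == 0:
            for ind in [p for p in population if p.alive]:
                rec_view = IndividualRecord(
                    id=ind.id, sex=ind.sex, birth_year=ind.birth_year,
                    first_step=0, last_step=frame.T - 1,
                    calving_years=ind.calving_years)
                if ind.sex != "F" or not is_available(rec_view, year, frame, vp):
                    continue
                # mean health over the gestation (previous) year; fall back to current
                prev = [h_store[(ind.id, t - k)] for k in range(1, 5)
                        if (ind.id, t - k) in h_store]
                h_bar = float(np.mean(prev)) if prev else ind.h
                length = expected_length(ind.age_years(t), ind.A, gp.k, gp.L0)
                phi = calving_probability(h_bar, length, True, vp)
                if rng.random() < phi:
                    ind.calving_years.append(year)
                    mother_ent = float(any(
                        ind.carrying_gear(t - k) for k in range(0, 5)))
                    A_mean = (gp.A0 + gp.birth_year_trend * (year - gp.birth_year_ref)
                              + gp.beta_A.get("mother_entangled", 0.0) * mother_ent)
                    calf = _Individual(
                        new_id(), "F" if rng.random() < 0.5 else "M",
                        birth_year=year, birth_step=t,
                        h0=float(np.clip(rng.normal(config.h_birth_mean,
                                                    config.h_birth_sd), 40, 100)),
                        A=sample_asymptote(A_mean, gp, rng),
                        mother=ind.id, mother_entangled=mother_ent)
                    population.append(calf)
                    mother_of[calf.id] = ind.id

        for ind in population:
            if not ind.alive or t < ind.birth_step:
                continue
            cls = ind.class_at(t, vp.maturity_age)
            z = rng.dirichlet(alpha[(cls, quarter, era)])
            z_store[(ind.id, t)] = z

            # exposure and events
            p_ent = entanglement_probability(z, G01[:, t], surfaces.ent_scalar[:, t],
                                             xp.iota1)
            if rng.random() < p_ent:
                sev = SEVERITIES[int(rng.choice(3, p=config.severity_probs))]
                mean_extra = config.mean_gear_steps[sev] - 1.0
                gear = 1 + (int(rng.poisson(mean_extra)) if mean_extra > 0 else 0)
                ind.entanglements.append(EntanglementEvent(t, sev, gear))
            p_str = individual_strike_probability(z, p_r[:, t])
            if rng.random() < p_str:
                inj = INJURIES[int(rng.choice(4, p=config.injury_probs))]
                ind.strikes.append(StrikeEvent(t, inj))

            prey_step_store[(ind.id, t)] = float(np.sum(z * surfaces.prey[:, t]))

            # health update (drift recomputed for this single step)
            prey_vals = [prey_step_store.get((ind.id, frame.step(year, q)))
                         for q in range(quarter + 1)]
            prey_annual = float(np.mean([v for v in prey_vals if v is not None]))
            prey_std = (prey_annual - prey_mean) / prey_sd
            prey_by_year = np.zeros(frame.n_years)
            prey_by_year[year_idx] = prey_std
            rec_view = IndividualRecord(
                id=ind.id, sex=ind.sex, birth_year=ind.birth_year,
                first_step=0, last_step=frame.T - 1,
                entanglements=[e for e in ind.entanglements if e.step >= max(ind.birth_step, 0)],
                strikes=ind.strikes, calving_years=ind.calving_years)
            # birth-step handling: drift for the single transition into step t
            if t == max(ind.birth_step, 0):
                h_new = ind.h  # first modelled step: initial condition
            else:
                d = health_drift(rec_view, frame, prey_by_year, hp, t - 1, t)[0]
                h_new = float(np.clip(ind.h + d + rng.normal(0, hp.sigma_h),
                                      hp.floor, hp.ceiling))
            ind.h = h_new
            h_store[(ind.id, t)] = h_new

            # survival through the step
            lam = float(hazard_rate(h_new, vp))
            if rng.random() < 1.0 - np.exp(-lam):
                ind.alive = False
                ind.death_step = t
                if ind.carrying_gear(t) or any(t - e.step <= 2 for e in ind.entanglements):
                    ind.death_cause = "entanglement"
                elif any(t - e.step <= 2 for e in ind.strikes):
                    ind.death_cause = "strike"
                else:
                    ind.death_cause = "other"

    # assemble dense truth arrays
    n = len(population)
    health = np.full((n, frame.T), np.nan)
    length = np.full((n, frame.T), np.nan)
    zarr = np.zeros((n, frame.T, frame.R))
    alive = np.zeros((n, frame.T), dtype=bool)
    prey_std_arr = np.zeros((n, frame.n_years))
    asym = np.zeros(n)
    records = []
    for i, ind in enumerate(population):
        asym[i] = ind.A
        t0 = max(ind.birth_step, 0)
        t1 = ind.death_step if ind.death_step is not None else frame.T - 1
        for t in range(t0, t1 + 1):
            if (ind.id, t) in h_store:
                health[i, t] = h_store[(ind.id, t)]
                zarr[i, t] = z_store[(ind.id, t)]
                alive[i, t] = True
                length[i, t] = expected_length(ind.age_years(t), ind.A, gp.k, gp.L0)
        step_prey = np.array([prey_step_store.get((ind.id, t), np.nan)
                              for t in range(frame.T)])
        by_year = step_prey.reshape(frame.n_years, 4)
        have = ~np.isnan(by_year)
        annual = np.where(have.any(axis=1),
                          np.nansum(np.where(have, by_year, 0.0), axis=1)
                          / np.maximum(have.sum(axis=1), 1), np.nan)
        prey_std_arr[i] = np.where(np.isnan(annual), 0.0, (annual - prey_mean) / prey_sd)
        records.append(IndividualRecord(
            id=ind.id, sex=ind.sex, birth_year=ind.birth_year,
            first_step=t0, last_step=t1, death_step=ind.death_step,
            death_cause=ind.death_cause,
            entanglements=[e for e in ind.entanglements if e.step >= t0],
            strikes=list(ind.strikes), calving_years=list(ind.calving_years)))

    return SimulationTruth(config=config, surfaces=surfaces, alpha=alpha,
                           records=records, health=health, length=length, z=zarr,
                           prey_std=prey_std_arr, asymptote=asym, alive=alive,
                           mother=mother_of, prey_constants=(prey_mean, prey_sd))


# ---------------------------------------------------------------------------
# observation masking

def generate_observations(truth: SimulationTruth, obs_params: ObservationParameters,
                          seed: int):
    """Mask the truth through the observation processes.

    Returns (observed records, ObservationSet).  Individuals never sighted are
    absent from the observed dataset; birth year is known only for whales first
    seen as calves.
    """
    rng = np.random.default_rng(seed)
    frame = truth.surfaces.frame
    p_det = obs_params.detection_row(frame)
    sight_rows, vha_rows, len_rows = [], [], []
    ent_rows, str_rows, calv_rows, death_rows = [], [], [], []
    observed_records = []

    for i, rec in enumerate(truth.records):
        seen_steps = []
        for t in range(rec.first_step, rec.last_step + 1):
            if not truth.alive[i, t]:
                continue
            z = truth.z[i, t]
            q = int(frame.quarter_of_step(t))
            p_seen = float(np.sum(z * p_det[:, q]))
            if rng.random() >= p_seen:
                continue
            w = z * p_det[:, q]
            region = frame.regions[int(rng.choice(frame.R, p=w / w.sum()))]
            seen_steps.append(t)
            sight_rows.append({"id": rec.id, "t": t, "region": region})
            h = truth.health[i, t]
            if rng.random() < obs_params.p_vha:
                for x in range(len(obs_params.vha_cutpoints)):
                    probs = np.atleast_2d(vha_category_probs(
                        h, obs_params.vha_cutpoints[x], obs_params.vha_tau[x]))[0]
                    score = int(rng.choice(len(probs), p=probs))
                    vha_rows.append({"id": rec.id, "t": t, "variable": x, "score": score})
            if rng.random() < obs_params.p_length:
                platform = ("drone" if frame.year_of_step(t) >= obs_params.drone_from_year
                            else "aircraft")
                P = truth.length[i, t] + rng.normal(0, obs_params.sigma_P[platform])
                len_rows.append({"id": rec.id, "t": t,
                                 "length_m": max(P, 0.1), "platform": platform})
        if not seen_steps:
            continue

        obs_ents, obs_strikes = [], []
        for ev in rec.entanglements:
            if rng.random() < obs_params.p_ent_detect:
                obs_ents.append(ev)
                ent_rows.append({"id": rec.id, "step": ev.step, "severity": ev.severity,
                                 "gear_steps": ev.gear_steps})
        for ev in rec.strikes:
            if rng.random() < obs_params.p_strike_detect:
                obs_strikes.append(ev)
                str_rows.append({"id": rec.id, "step": ev.step, "injury": ev.injury})

        for y in rec.calving_years:
            calv_rows.append({"id": rec.id, "year": y, "calved": 1})

        death_step = death_cause = None
        if rec.death_step is not None and rng.random() < obs_params.p_recovery:
            death_step = rec.death_step
            death_cause = rec.death_cause
            death_rows.append({"id": rec.id, "step": death_step, "cause": death_cause})

        first_seen = min(seen_steps)
        # birth year is known from the catalog for founders (pre-study history)
        # and for whales first photographed within a year of birth
        birth_known = rec.birth_year is not None and (
            rec.birth_year < frame.start_year
            or frame.year_of_step(first_seen) - rec.birth_year <= 1)
        observed_records.append(IndividualRecord(
            id=rec.id, sex=rec.sex,
            birth_year=rec.birth_year if birth_known else None,
            first_step=first_seen, last_step=max(seen_steps),
            death_step=death_step, death_cause=death_cause,
            entanglements=obs_ents, strikes=obs_strikes,
            calving_years=list(rec.calving_years)))

    def _df(rows, cols):
        return pd.DataFrame(rows, columns=cols) if rows else pd.DataFrame(columns=cols)

    obs = ObservationSet(
        sightings=_df(sight_rows, ["id", "t", "region"]),
        vha=_df(vha_rows, ["id", "t", "variable", "score"]),
        lengths=_df(len_rows, ["id", "t", "length_m", "platform"]),
        entanglements=_df(ent_rows, ["id", "step", "severity", "gear_steps"]),
        strikes=_df(str_rows, ["id", "step", "injury"]),
        calvings=_df(calv_rows, ["id", "year", "calved"]),
        deaths=_df(death_rows, ["id", "step", "cause"]),
    )
    return observed_records, obs


# ---------------------------------------------------------------------------
# one-call dataset generation and serialisation

def generate_dataset(config: SimulationConfig | None = None, seed: int = 0):
    """Surfaces + population + observations in one deterministic call."""
    config = config or SimulationConfig()
    root = np.random.SeedSequence(seed)
    s_surf, s_pop, s_obs = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(3)]
    surfaces = generate_surfaces(config.frame, config, s_surf)
    truth = generate_population(config.frame, surfaces, config, s_pop)
    records, obs = generate_observations(truth, config.obs, s_obs)
    return {"config": config, "surfaces": surfaces, "truth": truth,
            "records": records, "observations": obs}


def write_dataset(dataset: dict, directory) -> None:
    """Serialise a generated dataset: surfaces CSV, observation CSVs, truth JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_surfaces(dataset["surfaces"], directory / "surfaces.csv")
    write_individuals(dataset["records"], dataset["observations"], directory)
    truth = dataset["truth"]
    cfg = dataset["config"]
    summary = {
        "prey_constants": list(truth.prey_constants),
        "n_individuals": len(truth.records),
        "parameters": {
            "health": _dataclass_dict(cfg.health),
            "growth": _dataclass_dict(cfg.growth),
            "vitals": _dataclass_dict(cfg.vitals),
            "exposure": _dataclass_dict(cfg.exposure),
        },
        "asymptotes": {r.id: float(a) for r, a in zip(truth.records, truth.asymptote)},
    }
    with open(directory / "truth.json", "w") as fh:
        json.dump(summary, fh, indent=1, default=str)
    # latent trajectories in long form
    frame = truth.surfaces.frame
    rows = []
    for i, rec in enumerate(truth.records):
        for t in range(rec.first_step, rec.last_step + 1):
            if truth.alive[i, t]:
                rows.append((rec.id, t, truth.health[i, t], truth.length[i, t]))
    pd.DataFrame(rows, columns=["id", "t", "health", "length"]).to_csv(
        directory / "truth_trajectories.csv", index=False)


def _dataclass_dict(obj):
    return {k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(obj).items()}
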