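"""Stochastic population projection under stressor-reduction scenarios.

The projector carries the retrospective model's estimates forward: survival is
computed through the same hazard rate lambda(h) = exp(a_s - b_s h) (annualised
by summing quarterly hazards), calving is a function of health and length, and
somatic growth follows the length curve with scenario-dependent asymptotes for
newborns.  Health itself is forward-simulated as a mean-reverting AR(1)
process anchored at the uninjured-health mean — the fitted random walk is not
suitable for forward prediction because nothing constrains its long-run trend
— with entanglement and strike insults superimposed.

Scenario levers: an entanglement-risk multiplier, a prey regime (historical
variation vs persistently low), and a regime for the trend in asymptotic
length (continue declining to a floor, stabilise at the current mean, or
recover toward the historical maximum).  A vessel-strike multiplier exists as
a lever but is excluded from the default grid.  Parameter uncertainty is
propagated by running one trajectory per posterior draw.

All outputs carry a "demonstration-grade" flag: projections inherit every
assumption of the retrospective model and are not management advice.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .core_data import INJURIES, SEVERITIES
from .growth import expected_length

PREY_REGIMES = ("historical", "low")
LENGTH_REGIMES = ("decline", "stabilize", "recover")


@dataclass
class ScenarioSpec:
    ent_multiplier: float = 1.0
    strike_multiplier: float = 1.0
    prey_regime: str = "historical"
    length_regime: str = "stabilize"
    horizon_years: int = 100
    n_draws: int = 1000
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.ent_multiplier <= 1.0):
            raise ValueError("entanglement multiplier must lie in [0, 1]")
        if not (0.0 <= self.strike_multiplier <= 1.0):
            raise ValueError("strike multiplier must lie in [0, 1]")
        if self.prey_regime not in PREY_REGIMES:
            raise ValueError(f"prey regime must be one of {PREY_REGIMES}")
        if self.length_regime not in LENGTH_REGIMES:
            raise ValueError(f"length regime must be one of {LENGTH_REGIMES}")
        if self.horizon_years < 1:
            raise ValueError("horizon must be at least one year")


@dataclass
class ProjectionParameters:
    """One parameter draw for one projected trajectory."""

    a_s: float = -1.5
    b_s: float = 0.05
    c0: float = -1.2
    c1: float = 0.04
    c2: float = 0.8
    h_ref: float = 70.0
    L_ref: float = 13.0
    k: float = 0.3
    L0: float = 4.5
    sigma_A: float = 0.5
    # forward health process (AR(1) around the uninjured mean)
    h_mean: float = 80.0
    rho: float = 0.7
    sigma_h_annual: float = 3.0
    beta_prey: float = 3.0
    # annual stressor event model
    p_ent_annual: float = 0.18
    p_strike_annual: float = 0.02
    delta_sev: dict = field(default_factory=lambda: {
        "minor": -2.0, "moderate": -8.0, "severe": -15.0})
    delta_gear: float = -2.0
    gamma_gear_prey: float = 0.0
    gear_years: dict = field(default_factory=lambda: {
        "minor": 0.25, "moderate": 0.5, "severe": 1.0})
    delta_inj: dict = field(default_factory=lambda: {
        "superficial": -2.0, "shallow": -6.0, "deep": -15.0, "blunt": -20.0})
    severity_probs: tuple = (0.5, 0.35, 0.15)
    injury_probs: tuple = (0.35, 0.3, 0.2, 0.15)
    # length-trend machinery
    length_trend: float = -0.03        # m per year, current decline rate
    length_floor: float = 10.0
    length_current_mean: float = 11.8
    length_historical_max: float = 14.0
    maturity_age: int = 9
    min_calving_interval: int = 2
    # test/diagnostic overrides
    fixed_survival: float | None = None
    calving_off: bool = False


@dataclass
class InitialPopulation:
    age: np.ndarray
    sex: np.ndarray          # 'F'/'M'
    health: np.ndarray
    asymptote: np.ndarray
    years_since_calving: np.ndarray


def default_initial_population(n: int = 300, seed: int = 0,
                               params: ProjectionParameters | None = None) -> InitialPopulation:
    """A synthetic standing population with a plausible age/sex structure."""
    params = params or ProjectionParameters()
    rng = np.random.default_rng(seed)
    age = rng.integers(0, 40, size=n).astype(float)
    sex = np.where(rng.random(n) < 0.5, "F", "M")
    health = np.clip(rng.normal(params.h_mean, 6.0, size=n), 30, 100)
    asym = np.clip(rng.normal(params.length_current_mean, params.sigma_A, size=n),
                   params.L0 + 1.0, None)
    ysc = rng.integers(0, 6, size=n).astype(float)
    return InitialPopulation(age=age, sex=sex, health=health, asymptote=asym,
                             years_since_calving=ysc)


@dataclass
class ProjectionResult:
    scenario: ScenarioSpec
    sizes: np.ndarray               # (n_draws, horizon + 1) total population
    ent_events: np.ndarray          # (n_draws,) total entanglement events
    strike_events: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.metadata.setdefault("demonstration_grade", True)
        self.metadata.setdefault(
            "caveat", "demonstrative projection; not for management use")


def _newborn_asymptote_mean(regime: str, year: int, params: ProjectionParameters) -> float:
    if regime == "decline":
        return max(params.length_current_mean + params.length_trend * year,
                   params.length_floor)
    if regime == "stabilize":
        return params.length_current_mean
    return min(params.length_current_mean - params.length_trend * year,
               params.length_historical_max)


def project(param_draws, scenario: ScenarioSpec, initial: InitialPopulation | None = None,
            seed: int | None = None) -> ProjectionResult:
    """Project the population forward under one scenario.

    ``param_draws`` is a sequence of :class:`ProjectionParameters` (one per
    trajectory; cycled if shorter than ``scenario.n_draws``).
    """
    if isinstance(param_draws, ProjectionParameters):
        param_draws = [param_draws]
    seed = scenario.seed if seed is None else seed
    rng_root = np.random.SeedSequence(seed)
    n_draws = scenario.n_draws
    horizon = scenario.horizon_years
    sizes = np.zeros((n_draws, horizon + 1), dtype=int)
    ent_events = np.zeros(n_draws, dtype=int)
    strike_events = np.zeros(n_draws, dtype=int)
    init0 = initial if initial is not None else default_initial_population(seed=seed)

    for d, child in enumerate(rng_root.spawn(n_draws)):
        rng = np.random.default_rng(child)
        par = param_draws[d % len(param_draws)]
        age = init0.age.copy()
        sex = init0.sex.copy()
        h = init0.health.copy()
        A = init0.asymptote.copy()
        ysc = init0.years_since_calving.copy()
        sizes[d, 0] = len(age)

        for year in range(1, horizon + 1):
            n = len(age)
            if n == 0:
                sizes[d, year:] = 0
                break
            prey_std = (rng.normal(0.0, 1.0) if scenario.prey_regime == "historical"
                        else rng.normal(-1.0, 0.5))

            # stressor insults on health
            insult = np.zeros(n)
            ent = rng.random(n) < par.p_ent_annual * scenario.ent_multiplier
            if ent.any():
                sev_idx = rng.choice(len(SEVERITIES), size=int(ent.sum()),
                                     p=np.asarray(par.severity_probs))
                for which, si in zip(np.where(ent)[0], sev_idx):
                    s = SEVERITIES[si]
                    gear = (par.delta_gear + par.gamma_gear_prey * prey_std)
                    insult[which] += par.delta_sev[s] + 4 * par.gear_years[s] * gear
                ent_events[d] += int(ent.sum())
            struck = rng.random(n) < par.p_strike_annual * scenario.strike_multiplier
            if struck.any():
                inj_idx = rng.choice(len(INJURIES), size=int(struck.sum()),
                                     p=np.asarray(par.injury_probs))
                for which, ji in zip(np.where(struck)[0], inj_idx):
                    insult[which] += par.delta_inj[INJURIES[ji]]
                strike_events[d] += int(struck.sum())

            # mean-reverting health update
            h = (par.h_mean + par.rho * (h - par.h_mean)
                 + par.beta_prey * prey_std + insult
                 + rng.normal(0.0, par.sigma_h_annual, size=n))
            h = np.clip(h, 1.0, 100.0)

            # survival through the year
            if par.fixed_survival is not None:
                surv_p = np.full(n, par.fixed_survival)
            else:
                lam = 4.0 * np.exp(par.a_s - par.b_s * h)
                surv_p = np.exp(-lam)
            alive = rng.random(n) < surv_p

            # calving
            newborns = 0
            if not par.calving_off:
                L = expected_length(age, A, par.k, par.L0)
                available = (alive & (sex == "F") & (age >= par.maturity_age)
                             & (ysc > par.min_calving_interval))
                phi = expit(par.c0 + par.c1 * (h - par.h_ref) + par.c2 * (L - par.L_ref))
                calved = available & (rng.random(n) < phi)
                newborns = int(calved.sum())
                ysc = np.where(calved, 0.0, ysc + 1.0)
            else:
                ysc = ysc + 1.0

            age = age[alive] + 1.0
            sex = sex[alive]
            h = h[alive]
            A = A[alive]
            ysc = ysc[alive]
            if newborns:
                A_mean = _newborn_asymptote_mean(scenario.length_regime, year, par)
                age = np.concatenate([age, np.zeros(newborns)])
                sex = np.concatenate([sex, np.where(rng.random(newborns) < 0.5, "F", "M")])
                h = np.concatenate([h, np.clip(
                    rng.normal(par.h_mean, 5.0, size=newborns), 30, 100)])
                A = np.concatenate([A, np.clip(
                    rng.normal(A_mean, par.sigma_A, size=newborns), par.L0 + 0.5, None)])
                ysc = np.concatenate([ysc, np.zeros(newborns)])
            sizes[d, year] = len(age)

    return ProjectionResult(scenario=scenario, sizes=sizes, ent_events=ent_events,
                            strike_events=strike_events,
                            metadata={"seed": seed, "n_draws": n_draws})


def scenario_grid(levers: dict, horizon_years: int = 100, n_draws: int = 1000,
                  seed: int = 0) -> list:
    """Full factorial of scenario levers.

    ``levers`` maps lever name (ent_multiplier, prey_regime, length_regime,
    strike_multiplier) to a list of values; every lever needs at least one
    value.  The demonstration grid {1.0, 0.5, 0.0} x {historical, low} x
    {decline, stabilize, recover} yields 18 scenarios.
    """
    if not levers or any(len(v) == 0 for v in levers.values()):
        raise ValueError("every supplied lever needs at least one value")
    allowed = {"ent_multiplier", "strike_multiplier", "prey_regime", "length_regime"}
    unknown = set(levers) - allowed
    if unknown:
        raise KeyError(f"unknown levers {sorted(unknown)}; allowed: {sorted(allowed)}")
    names = list(levers)
    specs = []
    for combo in itertools.product(*(levers[n] for n in names)):
        kwargs = dict(zip(names, combo))
        specs.append(ScenarioSpec(horizon_years=horizon_years, n_draws=n_draws,
                                  seed=seed, **kwargs))
    return specs


def summarize_trajectories(result: ProjectionResult, thresholds=(0, 50, 100)) -> dict:
    """Per-year quantiles and quasi-extinction probabilities.

    Quasi-extinction by year y = fraction of trajectories whose running
    minimum has fallen below the threshold by year y (at or below for 0).
    """
    sizes = result.sizes
    qs = np.percentile(sizes, [2.5, 25, 50, 75, 97.5], axis=0)
    running_min = np.minimum.accumulate(sizes, axis=1)
    quasi = {}
    for thr in thresholds:
        hit = running_min <= thr if thr == 0 else running_min < thr
        quasi[thr] = hit.mean(axis=0)
    return {"quantiles": {"q2.5": qs[0], "q25": qs[1], "median": qs[2],
                          "q75": qs[3], "q97.5": qs[4]},
            "quasi_extinction": quasi,
            "metadata": dict(result.metadata)}


def projection_params_from_posterior(draws: dict, n: int, rng: np.random.Generator,
                                     **overrides) -> list:
    """Build per-trajectory parameter draws from a posterior draws dict."""
    flat = {k: np.asarray(v).ravel() for k, v in draws.items()}
    size = len(next(iter(flat.values())))
    idx = rng.integers(0, size, size=n)
    out = []
    for j in idx:
        kw = {}
        for name in ("a_s", "b_s", "c0", "c1", "c2", "k", "sigma_A", "beta_prey",
                     "delta_gear", "gamma_gear_prey"):
            if name in flat:
                kw[name] = float(flat[name][j])
        if "delta_sev_minor" in flat:
            kw["delta_sev"] = {s: float(flat[f"delta_sev_{s}"][j]) for s in SEVERITIES}
        if "delta_inj_superficial" in flat:
            kw["delta_inj"] = {i: float(flat[f"delta_inj_{i}"][j]) for i in INJURIES}
        kw.update(overrides)
        out.append(ProjectionParameters(**kw))
    return out
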