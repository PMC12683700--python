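"""Latent health: a bounded random walk driven by intrinsic covariates,
traumatic events, prey conditions, and one active combined-effect term.

Health lives on a (0, 100] scale (matching the visual-health literature, so
effect sizes read as points of body condition).  Per quarterly step,

    h_t = clamp( h_{t-1} + drift_t + noise, floor, 100 )

where drift_t collects:

* intrinsic terms — the one-off calf-to-juvenile transition cost and a
  per-step lactation cost for nursing females;
* a new entanglement of severity s: the immediate effect delta_sev[s] plus one
  step of the prolonged gear-carrying effect (the prolonged effect does not
  apply separately in the event step; its first step is folded into the event
  step), plus any active prior-entanglement modifier;
* carrying previously-acquired gear: the prolonged effect per step;
* a vessel strike of injury class j: delta_inj[j];
* prey: beta_prey * standardised annual prey, entering in the Jun-Aug step;
* combined effects: each pairing adds gamma * prey_std to the corresponding
  main effect (additive on the health scale); only the variant named in
  ``active_interaction`` is live in a fit.

A positive coefficient means an improvement in health.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import truncnorm

from .core_data import INJURIES, JUN_AUG, SEVERITIES, StudyFrame

INTERACTIONS = ("gear_prey", "sev_prey", "inj_prey", "nprior", "prior_any", "prior_2yr")
PRIOR_WINDOW_STEPS = 8  # "previous 2 years" = 8 quarterly steps, boundary inclusive


@dataclass
class HealthParameters:
    sigma_h: float = 2.0
    delta_transition: float = -3.0          # calf -> juvenile weaning cost
    delta_lactation: float = -2.0           # per lactating step
    delta_sev: dict = field(default_factory=lambda: {
        "minor": -2.0, "moderate": -8.0, "severe": -15.0})
    delta_gear: float = -2.0                # prolonged gear-carrying, per step
    delta_inj: dict = field(default_factory=lambda: {
        "superficial": -2.0, "shallow": -6.0, "deep": -15.0, "blunt": -20.0})
    beta_prey: float = 3.0                  # per SD of annual prey, Jun-Aug step
    # combined-effect coefficients (additive on the health scale)
    gamma_gear_prey: float = 0.0
    gamma_sev_prey: dict = field(default_factory=lambda: {s: 0.0 for s in SEVERITIES})
    gamma_inj_prey: dict = field(default_factory=lambda: {j: 0.0 for j in INJURIES})
    gamma_nprior: float = 0.0
    gamma_prior_any: float = 0.0
    gamma_prior_2yr: float = 0.0
    active_interaction: str | None = None   # one live variant per fitted model
    floor: float = 0.01
    ceiling: float = 100.0

    def __post_init__(self):
        if self.sigma_h <= 0:
            raise ValueError("sigma_h must be positive")
        if self.active_interaction is not None and self.active_interaction not in INTERACTIONS:
            raise ValueError(f"unknown interaction variant {self.active_interaction!r}")

    def _on(self, name: str) -> bool:
        return self.active_interaction == name


def event_history_features(event_steps, t: int):
    """(n_prior, any_prior, any_prior_2yr) from entanglement steps strictly before t.

    The 2-year window spans 8 quarterly steps with an inclusive boundary: an
    event exactly 8 steps earlier still counts as recent.
    """
    prior = [s for s in event_steps if s < t]
    n_prior = len(prior)
    any_2yr = int(any(t - s <= PRIOR_WINDOW_STEPS for s in prior))
    return n_prior, int(n_prior > 0), any_2yr


def entanglement_effect(severity: str, prey_std: float, n_prior: int,
                        any_prior: int, any_prior_2yr: int,
                        params: HealthParameters) -> float:
    """Health contribution of a new entanglement event, event step inclusive.

    Composition: immediate severity effect (+ its prey interaction when live)
    + one step of the prolonged gear effect (+ its interaction when live)
    + the active prior-entanglement modifier.
    """
    eff = params.delta_sev[severity]
    if params._on("sev_prey"):
        eff += params.gamma_sev_prey[severity] * prey_std
    eff += gear_effect(prey_std, params)
    if params._on("nprior"):
        eff += params.gamma_nprior * n_prior
    if params._on("prior_any"):
        eff += params.gamma_prior_any * any_prior
    if params._on("prior_2yr"):
        eff += params.gamma_prior_2yr * any_prior_2yr
    return eff


def gear_effect(prey_std: float, params: HealthParameters) -> float:
    """Per-step cost of carrying gear, with the prey interaction when live."""
    eff = params.delta_gear
    if params._on("gear_prey"):
        eff += params.gamma_gear_prey * prey_std
    return eff


def strike_effect(injury: str, prey_std: float, params: HealthParameters) -> float:
    eff = params.delta_inj[injury]
    if params._on("inj_prey"):
        eff += params.gamma_inj_prey[injury] * prey_std
    return eff


def health_drift(record, frame: StudyFrame, prey_std_by_year: np.ndarray,
                 params: HealthParameters, t_start: int, t_end: int) -> np.ndarray:
    """Deterministic drift of the health walk for steps t_start+1 .. t_end.

    ``prey_std_by_year`` is indexed by (year - frame.start_year).  Returns an
    array d where d[k] is the drift entering h at step t_start+1+k.
    """
    steps = np.arange(t_start + 1, t_end + 1)
    drift = np.zeros(len(steps))
    ent_steps = sorted(ev.step for ev in record.entanglements)
    birth_step = record.birth_step(frame)
    for k, t in enumerate(steps):
        year_idx = int(frame.year_of_step(t)) - frame.start_year
        prey_std = float(prey_std_by_year[year_idx])
        d = 0.0
        if birth_step is not None and t - birth_step == 4:
            d += params.delta_transition  # calf -> juvenile at age 1
        if record.lactating(t, frame):
            d += params.delta_lactation
        if frame.quarter_of_step(t) == JUN_AUG:
            d += params.beta_prey * prey_std
        # gear carrying is a binary state: one prolonged effect per step,
        # regardless of how many gear sets are attached
        carrying = any(ev.step <= t < ev.step + ev.gear_steps
                       for ev in record.entanglements)
        for ev in record.entanglements:
            if ev.step == t:
                feats = event_history_features(ent_steps, t)
                d += params.delta_sev[ev.severity]
                if params._on("sev_prey"):
                    d += params.gamma_sev_prey[ev.severity] * prey_std
                if params._on("nprior"):
                    d += params.gamma_nprior * feats[0]
                if params._on("prior_any"):
                    d += params.gamma_prior_any * feats[1]
                if params._on("prior_2yr"):
                    d += params.gamma_prior_2yr * feats[2]
        if carrying:
            d += gear_effect(prey_std, params)
        for ev in record.strikes:
            if ev.step == t:
                d += strike_effect(ev.injury, prey_std, params)
        drift[k] = d
    return drift


def health_step(h_prev: float, drift: float, noise: float,
                params: HealthParameters) -> float:
    """One transition of the bounded walk: clamp(h_prev + drift + noise)."""
    if not (0 < h_prev <= params.ceiling):
        raise ValueError(f"h_prev={h_prev} outside (0, {params.ceiling}]")
    return float(np.clip(h_prev + drift + noise, params.floor, params.ceiling))


def simulate_health(h0: float, drift: np.ndarray, params: HealthParameters,
                    rng: np.random.Generator) -> np.ndarray:
    """Forward-simulate the walk; returns the trajectory including h0."""
    h = np.empty(len(drift) + 1)
    h[0] = h0
    noise = rng.normal(0.0, params.sigma_h, size=len(drift))
    for k in range(len(drift)):
        h[k + 1] = np.clip(h[k] + drift[k] + noise[k], params.floor, params.ceiling)
    return h


def health_loglik(trajectory: np.ndarray, drift: np.ndarray,
                  params: HealthParameters) -> float:
    """Sum of truncated-Gaussian increment log-densities along a trajectory.

    trajectory has length len(drift) + 1; increment t is
    TruncNormal(h_{t-1} + drift_t, sigma_h) on [floor, ceiling].
    """
    h = np.asarray(trajectory, dtype=float)
    if np.any(h <= 0) or np.any(h > params.ceiling):
        raise ValueError("health trajectory outside (0, ceiling]")
    if len(h) != len(drift) + 1:
        raise ValueError("trajectory must be one longer than the drift sequence")
    mu = h[:-1] + np.asarray(drift)
    a = (params.floor - mu) / params.sigma_h
    b = (params.ceiling - mu) / params.sigma_h
    return float(np.sum(truncnorm.logpdf(h[1:], a, b, loc=mu, scale=params.sigma_h)))
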