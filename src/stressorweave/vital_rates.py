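"""Vital rates: health -> quarterly survival, health + length -> annual calving.

Survival is written in hazard form so that the retrospective model and the
forward projection share the identical quantity:

    lambda(h) = exp(a_s - b_s * h)        (quarterly hazard)
    theta(h)  = exp(-lambda(h))           (quarterly survival probability)

which is exactly the complementary log-log link between health and survival:
cloglog(1 - theta) = a_s - b_s * h.  Annual hazards add over the four quarters.
Because the link is nonlinear, health insults that are additive on the health
scale are non-additive on the survival scale.

Calving, for available adult females, is logistic in mean annual health and
length:  phi = expit(c0 + c1 * (hbar - h_ref) + c2 * (L - L_ref)); a female is
available if mature and at least ``min_calving_interval`` full calendar years
have passed since her last calving.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .core_data import ADULT_FEMALE, CALF, JUVENILE, StudyFrame


@dataclass
class VitalRateParameters:
    a_s: float = -1.5           # survival intercept, cloglog/hazard scale
    b_s: float = 0.05           # health slope (>= 0: healthier -> safer)
    c0: float = -1.2            # calving intercept, logit scale
    c1: float = 0.04            # health slope on calving
    c2: float = 0.8             # length slope on calving (>= 0)
    h_ref: float = 70.0
    L_ref: float = 13.0
    min_calving_interval: int = 2   # full calendar years between calvings
    maturity_age: int = 9

    def __post_init__(self):
        if self.b_s < 0:
            raise ValueError("b_s must be nonnegative (health cannot reduce survival)")
        if self.c2 < 0:
            raise ValueError("c2 must be nonnegative (longer females calve more)")


def hazard_rate(h, params: VitalRateParameters):
    """Quarterly mortality hazard lambda = exp(a_s - b_s * h)."""
    h = np.asarray(h, dtype=float)
    if np.any(h <= 0) or np.any(h > 100):
        raise ValueError("health must lie in (0, 100]")
    return np.exp(params.a_s - params.b_s * h)


def survival_probability(h, params: VitalRateParameters):
    """Quarterly survival theta = exp(-lambda(h))."""
    return np.exp(-hazard_rate(h, params))


def annual_hazard(h_four_quarters, params: VitalRateParameters) -> float:
    """Annual hazard as the sum of the four quarterly hazards."""
    h = np.asarray(h_four_quarters, dtype=float)
    if h.shape[-1] != 4:
        raise ValueError("expected four quarterly health values")
    return float(np.sum(hazard_rate(h, params)))


def calving_probability(h_bar: float, length: float, available: bool,
                        params: VitalRateParameters) -> float:
    """Annual calving probability for an adult female; 0 when unavailable."""
    if not available:
        return 0.0
    return float(expit(params.c0 + params.c1 * (h_bar - params.h_ref)
                       + params.c2 * (length - params.L_ref)))


def is_available(record, year: int, frame: StudyFrame,
                 params: VitalRateParameters) -> bool:
    """Availability: mature adult female with no calving in the preceding interval."""
    t = frame.step(year, 0)
    if record.class_at(t, frame, params.maturity_age) != ADULT_FEMALE:
        return False
    recent = [y for y in record.calving_years
              if 0 < year - y <= params.min_calving_interval]
    return not recent


def demographic_transition(cls: str, age_years: float, sex: str,
                           alive: bool, maturity_age: int = 9) -> str:
    """Class at the next step: calf->juvenile at age 1, juvenile->adult at maturity;
    death is absorbing (returns 'dead')."""
    if not alive or cls == "dead":
        return "dead"
    next_age = age_years + 0.25
    if next_age < 1:
        return CALF
    if next_age < maturity_age:
        return JUVENILE
    return ADULT_FEMALE if sex == "F" else "adult male"
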