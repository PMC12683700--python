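"""Somatic growth to an individual asymptotic length.

Length follows a von-Bertalanffy-type curve with a shared growth rate k and
length at age 0, and an individual asymptote A_i:

    L(age) = A_i - (A_i - L0) * exp(-k * age)

The asymptote mean carries a birth-year trend (the documented decline in
maximum body length) and, in the covariate models, one active block of
stressor covariates (prolonged health, maternal health/entanglement during
lactation, or mean prey x mean entanglement status over an early-life window).
Female length feeds the calving-probability pathway.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

LENGTH_WINDOWS = (15, 10, 5, 2, 1)  # years of early life for "prolonged" covariates


@dataclass
class GrowthParameters:
    A0: float = 13.5            # population asymptote intercept (m)
    birth_year_trend: float = 0.0   # m per birth year
    birth_year_ref: int = 1980
    k: float = 0.3              # per year
    L0: float = 4.5             # length at age 0 (m)
    sigma_A: float = 0.5        # individual asymptote SD (m)
    beta_A: dict = field(default_factory=dict)  # covariate name -> coefficient

    def __post_init__(self):
        if self.k <= 0 or self.sigma_A <= 0:
            raise ValueError("k and sigma_A must be positive")
        if self.L0 >= self.A0:
            raise ValueError("L0 must be below the asymptote intercept")


def expected_length(age, A_i, k: float, L0: float):
    """Deterministic length at a given age (years); vectorised in age."""
    age = np.asarray(age, dtype=float)
    if np.any(age < 0):
        raise ValueError("age must be nonnegative")
    return A_i - (A_i - L0) * np.exp(-k * age)


def asymptote_predictor(covariates: dict, params: GrowthParameters,
                        birth_year: int) -> float:
    """Mean of the individual asymptote: intercept + birth-year trend + X beta.

    ``covariates`` maps names to standardised values; every name must have a
    coefficient in ``params.beta_A`` (fail-closed against silent typos).
    """
    mean = params.A0 + params.birth_year_trend * (birth_year - params.birth_year_ref)
    for name, x in covariates.items():
        if name not in params.beta_A:
            raise KeyError(f"no asymptote coefficient for covariate {name!r}")
        mean += params.beta_A[name] * x
    return float(mean)


def sample_asymptote(mean: float, params: GrowthParameters,
                     rng: np.random.Generator) -> float:
    """Individual asymptote ~ Normal(mean, sigma_A), truncated above L0."""
    for _ in range(1000):
        a = rng.normal(mean, params.sigma_A)
        if a > params.L0:
            return float(a)
    return float(params.L0 + 0.1)  # pathological mean far below L0


def growth_covariate_windows(health: np.ndarray, prey_std: np.ndarray,
                             gear_carrying: np.ndarray, window_years: int):
    """Early-life covariate means over the first ``window_years`` of life.

    Inputs are per-quarter series starting at birth (health, annual prey_std
    expanded to steps, 0/1 gear-carrying).  When the window exceeds the
    observed lifespan, means are taken over the available steps and the
    result carries coverage < 1.

    Returns dict with mean_health, mean_prey, mean_entanglement and coverage
    (fraction of the requested window actually observed).
    """
    n_steps = min(len(health), 4 * window_years)
    if n_steps == 0:
        raise ValueError("no observed steps to summarise")
    return {
        "mean_health": float(np.mean(health[:n_steps])),
        "mean_prey": float(np.mean(prey_std[:n_steps])),
        "mean_entanglement": float(np.mean(gear_carrying[:n_steps])),
        "coverage": n_steps / (4 * window_years),
    }
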