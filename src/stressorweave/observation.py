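"""Observation models linking latent states to the data streams.

* sightings: Bernoulli per step with detection probability varying by region
  and quarter, weighted by the individual's occupancy (an animal is only
  detectable where it is, and only while alive);
* visual-health scores: ordered-categorical with monotone cutpoints on the
  health scale and a per-variable noise SD;
* photogrammetric lengths: Gaussian around latent length, with a platform-
  specific measurement SD (occupied aircraft vs drone);
* carcass recovery: Bernoulli, determining whether a death (and its cause) is
  ever observed;
* terminal-event imputation: at most one unobserved entanglement and one
  unobserved vessel strike after an individual's last sighting, capturing
  cryptic deaths; the event time is distributed over post-last-sighting steps
  proportionally to exposure probability and the severity/injury class comes
  from a categorical prior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr
from scipy.stats import norm

from .core_data import INJURIES, SEVERITIES, StudyFrame


@dataclass
class ObservationParameters:
    p_det: np.ndarray | float = 0.45      # detection prob, scalar or (R, 4)
    vha_cutpoints: tuple = ((55.0, 75.0),) * 4  # per variable, monotone on health scale
    vha_tau: tuple = (8.0, 8.0, 8.0, 8.0)       # per-variable noise SD
    p_vha: float = 0.7                    # prob a sighting yields VHA scores
    sigma_P: dict = field(default_factory=lambda: {"aircraft": 0.25, "drone": 0.10})
    p_length: float = 0.08                # prob a sighting yields a length measurement
    drone_from_year: int = 2016
    p_recovery: float = 0.4               # carcass recovery probability
    p_ent_detect: float = 0.85            # entanglement event detected (gear/scars)
    p_strike_detect: float = 0.6          # strike event detected (wounds)
    severity_prior: tuple = (0.5, 0.35, 0.15)          # minor, moderate, severe
    injury_prior: tuple = (0.35, 0.3, 0.2, 0.15)       # superficial..blunt

    def __post_init__(self):
        for cuts in self.vha_cutpoints:
            if any(b <= a for a, b in zip(cuts, cuts[1:])):
                raise ValueError("VHA cutpoints must be strictly increasing")
        for v in self.sigma_P.values():
            if v <= 0:
                raise ValueError("measurement SDs must be positive")

    def detection_row(self, frame: StudyFrame) -> np.ndarray:
        p = np.asarray(self.p_det, dtype=float)
        if p.ndim == 0:
            p = np.full((frame.R, 4), float(p))
        if p.shape != (frame.R, 4):
            raise ValueError("p_det must be scalar or (R, 4)")
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("detection probabilities must lie in [0, 1]")
        return p


# ---------------------------------------------------------------------------
# sightings

def sighting_probability(z: np.ndarray, p_det_rq: np.ndarray, quarter: int) -> float:
    """P(seen in a step | alive) = sum_l z_l * p_det[l, quarter]."""
    return float(np.sum(np.asarray(z) * p_det_rq[:, quarter]))


def sighting_loglik(seen: np.ndarray, alive: np.ndarray, z_t: np.ndarray,
                    p_det_rq: np.ndarray, quarters: np.ndarray) -> float:
    """Bernoulli log-likelihood of a 0/1 sighting series.

    ``z_t`` is (T_obs, R); a dead step has P(seen) = 0 (a sighting while dead
    has -inf likelihood, which the data invariants exclude upstream).
    """
    p = np.einsum("tr,tr->t", z_t, p_det_rq[:, quarters].T) * alive
    p = np.clip(p, 1e-12, 1 - 1e-12)
    p = np.where(alive.astype(bool), p, 1e-12)
    seen = np.asarray(seen, dtype=float)
    return float(np.sum(seen * np.log(p) + (1 - seen) * np.log1p(-p)))


# ---------------------------------------------------------------------------
# ordinal visual-health scores

def vha_category_probs(h, cutpoints, tau: float) -> np.ndarray:
    """Ordered-categorical probabilities: P(c) = Phi((k_c - h)/tau) - Phi((k_{c-1} - h)/tau)."""
    h = np.atleast_1d(np.asarray(h, dtype=float))
    edges = np.concatenate([[-np.inf], np.asarray(cutpoints, dtype=float), [np.inf]])
    with np.errstate(invalid="ignore"):
        cdf = ndtr((edges[None, :] - h[:, None]) / tau)
    cdf[:, 0] = 0.0
    cdf[:, -1] = 1.0
    probs = np.diff(cdf, axis=1)
    return probs[0] if np.ndim(h) == 1 and len(h) == 1 else probs


def vha_loglik(scores: np.ndarray, h: np.ndarray, variable: np.ndarray,
               params: ObservationParameters) -> float:
    """Log-likelihood of ordinal scores given latent health at the scored steps."""
    total = 0.0
    scores = np.asarray(scores, dtype=int)
    h = np.asarray(h, dtype=float)
    variable = np.asarray(variable, dtype=int)
    for x in np.unique(variable):
        m = variable == x
        probs = vha_category_probs(h[m], params.vha_cutpoints[x], params.vha_tau[x])
        probs = np.atleast_2d(probs)
        total += float(np.sum(np.log(np.clip(probs[np.arange(m.sum()), scores[m]], 1e-300, None))))
    return total


# ---------------------------------------------------------------------------
# photogrammetric lengths

def length_measurement_loglik(P, L, platform, params: ObservationParameters) -> float:
    """Gaussian log-density of measured lengths around latent lengths."""
    P = np.atleast_1d(np.asarray(P, dtype=float))
    L = np.atleast_1d(np.asarray(L, dtype=float))
    if np.any(P <= 0):
        raise ValueError("photogrammetric lengths must be positive")
    sig = np.array([params.sigma_P[p] for p in np.atleast_1d(platform)])
    return float(np.sum(norm.logpdf(P, loc=L, scale=sig)))


# ---------------------------------------------------------------------------
# terminal unobserved events (cryptic deaths)

def terminal_event_time_distribution(exposure_probs: np.ndarray) -> np.ndarray:
    """Conditional event-time mass over candidate post-last-sighting steps.

    Proportional to the per-step exposure probability; an all-zero exposure
    vector means the event cannot occur (returns all zeros rather than a
    normalised distribution).
    """
    p = np.asarray(exposure_probs, dtype=float)
    if np.any(p < 0):
        raise ValueError("exposure probabilities must be nonnegative")
    total = p.sum()
    if total == 0:
        return np.zeros_like(p)
    return p / total


def impute_terminal_events(record, candidate_steps: np.ndarray,
                           p_ent: np.ndarray, p_strike: np.ndarray,
                           params: ObservationParameters,
                           rng: np.random.Generator):
    """Draw at most one unobserved entanglement and one unobserved strike
    after the last sighting.

    ``candidate_steps`` are the steps after the individual's last sighting;
    ``p_ent`` / ``p_strike`` are the exposure probabilities at those steps.
    An individual recovered dead with a known cause is never augmented.
    Each event occurs with probability 1 - prod(1 - p) over the candidate
    window; given occurrence, its time is exposure-weighted and its class is
    drawn from the categorical prior.

    Returns a dict with optional "entanglement" / "strike" entries of the form
    (step, class_label).
    """
    out = {}
    if record.death_step is not None and record.death_cause is not None:
        return out
    candidate_steps = np.asarray(candidate_steps, dtype=int)
    if len(candidate_steps) == 0:
        return out
    for kind, probs, labels, prior in (
            ("entanglement", np.asarray(p_ent, float), SEVERITIES, params.severity_prior),
            ("strike", np.asarray(p_strike, float), INJURIES, params.injury_prior)):
        p_any = 1.0 - np.prod(1.0 - probs)
        if p_any > 0 and rng.random() < p_any:
            mass = terminal_event_time_distribution(probs)
            step = int(rng.choice(candidate_steps, p=mass))
            label = labels[int(rng.choice(len(labels), p=np.asarray(prior) / np.sum(prior)))]
            out[kind] = (step, label)
    return out
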