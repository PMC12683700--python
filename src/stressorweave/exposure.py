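"""Exposure layer: occupancy x stressor surfaces -> per-individual probabilities.

Converts an individual's occupancy simplex plus the regional stressor surfaces
into a per-step probability of entanglement, a per-step probability of vessel
strike, and an experienced prey index, including the temporal and spatial
extrapolation scalars used to extend the surfaces beyond their native coverage:

* entanglement probability: p_e = iota1 * sum_l z_l * G_l * e_l, with G the
  unit-rescaled risk surface and e a landings-derived backcast multiplier
  applied to years before the surface's reference window;
* regional strike probability: logit(p_r) = logit(iota2 * AIS_l) + v * (ref_year
  - year), i.e. proportional to the AIS-derived risk in the reference year and
  linear on the logit scale going back in time;
* individual strike probability: the occupancy-weighted mean of p_r;
* experienced prey: the occupancy-weighted mean of the prey surface, averaged
  within each year and standardised by the mean/SD across annual means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit

from .core_data import StudyFrame, rescale_unit  # noqa: F401  (re-exported convenience)


@dataclass
class ExposureParameters:
    """Conversion coefficients from relative risk to per-step probability.

    iota1 and iota2 must lie in supports guaranteeing that every resulting
    probability is a probability (iota * max rescaled risk * max scalar <= 1);
    draws outside the support are rejected upstream, never clipped here.
    """

    iota1: float = 0.05     # entanglement conversion (prob per unit rescaled risk)
    iota2: float = 0.01     # strike conversion
    v_trend: float = 0.0    # strike-risk temporal trend per year, logit scale
    prey_mean: float = 0.0  # standardisation constants over annual means
    prey_sd: float = 1.0
    reference_year: int = 2019


def _check_simplex(z: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    z = np.asarray(z, dtype=float)
    if np.any(z < -tol) or abs(z.sum() - 1.0) > 1e-6:
        raise ValueError("occupancy z must be a simplex (nonnegative, summing to 1)")
    return z


def entanglement_probability(z, G_row, e_row, iota1: float) -> float:
    """Per-step entanglement probability p_e = iota1 * sum_l z_l G_l e_l.

    ``G_row`` must already be rescaled to [0, 1]; ``e_row`` is the landings
    backcast scalar.  A result above 1 signals an invalid iota1/e combination
    and raises rather than clipping.
    """
    z = _check_simplex(z)
    G_row = np.asarray(G_row, dtype=float)
    e_row = np.asarray(e_row, dtype=float)
    if np.any(G_row < 0) or np.any(G_row > 1 + 1e-12):
        raise ValueError("G_row must be rescaled to [0, 1]")
    if np.any(e_row < 0):
        raise ValueError("backcast scalars must be nonnegative")
    p = float(iota1 * np.sum(z * G_row * e_row))
    if p > 1.0:
        raise ValueError(f"entanglement probability {p} > 1: iota1/e outside valid support")
    return p


def regional_strike_probability(ais_row, iota2: float, v_trend: float, year: int,
                                reference_year: int = 2019) -> np.ndarray:
    """Per-region strike probability with a logit-linear temporal trend.

    p_r[l] = expit( logit(iota2 * AIS_l) + v_trend * (reference_year - year) ).
    AIS_l = 0 maps to 0 (the logit limit); iota2 * AIS_l = 1 is rejected.
    """
    ais_row = np.asarray(ais_row, dtype=float)
    if np.any(ais_row < 0) or np.any(ais_row > 1 + 1e-12):
        raise ValueError("AIS risk must lie in [0, 1]")
    base = iota2 * ais_row
    if np.any(base >= 1.0):
        raise ValueError("iota2 * AIS reached 1: logit undefined, iota2 outside support")
    out = np.zeros_like(base)
    pos = base > 0
    out[pos] = expit(logit(base[pos]) + v_trend * (reference_year - year))
    return out


def individual_strike_probability(z, p_r_row) -> float:
    """Occupancy-weighted strike probability: a convex combination of p_r."""
    z = _check_simplex(z)
    p_r_row = np.asarray(p_r_row, dtype=float)
    if np.any(p_r_row < 0) or np.any(p_r_row > 1):
        raise ValueError("regional strike probabilities must lie in [0, 1]")
    return float(np.sum(z * p_r_row))


def individual_prey_index(z, prey_row) -> float:
    """Occupancy-weighted prey concentration (g/m^3) experienced in one step."""
    z = _check_simplex(z)
    prey_row = np.asarray(prey_row, dtype=float)
    if np.any(prey_row < 0):
        raise ValueError("prey concentrations must be nonnegative")
    return float(np.sum(z * prey_row))


def annualize_and_standardize(step_values: np.ndarray, frame: StudyFrame,
                              constants: tuple | None = None):
    """Annual means of per-step experienced prey, standardised population-wide.

    ``step_values`` is (n_individuals, T) or (T,).  Annual means are taken over
    each year's four steps; the standardisation constants are the mean and
    sample SD across *all* annual means (individuals x years) unless supplied.
    Returns (standardised (n, n_years) array, (mean, sd)).
    """
    vals = np.atleast_2d(np.asarray(step_values, dtype=float))
    if vals.shape[1] != frame.T:
        raise ValueError("step_values must have T columns")
    annual = vals.reshape(vals.shape[0], frame.n_years, 4).mean(axis=2)
    if constants is None:
        mean = float(np.nanmean(annual))
        sd = float(np.nanstd(annual, ddof=1))
        if not np.isfinite(sd) or sd == 0:
            raise ValueError("degenerate standardisation: SD of annual means is 0")
    else:
        mean, sd = constants
        if sd <= 0:
            raise ValueError("degenerate standardisation: SD must be positive")
    std = (annual - mean) / sd
    if np.asarray(step_values).ndim == 1:
        return std[0], (mean, sd)
    return std, (mean, sd)


# ---------------------------------------------------------------------------
# temporal / spatial extrapolation of the surfaces

def backcast_entanglement_scalars(landings: dict, region_groups: dict,
                                  baseline_years: tuple, frame: StudyFrame,
                                  cutoff_year: int = 2015) -> np.ndarray:
    """Landings-trend backcast multipliers e[l, t].

    ``landings`` maps fishery-group name -> {year: landings}; ``region_groups``
    maps region label -> group name.  For years before ``cutoff_year``,
    e = landings(year, group) / mean landings over the baseline years; from the
    cutoff onward e = 1 (the risk surface itself reflects that period).
    """
    e = np.ones((frame.R, frame.T))
    years = frame.year_of_step(np.arange(frame.T))
    for li, region in enumerate(frame.regions):
        group = region_groups.get(region)
        if group is None:
            continue
        series = landings[group]
        base = np.mean([series[y] for y in range(baseline_years[0], baseline_years[1] + 1)])
        if base <= 0:
            raise ValueError(f"baseline landings for group {group!r} must be positive")
        for t in range(frame.T):
            y = int(years[t])
            if y < cutoff_year and y in series:
                e[li, t] = series[y] / base
    return e


def extrapolate_canadian_entanglement(G: np.ndarray, frame: StudyFrame,
                                      canadian_landings: dict,
                                      us_north_landings: dict,
                                      canadian_regions: list,
                                      northern_us_regions: list) -> np.ndarray:
    """Extend the entanglement-risk surface into regions it does not cover.

    For each listed Canadian region l and step t,
    G_can[l, t] = (sum of G over northern US regions at t)
                  * canadian_landings[l][year] / us_north_landings[year].
    """
    G = np.array(G, dtype=float)
    us_idx = [frame.region_index(r) for r in northern_us_regions]
    years = frame.year_of_step(np.arange(frame.T))
    for region in canadian_regions:
        li = frame.region_index(region)
        series = canadian_landings[region]
        for t in range(frame.T):
            y = int(years[t])
            denom = us_north_landings[y]
            if denom <= 0:
                raise ValueError(f"US northern landings must be positive in {y}")
            G[li, t] = G[us_idx, t].sum() * series.get(y, 0.0) / denom
    return G


def backcast_prey(index_years: np.ndarray, index_values: np.ndarray,
                  anomaly_by_year: dict, predict_years: np.ndarray):
    """Log-linear backcast of the prey index from an abundance-anomaly series.

    Fits log(index) = a + b * anomaly on the overlap years, then predicts
    exp(a + b * anomaly) for ``predict_years``.  Returns (predictions, fit)
    where fit carries the coefficients and in-sample R^2.
    """
    index_years = np.asarray(index_years, dtype=int)
    index_values = np.asarray(index_values, dtype=float)
    if np.any(index_values <= 0):
        raise ValueError("prey index values must be positive for the log-linear fit")
    overlap = [(y, v) for y, v in zip(index_years, index_values) if y in anomaly_by_year]
    if len(overlap) < 5:
        raise ValueError("need at least 5 overlapping years between index and anomalies")
    x = np.array([anomaly_by_year[y] for y, _ in overlap])
    if np.ptp(x) == 0:
        raise ValueError("anomaly series is constant over the overlap: slope unidentifiable")
    ylog = np.log(np.array([v for _, v in overlap]))
    b, a = np.polyfit(x, ylog, 1)
    resid = ylog - (a + b * x)
    r2 = 1.0 - resid.var() / ylog.var()
    missing = [int(y) for y in predict_years if y not in anomaly_by_year]
    if missing:
        raise KeyError(f"no anomaly value for prediction years {missing}")
    preds = np.exp(a + b * np.array([anomaly_by_year[int(y)] for y in predict_years]))
    return preds, {"intercept": float(a), "slope": float(b), "r2": float(r2),
                   "n_overlap": len(overlap)}


# ---------------------------------------------------------------------------
# batch evaluation over a dataset

def exposure_states(z_it: np.ndarray, surfaces, params: ExposureParameters,
                    frame: StudyFrame):
    """Vectorised exposure for stacked occupancy z_it of shape (n, T, R).

    Returns dict with p_ent (n, T), p_strike (n, T), prey_step (n, T),
    prey_std (n, n_years) and the standardisation constants actually used.
    G and AIS are unit-rescaled here; the backcast scalar comes from the
    surface set.
    """
    z_it = np.asarray(z_it, dtype=float)
    n, T, R = z_it.shape
    if (R, T) != (frame.R, frame.T):
        raise ValueError("z_it shape does not match the study frame")
    G = rescale_unit(surfaces.G)
    ais = surfaces.ais
    e = surfaces.ent_scalar
    years = frame.year_of_step(np.arange(frame.T))

    p_ent = params.iota1 * np.einsum("ntr,rt->nt", z_it, G * e)
    if np.any(p_ent > 1):
        raise ValueError("entanglement probability exceeded 1; iota1 outside support")

    p_r = np.zeros((R, T))
    for t in range(T):
        p_r[:, t] = regional_strike_probability(
            ais[:, t], params.iota2, params.v_trend, int(years[t]), params.reference_year)
    p_strike = np.einsum("ntr,rt->nt", z_it, p_r)

    prey_step = np.einsum("ntr,rt->nt", z_it, surfaces.prey)
    constants = None
    if params.prey_sd > 0 and (params.prey_mean != 0.0 or params.prey_sd != 1.0):
        constants = (params.prey_mean, params.prey_sd)
    prey_std, used = annualize_and_standardize(prey_step, frame, constants)
    return {"p_ent": p_ent, "p_strike": p_strike, "regional_strike": p_r,
            "prey_step": prey_step, "prey_std": prey_std, "prey_constants": used}
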