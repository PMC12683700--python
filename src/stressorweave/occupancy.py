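"""Per-individual proportional presence across regions (the occupancy simplex z).

Two formulations are provided, mirroring the sensitivity analysis between a
data-driven and a model-based spatial structure:

* **v1** — a Dirichlet compositional model fitted to per-individual sighting
  fractions, stratified by demographic class x quarter x era (pre/post the
  distribution-shift break year);
* **v2** — occupancy proportional to an external relative-density surface
  (DSM), rescaled by the proportional occurrence of each demographic class per
  region and quarter.  Density predictions are only available from a given
  year onward (default 2003); earlier steps reuse the mean of a reference
  window (default 2003-2009), and data-poor regions (e.g. Canadian polygons)
  can be filled by a sightings-to-abundance ratio against a reference region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma

from .core_data import CLASSES, ObservationSet, StudyFrame

ERAS = ("pre", "post")


# ---------------------------------------------------------------------------
# Dirichlet maximum likelihood (Minka fixed point)

def dirichlet_mle(compositions: np.ndarray, max_iter: int = 500, tol: float = 1e-10) -> np.ndarray:
    """Maximum-likelihood concentration vector for compositions on the simplex.

    Uses the standard fixed-point iteration on the digamma equations, started
    from a moment-matching estimate.  Compositions containing exact zeros must
    be smoothed by the caller first.
    """
    x = np.asarray(compositions, dtype=float)
    if x.ndim != 2:
        raise ValueError("compositions must be (n, R)")
    if np.any(x <= 0):
        raise ValueError("compositions must be strictly positive (apply smoothing first)")
    x = x / x.sum(axis=1, keepdims=True)
    n, R = x.shape
    logp_bar = np.log(x).mean(axis=0)

    # moment matching initialisation
    m = x.mean(axis=0)
    v = x.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.nanmedian((m * (1 - m)) / np.maximum(v, 1e-12) - 1)
    s = float(np.clip(s, 1e-2, 1e6))
    alpha = np.maximum(m * s, 1e-3)

    for _ in range(max_iter):
        new = _inverse_digamma(digamma(alpha.sum()) + logp_bar)
        new = np.maximum(new, 1e-8)
        if np.max(np.abs(new - alpha)) < tol:
            alpha = new
            break
        alpha = new
    return alpha


def _inverse_digamma(y: np.ndarray, n_iter: int = 8) -> np.ndarray:
    """Newton inversion of the digamma function (elementwise)."""
    y = np.asarray(y, dtype=float)
    x = np.where(y >= -2.22, np.exp(y) + 0.5, -1.0 / (y - digamma(1.0)))
    for _ in range(n_iter):
        x = x - (digamma(x) - y) / polygamma(1, x)
        x = np.maximum(x, 1e-10)
    return x


# ---------------------------------------------------------------------------
# v1: stratified Dirichlet occupancy

@dataclass
class DirichletOccupancyModel:
    """Concentration parameters per (class, quarter, era) stratum."""

    frame: StudyFrame
    alpha: dict = field(default_factory=dict)  # (class, quarter, era) -> (R,) array

    def stratum(self, cls: str, quarter: int, era: str) -> np.ndarray:
        key = (cls, int(quarter), era)
        if key not in self.alpha:
            # symmetric prior fallback for strata never fitted
            return np.ones(self.frame.R)
        return self.alpha[key]

    def mean(self, cls: str, quarter: int, era: str) -> np.ndarray:
        a = self.stratum(cls, quarter, era)
        return a / a.sum()


def sighting_compositions(obs: ObservationSet, records: list, frame: StudyFrame,
                          zero_smoothing: float = 0.5,
                          maturity_age: int = 9) -> pd.DataFrame:
    """Per individual x year x quarter region-count compositions from sightings.

    Each individual-quarter with >= 1 sighting yields one composition: region
    sighting counts plus additive smoothing, normalised.  Smoothing keeps all
    components positive (true zero presence is not identifiable from sparse
    sightings).
    """
    rec_by_id = {r.id: r for r in records}
    rows = []
    if len(obs.sightings) == 0:
        return pd.DataFrame(columns=["class", "quarter", "era"] + list(frame.regions))
    df = obs.sightings.copy()
    df["year"] = frame.year_of_step(df["t"].to_numpy())
    df["quarter"] = frame.quarter_of_step(df["t"].to_numpy())
    for (iid, year, quarter), grp in df.groupby(["id", "year", "quarter"]):
        rec = rec_by_id.get(iid)
        if rec is None:
            continue
        t0 = frame.step(int(year), int(quarter))
        counts = np.full(frame.R, zero_smoothing)
        for region in grp["region"]:
            counts[frame.region_index(region)] += 1
        comp = counts / counts.sum()
        rows.append({"class": rec.class_at(t0, frame, maturity_age),
                     "quarter": int(quarter),
                     "era": frame.era_of_step(t0),
                     **{reg: comp[i] for i, reg in enumerate(frame.regions)}})
    return pd.DataFrame(rows)


def fit_dirichlet_occupancy(obs: ObservationSet, records: list, frame: StudyFrame,
                            zero_smoothing: float = 0.5,
                            maturity_age: int = 9) -> DirichletOccupancyModel:
    """Fit the stratified Dirichlet occupancy model (v1).

    Strata with no compositions fall back to a symmetric alpha = 1.  A stratum
    whose compositions are (numerically) identical degenerate vertices gets a
    vertex-concentrated alpha instead of failing.
    """
    comps = sighting_compositions(obs, records, frame, zero_smoothing, maturity_age)
    model = DirichletOccupancyModel(frame=frame)
    if len(comps) == 0:
        return model
    region_cols = list(frame.regions)
    for (cls, quarter, era), grp in comps.groupby(["class", "quarter", "era"]):
        x = grp[region_cols].to_numpy(dtype=float)
        if len(x) < 2 or np.allclose(x.var(axis=0), 0):
            # degenerate stratum: concentrate on the observed mean composition
            m = x.mean(axis=0)
            model.alpha[(cls, int(quarter), era)] = np.maximum(m * 100.0, 1e-3)
            continue
        model.alpha[(cls, int(quarter), era)] = dirichlet_mle(x)
    return model


def occupancy_v1(model: DirichletOccupancyModel, record, t: int,
                 rng: np.random.Generator | None = None,
                 maturity_age: int = 9) -> np.ndarray:
    """Occupancy simplex for one individual at step t under the v1 model.

    Returns the stratum's mean composition (plug-in default), or a draw from
    the fitted Dirichlet when an ``rng`` is supplied.
    """
    frame = model.frame
    cls = record.class_at(t, frame, maturity_age)
    quarter = int(frame.quarter_of_step(t))
    era = frame.era_of_step(t)
    if rng is None:
        return model.mean(cls, quarter, era)
    return rng.dirichlet(model.stratum(cls, quarter, era))


# ---------------------------------------------------------------------------
# v2: density-surface occupancy

def canadian_dsm_fill(dsm: np.ndarray, obs: ObservationSet, frame: StudyFrame,
                      canadian_regions: list, reference_region: str) -> np.ndarray:
    """Fill data-poor regions of a density surface by sightings-ratio scaling.

    The relative abundance of each listed region is inferred as the reference
    region's modeled abundance times the ratio of sightings in that region to
    sightings in the reference region, per quarter.
    """
    dsm = np.array(dsm, dtype=float)
    ref = frame.region_index(reference_region)
    sight = obs.sightings
    if len(sight) == 0:
        return dsm
    q_of = frame.quarter_of_step(sight["t"].to_numpy())
    for region in canadian_regions:
        li = frame.region_index(region)
        for q in range(4):
            in_q = q_of == q
            n_can = np.sum(in_q & (sight["region"] == region).to_numpy())
            n_ref = np.sum(in_q & (sight["region"] == reference_region).to_numpy())
            ratio = (n_can / n_ref) if n_ref > 0 else 0.0
            steps = np.arange(frame.T)[frame.quarter_of_step(np.arange(frame.T)) == q]
            dsm[li, steps] = dsm[ref, steps] * ratio
    return dsm


def occupancy_v2(surfaces, class_props: np.ndarray, frame: StudyFrame,
                 dsm_start_year: int = 2003,
                 backfill_period: tuple = (2003, 2009)) -> np.ndarray:
    """Class-level occupancy from a relative-density surface (v2).

    ``class_props`` is (n_classes, 4, R): the proportional occurrence of each
    demographic class per quarter and region.  For each class c and step t,
    z[t, c, l] ~ DSM[l, t] * class_props[c, quarter(t), l], normalised over l.
    Steps before ``dsm_start_year`` reuse the class's mean occupancy over the
    backfill period for the same quarter.

    Returns z of shape (T, n_classes, R).
    """
    dsm = frame.check_shape(surfaces.dsm if hasattr(surfaces, "dsm") else surfaces, "dsm")
    class_props = np.asarray(class_props, dtype=float)
    n_classes = class_props.shape[0]
    if class_props.shape != (n_classes, 4, frame.R):
        raise ValueError("class_props must have shape (n_classes, 4, R)")

    z = np.zeros((frame.T, n_classes, frame.R))
    years = frame.year_of_step(np.arange(frame.T))
    quarters = frame.quarter_of_step(np.arange(frame.T))
    for t in range(frame.T):
        if years[t] < dsm_start_year:
            continue
        for c in range(n_classes):
            w = dsm[:, t] * class_props[c, quarters[t], :]
            total = w.sum()
            if total <= 0:
                raise ValueError(f"all-zero occupancy weight for class {c} at step {t}")
            z[t, c, :] = w / total

    # pre-DSM backfill: mean over the reference window, per class x quarter
    y0, y1 = backfill_period
    for q in range(4):
        window = [t for t in range(frame.T) if y0 <= years[t] <= y1 and quarters[t] == q]
        if not window:
            raise ValueError(f"backfill period {backfill_period} has no steps for quarter {q}")
        mean_z = z[window].mean(axis=0)  # (n_classes, R)
        mean_z = mean_z / mean_z.sum(axis=1, keepdims=True)
        for t in range(frame.T):
            if years[t] < dsm_start_year and quarters[t] == q:
                z[t] = mean_z
    return z


def empirical_class_props(obs: ObservationSet, records: list, frame: StudyFrame,
                          smoothing: float = 0.5, maturity_age: int = 9) -> np.ndarray:
    """Proportional occurrence of demographic classes per quarter x region from sightings."""
    counts = np.full((len(CLASSES), 4, frame.R), smoothing)
    rec_by_id = {r.id: r for r in records}
    for _, row in obs.sightings.iterrows():
        rec = rec_by_id.get(row["id"])
        if rec is None:
            continue
        t = int(row["t"])
        c = CLASSES.index(rec.class_at(t, frame, maturity_age))
        counts[c, int(frame.quarter_of_step(t)), frame.region_index(row["region"])] += 1
    return counts / counts.sum(axis=0, keepdims=True)
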