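"""Shared data model for the multi-stressor state-space analysis.

This module defines the study frame (regions x quarterly seasons x years),
the container for regional stressor surfaces, per-individual demographic
records, the observation tables, file readers/writers, and run-configuration
handling.  Everything downstream (occupancy, exposure, health, growth, vital
rates, inference, projection) indexes space and time through the conventions
fixed here:

* regions are categorical labels (default seven coastal polygons used for
  North Atlantic right whales: SEUS, MIDA, SNE, CCB, NEUS, GSL, MAR);
* the year is divided into four seasons (Dec-Feb, Mar-May, Jun-Aug, Sep-Nov),
  with Dec-Feb assigned to the calendar year containing January;
* time steps t = 0 .. T-1 enumerate year x quarter cells in chronological
  order, T = 4 x number of years;
* an "era" break year splits the study period into a pre/post regime
  (default 2010), capturing the documented distribution shift.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

# ---------------------------------------------------------------------------
# labels and enumerations

DEFAULT_REGIONS = ("SEUS", "MIDA", "SNE", "CCB", "NEUS", "GSL", "MAR")
DEFAULT_QUARTERS = ("Dec-Feb", "Mar-May", "Jun-Aug", "Sep-Nov")
JUN_AUG = 2  # quarter index at which the annual prey effect enters health

SEVERITIES = ("minor", "moderate", "severe")
INJURIES = ("superficial", "shallow", "deep", "blunt")

CALF = "calf"
JUVENILE = "juvenile"
ADULT_MALE = "adult male"
ADULT_FEMALE = "adult female"
CLASSES = (CALF, JUVENILE, ADULT_MALE, ADULT_FEMALE)

SURFACE_VARIABLES = ("G", "ent_scalar", "ais", "prey", "dsm")


# ---------------------------------------------------------------------------
# study frame

@dataclass(frozen=True)
class StudyFrame:
    """Region / season / year indexing frame shared by every array in the package."""

    regions: tuple = DEFAULT_REGIONS
    quarters: tuple = DEFAULT_QUARTERS
    start_year: int = 1970
    end_year: int = 2019
    era_break_year: int = 2010

    def __post_init__(self):
        object.__setattr__(self, "regions", tuple(self.regions))
        object.__setattr__(self, "quarters", tuple(self.quarters))
        if len(self.regions) < 2:
            raise ValueError("a StudyFrame needs at least 2 regions")
        if len(set(self.regions)) != len(self.regions):
            raise ValueError("region labels must be unique")
        if len(self.quarters) != 4:
            raise ValueError("exactly 4 quarterly seasons are required")
        if self.end_year < self.start_year:
            raise ValueError("end_year before start_year")

    # -- sizes ------------------------------------------------------------
    @property
    def R(self) -> int:
        return len(self.regions)

    @property
    def n_years(self) -> int:
        return self.end_year - self.start_year + 1

    @property
    def T(self) -> int:
        return 4 * self.n_years

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.end_year + 1)

    # -- index mapping ----------------------------------------------------
    def region_index(self, label: str) -> int:
        try:
            return self.regions.index(label)
        except ValueError:
            raise KeyError(f"unknown region {label!r}; known: {self.regions}") from None

    def quarter_index(self, label: str) -> int:
        try:
            return self.quarters.index(label)
        except ValueError:
            raise KeyError(f"unknown quarter {label!r}; known: {self.quarters}") from None

    def step(self, year: int, quarter) -> int:
        """Map (year, quarter) to the step index t.

        ``quarter`` may be a season label or an integer 0..3.  Dec-Feb belongs
        to the year containing its January.
        """
        q = quarter if isinstance(quarter, (int, np.integer)) else self.quarter_index(quarter)
        if not (0 <= q < 4):
            raise KeyError(f"quarter index {q} out of range")
        if not (self.start_year <= year <= self.end_year):
            raise KeyError(f"year {year} outside {self.start_year}-{self.end_year}")
        return (year - self.start_year) * 4 + q

    def year_of_step(self, t) -> np.ndarray:
        return self.start_year + np.asarray(t) // 4

    def quarter_of_step(self, t) -> np.ndarray:
        return np.asarray(t) % 4

    def era_of_step(self, t):
        """'pre' before the era break year, 'post' from it onward (vectorised)."""
        pre = self.year_of_step(t) < self.era_break_year
        if np.ndim(pre) == 0:
            return "pre" if pre else "post"
        return np.where(pre, "pre", "post")

    def steps_of_year(self, year: int) -> np.ndarray:
        t0 = self.step(year, 0)
        return np.arange(t0, t0 + 4)

    def check_shape(self, arr: np.ndarray, name: str = "array") -> np.ndarray:
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (self.R, self.T):
            raise ValueError(
                f"{name} has shape {arr.shape}, expected (R, T) = ({self.R}, {self.T})"
            )
        return arr


# ---------------------------------------------------------------------------
# regional stressor surfaces

@dataclass
class RegionalSurfaceSet:
    """Dense (R, T) surfaces: entanglement risk G, landings backcast scalar,
    vessel-traffic (AIS) risk, prey concentration (g/m^3), and relative whale
    density (DSM)."""

    frame: StudyFrame
    G: np.ndarray
    ent_scalar: np.ndarray
    ais: np.ndarray
    prey: np.ndarray
    dsm: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in SURFACE_VARIABLES:
            arr = self.frame.check_shape(getattr(self, self._attr(name)), name)
            if np.any(arr < 0):
                bad = np.argwhere(arr < 0)[0]
                raise ValueError(f"negative value in surface {name} at (region={bad[0]}, t={bad[1]})")
            setattr(self, self._attr(name), arr)
        if np.any(self.ais > 1.0 + 1e-12):
            raise ValueError("ais surface must be rescaled to [0, 1]")

    @staticmethod
    def _attr(variable: str) -> str:
        return {"G": "G", "ent_scalar": "ent_scalar", "ais": "ais",
                "prey": "prey", "dsm": "dsm"}[variable]

    def array(self, variable: str) -> np.ndarray:
        return getattr(self, self._attr(variable))


def rescale_unit(arr: np.ndarray) -> np.ndarray:
    """Rescale a nonnegative surface to [0, 1] by its global maximum.

    Dividing by the single global max over (region, t) preserves relative
    spatiotemporal structure; an all-zero surface is returned unchanged.
    """
    arr = np.asarray(arr, dtype=float)
    if np.any(arr < 0):
        raise ValueError("cannot rescale a surface with negative entries")
    m = arr.max()
    return arr if m == 0 else arr / m


# ---------------------------------------------------------------------------
# individuals and observations

@dataclass
class EntanglementEvent:
    step: int
    severity: str          # minor | moderate | severe
    gear_steps: int = 1    # steps carrying gear, event step included

    def __post_init__(self):
        if self.severity not in SEVERITIES:
            raise ValueError(f"unknown entanglement severity {self.severity!r}; allowed: {SEVERITIES}")
        if self.gear_steps < 1:
            raise ValueError("gear_steps must be >= 1 (the event step itself)")


@dataclass
class StrikeEvent:
    step: int
    injury: str  # superficial | shallow | deep | blunt

    def __post_init__(self):
        if self.injury not in INJURIES:
            raise ValueError(f"unknown strike injury {self.injury!r}; allowed: {INJURIES}")


@dataclass
class IndividualRecord:
    """Demographic covariates and event history of one whale."""

    id: str
    sex: str                      # 'F' or 'M'
    birth_year: int | None        # None when unknown
    first_step: int
    last_step: int                # last sighting step
    death_step: int | None = None
    death_cause: str | None = None   # 'entanglement' | 'strike' | 'other' | None
    entanglements: list = field(default_factory=list)
    strikes: list = field(default_factory=list)
    calving_years: list = field(default_factory=list)

    def __post_init__(self):
        if self.sex not in ("F", "M"):
            raise ValueError(f"sex must be 'F' or 'M', got {self.sex!r}")
        if self.death_step is not None and self.last_step > self.death_step:
            raise ValueError(
                f"individual {self.id}: sighting at step {self.last_step} "
                f"after recorded death at step {self.death_step}"
            )

    def birth_step(self, frame: StudyFrame) -> int | None:
        """Step index of the birth quarter; negative for pre-study births."""
        if self.birth_year is None:
            return None
        return (self.birth_year - frame.start_year) * 4

    def age_years(self, t: int, frame: StudyFrame) -> float | None:
        """Age in years at step t (quarter resolution); None when birth year unknown."""
        if self.birth_year is None:
            return None
        return (frame.year_of_step(t) - self.birth_year) + frame.quarter_of_step(t) / 4.0

    def class_at(self, t: int, frame: StudyFrame, maturity_age: int = 9) -> str:
        age = self.age_years(t, frame)
        if age is None:
            # unknown birth year: treated as adult (conservative default)
            return ADULT_FEMALE if self.sex == "F" else ADULT_MALE
        if age < 1:
            return CALF
        if age < maturity_age:
            return JUVENILE
        return ADULT_FEMALE if self.sex == "F" else ADULT_MALE

    def lactating(self, t: int, frame: StudyFrame) -> bool:
        """Lactation during the four quarters of a calving year (adult females)."""
        return self.sex == "F" and int(frame.year_of_step(t)) in self.calving_years

    def carrying_gear(self, t: int) -> bool:
        return any(ev.step <= t < ev.step + ev.gear_steps for ev in self.entanglements)


@dataclass
class ObservationSet:
    """Tabular observation streams masking the latent process.

    All tables are plain pandas DataFrames keyed by individual id:

    * ``sightings``: id, t, region
    * ``vha``: id, t, variable, score   (ordinal visual-health scores)
    * ``lengths``: id, t, length_m, platform  (aircraft | drone)
    * ``entanglements``: id, step, severity, gear_steps
    * ``strikes``: id, step, injury
    * ``calvings``: id, year, calved
    * ``deaths``: id, step, cause
    """

    sightings: pd.DataFrame
    vha: pd.DataFrame
    lengths: pd.DataFrame
    entanglements: pd.DataFrame
    strikes: pd.DataFrame
    calvings: pd.DataFrame
    deaths: pd.DataFrame

    TABLES = ("sightings", "vha", "lengths", "entanglements", "strikes", "calvings", "deaths")
    _COLUMNS = {
        "sightings": ["id", "t", "region"],
        "vha": ["id", "t", "variable", "score"],
        "lengths": ["id", "t", "length_m", "platform"],
        "entanglements": ["id", "step", "severity", "gear_steps"],
        "strikes": ["id", "step", "injury"],
        "calvings": ["id", "year", "calved"],
        "deaths": ["id", "step", "cause"],
    }

    def __post_init__(self):
        for name in self.TABLES:
            df = getattr(self, name)
            cols = self._COLUMNS[name]
            missing = [c for c in cols if c not in df.columns]
            if missing:
                raise ValueError(f"table {name} missing columns {missing}")
            setattr(self, name, df[cols].reset_index(drop=True))
        bad_sev = set(self.entanglements["severity"]) - set(SEVERITIES)
        if bad_sev:
            raise ValueError(f"unknown entanglement severity labels {sorted(bad_sev)}")
        bad_inj = set(self.strikes["injury"]) - set(INJURIES)
        if bad_inj:
            raise ValueError(f"unknown strike injury labels {sorted(bad_inj)}")
        if len(self.lengths) and (self.lengths["length_m"] <= 0).any():
            raise ValueError("photogrammetric lengths must be positive")

    def validate_against(self, records: list):
        """Cross-table invariants: no sightings after a recorded death."""
        deaths = {r.id: r.death_step for r in records if r.death_step is not None}
        for _, row in self.sightings.iterrows():
            d = deaths.get(row["id"])
            if d is not None and row["t"] > d:
                raise ValueError(
                    f"sighting of {row['id']} at step {int(row['t'])} after death at step {d}"
                )

    @staticmethod
    def empty() -> "ObservationSet":
        return ObservationSet(**{
            name: pd.DataFrame(columns=cols)
            for name, cols in ObservationSet._COLUMNS.items()
        })


# ---------------------------------------------------------------------------
# surface IO

def write_surfaces(surfaces: RegionalSurfaceSet, path) -> None:
    """Write a surface set as a long-format CSV (region, year, quarter, variable, value)."""
    frame = surfaces.frame
    rows = []
    for var in SURFACE_VARIABLES:
        arr = surfaces.array(var)
        for li, region in enumerate(frame.regions):
            for t in range(frame.T):
                rows.append((region, int(frame.year_of_step(t)),
                             frame.quarters[int(frame.quarter_of_step(t))], var, arr[li, t]))
    pd.DataFrame(rows, columns=["region", "year", "quarter", "variable", "value"]).to_csv(
        path, index=False)


def read_surfaces(path, frame: StudyFrame, fill: str = "region_season_mean") -> RegionalSurfaceSet:
    """Read a long-format surface table into dense (R, T) arrays.

    Missing cells are filled according to ``fill``:

    * ``"region_season_mean"`` (default): the mean of the same region x quarter
      over the years where the cell is observed (a simple climatology);
    * ``"error"``: raise on any missing cell.

    The policy and the list of filled cells are recorded in the result's metadata.
    """
    df = pd.read_csv(path)
    required = {"region", "year", "quarter", "variable", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"surface table needs columns {sorted(required)}")
    unknown_r = set(df["region"]) - set(frame.regions)
    if unknown_r:
        raise KeyError(f"unknown region labels {sorted(unknown_r)}")
    unknown_q = set(df["quarter"]) - set(frame.quarters)
    if unknown_q:
        raise KeyError(f"unknown quarter labels {sorted(unknown_q)}")
    unknown_v = set(df["variable"]) - set(SURFACE_VARIABLES)
    if unknown_v:
        raise KeyError(f"unknown surface variables {sorted(unknown_v)}")
    neg = df[df["value"] < 0]
    if len(neg):
        row = neg.iloc[0]
        raise ValueError(
            f"negative value {row['value']} at (region={row['region']}, year={row['year']}, "
            f"quarter={row['quarter']}, variable={row['variable']})"
        )
    dup = df.duplicated(subset=["region", "year", "quarter", "variable"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(
            f"duplicate cell (region={row['region']}, year={row['year']}, "
            f"quarter={row['quarter']}, variable={row['variable']})"
        )

    arrays = {}
    filled = []
    for var in SURFACE_VARIABLES:
        arr = np.full((frame.R, frame.T), np.nan)
        sub = df[df["variable"] == var]
        li = sub["region"].map(frame.region_index).to_numpy()
        tt = [frame.step(int(y), q) for y, q in zip(sub["year"], sub["quarter"])]
        arr[li, tt] = sub["value"].to_numpy()
        if np.isnan(arr).any():
            if fill == "error":
                bad = np.argwhere(np.isnan(arr))[0]
                raise ValueError(f"missing cell in {var} at (region={bad[0]}, t={bad[1]})")
            # region-season climatology
            by_season = arr.reshape(frame.R, frame.n_years, 4)
            clim = np.nanmean(by_season, axis=1)  # (R, 4)
            miss = np.argwhere(np.isnan(arr))
            for li0, t0 in miss:
                q0 = t0 % 4
                if np.isnan(clim[li0, q0]):
                    raise ValueError(
                        f"cannot fill {var} at (region={li0}, t={t0}): "
                        f"no observed year for that region-season"
                    )
                arr[li0, t0] = clim[li0, q0]
                filled.append({"variable": var, "region": frame.regions[li0], "t": int(t0)})
        arrays[var] = arr

    meta = {"fill_policy": fill, "filled_cells": filled, "source": str(path)}
    return RegionalSurfaceSet(frame=frame, G=arrays["G"], ent_scalar=arrays["ent_scalar"],
                              ais=arrays["ais"], prey=arrays["prey"], dsm=arrays["dsm"],
                              metadata=meta)


# ---------------------------------------------------------------------------
# individual / observation IO

def write_individuals(records: list, obs: ObservationSet, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for r in records:
        rows.append({
            "id": r.id, "sex": r.sex,
            "birth_year": "" if r.birth_year is None else r.birth_year,
            "first_step": r.first_step, "last_step": r.last_step,
            "death_step": "" if r.death_step is None else r.death_step,
            "death_cause": "" if r.death_cause is None else r.death_cause,
        })
    pd.DataFrame(rows, columns=["id", "sex", "birth_year", "first_step", "last_step",
                                "death_step", "death_cause"]).to_csv(
        directory / "individuals.csv", index=False)
    for name in ObservationSet.TABLES:
        getattr(obs, name).to_csv(directory / f"{name}.csv", index=False)


def read_individuals(directory, frame: StudyFrame):
    """Read the individuals table plus observation tables written by ``write_individuals``.

    Returns (records, observations).  Individuals with unknown birth year keep
    ``birth_year=None`` (no imputation here).  Raises if a sighting postdates a
    recorded death or an event label is unknown.
    """
    directory = Path(directory)
    ind = pd.read_csv(directory / "individuals.csv", dtype={"id": str})
    tables = {}
    for name in ObservationSet.TABLES:
        p = directory / f"{name}.csv"
        if p.exists():
            tables[name] = pd.read_csv(p, dtype={"id": str})
        else:
            tables[name] = pd.DataFrame(columns=ObservationSet._COLUMNS[name])
    obs = ObservationSet(**tables)

    records = []
    for _, row in ind.iterrows():
        rid = str(row["id"])
        ents = [EntanglementEvent(int(e["step"]), e["severity"], int(e["gear_steps"]))
                for _, e in obs.entanglements[obs.entanglements["id"] == rid].iterrows()]
        strikes = [StrikeEvent(int(s["step"]), s["injury"])
                   for _, s in obs.strikes[obs.strikes["id"] == rid].iterrows()]
        calvings = [int(y) for y in
                    obs.calvings[(obs.calvings["id"] == rid) & (obs.calvings["calved"] == 1)]["year"]]
        records.append(IndividualRecord(
            id=rid, sex=row["sex"],
            birth_year=None if pd.isna(row["birth_year"]) or row["birth_year"] == ""
            else int(row["birth_year"]),
            first_step=int(row["first_step"]), last_step=int(row["last_step"]),
            death_step=None if pd.isna(row["death_step"]) or row["death_step"] == ""
            else int(row["death_step"]),
            death_cause=None if pd.isna(row.get("death_cause", np.nan)) or row.get("death_cause") == ""
            else str(row["death_cause"]),
            entanglements=ents, strikes=strikes, calving_years=calvings,
        ))
    obs.validate_against(records)
    return records, obs


# ---------------------------------------------------------------------------
# run configuration

DEFAULT_CONFIG = {
    "frame": {
        "regions": list(DEFAULT_REGIONS),
        "quarters": list(DEFAULT_QUARTERS),
        "start_year": 1970,
        "end_year": 2019,
        "era_break_year": 2010,
    },
    "occupancy": {
        "version": "v1",
        "zero_smoothing": 0.5,       # additive count smoothing before Dirichlet fitting
        "dsm_backfill_period": [2003, 2009],
        "canadian_regions": ["GSL", "MAR"],
        "reference_us_region": "NEUS",
    },
    "exposure": {
        "reference_year": 2019,      # AIS surface anchor year
        "ent_scalar_cutoff_year": 2015,
        "northern_us_regions": ["NEUS", "CCB", "SNE"],
    },
    "health": {
        "floor": 0.01,
        "ceiling": 100.0,
        "h_ref": 70.0,
        "maturity_age": 9,
        "min_calving_interval": 2,
        "vha_variables": 4,
        "vha_categories": 3,
    },
    "growth": {
        "birth_year_ref": 1980,
        "length_ref": 13.0,
    },
    "mcmc": {
        "n_iter": 1500,
        "warmup": 500,
        "chains": 2,
        "seed": 0,
    },
    "scenario": {
        "entanglement_multipliers": [1.0, 0.5, 0.0],
        "prey_regimes": ["historical", "low"],
        "length_regimes": ["decline", "stabilize", "recover"],
        "horizon_years": 100,
        "n_draws": 1000,
    },
}


def _merge_config(defaults: dict, user: dict, path: str = "") -> dict:
    out = {}
    for key, dval in defaults.items():
        if isinstance(dval, dict):
            out[key] = _merge_config(dval, user.get(key, {}) or {}, f"{path}{key}.")
        else:
            out[key] = user.get(key, dval)
    unknown = set(user) - set(defaults)
    if unknown:
        raise KeyError(
            f"unknown configuration key(s) {sorted(path + k for k in unknown)}; "
            f"valid keys at this level: {sorted(path + k for k in defaults)}"
        )
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Load a YAML run configuration, applying documented defaults fail-closed.

    Unknown keys at any nesting level raise a ``KeyError`` listing the valid
    alternatives, so a misspelled key can never silently fall back to a default.
    """
    user = {}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
    if overrides:
        user = _merge_shallow(user, overrides)
    return _merge_config(DEFAULT_CONFIG, user)


def _merge_shallow(base: dict, extra: dict) -> dict:
    out = dict(base)
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge_shallow(out[k], v)
        else:
            out[k] = v
    return out


def frame_from_config(config: dict) -> StudyFrame:
    fc = config["frame"]
    return StudyFrame(regions=tuple(fc["regions"]), quarters=tuple(fc["quarters"]),
                      start_year=fc["start_year"], end_year=fc["end_year"],
                      era_break_year=fc["era_break_year"])
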