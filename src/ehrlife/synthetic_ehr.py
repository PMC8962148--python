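"""Synthetic electronic-health-record (EHR) cohorts for studying immortal time bias.

The generator emulates a primary-care research database in which a rare
*life-long* condition (present from birth) is recorded with a delay: the first
diagnosis appears on the record some years after the patient becomes
observable, recording intensity surges inside a policy-driven calendar window,
the written diagnosis date is sometimes backdated to the date of birth, and the
administrative "system date" attached to the diagnosis is sometimes overwritten
by later events (transfers, software updates), occasionally even after the
patient has died or left the practice.  Follow-up during which the condition
exists but has not yet been recorded is *immortal*: by construction no death
can be observed in it once analysis is conditioned on the recorded diagnosis.

Patients are emitted as a :class:`pandas.DataFrame`, one row per person, with a
hidden ``true_exposed`` column recording exposure in truth (people who die
before their condition is ever recorded look unexposed to the analysis; the
truth column exists only so oracle computations in tests can see through the
recording process — analysis code must never read it).

All dates are whole days; durations in years are days / 365.25; intervals are
half-open ``[start, end)``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

DAYS_PER_YEAR = 365.25

#: sentinel day number used internally for "no date / far future"
FAR_FUTURE_DAY = int(np.datetime64("2500-01-01", "D").astype("int64"))

#: latest representable death date (datetime64[ns] cannot reach past 2262);
#: lifetimes running beyond it are truncated here, far outside any analysis
MAX_DATE_DAY = int(np.datetime64("2250-01-01", "D").astype("int64"))

#: column order of the patient table (the external CSV interface)
PATIENT_COLUMNS = (
    "patient_id",
    "birth_date",
    "registration_date",
    "uts_date",
    "transfer_out_date",
    "last_collection_date",
    "death_date",
    "exposed",
    "first_diagnosis_date",
    "first_diagnosis_sysdate",
    "true_exposed",
)

_DATE_COLUMNS = (
    "birth_date",
    "registration_date",
    "uts_date",
    "transfer_out_date",
    "last_collection_date",
    "death_date",
    "first_diagnosis_date",
    "first_diagnosis_sysdate",
)

# number of uniform variates reserved per patient (one column per decision)
_N_UNIFORMS = 10
_U_EXPOSED, _U_BIRTH, _U_REG, _U_UTS, _U_DEATH, _U_TRANSFER = range(6)
_U_DELAY, _U_BACKDATE, _U_SYS_BRANCH, _U_SYS_POS = range(6, 10)


class ConfigError(ValueError):
    """Invalid scenario or analysis configuration; message names the field."""


class PatientTableError(ValueError):
    """Malformed or invariant-violating patient table; message names the row."""


# ---------------------------------------------------------------------------
# date helpers
# ---------------------------------------------------------------------------

def to_day_number(value: Any) -> int:
    """Convert a date-like value (ISO string, date, Timestamp) to days since 1970-01-01."""
    return int(np.datetime64(pd.Timestamp(value).date(), "D").astype("int64"))


def day_to_datetime(days: np.ndarray | int) -> np.ndarray:
    """Convert integer day numbers to numpy datetime64[ns] (vectorised)."""
    return np.asarray(days, dtype="int64").astype("datetime64[D]").astype("datetime64[ns]")


def date_col_to_days(col: pd.Series, missing: int = FAR_FUTURE_DAY) -> np.ndarray:
    """Datetime series -> int64 day numbers, NaT mapped to ``missing``."""
    vals = col.values.astype("datetime64[D]").astype("int64")
    out = np.where(col.isna().values, np.int64(missing), vals)
    return out.astype("int64")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnalysisSettings:
    """Settings shared by the cohort-construction and life-table analysis.

    ``periods`` are closed calendar-year intervals (start year, end year); the
    exclusive period boundary is 1 Jan of the following year.  ``band_starts``
    are the abridged life-table age-band starts in years; the last band is
    open-ended.  ``a_fraction`` is Chiang's fraction of the interval lived by
    those dying in it.
    """

    study_start: str = "2000-01-01"
    study_end: str = "2019-09-29"
    min_age: float = 10.0
    periods: tuple[tuple[int, int], ...] = (
        (2000, 2004),
        (2005, 2009),
        (2010, 2014),
        (2015, 2019),
    )
    band_starts: tuple[float, ...] = tuple(float(x) for x in range(10, 95, 5))
    match_ratio: int = 10
    match_window_days: int = 150
    match_unique_controls: bool = True
    alpha: float = 0.05
    a_fraction: float = 0.5
    radix: float = 100_000.0

    # -- derived helpers ----------------------------------------------------
    @property
    def study_start_day(self) -> int:
        return to_day_number(self.study_start)

    @property
    def study_end_day(self) -> int:
        return to_day_number(self.study_end)

    def period_label(self, period: tuple[int, int]) -> str:
        return f"{period[0]}-{period[1]}"

    def normalize_period(self, period: Any) -> tuple[int, int]:
        """Accept (y0, y1) tuples or 'y0-y1' labels."""
        if isinstance(period, str):
            y0, y1 = period.split("-")
            period = (int(y0), int(y1))
        period = (int(period[0]), int(period[1]))
        if period not in tuple(tuple(p) for p in self.periods):
            raise ConfigError(f"periods: {period} is not a configured calendar period")
        return period

    def period_bounds(self, period: tuple[int, int]) -> tuple[int, int]:
        """(inclusive start day, exclusive end day) of a calendar period."""
        y0, y1 = period
        return to_day_number(f"{y0}-01-01"), to_day_number(f"{y1 + 1}-01-01")

    def validate(self) -> "AnalysisSettings":
        if self.study_start_day >= self.study_end_day:
            raise ConfigError("study_start: must precede study_end")
        if self.min_age < 0:
            raise ConfigError("min_age: must be >= 0")
        for p in self.periods:
            if len(p) != 2 or p[0] > p[1]:
                raise ConfigError(f"periods: bad period {p!r}")
        starts = [p[0] for p in self.periods]
        if sorted(starts) != starts:
            raise ConfigError("periods: must be sorted")
        bands = tuple(self.band_starts)
        if len(bands) < 1 or any(b1 <= b0 for b0, b1 in zip(bands, bands[1:])):
            raise ConfigError("band_starts: must be strictly increasing")
        if bands[0] != self.min_age:
            raise ConfigError("band_starts: first band start must equal min_age")
        if self.match_ratio < 1:
            raise ConfigError("match_ratio: must be >= 1")
        if self.match_window_days < 0:
            raise ConfigError("match_window_days: must be >= 0")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha: must be in (0, 1)")
        if not 0 < self.a_fraction < 1:
            raise ConfigError("a_fraction: must be in (0, 1)")
        if self.radix <= 0:
            raise ConfigError("radix: must be > 0")
        return self


_DELAY_FAMILIES = {"exponential": ("mean_years",), "fixed": ("delay_years",)}
_UTS_FAMILIES = {"constant": ("days",), "uniform": ("low_days", "high_days")}


@dataclass(frozen=True)
class ScenarioConfig:
    """Full parameterisation of the synthetic data-generating process.

    The defaults describe the study conditions emulated throughout: a ~3%
    prevalent life-long exposure carrying excess mortality, a 2000–2019 study
    window, exponential diagnosis-recording delays with a five-fold recording
    surge over 2004–2008 (mirroring primary-care incentive programmes),
    occasional backdating of the written diagnosis date to the date of birth,
    and frequent administrative overwrites of the diagnosis system date.
    """

    n_patients: int = 50_000
    exposure_prevalence: float = 0.03
    baseline_hazard: tuple[tuple[float, float], ...] = (
        (0.0, 0.0015),
        (10.0, 0.0003),
        (20.0, 0.0006),
        (30.0, 0.0010),
        (40.0, 0.0020),
        (50.0, 0.0045),
        (60.0, 0.0110),
        (70.0, 0.0280),
        (80.0, 0.0700),
        (90.0, 0.1800),
    )
    exposure_rate_ratio: float = 2.5
    birth_window: tuple[str, str] = ("1920-01-01", "2009-09-28")
    registration_window: tuple[str, str] = ("1985-01-01", "2019-09-29")
    uts_offset_distribution: Mapping[str, Any] = field(
        default_factory=lambda: {"family": "constant", "days": 0}
    )
    diagnosis_delay_distribution: Mapping[str, Any] = field(
        default_factory=lambda: {"family": "exponential", "mean_years": 3.0}
    )
    surge_window: tuple[str, str] = ("2004-01-01", "2008-12-31")
    surge_multiplier: float = 5.0
    backdating_probability: float = 0.15
    sysdate_overwrite_probability: float = 0.60
    sysdate_post_exit_probability: float = 0.02
    transfer_out_rate: float = 0.05
    seed: int = 0
    analysis: AnalysisSettings = field(default_factory=AnalysisSettings)

    # -- validation ---------------------------------------------------------
    def validate(self) -> "ScenarioConfig":
        if self.n_patients < 0:
            raise ConfigError("n_patients: must be >= 0")
        for name in (
            "exposure_prevalence",
            "backdating_probability",
            "sysdate_overwrite_probability",
            "sysdate_post_exit_probability",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}: probability must be in [0, 1]")
        if self.sysdate_overwrite_probability + self.sysdate_post_exit_probability > 1.0:
            raise ConfigError(
                "sysdate_overwrite_probability: overwrite and post-exit "
                "probabilities must sum to at most 1"
            )
        if self.exposure_rate_ratio < 0:
            raise ConfigError("exposure_rate_ratio: must be >= 0")
        if self.transfer_out_rate < 0:
            raise ConfigError("transfer_out_rate: must be >= 0")
        if self.surge_multiplier < 0:
            raise ConfigError("surge_multiplier: must be >= 0")
        self.analysis.validate()

        hz = tuple(self.baseline_hazard)
        if not hz:
            raise ConfigError("baseline_hazard: at least one age band is required")
        starts = [s for s, _ in hz]
        if sorted(starts) != starts or len(set(starts)) != len(starts):
            raise ConfigError("baseline_hazard: band starts must be strictly increasing")
        if starts[0] > self.analysis.min_age:
            raise ConfigError("baseline_hazard: first band must start at or below min_age")
        if any(r < 0 for _, r in hz):
            raise ConfigError("baseline_hazard: rates must be >= 0")

        b_lo, b_hi = (to_day_number(d) for d in self.birth_window)
        if b_lo > b_hi:
            raise ConfigError("birth_window: earliest date must not exceed latest")
        r_lo, r_hi = (to_day_number(d) for d in self.registration_window)
        if r_lo > r_hi:
            raise ConfigError("registration_window: earliest date must not exceed latest")
        s_lo, s_hi = (to_day_number(d) for d in self.surge_window)
        if s_lo > s_hi:
            raise ConfigError("surge_window: start must not exceed end")
        a = self.analysis
        if s_lo < a.study_start_day or s_hi > a.study_end_day:
            raise ConfigError("surge_window: must lie within the study window")

        self._validate_dist("uts_offset_distribution", _UTS_FAMILIES)
        self._validate_dist("diagnosis_delay_distribution", _DELAY_FAMILIES)
        d = self.diagnosis_delay_distribution
        if d["family"] == "exponential" and d["mean_years"] <= 0:
            raise ConfigError("diagnosis_delay_distribution: mean_years must be > 0")
        if d["family"] == "fixed" and d["delay_years"] < 0:
            raise ConfigError("diagnosis_delay_distribution: delay_years must be >= 0")
        u = self.uts_offset_distribution
        if u["family"] == "uniform" and u["low_days"] > u["high_days"]:
            raise ConfigError("uts_offset_distribution: low_days must not exceed high_days")
        return self

    def _validate_dist(self, name: str, families: Mapping[str, tuple[str, ...]]) -> None:
        d = getattr(self, name)
        if not isinstance(d, Mapping) or "family" not in d:
            raise ConfigError(f"{name}: expected a mapping with a 'family' key")
        fam = d["family"]
        if fam not in families:
            raise ConfigError(f"{name}: unknown family {fam!r} (allowed: {sorted(families)})")
        expected = set(families[fam]) | {"family"}
        if set(d) != expected:
            raise ConfigError(f"{name}: family {fam!r} takes parameters {sorted(expected - {'family'})}")

    # -- (de)serialisation --------------------------------------------------
    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "ScenarioConfig":
        raw = dict(raw)
        scenario = dict(raw.pop("scenario", {}))
        analysis = dict(raw.pop("analysis", {}))
        if raw:
            raise ConfigError(f"unknown top-level config keys: {sorted(raw)}")
        known_s = {f.name for f in dataclasses.fields(cls)} - {"analysis"}
        unknown = set(scenario) - known_s
        if unknown:
            raise ConfigError(f"scenario: unknown keys: {sorted(unknown)}")
        known_a = {f.name for f in dataclasses.fields(AnalysisSettings)}
        unknown = set(analysis) - known_a
        if unknown:
            raise ConfigError(f"analysis: unknown keys: {sorted(unknown)}")
        for key in ("baseline_hazard",):
            if key in scenario:
                scenario[key] = tuple(tuple(x) for x in scenario[key])
        for key in ("birth_window", "registration_window", "surge_window"):
            if key in scenario:
                scenario[key] = tuple(scenario[key])
        if "periods" in analysis:
            analysis["periods"] = tuple(tuple(p) for p in analysis["periods"])
        if "band_starts" in analysis:
            analysis["band_starts"] = tuple(float(b) for b in analysis["band_starts"])
        cfg = cls(**scenario, analysis=AnalysisSettings(**analysis))
        return cfg.validate()

    @classmethod
    def from_yaml(cls, path: Any) -> "ScenarioConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        analysis = d.pop("analysis")
        return {"scenario": d, "analysis": analysis}


# ---------------------------------------------------------------------------
# mortality model
# ---------------------------------------------------------------------------

def _hazard_arrays(config: ScenarioConfig, exposed: bool) -> tuple[np.ndarray, np.ndarray]:
    starts = np.array([s for s, _ in config.baseline_hazard], dtype=float)
    rates = np.array([r for _, r in config.baseline_hazard], dtype=float)
    if exposed:
        rates = rates * config.exposure_rate_ratio
    return starts, rates


def death_age_from_uniform(
    u: np.ndarray, exposed: np.ndarray, config: ScenarioConfig
) -> np.ndarray:
    """Invert the piecewise-exponential lifetime distribution at uniforms ``u``.

    Band rates are the baseline rates, multiplied by ``exposure_rate_ratio``
    for exposed individuals.  The survival function is continuous across band
    boundaries (cumulative hazard is piecewise linear in age).
    """
    u = np.asarray(u, dtype=float)
    exposed = np.asarray(exposed, dtype=bool)
    ages = np.empty(u.shape, dtype=float)
    energy = -np.log1p(-u)  # Exp(1) draws by inversion
    for is_exp in (False, True):
        mask = exposed == is_exp
        if not mask.any():
            continue
        starts, rates = _hazard_arrays(config, is_exp)
        if rates[-1] <= 0:
            raise ConfigError(
                "baseline_hazard: final open band has zero effective rate; "
                "the lifetime distribution is improper"
            )
        edges = np.concatenate(([0.0], np.cumsum(rates[:-1] * np.diff(starts))))
        k = np.searchsorted(edges, energy[mask], side="right") - 1
        # zero-rate bands have zero-width cumulative-hazard increments, so
        # searchsorted steps straight over them; k lands on a zero rate only
        # at the measure-zero points where energy equals the band edge exactly
        rk = rates[k]
        excess = np.where(rk > 0, (energy[mask] - edges[k]) / np.where(rk > 0, rk, 1.0), 0.0)
        ages[mask] = starts[k] + excess
    return ages


def sample_death_age(
    exposed: np.ndarray | bool, config: ScenarioConfig, rng: np.random.Generator
) -> np.ndarray:
    """Draw ages at death (years) from the piecewise-exponential mortality model."""
    exposed = np.atleast_1d(np.asarray(exposed, dtype=bool))
    u = rng.random(exposed.shape)
    return death_age_from_uniform(u, exposed, config)


def expected_survival(age: float, config: ScenarioConfig, exposed: bool = False) -> float:
    """Closed-form S(age) under the model; handy as an independent oracle."""
    starts, rates = _hazard_arrays(config, exposed)
    edges = np.append(starts, np.inf)
    lived = np.clip(np.minimum(edges[1:], age) - starts, 0.0, None)
    return float(np.exp(-np.sum(rates * lived)))


# ---------------------------------------------------------------------------
# diagnosis recording
# ---------------------------------------------------------------------------

def _recording_day_from_uniform(
    u: np.ndarray, eligible_day: np.ndarray, config: ScenarioConfig
) -> np.ndarray:
    """Inverse-transform sample the diagnosis recording day (may be far future).

    The recording intensity is the delay distribution's hazard in time since
    eligibility (the later of registration and study start), multiplied by
    ``surge_multiplier`` whenever the calendar date lies inside the surge
    window.  For the 'fixed' family the surge has no effect (the recording
    time is deterministic).
    """
    dist = config.diagnosis_delay_distribution
    s = np.asarray(eligible_day, dtype=float)
    if dist["family"] == "fixed":
        return np.round(s + float(dist["delay_years"]) * DAYS_PER_YEAR).astype("int64")

    lam = 1.0 / float(dist["mean_years"])  # per year
    mult = config.surge_multiplier
    w0 = float(to_day_number(config.surge_window[0]))
    w1 = float(to_day_number(config.surge_window[1])) + 1.0  # half-open window
    b1 = np.maximum(s, w0)  # start of in-surge stretch
    b2 = np.maximum(s, w1)  # end of in-surge stretch
    h1 = (b1 - s) / DAYS_PER_YEAR * lam
    h2 = h1 + (b2 - b1) / DAYS_PER_YEAR * lam * mult
    energy = -np.log1p(-np.asarray(u, dtype=float))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_pre = s + energy / lam * DAYS_PER_YEAR
        t_in = b1 + (energy - h1) / (lam * mult) * DAYS_PER_YEAR
        t_post = b2 + (energy - h2) / lam * DAYS_PER_YEAR
    t = np.where(energy <= h1, t_pre, np.where(energy <= h2, t_in, t_post))
    # a zero-multiplier surge makes the in-window stretch hazard-free
    t = np.where(np.isfinite(t), t, FAR_FUTURE_DAY)
    return np.minimum(np.round(t), FAR_FUTURE_DAY).astype("int64")


def _assign_diagnosis(records: pd.DataFrame, config: ScenarioConfig, u: np.ndarray) -> pd.DataFrame:
    """Populate diagnosis fields on truth-exposed records given uniforms ``u`` (n, 4)."""
    out = records.copy()
    n = len(out)
    if n == 0:
        out["exposed"] = out.get("exposed", pd.Series(dtype=bool))
        return out

    start_day = config.analysis.study_start_day
    reg = date_col_to_days(out["registration_date"])
    birth = date_col_to_days(out["birth_date"])
    death = date_col_to_days(out["death_date"])
    transfer = date_col_to_days(out["transfer_out_date"])
    last_coll = date_col_to_days(out["last_collection_date"])
    exit_obs = np.minimum(np.minimum(death, transfer), last_coll)

    eligible = np.maximum(reg, start_day)
    rec = _recording_day_from_uniform(u[:, 0], eligible, config)
    diagnosed = rec < exit_obs  # recording truncated at exit from observation

    backdated = u[:, 1] < config.backdating_probability
    dx = np.where(backdated, birth, rec)

    branch = u[:, 2]
    post_exit = branch < config.sysdate_post_exit_probability
    in_obs = (~post_exit) & (
        branch < config.sysdate_post_exit_probability + config.sysdate_overwrite_probability
    )
    gap = np.maximum(exit_obs - rec, 1)
    sysdate = rec.copy()
    sysdate = np.where(in_obs, rec + np.floor(u[:, 3] * gap).astype("int64"), sysdate)
    sysdate = np.where(post_exit, exit_obs + 1 + np.floor(u[:, 3] * 730).astype("int64"), sysdate)

    dx_dt = day_to_datetime(dx)
    sys_dt = day_to_datetime(sysdate)
    out["exposed"] = diagnosed
    out["first_diagnosis_date"] = pd.Series(dx_dt, index=out.index).where(diagnosed, pd.NaT)
    out["first_diagnosis_sysdate"] = pd.Series(sys_dt, index=out.index).where(diagnosed, pd.NaT)
    return out


def assign_diagnosis_recording(
    records: pd.DataFrame, config: ScenarioConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Assign diagnosis recording dates to exposed-in-truth patient records.

    Draws a recording time from ``diagnosis_delay_distribution`` (intensity
    boosted inside the surge window), truncates it at exit from observation
    (patients dying first remain exposed in truth but are emitted looking
    unexposed), backdates the written diagnosis date to the birth date with
    ``backdating_probability``, and overwrites the system date with a later
    in-observation or post-exit administrative date with the configured
    probabilities.

    Raises ``ValueError`` if any record is not exposed in truth.
    """
    flag_col = "true_exposed" if "true_exposed" in records.columns else "exposed"
    if not records[flag_col].astype(bool).all():
        raise ValueError("assign_diagnosis_recording called on unexposed record(s)")
    u = rng.random((len(records), 4))
    return _assign_diagnosis(records, config, u)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _uts_days(u: np.ndarray, config: ScenarioConfig) -> np.ndarray:
    dist = config.uts_offset_distribution
    base = config.analysis.study_start_day
    if dist["family"] == "constant":
        return np.full(u.shape, base + int(dist["days"]), dtype="int64")
    lo, hi = int(dist["low_days"]), int(dist["high_days"])
    return base + lo + np.floor(u * (hi - lo + 1)).astype("int64")


def generate_cohort(config: ScenarioConfig) -> pd.DataFrame:
    """Generate a synthetic patient table under ``config``.

    Deterministic given the config (including its seed): each patient's
    variates occupy a fixed block of one seeded uniform stream, so patient
    ``i``'s history depends only on the seed and ``i``.
    """
    config.validate()
    n = config.n_patients
    u = np.random.default_rng(config.seed).random((n, _N_UNIFORMS))

    b_lo, b_hi = (to_day_number(d) for d in config.birth_window)
    r_lo, r_hi = (to_day_number(d) for d in config.registration_window)

    true_exposed = u[:, _U_EXPOSED] < config.exposure_prevalence
    birth = b_lo + np.floor(u[:, _U_BIRTH] * (b_hi - b_lo + 1)).astype("int64")
    reg = np.maximum(birth, r_lo + np.floor(u[:, _U_REG] * (r_hi - r_lo + 1)).astype("int64"))
    uts = _uts_days(u[:, _U_UTS], config)

    death_age = death_age_from_uniform(u[:, _U_DEATH], true_exposed, config)
    death_days = np.minimum(np.round(death_age * DAYS_PER_YEAR), 1e7).astype("int64")
    death = np.minimum(birth + np.maximum(death_days, 1), MAX_DATE_DAY)

    last_coll = np.full(n, config.analysis.study_end_day, dtype="int64")
    if config.transfer_out_rate > 0:
        t_years = -np.log1p(-u[:, _U_TRANSFER]) / config.transfer_out_rate
        transfer = reg + np.round(t_years * DAYS_PER_YEAR).astype("int64")
        transfer = np.where(transfer < np.minimum(death, last_coll), transfer, FAR_FUTURE_DAY)
    else:
        transfer = np.full(n, FAR_FUTURE_DAY, dtype="int64")

    patients = pd.DataFrame(
        {
            "patient_id": np.arange(n, dtype="int64"),
            "birth_date": day_to_datetime(birth),
            "registration_date": day_to_datetime(reg),
            "uts_date": day_to_datetime(uts),
            "transfer_out_date": pd.Series(day_to_datetime(transfer)).where(
                transfer < FAR_FUTURE_DAY, pd.NaT
            ),
            "last_collection_date": day_to_datetime(last_coll),
            "death_date": day_to_datetime(death),
            "exposed": np.zeros(n, dtype=bool),
            "first_diagnosis_date": pd.Series(np.full(n, np.datetime64("NaT", "ns"))),
            "first_diagnosis_sysdate": pd.Series(np.full(n, np.datetime64("NaT", "ns"))),
            "true_exposed": true_exposed,
        }
    )

    if true_exposed.any():
        sub = patients.loc[true_exposed]
        assigned = _assign_diagnosis(sub, config, u[true_exposed][:, _U_DELAY:_U_SYS_POS + 1])
        for col in ("exposed", "first_diagnosis_date", "first_diagnosis_sysdate"):
            patients.loc[true_exposed, col] = assigned[col]
    patients["exposed"] = patients["exposed"].astype(bool)
    return patients[list(PATIENT_COLUMNS)]


# ---------------------------------------------------------------------------
# patient table I/O
# ---------------------------------------------------------------------------

def write_patients(patients: pd.DataFrame, path: Any, include_truth: bool = True) -> None:
    """Write a patient table as CSV (ISO-8601 dates, empty fields for missing).

    ``include_truth=False`` drops the hidden ``true_exposed`` oracle column,
    producing exactly what a real extract would contain.
    """
    df = patients.copy()
    for col in _DATE_COLUMNS:
        df[col] = pd.to_datetime(df[col]).dt.strftime("%Y-%m-%d").fillna("")
    for col in ("exposed", "true_exposed"):
        if col in df.columns:
            df[col] = df[col].astype(int)
    if not include_truth:
        df = df.drop(columns=["true_exposed"], errors="ignore")
    df.to_csv(path, index=False)


def _parse_date_column(raw: pd.Series, name: str) -> pd.Series:
    txt = raw.fillna("").astype(str).str.strip()
    parsed = pd.to_datetime(txt.where(txt != "", None), format="%Y-%m-%d", errors="coerce")
    bad = parsed.isna() & (txt != "")
    if bad.any():
        row = int(np.flatnonzero(bad.values)[0]) + 2  # +1 header, +1 one-based
        raise PatientTableError(f"line {row}: malformed date {txt[bad].iloc[0]!r} in column {name}")
    return parsed


def read_patients(path: Any) -> pd.DataFrame:
    """Read and validate a patient table written by :func:`write_patients`.

    Enforces the record invariants (date ordering, diagnosis fields present
    exactly for exposed patients, unique patient ids); violations are reported
    with the offending file line.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    expected = set(PATIENT_COLUMNS)
    cols = set(df.columns)
    missing = expected - cols - {"true_exposed"}
    if missing:
        raise PatientTableError(f"missing columns: {sorted(missing)}")
    unknown = cols - expected
    if unknown:
        raise PatientTableError(f"unknown columns: {sorted(unknown)}")

    out = pd.DataFrame()
    pid = df["patient_id"]
    try:
        out["patient_id"] = pd.to_numeric(pid)
    except (ValueError, TypeError):
        out["patient_id"] = pid
    dup = out["patient_id"].duplicated()
    if dup.any():
        row = int(np.flatnonzero(dup.values)[0]) + 2
        raise PatientTableError(f"line {row}: duplicate patient_id {pid[dup].iloc[0]!r}")
    for col in _DATE_COLUMNS:
        out[col] = _parse_date_column(df[col], col)
    for col in ("exposed", "true_exposed"):
        if col in df.columns:
            vals = df[col].str.strip()
            if not vals.isin({"0", "1", "True", "False"}).all():
                bad = ~vals.isin({"0", "1", "True", "False"})
                row = int(np.flatnonzero(bad.values)[0]) + 2
                raise PatientTableError(f"line {row}: {col} must be 0/1")
            out[col] = vals.isin({"1", "True"})
    if "true_exposed" not in out.columns:
        out["true_exposed"] = out["exposed"]

    def _reject(mask: pd.Series, message: str) -> None:
        if mask.any():
            row = int(np.flatnonzero(mask.values)[0]) + 2
            raise PatientTableError(f"line {row}: {message}")

    _reject(out["birth_date"].isna(), "birth_date is required")
    _reject(out["registration_date"].isna(), "registration_date is required")
    _reject(out["birth_date"] > out["registration_date"], "birth_date after registration_date")
    _reject(
        out["death_date"].notna() & (out["death_date"] <= out["birth_date"]),
        "death_date on or before birth_date",
    )
    _reject(out["exposed"] & out["first_diagnosis_date"].isna(),
            "exposed patient without first_diagnosis_date")
    _reject(~out["exposed"] & out["first_diagnosis_date"].notna(),
            "unexposed patient with first_diagnosis_date")
    _reject(~out["exposed"] & out["first_diagnosis_sysdate"].notna(),
            "unexposed patient with first_diagnosis_sysdate")
    return out[list(PATIENT_COLUMNS)]
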