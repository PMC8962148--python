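"""Cohort construction under five ways of handling immortal time.

Given a patient table, this module computes entry and exit dates, splits
follow-up into calendar-period segments with a fixed exposure label, and
implements the five cohort-construction methods for a life-long exposure:

* **M1 (immortal time included)** — no additional entry criteria; exposed
  people are labelled exposed from their ordinary entry date, so the pre-
  diagnosis stretch (in which no death can be observed for a recorded-
  diagnosis cohort) is silently counted as exposed follow-up.
* **M2 (immortal time excluded)** — exposed entry is deferred to the first
  recorded diagnosis date.
* **M3 (matched)** — exposed as M2; the comparison group is rebuilt by
  matching each exposed person to ``ratio`` controls whose entry falls in a
  window before the exposed person's diagnosis-based index date, and moving
  the controls' entry to the index date (the analogue of prescription
  time-distribution matching).  Controls may be never-exposed people or
  exposed people's own pre-diagnosis time.
* **M4 (proxy input date)** — exposed entry is further deferred to the
  administrative system date attached to the first diagnosis; people whose
  entry then falls on or after their exit are excluded (and counted).
* **M5 (time-dependent)** — exposure is a time-dependent label: diagnosed
  people contribute unexposed person-time from ordinary entry to diagnosis
  and exposed person-time thereafter.

Conventions: dates are whole days, segments are half-open ``[start, end)``,
deaths terminate a segment on the death date with ``death_at_end`` set, and a
death after the period-specific exit date is censored at exit.
"""

from __future__ import annotations

import enum
import logging
from typing import Any

import numpy as np
import pandas as pd

from .synthetic_ehr import (
    AnalysisSettings,
    FAR_FUTURE_DAY,
    date_col_to_days,
    day_to_datetime,
    to_day_number,
)

logger = logging.getLogger(__name__)

SEGMENT_COLUMNS = (
    "patient_id",
    "start_date",
    "end_date",
    "exposure_label",
    "period_label",
    "death_at_end",
)

MATCH_COLUMNS = ("exposed_id", "index_date", "control_id", "fallback_used")

EXPOSED, UNEXPOSED = "exposed", "unexposed"


class Method(enum.Enum):
    """The five immortal-time handling methods (closed enumeration)."""

    M1_IMMORTAL_INCLUDED = "M1"
    M2_IMMORTAL_EXCLUDED = "M2"
    M3_MATCHED = "M3"
    M4_PROXY_INPUT_DATE = "M4"
    M5_TIME_DEPENDENT = "M5"


def as_method(method: Any) -> Method:
    if isinstance(method, Method):
        return method
    try:
        return Method(method)
    except ValueError:
        pass
    try:
        return Method[str(method)]
    except KeyError:
        raise ValueError(
            f"unknown method {method!r}; expected one of "
            f"{[m.value for m in Method]}"
        ) from None


# ---------------------------------------------------------------------------
# entry / exit algebra
# ---------------------------------------------------------------------------

def add_years(dates: pd.Series, years: float) -> pd.Series:
    """Calendar-anniversary date shift (29 Feb maps to 28 Feb off leap years).

    Non-integer ``years`` fall back to day arithmetic at 365.25 days/year.
    """
    dates = pd.to_datetime(dates)
    if float(years) != int(years):
        return dates + pd.to_timedelta(np.round(float(years) * 365.25), unit="D")
    years = int(years)
    y = dates.dt.year + years
    m = dates.dt.month
    d = dates.dt.day
    leap = (y % 4 == 0) & ((y % 100 != 0) | (y % 400 == 0))
    d = d.where(~((m == 2) & (d == 29) & ~leap), 28)
    out = pd.to_datetime({"year": y, "month": m, "day": d})
    out.index = dates.index
    return out.where(dates.notna(), pd.NaT)


def entry_date_m1(patients: pd.DataFrame, settings: AnalysisSettings) -> pd.Series:
    """Ordinary cohort entry: the latest of study start, registration,
    practice up-to-standard date, and the date the patient turns ``min_age``."""
    study_start = pd.Timestamp(settings.study_start)
    age_date = add_years(patients["birth_date"], settings.min_age)
    entry = patients["registration_date"].copy()
    entry = entry.where(entry >= patients["uts_date"], patients["uts_date"])
    entry = entry.where(entry >= age_date, age_date)
    entry = entry.where(entry >= study_start, study_start)
    return entry.rename("entry_date")


def exit_date(
    patients: pd.DataFrame, period: Any, settings: AnalysisSettings
) -> tuple[pd.Series, pd.Series]:
    """Period-specific exit: earliest of death, end of calendar period, last
    practice collection, and transfer-out.  ``died`` is True iff death attains
    the minimum; a death after the exit date is censored at exit.
    """
    period = settings.normalize_period(period)
    p_start, p_next = settings.period_bounds(period)
    death = date_col_to_days(patients["death_date"])
    transfer = date_col_to_days(patients["transfer_out_date"])
    last_coll = date_col_to_days(patients["last_collection_date"])
    censor_excl = np.minimum(np.minimum(transfer, last_coll), p_next)
    died = death < censor_excl
    # displayed exit uses the closed period-end date (31 Dec), matching the
    # convention that a death on the boundary date belongs to that period
    exit_closed = np.minimum(
        np.minimum(death, np.minimum(transfer, last_coll)), p_next - 1
    )
    return (
        pd.Series(day_to_datetime(exit_closed), index=patients.index, name="exit_date"),
        pd.Series(died, index=patients.index, name="died"),
    )


# ---------------------------------------------------------------------------
# per-patient core arrays
# ---------------------------------------------------------------------------

class _Core:
    """Day-number arrays shared by the method builders (positional order)."""

    def __init__(self, patients: pd.DataFrame, settings: AnalysisSettings):
        self.patients = patients.reset_index(drop=True)
        self.settings = settings
        p = self.patients
        self.pid = p["patient_id"].to_numpy()
        self.entry0 = date_col_to_days(entry_date_m1(p, settings))
        self.death = date_col_to_days(p["death_date"])
        transfer = date_col_to_days(p["transfer_out_date"])
        last_coll = date_col_to_days(p["last_collection_date"])
        self.censor_obs = np.minimum(transfer, last_coll)  # exclusive censor, no period cap
        self.exit_obs = np.minimum(self.death, self.censor_obs)  # full-study exit
        self.exposed = p["exposed"].to_numpy(dtype=bool)
        self.dx = date_col_to_days(p["first_diagnosis_date"])
        self.sysdate = date_col_to_days(p["first_diagnosis_sysdate"])


def _split_periods(
    core: _Core,
    pos: np.ndarray,
    start: np.ndarray,
    end: np.ndarray,
    label: np.ndarray,
) -> pd.DataFrame:
    """Clip label intervals to each calendar period and the exit rule."""
    settings = core.settings
    frames = []
    for period in settings.periods:
        p_start, p_next = settings.period_bounds(tuple(period))
        censor = np.minimum(core.censor_obs[pos], p_next)
        died = core.death[pos] < censor
        end_obs = np.minimum(core.death[pos], censor)
        s = np.maximum(start, p_start)
        e = np.minimum(end, end_obs)
        keep = s < e
        if not keep.any():
            continue
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": core.pid[pos[keep]],
                    "start_date": day_to_datetime(s[keep]),
                    "end_date": day_to_datetime(e[keep]),
                    "exposure_label": label[keep],
                    "period_label": settings.period_label(tuple(period)),
                    "death_at_end": (died & (e == core.death[pos]))[keep],
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=list(SEGMENT_COLUMNS)).astype(
            {"death_at_end": bool}
        )
    out = pd.concat(frames, ignore_index=True)
    out = out.sort_values(
        ["patient_id", "period_label", "start_date", "exposure_label"],
        kind="mergesort",
    ).reset_index(drop=True)
    return out[list(SEGMENT_COLUMNS)]


def _labels(n: int, exposed_mask: np.ndarray) -> np.ndarray:
    return np.where(exposed_mask, EXPOSED, UNEXPOSED)


# ---------------------------------------------------------------------------
# method builders
# ---------------------------------------------------------------------------

def build_method_cohort(
    patients: pd.DataFrame,
    method: Any,
    settings: AnalysisSettings,
    matches: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Build the follow-up segments for one method.

    Returns a DataFrame with columns ``patient_id, start_date, end_date,
    exposure_label, period_label, death_at_end``; segments never cross a
    calendar-period boundary.  Method 3 requires a ``matches`` table from
    :func:`match_controls`.
    """
    method = as_method(method)
    settings.validate()
    core = _Core(patients, settings)
    n = len(core.patients)
    every = np.arange(n)

    if method is Method.M1_IMMORTAL_INCLUDED:
        pos, start = every, core.entry0
        end = np.full(n, FAR_FUTURE_DAY, dtype="int64")
        label = _labels(n, core.exposed)

    elif method is Method.M2_IMMORTAL_EXCLUDED:
        start = np.where(core.exposed, np.maximum(core.entry0, core.dx), core.entry0)
        pos, end = every, np.full(n, FAR_FUTURE_DAY, dtype="int64")
        label = _labels(n, core.exposed)

    elif method is Method.M4_PROXY_INPUT_DATE:
        m4_entry = np.maximum(np.maximum(core.entry0, core.dx), core.sysdate)
        start = np.where(core.exposed, m4_entry, core.entry0)
        pos, end = every, np.full(n, FAR_FUTURE_DAY, dtype="int64")
        label = _labels(n, core.exposed)

    elif method is Method.M5_TIME_DEPENDENT:
        dx_eff = np.where(core.exposed, np.maximum(core.entry0, core.dx), core.entry0)
        # pre-diagnosis (unexposed) stretch for diagnosed people, plus the
        # whole follow-up of never-diagnosed people
        pre_pos = every
        pre_start = core.entry0
        pre_end = np.where(core.exposed, dx_eff, np.full(n, FAR_FUTURE_DAY, dtype="int64"))
        post_pos = every[core.exposed]
        post_start = dx_eff[core.exposed]
        post_end = np.full(post_pos.size, FAR_FUTURE_DAY, dtype="int64")
        pos = np.concatenate([pre_pos, post_pos])
        start = np.concatenate([pre_start, post_start])
        end = np.concatenate([pre_end, post_end])
        label = np.concatenate(
            [np.full(n, UNEXPOSED), np.full(post_pos.size, EXPOSED)]
        )

    elif method is Method.M3_MATCHED:
        if matches is None:
            raise ValueError("Method 3 requires a matches table from match_controls()")
        exp_pos = every[core.exposed]
        exp_start = np.maximum(core.entry0, core.dx)[core.exposed]
        exp_end = np.full(exp_pos.size, FAR_FUTURE_DAY, dtype="int64")

        m = matches.dropna(subset=["control_id"])
        pos_of = pd.Series(every, index=core.pid)
        ctl_pos = pos_of.loc[m["control_id"].to_numpy()].to_numpy()
        ctl_start = m["index_date"].to_numpy().astype("datetime64[D]").astype("int64")
        # an ever-exposed control contributes pre-diagnosis time only
        ctl_end = np.where(
            core.exposed[ctl_pos], core.dx[ctl_pos], np.int64(FAR_FUTURE_DAY)
        )
        pos = np.concatenate([exp_pos, ctl_pos])
        start = np.concatenate([exp_start, ctl_start])
        end = np.concatenate([exp_end, ctl_end])
        label = np.concatenate(
            [np.full(exp_pos.size, EXPOSED), np.full(ctl_pos.size, UNEXPOSED)]
        )
    else:  # pragma: no cover - closed enumeration
        raise ValueError(f"unknown method {method!r}")

    return _split_periods(core, pos, start, end, label)


def method4_exclusions(patients: pd.DataFrame, settings: AnalysisSettings) -> np.ndarray:
    """Patient ids excluded under Method 4: exposed people whose system-date
    entry falls on or after their exit although their Method-2 entry did not."""
    core = _Core(patients, settings)
    m2_entry = np.maximum(core.entry0, core.dx)
    m4_entry = np.maximum(m2_entry, core.sysdate)
    excluded = core.exposed & (m4_entry >= core.exit_obs) & (m2_entry < core.exit_obs)
    return core.pid[excluded]


# ---------------------------------------------------------------------------
# entry-date matching (Method 3)
# ---------------------------------------------------------------------------

def match_controls(
    patients: pd.DataFrame,
    settings: AnalysisSettings,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Match each exposed person to up to ``settings.match_ratio`` controls.

    Controls are sampled uniformly without replacement from people at risk at
    the exposed person's index date (their diagnosis-based Method-2 entry)
    whose own entry lies within ``settings.match_window_days`` before the
    index date; when too few are in the window, the remainder come from the
    fallback pool of anyone entering at any time before the index date and
    still at risk, and ``fallback_used`` is set on those rows.  The candidate
    pool contains never-exposed people and exposed people's pre-diagnosis
    time.  With ``settings.match_unique_controls`` (default) a control serves
    at most one exposed person.

    Exposed people are processed in ascending (index date, patient id) order,
    so the result is deterministic given the seed and independent of input
    row order.  An exposed person with an empty pool even after fallback is
    emitted with a null ``control_id`` and a logged warning.
    """
    settings.validate()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    order = np.argsort(patients["patient_id"].to_numpy(), kind="mergesort")
    core = _Core(patients.iloc[order], settings)

    cand_entry = core.entry0
    cand_risk_end = np.where(core.exposed, np.minimum(core.dx, core.exit_obs), core.exit_obs)
    usable = cand_entry < cand_risk_end

    exp_mask = core.exposed & (np.maximum(core.entry0, core.dx) < core.exit_obs)
    exp_pos = np.flatnonzero(exp_mask)
    index_day = np.maximum(core.entry0, core.dx)[exp_pos]
    proc = np.lexsort((core.pid[exp_pos], index_day))
    exp_pos, index_day = exp_pos[proc], index_day[proc]

    available = usable.copy()
    window = settings.match_window_days
    ratio = settings.match_ratio
    rows: list[tuple] = []
    n_unmatched = 0
    for pos_i, t in zip(exp_pos, index_day):
        elig = available & (cand_entry <= t) & (t < cand_risk_end)
        elig[pos_i] = False  # a person cannot control for themself
        in_window = elig & (cand_entry >= t - window)
        idx_in = np.flatnonzero(in_window)
        take = min(ratio, idx_in.size)
        chosen_in = rng.choice(idx_in, size=take, replace=False) if take else np.empty(0, int)
        chosen_fb = np.empty(0, int)
        if take < ratio:
            idx_fb = np.flatnonzero(elig & ~in_window)
            take_fb = min(ratio - take, idx_fb.size)
            if take_fb:
                chosen_fb = rng.choice(idx_fb, size=take_fb, replace=False)
        chosen = np.concatenate([np.sort(chosen_in), np.sort(chosen_fb)])
        if chosen.size == 0:
            logger.warning(
                "no eligible controls for exposed patient %r at index day %d",
                core.pid[pos_i], int(t),
            )
            n_unmatched += 1
            rows.append((core.pid[pos_i], t, None, False))
            continue
        if settings.match_unique_controls:
            available[chosen] = False
        for c in np.sort(chosen_in):
            rows.append((core.pid[pos_i], t, core.pid[c], False))
        for c in np.sort(chosen_fb):
            rows.append((core.pid[pos_i], t, core.pid[c], True))

    out = pd.DataFrame(rows, columns=list(MATCH_COLUMNS))
    out["index_date"] = day_to_datetime(out["index_date"].to_numpy(dtype="int64")) if len(out) else pd.Series(dtype="datetime64[ns]")
    out["fallback_used"] = out["fallback_used"].astype(bool) if len(out) else pd.Series(dtype=bool)
    if n_unmatched:
        logger.warning("%d exposed patients have no matched controls", n_unmatched)
    return out


def person_time_years(segments: pd.DataFrame) -> float:
    """Total person-time (years) in a segment table."""
    if len(segments) == 0:
        return 0.0
    days = (segments["end_date"] - segments["start_date"]).dt.days
    return float(days.sum() / 365.25)
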