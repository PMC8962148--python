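"""Chiang abridged (period) life tables with Chiang-II confidence intervals.

Deaths ``D`` and person-years ``Y`` are tabulated into age bands from
follow-up segments; the central rate ``m = D/Y`` is converted to the interval
death probability

    q = n*m / (1 + n*(1 - a)*m)

for closed bands of width ``n`` (``a`` is the average fraction of the band
lived by those dying in it, 0.5 by default), and ``q = 1`` in the final open
band whose person-years lived are ``L = l/m``.  Survivors ``l`` start at the
radix, ``d = l*q``, ``L = n*(l - d) + a*n*d``, ``T`` cumulates ``L`` from the
oldest band down, and life expectancy is ``e = T/l``.

The sampling variance of ``q`` in a closed band is ``q^2 (1-q) / D`` and the
variance of ``e_x`` is the usual Chiang weighted sum over bands at or above
``x``, plus the final-interval correction term ``l_w^2 / (m_w^2 D_w)`` (the
delta-method variance of ``e_w = 1/m_w`` with Poisson deaths) that the plain
Chiang variance sets to zero.  Intervals are normal-approximation
``e ± z_{1-alpha/2} * SE``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_ehr import DAYS_PER_YEAR

TAB_COLUMNS = ("exposure_label", "period_label", "band_start", "D", "Y")


class LifeTableError(ValueError):
    """Degenerate tabulation (empty band, no deaths in the final band, ...)."""


@dataclass(frozen=True)
class AgeBandSpec:
    """Abridged life-table age bands: ascending starts, final band open-ended."""

    band_starts: tuple[float, ...]

    def __post_init__(self) -> None:
        bs = tuple(float(b) for b in self.band_starts)
        if len(bs) < 1:
            raise LifeTableError("at least one age band is required")
        if any(b1 <= b0 for b0, b1 in zip(bs, bs[1:])):
            raise LifeTableError("band starts must be strictly increasing")
        object.__setattr__(self, "band_starts", bs)

    @property
    def widths(self) -> np.ndarray:
        return np.append(np.diff(self.band_starts), np.inf)

    @property
    def starts(self) -> np.ndarray:
        return np.asarray(self.band_starts, dtype=float)

    def band_of(self, age: np.ndarray) -> np.ndarray:
        """Index of the band containing each age (ages below the first band
        raise; the final band is open)."""
        age = np.asarray(age, dtype=float)
        if age.size and age.min() < self.band_starts[0]:
            raise LifeTableError(
                f"age {age.min():.3f} below the first band start {self.band_starts[0]}"
            )
        return np.searchsorted(self.starts, age, side="right") - 1


def bands_from_settings(settings) -> AgeBandSpec:
    return AgeBandSpec(tuple(settings.band_starts))


# ---------------------------------------------------------------------------
# person-time tabulation
# ---------------------------------------------------------------------------

def tabulate(
    segments: pd.DataFrame, bands: AgeBandSpec, patients: pd.DataFrame
) -> pd.DataFrame:
    """Tabulate deaths and exact fractional person-years per
    (exposure_label, period_label, age band).

    Each segment is split at the ages where the patient crosses a band
    boundary; age is (days since birth)/365.25.  Ages up to ~one day below
    the first band start (entry dates are whole days) are clipped into the
    first band; anything lower is an error.  Deaths increment the band
    containing the age at death.
    """
    birth = patients.set_index("patient_id")["birth_date"]
    if birth.index.duplicated().any():
        raise LifeTableError("duplicate patient_id in patient table")
    seg_birth = segments["patient_id"].map(birth)
    if seg_birth.isna().any():
        missing = segments.loc[seg_birth.isna(), "patient_id"].iloc[0]
        raise LifeTableError(f"segment for patient {missing!r} with missing birth date")

    starts = bands.starts
    if len(segments):
        a0 = (segments["start_date"] - seg_birth).dt.days.to_numpy() / DAYS_PER_YEAR
        a1 = (segments["end_date"] - seg_birth).dt.days.to_numpy() / DAYS_PER_YEAR
    else:
        a0 = a1 = np.empty(0)
    tol = 2.0 / DAYS_PER_YEAR
    if a0.size and a0.min() < starts[0] - tol:
        raise LifeTableError(
            f"segment starts at age {a0.min():.3f}, below first band start {starts[0]}"
        )

    if len(segments):
        keys = segments[["exposure_label", "period_label"]].astype(str)
        codes, groups = pd.factorize(
            pd.Series(list(zip(keys["exposure_label"], keys["period_label"])))
        )
    else:
        codes, groups = np.empty(0, dtype=int), pd.Index([])
    n_groups = len(groups)
    n_bands = len(starts)
    # whole-day entry dates can sit up to ~2 days below the first band's
    # calendar age; that sliver belongs to the first band so that person-time
    # is conserved exactly
    edges = np.append(starts, np.inf)
    edges = np.concatenate(([-np.inf], edges[1:]))

    Y = np.zeros((n_groups, n_bands))
    D = np.zeros((n_groups, n_bands), dtype="int64")
    for b in range(n_bands):
        contrib = np.clip(np.minimum(a1, edges[b + 1]) - np.maximum(a0, edges[b]), 0.0, None)
        if contrib.size:
            np.add.at(Y, (codes, b), contrib)
    death = segments["death_at_end"].to_numpy(dtype=bool) if len(segments) else np.empty(0, bool)
    if death.any():
        db = bands.band_of(np.maximum(a1[death], starts[0]))
        np.add.at(D, (codes[death], db), 1)

    rows = []
    for g, (exp_label, per_label) in enumerate(groups):
        for b in range(n_bands):
            rows.append((exp_label, per_label, starts[b], int(D[g, b]), float(Y[g, b])))
    return pd.DataFrame(rows, columns=list(TAB_COLUMNS))


def tab_group(tab: pd.DataFrame, exposure_label: str, period_label: str) -> pd.DataFrame:
    """Select one (exposure, period) group: columns band_start, D, Y."""
    sel = tab[(tab["exposure_label"] == exposure_label) & (tab["period_label"] == period_label)]
    return sel[["band_start", "D", "Y"]].sort_values("band_start").reset_index(drop=True)


# ---------------------------------------------------------------------------
# band merging for sparse data
# ---------------------------------------------------------------------------

def merge_band(
    group: pd.DataFrame, bands: AgeBandSpec, band_start: float
) -> tuple[pd.DataFrame, AgeBandSpec]:
    """Merge the band starting at ``band_start`` with its successor, summing
    D and Y.  The final band has no successor and cannot be named."""
    starts = list(bands.band_starts)
    if band_start not in starts:
        raise LifeTableError(f"no band starts at {band_start}; bands: {starts}")
    i = starts.index(band_start)
    if i == len(starts) - 1:
        raise LifeTableError("the final open band has no successor to merge with")
    g = group.sort_values("band_start").reset_index(drop=True)
    if list(g["band_start"]) != starts:
        raise LifeTableError("tabulated bands do not match the band specification")
    g.loc[i, "D"] = g.loc[i, "D"] + g.loc[i + 1, "D"]
    g.loc[i, "Y"] = g.loc[i, "Y"] + g.loc[i + 1, "Y"]
    g = g.drop(index=i + 1).reset_index(drop=True)
    new_bands = AgeBandSpec(tuple(s for j, s in enumerate(starts) if j != i + 1))
    g["band_start"] = new_bands.starts
    return g, new_bands


def collapse_sparse_bands(
    group: pd.DataFrame, bands: AgeBandSpec
) -> tuple[pd.DataFrame, AgeBandSpec]:
    """Repeatedly merge bands until every band has Y > 0 and the final band
    has at least one death; raises if the whole table is empty of deaths or
    person-years."""
    g, b = group.sort_values("band_start").reset_index(drop=True), bands
    if g["Y"].sum() <= 0:
        raise LifeTableError("no person-years in any band")
    if g["D"].sum() <= 0:
        raise LifeTableError("no deaths in any band; no life table can be formed")
    changed = True
    while changed:
        changed = False
        if len(b.band_starts) == 1:
            break
        # final band needs D > 0 (its rate closes the table)
        if g["D"].iloc[-1] <= 0 or g["Y"].iloc[-1] <= 0:
            g, b = merge_band(g, b, b.band_starts[-2])
            changed = True
            continue
        zero = g.index[(g["Y"] <= 0)]
        if len(zero):
            i = int(zero[0])
            g, b = merge_band(g, b, b.band_starts[min(i, len(b.band_starts) - 2)])
            changed = True
    if g["Y"].le(0).any() or g["D"].iloc[-1] <= 0:
        raise LifeTableError("could not form a usable life table by merging bands")
    return g, b


# ---------------------------------------------------------------------------
# Chiang life table
# ---------------------------------------------------------------------------

def chiang_life_table(
    group: pd.DataFrame,
    bands: AgeBandSpec,
    a_default: float | Sequence[float] = 0.5,
    radix: float = 100_000.0,
) -> pd.DataFrame:
    """Build a Chiang abridged life table from one group's (band, D, Y) rows.

    Raises :class:`LifeTableError` for bands with zero person-years (merge
    first, e.g. with :func:`collapse_sparse_bands`) and for a final open band
    with no deaths (its rate, hence the closing expectation 1/m, is
    undefined).
    """
    g = group.sort_values("band_start").reset_index(drop=True)
    starts = bands.starts
    if list(g["band_start"]) != list(starts):
        raise LifeTableError("tabulated bands do not match the band specification")
    D = g["D"].to_numpy(dtype=float)
    Y = g["Y"].to_numpy(dtype=float)
    if (Y <= 0).any():
        bad = starts[int(np.flatnonzero(Y <= 0)[0])]
        raise LifeTableError(
            f"band starting at {bad:g} has zero person-years; merge it with a "
            "neighbour (merge_band / collapse_sparse_bands) before fitting"
        )
    if D[-1] <= 0:
        raise LifeTableError(
            "final open band has no deaths; its closing rate is undefined — "
            "merge it downward before fitting"
        )
    n = bands.widths
    a = np.broadcast_to(np.asarray(a_default, dtype=float), D.shape).copy()
    if ((a <= 0) | (a >= 1)).any():
        raise LifeTableError("a_default must lie in (0, 1)")
    m = D / Y
    q = np.empty_like(m)
    closed = slice(0, len(m) - 1)
    q[closed] = n[closed] * m[closed] / (1.0 + n[closed] * (1.0 - a[closed]) * m[closed])
    q = np.minimum(q, 1.0)
    q[-1] = 1.0

    l = np.empty_like(q)
    l[0] = radix
    for i in range(1, len(q)):
        l[i] = l[i - 1] * (1.0 - q[i - 1])
    d = l * q
    L = np.empty_like(l)
    L[closed] = n[closed] * (l[closed] - d[closed]) + a[closed] * n[closed] * d[closed]
    L[-1] = l[-1] / m[-1]
    T = np.cumsum(L[::-1])[::-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(l > 0, T / np.where(l > 0, l, 1.0), 0.0)
    return pd.DataFrame(
        {
            "band_start": starts,
            "n": n,
            "D": D.astype("int64"),
            "Y": Y,
            "m": m,
            "a": a,
            "q": q,
            "l": l,
            "d": d,
            "L": L,
            "T": T,
            "e": e,
        }
    )


def chiang2_confidence_interval(
    life_table: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Attach Chiang-II normal-approximation confidence limits for ``e``.

    Closed-band variance of ``q`` is ``q^2(1-q)/D`` (zero when D = 0); the
    final open interval contributes ``l_w^2/(m_w^2 D_w)`` instead of the zero
    the plain Chiang variance assumes.
    """
    lt = life_table.reset_index(drop=True)
    D = lt["D"].to_numpy(dtype=float)
    if D.sum() <= 0:
        raise LifeTableError("no deaths anywhere; the variance of e is not estimable")
    if D[-1] <= 0:
        raise LifeTableError("final open band has no deaths; Chiang-II term undefined")
    q = lt["q"].to_numpy()
    l = lt["l"].to_numpy()
    e = lt["e"].to_numpy()
    n = lt["n"].to_numpy()
    a = lt["a"].to_numpy()
    m = lt["m"].to_numpy()

    var_q = np.zeros_like(q)
    nz = D > 0
    var_q[nz] = q[nz] ** 2 * (1.0 - q[nz]) / D[nz]
    e_next = np.append(e[1:], 0.0)
    n_closed = np.where(np.isfinite(n), n, 0.0)  # final band handled separately
    w = l**2 * ((1.0 - a) * n_closed + e_next) ** 2 * var_q
    w[-1] = l[-1] ** 2 / (m[-1] ** 2 * D[-1])  # final-interval correction
    S = np.cumsum(w[::-1])[::-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        var_e = np.where(l > 0, S / np.where(l > 0, l, 1.0) ** 2, 0.0)
    se = np.sqrt(var_e)
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    out = lt.copy()
    out["se_e"] = se
    out["e_lo"] = out["e"] - z * se
    out["e_hi"] = out["e"] + z * se
    return out


def life_expectancy_at(life_table: pd.DataFrame, age: float) -> float:
    """Life expectancy at a band start; other ages are a contract error."""
    starts = life_table["band_start"].to_numpy(dtype=float)
    hit = np.flatnonzero(starts == float(age))
    if hit.size == 0:
        raise ValueError(
            f"age {age} is not a band start; valid ages: {list(starts)}"
        )
    return float(life_table["e"].iloc[int(hit[0])])
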