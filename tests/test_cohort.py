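"""Entry/exit algebra, the five method builders, period splitting, matching."""

import numpy as np
import pandas as pd
import pytest

import ehrlife as el
from ehrlife.cohort import EXPOSED, UNEXPOSED


def seg_days(segments: pd.DataFrame) -> pd.Series:
    return (segments["end_date"] - segments["start_date"]).dt.days


# ---------------------------------------------------------------------------
# entry date
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "row, expected",
    [
        # the study-start floor dominates
        ({"birth_date": "1985-01-01", "registration_date": "1995-03-01",
          "uts_date": "1998-07-01"}, "2000-01-01"),
        # turning min_age dominates
        ({"birth_date": "1995-06-01", "registration_date": "1995-06-01",
          "uts_date": "1996-01-01"}, "2005-06-01"),
        # late registration dominates
        ({"birth_date": "1985-01-01", "registration_date": "2010-03-15",
          "uts_date": "2000-01-01"}, "2010-03-15"),
    ],
)
def test_entry_is_latest_of_four_criteria(patients_factory, default_settings, row, expected):
    pats = patients_factory(row)
    entry = el.entry_date_m1(pats, default_settings)
    assert entry.iloc[0] == pd.Timestamp(expected)


def test_leap_day_birthday_anniversary(patients_factory, default_settings):
    pats = patients_factory({"birth_date": "1996-02-29", "registration_date": "1996-02-29"})
    entry = el.entry_date_m1(pats, default_settings)
    assert entry.iloc[0] == pd.Timestamp("2006-02-28")


# ---------------------------------------------------------------------------
# exit date
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "row, period, expected_exit, expected_died",
    [
        ({"death_date": "2003-05-01"}, (2000, 2004), "2003-05-01", True),
        ({"death_date": "2006-02-01"}, (2000, 2004), "2004-12-31", False),
        ({"transfer_out_date": "2012-07-01", "death_date": "2013-03-01"},
         (2010, 2014), "2012-07-01", False),
        # a death on the period boundary date belongs to that period
        ({"death_date": "2004-12-31"}, (2000, 2004), "2004-12-31", True),
    ],
)
def test_exit_is_earliest_of_four_dates(
    patients_factory, default_settings, row, period, expected_exit, expected_died
):
    pats = patients_factory(row)
    exit_, died = el.exit_date(pats, period, default_settings)
    assert exit_.iloc[0] == pd.Timestamp(expected_exit)
    assert bool(died.iloc[0]) is expected_died


# ---------------------------------------------------------------------------
# method builders
# ---------------------------------------------------------------------------

def test_m5_hand_trace(patients_factory, default_settings):
    pats = patients_factory(
        {
            "exposed": True,
            "first_diagnosis_date": "2003-04-01",
            "first_diagnosis_sysdate": "2003-04-01",
            "death_date": "2006-01-01",
        }
    )
    segs = el.build_method_cohort(pats, "M5", default_settings)
    got = [
        (str(r.start_date.date()), str(r.end_date.date()), r.exposure_label,
         r.period_label, r.death_at_end)
        for r in segs.itertuples()
    ]
    assert got == [
        ("2000-01-01", "2003-04-01", UNEXPOSED, "2000-2004", False),
        ("2003-04-01", "2005-01-01", EXPOSED, "2000-2004", False),
        ("2005-01-01", "2006-01-01", EXPOSED, "2005-2009", True),
    ]


def test_death_before_diagnosis_is_unexposed_under_every_method(
    patients_factory, default_settings
):
    # exposed in truth, but the record never received a diagnosis
    pats = patients_factory(
        {"exposed": False, "true_exposed": True, "death_date": "2003-02-01"}
    )
    for method in el.Method:
        matches = (
            el.match_controls(pats, default_settings, rng=0)
            if method is el.Method.M3_MATCHED
            else None
        )
        segs = el.build_method_cohort(pats, method, default_settings, matches=matches)
        assert (segs["exposure_label"] == UNEXPOSED).all() or len(segs) == 0


def test_zero_delay_collapses_m1_m2_m4_m5(zero_delay_config):
    pats = el.generate_cohort(zero_delay_config)
    settings = zero_delay_config.analysis
    ref = el.build_method_cohort(pats, "M1", settings)
    for method in ("M2", "M4", "M5"):
        got = el.build_method_cohort(pats, method, settings)
        pd.testing.assert_frame_equal(ref, got)


def test_m4_requires_matches_error_and_unknown_method(patients_factory, default_settings):
    pats = patients_factory({})
    with pytest.raises(ValueError, match="match_controls"):
        el.build_method_cohort(pats, "M3", default_settings)
    with pytest.raises(ValueError, match="unknown method"):
        el.build_method_cohort(pats, "M7", default_settings)


def test_m4_exclusion_counts_sysdate_after_exit(patients_factory, default_settings):
    pats = patients_factory(
        {  # sysdate after death: excluded under M4
            "exposed": True,
            "first_diagnosis_date": "2002-01-01",
            "first_diagnosis_sysdate": "2007-06-01",
            "death_date": "2006-01-01",
        },
        {  # clean sysdate: kept
            "exposed": True,
            "first_diagnosis_date": "2002-01-01",
            "first_diagnosis_sysdate": "2002-01-01",
            "death_date": "2006-01-01",
        },
    )
    excluded = el.method4_exclusions(pats, default_settings)
    assert list(excluded) == [0]
    segs = el.build_method_cohort(pats, "M4", default_settings)
    assert set(segs["patient_id"]) == {1}


# ---------------------------------------------------------------------------
# structural invariants on a generated scenario
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def default_cohort_segments(small_cohort):
    settings = el.AnalysisSettings()
    matches = el.match_controls(small_cohort, settings, rng=1)
    segs = {}
    for m in el.Method:
        segs[m.value] = el.build_method_cohort(
            small_cohort, m, settings,
            matches=matches if m is el.Method.M3_MATCHED else None,
        )
    return settings, matches, segs


def test_person_time_conservation_m5_equals_m1(default_cohort_segments):
    _, _, segs = default_cohort_segments
    t1 = seg_days(segs["M1"]).groupby(segs["M1"]["patient_id"]).sum()
    t5 = seg_days(segs["M5"]).groupby(segs["M5"]["patient_id"]).sum()
    pd.testing.assert_series_equal(t1, t5)


def test_exposed_person_time_monotone_m4_m2_m1(default_cohort_segments):
    _, _, segs = default_cohort_segments
    totals = {}
    deaths = {}
    for m in ("M1", "M2", "M4"):
        sub = segs[m][segs[m]["exposure_label"] == EXPOSED]
        totals[m] = seg_days(sub).sum()
        deaths[m] = sub["death_at_end"].sum()
    assert totals["M4"] < totals["M2"] < totals["M1"]
    assert deaths["M4"] <= deaths["M2"] <= deaths["M1"]


def test_exposed_results_identical_m2_m3_m5(default_cohort_segments):
    _, _, segs = default_cohort_segments
    ref = None
    for m in ("M2", "M3", "M5"):
        sub = (
            segs[m][segs[m]["exposure_label"] == EXPOSED]
            .sort_values(["patient_id", "period_label", "start_date"])
            .reset_index(drop=True)
        )
        if ref is None:
            ref = sub
        else:
            pd.testing.assert_frame_equal(ref, sub)


def test_segments_respect_period_boundaries_and_do_not_overlap(default_cohort_segments):
    settings, _, segs = default_cohort_segments
    bounds = {
        settings.period_label(p): settings.period_bounds(p) for p in settings.periods
    }
    for m, df in segs.items():
        start = df["start_date"].values.astype("datetime64[D]").astype("int64")
        end = df["end_date"].values.astype("datetime64[D]").astype("int64")
        assert (start < end).all()
        for label, (p_start, p_next) in bounds.items():
            sel = (df["period_label"] == label).to_numpy()
            assert (start[sel] >= p_start).all() and (end[sel] <= p_next).all()
        # within (patient, period) segments tile an interval without overlap
        df = df.sort_values(["patient_id", "period_label", "start_date"])
        same = (
            df["patient_id"].eq(df["patient_id"].shift())
            & df["period_label"].eq(df["period_label"].shift())
        )
        assert (
            df.loc[same, "start_date"] == df["end_date"].shift()[same]
        ).all(), m


def test_death_flag_set_once_and_on_death_date(small_cohort, default_cohort_segments):
    _, _, segs = default_cohort_segments
    death = small_cohort.set_index("patient_id")["death_date"]
    for m, df in segs.items():
        flagged = df[df["death_at_end"]]
        assert not flagged["patient_id"].duplicated().any()
        assert (flagged["end_date"] == death.loc[flagged["patient_id"]].values).all()


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------

def _exposed_row(dx="2005-01-01", **kw):
    row = {
        "exposed": True,
        "first_diagnosis_date": dx,
        "first_diagnosis_sysdate": dx,
        "registration_date": "2000-01-01",
        "birth_date": "1970-01-01",
    }
    row.update(kw)
    return row


def test_single_in_window_candidate_matched(patients_factory):
    settings = el.AnalysisSettings(match_ratio=1)
    pats = patients_factory(
        _exposed_row(),
        {"registration_date": "2004-09-23", "birth_date": "1970-01-01"},  # 100 d before
    )
    matches = el.match_controls(pats, settings, rng=0)
    assert len(matches) == 1
    row = matches.iloc[0]
    assert row["exposed_id"] == 0 and row["control_id"] == 1
    assert row["index_date"] == pd.Timestamp("2005-01-01")
    assert not row["fallback_used"]


def test_out_of_window_candidates_drawn_via_fallback(patients_factory):
    settings = el.AnalysisSettings(match_ratio=10)
    rows = [_exposed_row()]
    rows += [
        {"registration_date": "2004-06-15", "birth_date": "1970-01-01"}
        for _ in range(12)
    ]  # 200 days before the index date, outside the 150-day window
    pats = patients_factory(*rows)
    matches = el.match_controls(pats, settings, rng=0)
    assert len(matches) == 10
    assert matches["fallback_used"].all()
    assert (matches["control_id"] != 0).all()


def test_candidate_exited_before_index_never_selected(patients_factory):
    settings = el.AnalysisSettings(match_ratio=10)
    pats = patients_factory(
        _exposed_row(),
        {"registration_date": "2004-10-01"},                                  # at risk
        {"registration_date": "2004-10-01", "death_date": "2004-12-01"},      # dead
        {"registration_date": "2004-10-01", "transfer_out_date": "2004-11-01"},  # left
        {"registration_date": "2005-02-01"},                                  # enters later
    )
    matches = el.match_controls(pats, settings, rng=0)
    # independent brute-force risk set at the index date 2005-01-01
    idx = pd.Timestamp("2005-01-01")
    eligible = set()
    for r in pats.itertuples():
        if r.patient_id == 0:
            continue
        entry = max(r.registration_date, r.uts_date, pd.Timestamp("2000-01-01"))
        exit_ = min(
            x for x in (r.death_date, r.transfer_out_date, r.last_collection_date)
            if pd.notna(x)
        )
        if entry <= idx < exit_:
            eligible.add(r.patient_id)
    assert eligible == {1}
    assert set(matches["control_id"].dropna()) == eligible


def test_unmatched_exposed_emitted_with_empty_control_list(patients_factory, caplog):
    pats = patients_factory(_exposed_row())
    with caplog.at_level("WARNING"):
        matches = el.match_controls(pats, el.AnalysisSettings(), rng=0)
    assert len(matches) == 1
    assert matches["control_id"].isna().all()
    assert "no eligible controls" in caplog.text


def test_matching_contract_on_generated_cohort(default_cohort_segments):
    settings, matches, segs = default_cohort_segments
    m = matches.dropna(subset=["control_id"])
    # a control serves at most one exposed person (global without-replacement)
    assert not m["control_id"].duplicated().any()
    # within the ratio
    per_exposed = m.groupby("exposed_id").size()
    assert (per_exposed <= settings.match_ratio).all()
    # every control segment starts at its index date
    ctl = segs["M3"][segs["M3"]["exposure_label"] == UNEXPOSED]
    first = ctl.groupby("patient_id")["start_date"].min()
    index_of = m.set_index("control_id")["index_date"]
    assert (first.loc[index_of.index] == index_of).all()


def test_matching_is_order_independent(small_cohort):
    settings = el.AnalysisSettings()
    a = el.match_controls(small_cohort, settings, rng=42)
    shuffled = small_cohort.sample(frac=1.0, random_state=0).reset_index(drop=True)
    b = el.match_controls(shuffled, settings, rng=42)
    pd.testing.assert_frame_equal(a, b)
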