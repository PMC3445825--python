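"""Time-interval recoder: printed-table fidelity and tiling properties."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from perilink import svti
from perilink.svti import (
    MONTH_SCHEME,
    YEAR_SCHEME,
    IntervalScheme,
    add_timing_columns,
    bucket_label,
    compute_admdays,
    gestation_weeks_to_days,
    recode_admmonth,
    recode_interval,
    recode_interval_array,
)

# ---------------------------------------------------------------------------
# Oracle: a literal lookup over the published recode ranges, written out
# interval by interval.  Kept independent of the floor-division arithmetic
# it checks.
# ---------------------------------------------------------------------------

_PRE_RANGES = [(-(10**9), -361, 0)] + [
    (-360 + 30 * (k - 1), -331 + 30 * (k - 1), k) for k in range(1, 13)
]
_PREG_RANGES = [(30 * (k - 13), 29 + 30 * (k - 13), k) for k in range(13, 24)]
_POST_RANGES = [(30 * (k - 24), 29 + 30 * (k - 24), k) for k in range(24, 36)] + [
    (360, 10**9, 36)
]


def oracle_admmonth(admdays, gage_days):
    if admdays >= 0:
        table, x = _POST_RANGES, admdays
    else:
        x = admdays + gage_days
        table = _PRE_RANGES if x < 0 else _PREG_RANGES
    for lo, hi, bucket in table:
        if lo <= x <= hi:
            return bucket
    return None


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "adm, birth, expected",
    [(10100, 10000, 100), (10000, 10000, 0), (9900, 10000, -100)],
)
def test_admdays_is_signed_difference(adm, birth, expected):
    assert compute_admdays(adm, birth) == expected


def test_admdays_missing_input_propagates():
    assert compute_admdays(None, 10000) is None
    assert compute_admdays(10000, None) is None


@pytest.mark.parametrize("weeks, days", [(40, 280), (20, 140), (44, 308)])
def test_gestation_conversion(weeks, days):
    assert gestation_weeks_to_days(weeks) == days


@pytest.mark.parametrize("weeks", [0, -3, 19, 46])
def test_gestation_out_of_band_rejected(weeks):
    with pytest.raises(ValueError):
        gestation_weeks_to_days(weeks)


def test_gestation_missing_stays_missing():
    assert gestation_weeks_to_days(None) is None


# ---------------------------------------------------------------------------
# Month recode: printed boundaries and full-domain oracle agreement
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "admdays, gage, expected",
    [
        (-625, 265, 1),    # day -360 from pregnancy start: 12th month before
        (-281, 280, 12),   # day -1: last month before pregnancy
        (-280, 280, 13),   # day 0: first month of pregnancy
        (-1, 280, 22),     # day 279 of pregnancy: 13 + 279 // 30
        (0, 280, 24),      # day of birth: first month after birth
        (359, 280, 35),    # last day of the 12th month after birth
        (360, 280, 36),    # open-ended final bucket
        (-680, 280, 0),    # day -400: before the 12th month before pregnancy
        (-641, 280, 0),    # day -361: last day of bucket 0
        (-640, 280, 1),    # day -360: first day of bucket 1
        (-311, 280, 11),   # day -31: second month before pregnancy
    ],
)
def test_admmonth_printed_boundaries(admdays, gage, expected):
    bucket, flag = recode_admmonth(admdays, gage)
    assert bucket == expected
    assert flag == ""


def test_admmonth_full_sweep_matches_printed_ranges():
    """Every (admdays, gage) over a wide domain agrees with the literal
    transcription of the published recode table, with zero mismatches."""
    mismatches = 0
    for gage_weeks in range(20, 45):
        gage = gage_weeks * 7
        for admdays in range(-2000, 2001):
            got, _ = recode_admmonth(admdays, gage)
            if got != oracle_admmonth(admdays, gage):
                mismatches += 1
    assert mismatches == 0


def test_missing_inputs_flagged():
    assert recode_admmonth(None, 280) == (None, svti.FLAG_MISSING_ADMDAYS)
    assert recode_admmonth(-10, None) == (None, svti.FLAG_MISSING_GAGE)
    # gestation irrelevant after birth
    assert recode_admmonth(5, None) == (24, "")


def test_pregnancy_overrun_is_missing_with_warning():
    # A pre-birth day of 330+ from pregnancy start has no printed bucket;
    # unreachable for gestations <= 47 weeks but guarded explicitly.
    scheme = MONTH_SCHEME
    bucket, flag = recode_interval(-5, 340, scheme)
    assert bucket is None
    assert flag == svti.FLAG_PREGNANCY_OVERRUN


# ---------------------------------------------------------------------------
# Properties: tiling, monotonicity, widths, week-resolution caveat
# ---------------------------------------------------------------------------


@settings(max_examples=300, derandomize=True)
@given(
    admdays=st.integers(min_value=-3000, max_value=3000),
    gage_weeks=st.integers(min_value=20, max_value=44),
)
def test_partition_totality_and_monotonicity(admdays, gage_weeks):
    gage = gage_weeks * 7
    bucket, flag = recode_admmonth(admdays, gage)
    assert bucket is not None and flag == ""
    assert 0 <= bucket <= 36
    nxt, _ = recode_admmonth(admdays + 1, gage)
    assert nxt >= bucket


def test_interior_bucket_widths_are_exact():
    """Consecutive boundary differences: every interior month bucket spans
    exactly 30 day-values and every interior year bucket 360.

    The recode switches axis at birth — pre-birth buckets live on the
    day-from-pregnancy-start axis, post-birth buckets on the
    day-from-birth axis — so widths are measured per axis.  A gestation
    longer than the pregnancy ladder is used so every pregnancy bucket
    is exercised end to end (real gestations stop short of the last
    ones; the arithmetic must tile regardless).
    """
    for scheme, width in ((MONTH_SCHEME, 30), (YEAR_SCHEME, 360)):
        gage = scheme.n_pregnancy * width + width  # covers the full ladder
        span = (scheme.n_pre + scheme.n_pregnancy + 2) * width
        # pre-birth buckets 1..(n_pre + n_pregnancy): sweep admdays < 0,
        # equivalently d = admdays + gage over the whole pre-birth axis
        pre = np.array(
            [recode_interval(a, gage, scheme)[0] for a in range(-gage - span, 0)],
            dtype=float,
        )
        for b in range(1, scheme.post_birth_start_bucket):
            assert (pre == b).sum() == width, (scheme.unit, b)
        # post-birth buckets: sweep admdays >= 0
        post = np.array(
            [recode_interval(a, gage, scheme)[0] for a in range(0, (scheme.n_post + 2) * width)],
            dtype=float,
        )
        for b in range(scheme.post_birth_start_bucket, scheme.last_bucket):
            assert (post == b).sum() == width, (scheme.unit, b)


@settings(max_examples=200, derandomize=True)
@given(
    admdays=st.integers(min_value=-3000, max_value=-7),
    gage_weeks=st.integers(min_value=20, max_value=44),
    delta=st.integers(min_value=1, max_value=6),
)
def test_week_resolution_caveat(admdays, gage_weeks, delta):
    """Gestation is reported in completed weeks, so a <7-day shift of a
    pre-birth admission never moves it across more than one month bucket
    (both admissions staying before birth)."""
    gage = gage_weeks * 7
    b1, _ = recode_admmonth(admdays, gage)
    b2, _ = recode_admmonth(admdays + delta, gage)
    assert abs(b2 - b1) <= 1


@settings(max_examples=500, derandomize=True)
@given(
    admdays=st.integers(min_value=-3000, max_value=3000),
    gage_weeks=st.integers(min_value=20, max_value=44),
)
def test_month_preset_of_generic_recoder_equals_admmonth(admdays, gage_weeks):
    gage = gage_weeks * 7
    assert recode_interval(admdays, gage, MONTH_SCHEME) == recode_admmonth(
        admdays, gage
    )


@pytest.mark.parametrize(
    "admdays, gage, expected",
    [
        (-400, 280, 1),   # day -120: within the year before pregnancy
        (-640, 280, 1),   # day -360: first day of the pre-pregnancy year
        (-725, 280, 0),   # day -445: before the single labelled pre-pregnancy year
        (-1085, 280, 0),  # far earlier
        (-100, 280, 2),   # during pregnancy
        (0, 280, 3),      # first year after birth
        (360, 280, 4),    # open-ended final year bucket
    ],
)
def test_year_preset(admdays, gage, expected):
    bucket, flag = recode_interval(admdays, gage, YEAR_SCHEME)
    assert (bucket, flag) == (expected, "")


def test_vectorised_recode_matches_scalar():
    rng = np.random.default_rng(5)
    admdays = rng.integers(-2000, 2001, size=5000).astype(float)
    gage = (rng.integers(20, 45, size=5000) * 7).astype(float)
    admdays[::17] = np.nan
    gage[::23] = np.nan
    buckets, flags = recode_interval_array(admdays, gage, MONTH_SCHEME)
    for i in range(5000):
        a = None if np.isnan(admdays[i]) else int(admdays[i])
        g = None if np.isnan(gage[i]) else int(gage[i])
        b, f = recode_admmonth(a, g)
        assert flags[i] == f
        if b is None:
            assert np.isnan(buckets[i])
        else:
            assert buckets[i] == b


def test_labels_cover_all_buckets():
    labels = [bucket_label(b) for b in range(37)]
    assert len(set(labels)) == 37
    assert labels[0] == "before the 12th month before pregnancy"
    assert labels[12] == "the 1st month before pregnancy"
    assert labels[13] == "the 1st month of pregnancy"
    assert labels[24] == "the 1st month after birth"
    assert labels[36] == "after the 12th month after birth"


def test_invalid_scheme_rejected():
    with pytest.raises(Exception):
        IntervalScheme(width_days=0, n_pre=1, n_pregnancy=1, n_post=1)


def test_add_timing_columns_appends_and_flags():
    df = pd.DataFrame(
        {
            "AGEAdmMum": [10100, 9700, 9500, np.nan],
            "AgeBirthMum": [10000, 10000, 10000, 10000],
            "GageDays": [280, 280, np.nan, 280],
        }
    )
    out = add_timing_columns(df)
    assert list(out["Admdays"].fillna(-1)) == [100, -300, -500, -1]
    assert out.loc[0, "Admmonth"] == 27
    assert out.loc[1, "Admmonth"] == 12  # day -20 from pregnancy start
    assert np.isnan(out.loc[2, "Admmonth"]) and out.loc[2, "SvtiFlag"] == "missing_gage"
    assert np.isnan(out.loc[3, "Admmonth"]) and out.loc[3, "SvtiFlag"] == "missing_admdays"
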