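"""Window filtering, per-mother summaries and admission sequencing.

Operates on the master table after the timing recode (``Admmonth``) and
diagnosis grouping (``Prin1``..``Prin10``) have been appended.  The
canonical analysis window is pregnancy, Admmonth in [13, 23] inclusive;
other named windows cover the pre-pregnancy year, the first postnatal
year, and the whole tracked timeline.

Sequencing sorts each mother's windowed admissions by admission age (ties
broken deterministically by admission identifier, i.e. input order) and
assigns ``Morder`` = within-mother rank plus, per diagnosis group, the
cumulative rank among that mother's flagged admissions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import schemas
from .schemas import (
    ADMISSION_ID,
    ADMMONTH,
    AGE_ADM_MUM,
    AGE_DIS_MUM,
    MORDER,
    PPN_MUM,
    ConfigurationError,
)
from .svti import MONTH_SCHEME, bucket_label

__all__ = [
    "PeriodWindow",
    "WINDOW_PRESETS",
    "filter_window",
    "count_flag_per_mother",
    "sequence_admissions",
    "total_length_of_stay",
    "admission_rate_series",
]


@dataclass(frozen=True)
class PeriodWindow:
    """Inclusive month-bucket window [lo_bucket, hi_bucket]."""

    lo_bucket: int
    hi_bucket: int
    name: str = ""

    def __post_init__(self):
        if not 0 <= self.lo_bucket <= self.hi_bucket <= MONTH_SCHEME.last_bucket:
            raise ConfigurationError(
                f"window [{self.lo_bucket}, {self.hi_bucket}] must satisfy "
                f"0 <= lo <= hi <= {MONTH_SCHEME.last_bucket}"
            )


WINDOW_PRESETS = {
    "pregnancy": PeriodWindow(13, 23, "pregnancy"),
    "pre_pregnancy_year": PeriodWindow(1, 12, "pre_pregnancy_year"),
    "first_year_post": PeriodWindow(24, 35, "first_year_post"),
    "tracked": PeriodWindow(1, 36, "tracked"),
    "full": PeriodWindow(0, 36, "full"),
}


def filter_window(rows: pd.DataFrame, window: PeriodWindow):
    """Retain rows whose Admmonth lies in the window (both ends inclusive).

    Returns ``(subset, report)``; the report accounts for every input
    row: retained + out_of_window + missing_bucket = input rows.  Rows
    with a missing bucket can belong to no window and are excluded.
    """
    schemas.require_columns(rows, [ADMMONTH], "master")
    bucket = pd.to_numeric(rows[ADMMONTH], errors="coerce")
    missing = bucket.isna()
    inside = ~missing & (bucket >= window.lo_bucket) & (bucket <= window.hi_bucket)
    report = {
        "window": (window.lo_bucket, window.hi_bucket),
        "input_rows": int(len(rows)),
        "retained": int(inside.sum()),
        "out_of_window": int((~inside & ~missing).sum()),
        "missing_bucket": int(missing.sum()),
    }
    return rows[inside].copy(), report


def count_flag_per_mother(rows: pd.DataFrame, flag_name: str, mothers=None) -> pd.Series:
    """Per-mother sum of a binary flag over (windowed) rows.

    ``mothers`` optionally supplies the full mother universe so that
    mothers with no rows in the window appear with count 0.
    """
    if flag_name not in rows.columns:
        raise ConfigurationError(f"unknown flag column {flag_name!r}")
    counts = rows.groupby(PPN_MUM)[flag_name].sum().astype(int)
    if mothers is not None:
        counts = counts.reindex(pd.Index(sorted(set(mothers)), name=PPN_MUM), fill_value=0)
    return counts.rename(f"{flag_name}_sum")


def sequence_admissions(rows: pd.DataFrame, group_flags=()) -> pd.DataFrame:
    """Order each mother's admissions and rank them overall and per group.

    Sorts by (mother, admission age, admission id) — the id carries input
    order and makes same-day ties deterministic.  ``Morder`` is the
    1-based within-mother rank.  For each flag column K in
    ``group_flags``, ``K_order`` is the 1-based rank among the mother's
    flagged rows, assigned only where the flag is 1 (missing elsewhere).
    """
    schemas.require_columns(rows, [PPN_MUM, AGE_ADM_MUM], "master")
    sort_cols = [PPN_MUM, AGE_ADM_MUM]
    if ADMISSION_ID in rows.columns:
        sort_cols.append(ADMISSION_ID)
    out = rows.sort_values(sort_cols, kind="mergesort").reset_index(drop=True)
    out[MORDER] = out.groupby(PPN_MUM).cumcount() + 1
    for flag in group_flags:
        if flag not in out.columns:
            raise ConfigurationError(f"unknown flag column {flag!r}")
        cum = out.groupby(PPN_MUM)[flag].cumsum()
        out[f"{flag}_order"] = cum.where(out[flag] == 1).astype("Int64")
    return out


def total_length_of_stay(rows: pd.DataFrame, mothers=None):
    """Per-mother total days of hospital stay over the (windowed) rows.

    Row length of stay = discharge age minus admission age; a stay that
    ends outside the window is counted in full.  Rows with discharge
    before admission are excluded and reported, never summed.

    Returns ``(per_mother_totals, bad_rows)``.
    """
    schemas.require_columns(rows, [PPN_MUM, AGE_ADM_MUM, AGE_DIS_MUM], "master")
    los = pd.to_numeric(rows[AGE_DIS_MUM], errors="coerce") - pd.to_numeric(
        rows[AGE_ADM_MUM], errors="coerce"
    )
    bad = rows[los < 0].copy()
    good = rows[~(los < 0)].copy()
    good["_los"] = los[~(los < 0)]
    totals = good.groupby(PPN_MUM)["_los"].sum().astype(int)
    if mothers is not None:
        totals = totals.reindex(pd.Index(sorted(set(mothers)), name=PPN_MUM), fill_value=0)
    return totals.rename("total_los_days"), bad


def admission_rate_series(
    rows: pd.DataFrame,
    mothers_total: int,
    flag_name: str,
    per: float = 1000.0,
) -> pd.DataFrame:
    """Per-bucket counts and rates of flagged admissions across the whole
    0..36 month timeline — the trend of admissions before and after birth.

    Rate = ``per`` x count / mothers_total (default per 1000 mothers).
    The series always covers every bucket, zeros included, and its counts
    sum to the total number of flagged rows with a known bucket.
    """
    if mothers_total <= 0:
        raise ConfigurationError("mothers_total must be positive")
    if flag_name not in rows.columns:
        raise ConfigurationError(f"unknown flag column {flag_name!r}")
    bucket = pd.to_numeric(rows[ADMMONTH], errors="coerce")
    flagged = rows[flag_name] == 1
    counts = (
        bucket[flagged]
        .dropna()
        .astype(int)
        .value_counts()
        .reindex(range(MONTH_SCHEME.n_buckets), fill_value=0)
        .sort_index()
    )
    return pd.DataFrame(
        {
            "bucket": counts.index,
            "label": [bucket_label(b) for b in counts.index],
            "count": counts.to_numpy(),
            "rate": per * counts.to_numpy() / mothers_total,
        }
    )
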