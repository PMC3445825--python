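"""Statistical variable of time interval (SVTI).

Assigns each hospital admission to a time bucket relative to the start of
pregnancy and to birth, working entirely in ages-in-days.  The month
variable ``Admmonth`` partitions the timeline into 37 buckets:

========  =======================================================
bucket    meaning
========  =======================================================
0         before the 12th month before pregnancy
1..12     30-day months before pregnancy (1 = earliest, 12 = last)
13..23    30-day months of pregnancy (13 = first)
24..35    30-day months after birth (24 = first)
36        after the 12th month after birth
========  =======================================================

Conventions: a month is 30 days and a year 360 days; "pregnancy start" is
the first day of the last menstrual period as implied by gestational age
in completed weeks (no conception-date adjustment).  Because gestation is
reported in completed weeks, pre-birth timing is accurate to a week, not
a day.

Two inputs drive the recode: ``admdays`` (admission age minus maternal
age at birth; negative means before birth) and ``gage_days`` (gestational
age converted to days).  Admissions before birth are positioned relative
to pregnancy start as ``d = admdays + gage_days``; admissions on or after
the day of birth are positioned by ``admdays`` alone.

The same branch logic generalises to any bucket width (e.g. 360-day years
as ``Admyear``) through :class:`IntervalScheme`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import schemas
from .schemas import ConfigurationError

__all__ = [
    "IntervalScheme",
    "MONTH_SCHEME",
    "YEAR_SCHEME",
    "compute_admdays",
    "gestation_weeks_to_days",
    "recode_admmonth",
    "recode_interval",
    "recode_interval_array",
    "bucket_label",
    "add_timing_columns",
]

# Flag values explaining a missing bucket.
FLAG_OK = ""
FLAG_MISSING_ADMDAYS = "missing_admdays"
FLAG_MISSING_GAGE = "missing_gage"
FLAG_PREGNANCY_OVERRUN = "pregnancy_overrun"

GESTATION_VALID_WEEKS = (20, 45)


@dataclass(frozen=True)
class IntervalScheme:
    """Bucket layout for one interval width.

    Parameters
    ----------
    width_days
        Days per interior bucket (30 for months, 360 for years).
    n_pre
        Number of labelled buckets before pregnancy start; anything
        earlier falls into the open-ended bucket 0.
    n_pregnancy
        Number of labelled pregnancy buckets.  A pre-birth admission
        whose day-from-pregnancy-start does not fit in these buckets is
        unrecodable (gestation longer than the recode anticipates) and
        yields a missing bucket with a warning flag.
    n_post
        Number of labelled buckets after birth; anything later falls
        into the open-ended final bucket.
    unit
        Label word for bucket descriptions ("month", "year").
    """

    width_days: int
    n_pre: int
    n_pregnancy: int
    n_post: int
    unit: str = "interval"

    def __post_init__(self):
        for field in ("width_days", "n_pre", "n_pregnancy", "n_post"):
            if getattr(self, field) <= 0:
                raise ConfigurationError(f"IntervalScheme.{field} must be positive")

    @property
    def pregnancy_start_bucket(self) -> int:
        return self.n_pre + 1

    @property
    def post_birth_start_bucket(self) -> int:
        return self.n_pre + self.n_pregnancy + 1

    @property
    def last_bucket(self) -> int:
        return self.n_pre + self.n_pregnancy + self.n_post + 1

    @property
    def n_buckets(self) -> int:
        return self.last_bucket + 1


#: 30-day months: buckets 0..36.
MONTH_SCHEME = IntervalScheme(width_days=30, n_pre=12, n_pregnancy=11, n_post=12, unit="month")

#: 360-day years: bucket 0 = earlier, 1 = year before pregnancy,
#: 2 = pregnancy, 3 = first year after birth, 4 = later.
YEAR_SCHEME = IntervalScheme(width_days=360, n_pre=1, n_pregnancy=1, n_post=1, unit="year")


def compute_admdays(age_adm_mum, age_birth_mum):
    """Days between hospital admission and birth: admission age minus
    maternal age at birth.  Negative values mean the admission was before
    birth.  A missing input propagates to a missing (``None``) result."""
    if age_adm_mum is None or age_birth_mum is None:
        return None
    adm, birth = int(age_adm_mum), int(age_birth_mum)
    if adm < 0 or birth < 0:
        raise ValueError("ages in days must be non-negative")
    return adm - birth


def gestation_weeks_to_days(weeks, valid_weeks=GESTATION_VALID_WEEKS):
    """Convert gestational age from completed weeks to days (weeks x 7).

    Weeks outside ``valid_weeks`` raise; the registry definition admits
    gestations of at least 20 completed weeks, and values above ~45 weeks
    are recording errors.  ``None`` stays ``None`` (pre-birth buckets are
    then undefined downstream).
    """
    if weeks is None:
        return None
    weeks = int(weeks)
    lo, hi = valid_weeks
    if not lo <= weeks <= hi:
        raise ValueError(
            f"gestational age {weeks} completed weeks outside valid band [{lo}, {hi}]"
        )
    return weeks * 7


def recode_interval(admdays, gage_days, scheme: IntervalScheme):
    """Assign one admission to a bucket of ``scheme``.

    Returns ``(bucket, flag)`` where ``bucket`` is an int or ``None`` and
    ``flag`` explains a missing bucket.  Branches:

    * ``admdays >= 0`` (on/after birth): bucket by ``admdays`` alone;
      the final bucket is open-ended.
    * ``admdays < 0`` (before birth): position ``d = admdays + gage_days``
      relative to pregnancy start; ``d < 0`` falls in the pre-pregnancy
      ladder (open-ended bucket 0 below it), ``d >= 0`` in the pregnancy
      buckets.  ``d`` beyond the last pregnancy bucket is unrecodable.
    """
    if admdays is None:
        return None, FLAG_MISSING_ADMDAYS
    admdays = int(admdays)
    w = scheme.width_days
    if admdays >= 0:
        if admdays >= scheme.n_post * w:
            return scheme.last_bucket, FLAG_OK
        return scheme.post_birth_start_bucket + admdays // w, FLAG_OK
    if gage_days is None:
        return None, FLAG_MISSING_GAGE
    d = admdays + int(gage_days)
    if d < -scheme.n_pre * w:
        return 0, FLAG_OK
    if d < 0:
        # Pre-pregnancy ladder: bucket n_pre ends on day -1, each bucket
        # spans w days counting backwards.
        return scheme.n_pre - (-d - 1) // w, FLAG_OK
    if d >= scheme.n_pregnancy * w:
        return None, FLAG_PREGNANCY_OVERRUN
    return scheme.pregnancy_start_bucket + d // w, FLAG_OK


def recode_admmonth(admdays, gage_days):
    """The 37-bucket month recode (see module docstring).  Returns
    ``(bucket, flag)``."""
    return recode_interval(admdays, gage_days, MONTH_SCHEME)


def recode_interval_array(admdays, gage_days, scheme: IntervalScheme):
    """Vectorised :func:`recode_interval` over aligned arrays.

    ``admdays`` and ``gage_days`` are float arrays with NaN for missing.
    Returns ``(buckets, flags)``: a float array (NaN = missing bucket)
    and an object array of flag strings.
    """
    admdays = np.asarray(admdays, dtype=float)
    gage = np.asarray(gage_days, dtype=float)
    n = admdays.shape[0]
    out = np.full(n, np.nan)
    flags = np.full(n, FLAG_OK, dtype=object)
    w = scheme.width_days

    miss_adm = np.isnan(admdays)
    flags[miss_adm] = FLAG_MISSING_ADMDAYS

    post = ~miss_adm & (admdays >= 0)
    out[post] = np.minimum(
        scheme.post_birth_start_bucket + admdays[post] // w, scheme.last_bucket
    )

    pre = ~miss_adm & (admdays < 0)
    miss_gage = pre & np.isnan(gage)
    flags[miss_gage] = FLAG_MISSING_GAGE
    pre &= ~np.isnan(gage)
    d = admdays + gage

    before_preg = pre & (d < 0)
    out[before_preg] = np.maximum(scheme.n_pre - (-d[before_preg] - 1) // w, 0)

    in_preg = pre & (d >= 0) & (d < scheme.n_pregnancy * w)
    out[in_preg] = scheme.pregnancy_start_bucket + d[in_preg] // w

    overrun = pre & (d >= scheme.n_pregnancy * w)
    flags[overrun] = FLAG_PREGNANCY_OVERRUN
    return out, flags


def _ordinal(n: int) -> str:
    if 10 <= n % 100 <= 20:
        suffix = "th"
    else:
        suffix = {1: "st", 2: "nd", 3: "rd"}.get(n % 10, "th")
    return f"{n}{suffix}"


def bucket_label(bucket: int, scheme: IntervalScheme = MONTH_SCHEME) -> str:
    """Human-readable label of a bucket index under ``scheme``."""
    if not 0 <= bucket <= scheme.last_bucket:
        raise ValueError(f"bucket {bucket} outside [0, {scheme.last_bucket}]")
    u = scheme.unit
    if bucket == 0:
        return f"before the {_ordinal(scheme.n_pre)} {u} before pregnancy"
    if bucket <= scheme.n_pre:
        return f"the {_ordinal(scheme.n_pre - bucket + 1)} {u} before pregnancy"
    if bucket < scheme.post_birth_start_bucket:
        return f"the {_ordinal(bucket - scheme.n_pre)} {u} of pregnancy"
    if bucket < scheme.last_bucket:
        return f"the {_ordinal(bucket - scheme.post_birth_start_bucket + 1)} {u} after birth"
    return f"after the {_ordinal(scheme.n_post)} {u} after birth"


def add_timing_columns(
    master: pd.DataFrame,
    month_scheme: IntervalScheme = MONTH_SCHEME,
    year_scheme: IntervalScheme = YEAR_SCHEME,
) -> pd.DataFrame:
    """Append Admdays, Admmonth, Admyear and a missing-reason flag to the
    master table.

    Requires ``AGEAdmMum``, ``AgeBirthMum`` and ``GageDays`` columns
    (missing encoded as NaN).  Returns a copy; the flag column records,
    per row, why a month bucket is missing (empty when it is not).
    """
    schemas.require_columns(
        master, [schemas.AGE_ADM_MUM, schemas.AGE_BIRTH_MUM, schemas.GAGE_DAYS], "master"
    )
    out = master.copy()
    adm = pd.to_numeric(out[schemas.AGE_ADM_MUM], errors="coerce").to_numpy(dtype=float)
    birth = pd.to_numeric(out[schemas.AGE_BIRTH_MUM], errors="coerce").to_numpy(dtype=float)
    gage = pd.to_numeric(out[schemas.GAGE_DAYS], errors="coerce").to_numpy(dtype=float)
    admdays = adm - birth
    months, flags = recode_interval_array(admdays, gage, month_scheme)
    years, _ = recode_interval_array(admdays, gage, year_scheme)
    out[schemas.ADMDAYS] = admdays
    out[schemas.ADMMONTH] = months
    out[schemas.ADMYEAR] = years
    out[schemas.SVTI_FLAG] = flags
    return out
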