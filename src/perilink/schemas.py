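"""Column-name contracts and shared conventions for the linked registry tables.

The four input collections are tabular CSV extracts keyed by a Project
Person Number (PPN) assigned by an upstream linkage unit.  All timing is
expressed as the person's age in days rather than calendar dates — a
privacy convention of the source registries — so no date arithmetic
appears anywhere in the package.
"""

from __future__ import annotations

# -- linkage keys ------------------------------------------------------------
PPN_MUM = "PPN_mum"
PPN_BABY = "PPN_baby"

# -- births (midwives-collection style) --------------------------------------
AGE_BIRTH_MUM = "AgeBirthMum"  # maternal age in days at birth
GAGE_WEEKS = "GageWeeks"       # gestational age in completed weeks
BIRTH_ORDER = "BirthOrder"     # 1-based order of the mother's births in-study
COB = "Cob"                    # mother's country of birth (repeated covariate)
SMOKING = "SmokingPreg"
BIRTHWEIGHT = "Birthweight"

# -- congenital-conditions register ------------------------------------------
DEFECT_CODE = "DefectCode"
DEFECT_COUNT = "DefectCount"
DEFECT_ANY = "DefectAny"

# -- admitted-patient collection ---------------------------------------------
ADMISSION_ID = "AdmissionID"   # preserves input order; tie-break key
AGE_ADM_MUM = "AGEAdmMum"      # maternal age in days at admission
AGE_DIS_MUM = "AGEDisMum"      # maternal age in days at discharge
DIAG_PREFIX = "icd10d"         # diagnosis slots icd10d1 .. icd10d55
N_DIAG_SLOTS = 55

# -- opioid-treatment register -----------------------------------------------
AGE_START = "AgeStart"
AGE_END = "AgeEnd"
OPIOID_ANY = "OpioidAny"
OPIOID_EPISODES = "OpioidEpisodes"

# -- derived master-dataset columns ------------------------------------------
GAGE_DAYS = "GageDays"         # gestational age converted to days
INDEX_BIRTH_ORDER = "IndexBirthOrder"
ADMDAYS = "Admdays"            # admission day relative to birth (negative = before)
ADMMONTH = "Admmonth"          # 0-36 month bucket relative to pregnancy/birth
ADMYEAR = "Admyear"            # year-width analogue of Admmonth
SVTI_FLAG = "SvtiFlag"         # reason a bucket is missing, else empty
MORDER = "Morder"              # within-mother admission rank in window

# Explicit missing sentinel for categorical covariates.  Distinct from the
# empty string so that a CSV round-trip cannot silently turn "missing"
# into "empty field".
MISSING = "MISSING"


def diag_col(slot: int) -> str:
    """Column name of diagnosis slot ``slot`` (1 = principal, 2 = stay)."""
    if not 1 <= slot <= N_DIAG_SLOTS:
        raise ValueError(f"diagnosis slot must be in 1..{N_DIAG_SLOTS}, got {slot}")
    return f"{DIAG_PREFIX}{slot}"


DIAG_COLS = [diag_col(i) for i in range(1, N_DIAG_SLOTS + 1)]


class PerilinkError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PerilinkError):
    """A configuration value is invalid; the message names the field."""


class IntegrityError(PerilinkError):
    """Input tables violate a structural precondition (e.g. duplicate keys)."""


class SchemaError(PerilinkError):
    """A table is missing required columns."""


def require_columns(df, columns, table: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"table {table!r} is missing columns: {missing}")
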