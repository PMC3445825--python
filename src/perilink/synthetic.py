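"""Synthetic linked perinatal cohort with planted ground truth.

Emulates the four person-linked collections the toolkit consumes — a
births table, a congenital-conditions register, a hospital-admissions
table with 55 ICD-10-AM diagnosis slots, and an opioid-treatment
register — using the registries' privacy convention of ages-in-days
(no calendar dates exist anywhere).  Every admission is planted at a
known day relative to one of the mother's births, and the generator
records the truth (relative days, month bucket, diagnosis group) so
each downstream stage can be verified without any real data.

Study-population conventions baked into the defaults: mothers aged 18-44
years at birth, gestations of at least 20 completed weeks, admissions
spanning at least two years before and after birth.

The planted month bucket is derived from a literal transcription of the
printed 37-bucket recode ranges kept in this module — an independent
route from the floor-division arithmetic in :mod:`perilink.svti`, so
ground-truth recovery genuinely cross-checks the recoder.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import schemas
from .schemas import (
    ADMISSION_ID,
    AGE_ADM_MUM,
    AGE_BIRTH_MUM,
    AGE_DIS_MUM,
    AGE_END,
    AGE_START,
    BIRTH_ORDER,
    BIRTHWEIGHT,
    COB,
    DEFECT_CODE,
    DIAG_COLS,
    GAGE_WEEKS,
    MISSING,
    PPN_BABY,
    PPN_MUM,
    SMOKING,
    ConfigurationError,
    diag_col,
)

__all__ = ["GeneratorConfig", "generate_cohort", "write_cohort", "Cohort"]

# Code pool entries: (code, sampling weight, diagnosis group).  Group is
# 1..9 for the specific psychiatric groups, 10 for codes inside the
# overall mental-illness chapter but captured by no specific group, and
# 0 for non-psychiatric codes.  The groups are hand-annotated from the
# published ranges and frozen here so the planted truth does not depend
# on the classifier under test.
DEFAULT_CODE_POOL = (
    ("F20", 2.0, 1),
    ("F25", 1.0, 1),
    ("F32.0", 2.0, 2),
    ("F53.0", 1.0, 2),
    ("F23", 1.0, 3),
    ("F30.9", 1.0, 4),
    ("F43.0", 2.0, 5),
    ("F41.1", 2.0, 6),
    ("F60.3", 1.0, 7),
    ("F10.0", 2.0, 8),
    ("F11.2", 1.0, 8),
    ("F05", 1.0, 9),
    ("F45.0", 1.0, 9),
    ("F33.0", 1.0, 10),   # inside F00-F99 but in no specific group
    ("O80", 4.0, 0),
    ("Z37.0", 2.0, 0),
    ("I10", 1.0, 0),
    ("R10.4", 1.0, 0),
)

_COB_VALUES = ("AUS", "NZ", "UK", "CHN", "IND", "VNM", "LBN")
_DEFECT_CODES = ("Q21.1", "Q36.9", "Q66.8", "Q90.9")


def _pre_pregnancy_ranges():
    # Printed ladder: (lowest..-361 -> 0), (-360..-331 -> 1), ... (-30..-1 -> 12)
    ranges = [(-(10**9), -361, 0)]
    for k in range(1, 13):
        lo = -360 + (k - 1) * 30
        ranges.append((lo, lo + 29, k))
    return ranges


def _pregnancy_ranges():
    # (0..29 -> 13), (30..59 -> 14), ... (300..329 -> 23)
    return [(30 * (k - 13), 30 * (k - 13) + 29, k) for k in range(13, 24)]


def _post_birth_ranges():
    # (0..29 -> 24), ... (330..359 -> 35), (360..highest -> 36)
    ranges = [(30 * (k - 24), 30 * (k - 24) + 29, k) for k in range(24, 36)]
    ranges.append((360, 10**9, 36))
    return ranges


_PRE = _pre_pregnancy_ranges()
_PREG = _pregnancy_ranges()
_POST = _post_birth_ranges()


def true_admmonth(rel_day_birth: int, gage_days: int):
    """Planted month bucket from the literal printed recode ranges."""
    if rel_day_birth >= 0:
        table = _POST
        x = rel_day_birth
    else:
        x = rel_day_birth + gage_days
        table = _PRE if x < 0 else _PREG
    for lo, hi, bucket in table:
        if lo <= x <= hi:
            return bucket
    return None  # pre-birth day beyond the last pregnancy bucket


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic cohort; defaults are the study conditions.

    ``births_per_mother_probs`` is the probability vector over one or two
    in-study births; ``admission_rate`` is the expected number of
    admissions per mother over the observation window;
    ``relative_day_range`` bounds the planted admission day relative to
    the target birth (default three years either side, comfortably
    covering the two-year tracing requirement); ``missing_rate`` /
    ``conflict_rate`` plant repair work for the consistency stage.
    """

    n_mothers: int = 1000
    births_per_mother_probs: tuple = (0.8, 0.2)
    maternal_age_range_years: tuple = (18, 44)
    gestation_weeks_range: tuple = (20, 44)
    admission_rate: float = 3.0
    relative_day_range: tuple = (-1080, 1080)
    los_days_range: tuple = (0, 60)
    code_pool: tuple = DEFAULT_CODE_POOL
    missing_rate: float = 0.10
    conflict_rate: float = 0.02
    temporal_profile: str = "uniform"   # "uniform" | "peaked"
    phdas_rate: float = 0.05
    defect_rate: float = 0.03
    extra_diagnosis_mean: float = 1.0
    n_orphan_admissions: int = 0
    seed: int = 0

    def validate(self) -> None:
        if self.n_mothers < 0:
            raise ConfigurationError("n_mothers must be >= 0")
        if not self.code_pool:
            raise ConfigurationError("code_pool must be non-empty")
        if abs(sum(p for p in self.births_per_mother_probs) - 1.0) > 1e-9:
            raise ConfigurationError("births_per_mother_probs must sum to 1")
        for name in ("maternal_age_range_years", "gestation_weeks_range",
                     "relative_day_range", "los_days_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ConfigurationError(f"{name} is inverted: [{lo}, {hi}]")
        if self.gestation_weeks_range[0] < 20:
            raise ConfigurationError(
                "gestation_weeks_range lower bound must be >= 20 completed weeks"
            )
        for name in ("missing_rate", "conflict_rate", "phdas_rate", "defect_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be a probability, got {v}")
        for name in ("admission_rate", "extra_diagnosis_mean"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.temporal_profile not in ("uniform", "peaked"):
            raise ConfigurationError(
                f"temporal_profile must be 'uniform' or 'peaked', got {self.temporal_profile!r}"
            )
        if self.n_orphan_admissions < 0:
            raise ConfigurationError("n_orphan_admissions must be >= 0")


@dataclass
class Cohort:
    """The four generated tables plus the planted ground truth."""

    births: pd.DataFrame
    rcc: pd.DataFrame
    admissions: pd.DataFrame
    phdas: pd.DataFrame
    ground_truth: pd.DataFrame
    mother_truth: pd.DataFrame
    config: GeneratorConfig = field(repr=False, default=None)


def _choose_index_birth(adm_age, birth_entries):
    """Nearest birth on/after the admission day, else nearest before —
    the default downstream referencing rule, recomputed here so the
    planted truth states what the pipeline should produce."""
    subsequent = [e for e in birth_entries if e[0] >= adm_age]
    if subsequent:
        return min(subsequent)
    return max(e for e in birth_entries if e[0] < adm_age)


def generate_cohort(config: GeneratorConfig) -> Cohort:
    """Generate the linked tables; identical config + seed reproduces
    identical tables."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    codes = [c for c, _, _ in config.code_pool]
    weights = np.array([w for _, w, _ in config.code_pool], dtype=float)
    weights /= weights.sum()
    group_of = {c: g for c, _, g in config.code_pool}

    age_lo = config.maternal_age_range_years[0] * 365
    age_hi = config.maternal_age_range_years[1] * 365
    gw_lo, gw_hi = config.gestation_weeks_range
    rel_lo, rel_hi = config.relative_day_range
    los_lo, los_hi = config.los_days_range

    birth_rows, rcc_rows, adm_rows, phdas_rows = [], [], [], []
    truth_rows, mother_truth_rows = [], []
    adm_counter = 0

    for i in range(config.n_mothers):
        ppn = f"M{i:06d}"
        n_births = 1 + rng.choice(len(config.births_per_mother_probs),
                                  p=np.asarray(config.births_per_mother_probs))
        if n_births == 2:
            gap = int(rng.integers(300, 731))
            first_age = int(rng.integers(age_lo, age_hi - gap + 1))
            birth_ages = [first_age, first_age + gap]
        else:
            birth_ages = [int(rng.integers(age_lo, age_hi + 1))]

        true_cob = str(rng.choice(_COB_VALUES))
        conflict = n_births == 2 and rng.random() < config.conflict_rate
        cob_values = [true_cob] * n_births
        if conflict:
            alternates = [c for c in _COB_VALUES if c != true_cob]
            cob_values[0] = str(rng.choice(alternates))
        cob_values = [
            MISSING if rng.random() < config.missing_rate else v for v in cob_values
        ]
        mother_truth_rows.append(
            {PPN_MUM: ppn, "true_cob": true_cob, "cob_conflict": int(conflict)}
        )

        entries = []  # (birth age, gage days)
        for order, b_age in enumerate(birth_ages, start=1):
            gw = int(rng.integers(gw_lo, gw_hi + 1))
            entries.append((b_age, gw * 7))
            birth_rows.append(
                {
                    PPN_MUM: ppn,
                    PPN_BABY: f"B{i:06d}_{order}",
                    BIRTH_ORDER: order,
                    AGE_BIRTH_MUM: b_age,
                    GAGE_WEEKS: gw,
                    COB: cob_values[order - 1],
                    SMOKING: str(rng.choice(["N", "N", "N", "Y"])),
                    BIRTHWEIGHT: int(rng.normal(3400, 500)),
                }
            )
            if rng.random() < config.defect_rate:
                for _ in range(int(rng.integers(1, 4))):
                    rcc_rows.append(
                        {
                            PPN_BABY: f"B{i:06d}_{order}",
                            DEFECT_CODE: str(rng.choice(_DEFECT_CODES)),
                        }
                    )

        n_adm = int(rng.poisson(config.admission_rate))
        for _ in range(n_adm):
            target = int(rng.integers(0, n_births))
            if config.temporal_profile == "peaked" and rng.random() < 0.6:
                rel = int(np.clip(round(rng.normal(0.0, 120.0)), rel_lo, rel_hi))
            else:
                rel = int(rng.integers(rel_lo, rel_hi + 1))
            adm_age = birth_ages[target] + rel
            los = int(rng.integers(los_lo, los_hi + 1))
            principal = codes[int(rng.choice(len(codes), p=weights))]
            diagnoses = {c: "" for c in DIAG_COLS}
            diagnoses[diag_col(1)] = principal
            n_extra = min(int(rng.poisson(config.extra_diagnosis_mean)), 4)
            for slot in range(2, 2 + n_extra):
                diagnoses[diag_col(slot)] = codes[int(rng.choice(len(codes), p=weights))]
            adm_id = f"A{adm_counter:07d}"
            adm_counter += 1
            adm_rows.append(
                {
                    ADMISSION_ID: adm_id,
                    PPN_MUM: ppn,
                    AGE_ADM_MUM: adm_age,
                    AGE_DIS_MUM: adm_age + los,
                    **diagnoses,
                }
            )
            # Truth is stated against the birth the default referencing
            # rule selects for this admission age.
            idx_age, idx_gage = _choose_index_birth(adm_age, entries)
            true_rel = adm_age - idx_age
            truth_rows.append(
                {
                    ADMISSION_ID: adm_id,
                    PPN_MUM: ppn,
                    "true_rel_day_birth": true_rel,
                    "true_rel_day_pregnancy": (
                        true_rel + idx_gage if true_rel < 0 else np.nan
                    ),
                    "true_admmonth": true_admmonth(true_rel, idx_gage),
                    "true_prin_group": group_of[principal],
                }
            )

        if rng.random() < config.phdas_rate:
            for _ in range(int(rng.integers(1, 3))):
                start = birth_ages[0] + int(rng.integers(rel_lo, rel_hi + 1))
                phdas_rows.append(
                    {
                        PPN_MUM: ppn,
                        AGE_START: start,
                        AGE_END: start + int(rng.integers(30, 366)),
                    }
                )

    for j in range(config.n_orphan_admissions):
        adm_age = int(rng.integers(age_lo, age_hi))
        diagnoses = {c: "" for c in DIAG_COLS}
        diagnoses[diag_col(1)] = codes[int(rng.choice(len(codes), p=weights))]
        adm_rows.append(
            {
                ADMISSION_ID: f"A{adm_counter:07d}",
                PPN_MUM: f"X{j:04d}",
                AGE_ADM_MUM: adm_age,
                AGE_DIS_MUM: adm_age + int(rng.integers(los_lo, los_hi + 1)),
                **diagnoses,
            }
        )
        adm_counter += 1

    birth_cols = [PPN_MUM, PPN_BABY, BIRTH_ORDER, AGE_BIRTH_MUM, GAGE_WEEKS,
                  COB, SMOKING, BIRTHWEIGHT]
    adm_cols = [ADMISSION_ID, PPN_MUM, AGE_ADM_MUM, AGE_DIS_MUM, *DIAG_COLS]
    truth_cols = [ADMISSION_ID, PPN_MUM, "true_rel_day_birth",
                  "true_rel_day_pregnancy", "true_admmonth", "true_prin_group"]
    return Cohort(
        births=pd.DataFrame(birth_rows, columns=birth_cols),
        rcc=pd.DataFrame(rcc_rows, columns=[PPN_BABY, DEFECT_CODE]),
        admissions=pd.DataFrame(adm_rows, columns=adm_cols),
        phdas=pd.DataFrame(phdas_rows, columns=[PPN_MUM, AGE_START, AGE_END]),
        ground_truth=pd.DataFrame(truth_rows, columns=truth_cols),
        mother_truth=pd.DataFrame(
            mother_truth_rows, columns=[PPN_MUM, "true_cob", "cob_conflict"]
        ),
        config=config,
    )


def write_cohort(cohort: Cohort, outdir) -> dict:
    """Write the cohort as CSVs plus a JSON sidecar echoing config+seed.

    Returns the mapping of table name to file path.  Output is
    deterministic byte-for-byte for a fixed config.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in [
        ("births", cohort.births),
        ("rcc", cohort.rcc),
        ("admissions", cohort.admissions),
        ("phdas", cohort.phdas),
        ("ground_truth", cohort.ground_truth),
        ("mother_truth", cohort.mother_truth),
    ]:
        path = outdir / f"{name}.csv"
        df.to_csv(path, index=False, lineterminator="\n")
        paths[name] = str(path)
    sidecar = outdir / "cohort_config.json"
    cfg = asdict(cohort.config)
    cfg["code_pool"] = [list(e) for e in cfg["code_pool"]]
    sidecar.write_text(json.dumps(cfg, indent=2, sort_keys=True) + "\n")
    paths["config"] = str(sidecar)
    return paths
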