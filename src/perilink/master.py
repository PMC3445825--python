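"""Master-dataset construction from the four linked collections.

The build follows the registry-linkage pattern: (1) merge births with the
congenital-conditions register per baby, (2) consolidate each mother's
births into one wide record keyed by birth order, repairing repeated
covariates for consistency and completeness, (3) left-join the mother's
hospital admissions and opioid-treatment episodes by her person number,
referencing every admission to exactly one index birth.

Nothing is silently dropped: admissions or defect records whose person
number matches no birth are routed to orphan reports, and covariate
repair is summarised in a per-(mother, field) consistency report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import schemas
from .schemas import (
    AGE_ADM_MUM,
    AGE_BIRTH_MUM,
    BIRTH_ORDER,
    GAGE_DAYS,
    GAGE_WEEKS,
    INDEX_BIRTH_ORDER,
    MISSING,
    OPIOID_ANY,
    OPIOID_EPISODES,
    PPN_BABY,
    PPN_MUM,
    IntegrityError,
)

__all__ = [
    "INDEX_BIRTH_POLICIES",
    "resolve_repeated_variable",
    "merge_birth_defects",
    "reshape_births_by_mother",
    "join_mother_admissions",
    "build_master",
    "MasterBuild",
]

#: Known rules for referencing an admission to one of the mother's births.
INDEX_BIRTH_POLICIES = (
    "nearest_subsequent_else_previous",
    "nearest_previous_else_subsequent",
    "nearest",
)

_REPEATED_COVARIATES = (schemas.COB, schemas.SMOKING)


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and np.isnan(value):
        return True
    s = str(value).strip()
    return s == "" or s == MISSING


def resolve_repeated_variable(values):
    """Resolve one mother's repeated categorical values across her births.

    ``values`` is ordered by birth order.  Returns ``(resolved, conflict)``:

    * all values missing -> (``MISSING``, False)
    * all non-missing values identical -> that value, False (missing
      cells are thereby filled — the consistency-repair payoff of the
      master dataset)
    * otherwise -> majority value, ties broken by the latest birth,
      conflict = True.
    """
    if not values:
        raise ValueError("resolve_repeated_variable requires a non-empty list")
    observed = [(i, v) for i, v in enumerate(values) if not _is_missing(v)]
    if not observed:
        return MISSING, False
    distinct = {v for _, v in observed}
    if len(distinct) == 1:
        return observed[0][1], False
    counts: dict = {}
    last_seen: dict = {}
    for i, v in observed:
        counts[v] = counts.get(v, 0) + 1
        last_seen[v] = i
    best = max(counts.values())
    winner = max((v for v in counts if counts[v] == best), key=last_seen.get)
    return winner, True


def merge_birth_defects(births: pd.DataFrame, rcc: pd.DataFrame):
    """Left-join defect counts from the congenital register onto births.

    Returns ``(births_with_defects, unmatched_rcc)``.  Every birth is
    preserved; ``DefectCount`` is the number of register rows for the
    baby and ``DefectAny`` its indicator.  Register rows whose baby is
    absent from the births table are reported, never dropped silently.
    """
    schemas.require_columns(births, [PPN_BABY], "births")
    schemas.require_columns(rcc, [PPN_BABY], "rcc")
    dup = births[PPN_BABY][births[PPN_BABY].duplicated()]
    if len(dup):
        raise IntegrityError(
            f"duplicate {PPN_BABY} in births table: {sorted(dup.unique())[:10]}"
        )
    counts = rcc.groupby(PPN_BABY).size()
    out = births.copy()
    out[schemas.DEFECT_COUNT] = (
        out[PPN_BABY].map(counts).fillna(0).astype(int)
    )
    out[schemas.DEFECT_ANY] = (out[schemas.DEFECT_COUNT] > 0).astype(int)
    unmatched = rcc[~rcc[PPN_BABY].isin(set(births[PPN_BABY]))].copy()
    return out, unmatched


def reshape_births_by_mother(births: pd.DataFrame) -> pd.DataFrame:
    """One wide row per mother with birth-order-suffixed columns.

    Every birth field ``X`` becomes ``X_b1``, ``X_b2``, ... in birth
    order; no field is lost.  Repeated covariates are additionally
    resolved into ``X_resolved`` / ``X_conflict`` columns (see
    :func:`resolve_repeated_variable`).
    """
    schemas.require_columns(births, [PPN_MUM, BIRTH_ORDER], "births")
    dup = births[[PPN_MUM, BIRTH_ORDER]].duplicated()
    if dup.any():
        offenders = births.loc[dup, [PPN_MUM, BIRTH_ORDER]].to_records(index=False)
        raise IntegrityError(
            f"duplicate (mother, birth order) pairs: {list(offenders)[:10]}"
        )
    value_cols = [c for c in births.columns if c != PPN_MUM]
    wide = births.pivot(index=PPN_MUM, columns=BIRTH_ORDER, values=value_cols)
    wide.columns = [f"{col}_b{order}" for col, order in wide.columns]
    wide = wide.reset_index().sort_values(PPN_MUM).reset_index(drop=True)

    orders = sorted(births[BIRTH_ORDER].unique())
    for cov in _REPEATED_COVARIATES:
        if cov not in births.columns:
            continue
        cols = [f"{cov}_b{o}" for o in orders if f"{cov}_b{o}" in wide.columns]
        resolved, conflict = [], []
        for _, row in wide[cols].iterrows():
            values = [row[c] for c in cols if not pd.isna(row[c])]
            r, c = resolve_repeated_variable(values if values else [MISSING])
            resolved.append(r)
            conflict.append(int(c))
        wide[f"{cov}_resolved"] = resolved
        wide[f"{cov}_conflict"] = conflict
    return wide


def consistency_report(births: pd.DataFrame, fields=_REPEATED_COVARIATES) -> pd.DataFrame:
    """Per-(mother, field) account of the repeated-covariate repair.

    Columns: mother, field, n_records, n_missing_before, n_missing_after,
    conflict, resolved_value.  Missingness never increases: after repair
    a mother's missing count is 0 unless every record was missing.
    """
    rows = []
    for ppn, grp in births.sort_values(BIRTH_ORDER).groupby(PPN_MUM, sort=True):
        for fld in fields:
            if fld not in births.columns:
                continue
            values = list(grp[fld])
            resolved, conflict = resolve_repeated_variable(values)
            n_missing_before = sum(_is_missing(v) for v in values)
            n_missing_after = len(values) if _is_missing(resolved) else 0
            rows.append(
                {
                    PPN_MUM: ppn,
                    "field": fld,
                    "n_records": len(values),
                    "n_missing_before": n_missing_before,
                    "n_missing_after": n_missing_after,
                    "conflict": int(conflict),
                    "resolved_value": resolved,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            PPN_MUM,
            "field",
            "n_records",
            "n_missing_before",
            "n_missing_after",
            "conflict",
            "resolved_value",
        ],
    )


def _choose_index_birth(adm_age: float, birth_ages: np.ndarray, policy: str) -> int:
    """Index (into sorted birth_ages) of the birth an admission refers to."""
    subsequent = np.nonzero(birth_ages >= adm_age)[0]
    previous = np.nonzero(birth_ages < adm_age)[0]
    if policy == "nearest_subsequent_else_previous":
        return int(subsequent[0]) if len(subsequent) else int(previous[-1])
    if policy == "nearest_previous_else_subsequent":
        return int(previous[-1]) if len(previous) else int(subsequent[0])
    if policy == "nearest":
        return int(np.argmin(np.abs(birth_ages - adm_age)))
    raise schemas.ConfigurationError(
        f"unknown index_birth_policy {policy!r}; known: {INDEX_BIRTH_POLICIES}"
    )


@dataclass
class MasterBuild:
    """Artifacts of a full master-dataset build."""

    master: pd.DataFrame          # one row per admission joined to its mother
    mothers: pd.DataFrame         # one row per mother (wide births + PHDAS attrs)
    orphan_admissions: pd.DataFrame
    orphan_rcc: pd.DataFrame = field(default_factory=pd.DataFrame)
    orphan_phdas: pd.DataFrame = field(default_factory=pd.DataFrame)
    consistency: pd.DataFrame = field(default_factory=pd.DataFrame)


def join_mother_admissions(
    mothers: pd.DataFrame,
    admissions: pd.DataFrame,
    phdas: pd.DataFrame | None = None,
    index_birth_policy: str = "nearest_subsequent_else_previous",
):
    """Join admissions (and treatment episodes) to the mother-level table.

    Left join on the mother's person number: mothers without admissions
    stay in the mother-level output and contribute zero master rows;
    admissions whose person number matches no mother go to an orphan
    report.  Each admission is referenced to exactly one index birth
    chosen by ``index_birth_policy`` (default: the nearest birth on or
    after the admission day, else the nearest before), and the index
    birth's age-at-birth and gestation-in-days are attached for the
    timing recode downstream.

    Opioid-treatment episodes are folded in as mother-level attributes
    (any-treatment flag and episode count), not expanded rows.

    Returns a :class:`MasterBuild` (without consistency report).
    """
    schemas.require_columns(mothers, [PPN_MUM], "mothers")
    schemas.require_columns(admissions, [PPN_MUM, AGE_ADM_MUM], "admissions")
    if index_birth_policy not in INDEX_BIRTH_POLICIES:
        raise schemas.ConfigurationError(
            f"unknown index_birth_policy {index_birth_policy!r}; known: {INDEX_BIRTH_POLICIES}"
        )

    birth_age_cols = sorted(
        (c for c in mothers.columns if c.startswith(f"{AGE_BIRTH_MUM}_b")),
        key=lambda c: int(c.rsplit("_b", 1)[1]),
    )
    orders = [int(c.rsplit("_b", 1)[1]) for c in birth_age_cols]
    gage_cols = [f"{GAGE_WEEKS}_b{o}" for o in orders]

    birth_lookup = {}
    for _, row in mothers.iterrows():
        entries = []
        for order, acol, gcol in zip(orders, birth_age_cols, gage_cols):
            age = row.get(acol)
            if pd.isna(age):
                continue
            gw = row.get(gcol) if gcol in mothers.columns else np.nan
            entries.append((float(age), order, float(gw) if not pd.isna(gw) else np.nan))
        entries.sort()
        birth_lookup[row[PPN_MUM]] = entries

    known = admissions[PPN_MUM].isin(birth_lookup.keys())
    orphans = admissions[~known].copy()
    kept = admissions[known].copy()

    idx_age, idx_order, idx_gage = [], [], []
    for ppn, adm_age in zip(kept[PPN_MUM], kept[AGE_ADM_MUM]):
        entries = birth_lookup[ppn]
        ages = np.array([e[0] for e in entries])
        i = _choose_index_birth(float(adm_age), ages, index_birth_policy)
        age, order, gw = entries[i]
        idx_age.append(age)
        idx_order.append(order)
        idx_gage.append(gw * 7 if not np.isnan(gw) else np.nan)
    kept[AGE_BIRTH_MUM] = idx_age
    kept[INDEX_BIRTH_ORDER] = idx_order
    kept[GAGE_DAYS] = idx_gage

    mothers_out = mothers.copy()
    if phdas is not None and len(phdas):
        schemas.require_columns(phdas, [PPN_MUM], "phdas")
        counts = phdas.groupby(PPN_MUM).size()
        mothers_out[OPIOID_EPISODES] = (
            mothers_out[PPN_MUM].map(counts).fillna(0).astype(int)
        )
        orphan_phdas = phdas[~phdas[PPN_MUM].isin(set(mothers[PPN_MUM]))].copy()
    else:
        mothers_out[OPIOID_EPISODES] = 0
        orphan_phdas = pd.DataFrame(columns=[PPN_MUM])
    mothers_out[OPIOID_ANY] = (mothers_out[OPIOID_EPISODES] > 0).astype(int)

    return MasterBuild(
        master=kept.reset_index(drop=True),
        mothers=mothers_out,
        orphan_admissions=orphans.reset_index(drop=True),
        orphan_phdas=orphan_phdas.reset_index(drop=True),
    )


def build_master(
    births: pd.DataFrame,
    rcc: pd.DataFrame,
    admissions: pd.DataFrame,
    phdas: pd.DataFrame | None = None,
    index_birth_policy: str = "nearest_subsequent_else_previous",
) -> MasterBuild:
    """Full build: defects onto births, births wide per mother with
    covariate repair, then admissions/treatment joined per mother."""
    births_d, orphan_rcc = merge_birth_defects(births, rcc)
    mothers = reshape_births_by_mother(births_d)
    build = join_mother_admissions(mothers, admissions, phdas, index_birth_policy)
    build.orphan_rcc = orphan_rcc
    build.consistency = consistency_report(births)
    return build
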