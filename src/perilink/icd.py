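"""ICD-10-AM psychiatric diagnosis grouping by code ranges.

Ten diagnosis groups over ICD-10 Chapter F (mental and behavioural
disorders, F00-F99), defined as inclusive code intervals and single
codes:

1. schizophrenia and schizophrenia-like disorders
2. unipolar depressions (incl. puerperal F53.0)
3. acute psychotic episodes
4. bipolar affective disorders
5. adjustment disorders
6. anxiety disorders
7. personality disorders
8. mental illness due to substance use
9. remaining F-chapter diagnoses (explicitly listed ranges)
10. overall mental illness (F00-F99)

The ranges are a frozen transcription of the source study's grouping and
are applied by plain byte-wise lexicographic comparison on dotted
canonical codes ('F32.1'), which reproduces blank-padded string
comparison in SPSS-style systems because a proper prefix always sorts
before its extensions.  The transcription is deliberately kept verbatim,
including its gaps: real codes such as F19.9, F33.0, F44.0-F44.4 and F70
fall in no group 1-9 although they are inside group 10.
:func:`audit_partition` makes those gaps (and any overlaps) visible
rather than silently repairing them.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass

from .schemas import PerilinkError

__all__ = [
    "IcdCodeError",
    "CodeInterval",
    "GroupRuleSet",
    "TABLE_RULESET_V1",
    "RULESETS",
    "N_GROUPS",
    "normalize_code",
    "code_in_interval",
    "classify_principal",
    "classify_any",
    "classify_table",
    "audit_partition",
    "chapter_f_universe",
]

N_GROUPS = 10

_CODE_RE = re.compile(r"^[A-Z][0-9]{2}(\.[0-9]{1,2})?$")


class IcdCodeError(PerilinkError):
    """Raised for a diagnosis code that cannot be canonicalised."""


def normalize_code(raw: str) -> str:
    """Canonicalise a raw diagnosis code to dotted upper-case form.

    Accepts the dotless dialect used by some extracts ('F320' -> 'F32.0');
    strips whitespace and upper-cases.  Anything not matching
    letter + 2 digits + optional '.' + 1-2 digits is rejected.
    """
    if raw is None:
        raise IcdCodeError("diagnosis code is None")
    s = str(raw).strip().upper().replace(" ", "")
    if not s:
        raise IcdCodeError("diagnosis code is empty")
    if "." not in s and len(s) > 3:
        s = s[:3] + "." + s[3:]
    if not _CODE_RE.match(s):
        raise IcdCodeError(f"unparseable diagnosis code: {raw!r}")
    return s


@dataclass(frozen=True)
class CodeInterval:
    """Inclusive code interval [lo, hi] under lexicographic order."""

    lo: str
    hi: str

    def __post_init__(self):
        if self.lo > self.hi:
            raise ValueError(f"inverted code interval [{self.lo}, {self.hi}]")

    @classmethod
    def single(cls, code: str) -> "CodeInterval":
        return cls(code, code)


def code_in_interval(code: str, interval: CodeInterval) -> bool:
    """True iff lo <= code <= hi byte-wise on canonical dotted codes."""
    return interval.lo <= code <= interval.hi


def _iv(lo, hi=None):
    return CodeInterval(lo, hi if hi is not None else lo)


@dataclass(frozen=True)
class GroupRuleSet:
    """A named, versioned set of ten diagnosis-group interval lists.

    The transcription is frozen: any edit must ship as a new version
    name so that classified outputs remain traceable to the exact rules.
    """

    version: str
    groups: tuple  # tuple of (group index 1..10, tuple[CodeInterval, ...])

    def intervals(self, group: int):
        for k, ivs in self.groups:
            if k == group:
                return ivs
        raise KeyError(group)

    def to_json(self) -> str:
        doc = {
            "version": self.version,
            "groups": {
                str(k): [[iv.lo, iv.hi] for iv in ivs] for k, ivs in self.groups
            },
        }
        return json.dumps(doc, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroupRuleSet":
        doc = json.loads(text)
        groups = tuple(
            (int(k), tuple(CodeInterval(lo, hi) for lo, hi in ivs))
            for k, ivs in sorted(doc["groups"].items(), key=lambda kv: int(kv[0]))
        )
        return cls(version=doc["version"], groups=groups)


#: Frozen transcription of the published grouping (see module docstring).
TABLE_RULESET_V1 = GroupRuleSet(
    version="table2-v1",
    groups=(
        (1, (_iv("F20", "F22.9"), _iv("F24", "F29"))),
        (2, (
            _iv("F32", "F32.21"),
            _iv("F32.8", "F32.91"),
            _iv("F53.0"),
            _iv("F34.1"),
            _iv("F38.1"),
            _iv("F38.8"),
        )),
        (3, (
            _iv("F23", "F23.91"),
            _iv("F32.3", "F32.31"),
            _iv("F30.2"),
            _iv("F33.3"),
            _iv("F39"),
            _iv("F53.1"),
        )),
        (4, (
            _iv("F30.8", "F30.9"),
            _iv("F31", "F31.6"),
            _iv("F31.8", "F31.9"),
            _iv("F30.0"),
            _iv("F34.0"),
            _iv("F38.0"),
        )),
        (5, (_iv("F43", "F43.9"),)),
        (6, (_iv("F40", "F42.9"),)),
        (7, (_iv("F60", "F69"),)),
        (8, (_iv("F10", "F19.8"),)),
        (9, (
            _iv("F00", "F09"),
            _iv("F30.1"),
            _iv("F31.7"),
            _iv("F33.1", "F33.2"),
            _iv("F33.8", "F33.9"),
            _iv("F34.9"),
            _iv("F44.5", "F52.9"),
            _iv("F53.8", "F59"),
            _iv("F70.1", "F99"),
        )),
        (10, (_iv("F00", "F99"),)),
    ),
)

RULESETS = {TABLE_RULESET_V1.version: TABLE_RULESET_V1}


def classify_principal(code: str, rules: GroupRuleSet = TABLE_RULESET_V1) -> dict:
    """Group flags for one principal diagnosis code.

    Returns ``{1: 0/1, ..., 10: 0/1}``.  The code is canonicalised first;
    codes outside the rule intervals (e.g. anything not in Chapter F)
    yield all zeros.
    """
    canonical = normalize_code(code)
    flags = {}
    for k, ivs in rules.groups:
        flags[k] = int(any(code_in_interval(canonical, iv) for iv in ivs))
    return flags


def classify_any(codes, rules: GroupRuleSet = TABLE_RULESET_V1) -> dict:
    """Group flags over a list of diagnosis slots (stay + other diagnoses).

    Empty / None slots are ignored; flag K is 1 iff any non-empty slot
    falls in group K.
    """
    flags = {k: 0 for k, _ in rules.groups}
    for raw in codes:
        if raw is None or str(raw).strip() == "":
            continue
        for k, v in classify_principal(raw, rules).items():
            flags[k] |= v
    return flags


def chapter_f_universe(depths=(3, 4, 5)) -> list:
    """All syntactically valid Chapter F codes at the given significant-
    character depths: 'F00'..'F99' (3), one decimal ('F32.1', 4) and two
    decimals ('F32.01', 5).  Sorted, deduplicated."""
    out = []
    for n in range(100):
        stem = f"F{n:02d}"
        if 3 in depths:
            out.append(stem)
        if 4 in depths:
            out.extend(f"{stem}.{d}" for d in range(10))
        if 5 in depths:
            out.extend(f"{stem}.{d}{e}" for d in range(10) for e in range(10))
    return sorted(set(out))


def classify_table(master, rules: GroupRuleSet = TABLE_RULESET_V1, last_other_slot: int = 52):
    """Append Prin1..Prin10 and Other1..Other10 columns to a master table.

    ``PrinK`` flags the principal diagnosis (slot 1); ``OtherK`` flags
    the stay and other diagnoses (slots 2..``last_other_slot``).  Unknown
    or empty principal codes yield all-zero flags.  Returns a copy.
    """
    import pandas as pd

    from .schemas import diag_col

    out = master.copy()
    principal_flags = {k: [] for k, _ in rules.groups}
    cache: dict = {}
    col1 = diag_col(1)
    for raw in out[col1] if col1 in out.columns else []:
        key = str(raw)
        if key not in cache:
            try:
                cache[key] = classify_principal(key, rules)
            except IcdCodeError:
                cache[key] = {k: 0 for k, _ in rules.groups}
        for k, v in cache[key].items():
            principal_flags[k].append(v)
    for k in principal_flags:
        out[f"Prin{k}"] = principal_flags[k]

    other_cols = [
        diag_col(i) for i in range(2, last_other_slot + 1)
        if diag_col(i) in out.columns
    ]
    if other_cols:
        other_flags = {k: [] for k, _ in rules.groups}
        for _, row in out[other_cols].iterrows():
            slot_flags = {k: 0 for k, _ in rules.groups}
            for raw in row:
                key = str(raw)
                if not key.strip() or pd.isna(raw):
                    continue
                if key not in cache:
                    try:
                        cache[key] = classify_principal(key, rules)
                    except IcdCodeError:
                        cache[key] = {k: 0 for k, _ in rules.groups}
                for k, v in cache[key].items():
                    slot_flags[k] |= v
            for k, v in slot_flags.items():
                other_flags[k].append(v)
        for k in other_flags:
            out[f"Other{k}"] = other_flags[k]
    return out


def audit_partition(universe, rules: GroupRuleSet = TABLE_RULESET_V1) -> dict:
    """Audit the rule intervals over a code universe.

    Returns a dict with:

    * ``hits``: sorted list of (code, tuple of groups 1..9 hit)
    * ``gaps``: Chapter F codes hit by no group 1..9 (visible coverage
      holes in the published ranges)
    * ``overlaps``: codes hit by two or more of groups 1..9

    Deterministic: inputs are canonicalised, deduplicated and sorted.
    """
    canon = sorted({normalize_code(c) for c in universe})
    hits, gaps, overlaps = [], [], []
    for code in canon:
        flags = classify_principal(code, rules)
        groups = tuple(k for k in range(1, N_GROUPS) if flags[k])
        hits.append((code, groups))
        if code.startswith("F") and not groups:
            gaps.append(code)
        if len(groups) >= 2:
            overlaps.append(code)
    return {"hits": hits, "gaps": gaps, "overlaps": overlaps}
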