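# Methods

## The preparation model

The toolkit treats a perinatal linked-data study as four tables keyed by
an upstream Project Person Number: births (one row per baby, carrying the
mother's age in days at birth, gestational age in completed weeks and
maternal covariates), congenital conditions (rows per notified defect),
hospital admissions (one row per episode with ages in days at admission
and discharge and up to 55 ICD-10-AM diagnosis slots: slot 1 principal,
slot 2 stay, 3+ other), and opioid-treatment episodes. Probabilistic
linkage itself happens upstream; person numbers are taken as given, and
linkage quality is out of scope. All timing is ages-in-days — a privacy
design of the source registries — so the package contains no calendar
arithmetic at all.

## Time-interval recode

An admission's position is `Admdays = AGEAdmMum − AgeBirthMum`. Pre-birth
admissions are positioned relative to pregnancy start as
`d = Admdays + Gage`, where `Gage` is gestational age converted from
completed weeks to days (×7). "Pregnancy start" is therefore the first
day of the last menstrual period as implied by the recorded gestation;
conception sits about 14 days later, and no adjustment for it is applied
or exposed — the recode follows the registry convention.

The month variable uses 30-day months and 360-day years. The bucket
layout (0 open-ended early; 1–12 pre-pregnancy; 13–23 pregnancy; 24–35
post-birth; 36 open-ended late) is computed by floor division, which the
test suite proves equivalent — over `Admdays ∈ [−2000, 2000]` ×
gestations of 20–44 weeks, with zero mismatches — to a literal lookup
transcription of the published 37-interval recode table kept as the test
oracle.

Three numerical details worth knowing:

- **Axis switch at birth.** Pre-birth buckets live on the
  day-from-pregnancy-start axis, post-birth buckets on the
  day-from-birth axis. At a fixed gestation shorter than 330 days the
  last pregnancy buckets are unreachable (a 280-day gestation ends in
  bucket 22); bucket widths are therefore verified per axis, not on one
  merged timeline.
- **Pregnancy overrun.** A pre-birth admission whose `d` exceeds the last
  pregnancy bucket (≥ 330 days at month width) has no defined bucket.
  This cannot occur for valid gestations (≤ 45 weeks = 315 days) but is
  guarded: the recoder returns a missing bucket with a
  `pregnancy_overrun` flag rather than inventing semantics.
- **Week resolution.** Gestation in completed weeks limits pre-birth
  timing accuracy to a week; a property test confirms a shift of < 7
  days never moves a pre-birth admission across more than one bucket.

The generalised recoder takes an `IntervalScheme(width_days, n_pre,
n_pregnancy, n_post)`. The year preset is width 360 with one labelled
bucket on each side of pregnancy plus the two open-ended extremes
(buckets 0–4). Only the width is prescribed by the method; the bucket
count is configuration, and this minimal default keeps the year series
comparable to the month series' open-ended tails. Under it, a day 445
before pregnancy start falls in bucket 0, before the single labelled
pre-pregnancy year.

## Diagnosis grouping

Codes are canonicalised to dotted upper-case form (`F320 → F32.0`) and
compared byte-wise lexicographically. This reproduces the blank-padded
fixed-width string comparison of the SPSS-style source system because a
proper prefix always sorts before its extensions; a property test checks
the equivalence against a padding oracle over the full Chapter F
universe.

The ten group definitions are a frozen, versioned transcription
(`table2-v1`) applied verbatim — including its imperfections. The
auditor shows that over all 3/4/5-character Chapter F codes the nine
specific groups are pairwise disjoint, but also that real codes fall
through the ranges: F19.9 (substance-use group stops at F19.8), F33.0,
F34.8, bare F38 and F38.9, F44.0–F44.4, F70/F70.0, and codes above F99
such as F99.9 (the `F00–F99` interval excludes extensions of its upper
endpoint). These land in the overall group 10 (or, for F99.x, nowhere)
while hitting no specific group. Fidelity to the published method was
chosen over repair; the audit makes the gaps visible, and any corrected
variant would ship as a new ruleset version rather than silently
replacing the default.

## Master dataset

Births are merged with defect counts per baby (left join; unmatched
defect rows reported), consolidated one-row-per-mother with
birth-order-suffixed columns, then admissions and treatment episodes are
left-joined per mother. Design choices where the method leaves the rule
open:

- **Index birth.** Which birth an admission's timing is computed against
  is undefined for multi-birth mothers with overlapping windows. Default
  policy: nearest birth on or after the admission day, else nearest
  before — an admission during a pregnancy thereby references the birth
  it precedes. The policy is configurable
  (`nearest_previous_else_subsequent`, `nearest`) and logged in the
  stage's provenance sidecar. Admissions spanning birth (admitted
  before, discharged after) are referenced by admission age alone,
  matching the method's arithmetic.
- **Repeated-covariate repair.** A mother's repeated categorical values
  (e.g. country of birth) resolve to the unique non-missing value when
  consistent — filling missing cells — and otherwise to the majority
  value with ties broken by the latest birth, flagged as a conflict.
  Majority-with-latest-tiebreak maximises agreement across records while
  staying deterministic. Repair never increases missingness and is
  idempotent; a consistency report accounts for every (mother, field).
- **Treatment episodes** are folded in as mother-level attributes
  (any-treatment flag, episode count) rather than row expansion; they
  are an auxiliary source, not an analysis axis here.

## Aggregation

Window filtering is inclusive at both bucket boundaries (pregnancy =
[13, 23]). Sequencing sorts by (mother, admission age, admission id);
the id preserves input order and makes same-day ties deterministic, a
tie-break the lag-based original leaves unspecified. The original
running-counter fragment for the within-group order mis-initialises on
some flag patterns; the implementation computes the documented intent —
the cumulative rank of a mother's flagged admissions — and is proven
against a brute-force sort-and-rank oracle. Length of stay is discharge
age minus admission age, summed per mother; a stay beginning inside the
window counts in full (no truncation, matching the method's arithmetic),
and rows with discharge before admission are excluded and reported. The
rate series reports, per bucket 0–36, the flagged-admission count and a
rate per 1000 mothers (denominator scale is configuration; the source
figure does not state its axis units).

## Synthetic cohort

The generator emulates the study conditions: mothers aged 18–44 years at
birth, gestations of 20–44 completed weeks, admissions planted uniformly
over ±1080 days around a birth (three years, covering the two-year
tracing requirement), length of stay 0–60 days, 80/20 split of one- vs
two-birth mothers with second births at least 300 days after the first,
an expected 3 admissions per mother, 10% missing and 2% conflicting
repeated covariates, 5% of mothers with treatment episodes and 3% of
babies with defect notifications. Where the study conditions state no
value, these defaults were chosen once as plausible for an
administrative perinatal cohort and are not tuned. Principal codes are
drawn from a weighted pool covering every diagnosis group plus
non-psychiatric codes, each hand-annotated with its true group so the
planted truth does not depend on the classifier under test; the planted
month bucket comes from a literal transcription of the printed recode
ranges, independent of the floor-division recoder it later verifies.

What the generator does **not** emulate: realistic prevalence of
specific disorders, linkage errors (false links appear only as
explicitly requested orphan admissions), seasonal or figure-shaped
admission peaks (a `peaked` profile exists but the default is uniform so
flat-series properties are testable), and correlations between
covariates and admission risk. Passing ground-truth recovery therefore
demonstrates the pipeline's arithmetic and joins are exact, not that the
synthetic data statistically resembles any real population.

## Problem sizes and determinism

Tests run on cohorts of 200–3000 mothers (roughly 10⁴ admissions for the
aggregation oracles) — sizes at which the brute-force oracles remain
exact and fast. All randomness flows from a single integer seed through
one NumPy generator; regenerating with the same seed is byte-identical,
and each CLI stage writes a provenance sidecar (inputs, row counts,
ruleset version, seed — no timestamps) sufficient to reproduce its
artifact.

## Known limitations

- Person-level deduplication, probabilistic linkage and
  under-ascertainment correction are out of scope by design.
- The verbatim ruleset's gaps mean some genuine psychiatric codes count
  only toward the overall group; users wanting gap-free phenotyping must
  register a new ruleset version.
- Gestational-age imputation is not attempted: pre-birth buckets of
  admissions whose index birth lacks a gestation are missing, with a
  flag.
- Trimester definitions and calendar-date logic are deliberately absent.
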