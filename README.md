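# perilink

Preparation toolkit for person-linked perinatal registry data.

Perinatal psychiatric epidemiology increasingly relies on linked
administrative collections: a births register, a hospital admitted-patient
collection, a congenital-conditions register and a drugs-of-addiction
treatment register, all joined by an upstream-assigned Project Person
Number (PPN). For privacy, such extracts carry **ages in days** instead of
calendar dates, which means every timing computation has to be done in
relative-day arithmetic. `perilink` implements the four preparation steps
such a study needs before any analysis can start:

1. **Master dataset construction** — merge births with congenital
   conditions per baby, consolidate each mother's births into one wide
   record (repairing repeated covariates such as country of birth for
   consistency and completeness), and left-join hospital admissions and
   opioid-treatment episodes per mother. Orphan records are reported,
   never dropped silently.
2. **Time-interval binning (SVTI)** — assign each admission a month
   bucket `Admmonth ∈ {0,…,36}` relative to pregnancy start and birth.
   With `Admdays = AGEAdmMum − AgeBirthMum` and gestational age
   `Gage = 7 × completed weeks`:

   - `Admdays < 0` (before birth): let `d = Admdays + Gage` be the day
     relative to pregnancy start. `d ≤ −361 → 0`; 30-day buckets
     `1…12` cover `d ∈ [−360, −1]`; buckets `13…23 = 13 + ⌊d/30⌋`
     cover `d ∈ [0, 329]`.
   - `Admdays ≥ 0` (on/after birth): buckets `24…35 = 24 + ⌊Admdays/30⌋`
     for `Admdays ∈ [0, 359]`; `Admdays ≥ 360 → 36`.

   A month is 30 days and a year 360 days; the same logic at width 360
   yields `Admyear`. Because gestation is reported in completed weeks,
   pre-birth timing is accurate to a week.
3. **Diagnosis grouping** — classify ICD-10-AM principal (and stay/other)
   diagnoses into ten psychiatric groups defined as inclusive code
   intervals (e.g. group 1, schizophrenia-like: `F20–F22.9 ∪ F24–F29`;
   group 10, any mental illness: `F00–F99`), applied by lexicographic
   comparison on canonical dotted codes. The transcription is frozen and
   applied verbatim; an auditor reports its gaps and overlaps instead of
   silently repairing them.
4. **Aggregation & sequencing** — window filtering (pregnancy =
   `Admmonth ∈ [13, 23]`), per-mother admission counts (`Prin10_sum`),
   within-mother admission order (`Morder`, `Prin10_order`), total length
   of stay, and the per-bucket admission-rate series.

Because the real registry extracts are confidential, the package ships a
**synthetic cohort generator** that emulates the four schemas (ages in
days, mothers 18–44 years, gestations ≥ 20 completed weeks, admissions
traced two+ years either side of birth) and records planted ground truth
for every admission, so the full pipeline is testable end to end.

## Worked example

```python
import perilink as pl

cfg = pl.GeneratorConfig(n_mothers=500, seed=42)
cohort = pl.generate_cohort(cfg)
build = pl.build_master(cohort.births, cohort.rcc, cohort.admissions, cohort.phdas)
df = pl.classify_table(pl.add_timing_columns(build.master))
subset, report = pl.filter_window(df, pl.WINDOW_PRESETS["pregnancy"])
sums = pl.count_flag_per_mother(subset, "Prin10", mothers=build.mothers["PPN_mum"])

print("births:", len(cohort.births), "admissions:", len(cohort.admissions))
print("in pregnancy window:", report["retained"])
print("mothers with >=1 psychiatric admission in pregnancy:", int((sums > 0).sum()))
print(pl.recode_admmonth(-625, 265))   # day -360 from pregnancy start
print(pl.bucket_label(1))
```

prints

```
births: 580 admissions: 1508
in pregnancy window: 156
mothers with >=1 psychiatric admission in pregnancy: 95
(1, '')
the 12th month before pregnancy
```

580 births belong to 500 mothers (some have two in-study births); 1508
admissions survive the join (none orphaned), 156 fall in the pregnancy
window, and 95 mothers have at least one admission there with a
psychiatric principal diagnosis. An admission 625 days before birth with
a 265-day gestation sits exactly 360 days before pregnancy start — the
first day of the 12th month before pregnancy, bucket 1.

The same pipeline runs from the shell:

```bash
perilink run --out out/ --seed 7            # simulate → … → rates
perilink audit-codes --out out/             # gap/overlap audit of the ranges
```

Every stage writes its artifact CSV plus a JSON provenance sidecar, and
rerunning with the same seed reproduces identical bytes.

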