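# gdlaudit

**Guideline-compliance auditing for stroke registries with a computable
guideline formalism — and a built-in proof that it agrees with
conventional statistical analysis.**

`gdlaudit` is a small clinical-informatics toolkit for checking cohorts of
treated acute-ischaemic-stroke patients against the eleven European
contraindications to intravenous thrombolysis (NIHSS > 25, anticoagulation
treatment, SBP > 185 / > 184 mmHg, DBP > 110 / > 109 mmHg, diabetes with
previous stroke, blood glucose < 50 or > 400 mg/dl, age > 80 years, and
stroke onset > 3 h / > 4.5 h before treatment). Treating a patient despite
a contraindication constitutes guideline *non-compliance*; registries audit
the non-compliance rate per contraindication and time period.

The package computes every rate twice, by two deliberately independent
routes:

1. **The guideline-engine arm.** Each contraindication is expressed in a
   textual subset of the openEHR Guideline Definition Language (GDL): rules
   reference patient data through local `gt`-codes bound to archetype
   element paths (e.g. `gt0018` ↦
   `/data[at0001]/events[at0002]/data[at0003]/items[at0078.2]` in a blood
   glucose observation archetype), with conditions such as

   ```
   ["gt0004"] = (RULE) <
       when = <"$gt0020==null", "($gt0018<50,mg/dl)||($gt0018>400,mg/dl)">
       then = <"$gt0049=true", "$gt0020=true">
   >
   ```

   The registry CSV is split into per-archetype datasets, quantities are
   converted to the rule's units (mmol/l → mg/dl × 18.016, h → min × 60),
   and a forward-chaining engine fires rules to fixpoint per patient.
   Conditions evaluate under three-valued Kleene logic, so a missing value
   yields UNKNOWN rather than silently passing or failing a threshold;
   companion rules route patients with missing inputs to an *excluded*
   count.

2. **The conventional-analysis arm.** The same rates scripted directly
   against the raw registry table with plain pandas predicates
   (`sbp > 185`, …), sharing no code with the engine.

For each contraindication *c* and period, with *k* patients flagged, *d*
patients evaluable (no required value missing) and *m* excluded as missing,

```
rate(c) = 100 · k / d ,   d + m = cohort size
```

and the audit asserts **integer-exact equality** of (*k*, *d*, *m*) between
the two arms — not merely equality of rounded percentages. The `run` and
`compare` commands exit non-zero on any discrepancy, so the equivalence can
be enforced in CI.

Because real stroke registries (such as SITS, the Safe Implementation of
Treatments in Stroke registry) are access-restricted, the package ships a
seeded synthetic cohort generator that plants exact per-contraindication
prevalences, exact missingness fractions, and a two-period design in which
the later period shows the higher onset > 3 h and age > 80 non-compliance
characteristic of the 2008/2009 European guideline update (which extended
the treatment window to 4.5 h and lifted the age limit).

## Worked example

```bash
gdlaudit simulate --two-period --n 1000 --seed 42 -o registry.csv
gdlaudit run registry.csv -o audit/
```

prints

```
INFO gdlaudit: wrote 2000 patients to registry.csv
INFO gdlaudit.pipeline: read 2000 patients from registry.csv
INFO gdlaudit.pipeline: complete match: True (22 cells)
complete match: True (22 cells)
report written to audit/
```

Here 22 cells = 11 contraindications × 2 periods, each compared between
the two arms. `audit/report.csv` begins

```
contraindication_id,label,engine_pct_2006-2007,oracle_pct_2006-2007,engine_pct_2010-2011,oracle_pct_2010-2011
nihss_gt_25,NIHSS score > 25,1.1,1.1,1.7,1.7
anticoagulation,Anticoagulation treatment,2.4,2.4,3.1,3.1
sbp_gt_185,Systolic blood pressure > 185 mmHg,2.5,2.5,5.4,5.4
sbp_gt_184,Systolic blood pressure > 184 mmHg,4.0,4.0,6.3,6.3
```

Reading the first row: 1.1% of evaluable patients treated in 2006–2007
had an NIHSS score above 25 — a non-compliant treatment — and the engine
and conventional arms agree exactly; by 2010–2011 the rate is 1.7%. The
"Age > 80 years" and "Stroke onset > 3 h ago" rows rise from 8.9% to
17.2% and from 8.2% to 27.9% respectively — the planted guideline-update
signal. `audit/` also contains the per-patient `outcomes.csv`
(`noncompliant` / `compliant` / `missing` per contraindication), a
machine-readable `report.json` with the raw counts, and a `manifest.json`
recording input hashes and the seed.

The stages are also available separately (`gdlaudit map`, `check`,
`oracle`, `compare`) and as library functions
(`gdlaudit.run_end_to_end`, `gdlaudit.parse_guideline`,
`gdlaudit.generate_cohort`, …). Guideline files live in
`src/gdlaudit/guidelines/*.gdl2t` next to the registry-to-archetype
mapping (`mapping.yaml`); both are plain text and editable.

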