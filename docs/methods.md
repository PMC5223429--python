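# Methods

This note documents the models and design decisions behind `gdlaudit`:
the guideline formalism subset, the evaluation semantics, the
conventional-analysis oracle, the synthetic cohort generator, and what
the shipped tests do and do not establish.

## The guideline formalism subset

Guideline files (`.gdl2t`) are a deliberately small textual serialization
of the rule-and-binding core of the openEHR Guideline Definition
Language. A guideline consists of:

* **Archetype bindings** — each binds a local `gtNNNN` code to an element
  path inside one archetype (`/data[at0001]/.../items[at0078.2]`).
  `domain = EHR` marks read-only patient inputs; `domain = CDS` marks the
  guideline's outputs. Paths are treated as opaque strings: matching a
  patient value to a rule variable needs only (archetype id, gt-code),
  so no path grammar semantics are implemented.
* **Rules** — `when` is a list of condition strings (implicitly
  conjoined), `then` a list of assignments. Conditions support `==`,
  `!=`, `<`, `<=`, `>`, `>=`, `&&`, `||`, `!` with precedence
  `!` > `&&` > `||`; comparisons are non-associative (chained
  comparisons are rejected). Quantity literals are written
  `magnitude,unit` with no space (`50,mg/dl`).
* **Outputs** — an ordered pair of gt-codes: the contraindication flag
  and the missing/excluded flag.

The serializer is a strict inverse of the parser (`parse ∘ serialize =
id`, property-tested on randomized guidelines), and parsing is total:
malformed input always raises an error carrying line and column, never a
partial guideline. Static validation checks reference resolution, unit
consistency per comparison, output coverage, and that no rule writes to
an EHR-domain input.

Full GDL/ADL coverage, terminology bindings (SNOMED CT / ICD) and
multi-language description blocks are out of scope.

### Units

The guideline set needs exactly seven units, so the unit system is a
closed table rather than an open dimensional framework:
`mg/dl`, `mmol/l`, `mmHg`, `min`, `h`, `a` (years), `1` (dimensionless),
with `mmol/l → mg/dl` × 18.016 (glucose molar mass) and `h → min` × 60.
Comparisons convert the right operand into the left operand's unit;
incommensurable pairs are a validation error.

## Evaluation semantics

Conditions evaluate under three-valued Kleene logic
(TRUE/FALSE/UNKNOWN). A comparison with a missing operand is UNKNOWN —
missing data can neither trigger nor suppress a flag — with the single
exception of the explicit null tests: `x==null` is TRUE iff `x` is
missing, `x!=null` FALSE iff missing. `Or` is TRUE if any branch is
TRUE and FALSE only if all are; `And` is the dual; `Not(UNKNOWN)` is
UNKNOWN.

Rules execute by forward chaining with a **fire-once** discipline: scan
rules in declaration order, fire a rule when all its conditions are TRUE
and it has not fired yet, apply its assignments, repeat until a full
pass fires nothing (at most `|rules|` firings, so at most `|rules| + 1`
passes). Since no conflict-resolution strategy is part of the formalism,
fire-once plus guard conditions was chosen as the minimal discipline that
makes the final store independent of declaration order; the suite checks
this invariant exhaustively over rule permutations. The canonical
glucose rule carries a `$gt0020==null` guard whose `then` sets `gt0020`,
i.e. a re-fire latch; under fire-once the latch is redundant but it is
preserved verbatim as the canonical guarded-rule form.

An output never assigned stays *absent* from the value store —
distinguishable from one assigned `false` — so traces can tell "no rule
concluded anything" from "a rule concluded no".

Per patient the flag is: `noncompliant` if the contraindication output
is true; else `missing` if the excluded output is true; else
`compliant`. Each shipped guideline pairs its threshold rule with a
companion rule that sets the excluded flag when any required input
`==null`, mirroring how missing-value handling is configured in the
guideline artifact itself rather than hard-wired into the engine. For
every contraindication this makes `noncompliant`/`missing` mutually
exclusive: a conjunction with one flag missing and the other false is
FALSE under Kleene logic, but the patient is still routed to the
excluded count, matching the conventional arm's complete-case rule.

### Thresholds are strict

All eleven contraindications use strict inequalities: SBP exactly
185 mmHg, glucose exactly 50 or 400 mg/dl, age exactly 80 years, onset
exactly 180 or 270 min are all *compliant*. The 3 h and 4.5 h windows
are written in hours in the guidelines (`$gt0001>3,h`) and converted to
the minute-valued onset data at evaluation time.

## Registry mapping and the conventional arm

The wide registry CSV (one row per treated patient: id, period label,
age, NIHSS, SBP, DBP, glucose, onset-to-treatment minutes, and
anticoagulation/diabetes/previous-stroke flags) is split into one CSV
dataset per archetype according to a frozen, editable equivalence
mapping (`guidelines/mapping.yaml`). Column names are synthetic
stand-ins — real registry extracts use local names, which is exactly why
the mapping layer exists. Missing cells are preserved, never dropped;
per-column non-missing counts are invariant under the split. The period
label travels in a small admin dataset so the engine can report rates
per period. Onset-to-treatment is one duration column in minutes (the
engine never subtracts timestamps) and age is whole years, matching the
granularity of the thresholds. Dataset files carry two `#` metadata
lines (archetype id, column typing) making write/read an identity.

The **oracle** (`gdlaudit.oracle`) recomputes every rate directly from
the unsplit registry table with vectorised pandas predicates and shares
no expression evaluator, unit table or rule machinery with the engine.
Its complete-case convention — denominator = rows with all required
columns present — is the semantics the engine must reproduce through its
companion rules. Comparison (`gdlaudit.compare`) is integer-exact on
(numerator, denominator, missing); percentages are formatted to one
decimal for reports only, and a zero denominator is reported as
undefined (`NA`/null), never as 0.0.

Statistical comparison of rates across periods (χ², confidence
intervals) is deliberately excluded; the audit establishes equality of
the two computational arms, not significance of temporal change.

## Synthetic cohorts

`gdlaudit.synth` generates registry tables that are deterministic given
a seed (byte-identical CSVs):

* **Exact-counts mode** plants, per contraindication, exactly the
  requested number of rows strictly beyond the threshold and keeps all
  other rows strictly within it, from clinically plausible ranges (age
  18–100, NIHSS 0–42, SBP 80–260, DBP 40–160 mmHg, glucose 30–500 mg/dl,
  onset 30–600 min). Sampled mode draws binomial counts instead.
* Boundary values are never emitted, with one documented exception: the
  one-unit threshold pairs (SBP > 184 vs > 185, DBP > 109 vs > 110) can
  only be separated by integer rows at exactly the finer threshold
  (SBP 185, DBP 110). These rows are planted deliberately and double as
  a standing probe of strict-inequality handling in both arms. The
  3 h / 4.5 h pair has a proper gap band (181–269 min), so 180 and 270
  stay unemitted.
* Threshold pairs plant on the finest predicate plus a gap band; the
  coarser rate emerges, so the dominance invariants
  (rate(>184) ≥ rate(>185), etc.) are testable, not built in.
* For "diabetes and previous stroke" the planted count fixes the *joint*
  prevalence; background rows get independent marginal noise with the
  joint combination suppressed, since only the joint count affects the
  rate.
* **Missingness** blanks exactly `round(fraction · n)` cells per column,
  missing-completely-at-random from the seeded stream. Informative
  missingness is out of scope.
* The **two-period scenario** plants, per 1000 patients, the historical
  European non-compliance profile (e.g. age > 80: 8.9% → 17.2%;
  onset > 3 h: 8.2% → 27.9% across 2006–2007 → 2010–2011), giving a
  qualitative replica of the guideline-update signal at desk scale.
  Cohort sizes are configurable; n = 1000 per period keeps the default
  audit and test runs at a few seconds while exercising every code path
  at realistic prevalences.

### What the synthetic cohorts do and do not show

Passing the engine≡oracle audit on these cohorts shows that the
guideline formalism, the data mapping, the three-valued evaluation and
the denominator accounting are *computationally equivalent* to direct
statistical analysis across heterogeneous prevalences and missingness —
including at the planted strict-boundary probes. It does **not**
validate clinical realism: the synthetic marginals are uniform within
ranges, columns are independent apart from the planted structure,
missingness is MCAR, and real registry extracts bring coding quirks
(units, local column names, free text) that the mapping step would have
to absorb. Rates computed on synthetic cohorts are properties of the
generator's parameters, not estimates about any real patient population.

## Numerical and degenerate-input choices

* Unit conversion is a single multiplication with exact binary factors
  for the cases that matter (×60); equality comparisons between
  converted quantities are exact float comparisons, which is safe here
  because thresholds and data are integer-valued in the target units.
* Empty cohorts produce empty outcome tables and a vacuously complete
  match; all-missing columns produce a zero denominator reported as
  undefined.
* Patient sets must coincide across datasets (no partial joins); a
  patient absent from a required dataset is an error naming the dataset.
* Seeds: scenario and acceptance runs derive child seeds from a
  `SeedSequence`, masked into the 31-bit range.

## Known limitations

* The grammar covers the rule/binding subset only — no nested guideline
  definitions, terminology sections, or temporal/workflow constructs.
* The unit table is closed; adding a unit is a code change, by design.
* The engine's per-patient loop is pure Python (~10⁴ patients/s per
  guideline); cohorts of 10⁵+ patients would warrant vectorising the
  shipped single-threshold rules, which would blur the engine/oracle
  independence this package exists to test.
* `validate_guideline` checks unit consistency against literal operands;
  a guideline comparing two bound variables of different units is only
  caught at evaluation time.
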