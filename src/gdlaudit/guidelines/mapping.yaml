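# Equivalence mapping: registry column -> archetype element.
# Frozen from manual equivalence judgement; edit to adapt to another
# registry extract.  `kind` is quantity | boolean | label; quantities are
# converted from source_unit to target_unit during the split.
columns:
  - column: period
    archetype_id: openEHR-EHR-ADMIN_ENTRY.treatment_period.v1
    gt_code: gt0900
    path: /data[at0001]/items[at0004]
    kind: label
  - column: age
    archetype_id: openEHR-EHR-OBSERVATION.age.v1
    gt_code: gt0010
    path: /data[at0001]/events[at0002]/data[at0003]/items[at0004]
    kind: quantity
    source_unit: a
    target_unit: a
  - column: nihss
    archetype_id: openEHR-EHR-OBSERVATION.nihss.v1
    gt_code: gt0012
    path: /data[at0001]/events[at0002]/data[at0003]/items[at0005]
    kind: quantity
    source_unit: "1"
    target_unit: "1"
  - column: sbp
    archetype_id: openEHR-EHR-OBSERVATION.blood_pressure.v1
    gt_code: gt0014
    path: /data[at0001]/events[at0006]/data[at0003]/items[at0004]
    kind: quantity
    source_unit: mmHg
    target_unit: mmHg
  - column: dbp
    archetype_id: openEHR-EHR-OBSERVATION.blood_pressure.v1
    gt_code: gt0015
    path: /data[at0001]/events[at0006]/data[at0003]/items[at0005]
    kind: quantity
    source_unit: mmHg
    target_unit: mmHg
  - column: glucose
    archetype_id: openEHR-EHR-OBSERVATION.lab_test-blood_glucose.v1
    gt_code: gt0018
    path: /data[at0001]/events[at0002]/data[at0003]/items[at0078.2]
    kind: quantity
    source_unit: mg/dl
    target_unit: mg/dl
  - column: onset_to_treatment
    archetype_id: openEHR-EHR-OBSERVATION.stroke_onset.v1
    gt_code: gt0001
    path: /data[at0001]/events[at0002]/data[at0003]/items[at0004]
    kind: quantity
    source_unit: min
    target_unit: min
  - column: anticoagulation
    archetype_id: openEHR-EHR-EVALUATION.medication_summary.v1
    gt_code: gt0030
    path: /data[at0001]/items[at0002]
    kind: boolean
  - column: diabetes
    archetype_id: openEHR-EHR-EVALUATION.problem_diagnosis.v1
    gt_code: gt0032
    path: /data[at0001]/items[at0002]
    kind: boolean
  - column: previous_stroke
    archetype_id: openEHR-EHR-EVALUATION.problem_diagnosis.v1
    gt_code: gt0033
    path: /data[at0001]/items[at0003]
    kind: boolean
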