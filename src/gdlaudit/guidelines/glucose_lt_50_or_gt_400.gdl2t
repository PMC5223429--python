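(GUIDELINE) <
    id = <"glucose_lt_50_or_gt_400">
    name = <"Blood glucose < 50 mg/dl or > 400 mg/dl">
    outputs = <"gt0049", "gt0050">
    archetype_bindings = <
        ["gt0017"] = (ARCHETYPE_BINDING) <
            archetype_id = <"openEHR-EHR-OBSERVATION.lab_test-blood_glucose.v1">
            domain = <"EHR">
            elements = <
                ["gt0018"] = (ELEMENT_BINDING) <
                    path = <"/data[at0001]/events[at0002]/data[at0003]/items[at0078.2]">
                >
            >
        >
        ["gt0040"] = (ARCHETYPE_BINDING) <
            archetype_id = <"openEHR-EHR-EVALUATION.contraindication.v1">
            domain = <"CDS">
            elements = <
                ["gt0049"] = (ELEMENT_BINDING) <
                    path = <"/data[at0001]/items[at0002]">
                >
                ["gt0050"] = (ELEMENT_BINDING) <
                    path = <"/data[at0001]/items[at0003]">
                >
            >
        >
    >
    rules = <
        ["gt0004"] = (RULE) <
            when = <"$gt0020==null", "($gt0018<50,mg/dl)||($gt0018>400,mg/dl)">
            then = <"$gt0049=true", "$gt0020=true">
        >
        ["gt0005"] = (RULE) <
            when = <"$gt0018==null">
            then = <"$gt0050=true">
        >
    >
>
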