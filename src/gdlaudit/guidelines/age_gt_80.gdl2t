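(GUIDELINE) <
    id = <"age_gt_80">
    name = <"Age > 80 years">
    outputs = <"gt0049", "gt0050">
    archetype_bindings = <
        ["gt0009"] = (ARCHETYPE_BINDING) <
            archetype_id = <"openEHR-EHR-OBSERVATION.age.v1">
            domain = <"EHR">
            elements = <
                ["gt0010"] = (ELEMENT_BINDING) <
                    path = <"/data[at0001]/events[at0002]/data[at0003]/items[at0004]">
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
            when = <"$gt0010>80,a">
            then = <"$gt0049=true">
        >
        ["gt0005"] = (RULE) <
            when = <"$gt0010==null">
            then = <"$gt0050=true">
        >
    >
>
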