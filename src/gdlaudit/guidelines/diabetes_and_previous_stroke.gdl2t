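(GUIDELINE) <
    id = <"diabetes_and_previous_stroke">
    name = <"Diabetes and previous stroke">
    outputs = <"gt0049", "gt0050">
    archetype_bindings = <
        ["gt0031"] = (ARCHETYPE_BINDING) <
            archetype_id = <"openEHR-EHR-EVALUATION.problem_diagnosis.v1">
            domain = <"EHR">
            elements = <
                ["gt0032"] = (ELEMENT_BINDING) <
                    path = <"/data[at0001]/items[at0002]">
                >
                ["gt0033"] = (ELEMENT_BINDING) <
                    path = <"/data[at0001]/items[at0003]">
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
            when = <"$gt0032==true", "$gt0033==true">
            then = <"$gt0049=true">
        >
        ["gt0005"] = (RULE) <
            when = <"($gt0032==null)||($gt0033==null)">
            then = <"$gt0050=true">
        >
    >
>
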