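"""Seeded random generator of valid guideline objects for round-trip tests."""

import random

from gdlaudit.gdl.model import (
    And,
    ArchetypeBinding,
    Assignment,
    Comparison,
    ElementBinding,
    Guideline,
    Lit,
    Not,
    Or,
    Rule,
    Var,
)
from gdlaudit.units import Quantity

_UNITS = ["mg/dl", "mmol/l", "mmHg", "min", "h", "a", "1"]
_CMP_OPS = ["==", "!=", "<", "<=", ">", ">="]


class GuidelineGenerator:
    def __init__(self, seed: int):
        self.rnd = random.Random(seed)
        self._code_counter = 0

    def _code(self) -> str:
        self._code_counter += 1
        return f"gt{self._code_counter:04d}"

    def _magnitude(self) -> float:
        if self.rnd.random() < 0.5:
            return float(self.rnd.randint(0, 500))
        return self.rnd.randint(0, 500) + 0.5

    def _literal(self) -> Lit:
        roll = self.rnd.random()
        if roll < 0.7:
            return Lit(Quantity(self._magnitude(), self.rnd.choice(_UNITS)))
        if roll < 0.85:
            return Lit(self.rnd.random() < 0.5)
        return Lit(None)

    def _comparison(self, codes) -> Comparison:
        var = Var(self.rnd.choice(codes))
        lit = self._literal()
        if lit.value is None:
            op = self.rnd.choice(["==", "!="])
        elif isinstance(lit.value, bool):
            op = self.rnd.choice(["==", "!="])
        else:
            op = self.rnd.choice(_CMP_OPS)
        if self.rnd.random() < 0.2:
            return Comparison(op, lit, var)
        return Comparison(op, var, lit)

    def expression(self, codes, depth: int = 0):
        if depth >= 3 or self.rnd.random() < 0.4:
            return self._comparison(codes)
        kind = self.rnd.choice(["and", "or", "not"])
        if kind == "not":
            return Not(self.expression(codes, depth + 1))
        items = tuple(
            self.expression(codes, depth + 1)
            for _ in range(self.rnd.randint(2, 3))
        )
        return And(items) if kind == "and" else Or(items)

    def guideline(self) -> Guideline:
        self._code_counter = 0
        bindings = []
        ehr_codes = []
        for b in range(self.rnd.randint(1, 3)):
            bid = self._code()
            elements = []
            for e in range(self.rnd.randint(1, 3)):
                code = self._code()
                ehr_codes.append(code)
                elements.append(
                    ElementBinding(
                        id=code,
                        path=f"/data[at0001]/events[at{b + 2:04d}]"
                        f"/items[at{e + 10:04d}.{self.rnd.randint(1, 9)}]",
                    )
                )
            bindings.append(
                ArchetypeBinding(
                    id=bid,
                    archetype_id=f"openEHR-EHR-OBSERVATION.synthetic_{bid}.v1",
                    domain="EHR",
                    elements=tuple(elements),
                )
            )
        flag, miss = self._code(), self._code()
        bindings.append(
            ArchetypeBinding(
                id=self._code(),
                archetype_id="openEHR-EHR-EVALUATION.synthetic_output.v1",
                domain="CDS",
                elements=(
                    ElementBinding(id=flag, path="/data[at0001]/items[at0002]"),
                    ElementBinding(id=miss, path="/data[at0001]/items[at0003]"),
                ),
            )
        )
        rules = []
        for _ in range(self.rnd.randint(0, 4)):
            when = tuple(
                self.expression(ehr_codes)
                for _ in range(self.rnd.randint(1, 3))
            )
            then = tuple(
                Assignment(
                    target=self.rnd.choice([flag, miss]),
                    value=Lit(self.rnd.random() < 0.8),
                )
                for _ in range(self.rnd.randint(1, 2))
            )
            rules.append(Rule(id=self._code(), when=when, then=then))
        return Guideline(
            id=f"synthetic_{self.rnd.randint(0, 10**6)}",
            name=f"synthetic guideline {self.rnd.randint(0, 10**6)}",
            archetype_bindings=tuple(bindings),
            rules=tuple(rules),
            outputs=(flag, miss),
        )


def random_guidelines(seed: int, count: int):
    gen = GuidelineGenerator(seed)
    return [gen.guideline() for _ in range(count)]
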