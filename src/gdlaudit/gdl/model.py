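"""Domain model for the GDL subset.

A guideline binds local gt-codes to openEHR archetype element paths
(``ArchetypeBinding`` / ``ElementBinding``), and expresses its logic as
rules whose *when* conditions and *then* assignments reference those
gt-codes.  EHR-domain bindings are read-only patient inputs; CDS-domain
bindings hold the guideline's outputs (here: the contraindication flag
and the missing/excluded flag).

All nodes are immutable dataclasses with structural equality, which is
what the parse/serialize round-trip contract is stated over.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Union

from ..units import Quantity

_GT_CODE_RE = re.compile(r"^gt\d{4}$")
_AT_PATH_RE = re.compile(
    r"^(?:/[A-Za-z_][A-Za-z0-9_]*(?:\[at\d{4}(?:\.\d+)?\])?)+$"
)
_ARCHETYPE_ID_RE = re.compile(r"^openEHR-EHR-[A-Z_]+\.[A-Za-z0-9_.-]+\.v\d+$")

#: Comparison operators, in source form.
COMPARISON_OPS = ("==", "!=", "<=", ">=", "<", ">")


def is_gt_code(code: str) -> bool:
    """``gt`` followed by exactly four digits, e.g. ``gt0018``."""
    return bool(_GT_CODE_RE.match(code))


def is_at_path(path: str) -> bool:
    """Slash-separated archetype path with bracketed at-codes.

    e.g. ``/data[at0001]/events[at0002]/data[at0003]/items[at0078.2]``
    """
    return bool(_AT_PATH_RE.match(path))


def is_archetype_id(archetype_id: str) -> bool:
    return bool(_ARCHETYPE_ID_RE.match(archetype_id))


# --------------------------------------------------------------------------
# condition-expression AST

@dataclass(frozen=True)
class Var:
    """Reference to a bound element or rule output, written ``$gtNNNN``."""

    code: str

    def __post_init__(self):
        if not is_gt_code(self.code):
            raise ValueError(f"invalid gt-code: {self.code!r}")


@dataclass(frozen=True)
class Lit:
    """Literal: a unit-annotated quantity, a boolean, or null (None)."""

    value: Union[Quantity, bool, None]


@dataclass(frozen=True)
class Comparison:
    op: str
    lhs: Union[Var, Lit]
    rhs: Union[Var, Lit]

    def __post_init__(self):
        if self.op not in COMPARISON_OPS:
            raise ValueError(f"invalid comparison operator: {self.op!r}")


@dataclass(frozen=True)
class And:
    items: tuple

    def __post_init__(self):
        if len(self.items) < 2:
            raise ValueError("And requires at least two operands")


@dataclass(frozen=True)
class Or:
    items: tuple

    def __post_init__(self):
        if len(self.items) < 2:
            raise ValueError("Or requires at least two operands")


@dataclass(frozen=True)
class Not:
    child: "ConditionExpr"


ConditionExpr = Union[Comparison, And, Or, Not, Var, Lit]


def walk_vars(expr: ConditionExpr):
    """Yield every ``Var`` occurring in ``expr``."""
    if isinstance(expr, Var):
        yield expr
    elif isinstance(expr, Comparison):
        yield from walk_vars(expr.lhs)
        yield from walk_vars(expr.rhs)
    elif isinstance(expr, (And, Or)):
        for item in expr.items:
            yield from walk_vars(item)
    elif isinstance(expr, Not):
        yield from walk_vars(expr.child)


# --------------------------------------------------------------------------
# guideline structure

@dataclass(frozen=True)
class Assignment:
    """``$gtNNNN=<literal>`` in a rule's *then* list."""

    target: str
    value: Lit

    def __post_init__(self):
        if not is_gt_code(self.target):
            raise ValueError(f"invalid assignment target: {self.target!r}")


@dataclass(frozen=True)
class Rule:
    """A production rule: fires when every *when* condition holds.

    Multiple expressions in one *when* list are implicitly conjoined.
    """

    id: str
    when: tuple
    then: tuple

    def __post_init__(self):
        if not is_gt_code(self.id):
            raise ValueError(f"invalid rule id: {self.id!r}")
        if not self.when:
            raise ValueError(f"rule {self.id}: empty when-list")
        if not self.then:
            raise ValueError(f"rule {self.id}: empty then-list")


@dataclass(frozen=True)
class ElementBinding:
    id: str
    path: str

    def __post_init__(self):
        if not is_gt_code(self.id):
            raise ValueError(f"invalid element gt-code: {self.id!r}")
        if not is_at_path(self.path):
            raise ValueError(f"invalid archetype path: {self.path!r}")


@dataclass(frozen=True)
class ArchetypeBinding:
    """Binds gt-codes to elements of one archetype.

    ``domain`` is ``"EHR"`` for patient-data inputs and ``"CDS"`` for
    guideline outputs.
    """

    id: str
    archetype_id: str
    domain: str
    elements: tuple

    def __post_init__(self):
        if not is_gt_code(self.id):
            raise ValueError(f"invalid binding gt-code: {self.id!r}")
        if not is_archetype_id(self.archetype_id):
            raise ValueError(f"invalid archetype id: {self.archetype_id!r}")
        if self.domain not in ("EHR", "CDS"):
            raise ValueError(f"invalid domain: {self.domain!r}")


@dataclass(frozen=True)
class Guideline:
    """A parsed guideline artifact.

    ``outputs`` is the ordered pair of output gt-codes: the first is the
    contraindication flag, the second the missing/excluded flag.
    """

    id: str
    name: str
    archetype_bindings: tuple = field(default_factory=tuple)
    rules: tuple = field(default_factory=tuple)
    outputs: tuple = field(default_factory=tuple)

    @property
    def flag_code(self) -> Optional[str]:
        return self.outputs[0] if len(self.outputs) > 0 else None

    @property
    def missing_code(self) -> Optional[str]:
        return self.outputs[1] if len(self.outputs) > 1 else None

    def ehr_bindings(self) -> tuple:
        return tuple(b for b in self.archetype_bindings if b.domain == "EHR")

    def cds_bindings(self) -> tuple:
        return tuple(b for b in self.archetype_bindings if b.domain == "CDS")

    def bound_codes(self, domain: Optional[str] = None) -> set:
        return {
            e.id
            for b in self.archetype_bindings
            if domain is None or b.domain == domain
            for e in b.elements
        }

    def assigned_codes(self) -> set:
        return {a.target for r in self.rules for a in r.then}
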