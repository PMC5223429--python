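"""Static validation of parsed guidelines.

Returns a list of issues rather than raising: an empty list means the
guideline is ready for execution.  Checks cover reference resolution,
unit consistency inside comparisons, domain discipline (rules must not
write to EHR-domain input elements), and output-code coverage.
"""

from __future__ import annotations

from dataclasses import dataclass

from ..units import Quantity, _CANONICAL
from .model import And, Comparison, Guideline, Lit, Not, Or, Var, walk_vars


@dataclass(frozen=True)
class Issue:
    severity: str  # "error" | "warning"
    message: str

    def __str__(self) -> str:
        return f"{self.severity}: {self.message}"


def _walk_comparisons(expr):
    if isinstance(expr, Comparison):
        yield expr
    elif isinstance(expr, (And, Or)):
        for item in expr.items:
            yield from _walk_comparisons(item)
    elif isinstance(expr, Not):
        yield from _walk_comparisons(expr.child)


def validate_guideline(g: Guideline) -> list:
    """Validate ``g``; an empty result means no problems were found."""
    issues: list = []

    if not g.rules:
        issues.append(Issue("warning", "no rules"))

    # unique binding and element ids
    seen: set = set()
    for binding in g.archetype_bindings:
        for code in (binding.id, *[e.id for e in binding.elements]):
            if code in seen:
                issues.append(Issue("error", f"duplicate gt-code {code}"))
            seen.add(code)

    bound = g.bound_codes()
    ehr_codes = g.bound_codes("EHR")
    assigned = g.assigned_codes()
    known = bound | assigned

    # reference resolution
    unresolved = sorted(
        {
            var.code
            for rule in g.rules
            for cond in rule.when
            for var in walk_vars(cond)
            if var.code not in known
        }
    )
    for code in unresolved:
        issues.append(Issue("error", f"unresolved gt-code {code}"))

    # comparisons: null discipline and unit consistency
    var_units: dict = {}  # code -> set of canonical units it is compared against
    for rule in g.rules:
        for cond in rule.when:
            for cmp_ in _walk_comparisons(cond):
                sides = (cmp_.lhs, cmp_.rhs)
                if any(isinstance(s, Lit) and s.value is None for s in sides):
                    if cmp_.op not in ("==", "!="):
                        issues.append(
                            Issue(
                                "error",
                                f"rule {rule.id}: null may only be tested with == or !=",
                            )
                        )
                    continue
                lits = [s.value for s in sides if isinstance(s, Lit)]
                qty_units = [v.unit for v in lits if isinstance(v, Quantity)]
                if len(qty_units) == 2:
                    if _CANONICAL[qty_units[0]][0] != _CANONICAL[qty_units[1]][0]:
                        issues.append(
                            Issue(
                                "error",
                                f"rule {rule.id}: incommensurable units "
                                f"{qty_units[0]} vs {qty_units[1]}",
                            )
                        )
                    continue
                for side, other in ((cmp_.lhs, cmp_.rhs), (cmp_.rhs, cmp_.lhs)):
                    if isinstance(side, Var) and isinstance(other, Lit):
                        if isinstance(other.value, Quantity):
                            var_units.setdefault(side.code, set()).add(
                                _CANONICAL[other.value.unit][0]
                            )
    for code, canon in sorted(var_units.items()):
        if len(canon) > 1:
            issues.append(
                Issue(
                    "error",
                    f"incommensurable units compared against {code}: "
                    + ", ".join(sorted(canon)),
                )
            )

    # domain discipline: no writes to EHR input elements
    for rule in g.rules:
        for assignment in rule.then:
            if assignment.target in ehr_codes:
                issues.append(
                    Issue(
                        "error",
                        f"rule {rule.id}: write to input domain "
                        f"(EHR element {assignment.target})",
                    )
                )

    # declared outputs must be produced by at least one rule
    for code in g.outputs:
        if code not in assigned:
            issues.append(
                Issue("error", f"output code {code} is never assigned by any rule")
            )

    return issues
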