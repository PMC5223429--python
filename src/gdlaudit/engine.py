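"""Three-valued rule evaluation and forward-chaining execution.

Missing clinical values must neither trigger nor silently suppress a
contraindication flag, so conditions evaluate under Kleene logic with
truth values TRUE / FALSE / UNKNOWN:

* a comparison with a missing operand is UNKNOWN, except the explicit
  null tests: ``x==null`` is TRUE iff x is missing, ``x!=null`` is FALSE
  iff x is missing;
* ``Or`` is TRUE if any branch is TRUE, FALSE if all are FALSE, else
  UNKNOWN; ``And`` is the dual; ``Not(UNKNOWN)`` is UNKNOWN.

Rules fire by forward chaining: scan rules in declaration order, fire a
rule when every *when* condition is TRUE and it has not fired before,
apply its assignments, and repeat until a full pass fires nothing.
Fire-once plus guard conditions make the final store independent of
declaration order.
"""

from __future__ import annotations

import enum
import operator
from dataclasses import dataclass, field
from typing import Mapping, Optional, Union

import pandas as pd

from .errors import EngineError, UnitError
from .gdl.model import And, Comparison, Guideline, Lit, Not, Or, Var
from .units import Quantity, convert

Value = Union[Quantity, bool, None]


class TruthValue(enum.Enum):
    TRUE = "TRUE"
    FALSE = "FALSE"
    UNKNOWN = "UNKNOWN"


_CMP_FUNCS = {
    "==": operator.eq,
    "!=": operator.ne,
    "<": operator.lt,
    "<=": operator.le,
    ">": operator.gt,
    ">=": operator.ge,
}

_ORDERING_OPS = ("<", "<=", ">", ">=")


@dataclass(frozen=True)
class PatientRecord:
    """One patient's element values keyed by gt-code.

    A value of ``None`` marks a missing datum; a code absent from
    ``values`` is equally missing.
    """

    patient_id: str
    period: Optional[str] = None
    values: Mapping[str, Value] = field(default_factory=dict)


@dataclass
class FiringTrace:
    """Which rules fired (rule id, pass index) and the final value store."""

    firings: list
    store: dict


def _resolve(node, store: Mapping[str, Value]) -> Value:
    if isinstance(node, Var):
        return store.get(node.code)
    return node.value  # Lit


def eval_expr(expr, store: Mapping[str, Value]) -> TruthValue:
    """Evaluate a condition AST against a value store under Kleene logic."""
    if isinstance(expr, Comparison):
        return _eval_comparison(expr, store)
    if isinstance(expr, Or):
        saw_unknown = False
        for item in expr.items:
            tv = eval_expr(item, store)
            if tv is TruthValue.TRUE:
                return TruthValue.TRUE
            if tv is TruthValue.UNKNOWN:
                saw_unknown = True
        return TruthValue.UNKNOWN if saw_unknown else TruthValue.FALSE
    if isinstance(expr, And):
        saw_unknown = False
        for item in expr.items:
            tv = eval_expr(item, store)
            if tv is TruthValue.FALSE:
                return TruthValue.FALSE
            if tv is TruthValue.UNKNOWN:
                saw_unknown = True
        return TruthValue.UNKNOWN if saw_unknown else TruthValue.TRUE
    if isinstance(expr, Not):
        tv = eval_expr(expr.child, store)
        if tv is TruthValue.TRUE:
            return TruthValue.FALSE
        if tv is TruthValue.FALSE:
            return TruthValue.TRUE
        return TruthValue.UNKNOWN
    if isinstance(expr, (Var, Lit)):
        value = _resolve(expr, store)
        if value is None:
            return TruthValue.UNKNOWN
        if isinstance(value, bool):
            return TruthValue.TRUE if value else TruthValue.FALSE
        raise EngineError(f"non-boolean value used as a condition: {value!r}")
    raise EngineError(f"cannot evaluate node: {expr!r}")


def _eval_comparison(cmp_: Comparison, store: Mapping[str, Value]) -> TruthValue:
    # explicit null tests are the only comparisons defined on missing data
    for side, other in ((cmp_.rhs, cmp_.lhs), (cmp_.lhs, cmp_.rhs)):
        if isinstance(side, Lit) and side.value is None:
            if cmp_.op not in ("==", "!="):
                raise EngineError("null may only be tested with == or !=")
            missing = _resolve(other, store) is None
            if cmp_.op == "==":
                return TruthValue.TRUE if missing else TruthValue.FALSE
            return TruthValue.FALSE if missing else TruthValue.TRUE

    lhs = _resolve(cmp_.lhs, store)
    rhs = _resolve(cmp_.rhs, store)
    if lhs is None or rhs is None:
        return TruthValue.UNKNOWN

    if isinstance(lhs, Quantity) and isinstance(rhs, Quantity):
        try:
            rhs_mag = (
                rhs.magnitude
                if rhs.unit == lhs.unit
                else convert(rhs.magnitude, rhs.unit, lhs.unit)
            )
        except UnitError as err:
            raise EngineError(str(err)) from err
        result = _CMP_FUNCS[cmp_.op](lhs.magnitude, rhs_mag)
    elif isinstance(lhs, bool) and isinstance(rhs, bool):
        if cmp_.op in _ORDERING_OPS:
            raise EngineError("booleans admit only == and != comparisons")
        result = _CMP_FUNCS[cmp_.op](lhs, rhs)
    else:
        raise EngineError(
            f"type mismatch in comparison: {lhs!r} {cmp_.op} {rhs!r}"
        )
    return TruthValue.TRUE if result else TruthValue.FALSE


def fire_rules(g: Guideline, patient) -> FiringTrace:
    """Run ``g``'s rules to fixpoint for one patient.

    ``patient`` is a :class:`PatientRecord` or a plain mapping of gt-code
    to value.  Each rule fires at most once; a pass that fires nothing
    terminates the run.  Unassigned output codes stay absent from the
    store (distinct from an assigned ``False``).
    """
    values = patient.values if isinstance(patient, PatientRecord) else patient
    store = {code: v for code, v in values.items() if v is not None}
    fired: set = set()
    firings: list = []
    max_passes = len(g.rules) + 1
    for iteration in range(max_passes + 1):
        if iteration > max_passes:  # pragma: no cover - unreachable under fire-once
            raise EngineError("iteration cap exceeded")
        fired_this_pass = False
        for rule in g.rules:
            if rule.id in fired:
                continue
            if all(eval_expr(cond, store) is TruthValue.TRUE for cond in rule.when):
                for assignment in rule.then:
                    store[assignment.target] = assignment.value.value
                fired.add(rule.id)
                firings.append((rule.id, iteration))
                fired_this_pass = True
        if not fired_this_pass:
            break
    return FiringTrace(firings=firings, store=store)


def _classify(store: dict, flag_code, missing_code) -> str:
    if flag_code is not None and store.get(flag_code) is True:
        return "noncompliant"
    if missing_code is not None and store.get(missing_code) is True:
        return "missing"
    return "compliant"


def run_cohort(g: Guideline, datasets) -> pd.DataFrame:
    """Evaluate ``g`` over every patient in the archetype datasets.

    ``datasets`` maps archetype_id to :class:`~gdlaudit.registry.ArchetypeDataset`
    (a list/tuple of datasets is also accepted).  Returns a frame with one
    row per patient: ``patient_id``, ``period``, ``flag`` where flag is
    ``noncompliant`` | ``compliant`` | ``missing``.
    """
    from .registry import PERIOD_ARCHETYPE_ID, PERIOD_CODE  # local: avoid cycle

    if not isinstance(datasets, Mapping):
        datasets = {d.archetype_id: d for d in datasets}

    index = None
    columns = []  # (gt_code, python list of Value)
    for binding in g.ehr_bindings():
        ds = datasets.get(binding.archetype_id)
        if ds is None:
            raise EngineError(
                f"no dataset for archetype {binding.archetype_id!r} "
                f"required by guideline {g.id!r}"
            )
        if index is None:
            index = ds.data.index
        elif not index.equals(ds.data.index):
            raise EngineError("archetype datasets cover different patient sets")
        for element in binding.elements:
            if element.id not in ds.data.columns:
                raise EngineError(
                    f"dataset {binding.archetype_id!r} lacks element {element.id}"
                )
            kind = ds.kinds[element.id]
            series = ds.data[element.id]
            if kind == "quantity":
                unit = ds.units[element.id]
                values = [
                    None if pd.isna(v) else Quantity(float(v), unit)
                    for v in series.tolist()
                ]
            elif kind == "boolean":
                values = [None if pd.isna(v) else bool(v) for v in series.tolist()]
            else:
                values = [None if pd.isna(v) else v for v in series.tolist()]
            columns.append((element.id, values))

    if index is None:
        return pd.DataFrame(columns=["patient_id", "period", "flag"])

    period_ds = datasets.get(PERIOD_ARCHETYPE_ID)
    if period_ds is not None and PERIOD_CODE in period_ds.data.columns:
        periods = [
            None if pd.isna(v) else v
            for v in period_ds.data[PERIOD_CODE].reindex(index).tolist()
        ]
    else:
        periods = [None] * len(index)

    flag_code, missing_code = g.flag_code, g.missing_code
    flags = []
    for i in range(len(index)):
        store = {}
        for code, values in columns:
            v = values[i]
            if v is not None:
                store[code] = v
        trace = fire_rules(g, store)
        flags.append(_classify(trace.store, flag_code, missing_code))

    return pd.DataFrame(
        {"patient_id": list(index), "period": periods, "flag": flags}
    )
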