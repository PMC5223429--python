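"""Conventional-analysis arm: direct column predicates on the registry.

This module recomputes every non-compliance rate straight from the wide
registry table with plain pandas comparisons — the way a statistician
would script it — and deliberately shares no code with the guideline
interpreter or the rule engine.  It is the independent cross-check the
engine results are compared against.

For each contraindication the denominator is the set of patients whose
required columns are all non-missing; the numerator counts those
satisfying the predicate; all thresholds are strict inequalities.
"""

from __future__ import annotations

import pandas as pd

from .compliance import ComplianceResult
from .errors import RegistryError

#: contraindication id -> (required columns, row predicate)
ORACLE_PREDICATES = {
    "nihss_gt_25": (("nihss",), lambda d: d["nihss"] > 25),
    "anticoagulation": (("anticoagulation",), lambda d: d["anticoagulation"] == 1),
    "sbp_gt_185": (("sbp",), lambda d: d["sbp"] > 185),
    "sbp_gt_184": (("sbp",), lambda d: d["sbp"] > 184),
    "dbp_gt_110": (("dbp",), lambda d: d["dbp"] > 110),
    "dbp_gt_109": (("dbp",), lambda d: d["dbp"] > 109),
    "diabetes_and_previous_stroke": (
        ("diabetes", "previous_stroke"),
        lambda d: (d["diabetes"] == 1) & (d["previous_stroke"] == 1),
    ),
    "glucose_lt_50_or_gt_400": (
        ("glucose",),
        lambda d: (d["glucose"] < 50) | (d["glucose"] > 400),
    ),
    "age_gt_80": (("age",), lambda d: d["age"] > 80),
    # onset-to-treatment time is stored in minutes: 3 h = 180, 4.5 h = 270
    "onset_gt_3h": (("onset_to_treatment",), lambda d: d["onset_to_treatment"] > 180),
    "onset_gt_4_5h": (("onset_to_treatment",), lambda d: d["onset_to_treatment"] > 270),
}


def oracle_rates(registry: pd.DataFrame, predicates=None) -> list:
    """Compute per-(contraindication, period) results by direct predicates.

    ``predicates`` defaults to :data:`ORACLE_PREDICATES`; tests substitute
    deliberately mutated predicate tables to confirm that the comparison
    with the engine detects discrepancies.
    """
    predicates = predicates if predicates is not None else ORACLE_PREDICATES
    needed = {col for cols, _ in predicates.values() for col in cols}
    missing_cols = sorted(needed - set(registry.columns))
    if missing_cols:
        raise RegistryError(f"registry lacks columns: {', '.join(missing_cols)}")

    results = []
    for period, subset in registry.groupby("period", sort=True):
        for cid, (columns, predicate) in predicates.items():
            has_all = subset[list(columns)].notna().all(axis=1)
            evaluable = subset[has_all]
            hit = predicate(evaluable)
            results.append(
                ComplianceResult(
                    contraindication_id=cid,
                    period=period,
                    numerator=int(hit.sum()),
                    denominator=int(has_all.sum()),
                    missing=int((~has_all).sum()),
                )
            )
    return results
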