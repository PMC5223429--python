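"""Contraindication definitions, rate aggregation, comparison and reports.

A non-compliance rate is the percentage of *evaluable* treated patients
(those with no required value missing) who met a contraindication yet
were treated.  Patients with a missing required value are counted
separately and excluded from the denominator, so for every
contraindication and period::

    denominator + missing = cohort size
    rate = 100 * numerator / denominator        (undefined when denominator = 0)

Rates are reported to one decimal, but the engine-vs-oracle equivalence
is always asserted on the unrounded integer counts, since rounding could
mask a patient-level discrepancy.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

from .gdl.model import Guideline
from .gdl.parser import parse_guideline

#: Stable identifiers for the eleven European thrombolysis contraindications.
CONTRAINDICATION_IDS = (
    "nihss_gt_25",
    "anticoagulation",
    "sbp_gt_185",
    "sbp_gt_184",
    "dbp_gt_110",
    "dbp_gt_109",
    "diabetes_and_previous_stroke",
    "glucose_lt_50_or_gt_400",
    "age_gt_80",
    "onset_gt_3h",
    "onset_gt_4_5h",
)

_LABELS = {
    "nihss_gt_25": "NIHSS score > 25",
    "anticoagulation": "Anticoagulation treatment",
    "sbp_gt_185": "Systolic blood pressure > 185 mmHg",
    "sbp_gt_184": "Systolic blood pressure > 184 mmHg",
    "dbp_gt_110": "Diastolic blood pressure > 110 mmHg",
    "dbp_gt_109": "Diastolic blood pressure > 109 mmHg",
    "diabetes_and_previous_stroke": "Diabetes and previous stroke",
    "glucose_lt_50_or_gt_400": "Blood glucose < 50 mg/dl or > 400 mg/dl",
    "age_gt_80": "Age > 80 years",
    "onset_gt_3h": "Stroke onset > 3 h ago",
    "onset_gt_4_5h": "Stroke onset > 4.5 h ago",
}

_REQUIRED_COLUMNS = {
    "nihss_gt_25": ("nihss",),
    "anticoagulation": ("anticoagulation",),
    "sbp_gt_185": ("sbp",),
    "sbp_gt_184": ("sbp",),
    "dbp_gt_110": ("dbp",),
    "dbp_gt_109": ("dbp",),
    "diabetes_and_previous_stroke": ("diabetes", "previous_stroke"),
    "glucose_lt_50_or_gt_400": ("glucose",),
    "age_gt_80": ("age",),
    "onset_gt_3h": ("onset_to_treatment",),
    "onset_gt_4_5h": ("onset_to_treatment",),
}

_DESCRIPTIONS = {
    "nihss_gt_25": "stroke severity score above 25",
    "anticoagulation": "ongoing oral anticoagulation treatment",
    "sbp_gt_185": "systolic blood pressure strictly above 185 mmHg",
    "sbp_gt_184": "systolic blood pressure strictly above 184 mmHg",
    "dbp_gt_110": "diastolic blood pressure strictly above 110 mmHg",
    "dbp_gt_109": "diastolic blood pressure strictly above 109 mmHg",
    "diabetes_and_previous_stroke": "diabetes mellitus together with a prior stroke",
    "glucose_lt_50_or_gt_400": "blood glucose below 50 or above 400 mg/dl",
    "age_gt_80": "age strictly above 80 years",
    "onset_gt_3h": "onset-to-treatment time strictly above 3 hours",
    "onset_gt_4_5h": "onset-to-treatment time strictly above 4.5 hours",
}


@dataclass(frozen=True)
class ContraindicationDef:
    id: str
    label: str
    guideline_file: str
    required_columns: tuple
    description: str

    def load_guideline(self) -> Guideline:
        return parse_guideline(self.guideline_text())

    def guideline_text(self) -> str:
        return (
            importlib.resources.files("gdlaudit")
            .joinpath(f"guidelines/{self.guideline_file}")
            .read_text(encoding="utf-8")
        )


def builtin_contraindications() -> list:
    """The eleven shipped contraindication definitions, in report order."""
    return [
        ContraindicationDef(
            id=cid,
            label=_LABELS[cid],
            guideline_file=f"{cid}.gdl2t",
            required_columns=_REQUIRED_COLUMNS[cid],
            description=_DESCRIPTIONS[cid],
        )
        for cid in CONTRAINDICATION_IDS
    ]


def builtin_guideline_dir() -> Path:
    """Directory holding the shipped ``.gdl2t`` files."""
    return Path(importlib.resources.files("gdlaudit").joinpath("guidelines"))


# --------------------------------------------------------------------------
# results

@dataclass(frozen=True)
class ComplianceResult:
    """Counts and rate for one (contraindication, period) cell."""

    contraindication_id: str
    period: str
    numerator: int
    denominator: int
    missing: int

    @property
    def rate(self) -> Optional[float]:
        """Non-compliance rate in percent; ``None`` when undefined."""
        if self.denominator == 0:
            return None
        return 100.0 * self.numerator / self.denominator

    @property
    def rate_display(self) -> str:
        return "NA" if self.rate is None else f"{self.rate:.1f}"

    def counts_equal(self, other: "ComplianceResult") -> bool:
        return (
            self.numerator == other.numerator
            and self.denominator == other.denominator
            and self.missing == other.missing
        )


def compute_rates(outcomes: pd.DataFrame) -> list:
    """Aggregate a per-patient outcome table into compliance results.

    ``outcomes`` columns: patient_id, period, contraindication_id, flag
    (``noncompliant`` | ``compliant`` | ``missing``).
    """
    results = []
    if outcomes.empty:
        return results
    grouped = outcomes.groupby(["contraindication_id", "period"], sort=False)
    for (cid, period), group in grouped:
        flags = group["flag"]
        noncompliant = int((flags == "noncompliant").sum())
        missing = int((flags == "missing").sum())
        compliant = int((flags == "compliant").sum())
        results.append(
            ComplianceResult(
                contraindication_id=cid,
                period=period,
                numerator=noncompliant,
                denominator=noncompliant + compliant,
                missing=missing,
            )
        )
    return results


# --------------------------------------------------------------------------
# engine vs oracle comparison

@dataclass(frozen=True)
class MatchRow:
    contraindication_id: str
    period: str
    engine: ComplianceResult
    oracle: ComplianceResult

    @property
    def equal(self) -> bool:
        return self.engine.counts_equal(self.oracle)


@dataclass
class MatchReport:
    rows: list

    @property
    def complete_match(self) -> bool:
        return all(row.equal for row in self.rows)

    def discrepancies(self) -> list:
        return [
            (row.contraindication_id, row.period)
            for row in self.rows
            if not row.equal
        ]


def compare(engine_results, oracle_results) -> MatchReport:
    """Pair engine and oracle results and test integer-exact agreement.

    Raises ``ValueError`` when the two result sets cover different
    (contraindication, period) cells.
    """
    engine_map = {(r.contraindication_id, r.period): r for r in engine_results}
    oracle_map = {(r.contraindication_id, r.period): r for r in oracle_results}
    if set(engine_map) != set(oracle_map):
        only_engine = sorted(set(engine_map) - set(oracle_map))
        only_oracle = sorted(set(oracle_map) - set(engine_map))
        raise ValueError(
            "mismatched result sets: "
            f"engine-only={only_engine}, oracle-only={only_oracle}"
        )
    rows = [
        MatchRow(cid, period, engine_map[(cid, period)], oracle_map[(cid, period)])
        for cid, period in engine_map
    ]
    rows.sort(
        key=lambda r: (
            CONTRAINDICATION_IDS.index(r.contraindication_id)
            if r.contraindication_id in CONTRAINDICATION_IDS
            else len(CONTRAINDICATION_IDS),
            r.period,
        )
    )
    return MatchReport(rows=rows)


# --------------------------------------------------------------------------
# result (de)serialization and reporting

def results_to_json(results, path=None) -> str:
    payload = [
        {
            "contraindication_id": r.contraindication_id,
            "period": r.period,
            "numerator": r.numerator,
            "denominator": r.denominator,
            "missing": r.missing,
            "rate": r.rate,
        }
        for r in results
    ]
    text = json.dumps(payload, indent=2) + "\n"
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def results_from_json(path) -> list:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    return [
        ComplianceResult(
            contraindication_id=item["contraindication_id"],
            period=item["period"],
            numerator=item["numerator"],
            denominator=item["denominator"],
            missing=item["missing"],
        )
        for item in payload
    ]


def report(match: MatchReport, out_dir, labels=None) -> dict:
    """Write the per-contraindication rate table as CSV and JSON.

    One row per contraindication; per period, one engine and one oracle
    rate column (1-decimal strings, ``NA`` when undefined), plus the raw
    counts in the JSON file.  Returns the written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    labels = labels or _LABELS
    periods = sorted({row.period for row in match.rows})
    order = []
    by_cid: dict = {}
    for row in match.rows:
        if row.contraindication_id not in by_cid:
            order.append(row.contraindication_id)
        by_cid.setdefault(row.contraindication_id, {})[row.period] = row

    records = []
    for cid in order:
        rec: dict = {
            "contraindication_id": cid,
            "label": labels.get(cid, cid),
        }
        for period in periods:
            row = by_cid[cid].get(period)
            rec[f"engine_pct_{period}"] = row.engine.rate_display if row else "NA"
            rec[f"oracle_pct_{period}"] = row.oracle.rate_display if row else "NA"
        records.append(rec)
    table = pd.DataFrame.from_records(records)
    csv_path = out_dir / "report.csv"
    table.to_csv(csv_path, index=False, lineterminator="\n")

    json_path = out_dir / "report.json"
    payload = {
        "complete_match": match.complete_match,
        "periods": periods,
        "rows": [
            {
                "contraindication_id": row.contraindication_id,
                "label": labels.get(row.contraindication_id, row.contraindication_id),
                "period": row.period,
                "engine": {
                    "numerator": row.engine.numerator,
                    "denominator": row.engine.denominator,
                    "missing": row.engine.missing,
                    "rate": row.engine.rate,
                },
                "oracle": {
                    "numerator": row.oracle.numerator,
                    "denominator": row.oracle.denominator,
                    "missing": row.oracle.missing,
                    "rate": row.oracle.rate,
                },
                "equal": row.equal,
            }
            for row in match.rows
        ],
    }
    json_path.write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
    return {"csv": csv_path, "json": json_path}
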