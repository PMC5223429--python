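import json

import pandas as pd
import pytest

from gdlaudit.compliance import (
    CONTRAINDICATION_IDS,
    ComplianceResult,
    compare,
    compute_rates,
    report,
    results_from_json,
    results_to_json,
)
from gdlaudit.oracle import ORACLE_PREDICATES, oracle_rates


def test_builtin_set_has_eleven_defs(contraindications):
    assert len(contraindications) == 11
    assert [d.id for d in contraindications] == list(CONTRAINDICATION_IDS)
    labels = {d.label for d in contraindications}
    assert "Blood glucose < 50 mg/dl or > 400 mg/dl" in labels
    assert "Stroke onset > 4.5 h ago" in labels


def test_glucose_guideline_carries_canonical_rule(contraindications):
    d = next(c for c in contraindications if c.id == "glucose_lt_50_or_gt_400")
    text = d.guideline_text()
    assert "($gt0018<50,mg/dl)||($gt0018>400,mg/dl)" in text
    assert "$gt0020==null" in text
    assert "$gt0049=true" in text and "$gt0020=true" in text


def _outcomes(rows):
    return pd.DataFrame(
        rows, columns=["patient_id", "period", "contraindication_id", "flag"]
    )


class TestComputeRates:
    def test_large_cohort_rate(self):
        rows = [
            (f"p{i}", "2006-2007", "age_gt_80", "noncompliant" if i < 89 else "compliant")
            for i in range(1000)
        ]
        (result,) = compute_rates(_outcomes(rows))
        assert (result.numerator, result.denominator, result.missing) == (89, 1000, 0)
        assert result.rate_display == "8.9"

    def test_missing_excluded_from_denominator(self):
        rows = (
            [(f"p{i}", "2006-2007", "x", "noncompliant") for i in range(3)]
            + [(f"q{i}", "2006-2007", "x", "missing") for i in range(2)]
            + [(f"r{i}", "2006-2007", "x", "compliant") for i in range(5)]
        )
        (result,) = compute_rates(_outcomes(rows))
        assert (result.numerator, result.denominator, result.missing) == (3, 8, 2)
        assert result.rate == pytest.approx(37.5)

    def test_all_missing_is_undefined_not_zero(self):
        rows = [(f"p{i}", "2006-2007", "x", "missing") for i in range(4)]
        (result,) = compute_rates(_outcomes(rows))
        assert result.denominator == 0
        assert result.rate is None
        assert result.rate_display == "NA"

    def test_empty_outcomes(self):
        assert compute_rates(_outcomes([])) == []


class TestOracle:
    def test_sbp_quarter(self, registry_factory):
        df = registry_factory(
            [{"sbp": 190}, {"sbp": 120}, {"sbp": 185}, {"sbp": 100}]
        )
        rates = {r.contraindication_id: r for r in oracle_rates(df)}
        assert rates["sbp_gt_185"].rate == pytest.approx(25.0)
        # 185 exactly is compliant under the strict bound
        assert rates["sbp_gt_185"].numerator == 1

    def test_conjunction_with_one_flag_missing_is_excluded(self, registry_factory):
        df = registry_factory(
            [{"diabetes": 1, "previous_stroke": None}, {"diabetes": 1, "previous_stroke": 1}]
        )
        rates = {r.contraindication_id: r for r in oracle_rates(df)}
        r = rates["diabetes_and_previous_stroke"]
        assert (r.numerator, r.denominator, r.missing) == (1, 1, 1)


class TestCompare:
    def _results(self, numerator=5):
        return [
            ComplianceResult("age_gt_80", "2006-2007", numerator, 100, 2),
            ComplianceResult("sbp_gt_185", "2006-2007", 3, 100, 2),
        ]

    def test_identical_counts_match(self):
        match = compare(self._results(), self._results())
        assert match.complete_match
        assert match.discrepancies() == []

    def test_count_difference_names_contraindication(self):
        match = compare(self._results(5), self._results(6))
        assert not match.complete_match
        assert ("age_gt_80", "2006-2007") in match.discrepancies()

    def test_off_by_one_oracle_predicate_breaks_match(self, registry_factory):
        df = registry_factory([{"age": a} for a in (79, 81, 82, 83, 84, 90)])
        good = oracle_rates(df)
        mutated_predicates = dict(ORACLE_PREDICATES)
        mutated_predicates["age_gt_80"] = (("age",), lambda d: d["age"] > 84)
        bad = oracle_rates(df, predicates=mutated_predicates)
        match = compare(good, bad)
        assert not match.complete_match
        assert match.discrepancies() == [("age_gt_80", "2006-2007")]

    def test_empty_vs_empty_vacuously_matches(self):
        assert compare([], []).complete_match

    def test_mismatched_result_sets_rejected(self):
        with pytest.raises(ValueError, match="mismatched"):
            compare(self._results(), self._results()[:1])


def test_results_json_round_trip(tmp_path):
    results = [
        ComplianceResult("age_gt_80", "2006-2007", 89, 1000, 0),
        ComplianceResult("age_gt_80", "2010-2011", 0, 0, 10),
    ]
    path = tmp_path / "results.json"
    results_to_json(results, path)
    assert results_from_json(path) == results
    # undefined rate serializes as null, never as 0
    payload = json.loads(path.read_text())
    assert payload[1]["rate"] is None


def test_report_two_periods(tmp_path):
    engine = [
        ComplianceResult(cid, period, 10, 100, 5)
        for cid in CONTRAINDICATION_IDS
        for period in ("2006-2007", "2010-2011")
    ]
    match = compare(engine, engine)
    paths = report(match, tmp_path)
    table = pd.read_csv(paths["csv"], dtype=str)
    assert len(table) == 11
    rate_cols = [c for c in table.columns if c.endswith("2006-2007") or c.endswith("2010-2011")]
    assert len(rate_cols) == 4  # engine + oracle per period
    assert (table[rate_cols] == "10.0").all().all()
    payload = json.loads(paths["json"].read_text())
    assert payload["complete_match"] is True
    assert len(payload["rows"]) == 22


def test_report_single_period_round_trip(tmp_path):
    engine = [ComplianceResult("age_gt_80", "2006-2007", 3, 8, 2)]
    match = compare(engine, engine)
    paths = report(match, tmp_path)
    table = pd.read_csv(paths["csv"], dtype=str)
    rate_cols = [c for c in table.columns if "pct" in c]
    assert len(rate_cols) == 2
    # re-read rates equal the in-memory rates at 1-decimal precision
    assert table[rate_cols].iloc[0].tolist() == ["37.5", "37.5"]
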