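import pandas as pd
import pytest

from gdlaudit.errors import AssemblyError, RegistryError
from gdlaudit.registry import (
    MappingEntry,
    MappingSpec,
    PERIOD_ARCHETYPE_ID,
    assemble_patient,
    read_dataset_csv,
    read_registry_csv,
    split_registry,
    write_dataset_csv,
    write_registry_csv,
)
from gdlaudit.units import Quantity


GLUCOSE_ARCHETYPE = "openEHR-EHR-OBSERVATION.lab_test-blood_glucose.v1"


def test_split_preserves_patients_and_values(registry_factory, mapping):
    df = registry_factory(
        [{"glucose": 45}, {"glucose": 80}, {"glucose": None}, {}, {}] * 2
    )
    datasets = split_registry(df, mapping)
    for ds in datasets.values():
        assert len(ds.data) == len(df)  # no row loss, missing rows kept
        assert list(ds.data.index) == list(df["patient_id"])
    glu = datasets[GLUCOSE_ARCHETYPE].data["gt0018"]
    # conservation: non-missing count preserved per mapped column
    assert glu.notna().sum() == df["glucose"].notna().sum()
    assert glu.iloc[0] == 45.0 and pd.isna(glu.iloc[2])


def test_split_converts_mmol_per_l_to_mg_per_dl(registry_factory):
    spec = MappingSpec(
        entries=(
            MappingEntry(
                column="glucose",
                archetype_id=GLUCOSE_ARCHETYPE,
                gt_code="gt0018",
                path="/data[at0001]/items[at0078.2]",
                kind="quantity",
                source_unit="mmol/l",
                target_unit="mg/dl",
            ),
        )
    )
    df = registry_factory([{"glucose": 5.0}])
    datasets = split_registry(df, spec)
    assert datasets[GLUCOSE_ARCHETYPE].data["gt0018"].iloc[0] == pytest.approx(90.08)


def test_split_unknown_column_rejected(registry_factory):
    spec = MappingSpec(
        entries=(
            MappingEntry(
                column="cholesterol",
                archetype_id=GLUCOSE_ARCHETYPE,
                gt_code="gt0018",
                path="/data[at0001]/items[at0001]",
                kind="quantity",
                source_unit="mg/dl",
                target_unit="mg/dl",
            ),
        )
    )
    with pytest.raises(RegistryError, match="cholesterol"):
        split_registry(registry_factory([{}]), spec)


def test_registry_csv_round_trip(registry_factory, tmp_path):
    df = registry_factory([{"glucose": None}, {"sbp": 190}, {}])
    path = tmp_path / "reg.csv"
    write_registry_csv(df, path)
    back = read_registry_csv(path)
    pd.testing.assert_frame_equal(back, df, check_dtype=False)
    # and the empty cell is genuinely missing
    assert pd.isna(back["glucose"].iloc[0])


def test_dataset_csv_round_trip(registry_factory, mapping, tmp_path):
    df = registry_factory([{"glucose": 45}, {"glucose": None}, {"diabetes": 1}])
    datasets = split_registry(df, mapping)
    for ds in datasets.values():
        path = tmp_path / "ds.csv"
        write_dataset_csv(ds, path)
        back = read_dataset_csv(path)
        assert back.equals(ds), ds.archetype_id


def test_malformed_numeric_cell_reported_with_row(tmp_path, registry_factory):
    df = registry_factory([{}, {}])
    path = tmp_path / "reg.csv"
    write_registry_csv(df, path)
    text = path.read_text().replace("120", "abc", 1)
    path.write_text(text)
    with pytest.raises(RegistryError, match=r"row 2.*sbp.*abc"):
        read_registry_csv(path)


def test_duplicate_patient_id_rejected(tmp_path, registry_factory):
    df = registry_factory([{}, {}])
    df.loc[1, "patient_id"] = df.loc[0, "patient_id"]
    path = tmp_path / "reg.csv"
    write_registry_csv(df, path)
    with pytest.raises(RegistryError, match="duplicate patient id"):
        read_registry_csv(path)


class TestAssemblePatient:
    def test_values_typed_and_unit_tagged(self, registry_factory, mapping, guidelines):
        df = registry_factory([{"glucose": 45}])
        datasets = split_registry(df, mapping)
        record = assemble_patient(
            "P00001", datasets, guidelines["glucose_lt_50_or_gt_400"]
        )
        assert record.values == {"gt0018": Quantity(45.0, "mg/dl")}
        assert record.period == "2006-2007"

    def test_missing_cell_becomes_missing(self, registry_factory, mapping, guidelines):
        df = registry_factory([{"glucose": None}])
        datasets = split_registry(df, mapping)
        record = assemble_patient(
            "P00001", datasets, guidelines["glucose_lt_50_or_gt_400"]
        )
        assert record.values == {"gt0018": None}

    def test_unknown_patient_names_dataset(self, registry_factory, mapping, guidelines):
        df = registry_factory([{}])
        datasets = split_registry(df, mapping)
        with pytest.raises(AssemblyError, match="blood_glucose"):
            assemble_patient("NOPE", datasets, guidelines["glucose_lt_50_or_gt_400"])

    def test_record_contains_only_bound_codes(
        self, registry_factory, mapping, guidelines
    ):
        df = registry_factory([{}])
        datasets = split_registry(df, mapping)
        record = assemble_patient("P00001", datasets, guidelines["age_gt_80"])
        assert set(record.values) == {"gt0010"}


def test_period_travels_in_admin_dataset(registry_factory, mapping):
    df = registry_factory([{"period": "2010-2011"}])
    datasets = split_registry(df, mapping)
    assert PERIOD_ARCHETYPE_ID in datasets
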