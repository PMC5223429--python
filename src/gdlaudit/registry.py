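"""Registry CSV handling, archetype-aligned splitting, and patient assembly.

The wide registry extract (one row per treated patient) is split into one
CSV dataset per archetype, following a frozen equivalence mapping from
registry columns to archetype elements.  Missing cells are preserved as
missing — never dropped — because the missing counts feed the denominator
exclusion in the compliance calculations.

CSV dialect: UTF-8, comma separator, double-quote quoting, header row,
``.`` decimal point, empty string = missing, first column ``patient_id``.
Archetype dataset files carry two leading ``#`` metadata lines recording
the archetype id and the column typing, so write/read is an identity.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from .errors import AssemblyError, RegistryError
from .gdl.model import Guideline
from .engine import PatientRecord
from .units import Quantity, conversion_factor

#: Canonical registry schema: one row per treated patient.
REGISTRY_COLUMNS = (
    "patient_id",
    "period",
    "age",
    "nihss",
    "sbp",
    "dbp",
    "glucose",
    "onset_to_treatment",
    "anticoagulation",
    "diabetes",
    "previous_stroke",
)

PERIODS = ("2006-2007", "2010-2011")

BOOLEAN_COLUMNS = ("anticoagulation", "diabetes", "previous_stroke")
NUMERIC_COLUMNS = (
    "age",
    "nihss",
    "sbp",
    "dbp",
    "glucose",
    "onset_to_treatment",
) + BOOLEAN_COLUMNS

#: Pseudo-archetype carrying the treatment-period label through the split.
PERIOD_ARCHETYPE_ID = "openEHR-EHR-ADMIN_ENTRY.treatment_period.v1"
PERIOD_CODE = "gt0900"


@dataclass(frozen=True)
class MappingEntry:
    """One equivalence decision: registry column -> archetype element."""

    column: str
    archetype_id: str
    gt_code: str
    path: str
    kind: str  # "quantity" | "boolean" | "label"
    source_unit: Optional[str] = None
    target_unit: Optional[str] = None


@dataclass(frozen=True)
class MappingSpec:
    entries: tuple

    def by_column(self) -> dict:
        return {e.column: e for e in self.entries}


@dataclass
class ArchetypeDataset:
    """Per-archetype patient data: index patient_id, columns gt-codes."""

    archetype_id: str
    data: pd.DataFrame
    kinds: dict = field(default_factory=dict)  # gt_code -> kind
    units: dict = field(default_factory=dict)  # gt_code -> target unit (quantity only)

    def equals(self, other: "ArchetypeDataset") -> bool:
        if self.archetype_id != other.archetype_id:
            return False
        if self.kinds != other.kinds or self.units != other.units:
            return False
        try:
            pd.testing.assert_frame_equal(
                self.data, other.data, check_dtype=False, check_exact=True
            )
        except AssertionError:
            return False
        return True


# --------------------------------------------------------------------------
# mapping spec

def load_mapping(path) -> MappingSpec:
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    return _mapping_from_dict(raw)


def default_mapping() -> MappingSpec:
    """The shipped registry-to-archetype equivalence mapping."""
    text = (
        importlib.resources.files("gdlaudit")
        .joinpath("guidelines/mapping.yaml")
        .read_text(encoding="utf-8")
    )
    return _mapping_from_dict(yaml.safe_load(text))


def _mapping_from_dict(raw: dict) -> MappingSpec:
    entries = []
    seen_columns = set()
    for item in raw["columns"]:
        entry = MappingEntry(
            column=item["column"],
            archetype_id=item["archetype_id"],
            gt_code=item["gt_code"],
            path=item["path"],
            kind=item.get("kind", "quantity"),
            source_unit=(str(item["source_unit"]) if "source_unit" in item else None),
            target_unit=(str(item["target_unit"]) if "target_unit" in item else None),
        )
        if entry.column in seen_columns:
            raise RegistryError(f"column {entry.column!r} mapped twice")
        seen_columns.add(entry.column)
        if entry.kind == "quantity":
            # raises UnitError if the pair is not convertible
            conversion_factor(entry.source_unit, entry.target_unit)
        entries.append(entry)
    return MappingSpec(entries=tuple(entries))


# --------------------------------------------------------------------------
# registry CSV

def read_registry_csv(path) -> pd.DataFrame:
    """Read and validate a wide registry CSV.

    Numeric columns become nullable ``Int64``; empty cells become missing.
    Malformed numeric cells are reported with their row number (header is
    row 1).
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in REGISTRY_COLUMNS if c not in raw.columns]
    if missing_cols:
        raise RegistryError(f"registry lacks columns: {', '.join(missing_cols)}")
    return validate_registry(raw.copy())


def validate_registry(df: pd.DataFrame) -> pd.DataFrame:
    """Coerce a string-typed registry frame to the canonical schema."""
    if df["patient_id"].duplicated().any():
        dup = df.loc[df["patient_id"].duplicated(), "patient_id"].iloc[0]
        raise RegistryError(f"duplicate patient id: {dup!r}")
    bad_period = ~df["period"].isin(PERIODS)
    if bad_period.any():
        row = int(np.flatnonzero(bad_period.to_numpy())[0])
        raise RegistryError(
            f"row {row + 2}, column 'period': invalid label "
            f"{df['period'].iloc[row]!r} (expected one of {list(PERIODS)})"
        )
    out = df.copy()
    for col in NUMERIC_COLUMNS:
        cell = df[col].astype(str).str.strip()
        numeric = pd.to_numeric(cell.replace("", None), errors="coerce")
        bad = cell.ne("") & numeric.isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise RegistryError(
                f"row {row + 2}, column {col!r}: malformed numeric cell "
                f"{cell.iloc[row]!r}"
            )
        if (numeric.dropna() < 0).any():
            raise RegistryError(f"column {col!r}: negative value")
        if col in BOOLEAN_COLUMNS and not numeric.dropna().isin((0, 1)).all():
            raise RegistryError(f"column {col!r}: flags must be 0 or 1")
        out[col] = numeric.round().astype("Int64") if _is_integral(numeric) else numeric
    return out


def _is_integral(series: pd.Series) -> bool:
    values = series.dropna()
    return bool(len(values) == 0 or (values == values.round()).all())


def write_registry_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, lineterminator="\n")


# --------------------------------------------------------------------------
# splitting

def split_registry(df: pd.DataFrame, mapping: MappingSpec) -> dict:
    """Split a registry table into per-archetype datasets.

    Every patient appears in every dataset; missing values stay missing.
    Quantities are converted from the mapping's source unit to its target
    unit.  The period label travels in a dedicated admin dataset so the
    engine can report per-period rates.
    """
    for entry in mapping.entries:
        if entry.column not in df.columns:
            raise RegistryError(f"unknown registry column {entry.column!r}")

    index = pd.Index(df["patient_id"].astype(str), name="patient_id")
    grouped: dict = {}
    for entry in mapping.entries:
        grouped.setdefault(entry.archetype_id, []).append(entry)

    datasets: dict = {}
    for archetype_id, entries in grouped.items():
        data = {}
        kinds = {}
        units = {}
        for entry in entries:
            col = df[entry.column]
            kinds[entry.gt_code] = entry.kind
            if entry.kind == "quantity":
                factor = conversion_factor(entry.source_unit, entry.target_unit)
                data[entry.gt_code] = col.astype("Float64").astype(float) * factor
                units[entry.gt_code] = entry.target_unit
            elif entry.kind == "boolean":
                data[entry.gt_code] = col.map(
                    lambda v: pd.NA if pd.isna(v) else bool(v)
                ).astype("boolean")
            elif entry.kind == "label":
                data[entry.gt_code] = col.astype(str).where(~col.isna(), None)
            else:
                raise RegistryError(f"unknown mapping kind {entry.kind!r}")
        # align on row position, not on the source frame's index
        frame = pd.DataFrame(data)
        frame.index = index
        datasets[archetype_id] = ArchetypeDataset(
            archetype_id=archetype_id, data=frame, kinds=kinds, units=units
        )
    return datasets


# --------------------------------------------------------------------------
# dataset CSV round-trip

def write_dataset_csv(dataset: ArchetypeDataset, path) -> None:
    cols = list(dataset.data.columns)
    meta_cols = []
    for code in cols:
        kind = dataset.kinds[code]
        unit = dataset.units.get(code, "")
        meta_cols.append(f"{code}:{kind}:{unit}")
    export = pd.DataFrame(index=dataset.data.index)
    for code in cols:
        series = dataset.data[code]
        if dataset.kinds[code] == "boolean":
            export[code] = series.map(
                lambda v: "" if pd.isna(v) else ("true" if v else "false")
            )
        elif dataset.kinds[code] == "quantity":
            export[code] = series.map(lambda v: "" if pd.isna(v) else repr(float(v)))
        else:
            export[code] = series.map(lambda v: "" if pd.isna(v) else str(v))
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"#archetype_id={dataset.archetype_id}\n")
        fh.write("#columns=" + ",".join(meta_cols) + "\n")
        export.to_csv(fh, index=True, lineterminator="\n")


def read_dataset_csv(path) -> ArchetypeDataset:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().strip()
        columns_line = fh.readline().strip()
        if not header.startswith("#archetype_id=") or not columns_line.startswith(
            "#columns="
        ):
            raise RegistryError(f"{path.name}: missing dataset metadata lines")
        archetype_id = header.split("=", 1)[1]
        kinds = {}
        units = {}
        for spec in columns_line.split("=", 1)[1].split(","):
            code, kind, unit = spec.split(":")
            kinds[code] = kind
            if kind == "quantity":
                units[code] = unit
        raw = pd.read_csv(fh, dtype=str, keep_default_na=False)
    if "patient_id" not in raw.columns:
        raise RegistryError(f"{path.name}: first column must be patient_id")
    if raw["patient_id"].duplicated().any():
        raise RegistryError(f"{path.name}: duplicate patient id")
    index = pd.Index(raw["patient_id"], name="patient_id")
    data = {}
    for code, kind in kinds.items():
        cell = raw[code].str.strip()
        if kind == "quantity":
            numeric = pd.to_numeric(cell.replace("", None), errors="coerce")
            bad = cell.ne("") & numeric.isna()
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise RegistryError(
                    f"{path.name}: row {row + 3}, column {code!r}: "
                    f"malformed numeric cell {cell.iloc[row]!r}"
                )
            data[code] = numeric.astype(float)
        elif kind == "boolean":
            if not cell.isin(("", "true", "false")).all():
                raise RegistryError(f"{path.name}: column {code!r}: bad boolean cell")
            data[code] = cell.map(
                {"": pd.NA, "true": True, "false": False}
            ).astype("boolean")
        else:
            data[code] = cell.where(cell.ne(""), None)
    frame = pd.DataFrame(data)
    frame.index = index
    return ArchetypeDataset(
        archetype_id=archetype_id, data=frame, kinds=kinds, units=units
    )


def write_datasets(datasets: Mapping[str, ArchetypeDataset], out_dir) -> list:
    """Write every dataset to ``out_dir`` as ``<archetype_id>.csv``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for archetype_id in sorted(datasets):
        path = out_dir / f"{archetype_id}.csv"
        write_dataset_csv(datasets[archetype_id], path)
        paths.append(path)
    return paths


def read_datasets(in_dir) -> dict:
    datasets = {}
    for path in sorted(Path(in_dir).glob("*.csv")):
        ds = read_dataset_csv(path)
        datasets[ds.archetype_id] = ds
    return datasets


# --------------------------------------------------------------------------
# patient assembly

def assemble_patient(pid: str, datasets, g: Guideline) -> PatientRecord:
    """Build one patient's record with exactly the codes ``g`` binds.

    Values absent or empty in the datasets become missing (``None``).
    Raises :class:`AssemblyError` naming the dataset when the patient is
    not present in a required dataset.
    """
    if not isinstance(datasets, Mapping):
        datasets = {d.archetype_id: d for d in datasets}
    values: dict = {}
    for binding in g.ehr_bindings():
        ds = datasets.get(binding.archetype_id)
        if ds is None:
            raise AssemblyError(
                f"no dataset for archetype {binding.archetype_id!r}"
            )
        if pid not in ds.data.index:
            raise AssemblyError(
                f"patient {pid!r} absent from dataset {binding.archetype_id!r}"
            )
        for element in binding.elements:
            if element.id not in ds.data.columns:
                raise AssemblyError(
                    f"dataset {binding.archetype_id!r} lacks element {element.id}"
                )
            v = ds.data.at[pid, element.id]
            if pd.isna(v):
                values[element.id] = None
            elif ds.kinds[element.id] == "quantity":
                values[element.id] = Quantity(float(v), ds.units[element.id])
            elif ds.kinds[element.id] == "boolean":
                values[element.id] = bool(v)
            else:
                values[element.id] = v
    period = None
    period_ds = datasets.get(PERIOD_ARCHETYPE_ID)
    if period_ds is not None and pid in period_ds.data.index:
        v = period_ds.data.at[pid, PERIOD_CODE]
        period = None if pd.isna(v) else v
    return PatientRecord(patient_id=pid, period=period, values=values)
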