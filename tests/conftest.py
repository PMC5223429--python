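import pandas as pd
import pytest

from gdlaudit.compliance import builtin_contraindications
from gdlaudit.registry import REGISTRY_COLUMNS, default_mapping, validate_registry


@pytest.fixture(scope="session")
def contraindications():
    return builtin_contraindications()


@pytest.fixture(scope="session")
def guidelines(contraindications):
    """id -> parsed shipped guideline."""
    return {d.id: d.load_guideline() for d in contraindications}


@pytest.fixture(scope="session")
def mapping():
    return default_mapping()


def make_registry(rows):
    """Build a valid registry frame from partial row dicts.

    Unspecified clinical values default to clearly compliant ones; pass
    ``None`` to make a value missing.
    """
    defaults = {
        "period": "2006-2007",
        "age": 60,
        "nihss": 10,
        "sbp": 120,
        "dbp": 70,
        "glucose": 100,
        "onset_to_treatment": 90,
        "anticoagulation": 0,
        "diabetes": 0,
        "previous_stroke": 0,
    }
    records = []
    for i, row in enumerate(rows):
        rec = {"patient_id": f"P{i + 1:05d}", **defaults, **row}
        records.append(rec)
    df = pd.DataFrame.from_records(records, columns=REGISTRY_COLUMNS)
    as_str = df.astype(object).where(df.notna(), "").astype(str).replace("None", "")
    return validate_registry(as_str)


@pytest.fixture
def registry_factory():
    return make_registry
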