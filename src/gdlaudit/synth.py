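"""Seeded generator of SITS-like registry cohorts with planted prevalences.

The real SITS extract is access-restricted, so every pipeline component
is exercised on synthetic cohorts instead.  The generator plants, per
contraindication, an exact number (or sampled fraction) of patients whose
values lie strictly beyond the guideline threshold, keeps everyone else
strictly within it, and then blanks an exact per-column fraction of cells
(missing completely at random).  Threshold-boundary values are never
emitted, with one deliberate exception: the paired thresholds that differ
by one unit (SBP > 184 vs > 185, DBP > 109 vs > 110) can only be
separated by rows sitting exactly at the finer threshold (SBP 185,
DBP 110); those rows are part of the plant and double as a standing probe
of the strict-inequality semantics in both analysis arms.

The default two-period scenario plants per-1000 counts matching the
historical European profile: the 2010-2011 period has markedly higher
non-compliance with "Stroke onset > 3 h ago" and "Age > 80 years",
mirroring the 2008/2009 extension of the treatment window to 4.5 h and
the lifting of the age limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd

from .compliance import CONTRAINDICATION_IDS
from .errors import InfeasibleSpecError
from .registry import PERIODS, REGISTRY_COLUMNS

#: coarse threshold -> the strictly finer one it contains
_PAIRS = {
    "sbp_gt_184": "sbp_gt_185",
    "dbp_gt_109": "dbp_gt_110",
    "onset_gt_3h": "onset_gt_4_5h",
}

#: Planted per-period prevalences for the default two-period scenario
#: (fractions of the cohort; the later period carries the guideline-update
#: signal on onset>3h and age>80).
PERIOD_PROFILES = {
    "2006-2007": {
        "nihss_gt_25": 0.011,
        "anticoagulation": 0.024,
        "sbp_gt_185": 0.025,
        "sbp_gt_184": 0.040,
        "dbp_gt_110": 0.008,
        "dbp_gt_109": 0.021,
        "diabetes_and_previous_stroke": 0.025,
        "glucose_lt_50_or_gt_400": 0.003,
        "age_gt_80": 0.089,
        "onset_gt_3h": 0.082,
        "onset_gt_4_5h": 0.009,
    },
    "2010-2011": {
        "nihss_gt_25": 0.017,
        "anticoagulation": 0.031,
        "sbp_gt_185": 0.054,
        "sbp_gt_184": 0.063,
        "dbp_gt_110": 0.021,
        "dbp_gt_109": 0.036,
        "diabetes_and_previous_stroke": 0.028,
        "glucose_lt_50_or_gt_400": 0.003,
        "age_gt_80": 0.172,
        "onset_gt_3h": 0.279,
        "onset_gt_4_5h": 0.018,
    },
}


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic cohort.

    ``prevalence`` maps contraindication ids to planted fractions (floats
    in [0, 1]) or exact patient counts (ints).  In ``exact-counts`` mode a
    fraction is converted to ``round(fraction * n)``; in ``sampled`` mode
    it is a binomial probability.  ``missingness`` maps registry columns
    to the exact fraction of cells to blank.
    """

    n: int
    period: str = PERIODS[0]
    prevalence: Mapping[str, Union[float, int]] = field(default_factory=dict)
    missingness: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0
    mode: str = "exact-counts"
    id_prefix: str = "P"

    def __post_init__(self):
        if self.n < 0:
            raise InfeasibleSpecError("cohort size must be non-negative")
        if self.period not in PERIODS:
            raise InfeasibleSpecError(
                f"period must be one of {list(PERIODS)}, got {self.period!r}"
            )
        if self.mode not in ("exact-counts", "sampled"):
            raise InfeasibleSpecError(f"unknown mode {self.mode!r}")
        for cid in self.prevalence:
            if cid not in CONTRAINDICATION_IDS:
                raise InfeasibleSpecError(f"unknown contraindication id {cid!r}")
        for cid, value in self.prevalence.items():
            if isinstance(value, bool) or not isinstance(value, (int, float)):
                raise InfeasibleSpecError(f"bad prevalence for {cid}: {value!r}")
            if isinstance(value, float) and not 0.0 <= value <= 1.0:
                raise InfeasibleSpecError(f"fraction out of [0,1] for {cid}")
            if isinstance(value, int) and not 0 <= value <= self.n:
                raise InfeasibleSpecError(
                    f"planted count {value} exceeds cohort size {self.n} for {cid}"
                )
        for col, frac in self.missingness.items():
            if col not in REGISTRY_COLUMNS or col in ("patient_id", "period"):
                raise InfeasibleSpecError(f"cannot blank column {col!r}")
            if not 0.0 <= frac <= 1.0:
                raise InfeasibleSpecError(f"missingness fraction out of [0,1] for {col}")


def _resolve_counts(spec: CohortSpec, rng: np.random.Generator) -> dict:
    counts = {}
    for cid in CONTRAINDICATION_IDS:  # fixed order keeps the rng stream stable
        if cid not in spec.prevalence:
            counts[cid] = None
            continue
        value = spec.prevalence[cid]
        if isinstance(value, int):
            counts[cid] = value
        elif spec.mode == "exact-counts":
            counts[cid] = int(round(value * spec.n))
        else:
            counts[cid] = int(rng.binomial(spec.n, value))
    for coarse, fine in _PAIRS.items():
        k_fine = counts[fine] or 0
        if counts[coarse] is None:
            # unspecified coarse threshold: no extra rows in the gap band
            counts[coarse] = k_fine
        elif counts[coarse] < k_fine and spec.mode == "sampled":
            # independent binomial draws can invert the pair; restore the
            # subset structure by lifting the coarse count to the fine one
            counts[coarse] = k_fine
        elif counts[coarse] < k_fine:
            raise InfeasibleSpecError(
                f"{coarse} count ({counts[coarse]}) cannot be below "
                f"{fine} count ({k_fine}): the finer predicate implies the coarser"
            )
    for cid, k in counts.items():
        counts[cid] = k or 0
        if counts[cid] > spec.n:
            raise InfeasibleSpecError(
                f"planted count {counts[cid]} exceeds cohort size {spec.n} for {cid}"
            )
    return counts


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate one registry cohort; deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    counts = _resolve_counts(spec, rng)

    def plant_indices(k: int) -> np.ndarray:
        return rng.choice(n, size=k, replace=False) if k else np.empty(0, dtype=int)

    # age: compliant 18-79, contraindicated 81-100 (80 itself never emitted)
    age = rng.integers(18, 80, size=n)
    idx = plant_indices(counts["age_gt_80"])
    age[idx] = rng.integers(81, 101, size=len(idx))

    # NIHSS: compliant 0-24, contraindicated 26-42
    nihss = rng.integers(0, 25, size=n)
    idx = plant_indices(counts["nihss_gt_25"])
    nihss[idx] = rng.integers(26, 43, size=len(idx))

    # SBP: compliant 80-183; >185 plants 186-260; the 184-185 gap is exactly 185
    sbp = rng.integers(80, 184, size=n)
    k_fine, k_coarse = counts["sbp_gt_185"], counts["sbp_gt_184"]
    idx = plant_indices(k_coarse)
    sbp[idx[:k_fine]] = rng.integers(186, 261, size=k_fine)
    sbp[idx[k_fine:]] = 185

    # DBP: compliant 40-108; >110 plants 111-160; the 109-110 gap is exactly 110
    dbp = rng.integers(40, 109, size=n)
    k_fine, k_coarse = counts["dbp_gt_110"], counts["dbp_gt_109"]
    idx = plant_indices(k_coarse)
    dbp[idx[:k_fine]] = rng.integers(111, 161, size=k_fine)
    dbp[idx[k_fine:]] = 110

    # glucose: compliant 55-395 mg/dl; flagged rows go below 50 or above 400
    glucose = rng.integers(55, 396, size=n)
    idx = plant_indices(counts["glucose_lt_50_or_gt_400"])
    low = rng.random(len(idx)) < 0.5
    glucose[idx[low]] = rng.integers(30, 50, size=int(low.sum()))
    glucose[idx[~low]] = rng.integers(401, 501, size=int((~low).sum()))

    # onset-to-treatment (min): compliant 30-179; >4.5h plants 271-600;
    # the 3h-4.5h band plants 181-269 (180 and 270 never emitted)
    onset = rng.integers(30, 180, size=n)
    k_fine, k_coarse = counts["onset_gt_4_5h"], counts["onset_gt_3h"]
    idx = plant_indices(k_coarse)
    onset[idx[:k_fine]] = rng.integers(271, 601, size=k_fine)
    onset[idx[k_fine:]] = rng.integers(181, 270, size=k_coarse - k_fine)

    # anticoagulation flag
    anticoagulation = np.zeros(n, dtype=int)
    idx = plant_indices(counts["anticoagulation"])
    anticoagulation[idx] = 1

    # diabetes & previous stroke: the planted count controls the *joint*
    # prevalence; marginals elsewhere are background noise with the joint
    # combination suppressed
    diabetes = (rng.random(n) < 0.15).astype(int)
    previous_stroke = (rng.random(n) < 0.10).astype(int)
    previous_stroke[(diabetes == 1) & (previous_stroke == 1)] = 0
    idx = plant_indices(counts["diabetes_and_previous_stroke"])
    diabetes[idx] = 1
    previous_stroke[idx] = 1

    width = max(5, len(str(n)))
    df = pd.DataFrame(
        {
            "patient_id": [f"{spec.id_prefix}{i + 1:0{width}d}" for i in range(n)],
            "period": spec.period,
            "age": age,
            "nihss": nihss,
            "sbp": sbp,
            "dbp": dbp,
            "glucose": glucose,
            "onset_to_treatment": onset,
            "anticoagulation": anticoagulation,
            "diabetes": diabetes,
            "previous_stroke": previous_stroke,
        }
    )
    for col in df.columns[2:]:
        df[col] = df[col].astype("Int64")
    if spec.missingness:
        df = _blank_cells(df, spec.missingness, rng)
    return df


def _blank_cells(df, missingness, rng) -> pd.DataFrame:
    out = df.copy()
    n = len(out)
    for col in REGISTRY_COLUMNS:  # fixed iteration order for determinism
        if col not in missingness:
            continue
        k = int(round(missingness[col] * n))
        if k == 0:
            continue
        idx = rng.choice(n, size=k, replace=False)
        col_pos = out.columns.get_loc(col)
        out.iloc[idx, col_pos] = pd.NA
    return out


def inject_missingness(df: pd.DataFrame, missingness: Mapping[str, float], seed: int) -> pd.DataFrame:
    """Blank exactly ``round(fraction * n)`` cells per column, MCAR.

    Patient ids, the period label and untouched columns are preserved.
    """
    for col, frac in missingness.items():
        if col in ("patient_id", "period"):
            raise InfeasibleSpecError(f"cannot blank column {col!r}")
        if not 0.0 <= frac <= 1.0:
            raise InfeasibleSpecError(f"missingness fraction out of [0,1] for {col}")
    return _blank_cells(df, missingness, np.random.default_rng(seed))


def two_period_scenario(
    seed: int,
    n_per_period: int = 1000,
    missingness: Optional[Mapping[str, float]] = None,
) -> pd.DataFrame:
    """Concatenated two-period cohort carrying the guideline-update signal.

    Plants :data:`PERIOD_PROFILES` in exact-counts mode, so with the
    default ``n_per_period=1000`` the later period's onset > 3 h and
    age > 80 non-compliance exceed the earlier period's by construction.
    """
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s) & 0x7FFFFFFF for s in ss.generate_state(2)]
    frames = []
    for prefix, (period, profile), child_seed in zip(
        ("A", "B"), sorted(PERIOD_PROFILES.items()), child_seeds
    ):
        spec = CohortSpec(
            n=n_per_period,
            period=period,
            prevalence=profile,
            missingness=missingness or {},
            seed=child_seed,
            mode="exact-counts",
            id_prefix=prefix,
        )
        frames.append(generate_cohort(spec))
    return pd.concat(frames, ignore_index=True)


def random_cohort_spec(
    seed: int,
    n: int = 1000,
    period: str = PERIODS[0],
    mode: str = "exact-counts",
    max_prevalence: float = 0.30,
    max_missingness: float = 0.20,
) -> CohortSpec:
    """Draw a varied cohort specification from a seeded stream.

    Prevalences are uniform on [0, ``max_prevalence``] per contraindication
    (paired thresholds kept consistent), missingness uniform on
    [0, ``max_missingness``] per clinical column.  Used to sweep the
    engine-vs-oracle equivalence over heterogeneous cohorts.
    """
    rng = np.random.default_rng(seed)
    prevalence = {
        cid: float(rng.uniform(0.0, max_prevalence)) for cid in CONTRAINDICATION_IDS
    }
    for coarse, fine in _PAIRS.items():
        prevalence[coarse] = max(prevalence[coarse], prevalence[fine])
    missingness = {
        col: float(rng.uniform(0.0, max_missingness))
        for col in REGISTRY_COLUMNS
        if col not in ("patient_id", "period")
    }
    return CohortSpec(
        n=n,
        period=period,
        prevalence=prevalence,
        missingness=missingness,
        seed=int(rng.integers(2**31)),
        mode=mode,
    )


def spec_from_yaml_dict(raw: dict, n: int, period: str, seed: int) -> CohortSpec:
    """Build a :class:`CohortSpec` from a parsed YAML mapping."""
    return CohortSpec(
        n=n,
        period=period,
        prevalence=raw.get("prevalence", {}),
        missingness=raw.get("missingness", {}),
        seed=seed,
        mode=raw.get("mode", "exact-counts"),
    )
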