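"""Closed unit system for guideline quantities.

The guideline set only ever compares blood glucose (mg/dl, mmol/l),
blood pressure (mmHg), durations (min, h), age in years (``a``) and
dimensionless scores (``1``), so the unit system is a closed set of seven
units with a fixed conversion table rather than an open dimensional
framework: mmol/l -> mg/dl multiplies by 18.016 (glucose molar mass),
h -> min multiplies by 60.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import UnitError

#: The complete set of recognised units.
UNITS = frozenset({"mg/dl", "mmol/l", "mmHg", "min", "h", "a", "1"})

# unit -> (canonical unit, factor to canonical)
_CANONICAL: dict[str, tuple[str, float]] = {
    "mg/dl": ("mg/dl", 1.0),
    "mmol/l": ("mg/dl", 18.016),  # glucose-specific molar conversion
    "mmHg": ("mmHg", 1.0),
    "min": ("min", 1.0),
    "h": ("min", 60.0),
    "a": ("a", 1.0),
    "1": ("1", 1.0),
}


def check_unit(unit: str) -> str:
    if unit not in UNITS:
        raise UnitError(f"unknown unit {unit!r}; known units: {sorted(UNITS)}")
    return unit


def convertible(a: str, b: str) -> bool:
    """True when quantities in units ``a`` and ``b`` may be compared."""
    check_unit(a)
    check_unit(b)
    return _CANONICAL[a][0] == _CANONICAL[b][0]


def conversion_factor(src: str, dst: str) -> float:
    """Multiplicative factor taking a magnitude from ``src`` to ``dst``."""
    if not convertible(src, dst):
        raise UnitError(f"incommensurable units: {src!r} vs {dst!r}")
    return _CANONICAL[src][1] / _CANONICAL[dst][1]


def convert(magnitude: float, src: str, dst: str) -> float:
    return magnitude * conversion_factor(src, dst)


@dataclass(frozen=True)
class Quantity:
    """A magnitude with one of the closed-set units, e.g. ``50 mg/dl``."""

    magnitude: float
    unit: str

    def __post_init__(self):
        check_unit(self.unit)

    def to(self, unit: str) -> "Quantity":
        return Quantity(convert(self.magnitude, self.unit, unit), unit)

    def __str__(self) -> str:
        return f"{self.magnitude:g},{self.unit}"
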