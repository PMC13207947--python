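"""Quantity parsing and harmonization of affinities/exposures to nanomolar.

Pharmacology sources report potencies and exposures in a mix of molar
(nM, µM, mM, M) and mass-per-volume (ng/mL, µg/mL, mg/L, g/L) units.
Everything downstream of ingest works in nM; mass-per-volume values are
converted through the compound's molecular weight:

    nM = (value in mg/L) / MW (g/mol) × 10^6

Conversions use exact decimal factors. Unrecognized units raise rather
than being skipped, so data errors surface during ingest.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

__all__ = [
    "Quantity",
    "UnitError",
    "ConversionError",
    "parse_quantity",
    "to_nanomolar",
    "aggregate_values",
    "MOLAR_UNITS",
    "MASS_PER_VOLUME_UNITS",
]


class UnitError(ValueError):
    """A quantity string could not be parsed into (value, unit)."""


class ConversionError(ValueError):
    """A unit conversion is impossible with the information given."""


# factor to nM for molar units
MOLAR_UNITS: dict[str, float] = {
    "nM": 1.0,
    "µM": 1e3,
    "mM": 1e6,
    "M": 1e9,
}

# factor to mg/L for mass-per-volume units
MASS_PER_VOLUME_UNITS: dict[str, float] = {
    "ng/mL": 1e-3,
    "µg/mL": 1.0,
    "mg/L": 1.0,
    "g/L": 1e3,
}

# Canonical spellings. Micro may arrive as U+00B5, U+03BC or plain "u".
_UNIT_ALIASES: dict[str, str] = {
    "nm": "nM",
    "um": "µM",
    "µm": "µM",
    "μm": "µM",
    "mm": "mM",
    "m": "M",
    "mol/l": "M",
    "ng/ml": "ng/mL",
    "ug/ml": "µg/mL",
    "µg/ml": "µg/mL",
    "μg/ml": "µg/mL",
    "mg/l": "mg/L",
    "g/l": "g/L",
}

_QUANTITY_RE = re.compile(
    r"^\s*([0-9]*\.?[0-9]+(?:[eE][+-]?[0-9]+)?)\s*([^\s]+)\s*$"
)


@dataclass(frozen=True)
class Quantity:
    """A positive measured value with a recognized concentration unit."""

    value: float
    unit: str

    def __post_init__(self) -> None:
        if not (self.value > 0 and math.isfinite(self.value)):
            raise ValueError(f"quantity value must be positive and finite, got {self.value}")
        if self.unit not in MOLAR_UNITS and self.unit not in MASS_PER_VOLUME_UNITS:
            raise UnitError(f"unrecognized unit {self.unit!r}")


def _canonical_unit(token: str) -> str:
    key = token.strip().lower()
    if key in _UNIT_ALIASES:
        return _UNIT_ALIASES[key]
    raise UnitError(f"unrecognized unit token {token!r}")


def parse_quantity(text: str) -> Quantity:
    """Parse a string like ``"129 µM"`` or ``"0.5 ug/mL"`` into a Quantity.

    Both the micro sign and an ASCII ``u`` prefix are accepted.

    Raises
    ------
    UnitError
        If the string has no numeric part or the unit token is unknown.
    """
    if not text or not text.strip():
        raise UnitError("empty quantity string")
    m = _QUANTITY_RE.match(text)
    if m is None:
        raise UnitError(f"cannot parse quantity string {text!r}")
    value = float(m.group(1))
    unit = _canonical_unit(m.group(2))
    return Quantity(value=value, unit=unit)


def to_nanomolar(q: Quantity, molecular_weight: float | None = None) -> float:
    """Convert a Quantity to nM.

    Molar units need no molecular weight. Mass-per-volume units require
    the molecular weight in g/mol; without it a :class:`ConversionError`
    is raised with the message "MW required".
    """
    if q.unit in MOLAR_UNITS:
        return q.value * MOLAR_UNITS[q.unit]
    mg_per_l = q.value * MASS_PER_VOLUME_UNITS[q.unit]
    if molecular_weight is None:
        raise ConversionError(f"MW required to convert {q.unit} to nM")
    if molecular_weight <= 0:
        raise ConversionError(f"molecular weight must be positive, got {molecular_weight}")
    return mg_per_l / molecular_weight * 1e6


def aggregate_values(values: list[float]) -> float | None:
    """Median of multiple harmonized values; ``None`` marks missing data.

    For even counts the arithmetic mean of the two central values is used.
    An empty list yields ``None`` rather than an exception, so absent
    literature data propagates as a missing-data marker.
    """
    if not values:
        return None
    if any(v <= 0 for v in values):
        raise ValueError("concentrations must be positive")
    ordered = sorted(values)
    n = len(ordered)
    mid = n // 2
    if n % 2 == 1:
        return ordered[mid]
    return 0.5 * (ordered[mid - 1] + ordered[mid])
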