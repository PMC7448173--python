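"""Dose-unit parsing and conversion for dose-error-factor computation.

Pump dose units are compound strings of the form ``base[/per-kg][/per-time]``,
e.g. ``mg``, ``mcg/kg/min``, ``units/h``, ``mL/h``.  Two doses are comparable
when their units share a dimension signature (same base quantity and same
denominator chain); the conversion factor then scales the base quantity.
Doses with missing units are treated as unitless and excluded from factor
computation rather than guessed.
"""

from __future__ import annotations

from typing import Optional

# base-unit factors to an arbitrary canonical unit per dimension
_BASE_UNITS: dict[str, tuple[str, float]] = {
    # mass -> grams
    "g": ("mass", 1.0),
    "mg": ("mass", 1e-3),
    "mcg": ("mass", 1e-6),
    "ug": ("mass", 1e-6),
    "µg": ("mass", 1e-6),
    "ng": ("mass", 1e-9),
    # volume -> litres
    "l": ("volume", 1.0),
    "ml": ("volume", 1e-3),
    # activity -> units
    "units": ("activity", 1.0),
    "unit": ("activity", 1.0),
    "iu": ("activity", 1.0),
    "milliunits": ("activity", 1e-3),
    "mu": ("activity", 1e-3),
    # molar -> moles
    "mmol": ("molar", 1e-3),
    "mol": ("molar", 1.0),
    "meq": ("molar", 1e-3),
}

# per-denominators: canonical token + factor (time to hours, weight to kg)
_DENOMS: dict[str, tuple[str, float]] = {
    "kg": ("kg", 1.0),
    "h": ("h", 1.0),
    "hr": ("h", 1.0),
    "hour": ("h", 1.0),
    "min": ("h", 60.0),  # per-minute = 60x per-hour rate
    "day": ("h", 1.0 / 24.0),
    "24h": ("h", 1.0 / 24.0),
    "m2": ("m2", 1.0),
    "m^2": ("m2", 1.0),
}


class UnitError(ValueError):
    """Unit string unparseable or dimensionally incompatible."""


def parse_unit(unit: str) -> tuple[tuple[str, ...], float]:
    """Return (dimension signature, factor to canonical units).

    The signature is a tuple ``(base_dimension, *denominators)``; the factor
    converts a value in ``unit`` to the canonical unit of that signature.
    """
    text = unit.strip().lower()
    if not text:
        raise UnitError("empty unit")
    parts = [p.strip() for p in text.split("/")]
    base = parts[0]
    if base not in _BASE_UNITS:
        raise UnitError(f"unknown base unit {parts[0]!r} in {unit!r}")
    dim, factor = _BASE_UNITS[base]
    denoms: list[str] = []
    for token in parts[1:]:
        if token not in _DENOMS:
            raise UnitError(f"unknown denominator {token!r} in {unit!r}")
        canon, dfac = _DENOMS[token]
        denoms.append(canon)
        factor *= dfac
    return (dim, *sorted(denoms)), factor


def convert(value: float, from_unit: str, to_unit: str) -> float:
    """Convert ``value`` between compatible units; UnitError if incompatible."""
    sig_a, fac_a = parse_unit(from_unit)
    sig_b, fac_b = parse_unit(to_unit)
    if sig_a != sig_b:
        raise UnitError(
            f"incompatible units {from_unit!r} ({sig_a}) vs {to_unit!r} ({sig_b})"
        )
    return value * fac_a / fac_b


def doses_equal(
    value_a: Optional[float],
    unit_a: str,
    value_b: Optional[float],
    unit_b: str,
    rel_tol: float = 1e-6,
) -> Optional[bool]:
    """Unit-normalised dose equality at relative tolerance; None if undecidable.

    Returns None when either value is absent or the units are missing or
    incompatible — callers must not infer a dose error from an undecidable
    comparison.
    """
    if value_a is None or value_b is None:
        return None
    if not unit_a.strip() or not unit_b.strip():
        return None
    try:
        b_in_a = convert(value_b, unit_b, unit_a)
    except UnitError:
        return None
    scale = max(abs(value_a), abs(b_in_a), 1e-300)
    return abs(value_a - b_in_a) <= rel_tol * scale
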