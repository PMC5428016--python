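"""Lightweight unit parsing for configuration input.

Internally everything is SI with concentrations in mol/m^3 (numerically
identical to mM) and cell densities in cells/m^3.  Configuration files and
CLI flags may carry values either as bare numbers (interpreted as already
being in the internal unit) or as strings with a unit suffix, e.g.
``"250 um"``, ``"1.02 g/cm3"``, ``"0.5 mL/min"``.

Only the units that actually occur in trap design work are supported; the
point is to make the common conversions (micrometres, g/cm^3, mL/min,
cm^2/s, hours) impossible to get wrong, not to be a general unit system.
"""

from __future__ import annotations

import re

__all__ = ["UnitError", "parse_quantity", "to_si"]


class UnitError(ValueError):
    """Raised for an unrecognized or dimensionally wrong unit string."""


# factor converting one of <unit> to the internal unit of its dimension
_FACTORS: dict[str, dict[str, float]] = {
    "length": {
        "m": 1.0, "cm": 1e-2, "mm": 1e-3, "um": 1e-6, "µm": 1e-6, "nm": 1e-9,
    },
    "time": {
        "s": 1.0, "min": 60.0, "h": 3600.0, "hr": 3600.0, "d": 86400.0,
    },
    "mass_density": {
        "kg/m3": 1.0, "kg/m^3": 1.0, "g/cm3": 1000.0, "g/cm^3": 1000.0,
        "g/ml": 1000.0, "g/l": 1.0,
    },
    "viscosity": {
        "pa.s": 1.0, "pa*s": 1.0, "pa s": 1.0, "pas": 1.0,
        "mpa.s": 1e-3, "mpa s": 1e-3, "cp": 1e-3,
    },
    "acceleration": {"m/s2": 1.0, "m/s^2": 1.0, "g0": 9.81},
    "stress": {"pa": 1.0, "kpa": 1e3, "mpa": 1e6, "dyn/cm2": 0.1},
    "flow": {
        "m3/s": 1.0, "m^3/s": 1.0,
        "ml/min": 1e-6 / 60.0, "ml/s": 1e-6, "ml/h": 1e-6 / 3600.0,
        "ul/min": 1e-9 / 60.0, "ul/s": 1e-9, "ul/h": 1e-9 / 3600.0,
    },
    "volume": {
        "m3": 1.0, "m^3": 1.0, "l": 1e-3, "ml": 1e-6, "ul": 1e-9,
        "µl": 1e-9, "nl": 1e-12,
    },
    "area": {"m2": 1.0, "m^2": 1.0, "cm2": 1e-4, "mm2": 1e-6, "um2": 1e-12},
    # internal concentration unit is mol/m^3 == mM
    "concentration": {
        "mol/m3": 1.0, "mol/m^3": 1.0, "mm": 1.0, "m": 1e3, "um": 1e-3,
        "mmol/l": 1.0, "mol/l": 1e3,
    },
    "diffusivity": {"m2/s": 1.0, "m^2/s": 1.0, "cm2/s": 1e-4, "cm^2/s": 1e-4},
    "uptake_rate": {
        "mol/(cell.s)": 1.0, "mol/(cell*s)": 1.0, "mol/cell/s": 1.0,
        "mol/(cell s)": 1.0, "mol/cells": 1.0,
    },
    "cell_density": {
        "cells/m3": 1.0, "1/m3": 1.0, "cells/ul": 1e9, "cell/ul": 1e9,
        "cells/µl": 1e9, "cells/ml": 1e6,
    },
    "dimensionless": {"": 1.0},
}

_QUANTITY_RE = re.compile(r"^\s*([-+0-9.eE]+)\s*(.*?)\s*$")


def to_si(value: float, unit: str, dimension: str) -> float:
    """Convert ``value`` expressed in ``unit`` to the internal unit."""
    try:
        table = _FACTORS[dimension]
    except KeyError:
        raise UnitError(f"unknown dimension {dimension!r}") from None
    key = unit.strip().lower().replace("·", ".").replace("μ", "µ")
    # normalize the two micro signs to plain ascii 'u'
    key = key.replace("µ", "u")
    if key not in table:
        raise UnitError(
            f"unit {unit!r} not recognized for dimension {dimension!r}; "
            f"known: {sorted(table)}"
        )
    return value * table[key]


def parse_quantity(raw: float | int | str, dimension: str) -> float:
    """Parse a number or a ``"<number> <unit>"`` string to the internal unit.

    Bare numbers are taken to already be in the internal unit of
    ``dimension`` (SI; mol/m^3 for concentrations, cells/m^3 for cell
    densities).
    """
    if isinstance(raw, (int, float)) and not isinstance(raw, bool):
        return float(raw)
    if not isinstance(raw, str):
        raise UnitError(f"cannot parse quantity from {type(raw).__name__}")
    m = _QUANTITY_RE.match(raw)
    if m is None:
        raise UnitError(f"malformed quantity string {raw!r}")
    num, unit = m.groups()
    try:
        value = float(num)
    except ValueError:
        raise UnitError(f"malformed number in {raw!r}") from None
    if unit == "":
        return value
    return to_si(value, unit, dimension)
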