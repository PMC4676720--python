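"""Small unit helpers: explicit-unit concentration and temperature parsing.

All internal concentrations are molar and all temperatures kelvin; I/O
accepts tagged strings such as ``"3mM"``, ``"16.4 uM"``, ``"20C"`` or
``"293.15K"``.
"""

from __future__ import annotations

import re

_CONC_FACTORS = {
    "M": 1.0,
    "mM": 1e-3,
    "uM": 1e-6,
    "µM": 1e-6,  # µM
    "μM": 1e-6,  # μM
    "nM": 1e-9,
}

_CONC_RE = re.compile(r"^\s*([-+0-9.eE]+)\s*([A-Za-zµμ]*)\s*$")


def to_molar(value: float | str, unit: str | None = None) -> float:
    """Convert a concentration to molar.

    ``value`` may be a bare number (then ``unit`` is required, or molar is
    assumed when ``unit`` is None) or a tagged string like ``"3mM"``.
    """
    if isinstance(value, str):
        m = _CONC_RE.match(value)
        if m is None:
            raise ValueError(f"cannot parse concentration {value!r}")
        number, tag = float(m.group(1)), m.group(2)
        if tag and unit:
            raise ValueError(f"unit given twice for {value!r}")
        unit = tag or unit
        value = number
    if unit in (None, ""):
        return float(value)
    try:
        return float(value) * _CONC_FACTORS[unit]
    except KeyError:
        raise ValueError(
            f"unknown concentration unit {unit!r}; expected one of "
            f"{sorted(_CONC_FACTORS)}"
        ) from None


def to_kelvin(value: float | str) -> float:
    """Convert a temperature to kelvin; accepts ``"20C"``, ``"293.15K"`` or a
    bare kelvin number."""
    if isinstance(value, str):
        m = _CONC_RE.match(value)
        if m is None:
            raise ValueError(f"cannot parse temperature {value!r}")
        number, tag = float(m.group(1)), m.group(2)
        if tag in ("K", ""):
            return number
        if tag == "C":
            return number + 273.15
        raise ValueError(f"unknown temperature unit {tag!r}")
    return float(value)
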