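"""Tiny unit parser for CLI length/density arguments with explicit tags."""

from __future__ import annotations

import re

from .errors import DomainError

_LENGTH_FACTORS_M = {
    "nm": 1e-9,
    "um": 1e-6,
    "µm": 1e-6,
    "mm": 1e-3,
    "cm": 1e-2,
    "m": 1.0,
}

_DENSITY_FACTORS = {
    "kg/m3": 1.0,
    "g/cm3": 1000.0,
    "g/ml": 1000.0,
}

_NUM = r"([+-]?\d+(?:\.\d*)?(?:[eE][+-]?\d+)?)"


def parse_length_m(text: str) -> float:
    """'1.3mm' -> 0.0013; bare numbers are rejected (unit tag required)."""
    m = re.fullmatch(_NUM + r"\s*([a-zµ]+)", str(text).strip())
    if not m or m.group(2).lower() not in _LENGTH_FACTORS_M:
        raise DomainError(
            f"cannot parse length {text!r}; use e.g. 100um, 1.3mm, 5e-4m"
        )
    return float(m.group(1)) * _LENGTH_FACTORS_M[m.group(2).lower()]


def parse_length_um(text: str) -> float:
    return parse_length_m(text) * 1e6


def parse_density_kg_m3(text: str) -> float:
    """'3.184g/cm3' -> 3184.0; bare numbers are treated as kg/m^3."""
    s = str(text).strip().lower().replace(" ", "")
    m = re.fullmatch(_NUM, s)
    if m:
        return float(m.group(1))
    m = re.fullmatch(_NUM + r"([a-z/0-9]+)", s)
    if not m or m.group(2) not in _DENSITY_FACTORS:
        raise DomainError(f"cannot parse density {text!r}; use e.g. 3.184g/cm3")
    return float(m.group(1)) * _DENSITY_FACTORS[m.group(2)]
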