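"""Bundled element -> van der Waals radius table (Bondi-type values, angstrom).

Applied uniformly to every structure the package reads; individual entries
can be overridden through the ``radii`` mapping accepted by the readers.
"""

from __future__ import annotations

__all__ = ["VDW_RADII", "DEFAULT_RADIUS", "vdw_radius"]

VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "He": 1.40,
    "B": 1.92,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "Na": 2.27,
    "Mg": 1.73,
    "Si": 2.10,
    "P": 1.80,
    "S": 1.80,
    "Cl": 1.75,
    "K": 2.75,
    "Br": 1.85,
    "I": 1.98,
}

#: Fallback for elements absent from the table (carbon-like).
DEFAULT_RADIUS = 1.70


def vdw_radius(symbol: str, overrides: dict[str, float] | None = None) -> float:
    """Radius for an element symbol, honouring user overrides."""
    if overrides and symbol in overrides:
        return float(overrides[symbol])
    return VDW_RADII.get(symbol, DEFAULT_RADIUS)
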