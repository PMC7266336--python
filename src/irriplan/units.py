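"""Unit registry and conversions between U.S. field units and SI.

Irrigation practice in the U.S. Great Plains quotes areas in acres, water
depths in inches, farm water volumes in acre-inches, yields in bushels per
acre and water prices in dollars per acre-inch.  The planning models in this
package work internally in SI (m², m, m³, kg, $); field units appear only at
the I/O boundary.  All conversions are exact linear rescalings built from the
international definitions of the inch, the acre and the 56-lb corn bushel.
"""

from __future__ import annotations

# Exact defining constants
INCH_M = 0.0254                      # m per inch (international inch)
ACRE_M2 = 4046.8564224               # m² per acre (international acre)
ACRE_INCH_M3 = ACRE_M2 * INCH_M      # 102.790153... m³ per acre-inch
LB_KG = 0.45359237                   # kg per avoirdupois pound
BUSHEL_CORN_KG = 56.0 * LB_KG        # 25.4011727 kg per bushel of shelled corn

#: unit name -> (dimension, factor to the canonical SI unit of that dimension)
_REGISTRY: dict[str, tuple[str, float]] = {
    # area (canonical m²)
    "m2": ("area", 1.0),
    "acre": ("area", ACRE_M2),
    # depth (canonical m)
    "m": ("depth", 1.0),
    "mm": ("depth", 1e-3),
    "cm": ("depth", 1e-2),
    "inch": ("depth", INCH_M),
    # volume (canonical m³)
    "m3": ("volume", 1.0),
    "acre_inch": ("volume", ACRE_INCH_M3),
    # areal yield (canonical kg/m²)
    "kg_per_m2": ("areal_yield", 1.0),
    "bushel_per_acre": ("areal_yield", BUSHEL_CORN_KG / ACRE_M2),
    # volumetric water price (canonical $/m³)
    "usd_per_m3": ("water_price", 1.0),
    "usd_per_acre_inch": ("water_price", 1.0 / ACRE_INCH_M3),
    # crop price (canonical $/kg)
    "usd_per_kg": ("crop_price", 1.0),
    "usd_per_bushel": ("crop_price", 1.0 / BUSHEL_CORN_KG),
    # areal cost (canonical $/m²)
    "usd_per_m2": ("areal_cost", 1.0),
    "usd_per_acre": ("areal_cost", 1.0 / ACRE_M2),
    # mass (canonical kg)
    "kg": ("mass", 1.0),
    "bushel": ("mass", BUSHEL_CORN_KG),
    # currency (identity; lets config files declare '$' explicitly)
    "usd": ("currency", 1.0),
}


class UnitError(ValueError):
    """Raised for unknown units or a conversion across dimensions."""


def convert(value: float, from_unit: str, to_unit: str) -> float:
    """Convert ``value`` between two units of the same physical dimension.

    Conversion is an exact linear rescaling, so round trips are identities to
    floating-point precision.

    >>> round(convert(12.0, "usd_per_acre_inch", "usd_per_m3"), 4)
    0.1167
    """
    try:
        dim_f, fac_f = _REGISTRY[from_unit]
    except KeyError:
        raise UnitError(f"unknown unit {from_unit!r}") from None
    try:
        dim_t, fac_t = _REGISTRY[to_unit]
    except KeyError:
        raise UnitError(f"unknown unit {to_unit!r}") from None
    if dim_f != dim_t:
        raise UnitError(
            f"cannot convert {from_unit!r} ({dim_f}) to {to_unit!r} ({dim_t})"
        )
    return value * fac_f / fac_t


def known_units() -> list[str]:
    """Names accepted by :func:`convert`."""
    return sorted(_REGISTRY)
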