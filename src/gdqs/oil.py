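"""Liquid-oils category inference.

Respondents cannot reliably recall oil amounts, so the liquid-oils group is
never assessed with cubes.  Its category is inferred from three interview
signals: deep-frying at home with pourable oil, the number of mixed dishes
consumed, and whether oil was poured on food or used in preparation.
"""

from __future__ import annotations

from .taxonomy import QuantityCategory

__all__ = ["infer_oil_category", "OilInferenceError"]


class OilInferenceError(ValueError):
    pass


def infer_oil_category(
    home_deep_fried_pourable_oil: bool,
    mixed_dish_count: int,
    poured_or_used_oil: bool,
) -> QuantityCategory:
    """Infer the liquid-oils consumption band.

    ``HIGH`` if any trigger fires: deep-fried at home with pourable oil,
    two or more mixed dishes, or oil poured/used in preparation.  With
    exactly one mixed dish and no trigger, ``MIDDLE``.  Otherwise ``LOW``
    (no trigger, no mixed dish).
    """
    if mixed_dish_count < 0:
        raise OilInferenceError(
            f"mixed_dish_count must be non-negative, got {mixed_dish_count}"
        )
    if home_deep_fried_pourable_oil or mixed_dish_count >= 2 or poured_or_used_oil:
        return QuantityCategory.HIGH
    if mixed_dish_count == 1:
        return QuantityCategory.MIDDLE
    return QuantityCategory.LOW
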