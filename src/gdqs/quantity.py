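"""Cube selections -> quantity categories and gram point estimates.

A respondent visualizes the combined volume consumed per food group and
picks the closest cube.  Categorization compares the picked cube against the
group's boundary cubes; when the pick lands exactly on a boundary cube, a
confirmation answer ("as big or bigger" vs "smaller") decides which side of
the cutoff applies.  Gram point estimates multiply the group's mean density
by the selected cube's volume.

The two high-fat dairy subgroups (hard cheese / other) are collected
separately but reported as one group: cheese grams are converted to milk
equivalents (x 6.1) and added to the other-dairy grams, and the merged total
is categorized against the merged group's original gram cutoffs
(35 / 140 / 734 g).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .taxonomy import (
    CHEESE_TO_MILK_EQUIVALENT,
    HIGH_FAT_DAIRY,
    HIGH_FAT_DAIRY_CHEESE,
    HIGH_FAT_DAIRY_OTHER,
    AssessmentMode,
    QuantityCategory,
    TaxonomyConfig,
)

__all__ = [
    "BorderlineAnswer",
    "CubeSelection",
    "GroupQuantity",
    "QuantityError",
    "categorize_from_cube",
    "categorize_grams",
    "estimate_grams",
    "merge_high_fat_dairy",
]

#: original gram cutoffs of the merged (reporting) high-fat dairy group
MERGED_DAIRY_CUTOFFS_G = (35.0, 140.0, 734.0)


class QuantityError(ValueError):
    pass


class BorderlineAnswer(str, enum.Enum):
    """Confirmation answer when the picked cube sits exactly on a cutoff."""

    BIGGER_OR_EQUAL = "bigger_or_equal"
    SMALLER = "smaller"
    NOT_APPLICABLE = "not_applicable"


@dataclass(frozen=True)
class CubeSelection:
    group_id: str
    cube_index: int
    borderline_answer: BorderlineAnswer = BorderlineAnswer.NOT_APPLICABLE


@dataclass(frozen=True)
class GroupQuantity:
    """Per-reporting-group outcome: category plus a gram point estimate."""

    group_id: str
    category: QuantityCategory
    grams_estimate: float


def _require_cube_assessed(taxonomy: TaxonomyConfig, group_id: str) -> None:
    group = taxonomy.group(group_id)
    if group.assessment_mode is not AssessmentMode.CUBE:
        raise QuantityError(
            f"group {group_id!r} is not cube-assessed; its category is set by "
            "the oil-inference algorithm"
        )


def _validate_selection(taxonomy: TaxonomyConfig, selection: CubeSelection) -> None:
    _require_cube_assessed(taxonomy, selection.group_id)
    taxonomy.cube(selection.cube_index)
    on_boundary = selection.cube_index in taxonomy.boundary_cubes(selection.group_id)
    if on_boundary and selection.borderline_answer is BorderlineAnswer.NOT_APPLICABLE:
        raise QuantityError(
            f"{selection.group_id}: cube {selection.cube_index} sits exactly on "
            "a cutoff; a borderline confirmation answer is required"
        )
    if not on_boundary and selection.borderline_answer is not BorderlineAnswer.NOT_APPLICABLE:
        raise QuantityError(
            f"{selection.group_id}: cube {selection.cube_index} is not a "
            "boundary cube; borderline answer must be not_applicable"
        )


def categorize_from_cube(
    taxonomy: TaxonomyConfig, selection: CubeSelection
) -> QuantityCategory:
    """Map a cube selection to the group's quantity category.

    Cubes strictly below the first boundary cube give LOW; between boundary
    cubes MIDDLE; above the last boundary HIGH (VERY_HIGH above the third
    boundary of the dairy subgroups).  On a boundary cube the borderline
    answer resolves upward (bigger_or_equal) or downward (smaller).
    """
    _validate_selection(taxonomy, selection)
    boundary_cubes = taxonomy.boundary_cubes(selection.group_id)
    # category index = number of boundaries the selection clears
    cleared = 0
    for cube_index in sorted(boundary_cubes):
        if selection.cube_index > cube_index:
            cleared += 1
        elif selection.cube_index == cube_index:
            if selection.borderline_answer is BorderlineAnswer.BIGGER_OR_EQUAL:
                cleared += 1
    return QuantityCategory(cleared)


def estimate_grams(taxonomy: TaxonomyConfig, selection: CubeSelection | None) -> float:
    """Gram point estimate: mean group density x selected cube volume.

    ``None`` (group not reported) estimates 0 g.
    """
    if selection is None:
        return 0.0
    _require_cube_assessed(taxonomy, selection.group_id)
    density = taxonomy.density(selection.group_id).mean_density_g_per_cm3
    return density * taxonomy.cube(selection.cube_index).volume_cm3


def categorize_grams(
    taxonomy: TaxonomyConfig,
    group_id: str,
    grams: float,
    scale: str = "operationalized",
) -> QuantityCategory:
    """Categorize a gram amount against a group's cutoffs.

    ``scale`` picks the operationalized or the original gram cutoffs.
    Amounts exactly on a cutoff fall in the upper category ("equal to or
    above" the cutoff).
    """
    _require_cube_assessed(taxonomy, group_id)
    if grams < 0:
        raise QuantityError(f"{group_id}: negative gram amount {grams}")
    if scale not in ("operationalized", "original"):
        raise QuantityError(f"unknown cutoff scale {scale!r}")
    cleared = 0
    for b in taxonomy.boundaries_for(group_id):
        cutoff = b.operationalized_g if scale == "operationalized" else b.original_g
        if grams >= cutoff:
            cleared += 1
    return QuantityCategory(cleared)


def _categorize_merged_dairy_grams(grams: float) -> QuantityCategory:
    cleared = sum(grams >= c for c in MERGED_DAIRY_CUTOFFS_G)
    return QuantityCategory(cleared)


def merge_high_fat_dairy(
    taxonomy: TaxonomyConfig,
    cheese_selection: CubeSelection | None = None,
    other_dairy_selection: CubeSelection | None = None,
) -> GroupQuantity:
    """Merge the hard-cheese and other-dairy selections into one reporting
    quantity.

    Merged grams = 6.1 x cheese grams (milk equivalents) + other-dairy
    grams; the merged amount is categorized against the merged group's
    original cutoffs (35 / 140 / 734 g).
    """
    if cheese_selection is not None and cheese_selection.group_id != HIGH_FAT_DAIRY_CHEESE:
        raise QuantityError(
            f"cheese selection must target {HIGH_FAT_DAIRY_CHEESE!r}, "
            f"got {cheese_selection.group_id!r}"
        )
    if (
        other_dairy_selection is not None
        and other_dairy_selection.group_id != HIGH_FAT_DAIRY_OTHER
    ):
        raise QuantityError(
            f"other-dairy selection must target {HIGH_FAT_DAIRY_OTHER!r}, "
            f"got {other_dairy_selection.group_id!r}"
        )
    for sel in (cheese_selection, other_dairy_selection):
        if sel is not None:
            _validate_selection(taxonomy, sel)
    merged = CHEESE_TO_MILK_EQUIVALENT * estimate_grams(
        taxonomy, cheese_selection
    ) + estimate_grams(taxonomy, other_dairy_selection)
    return GroupQuantity(
        group_id=HIGH_FAT_DAIRY,
        category=_categorize_merged_dairy_grams(merged),
        grams_estimate=merged,
    )
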