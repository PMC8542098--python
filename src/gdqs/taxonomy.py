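"""Food-group taxonomy, cube set, cutoff tables and mean densities.

The GDQS instrument categorizes the quantity consumed per food group into
broad bands (low / middle / high, plus very-high for high-fat dairy) using a
shared set of 10 visual-aid cubes.  At collection time the high-fat dairy
group is split into "hard cheese" and "other", so the taxonomy temporarily
has 26 groups carrying 54 category boundaries; for reporting the two dairy
subgroups merge back into one group, giving 25 groups and 51 boundaries.

The shipped default configuration transcribes the published cutoff table
(original and operationalized gram cutoffs, cube assignments, nominal cube
side lengths) and the published mean food-group densities with their
representative food lists.  Gram cutoffs are authoritative; cube sides are
nominal visual-aid dimensions.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "QuantityCategory",
    "AssessmentMode",
    "BOUNDARY_LEVELS",
    "Cube",
    "FoodGroup",
    "CutoffBoundary",
    "DensityEntry",
    "TaxonomyConfig",
    "TaxonomyError",
    "load_taxonomy",
    "cutoff_consistency_report",
]

#: cheese grams -> milk-equivalent grams conversion factor for the dairy merge
CHEESE_TO_MILK_EQUIVALENT = 6.1

#: reporting id of the merged high-fat dairy group
HIGH_FAT_DAIRY = "high_fat_dairy"
HIGH_FAT_DAIRY_CHEESE = "high_fat_dairy_cheese"
HIGH_FAT_DAIRY_OTHER = "high_fat_dairy_other"
LIQUID_OILS = "liquid_oils"
PURCHASED_DEEP_FRIED = "purchased_deep_fried_foods"
SWEETS = "sweets_ice_cream"


class TaxonomyError(ValueError):
    """Configuration failed validation; message names the offending element."""


class AssessmentMode(str, enum.Enum):
    CUBE = "cube"
    OIL_ALGORITHM = "oil_algorithm"


class QuantityCategory(enum.IntEnum):
    """Ordered consumption band. ``VERY_HIGH`` exists only for high-fat dairy."""

    LOW = 0
    MIDDLE = 1
    HIGH = 2
    VERY_HIGH = 3

    def __str__(self) -> str:  # stable lowercase wire format
        return self.name.lower()

    @classmethod
    def from_str(cls, s: str) -> "QuantityCategory":
        return cls[s.upper()]


BOUNDARY_LEVELS = ("low_middle", "middle_high", "high_very_high")


@dataclass(frozen=True)
class Cube:
    """A hollow visual-aid cube of nominal side length ``side_mm``."""

    index: int
    side_mm: float

    @property
    def volume_cm3(self) -> float:
        return (self.side_mm / 10.0) ** 3


@dataclass(frozen=True)
class FoodGroup:
    group_id: str
    name: str
    assessment_mode: AssessmentMode
    reporting_group_id: str
    collection_time: bool = True


@dataclass(frozen=True)
class CutoffBoundary:
    """One category boundary of one collection-time group.

    Liquid oils has purely categorical boundaries: no grams, no cube (its
    category is set by the oil-inference algorithm, never by a cube).
    """

    group_id: str
    boundary: str  # one of BOUNDARY_LEVELS
    cube_index: int | None
    original_g: float | None
    operationalized_g: float | None


@dataclass(frozen=True)
class DensityEntry:
    group_id: str
    mean_density_g_per_cm3: float
    representative_foods: tuple[str, ...]


@dataclass
class TaxonomyConfig:
    """Validated taxonomy: groups, cubes, boundaries and densities."""

    groups: dict[str, FoodGroup]
    cubes: dict[int, Cube]
    boundaries: list[CutoffBoundary]
    densities: dict[str, DensityEntry]

    # -- lookups ---------------------------------------------------------
    def group(self, group_id: str) -> FoodGroup:
        try:
            return self.groups[group_id]
        except KeyError:
            raise TaxonomyError(f"unknown food group {group_id!r}") from None

    def cube(self, index: int) -> Cube:
        try:
            return self.cubes[index]
        except KeyError:
            raise TaxonomyError(f"unknown cube index {index!r}") from None

    def density(self, group_id: str) -> DensityEntry:
        try:
            return self.densities[group_id]
        except KeyError:
            raise TaxonomyError(
                f"no mean density configured for group {group_id!r}"
            ) from None

    def boundaries_for(self, group_id: str) -> list[CutoffBoundary]:
        order = {lvl: i for i, lvl in enumerate(BOUNDARY_LEVELS)}
        bs = [b for b in self.boundaries if b.group_id == group_id]
        return sorted(bs, key=lambda b: order[b.boundary])

    def boundary_cubes(self, group_id: str) -> dict[int, CutoffBoundary]:
        """Map cube index -> boundary, for the cubes that sit exactly on a cutoff."""
        return {
            b.cube_index: b
            for b in self.boundaries_for(group_id)
            if b.cube_index is not None
        }

    def cube_assessed_groups(self) -> list[FoodGroup]:
        return [
            g for g in self.groups.values() if g.assessment_mode is AssessmentMode.CUBE
        ]

    def reporting_group_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.groups.values():
            seen.setdefault(g.reporting_group_id, None)
        return list(seen)

    def reporting_boundary_count(self) -> int:
        """Boundary count after the dairy merge (the two subgroups' 3+3
        boundaries collapse to the merged group's 3)."""
        n = len(self.boundaries)
        dairy = [
            b
            for b in self.boundaries
            if b.group_id in (HIGH_FAT_DAIRY_CHEESE, HIGH_FAT_DAIRY_OTHER)
        ]
        return n - len(dairy) + 3

    def valid_categories(self, reporting_group_id: str) -> tuple[QuantityCategory, ...]:
        if reporting_group_id == HIGH_FAT_DAIRY:
            return (
                QuantityCategory.LOW,
                QuantityCategory.MIDDLE,
                QuantityCategory.HIGH,
                QuantityCategory.VERY_HIGH,
            )
        return (QuantityCategory.LOW, QuantityCategory.MIDDLE, QuantityCategory.HIGH)

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        collection = [g for g in self.groups.values() if g.collection_time]
        if len(collection) != 26:
            raise TaxonomyError(
                f"expected 26 collection-time groups, found {len(collection)}"
            )
        if len(set(self.reporting_group_ids())) != 25:
            raise TaxonomyError(
                f"expected 25 reporting groups, found {len(set(self.reporting_group_ids()))}"
            )
        oil = [
            g
            for g in self.groups.values()
            if g.assessment_mode is AssessmentMode.OIL_ALGORITHM
        ]
        if len(oil) != 1 or oil[0].group_id != LIQUID_OILS:
            raise TaxonomyError(
                "exactly one group must use the oil-inference algorithm (liquid oils)"
            )

        if sorted(self.cubes) != list(range(1, 11)):
            raise TaxonomyError("cube indices must be exactly 1..10")
        sides = [self.cubes[i].side_mm for i in range(1, 11)]
        if any(a >= b for a, b in zip(sides, sides[1:])):
            raise TaxonomyError("cube side lengths must strictly increase with index")

        if len(self.boundaries) != 54:
            raise TaxonomyError(
                f"expected 54 collection-time boundaries, found {len(self.boundaries)}"
            )
        if self.reporting_boundary_count() != 51:
            raise TaxonomyError(
                f"expected 51 reporting boundaries, found {self.reporting_boundary_count()}"
            )

        for b in self.boundaries:
            if b.group_id not in self.groups:
                raise TaxonomyError(f"boundary references unknown group {b.group_id!r}")
            if b.boundary not in BOUNDARY_LEVELS:
                raise TaxonomyError(
                    f"{b.group_id}: unknown boundary level {b.boundary!r}"
                )
            if b.cube_index is not None and b.cube_index not in self.cubes:
                raise TaxonomyError(
                    f"{b.group_id}/{b.boundary}: unknown cube index {b.cube_index}"
                )

        for g in self.groups.values():
            bs = self.boundaries_for(g.group_id)
            levels = [b.boundary for b in bs]
            if g.assessment_mode is AssessmentMode.OIL_ALGORITHM:
                if levels != ["low_middle", "middle_high"]:
                    raise TaxonomyError(
                        f"{g.group_id}: oil-inferred group must have exactly "
                        "low_middle and middle_high categorical boundaries"
                    )
                if any(
                    b.cube_index is not None or b.operationalized_g is not None
                    for b in bs
                ):
                    raise TaxonomyError(
                        f"{g.group_id}: oil-inferred boundaries carry no cube or grams"
                    )
                continue
            expected = (
                ["low_middle", "middle_high", "high_very_high"]
                if g.group_id in (HIGH_FAT_DAIRY_CHEESE, HIGH_FAT_DAIRY_OTHER)
                else ["low_middle", "middle_high"]
            )
            if levels != expected:
                raise TaxonomyError(
                    f"{g.group_id}: expected boundaries {expected}, found {levels}"
                )
            for b in bs:
                if b.cube_index is None or b.operationalized_g is None:
                    raise TaxonomyError(
                        f"{g.group_id}/{b.boundary}: cube-assessed boundary "
                        "requires a cube index and operationalized grams"
                    )
                if b.operationalized_g <= 0:
                    raise TaxonomyError(
                        f"{g.group_id}/{b.boundary}: grams must be positive"
                    )
            ops = [b.operationalized_g for b in bs]
            if any(a >= c for a, c in zip(ops, ops[1:])):
                raise TaxonomyError(
                    f"{g.group_id}: operationalized grams must strictly increase "
                    f"across boundaries (got {ops})"
                )
            idxs = [b.cube_index for b in bs]
            if any(a > c for a, c in zip(idxs, idxs[1:])):
                raise TaxonomyError(
                    f"{g.group_id}: cube indices must weakly increase across "
                    f"boundaries (got {idxs})"
                )

        for gid, d in self.densities.items():
            if gid not in self.groups:
                raise TaxonomyError(f"density entry references unknown group {gid!r}")
            if self.groups[gid].assessment_mode is not AssessmentMode.CUBE:
                raise TaxonomyError(
                    f"{gid}: density entries only apply to cube-assessed groups"
                )
            if not (d.mean_density_g_per_cm3 > 0):
                raise TaxonomyError(f"{gid}: mean density must be positive")
        missing = [
            g.group_id
            for g in self.cube_assessed_groups()
            if g.group_id not in self.densities
        ]
        if missing:
            raise TaxonomyError(f"missing mean density for groups: {missing}")

    # -- serialization ---------------------------------------------------
    def save(self, directory: str | Path) -> None:
        """Write the four configuration CSVs (groups, cubes, cutoffs, densities)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            [
                {
                    "group_id": g.group_id,
                    "name": g.name,
                    "assessment_mode": g.assessment_mode.value,
                    "reporting_group_id": g.reporting_group_id,
                }
                for g in self.groups.values()
            ]
        ).to_csv(directory / "groups.csv", index=False)
        pd.DataFrame(
            [{"index": c.index, "side_mm": c.side_mm} for c in self.cubes.values()]
        ).to_csv(directory / "cubes.csv", index=False)
        pd.DataFrame(
            [
                {
                    "group_id": b.group_id,
                    "boundary": b.boundary,
                    "cube_index": b.cube_index,
                    "original_g": b.original_g,
                    "operationalized_g": b.operationalized_g,
                }
                for b in self.boundaries
            ]
        ).to_csv(directory / "cutoffs.csv", index=False)
        pd.DataFrame(
            [
                {
                    "group_id": d.group_id,
                    "mean_density_g_per_cm3": d.mean_density_g_per_cm3,
                    "representative_foods": "|".join(d.representative_foods),
                }
                for d in self.densities.values()
            ]
        ).to_csv(directory / "densities.csv", index=False)


def _read_config_frames(source: str | Path | None):
    if source is None:
        base = resources.files("gdqs.data")
        read = lambda name: pd.read_csv(base / name)  # noqa: E731
    else:
        base = Path(source)
        if not base.is_dir():
            raise TaxonomyError(f"config directory not found: {base}")
        read = lambda name: pd.read_csv(base / name)  # noqa: E731
    return (
        read("groups.csv"),
        read("cubes.csv"),
        read("cutoffs.csv"),
        read("densities.csv"),
    )


def load_taxonomy(source: str | Path | None = None) -> TaxonomyConfig:
    """Load and validate a taxonomy configuration.

    Parameters
    ----------
    source:
        Directory holding ``groups.csv``, ``cubes.csv``, ``cutoffs.csv`` and
        ``densities.csv``.  ``None`` loads the shipped default configuration
        (the published cutoff and density tables).

    Raises
    ------
    TaxonomyError
        If the configuration is malformed or violates any structural
        invariant (group/boundary counts, monotonic cutoffs, cube references).
    """
    groups_df, cubes_df, cutoffs_df, dens_df = _read_config_frames(source)

    groups: dict[str, FoodGroup] = {}
    for row in groups_df.itertuples(index=False):
        if row.group_id in groups:
            raise TaxonomyError(f"duplicate group id {row.group_id!r}")
        try:
            mode = AssessmentMode(row.assessment_mode)
        except ValueError:
            raise TaxonomyError(
                f"{row.group_id}: unknown assessment_mode {row.assessment_mode!r}"
            ) from None
        groups[row.group_id] = FoodGroup(
            group_id=row.group_id,
            name=str(row.name),
            assessment_mode=mode,
            reporting_group_id=row.reporting_group_id,
        )

    cubes: dict[int, Cube] = {}
    for row in cubes_df.itertuples(index=False):
        idx = int(row.index)
        if idx in cubes:
            raise TaxonomyError(f"duplicate cube index {idx}")
        cubes[idx] = Cube(index=idx, side_mm=float(row.side_mm))

    boundaries: list[CutoffBoundary] = []
    for row in cutoffs_df.itertuples(index=False):
        boundaries.append(
            CutoffBoundary(
                group_id=row.group_id,
                boundary=row.boundary,
                cube_index=None if pd.isna(row.cube_index) else int(row.cube_index),
                original_g=None if pd.isna(row.original_g) else float(row.original_g),
                operationalized_g=(
                    None
                    if pd.isna(row.operationalized_g)
                    else float(row.operationalized_g)
                ),
            )
        )

    densities: dict[str, DensityEntry] = {}
    for row in dens_df.itertuples(index=False):
        foods = tuple(
            f for f in str(row.representative_foods).split("|") if f
        )
        densities[row.group_id] = DensityEntry(
            group_id=row.group_id,
            mean_density_g_per_cm3=float(row.mean_density_g_per_cm3),
            representative_foods=foods,
        )

    taxonomy = TaxonomyConfig(
        groups=groups, cubes=cubes, boundaries=boundaries, densities=densities
    )
    taxonomy.validate()
    return taxonomy


def cutoff_consistency_report(taxonomy: TaxonomyConfig) -> pd.DataFrame:
    """Audit how closely each operationalized gram cutoff matches its cube.

    By design each boundary cube should represent its gram cutoff exactly
    through ``grams = mean_density x cube_volume``; printed cube sides are
    rounded, so small relative deviations are expected.  Returns one row per
    cube-assessed boundary with the predicted grams and the relative
    deviation ``|operationalized - predicted| / operationalized``.
    """
    rows = []
    for b in taxonomy.boundaries:
        group = taxonomy.group(b.group_id)
        if group.assessment_mode is not AssessmentMode.CUBE:
            continue
        dens = taxonomy.density(b.group_id).mean_density_g_per_cm3
        vol = taxonomy.cube(b.cube_index).volume_cm3
        predicted = dens * vol
        rows.append(
            {
                "group_id": b.group_id,
                "boundary": b.boundary,
                "cube_index": b.cube_index,
                "cube_side_mm": taxonomy.cube(b.cube_index).side_mm,
                "mean_density_g_per_cm3": dens,
                "operationalized_g": b.operationalized_g,
                "predicted_g": predicted,
                "rel_deviation": abs(b.operationalized_g - predicted)
                / b.operationalized_g,
            }
        )
    return pd.DataFrame(rows)
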