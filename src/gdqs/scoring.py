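"""Point tables and score tabulation.

The metric assigns point values per reporting group based on the quantity
category.  Numeric point values are configuration, not code: a validated
table maps each of the 25 reporting groups and each of its valid categories
to points, and tags each group with a role (healthy, unhealthy, or
unhealthy-in-excess).  The total score is the sum over all groups; the
positive submetric sums the healthy groups, the negative submetric the
unhealthy and unhealthy-in-excess groups.

The table shipped at ``gdqs/data/example_points.csv`` carries EXAMPLE point
values for demonstrations and tests; it is not the published point table.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .taxonomy import (
    HIGH_FAT_DAIRY,
    LIQUID_OILS,
    QuantityCategory,
    TaxonomyConfig,
    load_taxonomy,
)
from .quantity import GroupQuantity

__all__ = [
    "GroupRole",
    "PointTable",
    "GDQSResult",
    "ScoringError",
    "load_point_table",
    "example_point_table",
    "score_session",
]


class ScoringError(ValueError):
    pass


class GroupRole(str, enum.Enum):
    HEALTHY = "healthy"
    UNHEALTHY = "unhealthy"
    UNHEALTHY_IN_EXCESS = "unhealthy_in_excess"


@dataclass(frozen=True)
class PointTable:
    """Points per (reporting group, category) plus the group roles."""

    points: dict[str, dict[QuantityCategory, float]]
    roles: dict[str, GroupRole]

    def score(self, group_id: str, category: QuantityCategory) -> float:
        if group_id not in self.points:
            raise ScoringError(f"group {group_id!r} missing from point table")
        try:
            return self.points[group_id][category]
        except KeyError:
            raise ScoringError(
                f"group {group_id!r}: no point value for category {category}"
            ) from None


@dataclass(frozen=True)
class GDQSResult:
    total: float
    submetric_plus: float
    submetric_minus: float
    per_group: dict[str, tuple[QuantityCategory, float]]

    def to_dict(self) -> dict:
        return {
            "total": self.total,
            "submetric_plus": self.submetric_plus,
            "submetric_minus": self.submetric_minus,
            "per_group": {
                g: {"category": str(cat), "points": pts}
                for g, (cat, pts) in self.per_group.items()
            },
        }


def _validate_point_table(table: PointTable, taxonomy: TaxonomyConfig) -> None:
    expected = set(taxonomy.reporting_group_ids())
    missing = expected - set(table.points)
    if missing:
        raise ScoringError(f"point table missing reporting groups: {sorted(missing)}")
    for gid in expected:
        if gid not in table.roles:
            raise ScoringError(f"point table missing role for group {gid!r}")
        for cat in taxonomy.valid_categories(gid):
            if cat not in table.points[gid]:
                raise ScoringError(
                    f"group {gid!r}: no point value for category {cat}"
                )
        if QuantityCategory.VERY_HIGH in table.points[gid] and gid != HIGH_FAT_DAIRY:
            raise ScoringError(
                f"group {gid!r}: very_high is only valid for high-fat dairy"
            )


def load_point_table(
    source: str | Path | pd.DataFrame, taxonomy: TaxonomyConfig | None = None
) -> PointTable:
    """Load a point table CSV with columns
    ``group_id, role, low, middle, high, very_high``."""
    taxonomy = taxonomy or load_taxonomy()
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    missing = {"group_id", "role", "low", "middle", "high"} - set(df.columns)
    if missing:
        raise ScoringError(f"point table missing columns: {sorted(missing)}")
    points: dict[str, dict[QuantityCategory, float]] = {}
    roles: dict[str, GroupRole] = {}
    for row in df.to_dict("records"):
        gid = str(row["group_id"]).strip()
        try:
            roles[gid] = GroupRole(str(row["role"]).strip())
        except ValueError:
            raise ScoringError(
                f"group {gid!r}: unknown role {row['role']!r}"
            ) from None
        pts = {
            QuantityCategory.LOW: float(row["low"]),
            QuantityCategory.MIDDLE: float(row["middle"]),
            QuantityCategory.HIGH: float(row["high"]),
        }
        vh = row.get("very_high")
        if vh is not None and pd.notna(vh) and str(vh).strip() != "":
            pts[QuantityCategory.VERY_HIGH] = float(vh)
        points[gid] = pts
    table = PointTable(points=points, roles=roles)
    _validate_point_table(table, taxonomy)
    return table


def example_point_table(taxonomy: TaxonomyConfig | None = None) -> PointTable:
    """The shipped example table (toy values, for demos and tests)."""
    with resources.as_file(
        resources.files("gdqs.data") / "example_points.csv"
    ) as path:
        return load_point_table(path, taxonomy)


def score_session(
    quantities: dict[str, GroupQuantity],
    oil_category: QuantityCategory,
    point_table: PointTable,
    taxonomy: TaxonomyConfig | None = None,
) -> GDQSResult:
    """Tabulate the score from per-reporting-group quantities.

    ``quantities`` is keyed by reporting group id (dairy already merged);
    groups absent from it are scored at category LOW.  The liquid-oils
    category comes from ``oil_category`` (the inference algorithm), never
    from ``quantities``.
    """
    taxonomy = taxonomy or load_taxonomy()
    _validate_point_table(point_table, taxonomy)
    reporting = taxonomy.reporting_group_ids()
    unknown = set(quantities) - set(reporting)
    if unknown:
        raise ScoringError(f"quantities reference unknown reporting groups: {sorted(unknown)}")

    per_group: dict[str, tuple[QuantityCategory, float]] = {}
    plus = minus = 0.0
    for gid in reporting:
        if gid == LIQUID_OILS:
            cat = oil_category
        elif gid in quantities:
            cat = quantities[gid].category
        else:
            cat = QuantityCategory.LOW
        pts = point_table.score(gid, cat)
        per_group[gid] = (cat, pts)
        if point_table.roles[gid] is GroupRole.HEALTHY:
            plus += pts
        else:
            minus += pts
    return GDQSResult(
        total=plus + minus,
        submetric_plus=plus,
        submetric_minus=minus,
        per_group=per_group,
    )
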