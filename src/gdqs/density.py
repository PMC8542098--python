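"""Derivation of mean food-group densities and the cube design.

The cube-based quantity method needs one mean density (g/cm3) per food
group to translate gram cutoffs into volumes.  The derivation pools 24-h
recall consumption tables from multiple survey datasets:

1. keep only each respondent's first recall;
2. per dataset, compute each food's percentage gram contribution to its
   group total (summed over respondents);
3. per dataset and group, rank the top 5 contributors (rank 1 = largest);
4. pool ranked foods across datasets (with 11 datasets, up to 55 candidate
   foods per group), compute mean ranks, and keep the 10 foods with the
   lowest mean rank as the group's representative foods;
5. the group mean density is the simple mean of the representative foods'
   densities.

The cube design then converts each group's original gram cutoffs to volumes
(grams / density), takes cube side lengths (volume^(1/3)), reduces them by
1-D agglomerative clustering (complete linkage) into a small core set whose
sides are cluster means, and appends a smallest and a largest flank cube
that correspond to no cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .taxonomy import AssessmentMode, TaxonomyConfig

__all__ = [
    "RepresentativeFoodSet",
    "CubeDesign",
    "DensityPipelineError",
    "filter_first_recall",
    "compute_contributions",
    "rank_top_foods",
    "aggregate_representatives",
    "boundaries_to_volumes",
    "cluster_cubes",
]

TOP_RANKS = 5
MAX_REPRESENTATIVES = 10


class DensityPipelineError(ValueError):
    pass


@dataclass(frozen=True)
class RepresentativeFoodSet:
    group_id: str
    foods: tuple[tuple[str, float], ...]  # (food_name, mean_rank), best first
    mean_density: float

    @property
    def food_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.foods)


@dataclass(frozen=True)
class CubeDesign:
    raw_boundaries: pd.DataFrame  # group_id, boundary, volume_cm3, side_mm
    clustered_cubes: tuple[dict, ...]  # {"side_mm", "members"} ascending
    flank_sides: tuple[float, float]
    k_core: int

    @property
    def cube_sides(self) -> tuple[float, ...]:
        """All k_core + 2 cube sides, ascending (flanks included)."""
        core = [c["side_mm"] for c in self.clustered_cubes]
        return tuple(sorted([self.flank_sides[0], *core, self.flank_sides[1]]))


REQUIRED_COLUMNS = ("dataset_id", "respondent_id", "food_name", "group_id", "grams")


def _check_columns(records: pd.DataFrame, extra: tuple[str, ...] = ()) -> None:
    missing = set(REQUIRED_COLUMNS + extra) - set(records.columns)
    if missing:
        raise DensityPipelineError(f"consumption table missing columns: {sorted(missing)}")


def filter_first_recall(records: pd.DataFrame) -> pd.DataFrame:
    """Keep only each (dataset, respondent)'s first recall (lowest recall_no)."""
    _check_columns(records, ("recall_no",))
    first = records.groupby(["dataset_id", "respondent_id"])["recall_no"].transform(
        "min"
    )
    return records[records["recall_no"] == first].reset_index(drop=True)


def compute_contributions(records: pd.DataFrame) -> pd.DataFrame:
    """Percentage gram contribution of each food to its group total.

    ``records`` must hold a single dataset's first recalls.  Foods are
    summed over all respondents; per group, contributions sum to 1 over the
    foods with positive grams.  Groups with zero total grams are omitted.
    """
    _check_columns(records)
    datasets = records["dataset_id"].unique()
    if len(datasets) != 1:
        raise DensityPipelineError(
            f"compute_contributions expects one dataset, got {sorted(map(str, datasets))}"
        )
    if (records["grams"] < 0).any():
        raise DensityPipelineError("negative gram amounts in consumption table")
    sums = (
        records.groupby(["group_id", "food_name"], as_index=False)["grams"]
        .sum()
        .rename(columns={"grams": "total_g"})
    )
    sums = sums[sums["total_g"] > 0]
    group_totals = sums.groupby("group_id")["total_g"].transform("sum")
    sums["pct_contribution"] = sums["total_g"] / group_totals
    sums.insert(0, "dataset_id", datasets[0])
    return sums.sort_values(
        ["group_id", "pct_contribution", "food_name"],
        ascending=[True, False, True],
    ).reset_index(drop=True)


def rank_top_foods(contributions: pd.DataFrame, top: int = TOP_RANKS) -> pd.DataFrame:
    """Rank the top ``top`` foods per (dataset, group) by contribution.

    Rank 1 is the largest contributor.  Ties break by greater gram total,
    then lexicographically smaller food name.
    """
    needed = {"dataset_id", "group_id", "food_name", "pct_contribution", "total_g"}
    missing = needed - set(contributions.columns)
    if missing:
        raise DensityPipelineError(f"contribution table missing columns: {sorted(missing)}")
    df = contributions.sort_values(
        ["dataset_id", "group_id", "pct_contribution", "total_g", "food_name"],
        ascending=[True, True, False, False, True],
    ).copy()
    df["rank"] = df.groupby(["dataset_id", "group_id"]).cumcount() + 1
    return df[df["rank"] <= top].reset_index(drop=True)


def aggregate_representatives(
    rank_entries: pd.DataFrame,
    densities: dict[str, float],
    max_foods: int = MAX_REPRESENTATIVES,
    absent_rank: float | None = None,
) -> dict[str, RepresentativeFoodSet]:
    """Pool per-dataset rankings into one representative food set per group.

    The candidate pool per group is the union of ranked foods across
    datasets.  Mean rank is computed, by default, over only the datasets in
    which a food was ranked; passing ``absent_rank`` instead charges that
    rank for every dataset where the food is absent from the top list.  The
    ``max_foods`` foods with the lowest mean rank are kept (ties break by
    greater pooled contribution, then name) and the group's mean density is
    the simple mean of their densities.
    """
    needed = {"dataset_id", "group_id", "food_name", "rank", "pct_contribution"}
    missing = needed - set(rank_entries.columns)
    if missing:
        raise DensityPipelineError(f"rank table missing columns: {sorted(missing)}")
    n_datasets = rank_entries["dataset_id"].nunique()
    out: dict[str, RepresentativeFoodSet] = {}
    for group_id, gdf in rank_entries.groupby("group_id"):
        stats = gdf.groupby("food_name").agg(
            rank_sum=("rank", "sum"),
            n_ranked=("rank", "size"),
            pooled_pct=("pct_contribution", "sum"),
        )
        if absent_rank is None:
            stats["mean_rank"] = stats["rank_sum"] / stats["n_ranked"]
        else:
            stats["mean_rank"] = (
                stats["rank_sum"] + absent_rank * (n_datasets - stats["n_ranked"])
            ) / n_datasets
        stats = stats.reset_index().sort_values(
            ["mean_rank", "pooled_pct", "food_name"],
            ascending=[True, False, True],
        )
        selected = stats.head(max_foods)
        missing_density = [
            f for f in selected["food_name"] if f not in densities
        ]
        if missing_density:
            raise DensityPipelineError(
                f"group {group_id!r}: no density for selected foods {missing_density}"
            )
        mean_density = float(
            np.mean([densities[f] for f in selected["food_name"]])
        )
        out[group_id] = RepresentativeFoodSet(
            group_id=group_id,
            foods=tuple(
                (row.food_name, float(row.mean_rank))
                for row in selected.itertuples(index=False)
            ),
            mean_density=mean_density,
        )
    return out


def boundaries_to_volumes(taxonomy: TaxonomyConfig) -> pd.DataFrame:
    """Convert original gram cutoffs to cube volumes and side lengths.

    volume_cm3 = original grams / mean group density; side_mm = volume^(1/3)
    in cm, times 10.  Only cube-assessed boundaries are included.
    """
    rows = []
    for b in taxonomy.boundaries:
        if taxonomy.group(b.group_id).assessment_mode is not AssessmentMode.CUBE:
            continue
        density = taxonomy.density(b.group_id).mean_density_g_per_cm3
        if density <= 0:
            raise DensityPipelineError(f"{b.group_id}: non-positive density {density}")
        if b.original_g is None:
            raise DensityPipelineError(
                f"{b.group_id}/{b.boundary}: no original gram cutoff"
            )
        volume = b.original_g / density
        rows.append(
            {
                "group_id": b.group_id,
                "boundary": b.boundary,
                "original_g": b.original_g,
                "volume_cm3": volume,
                "side_mm": volume ** (1.0 / 3.0) * 10.0,
            }
        )
    return pd.DataFrame(rows)


def cluster_cubes(
    raw_boundaries: pd.DataFrame,
    k_core: int = 8,
    flank_sides: tuple[float, float] = (18.0, 100.0),
) -> CubeDesign:
    """Reduce per-boundary cube sides to ``k_core`` cubes plus two flanks.

    1-D agglomerative clustering (complete linkage) on side length; each
    cluster's cube side is the mean of its members' sides.  The two flank
    cubes correspond to no cutoff and smooth the visual size progression.
    """
    if k_core < 1:
        raise DensityPipelineError(f"k_core must be >= 1, got {k_core}")
    missing = {"group_id", "boundary", "side_mm"} - set(raw_boundaries.columns)
    if missing:
        raise DensityPipelineError(f"boundary table missing columns: {sorted(missing)}")
    raw_boundaries = raw_boundaries.reset_index(drop=True)
    sides = raw_boundaries["side_mm"].to_numpy(dtype=float)
    if len(np.unique(sides)) < k_core:
        raise DensityPipelineError(
            f"need at least {k_core} distinct side lengths, got {len(np.unique(sides))}"
        )
    if len(sides) == k_core:
        labels = np.arange(1, k_core + 1)
    else:
        Z = linkage(sides.reshape(-1, 1), method="complete")
        labels = fcluster(Z, t=k_core, criterion="maxclust")
    clusters = []
    for lab in np.unique(labels):
        members = raw_boundaries[labels == lab]
        clusters.append(
            {
                "side_mm": float(members["side_mm"].mean()),
                "members": [
                    (r.group_id, r.boundary) for r in members.itertuples(index=False)
                ],
            }
        )
    clusters.sort(key=lambda c: c["side_mm"])
    core_sides = [c["side_mm"] for c in clusters]
    if any(a >= b for a, b in zip(core_sides, core_sides[1:])):
        raise DensityPipelineError("clustered cube sides are not strictly increasing")
    return CubeDesign(
        raw_boundaries=raw_boundaries.reset_index(drop=True),
        clustered_cubes=tuple(clusters),
        flank_sides=(float(flank_sides[0]), float(flank_sides[1])),
        k_core=k_core,
    )
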