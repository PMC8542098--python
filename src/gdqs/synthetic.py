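"""Seeded generators for every input the instrument consumes.

The package's inputs — a master food database, recall sessions, and the
multi-dataset consumption tables feeding the density pipeline — are survey
artifacts that cannot be shipped.  These generators produce structurally
equivalent fixtures deterministically from a seed: a master database with at
least one entry per collection group, probed (bread-like) entries and mixed
dishes; interview sessions exercising every step of the recall engine
including borderline cube picks and all oil-flag combinations; and
consumption tables emulating a multi-country collection of 24-h recall
datasets, with per-food densities.

Gram amounts per (respondent, food) are log-normal (sigma 0.4) around
food-level means set from target contribution shares; each respondent
consumes each food with probability 0.6.  These distributions are test
scaffolding: real recall data are burstier and correlated within
respondents, which nothing here emulates.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import recall
from .masterdb import MasterDB, load_master_db
from .quantity import BorderlineAnswer, CubeSelection
from .taxonomy import (
    AssessmentMode,
    TaxonomyConfig,
    load_taxonomy,
)

__all__ = [
    "GeneratorSpec",
    "gen_master_db",
    "gen_sessions",
    "gen_consumption_datasets",
]

GRAMS_SIGMA = 0.4
CONSUME_PROB = 0.6
SECOND_RECALL_FRACTION = 0.25
GRAMS_SCALE = 100.0  # overall gram scale of a group's daily total per respondent
DENSITY_RANGE = (0.40, 1.10)  # g/cm3, uniform per food


@dataclass(frozen=True)
class GeneratorSpec:
    """Study conditions for the synthetic fixtures."""

    seed: int = 0
    n_datasets: int = 11
    n_respondents_per_dataset: int = 120
    foods_per_group: int = 15
    #: group_id -> ((food_name, target contribution share), ...); shares per
    #: group must sum to <= 1.  Named foods are injected into every dataset.
    dominance_profile: dict[str, tuple[tuple[str, float], ...]] | None = None
    #: food names made unique per dataset (candidate pools then reach 5/dataset)
    disjoint_food_names: bool = False
    n_sessions: int = 12

    def validate(self) -> None:
        for gid, foods in (self.dominance_profile or {}).items():
            total = sum(share for _, share in foods)
            if not 0 < total <= 1:
                raise ValueError(
                    f"dominance shares for {gid!r} must sum to (0, 1], got {total}"
                )


# --------------------------------------------------------------------------
# master database
# --------------------------------------------------------------------------

_BASE_FOODS: dict[str, list[str]] = {
    "whole_grains": ["Oats", "Maize on cob"],
    "refined_grains_baked_goods": ["White rice", "Pasta"],
    "deep_orange_tubers": ["Orange sweet potato"],
    "white_roots_tubers": ["Potato", "Cassava"],
    "legumes": ["Lentils", "Kidney beans"],
    "nuts_seeds": ["Peanuts", "Almonds"],
    "fish_shellfish": ["Tilapia", "Tuna"],
    "poultry_game_meat": ["Chicken", "Duck"],
    "red_meat": ["Beef", "Goat meat"],
    "processed_meat": ["Ham", "Pork sausage"],
    "eggs": ["Chicken eggs"],
    "high_fat_dairy_cheese": ["Cheddar cheese"],
    "high_fat_dairy_other": ["Curd"],
    "low_fat_dairy": ["Low fat yogurt"],
    "deep_orange_fruits": ["Mango", "Papaya"],
    "citrus_fruits": ["Orange", "Lemon"],
    "other_fruits": ["Banana", "Watermelon", "Apple"],
    "dark_green_leafy_vegetables": ["Spinach", "Kale"],
    "deep_orange_vegetables": ["Carrot", "Pumpkin"],
    "cruciferous_vegetables": ["Cabbage", "Broccoli"],
    "other_vegetables": ["Tomato", "Onion"],
    "liquid_oils": ["Sunflower oil"],
    "juice": ["Orange juice"],
    "sugar_sweetened_beverages": ["Cola drink"],
    "sweets_ice_cream": ["Sugar", "Ice cream"],
    "purchased_deep_fried_foods": ["Fried doughnut", "Chips"],
}

_BEVERAGE_GROUPS = {"juice", "sugar_sweetened_beverages"}


def gen_master_db(
    spec: GeneratorSpec | int = 0, taxonomy: TaxonomyConfig | None = None
) -> MasterDB:
    """Deterministic master-database fixture.

    Contains at least one concrete entry per collection group, two probed
    entries (bread: white/brown; cheese: a depth-2 chain), and two mixed
    dishes.  Identical output for identical seeds.
    """
    if isinstance(spec, int):
        spec = GeneratorSpec(seed=spec)
    taxonomy = taxonomy or load_taxonomy()
    rows = []
    for gid, foods in _BASE_FOODS.items():
        for name in foods:
            rows.append(
                {
                    "name": name,
                    "kind": "beverage" if gid in _BEVERAGE_GROUPS else "single_food",
                    "group": gid,
                }
            )
    rows.append(
        {
            "name": "Bread",
            "kind": "single_food",
            "group": "ambiguous",
            "probe1_question": "Was the bread white or brown?",
            "probe1_map": "white:refined_grains_baked_goods|brown:whole_grains",
        }
    )
    rows.append(
        {
            "name": "Cheese",
            "kind": "single_food",
            "group": "ambiguous",
            "probe1_question": "Was it hard or soft cheese?",
            "probe1_map": "hard:high_fat_dairy_cheese|soft:probe2",
            "probe2_question": "Was the soft cheese low fat?",
            "probe2_map": "yes:low_fat_dairy|no:high_fat_dairy_other",
        }
    )
    rows.append({"name": "Chicken stew", "kind": "mixed_dish", "group": "ambiguous"})
    rows.append({"name": "Vegetable curry", "kind": "mixed_dish", "group": "ambiguous"})
    rows.append(
        {
            "name": "Fried chicken",
            "kind": "single_food",
            "group": "poultry_game_meat",
            "aliases": "deep fried chicken",
        }
    )
    df = pd.DataFrame(rows)
    df.insert(0, "entry_id", [f"f{i:04d}" for i in range(len(df))])
    return load_master_db(df, taxonomy)


# --------------------------------------------------------------------------
# recall sessions
# --------------------------------------------------------------------------

_OIL_FLAG_COMBOS = list(itertools.product([False, True], [0, 1, 2], [False, True]))


def gen_sessions(
    spec: GeneratorSpec | int = 0,
    db: MasterDB | None = None,
    taxonomy: TaxonomyConfig | None = None,
) -> list[recall.RecallSession]:
    """Deterministic recall sessions, driven through the engine's 7 steps.

    Sessions cycle through every oil-flag combination (home deep-frying x
    0/1/2 mixed dishes x pouring oil) and include boundary-cube picks with
    both borderline answers.  Sessions are returned at step 7, ready to
    finalize.
    """
    if isinstance(spec, int):
        spec = GeneratorSpec(seed=spec)
    taxonomy = taxonomy or load_taxonomy()
    db = db or gen_master_db(spec, taxonomy)
    rng = np.random.default_rng(spec.seed)

    concrete = sorted(
        (e for e in db.entries.values() if e.group_id not in ("ambiguous",)),
        key=lambda e: e.entry_id,
    )
    single_names = [
        e.name
        for e in concrete
        if e.kind.value != "mixed_dish" and e.group_id != "liquid_oils"
    ]
    sessions = []
    for i in range(spec.n_sessions):
        home_fried, n_dishes, poured = _OIL_FLAG_COMBOS[i % len(_OIL_FLAG_COMBOS)]
        s = recall.RecallSession(respondent_id=f"resp{i:03d}", recall_date="day 1")
        n_items = int(rng.integers(2, 5))
        picks = rng.choice(len(single_names), size=n_items, replace=False)
        occasions = ["breakfast", "lunch", "dinner", "snack"]
        for j, p in enumerate(picks):
            recall.add_item(s, single_names[p], occasions[j % 4], db)
        probed = bool(rng.random() < 0.5)
        if probed:
            recall.add_item(s, "Bread", "breakfast", db)
        dishes = []
        for d in range(n_dishes):
            dishes.append(
                recall.add_item(
                    s, "Chicken stew" if d == 0 else "Vegetable curry", "dinner", db
                )
            )
        s.advance_step()  # 2: decomposition
        for dish in dishes:
            recall.decompose_mixed_dish(s, dish, ["Chicken", "Tomato", "Onion"], db)
        s.advance_step()  # 3: classification
        answers = {"Bread": [str(rng.choice(["white", "brown"]))]} if probed else {}
        recall.classify_all(s, db, probe_answers=answers, taxonomy=taxonomy)
        s.advance_step()  # 4: deep-fried / oil questions
        recall.record_oil_questions(
            s,
            purchased_deep_fried=False,
            home_deep_fried_pourable_oil=home_fried,
            poured_or_used_oil=poured,
        )
        s.advance_step()  # 5: sweetener probe
        if rng.random() < 0.4:
            recall.add_sweeteners(s, ["Sugar"])
        s.advance_step()  # 6: cube capture
        for gid in sorted(recall.read_back_groups(s)):
            if taxonomy.group(gid).assessment_mode is not AssessmentMode.CUBE:
                continue
            cube = int(rng.integers(1, 11))
            boundary_cubes = taxonomy.boundary_cubes(gid)
            answer = (
                BorderlineAnswer(
                    str(rng.choice(["bigger_or_equal", "smaller"]))
                )
                if cube in boundary_cubes
                else BorderlineAnswer.NOT_APPLICABLE
            )
            recall.record_cube_selection(
                s, CubeSelection(gid, cube, answer), taxonomy
            )
        s.advance_step()  # 7: ready to finalize
        sessions.append(s)
    return sessions


# --------------------------------------------------------------------------
# consumption datasets for the density pipeline
# --------------------------------------------------------------------------


def _group_food_names(
    spec: GeneratorSpec, gid: str, dataset_id: str
) -> tuple[list[str], np.ndarray]:
    """Food names and target contribution shares for one group (one dataset)."""
    dominant = list((spec.dominance_profile or {}).get(gid, ()))
    n_filler = spec.foods_per_group - len(dominant)
    if n_filler < 0:
        raise ValueError(f"{gid}: more dominant foods than foods_per_group")
    suffix = f" ({dataset_id})" if spec.disjoint_food_names else ""
    names = [name for name, _ in dominant]
    shares = [share for _, share in dominant]
    remaining = 1.0 - sum(shares)
    names += [f"{gid} food {i + 1}{suffix}" for i in range(n_filler)]
    shares += [remaining / n_filler] * n_filler if n_filler else []
    return names, np.asarray(shares)


def gen_consumption_datasets(
    spec: GeneratorSpec | int = 0, taxonomy: TaxonomyConfig | None = None
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Synthetic multi-dataset consumption tables plus a food-density lookup.

    Returns a long table (dataset_id, respondent_id, recall_no, food_name,
    group_id, grams) covering every cube-assessed collection group, and a
    food -> density (g/cm3) mapping.  A quarter of respondents carry a
    second recall (recall_no 2) so first-recall filtering is exercised.
    Deterministic for a fixed spec.
    """
    if isinstance(spec, int):
        spec = GeneratorSpec(seed=spec)
    spec.validate()
    taxonomy = taxonomy or load_taxonomy()
    rng = np.random.default_rng(spec.seed)
    groups = sorted(
        g.group_id
        for g in taxonomy.cube_assessed_groups()
    )
    rows = []
    densities: dict[str, float] = {}
    for d in range(spec.n_datasets):
        dataset_id = f"dataset{d + 1:02d}"
        for gid in groups:
            names, shares = _group_food_names(spec, gid, dataset_id)
            for name in names:
                if name not in densities:
                    densities[name] = float(
                        rng.uniform(DENSITY_RANGE[0], DENSITY_RANGE[1])
                    )
            # log-normal food means proportional to the target shares
            mus = np.log(shares * GRAMS_SCALE) - GRAMS_SIGMA**2 / 2.0
            n_resp = spec.n_respondents_per_dataset
            n_second = int(n_resp * SECOND_RECALL_FRACTION)
            for recall_no, nr in ((1, n_resp), (2, n_second)):
                if nr == 0:
                    continue
                consumed = rng.random((nr, len(names))) < CONSUME_PROB
                grams = rng.lognormal(
                    mean=np.broadcast_to(mus, (nr, len(names))), sigma=GRAMS_SIGMA
                )
                r_idx, f_idx = np.nonzero(consumed)
                rows.append(
                    pd.DataFrame(
                        {
                            "dataset_id": dataset_id,
                            "respondent_id": [
                                f"{dataset_id}_r{r:04d}" for r in r_idx
                            ],
                            "recall_no": recall_no,
                            "food_name": [names[f] for f in f_idx],
                            "group_id": gid,
                            "grams": grams[r_idx, f_idx],
                        }
                    )
                )
    records = pd.concat(rows, ignore_index=True)
    return records, densities
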