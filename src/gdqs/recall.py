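"""The 7-step 24-h open-recall interview as an explicit state machine.

Steps
-----
1. Free listing of foods and beverages by eating occasion (first pass of a
   multipass 24-h recall).
2. Decomposition of mixed dishes into ingredients (exception foods such as
   bread are single foods and are never decomposed).
3. Classification: database-matched items resolve through their probe
   chains; free-text items receive a manual group; purchased deep-fried
   items are additionally tagged to the purchased-deep-fried group.
4. Deep-fried and oil questions (session-level flags feeding the liquid-oils
   inference).
5. Caloric-sweetener probe: reported sweeteners are added as items in the
   sweets-and-ice-cream group.
6. Per-group read-back and cube capture.
7. Finalization: quantities, oil inference, dairy merge and scoring.

Operations are rejected outside their step; ``advance_step`` moves forward
only (1 -> 7).  Sessions serialize to JSON and round-trip losslessly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .masterdb import (
    AMBIGUOUS,
    FoodEntry,
    FoodKind,
    MasterDB,
    MasterDBError,
    make_free_text_entry,
    resolve_entry,
)
from .oil import infer_oil_category
from .quantity import (
    BorderlineAnswer,
    CubeSelection,
    GroupQuantity,
    QuantityError,
    categorize_from_cube,
    estimate_grams,
    merge_high_fat_dairy,
)
from .scoring import GDQSResult, PointTable, score_session
from .taxonomy import (
    HIGH_FAT_DAIRY_CHEESE,
    HIGH_FAT_DAIRY_OTHER,
    PURCHASED_DEEP_FRIED,
    SWEETS,
    AssessmentMode,
    QuantityCategory,
    TaxonomyConfig,
)

__all__ = [
    "ReportedItem",
    "RecallSession",
    "RecallError",
    "StepError",
    "add_item",
    "decompose_mixed_dish",
    "classify_all",
    "record_oil_questions",
    "add_sweeteners",
    "record_cube_selection",
    "read_back_groups",
    "group_quantities",
    "finalize",
]


class RecallError(ValueError):
    pass


class StepError(RecallError):
    pass


@dataclass
class ReportedItem:
    raw_name: str
    occasion: str
    entry_id: str | None = None  # None for free-text items
    kind: FoodKind = FoodKind.SINGLE_FOOD
    parent_index: int | None = None  # index of the mixed dish this belongs to
    resolved_group: str | None = None
    dual_groups: list[str] = field(default_factory=list)
    provenance: str = "db_matched"  # or "free_text_manual"
    is_mixed_dish: bool = False
    decomposed: bool = False

    @property
    def is_leaf(self) -> bool:
        """Leaves contribute a food group; decomposed dishes do not."""
        return not (self.is_mixed_dish and self.decomposed)

    def to_dict(self) -> dict:
        return {
            "raw_name": self.raw_name,
            "occasion": self.occasion,
            "entry_id": self.entry_id,
            "kind": self.kind.value,
            "parent_index": self.parent_index,
            "resolved_group": self.resolved_group,
            "dual_groups": list(self.dual_groups),
            "provenance": self.provenance,
            "is_mixed_dish": self.is_mixed_dish,
            "decomposed": self.decomposed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ReportedItem":
        d = dict(d)
        d["kind"] = FoodKind(d["kind"])
        return cls(**d)


@dataclass
class RecallSession:
    respondent_id: str
    recall_date: str = ""
    items: list[ReportedItem] = field(default_factory=list)
    purchased_deep_fried: bool = False
    home_deep_fried_pourable_oil: bool = False
    poured_or_used_oil: bool = False
    cube_selections: dict[str, CubeSelection] = field(default_factory=dict)
    step: int = 1

    @property
    def mixed_dish_count(self) -> int:
        return sum(1 for it in self.items if it.is_mixed_dish)

    def advance_step(self) -> int:
        if self.step >= 7:
            raise StepError("session already at final step 7")
        self.step += 1
        return self.step

    # -- persistence -----------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "respondent_id": self.respondent_id,
                "recall_date": self.recall_date,
                "items": [it.to_dict() for it in self.items],
                "purchased_deep_fried": self.purchased_deep_fried,
                "home_deep_fried_pourable_oil": self.home_deep_fried_pourable_oil,
                "poured_or_used_oil": self.poured_or_used_oil,
                "cube_selections": {
                    gid: {
                        "group_id": sel.group_id,
                        "cube_index": sel.cube_index,
                        "borderline_answer": sel.borderline_answer.value,
                    }
                    for gid, sel in self.cube_selections.items()
                },
                "step": self.step,
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "RecallSession":
        d = json.loads(text)
        return cls(
            respondent_id=d["respondent_id"],
            recall_date=d.get("recall_date", ""),
            items=[ReportedItem.from_dict(it) for it in d["items"]],
            purchased_deep_fried=d["purchased_deep_fried"],
            home_deep_fried_pourable_oil=d["home_deep_fried_pourable_oil"],
            poured_or_used_oil=d["poured_or_used_oil"],
            cube_selections={
                gid: CubeSelection(
                    group_id=s["group_id"],
                    cube_index=s["cube_index"],
                    borderline_answer=BorderlineAnswer(s["borderline_answer"]),
                )
                for gid, s in d["cube_selections"].items()
            },
            step=d["step"],
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "RecallSession":
        return cls.from_json(Path(path).read_text())


def _require_step(session: RecallSession, step: int) -> None:
    if session.step != step:
        raise StepError(
            f"operation only valid at step {step}; session is at step {session.step}"
        )


def _match_entry(db: MasterDB, raw_name: str) -> FoodEntry | None:
    return db.by_name(raw_name)


def add_item(
    session: RecallSession, raw_name: str, occasion: str, db: MasterDB
) -> ReportedItem:
    """Step 1: record a reported food/beverage for an eating occasion.

    Exact (case-insensitive) name or alias matches bind to the database
    entry; anything else becomes a free-text item awaiting a manual group
    in step 3.
    """
    _require_step(session, 1)
    raw_name = raw_name.strip()
    if not raw_name:
        raise RecallError("reported food name is empty")
    entry = _match_entry(db, raw_name)
    if entry is not None:
        item = ReportedItem(
            raw_name=raw_name,
            occasion=occasion,
            entry_id=entry.entry_id,
            kind=entry.kind,
            is_mixed_dish=entry.kind is FoodKind.MIXED_DISH,
            provenance="db_matched",
        )
    else:
        item = ReportedItem(
            raw_name=raw_name,
            occasion=occasion,
            entry_id=None,
            provenance="free_text_manual",
        )
    session.items.append(item)
    return item


def decompose_mixed_dish(
    session: RecallSession,
    item: ReportedItem,
    ingredient_names: list[str],
    db: MasterDB,
) -> list[ReportedItem]:
    """Step 2: list a mixed dish's (main) ingredients as child items."""
    _require_step(session, 2)
    if not item.is_mixed_dish:
        raise RecallError(
            f"{item.raw_name!r} is a single food, not a mixed dish; exception "
            "foods such as bread and cakes are never decomposed"
        )
    if not ingredient_names:
        raise RecallError(
            f"{item.raw_name!r}: no ingredients listed; ask for the main "
            "ingredients at least"
        )
    parent_index = session.items.index(item)
    children = []
    for name in ingredient_names:
        name = name.strip()
        if not name:
            raise RecallError("ingredient name is empty")
        entry = _match_entry(db, name)
        child = ReportedItem(
            raw_name=name,
            occasion=item.occasion,
            entry_id=entry.entry_id if entry is not None else None,
            kind=entry.kind if entry is not None else FoodKind.SINGLE_FOOD,
            parent_index=parent_index,
            provenance="db_matched" if entry is not None else "free_text_manual",
        )
        session.items.append(child)
        children.append(child)
    item.decomposed = True
    return children


def classify_all(
    session: RecallSession,
    db: MasterDB,
    probe_answers: dict[str, list[str]] | None = None,
    manual_groups: dict[str, str] | None = None,
    purchased_deep_fried_items: list[str] | None = None,
    taxonomy: TaxonomyConfig | None = None,
) -> RecallSession:
    """Step 3: resolve every leaf item to a concrete food group.

    ``probe_answers`` maps raw item names to ordered probe answers;
    ``manual_groups`` maps free-text item names to enumerator-assigned
    groups; items named in ``purchased_deep_fried_items`` are additionally
    tagged to the purchased-deep-fried group (dual classification).
    Idempotent: re-running with the same arguments leaves the session
    unchanged.
    """
    _require_step(session, 3)
    probe_answers = probe_answers or {}
    manual_groups = manual_groups or {}
    purchased = set(purchased_deep_fried_items or [])
    pending: list[str] = []
    for item in session.items:
        if not item.is_leaf:
            item.resolved_group = None
            continue
        if item.is_mixed_dish:
            pending.append(f"{item.raw_name} (mixed dish not decomposed)")
            continue
        if item.entry_id is not None:
            entry = db.get(item.entry_id)
            if entry.group_id == AMBIGUOUS and item.raw_name not in probe_answers:
                pending.append(item.raw_name)
                continue
            item.resolved_group = resolve_entry(
                entry, probe_answers.get(item.raw_name, [])
            )
        else:
            if item.raw_name not in manual_groups:
                pending.append(item.raw_name)
                continue
            gid = manual_groups[item.raw_name]
            if taxonomy is not None and gid not in taxonomy.groups:
                raise RecallError(
                    f"free-text item {item.raw_name!r}: unknown group {gid!r}"
                )
            item.resolved_group = gid
        item.dual_groups = (
            [PURCHASED_DEEP_FRIED]
            if item.raw_name in purchased
            and item.resolved_group != PURCHASED_DEEP_FRIED
            else []
        )
    if pending:
        raise RecallError(
            "unresolved items (missing probe answers or manual groups): "
            f"{sorted(set(pending))}"
        )
    return session


def record_oil_questions(
    session: RecallSession,
    purchased_deep_fried: bool,
    home_deep_fried_pourable_oil: bool,
    poured_or_used_oil: bool,
) -> RecallSession:
    """Step 4: deep-fried and oil-use questions (session-level flags)."""
    _require_step(session, 4)
    session.purchased_deep_fried = purchased_deep_fried
    session.home_deep_fried_pourable_oil = home_deep_fried_pourable_oil
    session.poured_or_used_oil = poured_or_used_oil
    return session


def add_sweeteners(
    session: RecallSession, sweetener_names: list[str], occasion: str = "sweetener probe"
) -> list[ReportedItem]:
    """Step 5: add reported caloric sweeteners as sweets-group items."""
    _require_step(session, 5)
    added = []
    for name in sweetener_names:
        name = name.strip()
        if not name:
            raise RecallError("sweetener name is empty")
        item = ReportedItem(
            raw_name=name,
            occasion=occasion,
            resolved_group=SWEETS,
            provenance="db_matched",
        )
        session.items.append(item)
        added.append(item)
    return added


def read_back_groups(session: RecallSession) -> dict[str, list[str]]:
    """Groups with at least one classified item, with the item names to read
    back; dual-classified items appear under both their groups."""
    if session.step < 4:
        raise StepError(
            f"read-back requires classification to be complete (step >= 4); "
            f"session is at step {session.step}"
        )
    out: dict[str, list[str]] = {}
    for item in session.items:
        if not item.is_leaf or item.resolved_group is None:
            continue
        for gid in (item.resolved_group, *item.dual_groups):
            out.setdefault(gid, []).append(item.raw_name)
    return out


def record_cube_selection(
    session: RecallSession,
    selection: CubeSelection,
    taxonomy: TaxonomyConfig,
) -> RecallSession:
    """Step 6: record the cube picked for one food group.

    Only cube-assessed groups with at least one classified item may receive
    a selection; borderline cubes require a confirmation answer.
    """
    _require_step(session, 6)
    group = taxonomy.group(selection.group_id)
    if group.assessment_mode is not AssessmentMode.CUBE:
        raise RecallError(
            f"group {selection.group_id!r} is not assessed with cubes"
        )
    reported = {
        gid
        for item in session.items
        if item.is_leaf and item.resolved_group is not None
        for gid in (item.resolved_group, *item.dual_groups)
    }
    if selection.group_id not in reported:
        raise RecallError(
            f"no reported items in group {selection.group_id!r}; cube "
            "selections are only captured for reported groups"
        )
    categorize_from_cube(taxonomy, selection)  # validates borderline rules
    session.cube_selections[selection.group_id] = selection
    return session


def group_quantities(
    session: RecallSession, taxonomy: TaxonomyConfig
) -> dict[str, GroupQuantity]:
    """Per-reporting-group quantities from the session's cube selections,
    with the two high-fat dairy subgroups merged."""
    out: dict[str, GroupQuantity] = {}
    cheese = session.cube_selections.get(HIGH_FAT_DAIRY_CHEESE)
    other = session.cube_selections.get(HIGH_FAT_DAIRY_OTHER)
    if cheese is not None or other is not None:
        merged = merge_high_fat_dairy(taxonomy, cheese, other)
        out[merged.group_id] = merged
    for gid, sel in session.cube_selections.items():
        if gid in (HIGH_FAT_DAIRY_CHEESE, HIGH_FAT_DAIRY_OTHER):
            continue
        reporting = taxonomy.group(gid).reporting_group_id
        out[reporting] = GroupQuantity(
            group_id=reporting,
            category=categorize_from_cube(taxonomy, sel),
            grams_estimate=estimate_grams(taxonomy, sel),
        )
    return out


def finalize(
    session: RecallSession,
    taxonomy: TaxonomyConfig,
    point_table: PointTable,
) -> GDQSResult:
    """Step 7: oil inference, dairy merge, and score tabulation."""
    _require_step(session, 7)
    oil_category = infer_oil_category(
        session.home_deep_fried_pourable_oil,
        session.mixed_dish_count,
        session.poured_or_used_oil,
    )
    return score_session(
        group_quantities(session, taxonomy),
        oil_category,
        point_table,
        taxonomy,
    )
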