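"""The 7-step recall interview: step gating, classification, read-back."""

import pytest

from gdqs import GeneratorSpec, gen_master_db, gen_sessions
from gdqs import recall
from gdqs.quantity import BorderlineAnswer, CubeSelection
from gdqs.recall import (
    RecallError,
    RecallSession,
    StepError,
    add_item,
    add_sweeteners,
    classify_all,
    decompose_mixed_dish,
    read_back_groups,
    record_cube_selection,
    record_oil_questions,
)


@pytest.fixture()
def session():
    return RecallSession(respondent_id="r1", recall_date="day 1")


def test_add_item_matches_db_or_flags_free_text(session, master_db):
    banana = add_item(session, "Banana", "breakfast", master_db)
    assert banana.provenance == "db_matched" and not banana.is_mixed_dish
    stew = add_item(session, "Chicken stew", "dinner", master_db)
    assert stew.is_mixed_dish
    assert session.mixed_dish_count == 1
    free = add_item(session, "Grandma's porridge", "breakfast", master_db)
    assert free.provenance == "free_text_manual" and free.entry_id is None
    with pytest.raises(RecallError, match="empty"):
        add_item(session, "  ", "lunch", master_db)


def test_step_gating_rejects_out_of_step_operations(session, master_db):
    add_item(session, "Banana", "breakfast", master_db)
    session.advance_step()
    with pytest.raises(StepError):
        add_item(session, "Beef", "lunch", master_db)
    with pytest.raises(StepError):
        read_back_groups(session)  # classification not yet complete
    for _ in range(5):
        session.advance_step()
    assert session.step == 7
    with pytest.raises(StepError):
        session.advance_step()


def test_decompose_mixed_dish_and_exception_foods(session, master_db):
    stew = add_item(session, "Chicken stew", "dinner", master_db)
    bread = add_item(session, "Bread", "dinner", master_db)
    session.advance_step()
    children = decompose_mixed_dish(session, stew, ["Chicken", "Tomato", "Onion"], master_db)
    assert len(children) == 3
    assert all(c.parent_index == session.items.index(stew) for c in children)
    assert stew.decomposed and not stew.is_leaf
    # bread is an exception food: single food, never decomposed
    with pytest.raises(RecallError, match="single food"):
        decompose_mixed_dish(session, bread, ["flour"], master_db)
    with pytest.raises(RecallError, match="ingredient"):
        decompose_mixed_dish(session, stew, [], master_db)


def _classified_session(master_db, taxonomy):
    s = RecallSession(respondent_id="r2")
    add_item(s, "Banana", "morning", master_db)
    add_item(s, "Watermelon", "evening", master_db)
    add_item(s, "Bread", "morning", master_db)
    add_item(s, "Fried chicken", "lunch", master_db)
    stew = add_item(s, "Chicken stew", "dinner", master_db)
    s.advance_step()
    decompose_mixed_dish(s, stew, ["Chicken", "Tomato"], master_db)
    s.advance_step()
    classify_all(
        s,
        master_db,
        probe_answers={"Bread": ["white"]},
        purchased_deep_fried_items=["Fried chicken"],
        taxonomy=taxonomy,
    )
    return s


def test_classify_all_resolves_probes_and_dual_tags(master_db, taxonomy):
    s = _classified_session(master_db, taxonomy)
    by_name = {it.raw_name: it for it in s.items}
    assert by_name["Bread"].resolved_group == "refined_grains_baked_goods"
    assert by_name["Fried chicken"].resolved_group == "poultry_game_meat"
    assert by_name["Fried chicken"].dual_groups == ["purchased_deep_fried_foods"]
    assert by_name["Chicken stew"].resolved_group is None  # dish contributes no group
    assert by_name["Chicken"].resolved_group == "poultry_game_meat"


def test_classify_all_is_idempotent(master_db, taxonomy):
    s = _classified_session(master_db, taxonomy)
    snapshot = s.to_json()
    classify_all(
        s,
        master_db,
        probe_answers={"Bread": ["white"]},
        purchased_deep_fried_items=["Fried chicken"],
        taxonomy=taxonomy,
    )
    assert s.to_json() == snapshot


def test_classify_all_reports_pending_probes(master_db, taxonomy):
    s = RecallSession(respondent_id="r3")
    add_item(s, "Bread", "morning", master_db)
    s.advance_step()
    s.advance_step()
    with pytest.raises(RecallError, match="Bread"):
        classify_all(s, master_db, taxonomy=taxonomy)


def test_read_back_groups_contents(master_db, taxonomy):
    s = _classified_session(master_db, taxonomy)
    s.advance_step()  # step 4
    groups = read_back_groups(s)
    assert groups["other_fruits"] == ["Banana", "Watermelon"]
    # dual-classified item appears under both groups
    assert "Fried chicken" in groups["poultry_game_meat"]
    assert groups["purchased_deep_fried_foods"] == ["Fried chicken"]
    # the decomposed dish itself contributes nothing
    assert all("Chicken stew" not in names for names in groups.values())


def test_read_back_matches_leaf_groups_for_generated_sessions(taxonomy):
    """For any synthetic session, read-back groups are exactly the resolved
    groups of leaf items plus their dual tags."""
    db = gen_master_db(GeneratorSpec(seed=5), taxonomy)
    for s in gen_sessions(GeneratorSpec(seed=5, n_sessions=6), db, taxonomy):
        expected = {
            gid
            for it in s.items
            if it.is_leaf and it.resolved_group is not None
            for gid in (it.resolved_group, *it.dual_groups)
        }
        assert set(read_back_groups(s)) == expected


def test_empty_session_reads_back_nothing(taxonomy):
    s = RecallSession(respondent_id="r4")
    for _ in range(3):
        s.advance_step()
    assert read_back_groups(s) == {}


def test_sweetener_probe_adds_sweets_items(master_db):
    s = RecallSession(respondent_id="r5")
    add_item(s, "Banana", "morning", master_db)
    for _ in range(4):
        s.advance_step()
    items = add_sweeteners(s, ["Sugar in tea"])
    assert items[0].resolved_group == "sweets_ice_cream"


def test_cube_capture_only_for_reported_groups(master_db, taxonomy):
    s = _classified_session(master_db, taxonomy)
    for _ in range(3):
        s.advance_step()  # -> step 6
    record_cube_selection(s, CubeSelection("other_fruits", 3), taxonomy)
    assert "other_fruits" in s.cube_selections
    with pytest.raises(RecallError, match="no reported items"):
        record_cube_selection(s, CubeSelection("red_meat", 2, BorderlineAnswer.SMALLER), taxonomy)
    with pytest.raises(RecallError, match="not assessed"):
        record_cube_selection(s, CubeSelection("liquid_oils", 3), taxonomy)


def test_oil_questions_set_session_flags(master_db):
    s = RecallSession(respondent_id="r6")
    add_item(s, "Banana", "morning", master_db)
    for _ in range(3):
        s.advance_step()
    record_oil_questions(
        s,
        purchased_deep_fried=True,
        home_deep_fried_pourable_oil=False,
        poured_or_used_oil=True,
    )
    assert s.purchased_deep_fried and s.poured_or_used_oil
    assert not s.home_deep_fried_pourable_oil


def test_session_json_round_trip(master_db, taxonomy):
    s = _classified_session(master_db, taxonomy)
    for _ in range(3):
        s.advance_step()
    record_cube_selection(
        s, CubeSelection("other_fruits", 4, BorderlineAnswer.SMALLER), taxonomy
    )
    restored = RecallSession.from_json(s.to_json())
    assert restored == s
    assert restored.to_json() == s.to_json()
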