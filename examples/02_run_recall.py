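"""Drive one respondent through the 7-step recall interview and score it.

A small interview: fruit at two occasions, probed bread, a purchased
deep-fried item (dual-classified), and one mixed dish (which places the
liquid-oils category in the middle band).  Scores use the shipped EXAMPLE
point table — illustrative values, not the published ones.
"""

from gdqs import example_point_table, load_taxonomy
from gdqs.quantity import BorderlineAnswer, CubeSelection
from gdqs.recall import (
    RecallSession,
    add_item,
    classify_all,
    decompose_mixed_dish,
    finalize,
    read_back_groups,
    record_cube_selection,
    record_oil_questions,
)
from gdqs.synthetic import gen_master_db

taxonomy = load_taxonomy()
db = gen_master_db(0, taxonomy)

s = RecallSession(respondent_id="demo", recall_date="yesterday")
add_item(s, "Banana", "morning", db)
add_item(s, "Watermelon", "evening", db)
add_item(s, "Bread", "morning", db)
add_item(s, "Fried chicken", "lunch", db)
stew = add_item(s, "Chicken stew", "dinner", db)

s.advance_step()  # 2: decompose the mixed dish
decompose_mixed_dish(s, stew, ["Chicken", "Tomato", "Onion"], db)

s.advance_step()  # 3: classification (probe answer for bread; dual tag)
classify_all(
    s,
    db,
    probe_answers={"Bread": ["brown"]},
    purchased_deep_fried_items=["Fried chicken"],
    taxonomy=taxonomy,
)

s.advance_step()  # 4: deep-fried / oil questions
record_oil_questions(
    s, purchased_deep_fried=True, home_deep_fried_pourable_oil=False, poured_or_used_oil=False
)
s.advance_step()  # 5: no sweeteners reported

s.advance_step()  # 6: cube capture per reported group
print("read-back per group:")
for gid, names in sorted(read_back_groups(s).items()):
    print(f"  {gid:28s} {', '.join(names)}")

record_cube_selection(s, CubeSelection("other_fruits", 5), taxonomy)
record_cube_selection(
    s, CubeSelection("whole_grains", 3, BorderlineAnswer.BIGGER_OR_EQUAL), taxonomy
)
record_cube_selection(s, CubeSelection("poultry_game_meat", 4), taxonomy)
record_cube_selection(s, CubeSelection("purchased_deep_fried_foods", 4), taxonomy)
record_cube_selection(s, CubeSelection("other_vegetables", 3), taxonomy)

s.advance_step()  # 7: finalize
result = finalize(s, taxonomy, example_point_table(taxonomy))
print(f"\ntotal score      : {result.total}")
print(f"healthy submetric: {result.submetric_plus}")
print(f"other submetric  : {result.submetric_minus}")
print("non-low groups   :")
for gid, (cat, pts) in sorted(result.per_group.items()):
    if str(cat) != "low":
        print(f"  {gid:28s} {cat} ({pts} pts)")
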