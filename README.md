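# gdqs — operationalized Global Diet Quality Score instrument

The Global Diet Quality Score (GDQS) is a food-group-based metric of overall
diet quality for population surveys: foods reported in a 24-h open recall
are classified into 25 food groups, the quantity consumed per group is
binned into broad bands (low / middle / high, plus very-high for high-fat
dairy) against gram cutoffs, and band-specific points are summed into the
score and its healthy/unhealthy submetrics.

Collecting those data in the field is the hard part. This package implements
the operationalized collection instrument as a Python library (with a thin
`gdqs` CLI) for survey methodologists and nutrition researchers:

- **Taxonomy** — the 26 collection-time food groups (high-fat dairy is split
  into *hard cheese* and *other* during collection), their 54 category
  boundaries with original and operationalized gram cutoffs, the 10
  visual-aid cubes (sides 18–100 mm), and the mean food-group densities with
  their representative food lists; all shipped as editable CSV configuration
  and strictly validated.
- **Master food database** — preclassified foods/beverages/mixed dishes with
  approximate string search (exact > prefix > edit-distance hits) and probe
  descriptors (e.g. bread: *white* → refined grains, *brown* → whole grains).
- **Recall engine** — the 7-step interview as a state machine: free listing
  by eating occasion, mixed-dish decomposition into ingredients, probe and
  free-text classification (purchased deep-fried items are dual-classified),
  deep-fried/oil questions, caloric-sweetener probe, per-group read-back
  with cube capture, finalization.
- **Quantity estimation** — cube index → category with borderline
  confirmation ("as big or bigger" / "smaller") on cubes that sit exactly on
  a cutoff; gram point estimates as `density × cube volume`; the high-fat
  dairy merge (`grams = 6.1 × cheese + other`, categorized against the
  merged group's original 35 / 140 / 734 g cutoffs).
- **Liquid-oils inference** — the oils band is never cube-assessed: *high*
  if the respondent deep-fried at home with pourable oil, had ≥2 mixed
  dishes, or poured/used oil; *middle* with exactly one mixed dish; else
  *low*.
- **Scoring** — point values are configuration, not code; a validated table
  maps group × category → points and group → role. A clearly labeled example
  table ships for demos and tests.
- **Density pipeline** — the derivation that produced the cube design: per
  dataset, each food's percentage gram contribution to its group
  (first recalls only), top-5 ranking, cross-dataset mean-rank aggregation
  to ≤10 representative foods per group, simple-mean densities, conversion
  of gram cutoffs to cube volumes, and 1-D complete-linkage clustering of
  the 52 cutoff sides into 8 core cubes plus 2 flanks.
- **Synthetic data** — seeded generators for every input (master DB, recall
  sessions, multi-dataset consumption tables with food densities), so the
  whole package builds and tests without survey data.

## Worked example

`examples/02_run_recall.py` walks one respondent through the interview:
banana and watermelon (read back together under *other fruits*), probed
brown bread (*whole grains*), purchased fried chicken (classified under
*poultry and game meat* **and** *purchased deep fried foods*), and a chicken
stew decomposed into chicken/tomato/onion. With the example point table it
prints:

```
total score      : 19.0
healthy submetric: 5.0
other submetric  : 14.0
non-low groups   :
  liquid_oils                  middle (1.0 pts)
  other_fruits                 middle (1.0 pts)
  poultry_game_meat            middle (1.0 pts)
  purchased_deep_fried_foods   middle (1.0 pts)
  whole_grains                 high (2.0 pts)
```

The one mixed dish puts liquid oils in the *middle* band via the inference
rule; the whole-grains cube pick sat exactly on the middle/high boundary
cube and the "as big or bigger" confirmation resolved it upward.

The other examples validate the shipped taxonomy and audit its cutoffs
(`01`), recover designated dominant foods from 11 synthetic consumption
datasets (`03`), and re-derive the cube design — landing within a few mm of
the printed cube sides (`04`).

## Command line

```bash
gdqs config validate            # structural validation of the taxonomy
gdqs simulate --seed 7 --out sim/
gdqs db search "banan" --db sim/master_db.csv
gdqs score sim/sessions/resp000.json --points src/gdqs/data/example_points.csv
gdqs derive-densities sim/consumption.csv sim/food_densities.csv --out derived/
gdqs design-cubes --out cubes.json
```

Artifact-producing commands write a `manifest.json` (command, seed, version,
sha256 of outputs) beside their outputs.

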