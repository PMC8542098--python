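# Methods

## The instrument

The GDQS scores a day's diet from food-group membership and per-group
quantity bands rather than from nutrient composition. The collection
instrument implemented here has three scientific components: classification
of reported foods into the group taxonomy, translation of visualized
volumes into gram bands via cubes and mean group densities, and the
derivation pipeline that chose those densities and cube sizes in the first
place.

### Taxonomy and cutoffs

At collection time the taxonomy has 26 groups carrying 54 category
boundaries: 23 cube-assessed groups with two boundaries (low/middle and
middle/high), the two high-fat dairy subgroups (hard cheese, other) with a
third high/very-high boundary each, and liquid oils with two purely
categorical boundaries (no grams, no cube — its band comes from the
inference algorithm). For reporting, the dairy subgroups merge back into
one group: 25 groups, 51 boundaries.

Each cube-assessed boundary carries an *original* gram cutoff (from the
metric's validation) and an *operationalized* cutoff — the grams implied by
the shared cube assigned to that boundary. The shipped configuration
transcribes both, plus the 10 nominal cube sides
(18, 22, 27, 32, 38, 46, 52, 55, 89, 100 mm) and the mean densities. The
package treats the **printed operationalized grams as authoritative** and
the cube sides as nominal: recomputing `density × side³` shows a systematic
few-percent drift consistent with sides rounded to the millimetre, so grams
drive categorization and sides only describe the physical aids. A
consistency report exposes the per-boundary relative deviation; everything
is within 15% except the two fish-and-shellfish cutoffs (14 g and 71 g,
~20–25% off `density × volume`), which are preserved as printed and
documented as outliers rather than "corrected".

No rounding rule is asserted for operationalized grams — the printed table
is not consistent about one — so the configuration is a transcription, not
a formula.

### Classification

Database entries are preclassified; ambiguity is handled by up to two probe
descriptors per entry whose answers map to groups (or chain to the second
probe). Mixed dishes (a culinary name, ≥2 ingredients) contribute no group
themselves; their listed (main) ingredients do. Exception foods such as
bread and cakes are single foods and are never decomposed. Purchased
deep-fried items are classified in both their food group and the purchased
deep-fried group; both tags receive read-back, cube capture and scoring
(the dual tag exists precisely so the unhealthy group is assessed, and
scoring mechanics for dual tags are otherwise unspecified — counting both
is this package's decision).

Search over names and aliases is tiered so the ranking contract is visible
in the scores: exact case-insensitive matches score 1.0; prefix matches
score in (0.9, 1.0), increasing with the matched fraction; other candidates
score `0.9 × (1 − levenshtein/max_len)` and are kept only when the raw
ratio is ≥ 0.6. Ties break by entry id, making results independent of row
order. The metric and the 0.6 floor are this package's choices — the
instrument's description names fuzzy search without fixing either.

### Quantity from cubes

A respondent visualizes the combined volume of a group's foods and picks
the closest of the 10 cubes. The category is the number of boundary cubes
the pick clears; a pick landing exactly on a boundary cube triggers the
confirmation question, with "as big or bigger" resolving to the upper band
and "smaller" to the lower. Cubes 1 and 10 carry no cutoffs, so they always
map to the lowest and highest band. Gram point estimates use the full
volume of the selected cube (`mean density × side³`), not a midpoint
between cubes, because the protocol asks for the *closest* cube.

The dairy merge converts hard-cheese grams to milk equivalents with the
factor 6.1, adds other-dairy grams, and categorizes the sum against the
merged group's original cutoffs 35 / 140 / 734 g. Addition in the gram
domain when both subgroups are reported is this package's decision; the
protocol specifies only the conversion factor and that the subgroups are
recombined for reporting.

### Liquid oils

`high` iff (deep-fried at home with pourable oil) ∨ (mixed dishes ≥ 2) ∨
(poured/used oil); `middle` when exactly one mixed dish and no trigger;
`low` otherwise. The no-trigger default of `low` is a design choice — the
rule set leaves that case open. Purchased (not home-prepared) deep-fried
food alone triggers nothing.

### Density pipeline

Per dataset (first recall per respondent only), each food's percentage gram
contribution to its group is its gram sum over respondents divided by the
group's total; the top 5 get ranks 1–5, ties broken by larger gram total
then lexicographic name. Across datasets, the candidate pool per group is
the union of ranked foods (up to 55 with 11 datasets); the mean rank is
computed **over the datasets where the food is ranked** — the alternative of
charging a penalty rank for absent datasets is exposed as `absent_rank=`.
The 10 lowest mean ranks form the representative set and the group density
is their simple mean.

Cutoff volumes are `original grams / mean density`; side lengths are cube
roots. The reduction of 52 cutoff sides to 8 core cubes uses agglomerative
clustering with complete linkage on side length (only "similar in size" is
specified; complete linkage bounds within-cluster spread, which matches the
design intent of one cube standing for visually indistinguishable sizes),
with each core side the mean of its members and flank cubes of 18 and
100 mm appended. The recovered sides land within 3 mm of a printed cube
side for at least 6 of the 8 core cubes; exact recovery is impossible
because the authors' grouping (and the per-food source densities behind
Table-level mean densities) are not published, so tests claim plausibility,
not identity.

## Synthetic data

The generators provide deterministic, seed-driven stand-ins for the three
survey inputs.

* **Master DB** (50 entries): ≥1 entry per collection group with names
  drawn from the representative food lists, two probed entries (bread:
  white/brown; cheese: a depth-2 chain hard → soft/low-fat), two mixed
  dishes, and an aliased deep-fried item.
* **Sessions**: driven through all 7 engine steps; the 12 default sessions
  cycle the full 2×3×2 grid of oil-relevant conditions (home frying × 0/1/2
  mixed dishes × pouring oil) and include boundary-cube picks with both
  confirmation answers.
* **Consumption datasets**: 11 datasets × 120 respondents × 15 foods per
  cube-assessed group by default (the liquid-oils group is excluded, as in
  the real derivation). Grams per (respondent, food) are log-normal with
  σ = 0.4 and food-level means proportional to target contribution shares;
  each food is consumed with probability 0.6; a quarter of respondents
  carry a second recall so first-recall filtering is exercised; per-food
  densities are uniform on 0.40–1.10 g/cm³. A dominance profile pins
  designated foods to target shares (realized within ~2 percentage points
  at these sample sizes; tests assert 5). With these sizes the full
  pipeline runs in seconds on one CPU.

What this does **not** emulate: real consumption is zero-inflated and
correlated within respondents and across foods (shared dishes), food name
vocabularies overlap partially across countries rather than being identical
or disjoint, and densities cluster by food type rather than being uniform.
Passing tests therefore demonstrate the pipeline's correctness and
recovery behaviour under clean conditions, not robustness to survey
messiness.

## Numerical and interface choices

* Validation is strict and named: configuration errors identify the
  offending group/boundary; probe errors list the expected answers.
* Gram comparisons at cutoffs use ≥ (an amount equal to a cutoff falls in
  the upper band, matching the borderline rule's "as big or bigger").
* All tabular I/O is UTF-8 CSV with headers; sessions and results are JSON;
  sessions round-trip losslessly including the interview step.
* The CLI is a thin delegate over the library; artifact-producing commands
  emit a manifest with output hashes so deterministic runs are auditable.
* Scoring validates that the point table covers all 25 reporting groups and
  that `very_high` points exist only for high-fat dairy; unreported groups
  score at `low`. The shipped point table is an example: the published
  point values belong to the metric's validation literature and are
  deliberately not asserted here.

## Known limitations

* The real ~2700-entry master database and the 11 source consumption
  datasets are not public; everything database- or dataset-shaped here is
  synthetic and labeled as such.
* The cube-design recovery is plausibility-level (see above).
* The interview step semantics follow the published step list at the level
  of which operations exist and their order; the exact enumerator-facing
  wording is out of scope.
* No shared-plate adjustment, sampling weights, or country-specific cutoff
  adaptation.
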