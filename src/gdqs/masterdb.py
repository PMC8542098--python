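"""Master database of preclassified foods, beverages and mixed dishes.

Every entry is preclassified into a collection-time food group.  Entries
whose group depends on extra detail (white vs brown bread, full-fat vs
skimmed milk, ...) are marked ``ambiguous`` and carry up to two probe
descriptors — follow-up questions whose answers resolve the entry to a
concrete group.  Lookup during an interview uses approximate string
matching over names and aliases so the enumerator can pick a food after
typing a few letters.

Search scoring is tiered so the contract "exact match first, prefix matches
before other fuzzy hits" is reflected directly in the returned scores:

* exact case-insensitive match on a name or alias -> score 1.0
* prefix match -> score in (0.9, 1.0), increasing with matched fraction
* other fuzzy hits -> 0.9 x (1 - levenshtein / max_len), kept only when the
  underlying ratio is at least 0.6

Ties are broken by entry id, so results are deterministic and independent
of row order in the source table.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import edlib
import pandas as pd

from .taxonomy import AssessmentMode, TaxonomyConfig, load_taxonomy

__all__ = [
    "FoodKind",
    "Probe",
    "FoodEntry",
    "SearchResult",
    "MasterDB",
    "MasterDBError",
    "load_master_db",
    "search",
    "resolve_entry",
    "make_free_text_entry",
]

AMBIGUOUS = "ambiguous"
PROBE2 = "probe2"  # answer-map target meaning "continue with the second probe"

#: minimum normalized similarity for a non-prefix fuzzy hit to be returned
FUZZY_THRESHOLD = 0.6


class MasterDBError(ValueError):
    pass


class FoodKind(str, enum.Enum):
    SINGLE_FOOD = "single_food"
    BEVERAGE = "beverage"
    MIXED_DISH = "mixed_dish"


@dataclass(frozen=True)
class Probe:
    """A follow-up question; each answer maps to a group id (or to ``probe2``)."""

    question_text: str
    answer_map: dict[str, str]


@dataclass(frozen=True)
class FoodEntry:
    entry_id: str
    name: str
    kind: FoodKind
    group_id: str  # concrete group id, or AMBIGUOUS when probes decide
    aliases: tuple[str, ...] = ()
    probe1: Probe | None = None
    probe2: Probe | None = None
    provenance: str = "database"  # "database" or "free_text_manual"


@dataclass(frozen=True)
class SearchResult:
    entry: FoodEntry
    score: float


@dataclass
class MasterDB:
    entries: dict[str, FoodEntry]

    def __len__(self) -> int:
        return len(self.entries)

    def get(self, entry_id: str) -> FoodEntry:
        return self.entries[entry_id]

    def by_name(self, name: str) -> FoodEntry | None:
        """Exact case-insensitive lookup over names and aliases."""
        needle = name.strip().lower()
        for e in sorted(self.entries.values(), key=lambda e: e.entry_id):
            if e.name.lower() == needle or any(
                a.lower() == needle for a in e.aliases
            ):
                return e
        return None


def _parse_answer_map(raw: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in str(raw).split("|"):
        part = part.strip()
        if not part:
            continue
        if ":" not in part:
            raise MasterDBError(f"malformed probe answer {part!r} (want answer:target)")
        ans, target = part.split(":", 1)
        out[ans.strip()] = target.strip()
    if not out:
        raise MasterDBError("probe answer map is empty")
    return out


def _validate_entry(entry: FoodEntry, taxonomy: TaxonomyConfig) -> None:
    valid = sorted(taxonomy.groups)
    if entry.group_id != AMBIGUOUS and entry.group_id not in taxonomy.groups:
        raise MasterDBError(
            f"entry {entry.name!r}: unknown group {entry.group_id!r}; "
            f"valid groups: {valid}"
        )
    if (
        entry.group_id == AMBIGUOUS
        and entry.probe1 is None
        and entry.kind is not FoodKind.MIXED_DISH
    ):
        # mixed dishes contribute no group themselves (ingredients do), so
        # they alone may be ambiguous without probes
        raise MasterDBError(
            f"entry {entry.name!r}: ambiguous entries require at least one probe"
        )
    for probe, is_first in ((entry.probe1, True), (entry.probe2, False)):
        if probe is None:
            continue
        for ans, target in probe.answer_map.items():
            if target == PROBE2:
                if not is_first or entry.probe2 is None:
                    raise MasterDBError(
                        f"entry {entry.name!r}: answer {ans!r} chains to a "
                        "second probe that does not exist"
                    )
            elif target not in taxonomy.groups:
                raise MasterDBError(
                    f"entry {entry.name!r}: probe answer {ans!r} targets unknown "
                    f"group {target!r}; valid groups: {valid}"
                )


def load_master_db(
    source: str | Path | pd.DataFrame,
    taxonomy: TaxonomyConfig | None = None,
) -> MasterDB:
    """Read and validate a master database table (CSV path or DataFrame).

    Required columns: ``name``, ``kind``, ``group``.  Optional: ``entry_id``,
    ``aliases`` (pipe-separated), ``probe1_question``/``probe1_map`` and
    ``probe2_question``/``probe2_map`` with maps like
    ``"white:refined_grains_baked_goods|brown:whole_grains"``.
    """
    taxonomy = taxonomy or load_taxonomy()
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    missing = {"name", "kind", "group"} - set(df.columns)
    if missing:
        raise MasterDBError(f"master DB missing required columns: {sorted(missing)}")

    entries: dict[str, FoodEntry] = {}
    seen_names: set[str] = set()
    for i, row in enumerate(df.to_dict("records")):
        name = str(row["name"]).strip()
        if not name:
            raise MasterDBError(f"row {i}: empty food name")
        key = name.lower()
        if key in seen_names:
            raise MasterDBError(f"duplicate canonical food name {name!r}")
        seen_names.add(key)
        try:
            kind = FoodKind(str(row["kind"]))
        except ValueError:
            raise MasterDBError(
                f"entry {name!r}: unknown kind {row['kind']!r}"
            ) from None
        probes: list[Probe | None] = []
        for p in ("probe1", "probe2"):
            q, m = row.get(f"{p}_question"), row.get(f"{p}_map")
            if pd.notna(m) and str(m).strip():
                probes.append(
                    Probe(
                        question_text="" if pd.isna(q) else str(q),
                        answer_map=_parse_answer_map(m),
                    )
                )
            else:
                probes.append(None)
        entry_id = str(row.get("entry_id") or f"f{i:04d}")
        if entry_id in entries:
            raise MasterDBError(f"duplicate entry id {entry_id!r}")
        aliases_raw = row.get("aliases")
        aliases = (
            tuple(a.strip() for a in str(aliases_raw).split("|") if a.strip())
            if pd.notna(aliases_raw)
            else ()
        )
        entry = FoodEntry(
            entry_id=entry_id,
            name=name,
            kind=kind,
            group_id=str(row["group"]).strip(),
            aliases=aliases,
            probe1=probes[0],
            probe2=probes[1],
        )
        _validate_entry(entry, taxonomy)
        entries[entry_id] = entry
    return MasterDB(entries=entries)


def _levenshtein_ratio(a: str, b: str) -> float:
    if not a and not b:
        return 1.0
    d = edlib.align(a, b)["editDistance"]
    return 1.0 - d / max(len(a), len(b))


def _score_entry(entry: FoodEntry, query: str) -> float:
    names = [entry.name.lower(), *(a.lower() for a in entry.aliases)]
    if any(n == query for n in names):
        return 1.0
    prefix = [n for n in names if n.startswith(query)]
    if prefix:
        return 0.9 + 0.1 * max(len(query) / len(n) for n in prefix)
    ratio = max(_levenshtein_ratio(query, n) for n in names)
    return 0.9 * ratio if ratio >= FUZZY_THRESHOLD else 0.0


def search(db: MasterDB, query: str, limit: int = 10) -> list[SearchResult]:
    """Top-``limit`` entries by similarity over names and aliases."""
    q = query.strip().lower()
    if not q:
        raise MasterDBError("search query is empty")
    scored = [
        SearchResult(entry=e, score=s)
        for e in db.entries.values()
        if (s := _score_entry(e, q)) > 0.0
    ]
    scored.sort(key=lambda r: (-r.score, r.entry.entry_id))
    return scored[:limit]


def resolve_entry(entry: FoodEntry, probe_answers: list[str] | tuple[str, ...] = ()) -> str:
    """Resolve an entry to a concrete group id given its probe answers.

    Concrete entries return their group unchanged (answers ignored).
    Ambiguous entries walk the probe chain; a missing or unrecognized answer
    raises an error listing the expected answers.
    """
    if entry.group_id != AMBIGUOUS:
        return entry.group_id
    answers = list(probe_answers)
    probe = entry.probe1
    while probe is not None:
        expected = sorted(probe.answer_map)
        if not answers:
            raise MasterDBError(
                f"entry {entry.name!r}: unresolved probe "
                f"{probe.question_text!r}; expected one of {expected}"
            )
        ans = answers.pop(0)
        if ans not in probe.answer_map:
            raise MasterDBError(
                f"entry {entry.name!r}: unknown probe answer {ans!r}; "
                f"expected one of {expected}"
            )
        target = probe.answer_map[ans]
        if target == PROBE2:
            probe = entry.probe2
            continue
        return target
    raise MasterDBError(f"entry {entry.name!r}: probe chain did not terminate")


def make_free_text_entry(
    name: str,
    kind: FoodKind,
    group_id: str,
    taxonomy: TaxonomyConfig | None = None,
    entry_id: str | None = None,
) -> FoodEntry:
    """Entry for a food absent from the database, manually classified by the
    enumerator; provenance is flagged so downstream exports can audit it."""
    taxonomy = taxonomy or load_taxonomy()
    if group_id not in taxonomy.groups:
        raise MasterDBError(
            f"free-text entry {name!r}: unknown group {group_id!r}; "
            f"valid groups: {sorted(taxonomy.groups)}"
        )
    return FoodEntry(
        entry_id=entry_id or f"freetext:{name.strip().lower()}",
        name=name.strip(),
        kind=kind,
        group_id=group_id,
        provenance="free_text_manual",
    )
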