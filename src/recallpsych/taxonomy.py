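"""Item metadata: lexical categories and serial-position bins.

Each of the 50 idea units (25 per story) belongs to exactly one lexical
category — proper_name, verb, number, or other — with fixed aggregate
counts across the two stories of 9 proper names, 14 verbs, 4 numerical
expressions, and 23 "other".  Serial position is derived from the item
index alone: items 1-8 are "primacy", 9-17 "middle", 18-25 "recency".

The bundled default category mapping is *illustrative*: it satisfies the
category counts but the per-item assignments are a plausible stand-in,
not a published scoring key.  Supply your own taxonomy file for an exact
replication of a specific scoring template.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .datamodel import N_ITEMS_PER_STORY, STORIES, all_item_keys

__all__ = [
    "CATEGORIES",
    "SERIAL_POSITIONS",
    "EXPECTED_CATEGORY_COUNTS",
    "ItemTaxonomy",
    "assign_serial_position",
    "load_taxonomy",
    "default_taxonomy",
    "category_counts",
]

CATEGORIES = ("proper_name", "verb", "number", "other")
SERIAL_POSITIONS = ("primacy", "middle", "recency")

#: aggregate lexical-category counts over both stories
EXPECTED_CATEGORY_COUNTS = {"proper_name": 9, "verb": 14, "number": 4, "other": 23}


def assign_serial_position(index: int) -> str:
    """Serial-position bin of an item index: 1-8 primacy, 9-17 middle, 18-25 recency."""
    index = int(index)
    if not 1 <= index <= N_ITEMS_PER_STORY:
        raise ValueError(f"item index must be in 1..{N_ITEMS_PER_STORY}, got {index}")
    if index <= 8:
        return "primacy"
    if index <= 17:
        return "middle"
    return "recency"


@dataclass(frozen=True)
class ItemTaxonomy:
    """Mapping of every (story, item) idea unit to its lexical category."""

    category_map: dict[tuple[str, int], str]
    label: str = "unnamed"

    def category(self, story: str, index: int) -> str:
        return self.category_map[(story, index)]

    def items_in_category(self, category: str) -> list[tuple[str, int]]:
        return [k for k, c in self.category_map.items() if c == category]

    def items_in_position(self, position: str) -> list[tuple[str, int]]:
        return [k for k in self.category_map if assign_serial_position(k[1]) == position]

    def as_frame(self) -> pd.DataFrame:
        """Long table with story, item, category and serial_position columns."""
        rows = [
            {
                "story": s,
                "item": i,
                "category": self.category_map[(s, i)],
                "serial_position": assign_serial_position(i),
            }
            for (s, i) in all_item_keys()
        ]
        return pd.DataFrame(rows)


def _validate_counts(mapping: dict[tuple[str, int], str], label: str) -> None:
    observed = {c: 0 for c in CATEGORIES}
    for cat in mapping.values():
        observed[cat] += 1
    if observed != EXPECTED_CATEGORY_COUNTS:
        raise ValueError(
            f"taxonomy {label!r}: lexical category counts {observed} deviate from the "
            f"expected {EXPECTED_CATEGORY_COUNTS}"
        )


def _build(triples, label: str, validate: bool) -> ItemTaxonomy:
    mapping: dict[tuple[str, int], str] = {}
    for story, item, category in triples:
        story = str(story).strip().upper()
        item = int(item)
        category = str(category).strip().lower()
        if story not in STORIES:
            raise ValueError(f"taxonomy {label!r}: unknown story {story!r}")
        if not 1 <= item <= N_ITEMS_PER_STORY:
            raise ValueError(f"taxonomy {label!r}: item index {item} out of range")
        if category not in CATEGORIES:
            raise ValueError(f"taxonomy {label!r}: unknown category {category!r}")
        if (story, item) in mapping:
            raise ValueError(f"taxonomy {label!r}: duplicate item ({story}, {item})")
        mapping[(story, item)] = category
    missing = [k for k in all_item_keys() if k not in mapping]
    if missing:
        raise ValueError(f"taxonomy {label!r}: missing item(s) {missing[:5]}" +
                         (" ..." if len(missing) > 5 else ""))
    if validate:
        _validate_counts(mapping, label)
    return ItemTaxonomy(category_map=mapping, label=label)


def load_taxonomy(path: str | Path, validate: bool = True) -> ItemTaxonomy:
    """Load a 50-item taxonomy from CSV/TSV (story,item,category) or YAML/JSON.

    With ``validate=True`` (default) the aggregate category counts must
    equal 9 proper names / 14 verbs / 4 numbers / 23 other.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".yaml", ".yml", ".json"):
        raw = (
            json.loads(path.read_text(encoding="utf-8"))
            if suffix == ".json"
            else yaml.safe_load(path.read_text(encoding="utf-8"))
        )
        triples = [(r["story"], r["item"], r["category"]) for r in raw]
    else:
        sep = "\t" if suffix in (".tsv", ".tab") else ","
        df = pd.read_csv(path, sep=sep)
        for col in ("story", "item", "category"):
            if col not in df.columns:
                raise ValueError(f"taxonomy file {path}: missing column {col!r}")
        triples = list(df[["story", "item", "category"]].itertuples(index=False, name=None))
    return _build(triples, label=path.name, validate=validate)


def default_taxonomy() -> ItemTaxonomy:
    """The bundled illustrative taxonomy (correct counts, stand-in per-item map)."""
    with resources.as_file(
        resources.files("recallpsych").joinpath("data/default_taxonomy.csv")
    ) as p:
        return load_taxonomy(p)


def category_counts(taxonomy: ItemTaxonomy, story: str | None = None) -> dict[str, int]:
    """Number of items per lexical category, optionally within one story."""
    counts = {c: 0 for c in CATEGORIES}
    for (s, _i), cat in taxonomy.category_map.items():
        if story is None or s == story:
            counts[cat] += 1
    return counts
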