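"""Common-data-element list generation, categorization, and export.

A concept qualifies as a CDE when it occurs at least ``min_frequency`` times
overall and in at least ``min_contexts`` distinct documentation contexts
(defaults 2 and 2).
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Mapping, Sequence

from .concepts import parse_concept
from .frequency import count_frequencies
from .odm_io import AnnotatedItem, FormDocument, write_odm

__all__ = [
    "DEFAULT_CATEGORIES",
    "CDEEntry",
    "CDEList",
    "generate_cde_list",
    "assign_categories",
    "load_category_map",
    "export_cde",
]

DEFAULT_CATEGORIES = (
    "patient data",
    "timepoints",
    "patient history",
    "laboratory",
    "medication",
    "procedures",
    "examinations",
    "diagnosis",
    "ECG",
    "outcome",
)

UNCATEGORIZED = "uncategorized"


@dataclass(frozen=True)
class CDEEntry:
    concept_key: str
    display_name: str
    absolute_frequency: int
    relative_frequency_pct: float
    contexts: frozenset[str]
    category: str = UNCATEGORIZED
    parent_key: str | None = None  # display grouping only, never counting


@dataclass
class CDEList:
    entries: list[CDEEntry]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def keys(self) -> list[str]:
        return [e.concept_key for e in self.entries]


def _corpus_fingerprint(corpus: Sequence[FormDocument]) -> str:
    digest = hashlib.sha256()
    for form in corpus:
        digest.update(form.form_id.encode())
        digest.update(form.context.encode())
        for item in form.items:
            digest.update(item.item_id.encode())
            digest.update((item.code.key if item.code else "").encode())
            digest.update(item.excluded.encode())
    return digest.hexdigest()[:16]


def generate_cde_list(
    corpus: Sequence[FormDocument],
    min_frequency: int = 2,
    min_contexts: int = 2,
    display_names: Mapping[str, str] | None = None,
    precision: int = 1,
) -> CDEList:
    """Filter the corpus vocabulary down to common data elements.

    Entries are sorted by absolute frequency descending, ties broken by
    concept key.  A corpus with fewer distinct contexts than ``min_contexts``
    is rejected (the threshold is unreachable) unless lowered explicitly.
    """
    distinct_contexts = {form.context for form in corpus}
    if len(distinct_contexts) < min_contexts:
        raise ValueError(
            f"corpus has {len(distinct_contexts)} distinct context(s); "
            f"min_contexts={min_contexts} is unreachable — lower it explicitly"
        )
    table = count_frequencies(corpus, denominator_mode="all_items")
    display_names = display_names or {}
    entries = [
        CDEEntry(
            concept_key=row.key,
            display_name=display_names.get(row.key, row.key),
            absolute_frequency=row.absolute,
            relative_frequency_pct=row.relative_rounded(precision),
            contexts=row.contexts,
        )
        for row in table.rows
        if row.absolute >= min_frequency and len(row.contexts) >= min_contexts
    ]
    provenance = {
        "corpus_fingerprint": _corpus_fingerprint(corpus),
        "parameters": {
            "min_frequency": min_frequency,
            "min_contexts": min_contexts,
            "precision": precision,
        },
    }
    return CDEList(entries=entries, provenance=provenance)


def load_category_map(path: str | Path) -> dict[str, str]:
    """Two-column CSV ``concept_key,category`` (header required)."""
    result: dict[str, str] = {}
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.reader(handle)
        next(reader, None)
        for row in reader:
            if len(row) >= 2 and row[0].strip():
                result[row[0].strip()] = row[1].strip()
    return result


def assign_categories(
    cde_list: CDEList,
    category_map: Mapping[str, str],
    categories: Sequence[str] = DEFAULT_CATEGORIES,
) -> CDEList:
    """Attach categories from ``category_map``; unmapped entries stay
    uncategorized.  A map value outside the configured category list is a
    configuration error.
    """
    allowed = set(categories)
    bad = sorted(set(category_map.values()) - allowed)
    if bad:
        raise ValueError(
            f"categories {bad} are not in the configured list {sorted(allowed)}"
        )
    entries = [
        replace(entry, category=category_map.get(entry.concept_key, UNCATEGORIZED))
        for entry in cde_list.entries
    ]
    return CDEList(entries=entries, provenance=dict(cde_list.provenance))


def export_cde(cde_list: CDEList, dest: str | Path | IO, format: str = "csv") -> None:
    """Export a CDE list as CSV or as a single ODM form (one item per entry).

    The ODM rendering round-trips through the ODM reader: re-reading it
    reproduces every canonical concept key.
    """
    if format == "csv":
        _export_csv(cde_list, dest)
    elif format == "odm":
        _export_odm(cde_list, dest)
    elif format == "json":
        _export_json(cde_list, dest)
    else:
        raise ValueError(
            f"unknown format {format!r}; supported formats: csv, odm, json"
        )


def _export_csv(cde_list: CDEList, dest: str | Path | IO) -> None:
    own = isinstance(dest, (str, Path))
    handle = open(dest, "w", newline="", encoding="utf-8") if own else dest
    try:
        writer = csv.writer(handle)
        writer.writerow(
            [
                "concept_key",
                "display_name",
                "absolute_frequency",
                "relative_frequency_pct",
                "contexts",
                "category",
                "parent_key",
            ]
        )
        for e in cde_list.entries:
            writer.writerow(
                [
                    e.concept_key,
                    e.display_name,
                    e.absolute_frequency,
                    e.relative_frequency_pct,
                    ";".join(sorted(e.contexts)),
                    e.category,
                    e.parent_key or "",
                ]
            )
    finally:
        if own:
            handle.close()


def _export_odm(cde_list: CDEList, dest: str | Path | IO) -> None:
    items = [
        AnnotatedItem(
            item_id=f"CDE.{i}",
            name=entry.display_name,
            question=entry.display_name,
            datatype="text",
            code=parse_concept(entry.concept_key),
        )
        for i, entry in enumerate(cde_list.entries, start=1)
    ]
    form = FormDocument(
        form_id="CDE.LIST",
        title="Common data elements",
        context="recommendation",
        items=items,
    )
    write_odm(form, dest)


def _export_json(cde_list: CDEList, dest: str | Path | IO) -> None:
    payload = {
        "provenance": cde_list.provenance,
        "entries": [
            {
                "concept_key": e.concept_key,
                "display_name": e.display_name,
                "absolute_frequency": e.absolute_frequency,
                "relative_frequency_pct": e.relative_frequency_pct,
                "contexts": sorted(e.contexts),
                "category": e.category,
                "parent_key": e.parent_key,
            }
            for e in cde_list.entries
        ],
    }
    if isinstance(dest, (str, Path)):
        with open(dest, "w", encoding="utf-8") as handle:
            json.dump(payload, handle, indent=2, sort_keys=True)
    else:
        json.dump(payload, dest, indent=2, sort_keys=True)
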