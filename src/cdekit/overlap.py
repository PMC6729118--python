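"""Per-context unique-concept sets and pairwise / multi-way overlap.

Overlap is the *directional relative overlap* mutual/|set| per side (not
Jaccard, which is offered as an extra column in exports).  All operations
work on unique concept-key sets: frequencies are ignored.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import IO, Sequence

import pandas as pd

from ._rounding import pct, round_half_up
from .concepts import canonical_key
from .odm_io import FormDocument

__all__ = [
    "ConceptSet",
    "OverlapResult",
    "merge_context",
    "pairwise_overlap",
    "overlap_matrix",
    "common_core",
    "matrix_to_long_csv",
    "matrix_to_square_csv",
]


@dataclass(frozen=True)
class ConceptSet:
    """A labeled set of canonical concept keys (context, hospital, ...)."""

    label: str
    keys: frozenset[str]

    @property
    def size(self) -> int:
        return len(self.keys)


def merge_context(
    forms: Sequence[FormDocument], label: str | None = None
) -> ConceptSet:
    """Union of canonical keys over non-excluded coded items of ``forms``.

    The label defaults to the (single) context shared by the forms; supply
    ``label`` explicitly when merging across labels.
    """
    if label is None:
        labels = {form.context for form in forms}
        if len(labels) > 1:
            raise ValueError(
                f"forms span several contexts {sorted(labels)}; pass label="
            )
        label = labels.pop() if labels else ""
    keys = {
        canonical_key(item.code)
        for form in forms
        for item in form.items
        if item.counted and item.code is not None
    }
    return ConceptSet(label=label, keys=frozenset(keys))


@dataclass(frozen=True)
class OverlapResult:
    """Pairwise comparison of two concept sets.

    ``rel_a`` / ``rel_b`` are full-precision percentages (mutual / own size);
    ``None`` when the respective set is empty (relative overlap undefined).
    Use :meth:`rel_a_rounded` / :meth:`rel_b_rounded` for display.
    """

    label_a: str
    label_b: str
    size_a: int
    size_b: int
    mutual: int

    @property
    def rel_a(self) -> float | None:
        return pct(self.mutual, self.size_a) if self.size_a else None

    @property
    def rel_b(self) -> float | None:
        return pct(self.mutual, self.size_b) if self.size_b else None

    @property
    def jaccard(self) -> float | None:
        union = self.size_a + self.size_b - self.mutual
        return self.mutual / union if union else None

    def rel_a_rounded(self, ndigits: int = 1) -> float | None:
        return None if self.rel_a is None else round_half_up(self.rel_a, ndigits)

    def rel_b_rounded(self, ndigits: int = 1) -> float | None:
        return None if self.rel_b is None else round_half_up(self.rel_b, ndigits)

    def swapped(self) -> "OverlapResult":
        return OverlapResult(
            self.label_b, self.label_a, self.size_b, self.size_a, self.mutual
        )


def pairwise_overlap(a: ConceptSet, b: ConceptSet) -> OverlapResult:
    """Mutual concepts and directional relative overlaps of two sets."""
    mutual = len(a.keys & b.keys)
    return OverlapResult(
        label_a=a.label,
        label_b=b.label,
        size_a=a.size,
        size_b=b.size,
        mutual=mutual,
    )


def overlap_matrix(sets: Sequence[ConceptSet]) -> list[OverlapResult]:
    """All unordered pairs exactly once, in input order."""
    if len(sets) < 2:
        raise ValueError("need at least two concept sets")
    labels = [s.label for s in sets]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate labels in {labels}")
    return [pairwise_overlap(a, b) for a, b in combinations(sets, 2)]


def common_core(sets: Sequence[ConceptSet], label: str = "common_core") -> ConceptSet:
    """Intersection of all sets (concepts present in every set)."""
    if len(sets) < 2:
        raise ValueError("need at least two concept sets")
    keys = frozenset.intersection(*(s.keys for s in sets))
    return ConceptSet(label=label, keys=keys)


def matrix_to_long_csv(
    results: Sequence[OverlapResult],
    dest: str | Path | IO,
    precision: int = 1,
    include_jaccard: bool = False,
) -> None:
    data = {
        "label_a": [r.label_a for r in results],
        "label_b": [r.label_b for r in results],
        "size_a": [r.size_a for r in results],
        "size_b": [r.size_b for r in results],
        "mutual": [r.mutual for r in results],
        "rel_a_pct": [r.rel_a_rounded(precision) for r in results],
        "rel_b_pct": [r.rel_b_rounded(precision) for r in results],
    }
    if include_jaccard:
        data["jaccard"] = [
            None if r.jaccard is None else round(r.jaccard, 4) for r in results
        ]
    pd.DataFrame(data).to_csv(dest, index=False)


def matrix_to_square_csv(
    results: Sequence[OverlapResult], dest: str | Path | IO, precision: int = 1
) -> None:
    """Square matrix of directional relative overlaps.

    Cell (row, col) is |row ∩ col| / |row| in percent; the diagonal is 100.
    """
    labels: list[str] = []
    for r in results:
        for lab in (r.label_a, r.label_b):
            if lab not in labels:
                labels.append(lab)
    frame = pd.DataFrame(index=labels, columns=labels, dtype=float)
    for lab in labels:
        frame.loc[lab, lab] = 100.0
    for r in results:
        frame.loc[r.label_a, r.label_b] = r.rel_a_rounded(precision)
        frame.loc[r.label_b, r.label_a] = r.rel_b_rounded(precision)
    frame.to_csv(dest, index_label="label")
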