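"""Concept occurrence counts, coverage statistics, and the cumulative curve.

All computations run over *non-excluded* items only.  Occurrences of the
same concept within one form count separately (forms may re-ask a concept in
follow-up subforms), so absolute frequencies can exceed the number of forms.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Sequence

import pandas as pd

from ._rounding import pct, round_half_up
from .concepts import canonical_key
from .odm_io import FormDocument

__all__ = [
    "FrequencyRow",
    "ConceptFrequencyTable",
    "CoverageCurve",
    "VocabularyStats",
    "count_frequencies",
    "annotation_coverage",
    "cumulative_coverage",
    "head_size_for_coverage",
    "head_vocabulary_share",
    "vocabulary_stats",
]

DENOMINATOR_MODES = ("all_items", "coded_items")


@dataclass(frozen=True)
class FrequencyRow:
    key: str
    absolute: int
    relative: float  # percent, full precision
    contexts: frozenset[str] = frozenset()

    def relative_rounded(self, ndigits: int = 1) -> float:
        return round_half_up(self.relative, ndigits)


@dataclass
class ConceptFrequencyTable:
    """Per-concept frequencies sorted by count descending, key ascending."""

    rows: list[FrequencyRow]
    denominator_mode: str
    total_items: int
    coded_items: int

    @property
    def unique_concepts(self) -> int:
        return len(self.rows)

    @property
    def postcoordinated_unique(self) -> int:
        return sum(1 for r in self.rows if " " in r.key)

    @property
    def singleton_unique(self) -> int:
        return sum(1 for r in self.rows if r.absolute == 1)

    @property
    def totals(self) -> dict[str, int]:
        return {
            "total_items": self.total_items,
            "coded_items": self.coded_items,
            "unique_concepts": self.unique_concepts,
            "postcoordinated_unique": self.postcoordinated_unique,
            "singleton_unique": self.singleton_unique,
        }

    def row(self, key: str) -> FrequencyRow:
        for r in self.rows:
            if r.key == key:
                return r
        raise KeyError(key)

    def to_dataframe(self, precision: int = 1) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "concept_key": [r.key for r in self.rows],
                "absolute_frequency": [r.absolute for r in self.rows],
                "relative_frequency_pct": [
                    r.relative_rounded(precision) for r in self.rows
                ],
                "contexts_present": [
                    ";".join(sorted(r.contexts)) for r in self.rows
                ],
            }
        )

    def to_csv(self, dest: str | Path | IO, precision: int = 1) -> None:
        self.to_dataframe(precision).to_csv(dest, index=False)


def count_frequencies(
    corpus: Sequence[FormDocument], denominator_mode: str = "all_items"
) -> ConceptFrequencyTable:
    """Count canonical-key occurrences over non-excluded, coded items.

    ``denominator_mode`` selects the relative-frequency denominator:
    ``all_items`` (every non-excluded item, coded or not) or ``coded_items``.
    """
    if denominator_mode not in DENOMINATOR_MODES:
        raise ValueError(
            f"denominator_mode must be one of {DENOMINATOR_MODES}, "
            f"got {denominator_mode!r}"
        )
    counts: Counter[str] = Counter()
    contexts: dict[str, set[str]] = defaultdict(set)
    total_items = 0
    coded_items = 0
    for form in corpus:
        for item in form.items:
            if not item.counted:
                continue
            total_items += 1
            if item.code is None:
                continue
            coded_items += 1
            key = canonical_key(item.code)
            counts[key] += 1
            contexts[key].add(form.context)

    denominator = total_items if denominator_mode == "all_items" else coded_items
    rows = [
        FrequencyRow(
            key=key,
            absolute=count,
            relative=pct(count, denominator) if denominator else 0.0,
            contexts=frozenset(contexts[key]),
        )
        for key, count in counts.items()
    ]
    rows.sort(key=lambda r: (-r.absolute, r.key))
    return ConceptFrequencyTable(
        rows=rows,
        denominator_mode=denominator_mode,
        total_items=total_items,
        coded_items=coded_items,
    )


def annotation_coverage(corpus: Sequence[FormDocument]) -> float | None:
    """Share (%) of non-excluded items that carry a code, two decimals.

    Returns ``None`` (explicit not-applicable) for a corpus with zero
    countable items — never 0 or 100.
    """
    total = 0
    coded = 0
    for form in corpus:
        for item in form.items:
            if not item.counted:
                continue
            total += 1
            if item.code is not None:
                coded += 1
    if total == 0:
        return None
    return round_half_up(pct(coded, total), 2)


@dataclass
class CoverageCurve:
    """Cumulative share of coded occurrences captured by the top-r concepts.

    ``points[r-1]`` is the cumulative percentage after the r most frequent
    concepts (frequency descending, canonical key ascending on ties).
    """

    points: list[float]
    cumulative_counts: list[int] = field(default_factory=list)
    coded_items: int = 0

    def __len__(self) -> int:
        return len(self.points)

    def to_dataframe(self, precision: int = 1) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": range(1, len(self.points) + 1),
                "cumulative_pct": [
                    round_half_up(p, precision) for p in self.points
                ],
            }
        )

    def to_csv(self, dest: str | Path | IO, precision: int = 1) -> None:
        self.to_dataframe(precision).to_csv(dest, index=False)

    def plot(self, dest: str | Path | IO, thresholds: Sequence[float] = (25, 50, 75)):
        """Rank vs cumulative-percentage plot with threshold markers."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(7, 4.5))
        ranks = range(1, len(self.points) + 1)
        ax.plot(ranks, self.points, lw=1.5)
        for threshold in thresholds:
            try:
                rank = head_size_for_coverage(self, threshold)
            except ValueError:
                continue
            ax.scatter([rank], [self.points[rank - 1]], zorder=3)
            ax.annotate(
                f"{threshold:g}% @ {rank}",
                (rank, self.points[rank - 1]),
                textcoords="offset points",
                xytext=(6, -10),
                fontsize=8,
            )
        ax.set_xlabel("concept rank (by frequency)")
        ax.set_ylabel("cumulative occurrences (%)")
        ax.set_ylim(0, 105)
        fig.tight_layout()
        fig.savefig(dest)
        plt.close(fig)


def cumulative_coverage(table: ConceptFrequencyTable) -> CoverageCurve:
    """Sort-and-accumulate curve over the frequency table (empty table -> empty)."""
    if not table.rows:
        return CoverageCurve(points=[], cumulative_counts=[], coded_items=0)
    coded = table.coded_items
    cumulative = 0
    counts: list[int] = []
    points: list[float] = []
    for row in table.rows:  # rows already sorted desc / key asc
        cumulative += row.absolute
        counts.append(cumulative)
        points.append(pct(cumulative, coded))
    return CoverageCurve(points=points, cumulative_counts=counts, coded_items=coded)


def head_size_for_coverage(curve: CoverageCurve, threshold_pct: float) -> int:
    """Minimal rank whose cumulative coverage reaches ``threshold_pct``.

    Reaching the threshold exactly counts (comparison is >=, with a small
    float guard so 50.0 computed as 49.999999...% still qualifies).
    """
    if not 0 < threshold_pct <= 100:
        raise ValueError("threshold_pct must be in (0, 100]")
    if not curve.points:
        raise ValueError("empty coverage curve")
    for rank, value in enumerate(curve.points, start=1):
        if value >= threshold_pct - 1e-9:
            return rank
    return len(curve.points)  # pragma: no cover - final point is 100


@dataclass(frozen=True)
class VocabularyStats:
    unique_concepts: int
    postcoordinated_unique: int
    postcoordinated_share_pct: float  # one decimal, half-up
    singleton_unique: int
    singleton_tail_start: int  # rank after which every concept is a singleton

    def head_share(self, head_size: int, ndigits: int = 1) -> float:
        """Share (%) of the vocabulary made up by a head of ``head_size``."""
        return head_vocabulary_share(head_size, self.unique_concepts, ndigits)


def head_vocabulary_share(
    head_size: int, unique_concepts: int, ndigits: int = 1
) -> float:
    if unique_concepts <= 0:
        raise ValueError("unique_concepts must be positive")
    return round_half_up(pct(head_size, unique_concepts), ndigits)


def vocabulary_stats(table: ConceptFrequencyTable) -> VocabularyStats:
    """Vocabulary-level summary: size, postcoordination share, singleton tail."""
    unique = table.unique_concepts
    post = table.postcoordinated_unique
    singles = table.singleton_unique
    share = round_half_up(pct(post, unique), 1) if unique else 0.0
    return VocabularyStats(
        unique_concepts=unique,
        postcoordinated_unique=post,
        postcoordinated_share_pct=share,
        singleton_unique=singles,
        singleton_tail_start=unique - singles,
    )
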