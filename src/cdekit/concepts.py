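"""Concept identity, coding-rule linting, and declarative code cleaning.

A medical concept is identified by a non-empty set of UMLS concept unique
identifiers (CUIs).  A single CUI is a *precoordinated* code; two or more
CUIs form a *postcoordinated* code.  Identity is the unordered, deduplicated
CUI set; its canonical rendering (sorted CUIs joined by one space) is the key
used for counting and set operations everywhere downstream.
"""

from __future__ import annotations

import csv
import re
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .odm_io import FormDocument

__all__ = [
    "CUI_PATTERN",
    "ConceptCode",
    "ConceptError",
    "CleaningMap",
    "CleaningMapError",
    "LintRules",
    "Finding",
    "ValidationReport",
    "parse_concept",
    "canonical_key",
    "apply_cleaning",
    "lint_coding",
]

#: A CUI is the letter "C" followed by exactly seven decimal digits.
CUI_PATTERN = re.compile(r"^C[0-9]{7}$")


class ConceptError(ValueError):
    """Raised for syntactically invalid concept annotations."""


@dataclass(frozen=True)
class ConceptCode:
    """An unordered, deduplicated, non-empty set of valid CUIs."""

    cuis: frozenset[str]

    def __post_init__(self) -> None:
        if not self.cuis:
            raise ConceptError("a concept code needs at least one CUI")
        for cui in self.cuis:
            if not CUI_PATTERN.match(cui):
                raise ConceptError(f"invalid CUI {cui!r} (expected C + 7 digits)")
        if not isinstance(self.cuis, frozenset):
            object.__setattr__(self, "cuis", frozenset(self.cuis))

    @property
    def precoordinated(self) -> bool:
        return len(self.cuis) == 1

    @property
    def postcoordinated(self) -> bool:
        return len(self.cuis) >= 2

    @property
    def key(self) -> str:
        return canonical_key(self)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.key


def parse_concept(text: str) -> ConceptCode:
    """Parse an annotation string into a :class:`ConceptCode`.

    The string is split on whitespace; every token must be a valid CUI.
    Duplicates and ordering are irrelevant: ``"C0450429 C0019080 C0019080"``
    parses to the same code as ``"C0019080 C0450429"``.
    """
    tokens = text.split()
    if not tokens:
        raise ConceptError("empty concept annotation")
    for token in tokens:
        if not CUI_PATTERN.match(token):
            raise ConceptError(f"invalid CUI {token!r} in annotation {text!r}")
    return ConceptCode(frozenset(tokens))


def canonical_key(code: ConceptCode) -> str:
    """Sorted, space-joined CUIs. Equal sets map to equal keys and vice versa."""
    return " ".join(sorted(code.cuis))


# ---------------------------------------------------------------------------
# Code cleaning


class CleaningMapError(ValueError):
    """Raised for cyclic or otherwise unusable cleaning maps."""


@dataclass
class CleaningMap:
    """Declarative remapping of canonical concept keys (old -> new).

    Chains (A->B, B->C) are resolved to their endpoint by :meth:`closure`;
    cycles are rejected.  After closure the map is idempotent:
    ``map(map(x)) == map(x)``.
    """

    entries: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CleaningMap":
        """Load a two-column CSV ``old_key,new_key`` (header required)."""
        entries: dict[str, str] = {}
        with open(path, newline="", encoding="utf-8") as handle:
            reader = csv.reader(handle)
            header = next(reader, None)
            if header is None or len(header) < 2:
                raise CleaningMapError(f"{path}: expected header 'old_key,new_key'")
            for lineno, row in enumerate(reader, start=2):
                if not row or not "".join(row).strip():
                    continue
                if len(row) < 2:
                    raise CleaningMapError(f"{path}:{lineno}: expected two columns")
                old = canonical_key(parse_concept(row[0]))
                new = canonical_key(parse_concept(row[1]))
                entries[old] = new
        return cls(entries)

    def closure(self) -> "CleaningMap":
        """Resolve chains to their endpoints; raise on cycles."""
        resolved: dict[str, str] = {}
        for start in self.entries:
            seen = {start}
            current = start
            while current in self.entries:
                current = self.entries[current]
                if current in seen:
                    raise CleaningMapError(
                        f"cleaning map contains a cycle through {current!r}"
                    )
                seen.add(current)
            resolved[start] = current
        return CleaningMap(resolved)

    def apply_key(self, key: str) -> str:
        return self.entries.get(key, key)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class CleaningChange:
    item_id: str
    old: str
    new: str


def apply_cleaning(
    corpus: Sequence["FormDocument"], cleaning_map: CleaningMap
) -> tuple[list["FormDocument"], list[CleaningChange]]:
    """Remap concept codes across a corpus, returning a new corpus + change log.

    The map's closure is taken first (raising :class:`CleaningMapError` on
    cycles before any change is recorded).  Items whose canonical key is not
    in the map, and uncoded items, pass through untouched.  The corpus size
    and the multiset of item ids are preserved.
    """
    closed = cleaning_map.closure()
    changes: list[CleaningChange] = []
    new_corpus: list["FormDocument"] = []
    for form in corpus:
        new_items = []
        for item in form.items:
            if item.code is not None:
                old_key = canonical_key(item.code)
                new_key = closed.apply_key(old_key)
                if new_key != old_key:
                    changes.append(CleaningChange(item.item_id, old_key, new_key))
                    item = replace(item, code=parse_concept(new_key))
            new_items.append(item)
        new_corpus.append(replace(form, items=new_items))
    return new_corpus, changes


# ---------------------------------------------------------------------------
# Coding-principle lint

#: Name patterns for items that carry no distinct medical concept.
DEFAULT_NONDISTINCT_PATTERNS = (r"^other\b", r"\bother comments?\b")
#: Name patterns for administrative / study-internal items.
DEFAULT_ADMINISTRATIVE_PATTERNS = (r"\btechnician id\b", r"\bform version\b")


@dataclass
class LintRules:
    """Configuration for :func:`lint_coding`.

    ``max_cuis`` enforces the at-most-two-codes principle; the finding is a
    warning by default because third-party files may legitimately violate it.
    """

    max_cuis: int = 2
    max_cuis_severity: str = "warning"
    nondistinct_patterns: tuple[str, ...] = DEFAULT_NONDISTINCT_PATTERNS
    administrative_patterns: tuple[str, ...] = DEFAULT_ADMINISTRATIVE_PATTERNS

    @classmethod
    def from_yaml(cls, path: str | Path) -> "LintRules":
        import yaml

        with open(path, encoding="utf-8") as handle:
            data = yaml.safe_load(handle) or {}
        kwargs = {}
        for key in ("max_cuis", "max_cuis_severity"):
            if key in data:
                kwargs[key] = data[key]
        for key in ("nondistinct_patterns", "administrative_patterns"):
            if key in data:
                kwargs[key] = tuple(data[key])
        return cls(**kwargs)


@dataclass(frozen=True)
class Finding:
    item_id: str
    rule: str
    severity: str
    message: str


@dataclass
class ValidationReport:
    findings: list[Finding] = field(default_factory=list)

    @property
    def summary(self) -> dict[str, int]:
        return dict(Counter(f.rule for f in self.findings))

    def count(self, rule: str) -> int:
        return sum(1 for f in self.findings if f.rule == rule)

    def has_severity(self, severity: str) -> bool:
        return any(f.severity == severity for f in self.findings)

    def __iter__(self) -> Iterable[Finding]:  # pragma: no cover - convenience
        return iter(self.findings)

    def __len__(self) -> int:
        return len(self.findings)


def _matches_any(name: str, patterns: Iterable[str]) -> bool:
    return any(re.search(p, name, flags=re.IGNORECASE) for p in patterns)


def lint_coding(
    corpus: Sequence["FormDocument"],
    rules: LintRules | None = None,
    apply_exclusions: bool = False,
) -> ValidationReport:
    """Check a corpus against the coding principles.

    Flags items with more than ``rules.max_cuis`` CUIs, unannotated items
    (info), and items whose name matches a nondistinct or administrative
    pattern.  With ``apply_exclusions=True`` the pattern matches additionally
    set the item's ``excluded`` flag in place, removing them from all
    downstream statistics.
    """
    rules = rules or LintRules()
    report = ValidationReport()
    for form in corpus:
        for item in form.items:
            if item.code is not None and len(item.code.cuis) > rules.max_cuis:
                report.findings.append(
                    Finding(
                        item.item_id,
                        "max-two-codes",
                        rules.max_cuis_severity,
                        f"{len(item.code.cuis)} CUIs exceed the "
                        f"{rules.max_cuis}-code limit",
                    )
                )
            if item.code is None and item.excluded == "none":
                report.findings.append(
                    Finding(item.item_id, "unannotated", "info", "item has no code")
                )
            if _matches_any(item.name, rules.nondistinct_patterns):
                report.findings.append(
                    Finding(
                        item.item_id,
                        "nondistinct-name",
                        "warning",
                        f"name {item.name!r} suggests a nondistinct item",
                    )
                )
                if apply_exclusions:
                    item.excluded = "nondistinct"
            elif _matches_any(item.name, rules.administrative_patterns):
                report.findings.append(
                    Finding(
                        item.item_id,
                        "administrative-name",
                        "warning",
                        f"name {item.name!r} suggests administrative content",
                    )
                )
                if apply_exclusions:
                    item.excluded = "administrative"
    return report
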