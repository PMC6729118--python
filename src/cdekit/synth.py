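"""Seeded synthetic ODM corpora with the statistical shape the analysis
assumes: several documentation contexts drawing from a shared core
vocabulary plus context-private vocabularies, long-tailed (Zipf) concept
frequencies, partial annotatability, and a small postcoordination rate.

Every generated corpus comes with a :class:`GeneratorLedger` holding the
ground truth (true occurrence counts, per-context usage, unannotated count,
postcoordinated vocabulary), so pipeline measurements can be checked against
what was actually emitted rather than against expectations.
"""

from __future__ import annotations

import json
import random
from collections import Counter
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from .concepts import ConceptCode
from .odm_io import DATATYPES, AnnotatedItem, FormDocument, write_odm

__all__ = [
    "ContextSpec",
    "SynthConfig",
    "GeneratorLedger",
    "generate_corpus",
    "paper_like_preset",
    "exact_counts_corpus",
    "write_corpus",
]

#: Synthetic CUIs live in the C9xxxxxx block so they can never collide with
#: real codes used in documentation examples (C0001779, C1532338, ...).
_SYNTH_CUI_BASE = 9_000_000

_ITEM_DATATYPES = tuple(sorted(DATATYPES - {"codelist"})) + ("codelist",)


@dataclass(frozen=True)
class ContextSpec:
    label: str
    n_forms: int
    items_per_form: tuple[int, int]  # inclusive range


@dataclass
class SynthConfig:
    seed: int
    contexts: list[ContextSpec]
    core_vocab_size: int
    private_vocab_size_per_context: int
    zipf_exponent: float = 1.0
    p_annotatable: float = 0.98
    p_postcoordinated: float = 0.06
    p_repeat_within_form: float = 0.1

    def validate(self) -> None:
        for p_name in ("p_annotatable", "p_postcoordinated", "p_repeat_within_form"):
            p = getattr(self, p_name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{p_name}={p} outside [0, 1]")
        if self.core_vocab_size < 0 or self.private_vocab_size_per_context < 0:
            raise ValueError("vocabulary sizes must be >= 0")
        if self.zipf_exponent <= 0:
            raise ValueError("zipf_exponent must be > 0")
        total_vocab = self.core_vocab_size + self.private_vocab_size_per_context
        wants_items = any(
            c.n_forms > 0 and c.items_per_form[1] > 0 for c in self.contexts
        )
        if wants_items and total_vocab == 0:
            raise ValueError("cannot draw items from an empty vocabulary")
        for c in self.contexts:
            lo, hi = c.items_per_form
            if lo < 0 or hi < lo:
                raise ValueError(f"bad items_per_form range {c.items_per_form}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SynthConfig":
        with open(path, encoding="utf-8") as handle:
            data = yaml.safe_load(handle)
        contexts = [
            ContextSpec(
                label=c["label"],
                n_forms=int(c["n_forms"]),
                items_per_form=tuple(c["items_per_form"]),
            )
            for c in data.pop("contexts")
        ]
        return cls(contexts=contexts, **data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["contexts"] = [
            {
                "label": c.label,
                "n_forms": c.n_forms,
                "items_per_form": list(c.items_per_form),
            }
            for c in self.contexts
        ]
        with open(path, "w", encoding="utf-8") as handle:
            yaml.safe_dump(data, handle, sort_keys=True)


@dataclass
class GeneratorLedger:
    """Ground truth for a generated corpus."""

    #: canonical key -> "core" or the owning context label
    assignment: dict[str, str] = field(default_factory=dict)
    #: canonical key -> number of coded occurrences emitted
    occurrence_counts: Counter = field(default_factory=Counter)
    #: context label -> canonical key -> coded occurrences in that context
    per_context_counts: dict[str, Counter] = field(default_factory=dict)
    #: items emitted without a code
    unannotated_count: int = 0
    #: canonical keys of postcoordinated vocabulary concepts (used or not)
    postcoordinated_keys: list[str] = field(default_factory=list)
    #: full vocabulary keys in creation order
    vocabulary: list[str] = field(default_factory=list)

    @property
    def coded_occurrences(self) -> int:
        return sum(self.occurrence_counts.values())

    @property
    def used_vocabulary(self) -> set[str]:
        return set(self.occurrence_counts)

    def context_used_keys(self, label: str) -> set[str]:
        return set(self.per_context_counts.get(label, ()))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "assignment": self.assignment,
            "occurrence_counts": dict(self.occurrence_counts),
            "per_context_counts": {
                k: dict(v) for k, v in self.per_context_counts.items()
            },
            "unannotated_count": self.unannotated_count,
            "postcoordinated_keys": self.postcoordinated_keys,
            "vocabulary": self.vocabulary,
        }
        with open(path, "w", encoding="utf-8") as handle:
            json.dump(payload, handle, indent=1, sort_keys=True)


def _make_vocabulary(
    config: SynthConfig, rng: random.Random
) -> tuple[list[ConceptCode], dict[str, list[ConceptCode]], list[str]]:
    """Build core + private concept pools with synthetic CUIs."""
    counter = 0
    postcoordinated: list[str] = []

    def next_cui() -> str:
        nonlocal counter
        counter += 1
        return f"C{_SYNTH_CUI_BASE + counter:07d}"

    def make_concept() -> ConceptCode:
        if rng.random() < config.p_postcoordinated:
            code = ConceptCode(frozenset({next_cui(), next_cui()}))
            postcoordinated.append(code.key)
        else:
            code = ConceptCode(frozenset({next_cui()}))
        return code

    core = [make_concept() for _ in range(config.core_vocab_size)]
    private = {
        spec.label: [
            make_concept() for _ in range(config.private_vocab_size_per_context)
        ]
        for spec in config.contexts
    }
    return core, private, postcoordinated


def generate_corpus(
    config: SynthConfig,
) -> tuple[list[FormDocument], GeneratorLedger]:
    """Generate a deterministic multi-context form corpus.

    Concept sampling weights follow weight ∝ rank^-exponent over a seeded
    global ranking of the pooled vocabulary; each context samples from
    core ∪ its private pool with renormalized weights.  With probability
    ``p_repeat_within_form`` an item re-asks a concept already used in the
    same form; with probability ``1 - p_annotatable`` an item is emitted
    without a code.
    """
    config.validate()
    rng = random.Random(config.seed)
    core, private, postcoordinated = _make_vocabulary(config, rng)

    pool: list[ConceptCode] = list(core)
    for spec in config.contexts:
        pool.extend(private[spec.label])

    # Deterministic rank assignment over the pooled vocabulary: shared core
    # concepts take the top ranks (the most frequent concepts are the ones
    # every context asks for), private pools interleave round-robin behind
    # them so every context sees the same weight profile.
    ranked: list[ConceptCode] = list(core)
    private_lists = [private[spec.label] for spec in config.contexts]
    for depth in range(config.private_vocab_size_per_context):
        for plist in private_lists:
            ranked.append(plist[depth])
    weight_of = {
        code.key: (rank + 1) ** -config.zipf_exponent
        for rank, code in enumerate(ranked)
    }

    ledger = GeneratorLedger(
        postcoordinated_keys=list(postcoordinated),
        vocabulary=[c.key for c in pool],
    )
    for code in core:
        ledger.assignment[code.key] = "core"
    for spec in config.contexts:
        for code in private[spec.label]:
            ledger.assignment[code.key] = spec.label

    forms: list[FormDocument] = []
    form_no = 0
    for spec in config.contexts:
        accessible = core + private[spec.label]
        weights = [weight_of[c.key] for c in accessible]
        ledger.per_context_counts.setdefault(spec.label, Counter())
        for _ in range(spec.n_forms):
            form_no += 1
            form_id = f"F{form_no:03d}"
            n_items = rng.randint(*spec.items_per_form)
            used_in_form: list[ConceptCode] = []
            items: list[AnnotatedItem] = []
            for item_no in range(1, n_items + 1):
                if used_in_form and rng.random() < config.p_repeat_within_form:
                    concept = rng.choice(used_in_form)
                else:
                    concept = rng.choices(accessible, weights=weights, k=1)[0]
                coded = rng.random() < config.p_annotatable
                datatype = rng.choice(_ITEM_DATATYPES)
                item = AnnotatedItem(
                    item_id=f"{form_id}.I{item_no:03d}",
                    name=f"Item {item_no} ({spec.label})",
                    question=f"Synthetic question {form_no}.{item_no}",
                    datatype=datatype,
                    code=concept if coded else None,
                )
                items.append(item)
                if coded:
                    used_in_form.append(concept)
                    ledger.occurrence_counts[concept.key] += 1
                    ledger.per_context_counts[spec.label][concept.key] += 1
                else:
                    ledger.unannotated_count += 1
            forms.append(
                FormDocument(
                    form_id=form_id,
                    title=f"Synthetic form {form_no} ({spec.label})",
                    context=spec.label,
                    items=items,
                )
            )
    return forms, ledger


def paper_like_preset(seed: int = 1) -> SynthConfig:
    """A corpus shaped like a multi-context clinical-form collection:
    86 forms, ~3600-3700 items over 7 documentation contexts, ~98%
    annotatability, ~6% postcoordination, and a head-heavy Zipf frequency
    profile in which roughly the top 7% of the observed vocabulary covers
    half of all coded occurrences while well over 40% of observed concepts
    are singletons.

    Calibration constants (found by simulation over many seeds): core=120
    shared concepts, 400 private concepts per context, Zipf exponent 0.6
    over the deterministic pooled ranking, 12% within-form repeat rate.
    Observed over seeds 1-999: 3470-3710 items, 805-861 unique concepts,
    head-at-50% fraction 6.0-6.6% of the vocabulary, singleton share 56-63%.
    """
    contexts = [
        ContextSpec("routine", 25, (30, 50)),
        ContextSpec("registry", 7, (60, 100)),
        ContextSpec("study_crf", 2, (250, 350)),
        ContextSpec("eligibility", 34, (12, 32)),
        ContextSpec("quality_assurance", 6, (40, 60)),
        ContextSpec("recommendation", 2, (120, 180)),
        ContextSpec("risk_score", 10, (8, 14)),
    ]
    return SynthConfig(
        seed=seed,
        contexts=contexts,
        core_vocab_size=120,
        private_vocab_size_per_context=400,
        zipf_exponent=0.6,
        p_annotatable=0.98,
        p_postcoordinated=0.06,
        p_repeat_within_form=0.12,
    )


def exact_counts_corpus(
    total_items: int,
    coded_items: int,
    key_counts: Sequence[tuple[str, int]] = (),
    n_contexts: int = 2,
    items_per_form: int = 100,
    seed: int = 0,
) -> list[FormDocument]:
    """Deterministic corpus with exact item/coding totals.

    ``key_counts`` forces specific canonical keys to occur a given number of
    times; the remaining coded items are filled with distinct synthetic
    concepts.  Forms are spread round-robin over ``n_contexts`` contexts.
    Useful for exercising reporting arithmetic with known inputs.
    """
    if coded_items > total_items:
        raise ValueError("coded_items cannot exceed total_items")
    forced = sum(count for _, count in key_counts)
    if forced > coded_items:
        raise ValueError("forced key counts exceed coded_items")

    codes: list[ConceptCode | None] = []
    for key, count in key_counts:
        concept = ConceptCode(frozenset(key.split()))
        codes.extend([concept] * count)
    filler_base = _SYNTH_CUI_BASE + 500_000 + seed % 100_000
    for i in range(coded_items - forced):
        codes.append(ConceptCode(frozenset({f"C{filler_base + i:07d}"})))
    codes.extend([None] * (total_items - coded_items))

    contexts = [f"context_{c + 1}" for c in range(n_contexts)]
    forms: list[FormDocument] = []
    for start in range(0, total_items, items_per_form):
        chunk = codes[start : start + items_per_form]
        form_no = len(forms) + 1
        items = [
            AnnotatedItem(
                item_id=f"X{form_no:03d}.I{i:03d}",
                name=f"Item {i}",
                datatype="text",
                code=code,
            )
            for i, code in enumerate(chunk, start=1)
        ]
        forms.append(
            FormDocument(
                form_id=f"X{form_no:03d}",
                title=f"Fixed-count form {form_no}",
                context=contexts[(form_no - 1) % n_contexts],
                items=items,
            )
        )
    return forms


def write_corpus(
    forms: Sequence[FormDocument],
    ledger: GeneratorLedger | None,
    out_dir: str | Path,
) -> Path:
    """Write one ODM file per form plus a sidecar context map (and ledger)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    context_map = []
    for form in forms:
        filename = f"{form.form_id}.xml"
        write_odm(form, out / filename)
        context_map.append(
            {"path": filename, "context": form.context, "form_id": form.form_id}
        )
    with open(out / "context_map.yaml", "w", encoding="utf-8") as handle:
        yaml.safe_dump({"forms": context_map}, handle, sort_keys=False)
    if ledger is not None:
        ledger.to_json(out / "ledger.json")
    return out
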