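import random

import pytest
from hypothesis import strategies as st

from cdekit.concepts import ConceptCode
from cdekit.odm_io import DATATYPES, AnnotatedItem, FormDocument

# ---------------------------------------------------------------------------
# Hypothesis strategies


def cui_strategy():
    return st.integers(min_value=0, max_value=9_999_999).map(lambda n: f"C{n:07d}")


def concept_code_strategy(max_cuis: int = 3):
    return st.frozensets(cui_strategy(), min_size=1, max_size=max_cuis).map(
        ConceptCode
    )


def annotated_item_strategy(item_id: str):
    return st.builds(
        AnnotatedItem,
        item_id=st.just(item_id),
        name=st.text(
            alphabet=st.characters(whitelist_categories=("L", "N"), max_codepoint=127),
            min_size=1,
            max_size=20,
        ),
        question=st.text(
            alphabet=st.characters(whitelist_categories=("L", "N", "Z"), max_codepoint=127),
            max_size=40,
        ).map(str.strip),
        datatype=st.sampled_from(sorted(DATATYPES)),
        code=st.one_of(st.none(), concept_code_strategy()),
        excluded=st.sampled_from(["none", "none", "none", "nondistinct", "administrative"]),
    )


@st.composite
def form_strategy(draw, min_items: int = 0, max_items: int = 8):
    n = draw(st.integers(min_value=min_items, max_value=max_items))
    items = [draw(annotated_item_strategy(f"I.{i}")) for i in range(1, n + 1)]
    form_id = draw(st.from_regex(r"F[0-9]{1,4}", fullmatch=True))
    title = draw(st.text(min_size=1, max_size=30, alphabet="abcdefgh XYZ"))
    context = draw(
        st.sampled_from(["routine", "registry", "risk_score", "eligibility"])
    )
    return FormDocument(form_id=form_id, title=title.strip() or "t", context=context, items=items)


# ---------------------------------------------------------------------------
# Seeded random corpora (plain ``random``-based, independent of cdekit.synth)


def random_corpus(rng: random.Random, n_forms=5, max_items=30, vocab=40, n_contexts=3):
    """Small random corpus built without the synth module (for oracle tests)."""
    vocab_codes = []
    for i in range(vocab):
        if rng.random() < 0.15:
            cuis = frozenset({f"C{100 + i:07d}", f"C{5000 + i:07d}"})
        else:
            cuis = frozenset({f"C{100 + i:07d}"})
        vocab_codes.append(ConceptCode(cuis))
    forms = []
    for f in range(n_forms):
        items = []
        for j in range(rng.randint(0, max_items)):
            code = rng.choice(vocab_codes) if rng.random() < 0.9 else None
            excluded = "nondistinct" if rng.random() < 0.05 else "none"
            items.append(
                AnnotatedItem(
                    item_id=f"F{f}.I{j}",
                    name=f"item {j}",
                    datatype="text",
                    code=code,
                    excluded=excluded,
                )
            )
        forms.append(
            FormDocument(
                form_id=f"F{f}",
                title=f"Form {f}",
                context=f"ctx{f % n_contexts}",
                items=items,
            )
        )
    return forms


@pytest.fixture
def rng():
    return random.Random(20240901)


@pytest.fixture
def small_corpus(rng):
    return random_corpus(rng)
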