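# cdekit

Semantic comparison of UMLS-annotated clinical form definitions.

`cdekit` ingests CDISC ODM 1.3.x form metadata whose items carry UMLS
concept unique identifiers (CUIs) as `Alias` annotations, and computes:

- **concept frequencies** — absolute and relative occurrence counts per
  canonical concept (a concept is an unordered set of CUIs: one CUI =
  precoordinated, two or more = postcoordinated),
- **annotation coverage** — the share of form items that could be coded,
- **cumulative coverage curves** — how many top-ranked concepts are needed
  to cover a given share of all concept occurrences,
- **cross-context overlap** — directional relative overlap of the unique
  concept sets of documentation contexts (routine care, registries, study
  CRFs, eligibility criteria, quality assurance, recommendations, risk
  scores) or hospitals,
- **common data element (CDE) lists** — concepts passing frequency (≥2) and
  context (≥2) thresholds, optionally categorized and exported as CSV/ODM.

A seeded synthetic corpus generator (`cdekit.synth`) produces multi-context
ODM corpora with a shared core vocabulary, Zipf-distributed concept
frequencies, partial annotatability and a small postcoordination rate —
together with a ground-truth ledger — so the whole pipeline is testable
without any external data.

## CLI

```bash
# generate a synthetic 86-form corpus with ground truth
cdekit simulate --preset --seed 1 --out corpus/

# coding-principle checks (max two CUIs per item, nondistinct names, ...)
cdekit validate corpus/*.xml --context-map corpus/context_map.yaml --out checks/

# frequency table, coverage curve, vocabulary stats
cdekit analyze corpus/*.xml --context-map corpus/context_map.yaml --out analysis/

# pairwise context overlap matrices
cdekit overlap corpus/*.xml --context-map corpus/context_map.yaml --out overlaps/

# filtered, categorized common-data-element list
cdekit cde corpus/*.xml --context-map corpus/context_map.yaml \
    --min-frequency 2 --min-contexts 2 --out cde/
```

Common flags: `--cleaning-map old_key,new_key.csv` applies a declarative
concept remapping (the manual code-cleaning step); `--denominator
{all,coded}` selects the relative-frequency denominator; `--precision`
controls rounded display; `--force` allows writing into a non-empty output
directory; every run writes a `provenance.json` next to its outputs.
Outputs are byte-identical across repeated runs on fixed inputs and seeds.

## Library

```python
from cdekit import (
    generate_corpus, paper_like_preset,
    count_frequencies, cumulative_coverage, head_size_for_coverage,
    merge_context, overlap_matrix, generate_cde_list,
)

forms, ledger = generate_corpus(paper_like_preset(seed=1))
table = count_frequencies(forms)                  # per-concept counts
curve = cumulative_coverage(table)                # sorted cumulative %
head = head_size_for_coverage(curve, 50)          # concepts covering 50%
cde = generate_cde_list(forms, min_frequency=2, min_contexts=2)
```

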