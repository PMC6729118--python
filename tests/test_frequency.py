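import random

import pytest

from cdekit.concepts import parse_concept
from cdekit.frequency import (
    ConceptFrequencyTable,
    FrequencyRow,
    annotation_coverage,
    count_frequencies,
    cumulative_coverage,
    head_size_for_coverage,
    head_vocabulary_share,
    vocabulary_stats,
)
from cdekit.odm_io import AnnotatedItem, FormDocument
from cdekit.synth import exact_counts_corpus

from conftest import random_corpus


# --- independent oracles -----------------------------------------------------


def brute_force_counts(corpus):
    """Flat scan with a plain dict; the oracle for count_frequencies."""
    counts = {}
    total = coded = 0
    for form in corpus:
        for item in form.items:
            if item.excluded != "none":
                continue
            total += 1
            if item.code is None:
                continue
            coded += 1
            key = " ".join(sorted(item.code.cuis))
            counts[key] = counts.get(key, 0) + 1
    return counts, total, coded


def brute_force_curve(counts, coded):
    """Sort-and-prefix-sum oracle for cumulative_coverage."""
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    out, cum = [], 0
    for _, c in ordered:
        cum += c
        out.append(cum / coded * 100)
    return out


def brute_force_head(curve_points, threshold):
    for rank, value in enumerate(curve_points, 1):
        if value >= threshold - 1e-9:
            return rank
    return len(curve_points)


# --- count_frequencies -------------------------------------------------------


class TestCountFrequencies:
    def test_single_coded_item(self):
        corpus = [
            FormDocument(
                form_id="F1", title="t", context="routine",
                items=[AnnotatedItem("I1", "n", code=parse_concept("C0000001"))],
            )
        ]
        table = count_frequencies(corpus)
        assert len(table.rows) == 1
        assert table.rows[0].absolute == 1
        assert table.rows[0].relative == 100.0

    def test_paper_style_arithmetic(self):
        corpus = exact_counts_corpus(3710, 3637, key_counts=[("C1532338", 98)])
        table = count_frequencies(corpus, denominator_mode="all_items")
        row = table.row("C1532338")
        assert row.absolute == 98
        assert row.relative_rounded(1) == 2.6

    def test_coded_items_denominator(self):
        corpus = exact_counts_corpus(10, 5, key_counts=[("C0000001", 5)])
        table = count_frequencies(corpus, denominator_mode="coded_items")
        assert table.row("C0000001").relative == 100.0

    def test_excluded_items_never_counted(self):
        items = [
            AnnotatedItem("I1", "n", code=parse_concept("C0000001")),
            AnnotatedItem(
                "I2", "n", code=parse_concept("C0000001"), excluded="nondistinct"
            ),
        ]
        corpus = [FormDocument(form_id="F1", title="t", context="c", items=items)]
        table = count_frequencies(corpus)
        assert table.total_items == 1
        assert table.row("C0000001").absolute == 1

    def test_empty_corpus(self):
        table = count_frequencies([])
        assert table.rows == []
        assert table.totals == {
            "total_items": 0,
            "coded_items": 0,
            "unique_concepts": 0,
            "postcoordinated_unique": 0,
            "singleton_unique": 0,
        }

    def test_bad_mode_rejected(self):
        with pytest.raises(ValueError, match="denominator_mode"):
            count_frequencies([], denominator_mode="nope")

    @pytest.mark.parametrize("seed", range(5))
    def test_oracle_equivalence(self, seed):
        corpus = random_corpus(random.Random(seed), n_forms=8, max_items=70)
        table = count_frequencies(corpus)
        counts, total, coded = brute_force_counts(corpus)
        assert {r.key: r.absolute for r in table.rows} == counts
        assert table.total_items == total
        assert table.coded_items == coded
        assert sum(r.absolute for r in table.rows) == coded

    def test_form_order_invariance(self, rng):
        corpus = random_corpus(rng, n_forms=10)
        table_a = count_frequencies(corpus)
        shuffled = list(corpus)
        rng.shuffle(shuffled)
        table_b = count_frequencies(shuffled)
        assert table_a.rows == table_b.rows

    def test_contexts_present(self):
        forms = [
            FormDocument(
                form_id=f"F{i}", title="t", context=ctx,
                items=[AnnotatedItem("I1", "n", code=parse_concept("C0000001"))],
            )
            for i, ctx in enumerate(["routine", "registry"])
        ]
        table = count_frequencies(forms)
        assert table.rows[0].contexts == frozenset({"routine", "registry"})


# --- annotation_coverage -----------------------------------------------------


class TestAnnotationCoverage:
    def test_paper_arithmetic(self):
        corpus = exact_counts_corpus(3710, 3637)
        assert annotation_coverage(corpus) == 98.03

    def test_fully_coded(self):
        corpus = exact_counts_corpus(50, 50)
        assert annotation_coverage(corpus) == 100.00

    def test_zero_items_not_applicable(self):
        assert annotation_coverage([]) is None
        empty = [FormDocument(form_id="F1", title="t", context="c", items=[])]
        assert annotation_coverage(empty) is None

    def test_binomial_sampling(self):
        rng = random.Random(7)
        items = [
            AnnotatedItem(
                f"I{i}", "n",
                code=parse_concept("C0000001") if rng.random() < 0.9 else None,
            )
            for i in range(1000)
        ]
        corpus = [FormDocument(form_id="F1", title="t", context="c", items=items)]
        assert abs(annotation_coverage(corpus) - 90.0) < 2.0


# --- cumulative coverage and head size --------------------------------------


def table_from_counts(counts, coded=None):
    coded = coded if coded is not None else sum(counts.values())
    rows = [
        FrequencyRow(key=k, absolute=v, relative=v / coded * 100)
        for k, v in counts.items()
    ]
    rows.sort(key=lambda r: (-r.absolute, r.key))
    return ConceptFrequencyTable(
        rows=rows, denominator_mode="coded_items",
        total_items=coded, coded_items=coded,
    )


class TestCumulativeCoverage:
    def test_forced_arithmetic(self):
        table = table_from_counts({"C0000001": 3, "C0000002": 2, "C0000003": 1})
        curve = cumulative_coverage(table)
        assert [round(p, 1) for p in curve.points] == [50.0, 83.3, 100.0]

    def test_uniform_is_linear(self):
        table = table_from_counts({f"C{i:07d}": 4 for i in range(5)})
        curve = cumulative_coverage(table)
        assert curve.points == pytest.approx([20, 40, 60, 80, 100])

    def test_empty_table(self):
        assert cumulative_coverage(count_frequencies([])).points == []

    @pytest.mark.parametrize("seed", range(5))
    def test_oracle_equivalence(self, seed):
        rng = random.Random(100 + seed)
        counts = {f"C{i:07d}": rng.randint(1, 30) for i in range(rng.randint(1, 60))}
        table = table_from_counts(counts)
        curve = cumulative_coverage(table)
        assert curve.points == pytest.approx(
            brute_force_curve(counts, sum(counts.values()))
        )

    def test_monotone_and_terminates_at_100(self, rng):
        corpus = random_corpus(rng, n_forms=8, max_items=60)
        curve = cumulative_coverage(count_frequencies(corpus))
        assert all(a <= b + 1e-12 for a, b in zip(curve.points, curve.points[1:]))
        assert curve.points[-1] == pytest.approx(100.0)


class TestHeadSize:
    def test_trivial_curve(self):
        table = table_from_counts({"C0000001": 3, "C0000002": 2, "C0000003": 1})
        curve = cumulative_coverage(table)
        assert head_size_for_coverage(curve, 50) == 1
        assert head_size_for_coverage(curve, 100) == 3

    def test_exact_threshold_counts(self):
        table = table_from_counts({"C0000001": 1, "C0000002": 1})
        curve = cumulative_coverage(table)
        assert head_size_for_coverage(curve, 50) == 1

    def test_empty_curve_error(self):
        with pytest.raises(ValueError):
            head_size_for_coverage(cumulative_coverage(count_frequencies([])), 50)

    def test_bad_threshold(self):
        table = table_from_counts({"C0000001": 1})
        curve = cumulative_coverage(table)
        for t in (0, -1, 101):
            with pytest.raises(ValueError):
                head_size_for_coverage(curve, t)

    @pytest.mark.parametrize("seed", range(5))
    def test_linear_scan_oracle(self, seed):
        rng = random.Random(200 + seed)
        counts = {f"C{i:07d}": rng.randint(1, 20) for i in range(rng.randint(1, 40))}
        curve = cumulative_coverage(table_from_counts(counts))
        for threshold in (5, 25, 50, 75, 99, 100):
            assert head_size_for_coverage(curve, threshold) == brute_force_head(
                curve.points, threshold
            )

    def test_monotone_in_threshold(self, rng):
        corpus = random_corpus(rng, n_forms=6, max_items=50)
        curve = cumulative_coverage(count_frequencies(corpus))
        sizes = [head_size_for_coverage(curve, t) for t in range(1, 101)]
        assert sizes == sorted(sizes)


# --- vocabulary stats --------------------------------------------------------


class TestVocabularyStats:
    def test_paper_arithmetic(self):
        counts = {f"C{i:07d} C{9000 + i:07d}": 2 for i in range(52)}
        counts.update({f"C{1000 + i:07d}": 2 for i in range(842 - 52)})
        stats = vocabulary_stats(table_from_counts(counts))
        assert stats.unique_concepts == 842
        assert stats.postcoordinated_unique == 52
        assert stats.postcoordinated_share_pct == 6.2

    def test_no_postcoordinated(self):
        stats = vocabulary_stats(table_from_counts({"C0000001": 3}))
        assert stats.postcoordinated_share_pct == 0.0

    def test_head_vocabulary_share(self):
        assert head_vocabulary_share(60, 842) == 7.1

    def test_singleton_tail(self):
        counts = {"C0000001": 5, "C0000002": 2, "C0000003": 1, "C0000004": 1}
        stats = vocabulary_stats(table_from_counts(counts))
        assert stats.singleton_unique == 2
        assert stats.singleton_tail_start == 2


# --- exports -----------------------------------------------------------------


class TestExports:
    def test_frequency_csv(self, tmp_path, small_corpus):
        table = count_frequencies(small_corpus)
        path = tmp_path / "freq.csv"
        table.to_csv(path)
        lines = path.read_text().strip().splitlines()
        assert lines[0] == (
            "concept_key,absolute_frequency,relative_frequency_pct,contexts_present"
        )
        assert len(lines) == len(table.rows) + 1

    def test_curve_csv_and_plot(self, tmp_path, small_corpus):
        curve = cumulative_coverage(count_frequencies(small_corpus))
        curve.to_csv(tmp_path / "curve.csv")
        assert (tmp_path / "curve.csv").exists()
        curve.plot(tmp_path / "curve.png")
        assert (tmp_path / "curve.png").stat().st_size > 0
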