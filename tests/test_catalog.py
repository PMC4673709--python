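"""CNV records: spans, annotation, frequency conversion, breakpoints."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cnv_evodyn.catalog import (
    AmbiguousBreakpointError,
    CnvCall,
    RepeatPair,
    annotate,
    frequency_from_copy,
    infer_crossover_interval,
    load_deletions,
    load_duplications,
    percent_identity,
    read_catalog_tsv,
    span,
    summarize,
    write_catalog_tsv,
)
from cnv_evodyn.synthetic import Feature, GenomeModel


def call(start, end, kind="duplication", c=1.5, chrom="I", pop="P"):
    return CnvCall(
        population=pop, chromosome=chrom, start=start, end=end, kind=kind,
        copy_number=c,
    )


class TestSpan:
    @pytest.mark.parametrize(
        "start, end, expected",
        [
            (6_837_055, 6_879_497, 42_443),
            (14_037_517, 14_039_164, 1_648),
            (5, 5, 1),
        ],
    )
    def test_inclusive_arithmetic(self, start, end, expected):
        assert span(call(start, end)) == expected

    def test_all_printed_duplication_spans(self, fixtures):
        from cnv_evodyn.catalog import load_printed_spans

        table = load_printed_spans("duplication")
        for row, c in zip(table.itertuples(), fixtures.duplications):
            assert span(c) == row.span_bp

    def test_all_printed_deletion_spans(self, fixtures):
        from cnv_evodyn.catalog import load_printed_spans

        table = load_printed_spans("deletion")
        for row, c in zip(table.itertuples(), fixtures.deletions):
            assert span(c) == row.span_bp


class TestAnnotate:
    def _genome(self):
        feats = (
            Feature("I", 100, 200, "protein_coding", "g1"),
            Feature("I", 300, 400, "protein_coding", "g2"),
            Feature("I", 500, 600, "protein_coding", "g3"),
            Feature("I", 700, 750, "trna", "t1"),
        )
        return GenomeModel((("I", 1000),), probe_spacing=10, features=feats)

    def test_no_overlap_counts_zero(self):
        counts = annotate(call(800, 900), self._genome())
        assert sum(counts.values()) == 0

    def test_exact_cover_counts_all(self):
        counts = annotate(call(100, 600), self._genome())
        assert counts["protein_coding"] == 3
        assert counts["trna"] == 0

    def test_partial_overlap_counts(self):
        # ends one bp inside g2: partial overlap still counts
        counts = annotate(call(50, 300), self._genome())
        assert counts["protein_coding"] == 2

    def test_unknown_chromosome_raises(self):
        with pytest.raises(KeyError):
            annotate(call(1, 10, chrom="XII"), self._genome())


class TestFrequencyFromCopy:
    def test_duplication_above_two_clips_to_fixation(self):
        assert frequency_from_copy(call(1, 10, "duplication", c=2.19)) == 1.0

    def test_deep_deletion(self):
        assert frequency_from_copy(call(1, 10, "deletion", c=0.04)) == pytest.approx(0.96)

    def test_no_change_gives_zero(self):
        assert frequency_from_copy(call(1, 10, "duplication", c=1.0)) == 0.0
        assert frequency_from_copy(call(1, 10, "deletion", c=1.0)) == 0.0

    @given(q=st.floats(0, 1))
    def test_round_trip_identity(self, q):
        dup = call(1, 10, "duplication", c=1.0 + q)
        dele = call(1, 10, "deletion", c=1.0 - q)
        assert frequency_from_copy(dup) == pytest.approx(q, abs=1e-12)
        assert frequency_from_copy(dele) == pytest.approx(q, abs=1e-12)


class TestSummarize:
    def test_single_element_subset(self):
        s = summarize([call(1, 100)])
        assert s.span_median == s.span_min == s.span_max == 100

    def test_empty_subset_sentinel(self):
        s = summarize([], selector=None)
        assert s.empty
        assert s.span_median is None

    def test_even_count_median_averages_central_pair(self):
        calls = [call(1, n) for n in (10, 20, 40, 80)]
        assert summarize(calls).span_median == 30.0

    def test_permutation_invariant_and_matches_sort_oracle(self, rng):
        spans = rng.integers(1_000, 700_000, size=15)
        calls = [call(1, int(s)) for s in spans]
        base = summarize(calls)
        shuffled = list(calls)
        rng.shuffle(shuffled)
        again = summarize(shuffled)
        assert base.span_median == again.span_median == float(np.median(spans))
        assert (base.span_min, base.span_max) == (int(spans.min()), int(spans.max()))

    def test_recovery_duplication_median_span(self, fixtures):
        s = summarize(fixtures.duplications, selector=lambda c: c.population[0] != "C")
        assert s.n_events == 24
        assert s.span_median == 191_506.5  # 191.5 kb

    def test_deletion_median_span_and_gene_count(self, fixtures):
        s = summarize(fixtures.deletions)
        assert s.n_events == 25
        assert s.span_median == 12_514.0  # 12.5 kb
        assert s.feature_stats["protein_coding"][0] == 1.0


class TestRepeatPair:
    def _pair(self):
        up = "A" * 9 + "G" + "A" * 39 + "C" + "A" * 39 + "T" + "A" * 10
        down = "A" * 9 + "T" + "A" * 39 + "G" + "A" * 39 + "A" + "A" * 10
        return RepeatPair(upstream=up, downstream=down)  # sites at 10, 50, 90

    def test_informative_sites(self):
        assert self._pair().informative_sites == (10, 50, 90)

    def test_percent_identity_of_identical(self):
        pair = RepeatPair("ACGT", "ACGT")
        assert percent_identity(pair) == 100.0

    def test_percent_identity_of_disjoint(self):
        pair = RepeatPair("AAAA", "TTTT")
        assert percent_identity(pair) == 0.0

    def test_1031bp_repeat_with_41_mismatches_is_96_percent(self, rng):
        up = rng.choice(list("ACGT"), 1031)
        down = up.copy()
        sites = rng.choice(1031, size=41, replace=False)
        swap = {"A": "C", "C": "G", "G": "T", "T": "A"}
        for i in sites:
            down[i] = swap[up[i]]
        pair = RepeatPair("".join(up), "".join(down))
        assert percent_identity(pair) == pytest.approx(96.0, abs=0.05)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            RepeatPair("ACGT", "ACG")


class TestCrossoverInterval:
    def _pair(self):
        return TestRepeatPair()._pair()

    def _chimera(self, states):
        """Chimera matching downstream ('D') or upstream ('U') per site."""
        pair = self._pair()
        seq = list(pair.downstream)
        for state, pos in zip(states, pair.informative_sites):
            if state == "U":
                seq[pos - 1] = pair.upstream[pos - 1]
        return "".join(seq)

    def test_switch_between_sites(self):
        # downstream at 10 and 50, upstream at 90 -> crossover in (50, 90)
        assert infer_crossover_interval(self._pair(), self._chimera("DDU")) == (50, 90)

    def test_pure_downstream_chimera(self):
        interval = infer_crossover_interval(self._pair(), self._chimera("DDD"))
        assert interval == (90, 101)  # beyond the last informative site

    def test_pure_upstream_chimera(self):
        assert infer_crossover_interval(self._pair(), self._chimera("UUU")) == (0, 10)

    def test_distinct_gaps_mean_independent_events(self):
        first = infer_crossover_interval(self._pair(), self._chimera("DUU"))
        second = infer_crossover_interval(self._pair(), self._chimera("DDU"))
        assert first == (10, 50)
        assert second == (50, 90)
        assert first != second

    def test_unmatched_site_raises_with_positions(self):
        pair = self._pair()
        seq = list(pair.downstream)
        seq[49] = "N"
        with pytest.raises(AmbiguousBreakpointError) as err:
            infer_crossover_interval(pair, "".join(seq))
        assert err.value.positions == (50,)

    def test_double_switch_rejected(self):
        with pytest.raises(ValueError, match="more than once"):
            infer_crossover_interval(self._pair(), self._chimera("UDU"))


class TestFixtureTables:
    def test_duplication_copy_numbers_within_printed_range(self, fixtures):
        copies = [c.copy_number for c in fixtures.duplications]
        assert max(copies) == 2.19
        assert min(copies) == 1.19

    def test_deletion_copy_numbers(self, fixtures):
        copies = [c.copy_number for c in fixtures.deletions]
        assert min(copies) == 0.04
        assert max(copies) == 0.85

    def test_sequenced_breakpoints_flagged(self, fixtures):
        resolved = {
            (c.population, c.chromosome)
            for c in fixtures.duplications
            if c.breakpoint_resolved
        }
        assert resolved == {("16B", "V"), ("16E", "V"), ("50A", "V"),
                            ("66E", "V"), ("C2", "V")}

    def test_catalog_tsv_round_trip(self, tmp_path, fixtures):
        path = tmp_path / "catalog.tsv"
        write_catalog_tsv(list(fixtures.deletions), path)
        loaded = read_catalog_tsv(path)
        assert [(c.start, c.end, c.copy_number) for c in loaded] == [
            (c.start, c.end, c.copy_number) for c in fixtures.deletions
        ]
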