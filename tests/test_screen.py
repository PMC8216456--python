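"""Candidate criteria, Fisher aggregation, and query geometry."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from covscreen import (
    Region,
    SecondaryStructure,
    classify,
    codon_covariation_filter,
    expected_false_positives,
    fisher_aggregate,
    prepare_flanked_query,
    window_region,
)
from covscreen.covariation import PairCovariation
from covscreen.screen import ScreenAccounting, aggregate_screen


def _pair(i, j, evalue, subs=5):
    return PairCovariation(
        i=i, j=j, stat=10.0, evalue=evalue, subs_i=subs, subs_j=subs,
        has_power=True, is_significant=evalue <= 0.05,
    )


class TestFisherAggregate:
    def test_three_evalue_worked_example(self):
        # the weakest accepted positive control: E-values 6.5e-7, 0.0053, 0.0204
        p = fisher_aggregate([6.5e-7, 0.0053, 0.0204])
        assert p == pytest.approx(2.1e-8, rel=0.05)

    @pytest.mark.parametrize("p", [1e-6, 1e-4, 0.01, 0.25, 0.5, 0.9, 0.99])
    def test_single_value_identity(self, p):
        assert fisher_aggregate([p]) == pytest.approx(p, rel=1e-12)

    def test_two_halves_closed_form(self):
        # chi2_4 survival at -4 ln(1/2): exp(-x/2) * (1 + x/2)
        x = -4 * np.log(0.5)
        expected = np.exp(-x / 2) * (1 + x / 2)
        assert fisher_aggregate([0.5, 0.5]) == pytest.approx(expected, rel=1e-12)
        assert fisher_aggregate([0.5, 0.5]) == pytest.approx(0.59657, abs=5e-6)

    @given(
        ps=st.lists(st.floats(1e-8, 1.0, exclude_min=False), min_size=2, max_size=6),
        k=st.integers(0, 5),
        factor=st.floats(0.01, 0.99),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_monotone_in_each_argument(self, ps, k, factor):
        k = k % len(ps)
        smaller = list(ps)
        smaller[k] = ps[k] * factor
        assert fisher_aggregate(smaller) <= fisher_aggregate(ps) + 1e-15

    @pytest.mark.parametrize("bad", [[0.0], [-0.1], [1.1], []])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            fisher_aggregate(bad)


class TestExpectedFalsePositives:
    def test_whole_screen_accounting(self):
        p = fisher_aggregate([6.5e-7, 0.0053, 0.0204])
        assert expected_false_positives(134_000, p) == pytest.approx(0.003, abs=5e-4)

    @pytest.mark.parametrize(
        "n,p,expected", [(1000, 0.05, 50.0), (7, 0.0, 0.0), (0, 0.3, 0.0)]
    )
    def test_product(self, n, p, expected):
        assert expected_false_positives(n, p) == expected

    def test_accounting_invariant(self):
        acct = ScreenAccounting(n_tests=134_000, p_threshold=2.1e-8)
        assert acct.expected_false_positives == pytest.approx(134_000 * 2.1e-8)


class TestClassify:
    @pytest.fixture
    def stem_structure(self):
        # one 3-pair stem plus an isolated pair
        return SecondaryStructure.from_pairs([(1, 30), (2, 29), (3, 28), (10, 20)])

    def test_three_significant_two_in_one_stem_passes(self, stem_structure):
        pairs = [_pair(1, 30, 1e-3), _pair(2, 29, 1e-2), _pair(10, 20, 4e-2)]
        v = classify(pairs, stem_structure)
        assert v.verdict == "pass"
        assert v.n_significant == 3
        assert v.max_same_stem == 2

    def test_three_significant_in_distinct_stems_fails(self):
        ss = SecondaryStructure.from_pairs([(1, 30), (10, 20), (40, 50)])
        pairs = [_pair(1, 30, 1e-3), _pair(10, 20, 1e-3), _pair(40, 50, 1e-3)]
        v = classify(pairs, ss)
        assert v.verdict == "fail"
        assert v.max_same_stem == 1

    def test_single_very_strong_pair_rescues(self, stem_structure):
        pairs = [_pair(1, 30, 5e-5), _pair(2, 29, 0.5), _pair(10, 20, 0.9)]
        v = classify(pairs, stem_structure)
        assert v.verdict == "rescue"
        assert v.n_significant == 1

    def test_rescue_threshold_is_strict(self, stem_structure):
        pairs = [_pair(1, 30, 1e-4)]
        assert classify(pairs, stem_structure).verdict == "fail"

    def test_verdict_invariant_under_pair_permutation(self, stem_structure):
        pairs = [_pair(1, 30, 1e-3), _pair(2, 29, 1e-2), _pair(10, 20, 4e-2)]
        v1 = classify(pairs, stem_structure)
        v2 = classify(pairs[::-1], stem_structure)
        assert v1 == v2

    def test_aggregated_p_combines_significant_evalues(self, stem_structure):
        pairs = [_pair(1, 30, 6.5e-7), _pair(2, 29, 0.0053), _pair(10, 20, 0.0204)]
        v = classify(pairs, stem_structure)
        assert v.aggregated_p == pytest.approx(2.1e-8, rel=0.05)

    def test_no_significant_pairs_yields_aggregated_one(self, stem_structure):
        v = classify([_pair(1, 30, 0.9)], stem_structure)
        assert v.aggregated_p == 1.0
        assert v.verdict == "fail"


class TestCodonFilter:
    def _pairs_at_distances(self, distances):
        out = []
        pos = 1
        for d in distances:
            out.append(_pair(pos, pos + d, 1e-3))
            pos += 10
        return out

    def test_four_short_range_pairs_flagged(self):
        pairs = self._pairs_at_distances([1, 2, 1, 2])
        colmap = {c: c for c in range(1, 60)}
        flagged, n = codon_covariation_filter(pairs, colmap)
        assert flagged and n == 4

    def test_exactly_three_not_flagged(self):
        pairs = self._pairs_at_distances([1, 2, 2])
        colmap = {c: c for c in range(1, 60)}
        flagged, n = codon_covariation_filter(pairs, colmap)
        assert not flagged and n == 3

    def test_long_range_pairs_not_counted(self):
        pairs = self._pairs_at_distances([5, 9, 30])
        colmap = {c: c for c in range(1, 60)}
        flagged, n = codon_covariation_filter(pairs, colmap)
        assert not flagged and n == 0

    def test_distance_measured_on_consensus_positions(self):
        # columns 1 and 4 are three columns apart but adjacent once the
        # gappy columns 2-3 are unmapped
        pairs = [_pair(1, 4, 1e-3)] * 4
        colmap = {1: 1, 4: 2}
        flagged, n = codon_covariation_filter(pairs, colmap)
        assert flagged and n == 4


class TestWindowRegion:
    def test_worked_example_2500(self):
        wins = window_region(2500)
        assert wins == [(1, 1000), (501, 1500), (1001, 2000), (1501, 2500)]

    def test_at_threshold_single_window(self):
        assert window_region(1000) == [(1, 1000)]

    def test_below_minimum_is_empty(self):
        assert window_region(99) == []
        assert window_region(100) == [(1, 100)]

    @given(L=st.integers(100, 100_000))
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_windows_cover_region_without_oversize(self, L):
        wins = window_region(L)
        assert wins[0][0] == 1 and wins[-1][1] == L
        covered = 0  # rightmost covered position; windows are sorted
        for s, e in wins:
            assert 1 <= s <= e <= L
            assert e - s + 1 <= 1000
            assert s <= covered + 1
            covered = max(covered, e)
        assert covered == L


class TestPrepareFlankedQuery:
    def test_long_utr_keeps_2000_nearest_cds(self):
        utr = Region("chr1", 1, 3000, "+", "three_prime_UTR")
        cds = Region("chr1", 3001, 3500, "+", "CDS")
        utr_part, cds_part = prepare_flanked_query(utr, cds)
        assert (utr_part.start, utr_part.end) == (1001, 3000)
        assert (cds_part.start, cds_part.end) == (3001, 3500)

    def test_short_utr_unchanged(self):
        utr = Region("chr1", 1, 500, "+", "five_prime_UTR")
        cds = Region("chr1", 501, 2000, "+", "CDS")
        utr_part, _ = prepare_flanked_query(utr, cds)
        assert (utr_part.start, utr_part.end) == (1, 500)

    def test_long_cds_keeps_1000_nearest_junction(self):
        utr = Region("chr1", 2001, 2400, "+", "five_prime_UTR")
        cds = Region("chr1", 201, 2000, "+", "CDS")
        utr_part, cds_part = prepare_flanked_query(utr, cds)
        assert (cds_part.start, cds_part.end) == (1001, 2000)
        assert (utr_part.start, utr_part.end) == (2001, 2400)

    def test_non_adjacent_regions_raise(self):
        utr = Region("chr1", 1, 500)
        cds = Region("chr1", 600, 900, kind="CDS")
        with pytest.raises(ValueError, match="adjacent"):
            prepare_flanked_query(utr, cds)

    def test_different_contigs_raise(self):
        with pytest.raises(ValueError, match="contig"):
            prepare_flanked_query(Region("chr1", 1, 10), Region("chr2", 11, 20))


class TestAggregateScreen:
    def test_threshold_from_passing_verdicts(self):
        verdicts = [
            {"verdict": "pass", "n_significant": 3, "aggregated_p": 2.1e-8},
            {"verdict": "fail", "n_significant": 1, "aggregated_p": 0.5},
            {"verdict": "fail", "n_significant": 0, "aggregated_p": 1.0},
        ]
        summary = aggregate_screen(verdicts, n_tests=134_000)
        assert summary["p_threshold"] == pytest.approx(2.1e-8)
        assert summary["expected_false_positives"] == pytest.approx(0.003, abs=5e-4)
        assert summary["n_excluded_no_significant"] == 1

    def test_single_verdict_unit_tests(self):
        verdicts = [{"verdict": "pass", "n_significant": 3, "aggregated_p": 0.25}]
        summary = aggregate_screen(verdicts, n_tests=1)
        assert summary["expected_false_positives"] == pytest.approx(0.25)
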