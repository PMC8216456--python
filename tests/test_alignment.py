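"""Alignment container, Stockholm round-trips, and region surgery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from covscreen import (
    Alignment,
    ColumnSpan,
    Region,
    consensus_sequence,
    dedup_best_per_genome,
    extract_noncoding_span,
    read_fasta,
    read_region_table,
    read_stockholm,
    shuffle_columns,
    write_fasta,
    write_stockholm,
)
from covscreen.alignment import AlignmentParseError, ungapped_column_map

STOCKHOLM_TOY = """\
# STOCKHOLM 1.0

#=GS s2 GN genomeB
#=GS s2 SC 12.5
s1           GGCAAAGCC
s2           GACAAAGUC
s3           GU-AAA-AC
#=GC SS_cons <<<...>>>
//
"""


class TestStockholmIO:
    def test_reads_toy_file(self, tmp_path):
        f = tmp_path / "toy.sto"
        f.write_text(STOCKHOLM_TOY)
        aln = read_stockholm(f)
        assert aln.n_rows == 3
        assert aln.n_columns == 9
        assert aln.ss_cons == "<<<...>>>"
        assert aln.rows[1].genome_id == "genomeB"
        assert aln.rows[1].score == 12.5
        assert aln.rows[0].score is None

    def test_missing_header_is_parse_error(self, tmp_path):
        f = tmp_path / "bad.sto"
        f.write_text("s1 ACGU\n//\n")
        with pytest.raises(AlignmentParseError, match="STOCKHOLM"):
            read_stockholm(f)

    def test_ragged_rows_are_parse_error(self, tmp_path):
        f = tmp_path / "ragged.sto"
        f.write_text("# STOCKHOLM 1.0\ns1 ACGU\ns2 ACG\n//\n")
        with pytest.raises(AlignmentParseError, match="ragged"):
            read_stockholm(f)

    def test_unbalanced_ss_cons_is_parse_error(self, tmp_path):
        f = tmp_path / "unbal.sto"
        f.write_text("# STOCKHOLM 1.0\ns1 ACGUA\n#=GC SS_cons <<...\n//\n")
        with pytest.raises(AlignmentParseError, match="SS_cons"):
            read_stockholm(f)

    def test_round_trip_identity(self, tmp_path, toy_alignment):
        f = tmp_path / "rt.sto"
        aln = Alignment(
            rows=tuple(
                r if k != 1 else type(r)(r.seq_id, "genX", r.gapped_seq, 7.25)
                for k, r in enumerate(toy_alignment.rows)
            ),
            ss_cons=toy_alignment.ss_cons,
        )
        write_stockholm(aln, f)
        back = read_stockholm(f)
        assert back.rows == aln.rows
        assert back.ss_cons == aln.ss_cons
        # and writing again yields identical bytes
        f2 = tmp_path / "rt2.sto"
        write_stockholm(back, f2)
        assert f.read_text() == f2.read_text()

    def test_t_normalized_to_u_on_load(self, tmp_path):
        f = tmp_path / "dna.sto"
        f.write_text("# STOCKHOLM 1.0\ns1 ACGT\ns2 acgt\n//\n")
        aln = read_stockholm(f)
        assert all(r.gapped_seq == "ACGU" for r in aln.rows)


def test_fasta_round_trip(tmp_path):
    records = [("rna1", "ACGUACGU"), ("rna2", "GGGAAACCC")]
    f = tmp_path / "seqs.fa"
    write_fasta(records, f)
    assert read_fasta(f) == records


def test_region_table_read(tmp_path):
    f = tmp_path / "regions.tsv"
    f.write_text(
        "# contig\tstart\tend\tstrand\tkind\tname\n"
        "chr1\t100\t399\t+\tIGR\tigr1\n"
        "chr2\t10\t19\t-\tCDS\tgeneA\n"
    )
    regions = read_region_table(f)
    assert regions[0] == Region("chr1", 100, 399, "+", "IGR", "igr1")
    assert regions[1].length == 10


class TestExtractNoncodingSpan:
    def _aln(self, n_res_row: int, span_len: int = 60) -> Alignment:
        # one full row; one row with exactly n_res_row residues in the span
        full = "A" * span_len
        partial = "A" * n_res_row + "-" * (span_len - n_res_row)
        return Alignment.from_sequences([full, partial])

    @pytest.mark.parametrize("n_res,kept", [(49, 1), (50, 2), (51, 2)])
    def test_min_nt_boundary_is_inclusive(self, n_res, kept):
        aln = self._aln(n_res)
        out = extract_noncoding_span(aln, ColumnSpan(1, 60), min_nt=50)
        assert out.n_rows == kept

    def test_full_span_min0_is_identity(self, toy_alignment):
        out = extract_noncoding_span(
            toy_alignment, ColumnSpan(1, toy_alignment.n_columns), min_nt=0
        )
        assert [r.gapped_seq for r in out.rows] == [
            r.gapped_seq for r in toy_alignment.rows
        ]

    def test_empty_result_is_empty_alignment_not_error(self):
        aln = Alignment.from_sequences(["----", "----"])
        out = extract_noncoding_span(aln, ColumnSpan(1, 4), min_nt=1)
        assert out.n_rows == 0

    def test_ss_cons_projected_to_span(self, toy_alignment):
        out = extract_noncoding_span(toy_alignment, ColumnSpan(2, 8), min_nt=0)
        # pairs (1,9) leaves the span; (2,8),(3,7) survive shifted
        assert out.ss_cons == "((...))"

    def test_never_increases_rows_or_columns(self, toy_alignment):
        out = extract_noncoding_span(toy_alignment, ColumnSpan(3, 5), min_nt=1)
        assert out.n_rows <= toy_alignment.n_rows
        assert out.n_columns == 3


class TestDedupBestPerGenome:
    def test_keeps_top_scoring_hit(self):
        aln = Alignment.from_sequences(
            ["AAAA", "CCCC", "GGGG"],
            ids=["h1", "h2", "h3"],
            genomes=["gX", "gX", "gY"],
            scores=[7.5, 12.0, None],
        )
        out = dedup_best_per_genome(aln)
        assert [r.seq_id for r in out.rows] == ["h2", "h3"]

    def test_singletons_unchanged(self, toy_alignment):
        out = dedup_best_per_genome(toy_alignment)
        assert out.rows == toy_alignment.rows

    def test_tie_keeps_first_row(self):
        aln = Alignment.from_sequences(
            ["AAAA", "CCCC"], ids=["h1", "h2"], genomes=["g", "g"],
            scores=[10.0, 10.0],
        )
        out = dedup_best_per_genome(aln)
        assert [r.seq_id for r in out.rows] == ["h1"]

    def test_missing_score_with_multiple_rows_is_error(self):
        aln = Alignment.from_sequences(
            ["AAAA", "CCCC"], ids=["h1", "h2"], genomes=["g", "g"],
            scores=[None, 3.0],
        )
        with pytest.raises(ValueError, match="no score"):
            dedup_best_per_genome(aln)

    def test_output_genomes_distinct(self):
        aln = Alignment.from_sequences(
            ["AAAA", "CCCC", "GGGG", "UUUU"],
            genomes=["a", "b", "a", "b"],
            scores=[1.0, 2.0, 3.0, 4.0],
        )
        out = dedup_best_per_genome(aln)
        genomes = [r.genome_id for r in out.rows]
        assert len(genomes) == len(set(genomes))


class TestShuffleColumns:
    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_per_column_multisets_conserved(self, seed):
        aln = Alignment.from_sequences(
            ["ACGU-A", "AC-UUA", "GCGUAA", "ACGUCA"]
        )
        out = shuffle_columns(aln, seed)
        for c in range(1, aln.n_columns + 1):
            assert sorted(out.column(c)) == sorted(aln.column(c))

    def test_single_row_is_identity(self):
        aln = Alignment.from_sequences(["ACGUAC"])
        out = shuffle_columns(aln, 3)
        assert out.rows[0].gapped_seq == "ACGUAC"

    def test_matches_independent_fisher_yates_oracle(self):
        seqs = ["ACGUAC", "CCGAAU", "GGAUCG", "UUCGGA"]
        aln = Alignment.from_sequences(seqs)
        out = shuffle_columns(aln, seed=7)
        # oracle: same seed discipline, list-of-lists implementation
        rng = np.random.default_rng(7)
        cols = [[s[c] for s in seqs] for c in range(6)]
        expected_cols = [
            [col[k] for k in rng.permutation(4)] for col in cols
        ]
        expected = [
            "".join(expected_cols[c][r] for c in range(6)) for r in range(4)
        ]
        assert [r.gapped_seq for r in out.rows] == expected

    def test_deterministic_per_seed(self, toy_alignment):
        a = shuffle_columns(toy_alignment, 11)
        b = shuffle_columns(toy_alignment, 11)
        assert a.rows == b.rows


class TestConsensus:
    @pytest.mark.parametrize(
        "cols,expected",
        [
            (["A", "A", "A", "G"], "A"),  # majority
            (["A", "C", "G", "U"], "N"),  # no majority
            (["A", "-", "-", "-"], ""),  # 75% gaps: dropped
        ],
    )
    def test_single_column_rules(self, cols, expected):
        aln = Alignment.from_sequences(cols)
        assert consensus_sequence(aln, min_frac=0.5) == expected

    def test_mixed_columns(self):
        aln = Alignment.from_sequences(["AG-U", "AC-U", "AUAU", "AA-C"])
        # col1 all A; col2 no majority; col3 75% gaps dropped; col4 3/4 U
        assert consensus_sequence(aln) == "ANU"

    def test_ungapped_column_map_skips_gappy_columns(self):
        aln = Alignment.from_sequences(["A--U", "A--U", "AG-U"])
        assert ungapped_column_map(aln) == {1: 1, 4: 2}


def test_alphabet_validation_rejects_junk():
    with pytest.raises(ValueError, match="invalid residue"):
        Alignment.from_sequences(["ACGX"])
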