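"""Alignment data model, Stockholm/FASTA I/O, and region surgery.

The central container is :class:`Alignment`: an ordered set of gapped RNA
sequences over ``{A,C,G,U,-,.}`` (``T`` is normalized to ``U`` on load),
each carrying a sequence id, a genome label, and an optional homology-search
score, plus an optional consensus structure line (WUSS/dot-bracket).

The region-surgery operations implement the screen's alignment preparation:
extracting the non-coding column span of a coding-flanked alignment while
keeping only rows with enough residues in it, keeping the top-scoring hit
per genome (to avoid pseudogenes diluting covariation), per-column shuffling
for negative controls, and consensus-sequence extraction for guide matching.

Coordinates are 1-based inclusive throughout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .fold import StructureParseError, pairs_from_structure

__all__ = [
    "Alignment",
    "AlignmentRow",
    "Region",
    "ColumnSpan",
    "AlignmentParseError",
    "read_stockholm",
    "write_stockholm",
    "read_fasta",
    "write_fasta",
    "read_region_table",
    "extract_noncoding_span",
    "dedup_best_per_genome",
    "shuffle_columns",
    "consensus_sequence",
    "column_consensus",
    "ungapped_column_map",
]

GAP_CHARS = frozenset("-.")
RESIDUES = "ACGU"
_ALPHABET = frozenset("ACGU-.")


class AlignmentParseError(ValueError):
    """Raised on malformed Stockholm input, naming the offending line."""


def normalize_seq(seq: str, *, allow_gaps: bool = True) -> str:
    """Uppercase, map T to U, and validate the residue alphabet."""
    s = seq.upper().replace("T", "U")
    allowed = _ALPHABET if allow_gaps else frozenset(RESIDUES + "N")
    bad = set(s) - allowed
    if bad:
        raise ValueError(f"invalid residue symbols {sorted(bad)!r}")
    return s


@dataclass(frozen=True)
class AlignmentRow:
    seq_id: str
    genome_id: str
    gapped_seq: str
    score: float | None = None


def _default_genome(seq_id: str) -> str:
    # nhmmer-style hit names are "<source>/<start>-<end>"
    return seq_id.split("/", 1)[0]


@dataclass(frozen=True)
class Alignment:
    """Rows of gapped RNA sequences with an optional consensus structure."""

    rows: tuple
    ss_cons: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "rows", tuple(self.rows))
        widths = {len(r.gapped_seq) for r in self.rows}
        if len(widths) > 1:
            raise ValueError(f"rows have unequal lengths: {sorted(widths)}")
        if self.ss_cons is not None:
            if self.rows and len(self.ss_cons) != self.n_columns:
                raise ValueError("SS_cons length does not match alignment width")
            pairs_from_structure(self.ss_cons)  # raises if unbalanced

    @classmethod
    def from_sequences(
        cls,
        seqs: Sequence[str],
        ids: Sequence[str] | None = None,
        genomes: Sequence[str] | None = None,
        scores: Sequence[float | None] | None = None,
        ss_cons: str | None = None,
    ) -> "Alignment":
        n = len(seqs)
        ids = list(ids) if ids is not None else [f"seq{k+1}" for k in range(n)]
        genomes = list(genomes) if genomes is not None else [_default_genome(i) for i in ids]
        scores = list(scores) if scores is not None else [None] * n
        rows = tuple(
            AlignmentRow(i, g, normalize_seq(s), sc)
            for i, g, s, sc in zip(ids, genomes, seqs, scores)
        )
        return cls(rows=rows, ss_cons=ss_cons)

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0].gapped_seq) if self.rows else 0

    def column(self, c: int) -> str:
        """Residues of 1-based column *c*, top to bottom."""
        return "".join(r.gapped_seq[c - 1] for r in self.rows)

    def char_matrix(self) -> np.ndarray:
        """(n_rows, n_columns) array of single characters."""
        if not self.rows:
            return np.empty((0, 0), dtype="<U1")
        return np.array([list(r.gapped_seq) for r in self.rows], dtype="<U1")

    def with_sequences(self, seqs: Sequence[str]) -> "Alignment":
        rows = tuple(replace(r, gapped_seq=s) for r, s in zip(self.rows, seqs))
        return Alignment(rows=rows, ss_cons=self.ss_cons)


@dataclass(frozen=True)
class Region:
    """A 1-based inclusive genomic interval of a given annotation kind."""

    contig: str
    start: int
    end: int
    strand: str = "+"
    kind: str = "IGR"
    name: str = ""

    def __post_init__(self):
        if not 1 <= self.start <= self.end:
            raise ValueError(f"invalid region {self.start}..{self.end}")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ColumnSpan:
    """An inclusive 1-based range of alignment columns."""

    first_col: int
    last_col: int

    def __post_init__(self):
        if not 1 <= self.first_col <= self.last_col:
            raise ValueError(f"invalid span {self.first_col}..{self.last_col}")


# ---------------------------------------------------------------------------
# Stockholm I/O
#
# Single-block Stockholm 1.0 with per-row metadata as "#=GS <seq> GN <genome>"
# and "#=GS <seq> SC <score>" lines and the consensus structure as
# "#=GC SS_cons".  Multi-block (interleaved) files are also accepted on read.
# ---------------------------------------------------------------------------

def read_stockholm(path) -> Alignment:
    """Read a Stockholm 1.0 alignment, capturing SS_cons and GS metadata."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or not lines[0].startswith("# STOCKHOLM 1.0"):
        raise AlignmentParseError(f"{path}:1: missing '# STOCKHOLM 1.0' header")
    seqs: dict[str, str] = {}
    order: list[str] = []
    genomes: dict[str, str] = {}
    scores: dict[str, float] = {}
    ss_parts: list[str] = []
    for lineno, raw in enumerate(lines[1:], start=2):
        line = raw.rstrip()
        if not line:
            continue
        if line == "//":
            break
        if line.startswith("#=GS"):
            fields = line.split(None, 3)
            if len(fields) < 4:
                raise AlignmentParseError(f"{path}:{lineno}: malformed #=GS line")
            _, name, tag, value = fields
            if tag == "GN":
                genomes[name] = value.strip()
            elif tag == "SC":
                try:
                    scores[name] = float(value)
                except ValueError as exc:
                    raise AlignmentParseError(
                        f"{path}:{lineno}: bad score {value!r}"
                    ) from exc
            continue
        if line.startswith("#=GC"):
            fields = line.split()
            if len(fields) != 3:
                raise AlignmentParseError(f"{path}:{lineno}: malformed #=GC line")
            if fields[1] == "SS_cons":
                ss_parts.append(fields[2])
            continue
        if line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 2:
            raise AlignmentParseError(
                f"{path}:{lineno}: expected '<name> <sequence>', got {line!r}"
            )
        name, chunk = fields
        if name not in seqs:
            order.append(name)
            seqs[name] = ""
        seqs[name] += chunk
    if not order:
        raise AlignmentParseError(f"{path}: no sequences found")
    widths = {len(s) for s in seqs.values()}
    if len(widths) > 1:
        raise AlignmentParseError(
            f"{path}: ragged alignment, row lengths {sorted(widths)}"
        )
    ss = "".join(ss_parts) or None
    if ss is not None:
        if len(ss) != widths.pop():
            raise AlignmentParseError(f"{path}: SS_cons length mismatch")
        try:
            pairs_from_structure(ss)
        except StructureParseError as exc:
            raise AlignmentParseError(f"{path}: SS_cons: {exc}") from exc
    try:
        rows = tuple(
            AlignmentRow(
                seq_id=name,
                genome_id=genomes.get(name, _default_genome(name)),
                gapped_seq=normalize_seq(seqs[name]),
                score=scores.get(name),
            )
            for name in order
        )
    except ValueError as exc:
        raise AlignmentParseError(f"{path}: {exc}") from exc
    return Alignment(rows=rows, ss_cons=ss)


def write_stockholm(aln: Alignment, path) -> None:
    """Write a single-block Stockholm 1.0 file round-trippable by read_stockholm."""
    path = Path(path)
    name_w = max((len(r.seq_id) for r in aln.rows), default=0)
    name_w = max(name_w, len("#=GC SS_cons"))
    out = ["# STOCKHOLM 1.0", ""]
    for r in aln.rows:
        if r.genome_id != _default_genome(r.seq_id):
            out.append(f"#=GS {r.seq_id} GN {r.genome_id}")
        if r.score is not None:
            out.append(f"#=GS {r.seq_id} SC {r.score:g}")
    for r in aln.rows:
        out.append(f"{r.seq_id:<{name_w}} {r.gapped_seq}")
    if aln.ss_cons is not None:
        out.append(f"{'#=GC SS_cons':<{name_w}} {aln.ss_cons}")
    out.append("//")
    path.write_text("\n".join(out) + "\n")


def read_fasta(path) -> list[tuple[str, str]]:
    """Read ungapped RNA sequences from FASTA as (id, sequence) pairs."""
    return [
        (rec.id, normalize_seq(str(rec.seq), allow_gaps=False))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
        str(path),
        "fasta",
    )


_REGION_COLUMNS = ["contig", "start", "end", "strand", "kind", "name"]


def read_region_table(path) -> list[Region]:
    """Read a tab-separated region table (contig, start, end, strand, kind, name).

    Coordinates are 1-based inclusive; lines starting with '#' are comments.
    """
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=_REGION_COLUMNS,
        dtype={"contig": str, "name": str},
    )
    df["name"] = df["name"].fillna("")
    return [
        Region(
            contig=row.contig, start=int(row.start), end=int(row.end),
            strand=row.strand, kind=row.kind, name=row.name,
        )
        for row in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# Region surgery
# ---------------------------------------------------------------------------

def _project_ss(ss: str | None, first: int, last: int) -> str | None:
    """Slice SS_cons to a column span, erasing pairs that leave the span."""
    if ss is None:
        return None
    pairs, _ = pairs_from_structure(ss)
    chars = ["."] * (last - first + 1)
    kept = [(i, j) for i, j in pairs if first <= i and j <= last]
    if kept:
        from .fold import SecondaryStructure, render_dotbracket

        shifted = [(i - first + 1, j - first + 1) for i, j in kept]
        return render_dotbracket(
            SecondaryStructure.from_pairs(shifted), last - first + 1
        )
    return "".join(chars)


def extract_noncoding_span(
    aln: Alignment, span: ColumnSpan, min_nt: int = 50
) -> Alignment:
    """Restrict to a column span, keeping rows with >= *min_nt* residues in it.

    This is the flanked-mode extraction step: after an initial coding-flanked
    homology search, the non-coding columns are cut out and only sequences
    with at least *min_nt* nucleotides in that region are retained for the
    next search iteration.  An empty result is returned as an empty
    alignment, not an error.
    """
    if span.last_col > aln.n_columns:
        raise ValueError(
            f"span {span.first_col}..{span.last_col} exceeds "
            f"{aln.n_columns} columns"
        )
    lo, hi = span.first_col - 1, span.last_col
    kept = []
    for r in aln.rows:
        sub = r.gapped_seq[lo:hi]
        n_res = sum(1 for c in sub if c not in GAP_CHARS)
        if n_res >= min_nt:
            kept.append(replace(r, gapped_seq=sub))
    return Alignment(
        rows=tuple(kept),
        ss_cons=_project_ss(aln.ss_cons, span.first_col, span.last_col)
        if kept
        else None,
    )


def dedup_best_per_genome(aln: Alignment) -> Alignment:
    """Keep only the top-scoring hit per genome.

    Multiple hits in one genome are often pseudogenes whose decayed pairing
    dilutes covariation; retaining the best-scoring hit avoids this.  Ties
    keep the row appearing first.  A genome with several rows but missing
    scores is a configuration error.
    """
    best: dict[str, int] = {}
    counts: dict[str, int] = {}
    for idx, r in enumerate(aln.rows):
        counts[r.genome_id] = counts.get(r.genome_id, 0) + 1
    for idx, r in enumerate(aln.rows):
        if counts[r.genome_id] > 1 and r.score is None:
            raise ValueError(
                f"genome {r.genome_id!r} has multiple rows but row "
                f"{r.seq_id!r} has no score"
            )
        if r.genome_id not in best:
            best[r.genome_id] = idx
        else:
            cur = aln.rows[best[r.genome_id]]
            if r.score is not None and cur.score is not None and r.score > cur.score:
                best[r.genome_id] = idx
    keep = sorted(best.values())
    return Alignment(rows=tuple(aln.rows[k] for k in keep), ss_cons=aln.ss_cons)


def _shuffle_matrix(mat: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Permute each column independently (one rng.permutation call per column)."""
    out = mat.copy()
    n_rows = mat.shape[0]
    for c in range(mat.shape[1]):
        out[:, c] = mat[rng.permutation(n_rows), c]
    return out


def shuffle_columns(aln: Alignment, seed: int) -> Alignment:
    """Shuffle each column's residues (gaps included) independently across rows.

    This is the negative-control construction: covariation is destroyed
    while base composition and position-specific conservation are preserved
    exactly.  Deterministic for a given seed.
    """
    if aln.n_rows == 0:
        return aln
    rng = np.random.default_rng(seed)
    shuffled = _shuffle_matrix(aln.char_matrix(), rng)
    return aln.with_sequences(["".join(row) for row in shuffled])


def _column_call(column: str, min_frac: float) -> tuple[str, float]:
    """(consensus symbol, gap fraction) for one column string."""
    residues = [c for c in column if c not in GAP_CHARS]
    gap_frac = 1.0 - len(residues) / len(column) if column else 1.0
    if not residues:
        return "N", gap_frac
    counts: dict[str, int] = {}
    for c in residues:
        counts[c] = counts.get(c, 0) + 1
    # ties broken alphabetically (A < C < G < U) for determinism
    top = min(counts, key=lambda c: (-counts[c], c))
    if counts[top] / len(residues) >= min_frac:
        return top, gap_frac
    return "N", gap_frac


def column_consensus(aln: Alignment, min_frac: float = 0.5) -> str:
    """Full-length per-column consensus: majority residue or N, one per column."""
    return "".join(
        _column_call(aln.column(c), min_frac)[0] for c in range(1, aln.n_columns + 1)
    )


def consensus_sequence(aln: Alignment, min_frac: float = 0.5) -> str:
    """Display-style consensus: columns with more than 50% gaps are dropped.

    Per remaining column the most frequent residue is emitted if its
    gap-excluded frequency is at least *min_frac*, else ``N``.
    """
    out = []
    for c in range(1, aln.n_columns + 1):
        sym, gap_frac = _column_call(aln.column(c), min_frac)
        if gap_frac > 0.5:
            continue
        out.append(sym)
    return "".join(out)


def ungapped_column_map(aln: Alignment, max_gap_frac: float = 0.5) -> dict[int, int]:
    """Map alignment columns to consecutive ungapped consensus positions.

    Columns whose gap fraction exceeds *max_gap_frac* are unmapped.  Used by
    the codon-proximity filter, which measures pair separation on consensus
    positions so that gap columns do not dilute within-codon signal.
    """
    colmap: dict[int, int] = {}
    pos = 0
    for c in range(1, aln.n_columns + 1):
        col = aln.column(c)
        n_gap = sum(1 for ch in col if ch in GAP_CHARS)
        if col and n_gap / len(col) <= max_gap_frac:
            pos += 1
            colmap[c] = pos
    return colmap
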