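"""Seeded generators for synthetic alignments and guide-target fixtures.

These generators produce inputs with the statistical structure the rest of
the package assumes, so the whole pipeline is testable offline:

* structured alignments with planted stems maintained by compensatory base
  pair substitutions (rows drawn independently from one ancestor — a star
  phylogeny, under which the column-permutation null is exact);
* codon-like alignments whose short-range covariation mimics protein-coding
  sequence, for exercising the codon filter;
* guide/target pairs with one planted pseudouridylation pocket.

Same spec + seed always reproduces bit-identical output.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np

from .alignment import Alignment, ColumnSpan
from .fold import SecondaryStructure, render_dotbracket
from .snorna import guide_target_search

__all__ = [
    "StructuredAlignmentSpec",
    "CodingAlignmentSpec",
    "simulate_structured_alignment",
    "simulate_coding_alignment",
    "make_snorna_fixture",
]

_RES = "ACGU"
# complements usable by a compensatory substitution (wobble included)
_COMPLEMENTS = {"A": "U", "C": "G", "G": "CU", "U": "AG"}


@dataclass(frozen=True)
class StructuredAlignmentSpec:
    """Parameters of a star-tree alignment with planted covarying stems.

    ``stems`` entries are ``(i_start, j_start, stem_len)``: base pairs
    ``(i_start + k, j_start - k)`` for ``k < stem_len`` (1-based).
    ``per_site_sub_prob`` is the per-row, per-site substitution probability;
    a substitution at a paired site is compensated (partner switched to a
    complementary residue, wobble allowed) with ``compensation_prob``.
    Columns inside ``conserved_spans`` (e.g. H/ACA boxes) never mutate.
    """

    n_seqs: int = 40
    length: int = 120
    stems: tuple = ((20, 70, 6),)
    per_site_sub_prob: float = 0.3
    compensation_prob: float = 0.9
    conserved_spans: tuple = ()
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "stems", tuple(tuple(s) for s in self.stems))
        object.__setattr__(
            self,
            "conserved_spans",
            tuple(
                s if isinstance(s, ColumnSpan) else ColumnSpan(*s)
                for s in self.conserved_spans
            ),
        )
        for p in (self.per_site_sub_prob, self.compensation_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")
        self._validate_stems()

    def _validate_stems(self):
        used: set[int] = set()
        for i0, j0, L in self.stems:
            if L < 1:
                raise ValueError("stem_len must be >= 1")
            lo_end, hi_end = i0 + L - 1, j0 - L + 1
            if not (1 <= i0 <= lo_end < hi_end <= j0 <= self.length):
                raise ValueError(f"stem ({i0},{j0},{L}) has invalid geometry")
            cols = set(range(i0, i0 + L)) | set(range(j0 - L + 1, j0 + 1))
            if cols & used:
                raise ValueError("stems overlap")
            used |= cols
        # nested-compatibility: pairs must not cross between stems
        pairs = self.pairs()
        for a in pairs:
            for b in pairs:
                if a[0] < b[0] < a[1] < b[1]:
                    raise ValueError("stems are not nested-compatible")

    def pairs(self) -> list[tuple[int, int]]:
        out = []
        for i0, j0, L in self.stems:
            out.extend((i0 + k, j0 - k) for k in range(L))
        return out

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stems"] = [list(s) for s in self.stems]
        d["conserved_spans"] = [
            [s.first_col, s.last_col] for s in self.conserved_spans
        ]
        return d


@dataclass(frozen=True)
class CodingAlignmentSpec:
    """Parameters of a codon-structured alignment.

    Each codon slot has two variant codons differing at every position;
    a row copies one variant wholesale with probability
    ``within_codon_corr`` (producing distance-1 and distance-2 covariation)
    and otherwise draws each of the three positions independently.
    """

    n_seqs: int = 50
    n_codons: int = 30
    within_codon_corr: float = 0.9
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.within_codon_corr <= 1:
            raise ValueError("within_codon_corr must be in [0, 1]")
        if self.n_codons < 1 or self.n_seqs < 1:
            raise ValueError("n_codons and n_seqs must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


def _conserved_columns(spec: StructuredAlignmentSpec) -> set[int]:
    cols: set[int] = set()
    for span in spec.conserved_spans:
        cols.update(range(span.first_col, span.last_col + 1))
    return cols


def simulate_structured_alignment(spec: StructuredAlignmentSpec) -> Alignment:
    """Draw an alignment from a star tree with compensatory planted stems.

    A uniform-random ancestor is made complementary at every planted pair.
    Each row substitutes each unpaired site independently; each planted pair
    substitutes jointly: with probability ``per_site_sub_prob`` the 5'
    residue changes, and the 3' partner is switched to a complementary
    residue with ``compensation_prob`` (else redrawn freely, which usually
    breaks the pair).  The planted structure is recorded in ``ss_cons``.
    """
    rng = np.random.default_rng(spec.seed)
    n, L = spec.n_seqs, spec.length
    pairs = spec.pairs()
    conserved = _conserved_columns(spec)
    ancestor = rng.choice(list(_RES), size=L)
    for i, j in pairs:
        comp = _COMPLEMENTS[ancestor[i - 1]]
        ancestor[j - 1] = comp[rng.integers(len(comp))]
    paired_cols = {c for p in pairs for c in p}
    rows = []
    for _ in range(n):
        row = ancestor.copy()
        for c in range(1, L + 1):
            if c in paired_cols or c in conserved:
                continue
            if rng.random() < spec.per_site_sub_prob:
                others = _RES.replace(str(row[c - 1]), "")
                row[c - 1] = others[rng.integers(3)]
        for i, j in pairs:
            if i in conserved or j in conserved:
                continue
            if rng.random() < spec.per_site_sub_prob:
                others = _RES.replace(str(row[i - 1]), "")
                row[i - 1] = others[rng.integers(3)]
                if rng.random() < spec.compensation_prob:
                    comp = _COMPLEMENTS[row[i - 1]]
                    row[j - 1] = comp[rng.integers(len(comp))]
                else:
                    row[j - 1] = _RES[rng.integers(4)]
        rows.append("".join(row))
    ss = render_dotbracket(SecondaryStructure.from_pairs(pairs), L) if pairs else None
    return Alignment.from_sequences(
        rows,
        ids=[f"seq{k+1}" for k in range(n)],
        genomes=[f"genome{k+1}" for k in range(n)],
        ss_cons=ss,
    )


def simulate_coding_alignment(spec: CodingAlignmentSpec) -> Alignment:
    """Draw an alignment whose covariation mimics codon structure."""
    rng = np.random.default_rng(spec.seed)
    res = list(_RES)
    variant_pairs = []
    for _ in range(spec.n_codons):
        c1 = rng.choice(res, size=3)
        # second variant differs at every position so that joint draws
        # covary at distances 1 and 2
        c2 = np.array(
            [_RES.replace(str(b), "")[rng.integers(3)] for b in c1]
        )
        variant_pairs.append((c1, c2))
    rows = []
    for _ in range(spec.n_seqs):
        chunks = []
        for c1, c2 in variant_pairs:
            if rng.random() < spec.within_codon_corr:
                chunks.append(c1 if rng.random() < 0.5 else c2)
            else:
                chunks.append(
                    np.array(
                        [
                            (c1[k] if rng.random() < 0.5 else c2[k])
                            for k in range(3)
                        ]
                    )
                )
        rows.append("".join("".join(ch) for ch in chunks))
    return Alignment.from_sequences(
        rows,
        ids=[f"seq{k+1}" for k in range(spec.n_seqs)],
        genomes=[f"genome{k+1}" for k in range(spec.n_seqs)],
    )


_WC = {"A": "U", "U": "A", "G": "C", "C": "G"}


def make_snorna_fixture(
    seed: int,
    target_len: int = 60,
    guide_len: int = 6,
) -> tuple[str, str, str]:
    """Random guide halves and a target with exactly one planted pocket.

    The pocket sits around a uridine at mid-target: the upstream flank is
    the strict Watson-Crick complement of the guide's 3' strand and the
    downstream flank that of the 5' strand.  Construction retries (with the
    same seeded generator) until the planted pocket is the only match and
    ablating its U (U -> C) leaves no match at all.
    """
    rng = np.random.default_rng(seed)
    res = list(_RES)
    for _ in range(200):
        guide5 = "".join(rng.choice(res, size=guide_len))
        guide3 = "".join(rng.choice(res, size=guide_len))
        tgt = rng.choice(res, size=target_len)
        t = target_len // 2
        tgt[t - 1] = "U"
        for k in range(1, guide_len + 1):
            tgt[t - 1 - k] = _WC[guide3[k - 1]]
            tgt[t + k] = _WC[guide5[guide_len - k]]
        target = "".join(tgt)
        matches = guide_target_search(guide5, guide3, target)
        if [m.target_pos for m in matches] != [t]:
            continue
        ablated = target[: t - 1] + "C" + target[t:]
        if guide_target_search(guide5, guide3, ablated):
            continue
        return guide5, guide3, target
    raise RuntimeError("could not construct a unique-pocket fixture")
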