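"""Candidate decision layer: criteria, Fisher aggregation, and query geometry.

An alignment is called a conserved-structure candidate when it satisfies
two criteria: (i) at least three statistically significant covarying base
pairs (E-value at most 0.05) in total, and (ii) at least two of them in the
same stem of the proposed structure.  Alignments failing the criteria but
containing one exceptionally strong pair (E-value below 1e-4, over two
orders of magnitude beyond the default threshold) are routed to a rescue
path: primary-sequence alignments can be too poor for covariation analysis,
and such a pair warrants a structure-informed second pass.

Screen-level significance uses Fisher's method: the significant pairs'
E-values p_1..p_n (treated as P-values, clamped at 1) are combined as
-2*sum(ln p_i), which follows a chi-squared distribution with 2n degrees of
freedom under the null; the aggregated P-value is its survival function at
that statistic.  Multiplying the screen-wide P-value threshold by the number
of alignments tested gives the expected number of false positives.

Alignments whose significant covariations are dominated by pairs one or two
consensus positions apart are flagged as likely protein-coding (codon
structure produces exactly such short-range covariation) and removed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .alignment import Alignment, Region, column_consensus, ungapped_column_map
from .config import ScreenConfig
from .covariation import NullCalibration, PairCovariation, annotate_pairs
from .fold import SecondaryStructure, can_pair, constrained_fold, stems

__all__ = [
    "CandidateVerdict",
    "ScreenAccounting",
    "ScanResult",
    "fisher_aggregate",
    "expected_false_positives",
    "classify",
    "codon_covariation_filter",
    "window_region",
    "prepare_flanked_query",
    "scan_alignment",
    "aggregate_screen",
]


@dataclass(frozen=True)
class CandidateVerdict:
    """Outcome of the two-criterion candidate classification."""

    n_significant: int
    max_same_stem: int
    verdict: str  # pass | rescue | fail
    significant_evalues: tuple
    aggregated_p: float
    codon_flagged: bool = False
    n_codon_like: int = 0
    n_clamped: int = 0  # E-values > 1 clamped before aggregation

    def to_dict(self) -> dict:
        d = asdict(self)
        d["significant_evalues"] = list(self.significant_evalues)
        return d


@dataclass(frozen=True)
class ScreenAccounting:
    """Expected-false-positive bookkeeping for a whole screen."""

    n_tests: int
    p_threshold: float

    @property
    def expected_false_positives(self) -> float:
        return self.n_tests * self.p_threshold


def fisher_aggregate(p_values: Iterable[float]) -> float:
    """Combine independent P-values by Fisher's method.

    Returns the survival function of the chi-squared distribution with 2n
    degrees of freedom evaluated at -2*sum(ln p_i).  For a single value the
    result equals that value.
    """
    ps = np.asarray(list(p_values), dtype=float)
    if ps.size == 0:
        raise ValueError("need at least one P-value")
    if np.any(ps <= 0) or np.any(ps > 1):
        raise ValueError("P-values must lie in (0, 1]")
    x = -2.0 * np.log(ps).sum()
    return float(sps.chi2.sf(x, df=2 * ps.size))


def expected_false_positives(n_tests: int, p_threshold: float) -> float:
    """Expected false candidates: number of alignments tested times threshold."""
    if n_tests < 0:
        raise ValueError("n_tests must be >= 0")
    if not 0 <= p_threshold <= 1:
        raise ValueError("p_threshold must be in [0, 1]")
    return n_tests * p_threshold


def classify(
    pairs: Sequence[PairCovariation],
    ss: SecondaryStructure,
    alpha: float = 0.05,
    min_sig: int = 3,
    min_same_stem: int = 2,
    rescue_threshold: float = 1e-4,
    bulge_tol: int = 0,
) -> CandidateVerdict:
    """Apply the two candidate criteria with the single-strong-pair rescue path.

    ``pass`` requires at least *min_sig* significant pairs overall and at
    least *min_same_stem* of them within one stem of *ss*.  A non-passing
    alignment is ``rescue`` when any pair's E-value is below
    *rescue_threshold*, else ``fail``.  The aggregated P-value combines the
    significant pairs' E-values (clamped at 1) by Fisher's method.
    """
    sig = sorted(
        (p for p in pairs if p.evalue <= alpha), key=lambda p: (p.evalue, p.pair)
    )
    sig_pairs = {p.pair for p in sig}
    max_same = 0
    for stem in stems(ss, bulge_tol=bulge_tol):
        max_same = max(max_same, sum(1 for q in stem.pairs if q in sig_pairs))
    if len(sig) >= min_sig and max_same >= min_same_stem:
        verdict = "pass"
    elif any(p.evalue < rescue_threshold for p in pairs):
        verdict = "rescue"
    else:
        verdict = "fail"
    evalues = tuple(p.evalue for p in sig)
    n_clamped = sum(1 for e in evalues if e > 1.0)
    aggregated = (
        fisher_aggregate([min(e, 1.0) for e in evalues]) if evalues else 1.0
    )
    return CandidateVerdict(
        n_significant=len(sig),
        max_same_stem=max_same,
        verdict=verdict,
        significant_evalues=evalues,
        aggregated_p=aggregated,
        n_clamped=n_clamped,
    )


def codon_covariation_filter(
    pairs: Sequence[PairCovariation],
    colmap: Mapping[int, int],
    alpha: float = 0.05,
    max_allowed: int = 3,
) -> tuple[bool, int]:
    """Flag alignments whose covariation looks like codon structure.

    Counts significant pairs whose ungapped-consensus positions are one or
    two apart — the separations produced by interactions between positions
    of a codon — and flags the alignment when the count strictly exceeds
    *max_allowed*.
    """
    n_codon_like = 0
    for p in pairs:
        if p.evalue > alpha:
            continue
        pi, pj = colmap.get(p.i), colmap.get(p.j)
        if pi is None or pj is None:
            continue
        if abs(pj - pi) in (1, 2):
            n_codon_like += 1
    return n_codon_like > max_allowed, n_codon_like


def window_region(
    region_length: int,
    window: int = 1000,
    step_overlap: int = 500,
    min_len: int = 100,
) -> list[tuple[int, int]]:
    """Sliding windows over a region, 1-based inclusive.

    Regions shorter than *min_len* are not screened (too short for a
    specific homology hit).  Regions up to *window* long form a single
    window; longer ones are tiled with stride ``window - step_overlap``
    with a final remainder-covering window ending at the region end.
    """
    if region_length < 1:
        raise ValueError("region_length must be >= 1")
    if region_length < min_len:
        return []
    if region_length <= window:
        return [(1, region_length)]
    step = window - step_overlap
    out = []
    s = 1
    while True:
        e = s + window - 1
        if e >= region_length:
            out.append((s, region_length))
            break
        out.append((s, e))
        s += step
    return out


def prepare_flanked_query(
    utr: Region,
    cds: Region,
    utr_cap: int = 2000,
    cds_cap: int = 1000,
) -> tuple[Region, Region]:
    """Truncate a UTR/CDS pair to the capped lengths nearest their junction.

    The UTR keeps at most *utr_cap* nucleotides adjacent to the CDS and the
    flanking CDS at most *cds_cap* adjacent to the UTR, independent of
    strand (capping is junction-relative; the strand only determines whether
    the UTR is 5' or 3').  The regions must be adjacent on one contig.
    """
    if utr.contig != cds.contig:
        raise ValueError("UTR and CDS are on different contigs")
    if utr.end + 1 == cds.start:  # UTR left of CDS
        utr_part = replace(utr, start=max(utr.start, utr.end - utr_cap + 1))
        cds_part = replace(cds, end=min(cds.end, cds.start + cds_cap - 1))
    elif cds.end + 1 == utr.start:  # CDS left of UTR
        utr_part = replace(utr, end=min(utr.end, utr.start + utr_cap - 1))
        cds_part = replace(cds, start=max(cds.start, cds.end - cds_cap + 1))
    else:
        raise ValueError(
            f"regions {utr.start}..{utr.end} and {cds.start}..{cds.end} "
            "are not adjacent"
        )
    return utr_part, cds_part


# ---------------------------------------------------------------------------
# Orchestration: annotate -> fold -> classify
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScanResult:
    pairs: tuple
    structure: SecondaryStructure
    verdict: CandidateVerdict
    consensus: str

    def to_dict(self) -> dict:
        from .fold import render_dotbracket

        return {
            "verdict": self.verdict.to_dict(),
            "dotbracket": render_dotbracket(self.structure, len(self.consensus)),
            "consensus": self.consensus,
        }


def _forceable(pairs, consensus):
    """Greedy non-conflicting subset of significant pairs, strongest first."""
    chosen: list[tuple[int, int]] = []
    used: set[int] = set()
    for p in sorted(pairs, key=lambda p: (p.evalue, p.pair)):
        i, j = p.pair
        if i in used or j in used:
            continue
        if not can_pair(consensus[i - 1], consensus[j - 1]):
            continue
        chosen.append((i, j))
        used.update((i, j))
    return chosen


def scan_alignment(
    aln: Alignment,
    config: ScreenConfig | None = None,
    calibration: NullCalibration | None = None,
) -> ScanResult:
    """Run the full per-alignment pipeline: covariation, fold, classification.

    Significant pairs are forced into the covariation-constrained fold (with
    a score bonus), negative pairs are excluded, and the classifier is
    applied to the result.  A ``rescue`` verdict triggers a second fold with
    the rescuing pair forced, mirroring the structure-informed second pass.
    """
    cfg = config or ScreenConfig()
    pairs = annotate_pairs(
        aln,
        alpha=cfg.alpha,
        s_min=cfg.s_min,
        n_null=cfg.n_null,
        seed=cfg.seed,
        calibration=calibration,
    )
    consensus = column_consensus(aln)
    significant = [p for p in pairs if p.is_significant]
    forced = _forceable(significant, consensus)
    excluded = {p.pair for p in pairs if p.is_negative}
    weights = {p: cfg.w_cov for p in forced}
    ss = constrained_fold(
        consensus,
        forced=forced,
        excluded=excluded,
        weights=weights,
        min_loop=cfg.min_loop,
    )
    verdict = classify(
        pairs,
        ss,
        alpha=cfg.alpha,
        min_sig=cfg.min_sig,
        min_same_stem=cfg.min_same_stem,
        rescue_threshold=cfg.rescue_threshold,
        bulge_tol=cfg.bulge_tol,
    )
    if verdict.verdict == "rescue":
        best = min(pairs, key=lambda p: (p.evalue, p.pair))
        if can_pair(consensus[best.i - 1], consensus[best.j - 1]):
            refold = _forceable([best] + significant, consensus)
            ss = constrained_fold(
                consensus,
                forced=refold,
                excluded=excluded - {best.pair},
                weights={p: cfg.w_cov for p in refold},
                min_loop=cfg.min_loop,
            )
    flagged, n_codon = codon_covariation_filter(
        pairs,
        ungapped_column_map(aln),
        alpha=cfg.alpha,
        max_allowed=cfg.max_codon_like,
    )
    verdict = replace(verdict, codon_flagged=flagged, n_codon_like=n_codon)
    return ScanResult(
        pairs=tuple(pairs), structure=ss, verdict=verdict, consensus=consensus
    )


def aggregate_screen(
    verdicts: Sequence[Mapping | CandidateVerdict],
    n_tests: int,
) -> dict:
    """Screen-level summary: P-value threshold and expected false positives.

    The detection threshold is the largest aggregated P-value among passing
    candidates (the weakest accepted signal); multiplied by the number of
    alignments tested it bounds the expected false-positive count for the
    screen.  Verdicts with no significant pairs are excluded from the
    threshold computation and counted separately.
    """
    records = [v.to_dict() if isinstance(v, CandidateVerdict) else dict(v) for v in verdicts]
    if not records:
        raise ValueError("need at least one verdict")
    usable = [r for r in records if r.get("n_significant", 0) >= 1]
    n_empty = len(records) - len(usable)
    passing = [r for r in usable if r.get("verdict") == "pass"]
    pool = passing or usable
    threshold = max((r["aggregated_p"] for r in pool), default=1.0)
    acct = ScreenAccounting(n_tests=n_tests, p_threshold=threshold)
    return {
        "n_verdicts": len(records),
        "n_pass": sum(1 for r in records if r.get("verdict") == "pass"),
        "n_rescue": sum(1 for r in records if r.get("verdict") == "rescue"),
        "n_excluded_no_significant": n_empty,
        "p_threshold": threshold,
        "n_tests": n_tests,
        "expected_false_positives": acct.expected_false_positives,
    }
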