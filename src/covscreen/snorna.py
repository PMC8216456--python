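"""H/ACA snoRNA motif detection and guide-target search.

H/ACA box snoRNAs guide pseudouridylation of rRNA uridines.  They carry an
H box (ANANNA) between their two hairpins and an ACA box at the 3' end, and
present the substrate in a pseudouridylation pocket: the interior loop of a
hairpin whose two strands pair with the rRNA immediately upstream and
downstream of the target U.  In the canonical pocket the target U and the
residue 3' of it remain unpaired, the 3' strand of the guide pairs with the
rRNA upstream of the U, and the 5' strand pairs downstream.

A match requires at least ``min_bp`` (default 4) consecutive Watson-Crick
or G:U wobble pairs on each side, with no mismatches inside the paired
runs; ``N`` in a consensus guide pairs with nothing and breaks a run.
False-positive rates are estimated by mononucleotide shuffling of the
target sequence.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .alignment import normalize_seq

__all__ = [
    "BoxAnnotation",
    "GuideTargetMatch",
    "find_boxes",
    "guide_target_search",
    "fpr_by_shuffle",
]

_WC_WOBBLE = frozenset(
    {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
)
_H_BOX = re.compile(r"(?=(A[ACGU]A[ACGU][ACGU]A))")


def _pairs(a: str, b: str) -> bool:
    return (a, b) in _WC_WOBBLE


def _is_wobble(a: str, b: str) -> bool:
    return (a, b) in {("G", "U"), ("U", "G")}


@dataclass(frozen=True)
class BoxAnnotation:
    """H and ACA box locations (1-based inclusive), either possibly absent."""

    h_box: tuple | None = None  # (start, end, matched_text)
    aca_box: tuple | None = None  # (start, end)


@dataclass(frozen=True)
class GuideTargetMatch:
    """A candidate pseudouridylation site on a target sequence.

    ``target_pos`` is the 1-based position of the target uridine (psi);
    ``left_bp``/``right_bp`` are the consecutive pair counts of the upstream
    and downstream flanks and ``n_wobble`` the G:U pairs among them.
    """

    target_pos: int
    left_bp: int
    right_bp: int
    n_wobble: int
    fpr: float | None = None

    @property
    def total_bp(self) -> int:
        return self.left_bp + self.right_bp


def find_boxes(seq: str, aca_window: int = 5) -> BoxAnnotation:
    """Locate the H box (ANANNA) and ACA box of an ungapped snoRNA sequence.

    The ACA box is an ``ACA`` whose end lies within *aca_window* of the 3'
    terminus; the H box is the last ANANNA match preceding the 3'-terminal
    region (i.e. before the ACA box when present).  Either may be absent.
    """
    s = normalize_seq(seq, allow_gaps=False)
    n = len(s)
    aca = None
    for m in re.finditer("ACA", s):
        end = m.end()  # 1-based inclusive end equals m.end()
        if end >= n - aca_window + 1:
            aca = (m.start() + 1, end)
    h_limit = (aca[0] - 1) if aca else max(0, n - aca_window)
    h = None
    for m in _H_BOX.finditer(s[:h_limit]):
        text = m.group(1)
        if m.start() + len(text) <= h_limit:
            h = (m.start() + 1, m.start() + len(text), text)
    return BoxAnnotation(h_box=h, aca_box=aca)


def _flank_runs(guide5: str, guide3: str, target: str, t: int) -> tuple[int, int, int]:
    """(left_bp, right_bp, n_wobble) for the pocket around 1-based target U *t*.

    The 3' guide strand (5'->3') pairs antiparallel with the target upstream
    of psi starting at t-1; the 5' strand pairs antiparallel with the target
    from t+2 downstream (psi and psi+1 unpaired).
    """
    n = len(target)
    left = right = wob = 0
    for k in range(1, len(guide3) + 1):
        tp = t - k
        g = guide3[k - 1]
        if tp < 1 or g == "N" or not _pairs(g, target[tp - 1]):
            break
        left += 1
        wob += _is_wobble(g, target[tp - 1])
    for k in range(1, len(guide5) + 1):
        tp = t + 1 + k
        g = guide5[len(guide5) - k]
        if tp > n or g == "N" or not _pairs(g, target[tp - 1]):
            break
        right += 1
        wob += _is_wobble(g, target[tp - 1])
    return left, right, wob


def guide_target_search(
    guide5: str,
    guide3: str,
    target: str,
    min_bp: int = 4,
) -> list[GuideTargetMatch]:
    """All pseudouridylation pockets of *target* complementary to the guide.

    Every target uridine is tested for antiparallel WC/wobble pairing of the
    guide's 3' strand against its upstream flank and of the 5' strand
    against its downstream flank (the U and the following residue stay
    unpaired).  A match needs at least *min_bp* consecutive pairs on each
    side.
    """
    if not guide5 or not guide3:
        raise ValueError("guide halves must be non-empty")
    g5 = normalize_seq(guide5, allow_gaps=False)
    g3 = normalize_seq(guide3, allow_gaps=False)
    tgt = normalize_seq(target, allow_gaps=False)
    out = []
    for t, ch in enumerate(tgt, start=1):
        if ch != "U":
            continue
        left, right, wob = _flank_runs(g5, g3, tgt, t)
        if left >= min_bp and right >= min_bp:
            out.append(
                GuideTargetMatch(
                    target_pos=t, left_bp=left, right_bp=right, n_wobble=wob
                )
            )
    return out


def fpr_by_shuffle(
    guide5: str,
    guide3: str,
    target: str,
    observed: GuideTargetMatch,
    n_shuffles: int = 10000,
    seed: int = 0,
    min_bp: int = 4,
) -> float:
    """False-positive rate of a guide-target match by target shuffling.

    The fraction of mononucleotide (composition-preserving) shuffles of the
    target that contain at least one pocket with (i) as many total base
    pairs as the observed match and (ii) no more wobble pairs.  A degenerate
    observed match with zero required pairs is vacuously matched by every
    shuffle.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    if observed.total_bp <= 0:
        return 1.0
    tgt = list(normalize_seq(target, allow_gaps=False))
    rng = np.random.default_rng(seed)
    hits = 0
    arr = np.array(tgt)
    for _ in range(n_shuffles):
        shuffled = "".join(arr[rng.permutation(arr.size)])
        for m in guide_target_search(guide5, guide3, shuffled, min_bp=min_bp):
            if m.total_bp >= observed.total_bp and m.n_wobble <= observed.n_wobble:
                hits += 1
                break
    return hits / n_shuffles
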