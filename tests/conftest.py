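"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately re-derive quantities by the slowest, most
transparent route available (dictionary counting, exhaustive enumeration,
position-by-position checks) so they stay independent of the vectorized
implementation paths they validate.
"""

from __future__ import annotations

import math
from collections import Counter

import pytest

from covscreen import Alignment
from covscreen.fold import can_pair

GAPS = {"-", "."}


@pytest.fixture
def toy_alignment() -> Alignment:
    return Alignment.from_sequences(
        ["GGCAAAGCC", "GACAAAGUC", "GUCAAAGAC", "GCCAAAGGC"],
        ids=["s1", "s2", "s3", "s4"],
        ss_cons="<<<...>>>",
    )


def slow_g_statistic(aln: Alignment, i: int, j: int) -> float:
    """Dictionary-count G-test over gap-free rows of columns i, j (1-based)."""
    joint = Counter(
        (a, b)
        for a, b in zip(aln.column(i), aln.column(j))
        if a not in GAPS and b not in GAPS
    )
    n = sum(joint.values())
    if n < 2:
        return 0.0
    row = Counter()
    col = Counter()
    for (a, b), c in joint.items():
        row[a] += c
        col[b] += c
    g = 0.0
    for (a, b), c in joint.items():
        g += c * math.log(c * n / (row[a] * col[b]))
    return max(0.0, 2.0 * g)


def enumerate_nested_structures(seq: str, min_loop: int = 3):
    """Yield every nested structure (frozenset of 1-based pairs) of *seq*."""
    n = len(seq)

    def recurse(i: int, j: int):
        if i >= j:
            yield frozenset()
            return
        yield from recurse(i + 1, j)
        for k in range(i + min_loop + 1, j + 1):
            if can_pair(seq[i], seq[k]):
                for inner in recurse(i + 1, k - 1):
                    for outer in recurse(k + 1, j):
                        yield inner | outer | {(i + 1, k + 1)}

    yield from recurse(0, n - 1)


def brute_force_best_score(seq: str, min_loop: int = 3) -> float:
    """Maximum pair count over all nested structures, by full enumeration."""
    return max(
        (float(len(s)) for s in enumerate_nested_structures(seq, min_loop)),
        default=0.0,
    )


def brute_force_pocket_check(
    guide5: str, guide3: str, target: str, t: int, min_bp: int = 4
):
    """Re-validate a pseudouridylation pocket position-by-position.

    Returns (left_bp, right_bp, n_wobble) or None if the pocket fails the
    geometry (target U at t, >= min_bp consecutive WC/wobble pairs on each
    flank, psi and psi+1 unpaired).
    """
    ok = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
    wob = {("G", "U"), ("U", "G")}
    if target[t - 1] != "U":
        return None
    left = wobbles = 0
    for k in range(1, len(guide3) + 1):
        if t - k < 1:
            break
        g, tt = guide3[k - 1], target[t - k - 1]
        if g == "N" or (g, tt) not in ok:
            break
        left += 1
        wobbles += (g, tt) in wob
    right = 0
    for k in range(1, len(guide5) + 1):
        if t + 1 + k > len(target):
            break
        g, tt = guide5[-k], target[t + k]
        if g == "N" or (g, tt) not in ok:
            break
        right += 1
        wobbles += (g, tt) in wob
    if left < min_bp or right < min_bp:
        return None
    return left, right, wobbles
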