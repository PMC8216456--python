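"""Pairwise covariation statistics with permutation-null E-values.

For every pair of alignment columns a G-test of independence is computed
over the joint residue counts of the gap-free rows:

    G = 2 * sum_ab n_ab * ln( n_ab * N / (n_a * n_b) )

G is zero exactly when the joint counts factorize and grows with the
correlated variation (covariation) of the two columns.  Statistical
calibration uses a permutation null: columns are shuffled independently
across rows — destroying covariation while preserving composition and
per-column conservation — and the pooled all-pairs G distribution of many
such shuffled alignments yields an empirical survival function, optionally
smoothed beyond its maximum by a gamma fit to the upper tail.  E-values are
expected false pairs per alignment, i.e. the number of pairs tested times
the null survival probability.

Because rows are treated as exchangeable, these E-values are
anti-conservative for strongly phylogenetically structured alignments; an
externally computed (e.g. tree-aware) null can be supplied through the
``calibration`` hook of :func:`annotate_pairs`.

Covariation power is proxied per column by the substitution count: the
number of gap-free rows differing from the column's majority residue.  A
pair "has power" when both columns have at least ``s_min`` substitutions; a
pair with power but no significant covariation is a negative pair and is
excluded from proposed structures.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .alignment import GAP_CHARS, RESIDUES, Alignment, _shuffle_matrix

__all__ = [
    "PairCovariation",
    "NullCalibration",
    "encode",
    "pair_statistic",
    "gtest_matrix",
    "substitution_counts",
    "calibrate_null",
    "pair_evalue",
    "annotate_pairs",
    "write_pair_report",
]

_CODE = {c: k for k, c in enumerate(RESIDUES)}
_GAP_CODE = 4


@dataclass(frozen=True)
class PairCovariation:
    """Covariation call for one column pair (i < j, 1-based)."""

    i: int
    j: int
    stat: float
    evalue: float
    subs_i: int
    subs_j: int
    has_power: bool
    is_significant: bool

    @property
    def is_negative(self) -> bool:
        return self.has_power and not self.is_significant

    @property
    def pair(self) -> tuple[int, int]:
        return (self.i, self.j)


@dataclass(frozen=True)
class NullCalibration:
    """Pooled permutation-null statistics with an optional gamma upper tail.

    ``null_stats`` is sorted ascending.  ``tail_fit`` is
    ``(shape, scale, threshold, tail_mass)`` for a gamma fit to the
    exceedances over the empirical 95th percentile, used to extrapolate the
    survival function beyond the largest pooled null statistic.
    """

    n_null_alignments: int
    null_stats: np.ndarray
    seed: int
    tail_fit: tuple | None = None

    @property
    def n_pooled(self) -> int:
        return int(self.null_stats.size)

    def pvalues(self, stats: np.ndarray) -> np.ndarray:
        """Null survival P(stat' >= stat) with an add-one boundary rule."""
        stats = np.asarray(stats, dtype=float)
        ns = self.null_stats
        n = ns.size
        count_ge = n - np.searchsorted(ns, stats, side="left")
        p = (count_ge + 1.0) / (n + 1.0)
        if self.tail_fit is not None and n:
            shape, scale, threshold, tail_mass = self.tail_fit
            beyond = stats > ns[-1]
            if np.any(beyond):
                tail_p = tail_mass * sps.gamma.sf(
                    stats[beyond] - threshold, shape, scale=scale
                )
                p[beyond] = np.minimum(p[beyond], np.maximum(tail_p, 0.0))
        return p


def encode(aln: Alignment) -> np.ndarray:
    """Integer-code the alignment: A,C,G,U -> 0..3, gaps -> 4."""
    mat = aln.char_matrix()
    out = np.full(mat.shape, _GAP_CODE, dtype=np.int8)
    for c, k in _CODE.items():
        out[mat == c] = k
    return out


def _gtest_from_onehot(X: np.ndarray) -> np.ndarray:
    """All-pairs G matrix from a one-hot (rows, cols, 4) tensor."""
    n_cols = X.shape[1]
    # joint counts C[i, a, j, b] over rows gap-free at both columns
    C = np.tensordot(X, X, axes=([0], [0]))  # (cols, 4, cols, 4)
    C = C.transpose(0, 2, 1, 3)  # (i, j, a, b)
    N = C.sum(axis=(2, 3))
    A = C.sum(axis=3)  # (i, j, a)
    B = C.sum(axis=2)  # (i, j, b)
    with np.errstate(divide="ignore", invalid="ignore"):
        logterm = (
            np.log(C)
            + np.log(N)[:, :, None, None]
            - np.log(A)[:, :, :, None]
            - np.log(B)[:, :, None, :]
        )
    logterm[~(C > 0)] = 0.0
    G = 2.0 * (C * logterm).sum(axis=(2, 3))
    G[N < 2] = 0.0
    np.fill_diagonal(G, 0.0)
    return np.maximum(G, 0.0)


def gtest_matrix(coded: np.ndarray) -> np.ndarray:
    """Symmetric (n_cols, n_cols) matrix of pairwise G statistics."""
    X = np.zeros((*coded.shape, 4))
    for k in range(4):
        X[..., k] = coded == k
    return _gtest_from_onehot(X)


def _upper_triangle(G: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(G.shape[0], k=1)
    return G[iu]


def pair_statistic(aln: Alignment, i: int, j: int) -> float:
    """G statistic of independence for 1-based columns *i* < *j*.

    Computed over rows with no gap at either position; returns 0 when fewer
    than two such rows exist.
    """
    if not 1 <= i < j <= aln.n_columns:
        raise ValueError(f"need 1 <= i < j <= {aln.n_columns}, got ({i},{j})")
    ci, cj = aln.column(i), aln.column(j)
    codes = np.array(
        [
            (_CODE[a], _CODE[b])
            for a, b in zip(ci, cj)
            if a not in GAP_CHARS and b not in GAP_CHARS
        ],
        dtype=np.int8,
    ).reshape(-1, 2)
    if codes.shape[0] < 2:
        return 0.0
    C = np.zeros((4, 4))
    np.add.at(C, (codes[:, 0], codes[:, 1]), 1.0)
    N = C.sum()
    A, B = C.sum(axis=1), C.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        logterm = np.log(C) + np.log(N) - np.log(A)[:, None] - np.log(B)[None, :]
    logterm[~(C > 0)] = 0.0
    return float(max(0.0, 2.0 * (C * logterm).sum()))


def substitution_counts(aln: Alignment, i: int) -> int:
    """Number of gap-free rows in column *i* differing from its majority residue.

    The majority is taken over gap-free rows with ties broken alphabetically
    (A < C < G < U).  This is the per-column variation count used as the
    covariation-power proxy.
    """
    col = aln.column(i)
    residues = [c for c in col if c not in GAP_CHARS]
    if not residues:
        return 0
    counts: dict[str, int] = {}
    for c in residues:
        counts[c] = counts.get(c, 0) + 1
    top = min(counts, key=lambda c: (-counts[c], c))
    return len(residues) - counts[top]


def calibrate_null(
    aln: Alignment,
    n_null: int,
    seed: int,
    fit_tail: bool = True,
) -> NullCalibration:
    """Pool all-pairs G statistics over *n_null* column-shuffled alignments.

    Each null alignment is produced by independently permuting every column
    across rows (seeded; the per-shuffle seeds are drawn from a generator
    initialized with *seed*, so results are fully deterministic).  With
    ``fit_tail`` a gamma distribution is fitted to the exceedances over the
    pooled 95th percentile to allow survival extrapolation beyond the
    largest null statistic.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    if aln.n_columns < 2:
        raise ValueError("alignment must have at least 2 columns")
    coded = encode(aln)
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=n_null)
    pools = []
    for s in child_seeds:
        shuffled = _shuffle_matrix(coded, np.random.default_rng(int(s)))
        pools.append(_upper_triangle(gtest_matrix(shuffled)))
    null_stats = np.sort(np.concatenate(pools))
    tail = None
    if fit_tail and null_stats.size >= 40:
        threshold = float(np.quantile(null_stats, 0.95))
        exceed = null_stats[null_stats > threshold] - threshold
        if exceed.size >= 10 and exceed.max() > 0:
            shape, _, scale = sps.gamma.fit(exceed, floc=0)
            tail = (float(shape), float(scale), threshold,
                    exceed.size / null_stats.size)
    return NullCalibration(
        n_null_alignments=n_null, null_stats=null_stats, seed=int(seed),
        tail_fit=tail,
    )


def pair_evalue(stat: float, calib: NullCalibration, n_pairs_tested: int) -> float:
    """Expected false pairs at or above *stat*: n_pairs_tested * P_null(>= stat)."""
    if calib.n_pooled == 0:
        raise ValueError("calibration holds no null statistics")
    return float(n_pairs_tested * calib.pvalues(np.array([stat]))[0])


def annotate_pairs(
    aln: Alignment,
    alpha: float = 0.05,
    s_min: int = 2,
    n_null: int = 20,
    seed: int = 0,
    calibration: NullCalibration | None = None,
) -> list[PairCovariation]:
    """Covariation call for every column pair (i < j) of the alignment.

    A pair is significant when its E-value is at most *alpha*; it has power
    when both columns carry at least *s_min* substitutions.  Pass a
    precomputed *calibration* to reuse (or externally supply) null
    statistics; otherwise a permutation null is calibrated from the
    alignment itself.
    """
    if aln.n_columns < 2:
        raise ValueError("alignment must have at least 2 columns")
    if calibration is None:
        calibration = calibrate_null(aln, n_null=n_null, seed=seed)
    coded = encode(aln)
    G = gtest_matrix(coded)
    n_cols = aln.n_columns
    subs = [substitution_counts(aln, c) for c in range(1, n_cols + 1)]
    iu = np.triu_indices(n_cols, k=1)
    stats = G[iu]
    n_pairs = stats.size
    evalues = n_pairs * calibration.pvalues(stats)
    out = []
    for (i0, j0), g, e in zip(zip(*iu), stats, evalues):
        i, j = int(i0) + 1, int(j0) + 1
        out.append(
            PairCovariation(
                i=i, j=j, stat=float(g), evalue=float(e),
                subs_i=subs[i - 1], subs_j=subs[j - 1],
                has_power=min(subs[i - 1], subs[j - 1]) >= s_min,
                is_significant=bool(e <= alpha),
            )
        )
    return out


def write_pair_report(pairs: Sequence[PairCovariation], path) -> None:
    """Tab-separated per-pair report (one file per alignment)."""
    df = pd.DataFrame(
        {
            "i": [p.i for p in pairs],
            "j": [p.j for p in pairs],
            "stat": [p.stat for p in pairs],
            "evalue": [p.evalue for p in pairs],
            "subs_i": [p.subs_i for p in pairs],
            "subs_j": [p.subs_j for p in pairs],
            "power": [p.has_power for p in pairs],
            "significant": [p.is_significant for p in pairs],
            "negative": [p.is_negative for p in pairs],
        }
    )
    df.to_csv(Path(path), sep="\t", index=False)
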