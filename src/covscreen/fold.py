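"""Covariation-constrained maximum-pairing secondary structure prediction.

The fold here exists to organize covarying base pairs into stems, not to
predict a minimum-free-energy structure: scoring is pair-count based (one
point per eligible canonical/wobble pair) with a configurable bonus for
significantly covarying pairs, maximized by a Nussinov-style dynamic
program.  Significant pairs may be forced into the structure and negative
pairs (power but no covariation) excluded.  Forced pairs that cross the
chosen nested layer are never dropped; they are emitted in additional
pseudoknot layers, rendered with ``Aa``, ``Bb``, ... letters.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "SecondaryStructure",
    "Stem",
    "StructureParseError",
    "ConstraintError",
    "pairs_from_structure",
    "constrained_fold",
    "stems",
    "render_dotbracket",
]

#: Canonical Watson-Crick plus G:U wobble pairs.
CANONICAL_PAIRS = frozenset(
    {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
)

_OPEN = {"(": ")", "<": ">", "[": "]", "{": "}"}
_CLOSE = {v: k for k, v in _OPEN.items()}
_UNPAIRED = set(".,:_-~")


class StructureParseError(ValueError):
    """Raised when a WUSS/dot-bracket string cannot be parsed."""


class ConstraintError(ValueError):
    """Raised when folding constraints are mutually inconsistent."""


def can_pair(a: str, b: str) -> bool:
    """True if residues *a*, *b* may base pair (WC/wobble; N matches anything)."""
    if a == "N" or b == "N":
        return True
    return (a, b) in CANONICAL_PAIRS


def pairs_from_structure(text: str) -> tuple[frozenset, tuple]:
    """Parse a WUSS/dot-bracket string into base pairs.

    Returns ``(pairs, layers)`` where positions are 1-based.  All bracket
    types ``()<>[]{}`` count as the nested (primary) layer; uppercase /
    lowercase letter pairs (``Aa``, ``Bb``, ...) each form a pseudoknot
    layer.  Unrecognized unpaired symbols are tolerated.
    """
    bracket_stacks: dict[str, list[int]] = {b: [] for b in _OPEN}
    letter_stacks: dict[str, list[int]] = {}
    primary: set[tuple[int, int]] = set()
    letter_pairs: dict[str, set[tuple[int, int]]] = {}
    for pos, ch in enumerate(text, start=1):
        if ch in _OPEN:
            bracket_stacks[ch].append(pos)
        elif ch in _CLOSE:
            stack = bracket_stacks[_CLOSE[ch]]
            if not stack:
                raise StructureParseError(
                    f"unbalanced '{ch}' at structure position {pos}"
                )
            primary.add((stack.pop(), pos))
        elif ch in string.ascii_uppercase and ch != "N":
            letter_stacks.setdefault(ch, []).append(pos)
        elif ch in string.ascii_lowercase:
            up = ch.upper()
            stack = letter_stacks.get(up, [])
            if not stack:
                raise StructureParseError(
                    f"unbalanced '{ch}' at structure position {pos}"
                )
            letter_pairs.setdefault(up, set()).add((stack.pop(), pos))
        # everything else: unpaired / annotation symbol
    for b, stack in bracket_stacks.items():
        if stack:
            raise StructureParseError(
                f"unclosed '{b}' opened at structure position {stack[-1]}"
            )
    for letter, stack in letter_stacks.items():
        if stack:
            raise StructureParseError(
                f"unclosed '{letter}' opened at structure position {stack[-1]}"
            )
    layers = [frozenset(primary)]
    for letter in sorted(letter_pairs):
        layers.append(frozenset(letter_pairs[letter]))
    pairs = frozenset().union(*layers) if layers else frozenset()
    return pairs, tuple(layers)


@dataclass(frozen=True)
class SecondaryStructure:
    """A set of base pairs partitioned into a nested layer plus pseudoknots.

    ``layers[0]`` is the nested (primary) layer; subsequent layers hold
    crossing pairs.  Positions are 1-based; each position is used at most
    once across all layers.
    """

    layers: tuple = (frozenset(),)

    def __post_init__(self):
        seen: set[int] = set()
        for layer in self.layers:
            for i, j in layer:
                if not i < j:
                    raise ValueError(f"pair ({i},{j}) must have i < j")
                if i in seen or j in seen:
                    raise ValueError(f"position reused in pair ({i},{j})")
                seen.update((i, j))

    @property
    def pairs(self) -> frozenset:
        return frozenset().union(*self.layers)

    @property
    def n_pairs(self) -> int:
        return sum(len(layer) for layer in self.layers)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[int, int]]) -> "SecondaryStructure":
        """Build a structure, greedily pushing crossing pairs to pseudoknot layers."""
        return cls(layers=_layer_pairs(sorted(set(map(tuple, pairs)))))

    @classmethod
    def from_text(cls, text: str) -> "SecondaryStructure":
        _, layers = pairs_from_structure(text)
        return cls(layers=layers)


@dataclass(frozen=True)
class Stem:
    """A maximal run of stacked base pairs (a helix)."""

    pairs: tuple

    @property
    def length(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair) -> bool:
        return tuple(pair) in self.pairs


def _crosses(p: tuple[int, int], q: tuple[int, int]) -> bool:
    (a, b), (c, d) = p, q
    return (a < c < b < d) or (c < a < d < b)


def _conflicts(p: tuple[int, int], q: tuple[int, int]) -> bool:
    return bool({p[0], p[1]} & {q[0], q[1]})


def _layer_pairs(pairs: Sequence[tuple[int, int]]) -> tuple:
    """Greedy assignment of pairs to non-crossing layers (first-fit)."""
    layers: list[set] = [set()]
    for p in pairs:
        placed = False
        for layer in layers:
            if not any(_crosses(p, q) or _conflicts(p, q) for q in layer):
                layer.add(p)
                placed = True
                break
        if not placed:
            layers.append({p})
    return tuple(frozenset(l) for l in layers)


def _validate_constraints(consensus, forced, excluded):
    n = len(consensus)
    used: set[int] = set()
    for i, j in forced:
        if not (1 <= i < j <= n):
            raise ConstraintError(f"forced pair ({i},{j}) out of range 1..{n}")
        if i in used or j in used:
            raise ConstraintError(f"forced pairs conflict at position {i if i in used else j}")
        used.update((i, j))
        if not can_pair(consensus[i - 1], consensus[j - 1]):
            raise ConstraintError(
                f"forced pair ({i},{j}) = {consensus[i-1]}:{consensus[j-1]} "
                "is not a canonical/wobble pair"
            )
    clash = set(forced) & set(excluded)
    if clash:
        raise ConstraintError(f"pairs both forced and excluded: {sorted(clash)}")


def constrained_fold(
    consensus: str,
    forced: Iterable[tuple[int, int]] = (),
    excluded: Iterable[tuple[int, int]] = (),
    weights: Mapping[tuple[int, int], float] | None = None,
    min_loop: int = 3,
) -> SecondaryStructure:
    """Maximum-weight nested fold of *consensus* under pairing constraints.

    Dynamic-programming maximization of the summed pair weights (default 1
    per eligible pair plus any bonus from *weights*) over nested structures
    in which every non-crossing forced pair is included, every excluded pair
    is prohibited, and only Watson-Crick/wobble pairs of the consensus are
    eligible (``N`` matches anything).  Forced pairs that cannot sit in the
    nested layer (crossing, or hairpin shorter than *min_loop*) are emitted
    in additional pseudoknot layers.
    """
    consensus = consensus.upper().replace("T", "U")
    forced = {tuple(p) for p in forced}
    excluded = {tuple(p) for p in excluded}
    weights = dict(weights or {})
    _validate_constraints(consensus, forced, excluded)
    n = len(consensus)

    def pair_weight(p):
        return 1.0 + float(weights.get(p, 0.0))

    # Partition forced pairs: a greedy maximal non-crossing subset (by
    # descending weight) goes to the nested layer; the rest become knots.
    nestable = [p for p in sorted(forced, key=lambda p: (-pair_weight(p), p))
                if p[1] - p[0] - 1 >= min_loop]
    primary_forced: list[tuple[int, int]] = []
    for p in nestable:
        if not any(_crosses(p, q) for q in primary_forced):
            primary_forced.append(p)
    knot_forced = sorted(forced - set(primary_forced),
                         key=lambda p: (-pair_weight(p), p))

    partner = {}
    for i, j in primary_forced:
        partner[i - 1] = j - 1
        partner[j - 1] = i - 1
    knot_positions = {x - 1 for p in knot_forced for x in p}

    # Eligibility/score matrix, 0-based, -inf where pairing is disallowed.
    S = np.full((n, n), -np.inf)
    for i in range(n):
        for j in range(i + min_loop + 1, n):
            if (i + 1, j + 1) in excluded:
                continue
            if i in knot_positions or j in knot_positions:
                continue
            if i in partner and partner[i] != j:
                continue
            if j in partner and partner[j] != i:
                continue
            if can_pair(consensus[i], consensus[j]):
                S[i, j] = pair_weight((i + 1, j + 1))

    # best[i, j] = optimal score on i..j inclusive; padded so that empty
    # intervals (i > j) read as 0.
    best = np.zeros((n + 2, n + 2))
    NEG = -np.inf
    for i in range(n - 1, -1, -1):
        for j in range(i, n):
            leave = NEG if i in partner else best[i + 1, j]
            v = leave
            if j > i:
                cand = S[i, i + 1 : j + 1] + best[i + 1, i:j] + best[i + 2 : j + 2, j]
                if cand.size:
                    m = cand.max()
                    if m > v:
                        v = m
            best[i, j] = v

    if n and not np.isfinite(best[0, n - 1]):
        raise ConstraintError("constraints admit no nested structure")

    # Traceback (iterative, deterministic: unpaired branch first, then the
    # smallest k attaining the optimum).
    pairs: list[tuple[int, int]] = []
    stack = [(0, n - 1)] if n else []
    eps = 1e-9
    while stack:
        i, j = stack.pop()
        if i >= j:
            continue
        if i not in partner and best[i + 1, j] >= best[i, j] - eps:
            stack.append((i + 1, j))
            continue
        cand = S[i, i + 1 : j + 1] + best[i + 1, i:j] + best[i + 2 : j + 2, j]
        k_rel = int(np.argmax(cand >= best[i, j] - eps))
        k = i + 1 + k_rel
        pairs.append((i + 1, k + 1))
        stack.append((i + 1, k - 1))
        stack.append((k + 1, j))

    layers = [frozenset(pairs)]
    if knot_forced:
        layers.extend(_layer_pairs(knot_forced))
    return SecondaryStructure(layers=tuple(layers))


def stems(ss: SecondaryStructure, bulge_tol: int = 0) -> list[Stem]:
    """Partition the structure's pairs into maximal stacking runs.

    Consecutive members of a stem satisfy (i+1, j-1) stacking; with
    ``bulge_tol = k`` a run may jump up to *k* unpaired positions on either
    strand.  Runs never span pseudoknot layers.
    """
    out: list[Stem] = []
    step = 1 + bulge_tol
    for layer in ss.layers:
        run: list[tuple[int, int]] = []
        for i, j in sorted(layer):
            if run:
                pi, pj = run[-1]
                if pi < i <= pi + step and pj - step <= j < pj:
                    run.append((i, j))
                    continue
                out.append(Stem(pairs=tuple(run)))
            run = [(i, j)]
        if run:
            out.append(Stem(pairs=tuple(run)))
    return out


def render_dotbracket(ss: SecondaryStructure, length: int) -> str:
    """Dot-bracket text: primary layer as ``()``, knot layers as ``Aa``, ``Bb``, ..."""
    if ss.pairs and max(j for _, j in ss.pairs) > length:
        raise ValueError("structure contains positions beyond the given length")
    if len(ss.layers) - 1 > 26:
        raise ValueError("more pseudoknot layers than letters in the alphabet")
    chars = ["."] * length
    for level, layer in enumerate(ss.layers):
        if level == 0:
            op, cl = "(", ")"
        else:
            op = string.ascii_uppercase[level - 1]
            cl = op.lower()
        for i, j in layer:
            chars[i - 1] = op
            chars[j - 1] = cl
    return "".join(chars)
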