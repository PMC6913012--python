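"""Brute-force oracles and random-instance generators shared by the tests.

The oracles deliberately avoid the production code paths: chains and
conflict-free subsets are found by explicit subset enumeration over
bitmasks, so they stay independent of the dynamic programming and
branch-and-bound implementations they check.
"""

from __future__ import annotations

import numpy as np

from asmdiff.alignio import Alignment
from asmdiff.synteny import precedes


def random_forward_alignments(
    rng: np.random.Generator,
    n: int,
    coord_max: int = 1000,
    max_len: int = 120,
) -> list[Alignment]:
    """Random forward alignments of one chromosome pair, arbitrary overlaps."""
    out = []
    for i in range(n):
        rs = int(rng.integers(1, coord_max))
        qs = int(rng.integers(1, coord_max))
        rl = int(rng.integers(1, max_len))
        ql = int(rng.integers(1, max_len))
        ident = float(rng.uniform(0.8, 1.0))
        out.append(Alignment("r1", rs, rs + rl, "q1", qs, qs + ql, "+", ident, id=i))
    return out


def best_chain_score_bruteforce(alignments: list[Alignment]) -> float:
    """Maximum total score over every subset that forms a collinear chain.

    The chain predicate is an interval order, so pairwise comparability of a
    subset implies it is a chain; subsets are enumerated as bitmasks.
    """
    n = len(alignments)
    comp = [0] * n
    for i in range(n):
        for j in range(n):
            if i != j and (
                precedes(alignments[i], alignments[j])
                or precedes(alignments[j], alignments[i])
            ):
                comp[i] |= 1 << j
    scores = [a.score for a in alignments]
    valid = [False] * (1 << n)
    total = [0.0] * (1 << n)
    valid[0] = True
    best = 0.0
    for s in range(1, 1 << n):
        low = s & (-s)
        i = low.bit_length() - 1
        rest = s ^ low
        if valid[rest] and (rest & comp[i]) == rest:
            valid[s] = True
            total[s] = total[rest] + scores[i]
            if total[s] > best:
                best = total[s]
    return best


def mwis_bruteforce(weights: list[float], adj: list[set[int]]) -> float:
    """Maximum-weight independent set by explicit subset enumeration."""
    n = len(weights)
    nonadj = [0] * n
    for i in range(n):
        for j in range(n):
            if i != j and j not in adj[i]:
                nonadj[i] |= 1 << j
    valid = [False] * (1 << n)
    total = [0.0] * (1 << n)
    valid[0] = True
    best = 0.0
    for s in range(1, 1 << n):
        low = s & (-s)
        i = low.bit_length() - 1
        rest = s ^ low
        if valid[rest] and (rest & nonadj[i]) == rest:
            valid[s] = True
            total[s] = total[rest] + weights[i]
            if total[s] > best:
                best = total[s]
    return best


def random_conflict_instance(
    rng: np.random.Generator, n: int, p_edge: float = 0.3
) -> tuple[list[float], list[set[int]]]:
    weights = [float(rng.uniform(1, 100)) for _ in range(n)]
    adj: list[set[int]] = [set() for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p_edge:
                adj[i].add(j)
                adj[j].add(i)
    return weights, adj
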