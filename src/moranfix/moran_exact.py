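"""Exact fixation probabilities of the Moran birth-death process.

The process is a Markov chain on subsets S ⊆ V of vertices occupied by
invaders.  Each step one individual reproduces with probability
proportional to its fitness (r for invaders, 1 for residents) and its
offspring replaces a uniformly chosen neighbor; replacement weights are
w_ij = 1/d_i for neighbors, 0 otherwise.  On a connected undirected graph
the only recurrent states are ∅ (extinction) and V (fixation), so the
per-state fixation probabilities Φ_S solve a unique 2^N linear system.

Everything here is exact: fitness values are rationals and the linear
system is solved over arbitrary-precision rational arithmetic, so strict
comparisons against the well-mixed baseline are certificates, not
numerics.  States are encoded as bitmasks (bit i = vertex i); only
state-changing rates are materialised, giving a sparse system over the
2^N − 2 transient states ordered by invader count.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping

import networkx as nx

from ._ratsolve import QQ, solve_exact
from .graph_models import validate_graph

__all__ = [
    "FixationResult",
    "replacement_weight",
    "total_weight",
    "transition_probability",
    "fixation_vector",
    "average_fixation",
    "MAX_FULL_STATE_ORDER",
]

#: Full-state mode refuses graphs larger than this (2^N states).
MAX_FULL_STATE_ORDER = 14

RationalLike = Fraction | int | str | tuple


def _as_fraction(r) -> Fraction:
    if isinstance(r, tuple):
        return Fraction(*r)
    return Fraction(r)


def _as_mask(S, N: int) -> int:
    if isinstance(S, int):
        mask = S
    else:
        mask = 0
        for v in S:
            mask |= 1 << v
    if mask < 0 or mask >= (1 << N):
        raise ValueError(f"subset {S!r} is not a subset of 0..{N - 1}")
    return mask


@dataclass(frozen=True)
class FixationResult:
    """Exact solution of the fixation system for one graph and fitness."""

    graph_order: int
    fitness: Fraction
    per_state: Mapping[int, Fraction]  # bitmask -> Φ_S
    per_vertex: tuple[Fraction, ...]   # Φ_{i} for singleton starts
    average: Fraction                  # (1/N) Σ_i Φ_{i}


def replacement_weight(g: nx.Graph, i: int, j: int) -> Fraction:
    """w_ij = 1/d_i if i ∼ j else 0."""
    if i not in g or j not in g:
        raise ValueError(f"invalid vertex pair ({i}, {j})")
    return Fraction(1, g.degree(i)) if g.has_edge(i, j) else Fraction(0)

def total_weight(S, r: RationalLike, N: int) -> Fraction:
    """Total reproductive weight w_S = r·|S| + (N − |S|)."""
    k = bin(_as_mask(S, N)).count("1")
    return _as_fraction(r) * k + (N - k)


def transition_probability(g: nx.Graph, S, S2, r: RationalLike) -> Fraction:
    """One-step probability P_{S,S'} of the full-state chain.

    Nonzero only when S' differs from S by at most one vertex: a gain of j
    has rate r·Σ_{i∈S} w_ij / w_S, a loss of j has rate
    Σ_{i∉S} w_ij / w_S, and the self-loop carries the remaining mass.
    """
    N = g.number_of_nodes()
    rq = _as_fraction(r)
    m1, m2 = _as_mask(S, N), _as_mask(S2, N)
    wS = rq * bin(m1).count("1") + (N - bin(m1).count("1"))
    diff = m1 ^ m2
    if diff == 0:
        # self-loop: 1 minus all state-changing mass
        move = Fraction(0)
        for j in range(N):
            if m1 >> j & 1:
                move += sum(Fraction(1, g.degree(i)) for i in g.neighbors(j) if not m1 >> i & 1)
            else:
                move += rq * sum(Fraction(1, g.degree(i)) for i in g.neighbors(j) if m1 >> i & 1)
        return 1 - move / wS
    if bin(diff).count("1") > 1:
        return Fraction(0)
    j = diff.bit_length() - 1
    if m2 & diff:  # gain of j
        rate = rq * sum(Fraction(1, g.degree(i)) for i in g.neighbors(j) if m1 >> i & 1)
    else:          # loss of j
        rate = sum(Fraction(1, g.degree(i)) for i in g.neighbors(j) if not m1 >> i & 1)
    return rate / wS


def _transient_system(g: nx.Graph, r: Fraction):
    """Sparse (I − P) system over transient states, popcount-ordered.

    The total weight w_S cancels from the absorption equations (the
    embedded chain has the same absorption probabilities), so rows are
    built from unnormalised state-changing rates.
    """
    N = g.number_of_nodes()
    deg = [g.degree(i) for i in range(N)]
    nbrs = [list(g.neighbors(i)) for i in range(N)]
    full = (1 << N) - 1
    states = sorted(range(1, full), key=lambda s: (bin(s).count("1"), s))
    index = {s: i for i, s in enumerate(states)}
    rq = QQ(r.numerator, r.denominator)
    inv_deg = [QQ(1, d) for d in deg]

    rows, rhs = [], []
    for s in states:
        i = index[s]
        row = {}
        diag = QQ(0)
        for j in range(N):
            bit = 1 << j
            if s & bit:
                rate = sum((inv_deg[t] for t in nbrs[j] if not s >> t & 1), QQ(0))
                if rate:
                    diag += rate
                    if s != bit:  # loss to extinction contributes Φ_∅ = 0
                        row[index[s & ~bit]] = -rate
            else:
                rate = rq * sum((inv_deg[t] for t in nbrs[j] if s >> t & 1), QQ(0))
                if rate:
                    diag += rate
                    if s | bit != full:
                        row[index[s | bit]] = -rate
        row[i] = diag
        b = QQ(0)
        # rate into fixation, if any single gain completes V
        miss = full & ~s
        if bin(miss).count("1") == 1:
            j = miss.bit_length() - 1
            b = rq * sum((inv_deg[t] for t in nbrs[j] if s >> t & 1), QQ(0))
        rows.append(row)
        rhs.append(b)
    return states, rows, rhs


def fixation_vector(g: nx.Graph, r: RationalLike) -> FixationResult:
    """Exact Φ_S for every subset S, by solving the sparse transient system."""
    validate_graph(g)
    N = g.number_of_nodes()
    if N > MAX_FULL_STATE_ORDER:
        raise ValueError(
            f"full-state mode is capped at N = {MAX_FULL_STATE_ORDER} "
            f"(2^{N} states requested); use the lumped or Monte-Carlo modes"
        )
    rq = _as_fraction(r)
    if rq <= 0:
        raise ValueError(f"fitness must be positive, got {rq}")
    states, rows, rhs = _transient_system(g, rq)
    x = solve_exact(rows, rhs)
    per_state = {0: Fraction(0), (1 << N) - 1: Fraction(1)}
    for s, v in zip(states, x):
        per_state[s] = Fraction(int(v.numerator), int(v.denominator))
    per_vertex = tuple(per_state[1 << i] for i in range(N))
    avg = sum(per_vertex, Fraction(0)) / N
    return FixationResult(N, rq, per_state, per_vertex, avg)


def average_fixation(g: nx.Graph, r: RationalLike) -> Fraction:
    """Average fixation probability Φ(r) over uniform single-invader starts."""
    return fixation_vector(g, r).average
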