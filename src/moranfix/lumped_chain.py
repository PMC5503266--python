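"""Symmetry-reduced Moran chain for ℓ-graphs.

The automorphism group of the ℓ-graph of order N = 2n+2 contains all
permutations within each clique half, plus the swap exchanging (half A,
extra vertex u) with (half B, extra vertex v).  Orbits of invader sets
under this group are labeled by 4-tuples (e, k, k', e'): occupancy of one
extra vertex, invader counts in its attached half and in the other half,
and occupancy of the other extra vertex.  Since the partition into orbits
is induced by graph automorphisms, the chain is strongly lumpable: the
lumped chain is Markov and has exactly the same absorption probabilities,
with N(N+1)/2 states instead of 2^N.

The same machinery covers unbalanced variants (central clique split into
parts of sizes p ≠ q); there the swap symmetry is absent and states are
(e, k ≤ p, k' ≤ q, e') with no further identification.

Vertex labeling follows :func:`moranfix.graph_models.make_ell_graph`:
half A (or the p-part) first, then half B (the q-part), then u, then v.
"""

from __future__ import annotations

from fractions import Fraction
from typing import NamedTuple

from ._ratsolve import QQ, solve_sparse
from .graph_models import make_unbalanced_ell

__all__ = [
    "ReducedState",
    "reduce_state",
    "reduced_state_space",
    "lumped_transition",
    "reduced_fixation",
    "reduced_state_space_unbalanced",
    "reduced_fixation_unbalanced",
]


class ReducedState(NamedTuple):
    """Orbit label (e, k, k', e') of an invader set on an ℓ-variant."""

    e: int    # occupancy of extra vertex u (attached to the first part)
    k: int    # invaders in the first part
    kp: int   # invaders in the second part
    ep: int   # occupancy of extra vertex v


def _canonical(s: ReducedState, balanced: bool) -> ReducedState:
    """Swap-canonical representative: (k, e) >=lex (k', e') when balanced.

    The swap (A,u) <-> (B,v) maps (e,k,k',e') to (e',k',k,e); any
    consistent choice of orbit representative yields the same lumped
    chain, so ties (k = k', e = e') are fixed points and unambiguous.
    """
    if balanced and (s.k, s.e) < (s.kp, s.ep):
        return ReducedState(s.ep, s.kp, s.k, s.e)
    return s


def _as_mask(S, N: int) -> int:
    if isinstance(S, int):
        return S
    mask = 0
    for v in S:
        mask |= 1 << v
    if mask >= 1 << N:
        raise ValueError(f"subset {S!r} exceeds graph order {N}")
    return mask


def reduce_state(n: int, S) -> ReducedState:
    """Map a full invader set on ℓ_{2n+2} to its canonical orbit label."""
    if n < 2:
        raise ValueError(f"need n >= 2, got {n}")
    N = 2 * n + 2
    mask = _as_mask(S, N)
    k = bin(mask & ((1 << n) - 1)).count("1")
    kp = bin((mask >> n) & ((1 << n) - 1)).count("1")
    e = mask >> (2 * n) & 1
    ep = mask >> (2 * n + 1) & 1
    return _canonical(ReducedState(e, k, kp, ep), balanced=True)


def _state_space(p: int, q: int, balanced: bool) -> list[ReducedState]:
    states = set()
    for e in (0, 1):
        for ep in (0, 1):
            for k in range(p + 1):
                for kp in range(q + 1):
                    states.add(_canonical(ReducedState(e, k, kp, ep), balanced))
    # ordered by invader count first: keeps the linear system layer-banded
    return sorted(states, key=lambda s: (s.e + s.k + s.kp + s.ep, s))


def reduced_state_space(n: int) -> list[ReducedState]:
    """All canonical orbits of ℓ_{2n+2}; exactly N(N+1)/2 of them (N = 2n+2)."""
    if n < 2:
        raise ValueError(f"need n >= 2, got {n}")
    return _state_space(n, n, balanced=True)


def reduced_state_space_unbalanced(p: int, q: int) -> list[ReducedState]:
    """All states (e, k <= p, k' <= q, e') of the unbalanced variant."""
    return _state_space(p, q, balanced=False)


def _representative_mask(s: ReducedState, p: int, q: int) -> int:
    """One explicit full state in the orbit (first k of part one, etc.)."""
    mask = (1 << s.k) - 1
    mask |= ((1 << s.kp) - 1) << p
    mask |= s.e << (p + q)
    mask |= s.ep << (p + q + 1)
    return mask


def _row_rates(s: ReducedState, p: int, q: int, balanced: bool, rq, graph_data):
    """Unnormalised state-changing rates out of orbit s, grouped by target orbit."""
    deg, nbrs = graph_data
    N = p + q + 2
    mask = _representative_mask(s, p, q)
    out: dict[ReducedState, object] = {}
    for j in range(N):
        bit = 1 << j
        if mask & bit:
            rate = sum((QQ(1, deg[t]) for t in nbrs[j] if not mask >> t & 1), QQ(0))
        else:
            rate = rq * sum((QQ(1, deg[t]) for t in nbrs[j] if mask >> t & 1), QQ(0))
        if rate:
            target = mask ^ bit
            k = bin(target & ((1 << p) - 1)).count("1")
            kp = bin((target >> p) & ((1 << q) - 1)).count("1")
            t = _canonical(
                ReducedState(target >> (p + q) & 1, k, kp, target >> (p + q + 1) & 1),
                balanced,
            )
            out[t] = out.get(t, QQ(0)) + rate
    return out


def _graph_data(p: int, q: int):
    g = make_unbalanced_ell(p + q + 2, p, q)
    N = p + q + 2
    return [g.degree(i) for i in range(N)], [list(g.neighbors(i)) for i in range(N)]


def lumped_transition(n: int, s: ReducedState, s2: ReducedState, r) -> Fraction:
    """One-step probability of the lumped chain between canonical orbits.

    Equals Σ_{S' in orbit(s2)} P_{S,S'} for any representative S of s —
    well defined by strong lumpability.
    """
    if n < 2:
        raise ValueError(f"need n >= 2, got {n}")
    rf = Fraction(r) if not isinstance(r, tuple) else Fraction(*r)
    rq = QQ(rf.numerator, rf.denominator)
    s = _canonical(ReducedState(*s), balanced=True)
    s2 = _canonical(ReducedState(*s2), balanced=True)
    rates = _row_rates(s, n, n, True, rq, _graph_data(n, n))
    size = s.e + s.k + s.kp + s.ep
    N = 2 * n + 2
    wS = rf * size + (N - size)
    if s2 == s:
        move = sum((Fraction(int(v.numerator), int(v.denominator)) for v in rates.values()),
                   Fraction(0))
        return 1 - move / wS
    v = rates.get(s2, QQ(0))
    return Fraction(int(v.numerator), int(v.denominator)) / wS


def _solve(p: int, q: int, balanced: bool, r) -> dict[ReducedState, Fraction]:
    rf = Fraction(r) if not isinstance(r, tuple) else Fraction(*r)
    if rf <= 0:
        raise ValueError(f"fitness must be positive, got {rf}")
    rq = QQ(rf.numerator, rf.denominator)
    gdata = _graph_data(p, q)
    states = _state_space(p, q, balanced)
    extinction = ReducedState(0, 0, 0, 0)
    fixation = ReducedState(1, p, q, 1)
    transient = [s for s in states if s not in (extinction, fixation)]
    index = {s: i for i, s in enumerate(transient)}
    rows, rhs = [], []
    for s in transient:
        rates = _row_rates(s, p, q, balanced, rq, gdata)
        row = {index[s]: sum(rates.values(), QQ(0))}
        b = QQ(0)
        for t, rate in rates.items():
            if t == fixation:
                b += rate
            elif t != extinction:
                row[index[t]] = row.get(index[t], QQ(0)) - rate
        rows.append(row)
        rhs.append(b)
    x = solve_sparse(rows, rhs)
    phi = {extinction: Fraction(0), fixation: Fraction(1)}
    for s, v in zip(transient, x):
        phi[s] = Fraction(int(v.numerator), int(v.denominator))
    return phi


def reduced_fixation(n: int, r) -> Fraction:
    """Exact average fixation probability of ℓ_{2n+2} via the lumped chain.

    Uniform initialization: the 2n clique singletons map to the orbit
    (0,1,0,0) and the 2 extra-vertex singletons to (1,0,0,0).
    """
    if n < 2:
        raise ValueError(f"need n >= 2, got {n}")
    phi = _solve(n, n, True, r)
    clique = phi[_canonical(ReducedState(0, 1, 0, 0), True)]
    extra = phi[_canonical(ReducedState(1, 0, 0, 0), True)]
    N = 2 * n + 2
    return (2 * n * clique + 2 * extra) / N


def reduced_fixation_unbalanced(p: int, q: int, r) -> Fraction:
    """Exact average fixation probability of the (p, q) ℓ-variant."""
    phi = _solve(p, q, False, r)
    N = p + q + 2
    return (
        p * phi[ReducedState(0, 1, 0, 0)]
        + q * phi[ReducedState(0, 0, 1, 0)]
        + phi[ReducedState(1, 0, 0, 0)]
        + phi[ReducedState(0, 0, 0, 1)]
    ) / N
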