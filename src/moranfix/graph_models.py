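"""Graph families for evolutionary dynamics studies.

Constructs and validates the arenas of the birth-death Moran process:
complete graphs, stars, complete bipartite graphs, and the ℓ-family —
a complete graph K_{2n} split into two halves of n vertices, each half
wired to one of two mutually adjacent extra vertices.  Also provides
vertex temperatures (T_i = Σ_{j∼i} 1/d_j), the isothermal test, edge-list
serialization and exhaustive enumeration of small connected graphs up to
isomorphism.

Graphs are plain :class:`networkx.Graph` objects with vertices labeled
``0..N-1``.  The ℓ-graph labeling convention is load-bearing (the lumped
chain depends on it): half A is ``0..n-1``, half B is ``n..2n-1``, the
extra vertex attached to A is ``2n`` and the one attached to B is
``2n+1``.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from typing import Iterable, Iterator

import networkx as nx

__all__ = [
    "UndirectedGraph",
    "make_complete",
    "make_star",
    "make_complete_bipartite",
    "make_ell_graph",
    "make_unbalanced_ell",
    "vertex_temperature",
    "is_isothermal",
    "validate_graph",
    "enumerate_connected_graphs",
    "canonical_form",
    "read_edgelist",
    "write_edgelist",
]

#: In-memory graph container (simple undirected graph, vertices 0..N-1).
UndirectedGraph = nx.Graph

#: Exhaustive enumeration is refused above this order (N! * 2^(N(N-1)/2) blow-up).
MAX_ENUMERATION_ORDER = 7


def validate_graph(g: nx.Graph, require_connected: bool = True) -> None:
    """Check the structural invariants every fixation computation relies on.

    Raises ``ValueError`` on self-loops, non-0..N-1 labels, isolated
    vertices, or (by default) disconnectedness — absorption at fixation is
    only guaranteed from every state on a connected undirected graph.
    """
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError(f"graph must have at least 2 vertices, got {n}")
    if set(g.nodes) != set(range(n)):
        raise ValueError("vertices must be labeled 0..N-1")
    if any(g.has_edge(v, v) for v in g.nodes):
        raise ValueError("self-loops are not allowed")
    if any(d == 0 for _, d in g.degree):
        raise ValueError("isolated vertices are not allowed")
    if require_connected and not nx.is_connected(g):
        comps = [sorted(c) for c in nx.connected_components(g)]
        raise ValueError(f"graph is disconnected; components: {comps}")


def make_complete(N: int) -> nx.Graph:
    """Complete graph K_N — the well-mixed population of size N."""
    if N < 2:
        raise ValueError(f"complete graph needs N >= 2, got {N}")
    return nx.complete_graph(N)


def make_star(m: int) -> nx.Graph:
    """Star K_{1,m}: one center (vertex 0) joined to m leaves."""
    if m < 1:
        raise ValueError(f"star needs m >= 1 leaves, got {m}")
    return nx.star_graph(m)


def make_complete_bipartite(a: int, b: int) -> nx.Graph:
    """Complete bipartite K_{a,b}; part one is 0..a-1, part two a..a+b-1."""
    if a < 1 or b < 1:
        raise ValueError(f"bipartite parts must be >= 1, got ({a}, {b})")
    return nx.complete_bipartite_graph(a, b)


def make_ell_graph(n: int) -> nx.Graph:
    """Balanced ℓ-graph of order 2n+2.

    K_{2n} on vertices 0..2n-1 split into halves A = 0..n-1 and
    B = n..2n-1; extra vertex u = 2n is adjacent to all of A, extra
    vertex v = 2n+1 to all of B, and u ∼ v.  Clique vertices have degree
    2n, the extra vertices degree n+1.
    """
    if n < 2:
        raise ValueError(f"ell-graph needs half-size n >= 2, got {n}")
    return make_unbalanced_ell(2 * n + 2, n, n)


def make_unbalanced_ell(total_order: int, p: int, q: int) -> nx.Graph:
    """Unbalanced ℓ-variant: central clique K_{p+q} with an unequal split.

    Vertex u = p+q is adjacent to the p-part (0..p-1) and to v;
    v = p+q+1 is adjacent to the q-part (p..p+q-1) and to u.
    """
    if p < 1 or q < 1:
        raise ValueError(f"partition sizes must be >= 1, got ({p}, {q})")
    if p + q + 2 != total_order:
        raise ValueError(
            f"inconsistent spec: p + q + 2 = {p + q + 2} != total_order = {total_order}"
        )
    g = nx.complete_graph(p + q)
    u, v = p + q, p + q + 1
    g.add_edges_from((u, i) for i in range(p))
    g.add_edges_from((v, i) for i in range(p, p + q))
    g.add_edge(u, v)
    return g


def vertex_temperature(g: nx.Graph, i: int) -> Fraction:
    """Temperature T_i = Σ_{j∼i} 1/d_j as an exact rational."""
    if i not in g:
        raise ValueError(f"vertex {i} not in graph")
    return sum((Fraction(1, g.degree(j)) for j in g.neighbors(i)), Fraction(0))


def is_isothermal(g: nx.Graph) -> bool:
    """True iff all vertex temperatures are exactly equal.

    By the Circulation Theorem an isothermal graph has the same fixation
    probability as the well-mixed population of its size.
    """
    temps = {vertex_temperature(g, i) for i in g.nodes}
    return len(temps) == 1


# ---------------------------------------------------------------------------
# Enumeration and isomorphism
# ---------------------------------------------------------------------------


def canonical_form(g: nx.Graph) -> tuple:
    """Lexicographically minimal upper-triangle adjacency bit-string.

    Minimized over all N! vertex permutations; equal canonical forms
    characterise isomorphic graphs.  Only meant for small orders (N <= 7).
    """
    n = g.number_of_nodes()
    adj = [[1 if g.has_edge(i, j) else 0 for j in range(n)] for i in range(n)]
    pairs = list(itertools.combinations(range(n), 2))
    best = None
    for perm in itertools.permutations(range(n)):
        bits = tuple(adj[perm[i]][perm[j]] for i, j in pairs)
        if best is None or bits < best:
            best = bits
    return best


def enumerate_connected_graphs(N: int) -> list[nx.Graph]:
    """One representative per isomorphism class of connected graphs of order N.

    Backed by the networkx graph atlas (complete for orders <= 7);
    representatives are relabeled 0..N-1.  Larger orders are refused —
    the class counts explode (11117 at N = 8).
    """
    if N < 2:
        raise ValueError(f"need N >= 2, got {N}")
    if N > MAX_ENUMERATION_ORDER:
        raise ValueError(
            f"exhaustive enumeration is limited to N <= {MAX_ENUMERATION_ORDER}, got {N}"
        )
    out = []
    for g in nx.graph_atlas_g():
        if g.number_of_nodes() == N and nx.is_connected(g):
            out.append(nx.convert_node_labels_to_integers(g))
    return out


# ---------------------------------------------------------------------------
# Edge-list text format
# ---------------------------------------------------------------------------


def write_edgelist(g: nx.Graph, path) -> None:
    """Write one sorted ``i j`` pair per line (0-based ids, '#' comments)."""
    with open(path, "w") as fh:
        fh.write(f"# order {g.number_of_nodes()}\n")
        for i, j in sorted(tuple(sorted(e)) for e in g.edges):
            fh.write(f"{i} {j}\n")


def read_edgelist(source) -> nx.Graph:
    """Read the plain-text edge-list format (path or iterable of lines)."""
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        with open(source) as fh:
            lines: Iterable[str] = fh.readlines()
    else:
        lines = source
    g = nx.Graph()
    for ln, line in enumerate(lines, 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"line {ln}: expected two vertex ids, got {line!r}")
        i, j = int(parts[0]), int(parts[1])
        if i == j:
            raise ValueError(f"line {ln}: self-loop {i}")
        if i < 0 or j < 0:
            raise ValueError(f"line {ln}: negative vertex id")
        g.add_edge(i, j)
    if g.number_of_nodes() == 0:
        raise ValueError("edge list is empty")
    g.add_nodes_from(range(max(g.nodes) + 1))
    validate_graph(g, require_connected=False)
    return g
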