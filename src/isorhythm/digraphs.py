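"""Enumeration and canonical labeling of small directed circuit topologies.

The receiver circuits are simple digraphs: no self-loops, at most one arc
per ordered vertex pair.  Isomorphism classes are identified by a canonical
form — the lexicographically minimal row-major adjacency bit string over
all vertex relabelings.  A full permutation scan is exact and fast at the
sizes of interest (n <= 6); the enumeration of all ten-edge circuits on
five vertices (184,756 edge subsets, 120 permutations each) is vectorized
with numpy and completes in seconds.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

__all__ = [
    "Digraph",
    "CanonicalForm",
    "canonical_form",
    "enumerate_digraphs",
    "complete_digraph",
    "to_adjacency",
    "read_edge_list",
    "write_edge_list",
]


@dataclass(frozen=True)
class Digraph:
    """A labeled simple directed graph without self-loops.

    ``edges`` are ordered (tail, head) pairs, 0-based.
    """

    n_vertices: int
    edges: frozenset

    def __init__(self, n_vertices: int, edges) -> None:
        if n_vertices < 1:
            raise ValueError("n_vertices must be positive")
        edge_list = [(int(a), int(b)) for a, b in edges]
        edge_set = frozenset(edge_list)
        if len(edge_set) != len(edge_list):
            raise ValueError("duplicate edges")
        for a, b in edge_set:
            if a == b:
                raise ValueError(f"self-loop ({a}, {b}) not allowed")
            if not (0 <= a < n_vertices and 0 <= b < n_vertices):
                raise ValueError(f"edge ({a}, {b}) out of range for {n_vertices} vertices")
        object.__setattr__(self, "n_vertices", n_vertices)
        object.__setattr__(self, "edges", edge_set)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass(frozen=True)
class CanonicalForm:
    """Canonical label: row-major adjacency bits of the canonically relabeled graph.

    Two digraphs with equal ``n_vertices`` are isomorphic iff their labels
    are equal.
    """

    label: str


@lru_cache(maxsize=None)
def _arc_index(n: int):
    """Row-major positions of the n(n-1) off-diagonal arcs."""
    arcs = [(i, j) for i in range(n) for j in range(n) if i != j]
    pos = {arc: k for k, arc in enumerate(arcs)}
    return arcs, pos


@lru_cache(maxsize=None)
def _perm_columns(n: int) -> np.ndarray:
    """For every vertex permutation sigma, the arc-position remapping.

    Row p gives, for each arc slot (i, j) of the relabeled graph, the slot
    (sigma(i), sigma(j)) of the original it reads from.  Scanning all
    permutations covers relabelings and their inverses alike.
    """
    arcs, pos = _arc_index(n)
    perms = list(itertools.permutations(range(n)))
    cols = np.empty((len(perms), len(arcs)), dtype=np.intp)
    for p, sigma in enumerate(perms):
        for k, (i, j) in enumerate(arcs):
            cols[p, k] = pos[(sigma[i], sigma[j])]
    return cols


def _pack_weights(n_arcs: int) -> np.ndarray:
    # first arc slot = most significant bit, so integer order = lexicographic
    # order of the bit strings
    return (np.uint64(1) << np.arange(n_arcs - 1, -1, -1, dtype=np.uint64)).astype(np.uint64)


def _arc_key_to_label(key: int, n: int) -> str:
    """Expand a packed arc bit key into the full n*n row-major label."""
    arcs, _ = _arc_index(n)
    n_arcs = len(arcs)
    bits = format(int(key), f"0{n_arcs}b")
    mat = [["0"] * n for _ in range(n)]
    for bit, (i, j) in zip(bits, arcs):
        mat[i][j] = bit
    return "".join("".join(row) for row in mat)


def canonical_form(g: Digraph) -> CanonicalForm:
    """Lexicographically minimal row-major adjacency bit string over all relabelings.

    Since the diagonal is identically zero, minimizing over the off-diagonal
    arc slots is equivalent to minimizing the full n*n string.
    """
    n = g.n_vertices
    if n > 8:
        raise ValueError("full permutation scan is limited to n <= 8")
    _, pos = _arc_index(n)
    n_arcs = n * (n - 1)
    vec = np.zeros(n_arcs, dtype=np.uint64)
    for e in g.edges:
        vec[pos[e]] = 1
    cols = _perm_columns(n)
    weights = _pack_weights(n_arcs)
    keys = vec[cols] @ weights
    return CanonicalForm(label=_arc_key_to_label(int(keys.min()), n))


def enumerate_digraphs(
    n_vertices: int, n_edges: int, exclude_isolated: bool = False
) -> list[Digraph]:
    """All isomorphism classes of simple digraphs with the given size.

    Exhaustively iterates every ``n_edges``-subset of the n(n-1) possible
    arcs, canonicalizes each subset over all n! vertex permutations, and
    keeps the first representative (in lexicographic edge-set order) of
    each class.  Exact by construction; feasible for n <= 5 at any m and
    for larger n at small m.

    With ``exclude_isolated`` classes containing a vertex with no incident
    arc are dropped: an isolated vertex is an oscillator decoupled from the
    circuit, and the published census of five-vertex, ten-edge receiver
    circuits (1,665 topologies) counts only classes where every oscillator
    participates (the unconstrained count is 1,670; the five excluded
    classes pack all ten arcs among four vertices).

    Examples
    --------
    >>> len(enumerate_digraphs(3, 2))
    4
    >>> len(enumerate_digraphs(5, 10, exclude_isolated=True))
    1665
    """
    max_edges = n_vertices * (n_vertices - 1)
    if not 0 <= n_edges <= max_edges:
        raise ValueError(f"n_edges must be in [0, {max_edges}], got {n_edges}")
    arcs, _ = _arc_index(n_vertices)
    combos = list(itertools.combinations(range(max_edges), n_edges))
    if n_edges == 0:
        return [Digraph(n_vertices, [])]

    subset = np.zeros((len(combos), max_edges), dtype=np.uint64)
    rows = np.repeat(np.arange(len(combos)), n_edges)
    subset[rows, np.asarray(combos).ravel()] = 1

    cols = _perm_columns(n_vertices)
    weights = _pack_weights(max_edges)
    keys = subset[:, cols[0]] @ weights
    for perm_cols in cols[1:]:
        np.minimum(keys, subset[:, perm_cols] @ weights, out=keys)

    _, first = np.unique(keys, return_index=True)
    reps = []
    for idx in np.sort(first):
        g = Digraph(n_vertices, [arcs[k] for k in combos[idx]])
        if exclude_isolated:
            touched = {v for e in g.edges for v in e}
            if len(touched) < n_vertices:
                continue
        reps.append(g)
    return reps


def complete_digraph(n_vertices: int) -> Digraph:
    """All-to-all topology: every ordered pair (i, j), i != j."""
    if n_vertices < 1:
        raise ValueError("n_vertices must be positive")
    return Digraph(
        n_vertices,
        [(i, j) for i in range(n_vertices) for j in range(n_vertices) if i != j],
    )


def to_adjacency(g: Digraph) -> np.ndarray:
    """Binary adjacency matrix for the coupling model.

    Row i lists the inputs of oscillator i, so an edge (tail -> head) sets
    ``A[head, tail] = 1`` — the head receives input from the tail.
    """
    adj = np.zeros((g.n_vertices, g.n_vertices))
    for tail, head in g.edges:
        adj[head, tail] = 1.0
    return adj


def write_edge_list(graphs, path) -> None:
    """Write one or many digraphs as 'tail head' lines; graphs separated by '#'."""
    if isinstance(graphs, Digraph):
        graphs = [graphs]
    with open(path, "w") as fh:
        for gi, g in enumerate(graphs):
            if gi:
                fh.write("#\n")
            fh.write(f"n {g.n_vertices}\n")
            for tail, head in sorted(g.edges):
                fh.write(f"{tail} {head}\n")


def read_edge_list(path) -> list[Digraph]:
    """Read digraphs written by :func:`write_edge_list`."""
    graphs = []
    n = None
    edges: list[tuple[int, int]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line == "#":
                graphs.append(Digraph(n, edges))
                n, edges = None, []
            elif line.startswith("n "):
                n = int(line.split()[1])
            else:
                a, b = line.split()
                edges.append((int(a), int(b)))
    if n is not None:
        graphs.append(Digraph(n, edges))
    return graphs
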