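"""Parametric and random graph generation plus an independent activity oracle.

The generators exist to property-test the descriptor implementation: known
families (paths, cycles, stars, barbells) have hand-derivable closed forms,
and seeded random trees / connected graphs exercise arbitrary topologies.
Graphs here are abstract — no attempt is made at chemical realism.

`oracle_activity` recomputes D and zeta with deliberately different machinery
(Floyd-Warshall distances via scipy, naive per-vertex loops) so that
agreement with :func:`graphactivity.activity.compute_activity` is a real
cross-check, not the same code run twice.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Literal

import networkx as nx
import numpy as np

from .activity import ActivityResult
from .molgraph import MolecularGraph

__all__ = ["GraphSpec", "generate", "oracle_activity", "Family"]

Family = Literal["random_tree", "random_connected", "path", "cycle", "star", "barbell"]

_FAMILIES = ("random_tree", "random_connected", "path", "cycle", "star", "barbell")


@dataclass(frozen=True)
class GraphSpec:
    """Deterministic recipe for one test graph."""

    family: Family
    n: int
    seed: int = 0

    def __post_init__(self):  # noqa: D105
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        minimum = {"cycle": 3, "star": 2, "barbell": 6}.get(self.family, 2)
        if self.n < minimum:
            raise ValueError(f"family {self.family!r} needs n >= {minimum}")


def generate(spec: GraphSpec) -> MolecularGraph:
    """Build the graph described by ``spec``; identical spec, identical graph."""
    n, seed = spec.n, spec.seed
    name = f"{spec.family}-{n}-{seed}"
    if spec.family == "path":
        edges = [(i, i + 1) for i in range(n - 1)]
    elif spec.family == "cycle":
        edges = [(i, (i + 1) % n) for i in range(n)]
    elif spec.family == "star":
        edges = [(0, i) for i in range(1, n)]
    elif spec.family == "barbell":
        # two triangles joined by a path through the remaining n - 6 vertices
        a, b = (0, 1, 2), (n - 3, n - 2, n - 1)
        edges = [(a[0], a[1]), (a[0], a[2]), (a[1], a[2])]
        edges += [(b[0], b[1]), (b[0], b[2]), (b[1], b[2])]
        edges += [(i, i + 1) for i in range(2, n - 3)]
    elif spec.family == "random_tree":
        edges = _random_tree_edges(n, seed)
    else:  # random_connected
        edges = _random_tree_edges(n, seed)
        rng = np.random.default_rng(seed + 1)
        present = {frozenset(e) for e in edges}
        non_edges = [
            (u, v)
            for u in range(n)
            for v in range(u + 1, n)
            if frozenset((u, v)) not in present
        ]
        k = min(len(non_edges), int(rng.integers(0, n)))
        if k:
            extra = rng.choice(len(non_edges), size=k, replace=False)
            edges = edges + [non_edges[i] for i in sorted(extra)]
    return MolecularGraph.from_edge_list(edges, name=name)


def _random_tree_edges(n: int, seed: int) -> list[tuple[int, int]]:
    """Uniform random labelled tree via a seeded Pruefer sequence."""
    if n == 2:
        return [(0, 1)]
    rng = np.random.default_rng(seed)
    prufer = [int(x) for x in rng.integers(0, n, size=n - 2)]
    tree = nx.from_prufer_sequence(prufer)
    return [tuple(sorted(e)) for e in tree.edges()]


def oracle_activity(g: MolecularGraph) -> ActivityResult:
    """Brute-force D and zeta for small graphs (n <= 30).

    Independent of the main implementation: dense Floyd-Warshall distances
    and explicit loops over vertex pairs.
    """
    from scipy.sparse.csgraph import floyd_warshall

    n = g.n
    if n > 30:
        raise ValueError("oracle is for test-sized graphs only (n <= 30)")
    adj = np.zeros((n, n))
    for u, v in g.edges:
        adj[u, v] = adj[v, u] = 1
    dist = floyd_warshall(adj, unweighted=True).astype(int)

    degrees = [len(g.neighbors(v)) for v in range(n)]
    external = [v for v in range(n) if degrees[v] == 1]
    internal = [v for v in range(n) if degrees[v] > 1]

    ext_sum = 0
    for v in external:
        for u in external:
            ext_sum += int(dist[v, u])

    int_sum = Fraction(0)
    for v in internal:
        distinct = set()
        for u in g.neighbors(v):
            distinct.add(degrees[u])
        ecc = int(max(dist[v, u] for u in range(n)))
        int_sum += Fraction(len(distinct), degrees[v]) * ecc

    return ActivityResult(
        name=g.name,
        n=n,
        external_numerator=ext_sum,
        internal_numerator=int_sum,
        D=ext_sum / n**3,
        zeta=float(int_sum) / n**2,
    )
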