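"""Ready-made test instances: the worked graph-coloring example plus seeded
random generators for graphs, secondary structures, and binary networks.

The coloring instance extends plain graph coloring (one inequality constraint
per edge) by a feature counting the distinct colors on selected 4-cycles; it
reproduces the two worked evaluations 11 and 10 of its reference colorings.
The instance's edge set is a documented reconstruction: the union of four
4-cycles plus connector edges, chosen so that both reference colorings are
valid and the reference invalid partial assignment stays invalid.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .model import (DependencyHypergraph, FeatureNetwork, ModelError,
                    define_constraint_type, define_function_type)
from .phylo import PhyloNetwork
from .rna import SecondaryStructure

NotEquals = define_constraint_type(
    "NotEquals", lambda i, j: (i, j), lambda vals, i, j: vals[0] != vals[1])

Card = define_function_type(
    "Card", lambda i, j, k, l: (i, j, k, l), lambda vals, i, j, k, l: len(set(vals)))


@dataclass
class ColoringInstance:
    """Vertices 1..n_vertices, undirected edges, k colors, scored 4-cycles."""

    n_vertices: int
    edges: list[tuple[int, int]]
    k_colors: int
    cycles: list[tuple[int, int, int, int]] = field(default_factory=list)

    def __post_init__(self):
        if self.k_colors < 1:
            raise ModelError("need at least one color")
        for e in self.edges:
            if not all(1 <= v <= self.n_vertices for v in e):
                raise ModelError(f"edge {e} references unknown vertex")
        for cyc in self.cycles:
            if len(cyc) != 4:
                raise ModelError(f"scored cycles must have length 4, got {cyc}")
            if not all(1 <= v <= self.n_vertices for v in cyc):
                raise ModelError(f"cycle {cyc} references unknown vertex")


def reference_coloring_instance() -> ColoringInstance:
    """The 9-vertex running example with its three scored 4-cycles.

    The edge set is the union of the graph's four 4-cycles (2,3,5,6),
    (2,5,7,8), (5,6,7,8) and (5,6,8,9) -- only the first three carry Card
    functions -- plus connector edges (1,2), (1,4), (4,5) attaching v1 and
    v4.  Both reference colorings (1,2,3,3,4,2,1,3,1) and (1,2,4,3,4,2,1,3,1)
    are proper under this edge set, and the partial assignment
    {X2:2, X5:4, X6:3, X7:1, X8:3} is invalid via the (6,8) inequality.
    """
    cycle_edges = [
        (2, 3), (3, 6), (6, 5), (5, 2),      # cycle (2, 3, 5, 6)
        (5, 7), (7, 8), (8, 2),              # cycle (2, 5, 7, 8) with (2, 5) above
        (6, 7), (8, 5),                      # cycle (5, 6, 7, 8)
        (6, 8), (8, 9), (9, 5),              # cycle (5, 6, 8, 9), unscored
    ]
    connectors = [(1, 2), (1, 4), (4, 5)]
    edges = sorted({tuple(sorted(e)) for e in cycle_edges + connectors})
    return ColoringInstance(
        n_vertices=9, edges=edges, k_colors=4,
        cycles=[(2, 3, 5, 6), (2, 5, 7, 8), (5, 6, 7, 8)],
    )


#: the two reference colorings of the worked example (vertex 1..9 order)
X_COL = (1, 2, 3, 3, 4, 2, 1, 3, 1)
X_COL_PRIME = (1, 2, 4, 3, 4, 2, 1, 3, 1)


def coloring_model(instance: ColoringInstance) -> FeatureNetwork:
    """NotEquals per edge; one Card function per scored 4-cycle (feature
    ``card``).  Variable i-1 holds the color of vertex i (colors 1..k)."""
    net = FeatureNetwork()
    net.add_variables(instance.n_vertices, range(1, instance.k_colors + 1))
    for i, j in instance.edges:
        net.add_constraint(NotEquals(i - 1, j - 1))
    for i, j, k, l in instance.cycles:
        net.add_function(Card(i - 1, j - 1, k - 1, l - 1), "card")
    net.meta.update({"kind": "coloring", "n_vertices": instance.n_vertices})
    return net


def random_partial_ktree(n: int, k: int, edge_keep_prob: float = 1.0,
                         seed: int = 0) -> DependencyHypergraph:
    """Random k-tree on n vertices with edges dropped independently.

    Treewidth <= k is certified by construction (subgraph of a k-tree); with
    ``edge_keep_prob`` 1 and n > k the treewidth is exactly k.
    """
    if not (n > k >= 1):
        raise ModelError("need n > k >= 1")
    rng = random.Random(seed)
    edges = set()
    cliques = [tuple(range(k + 1))]
    for a in range(k + 1):
        for b in range(a + 1, k + 1):
            edges.add((a, b))
    for v in range(k + 1, n):
        base = cliques[rng.randrange(len(cliques))]
        drop = rng.randrange(len(base))
        sub = tuple(u for i, u in enumerate(base) if i != drop)
        for u in sub:
            edges.add((min(u, v), max(u, v)))
        cliques.append(tuple(sorted(sub + (v,))))
    kept = [e for e in sorted(edges) if rng.random() < edge_keep_prob]
    return DependencyHypergraph(
        variables=frozenset(range(n)),
        hyperedges=frozenset(frozenset(e) for e in kept),
    )


def random_structures(n: int, count: int = 1, pair_density: float = 0.4,
                      crossing: bool = False, min_loop: int = 3,
                      seed: int = 0) -> list[SecondaryStructure]:
    """Random triplet-free structures with about pair_density * n / 2 pairs.

    Noncrossing structures reject crossing candidate pairs; crossing ones are
    random triplet-free matchings.  ``min_loop`` is the minimum number of
    unpaired-or-other positions between the ends of a pair (j - i > min_loop).
    """
    if n < 1:
        raise ModelError("n must be >= 1")
    rng = random.Random(seed)
    target = round(pair_density * n / 2)
    out = []
    for _ in range(count):
        pairs: set[tuple[int, int]] = set()
        used: set[int] = set()
        attempts = 0
        while len(pairs) < target and attempts < 50 * max(1, target):
            attempts += 1
            i = rng.randrange(1, n + 1)
            j = rng.randrange(1, n + 1)
            i, j = min(i, j), max(i, j)
            if j - i <= min_loop or i in used or j in used:
                continue
            if not crossing and any(a < i < b < j or i < a < j < b
                                    for a, b in pairs):
                continue
            pairs.add((i, j))
            used.update((i, j))
        out.append(SecondaryStructure(n, frozenset(pairs)))
    return out


def random_binary_network(n_leaves: int, n_reticulations: int = 0,
                          seed: int = 0, max_tries: int = 1000) -> PhyloNetwork:
    """Random rooted binary tree with the requested number of reticulations.

    Each reticulation subdivides two tree-path-independent edges and links
    the new nodes, so every node keeps at most two children and two parents.
    """
    if n_reticulations < 0:
        raise ModelError("n_reticulations must be >= 0")
    rng = random.Random(seed)
    edges: list[list] = []
    next_internal = 0
    subtrees = [f"L{i}" for i in range(n_leaves)]
    while len(subtrees) > 1:
        a, b = rng.sample(range(len(subtrees)), 2)
        u, v = subtrees[a], subtrees[b]
        parent = f"I{next_internal}"
        next_internal += 1
        edges.append([u, parent])
        edges.append([v, parent])
        subtrees = [s for idx, s in enumerate(subtrees) if idx not in (a, b)]
        subtrees.append(parent)

    def ancestors(node, parent_map):
        out = set()
        stack = [node]
        while stack:
            x = stack.pop()
            for p in parent_map.get(x, []):
                if p not in out:
                    out.add(p)
                    stack.append(p)
        return out

    added = 0
    tries = 0
    next_new = 0
    while added < n_reticulations:
        tries += 1
        if tries > max_tries:
            raise ModelError("could not place the requested reticulations")
        i1, i2 = rng.sample(range(len(edges)), 2)
        (c1, p1), (c2, p2) = edges[i1], edges[i2]
        parent_map: dict = {}
        for c, p in edges:
            parent_map.setdefault(c, []).append(p)
        # the receiver edge (c1,p1) must not lie on or above the donor edge
        # (c2,p2): the new edge m1->m2 must not close a directed cycle
        if c1 == c2 or c1 == p2 or c1 in ancestors(p2, parent_map):
            continue
        m1, m2 = f"R{next_new}", f"S{next_new}"
        next_new += 1
        edges[i1] = [c1, m1]
        edges[i2] = [c2, m2]
        edges.append([m1, p1])
        edges.append([m2, p2])
        edges.append([m1, m2])  # m1 becomes the reticulation node
        added += 1
    net = PhyloNetwork([tuple(e) for e in edges])
    if len(net.reticulations) != n_reticulations or not net.is_binary:
        raise ModelError("generated network failed validation")
    return net
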