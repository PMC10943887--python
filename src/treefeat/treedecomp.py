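"""Tree decompositions of dependency hypergraphs.

A tree decomposition is a rooted tree of variable subsets (*bags*) that
covers every variable and every dependency hyperedge while keeping the
occurrences of each variable connected.  Its *width* (largest bag minus one)
governs the cost of the dynamic programming in :mod:`treefeat.engine`.

Decompositions here are produced by a randomized min-fill elimination
heuristic with restarts and then normalized to *gentle* form: an empty root
bag and exactly one introduced variable per non-root node, which gives one
tree edge per variable and a one-variable decision per traceback step.
A branch-and-bound-free exact treewidth routine (dynamic programming over
vertex subsets) is provided for small instances, mainly as a test oracle.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass

from .model import DependencyHypergraph, ModelError


@dataclass
class TreeDecomposition:
    """Rooted tree of bags; ``parent[root] is None``."""

    bags: dict[int, frozenset[int]]
    parent: dict[int, int | None]
    root: int

    def __post_init__(self) -> None:
        self._children: dict[int, list[int]] = {u: [] for u in self.bags}
        for u, p in self.parent.items():
            if p is not None:
                self._children[p].append(u)

    def children(self, u: int) -> list[int]:
        return self._children[u]

    def nodes(self) -> list[int]:
        return list(self.bags)

    def width(self) -> int:
        return max(len(b) for b in self.bags.values()) - 1

    def sep(self, u: int) -> frozenset[int]:
        p = self.parent[u]
        if p is None:
            return frozenset()
        return self.bags[u] & self.bags[p]

    def diff(self, u: int) -> frozenset[int]:
        return self.bags[u] - self.sep(u)

    @property
    def is_gentle(self) -> bool:
        if self.bags[self.root]:
            return False
        return all(len(self.diff(u)) == 1 for u in self.bags if u != self.root)

    def preorder(self) -> list[int]:
        order, stack = [], [self.root]
        while stack:
            u = stack.pop()
            order.append(u)
            stack.extend(self._children[u])
        return order

    def postorder(self) -> list[int]:
        return list(reversed(self.preorder()))

    # -- text format ---------------------------------------------------------

    def to_text(self) -> str:
        lines = []
        for u in self.preorder():
            lines.append("bag " + " ".join([str(u)] + [str(v) for v in sorted(self.bags[u])]))
        for u, p in self.parent.items():
            if p is not None:
                lines.append(f"edge {u} {p}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "TreeDecomposition":
        bags: dict[int, frozenset[int]] = {}
        parent: dict[int, int | None] = {}
        for line in text.splitlines():
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            if parts[0] == "bag":
                bags[int(parts[1])] = frozenset(int(v) for v in parts[2:])
            elif parts[0] == "edge":
                parent[int(parts[1])] = int(parts[2])
            else:
                raise ModelError(f"bad tree decomposition line: {line!r}")
        roots = [u for u in bags if u not in parent]
        if len(roots) != 1:
            raise ModelError(f"tree decomposition must have exactly one root, found {roots}")
        parent[roots[0]] = None
        return cls(bags, parent, roots[0])


@dataclass
class ValidationReport:
    """The three defining conditions, reported separately, plus gentleness."""

    variables_covered: bool
    hyperedges_covered: bool
    connected: bool
    is_gentle: bool

    @property
    def ok(self) -> bool:
        return self.variables_covered and self.hyperedges_covered and self.connected


def validate(td: TreeDecomposition, h: DependencyHypergraph) -> ValidationReport:
    union = frozenset().union(*td.bags.values()) if td.bags else frozenset()
    variables_covered = h.variables <= union
    hyperedges_covered = all(
        any(e <= bag for bag in td.bags.values()) for e in h.hyperedges
    )
    connected = True
    for x in union:
        tops = 0
        for u in td.bags:
            if x in td.bags[u]:
                p = td.parent[u]
                if p is None or x not in td.bags[p]:
                    tops += 1
        if tops != 1:
            connected = False
            break
    return ValidationReport(variables_covered, hyperedges_covered, connected, td.is_gentle)


def width(td: TreeDecomposition) -> int:
    return td.width()


# -- primal graph ------------------------------------------------------------


def _primal_adjacency(h: DependencyHypergraph) -> dict[int, set[int]]:
    """Cliquify every hyperedge; isolated variables keep empty neighborhoods."""
    adj: dict[int, set[int]] = {v: set() for v in h.variables}
    for e in h.hyperedges:
        for a, b in itertools.combinations(sorted(e), 2):
            adj[a].add(b)
            adj[b].add(a)
    return adj


# -- min-fill heuristic -------------------------------------------------------


def _min_fill_once(adj: dict[int, set[int]], rng: random.Random) -> TreeDecomposition:
    adj = {v: set(nb) for v, nb in adj.items()}
    remaining = sorted(adj)
    order: list[int] = []
    elim_bags: list[frozenset[int]] = []
    position: dict[int, int] = {}

    while remaining:
        best_fill, candidates = None, []
        for v in remaining:
            nb = adj[v]
            fill = 0
            nbl = sorted(nb)
            for i, a in enumerate(nbl):
                for b in nbl[i + 1:]:
                    if b not in adj[a]:
                        fill += 1
            if best_fill is None or fill < best_fill:
                best_fill, candidates = fill, [v]
            elif fill == best_fill:
                candidates.append(v)
        v = candidates[rng.randrange(len(candidates))]
        nb = sorted(adj[v])
        position[v] = len(order)
        order.append(v)
        elim_bags.append(frozenset([v] + nb))
        for i, a in enumerate(nb):
            for b in nb[i + 1:]:
                adj[a].add(b)
                adj[b].add(a)
        for a in nb:
            adj[a].discard(v)
        del adj[v]
        remaining.remove(v)

    n = len(order)
    parent: dict[int, int | None] = {}
    for i, bag in enumerate(elim_bags):
        rest = [position[x] for x in bag if position[x] > i]
        parent[i] = min(rest) if rest else None
    # attach any parentless bags (last bag, other components) under the last one
    root = n - 1
    for i in range(n):
        if parent[i] is None and i != root:
            parent[i] = root
    if n == 0:
        raise ModelError("cannot decompose an empty hypergraph")
    bags = {i: elim_bags[i] for i in range(n)}
    return TreeDecomposition(bags, parent, root)


def min_fill_decompose(
    h: DependencyHypergraph, seed: int = 0, restarts: int = 20
) -> TreeDecomposition:
    """Randomized min-fill elimination; the best of ``restarts`` runs wins.

    Deterministic for a fixed seed.  Ties among minimum-fill vertices are
    broken uniformly at random under the seeded generator.
    """
    if not h.variables:
        raise ModelError("cannot decompose an empty hypergraph")
    adj = _primal_adjacency(h)
    rng = random.Random(seed)
    best: TreeDecomposition | None = None
    for _ in range(max(1, restarts)):
        td = _min_fill_once(adj, rng)
        if best is None or td.width() < best.width():
            best = td
    return best


# -- gentle normalization -----------------------------------------------------


def make_gentle(td: TreeDecomposition) -> TreeDecomposition:
    """Equivalent decomposition with empty root and one introduced variable per node.

    Oversized difference sets are split into chains of bags introducing one
    variable each (in ascending variable order); edges introducing nothing are
    contracted.  Width is preserved exactly and the result has exactly one
    tree edge per variable.
    """
    bags: dict[int, frozenset[int]] = {}
    parent: dict[int, int | None] = {}
    next_id = 0

    def new_node(bag: frozenset[int], p: int | None) -> int:
        nonlocal next_id
        u = next_id
        next_id += 1
        bags[u] = bag
        parent[u] = p
        return u

    root = new_node(frozenset(), None)
    # old node -> new node carrying its full bag
    stack: list[tuple[int, int]] = [(td.root, root)]
    while stack:
        old, new_parent = stack.pop()
        pbag = bags[new_parent]
        obag = td.bags[old]
        introduced = sorted(obag - pbag)
        if not introduced:
            anchor = new_parent  # contracted: nothing introduced here
        else:
            anchor = new_parent
            sep = obag & pbag
            acc = set(sep)
            for v in introduced:
                acc.add(v)
                anchor = new_node(frozenset(acc), anchor)
        for child in td.children(old):
            stack.append((child, anchor))
    return TreeDecomposition(bags, parent, root)


# -- exact treewidth (small instances) ----------------------------------------


def exact_treewidth(h: DependencyHypergraph, max_vertices: int = 14) -> int:
    """Exact treewidth by dynamic programming over elimination-order subsets.

    Guarded to small instances (the state space is 2^n); intended as an
    independent oracle for validating the heuristic decomposer.
    """
    verts = sorted(h.variables)
    n = len(verts)
    if n == 0:
        raise ModelError("empty hypergraph")
    if n > max_vertices:
        raise ModelError(f"exact_treewidth limited to {max_vertices} vertices, got {n}")
    index = {v: i for i, v in enumerate(verts)}
    adj = [0] * n
    for v, nbs in _primal_adjacency(h).items():
        for w in nbs:
            adj[index[v]] |= 1 << index[w]

    def q(eliminated: int, v: int) -> int:
        """Degree of v toward non-eliminated vertices through eliminated ones."""
        seen = 1 << v
        boundary = 0
        stack = [v]
        while stack:
            u = stack.pop()
            nb = adj[u]
            boundary |= nb & ~eliminated
            inner = nb & eliminated & ~seen
            while inner:
                w = (inner & -inner).bit_length() - 1
                inner &= inner - 1
                seen |= 1 << w
                stack.append(w)
        boundary &= ~(1 << v)
        return bin(boundary).count("1")

    full = (1 << n) - 1
    tw = [0] * (full + 1)
    subsets_by_size: list[list[int]] = [[] for _ in range(n + 1)]
    for s in range(full + 1):
        subsets_by_size[bin(s).count("1")].append(s)
    for size in range(1, n + 1):
        for s in subsets_by_size[size]:
            best = n
            rest = s
            while rest:
                v = (rest & -rest).bit_length() - 1
                rest &= rest - 1
                prev = s & ~(1 << v)
                cand = max(tw[prev], q(prev, v))
                if cand < best:
                    best = cand
            tw[s] = best
    return tw[full]


# -- convenience --------------------------------------------------------------


def decompose(h: DependencyHypergraph, seed: int = 0, restarts: int = 20) -> TreeDecomposition:
    """Min-fill decomposition, normalized to gentle form."""
    return make_gentle(min_fill_decompose(h, seed=seed, restarts=restarts))
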