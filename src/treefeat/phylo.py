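"""Small parsimony on phylogenetic networks (hardwired and softwired).

A phylogenetic network is a rooted, connected DAG with edges pointing from
children to parents; *reticulation* nodes have two parents (binary networks).
Given leaf labels over a character alphabet, hardwired parsimony minimizes
the number of label changes over *all* edges; softwired parsimony lets each
reticulation node inherit from its more favorable parent only.

Both problems are modeled as feature networks with one variable per node
(leaf domains restricted to the observed label, no constraints) and one
distance function per edge; softwired adds a Boolean selector variable per
reticulation node, and the selector-gated distance returns +inf on the
non-selected parent edge, which the engine excludes under minimization.
Minimization is run as maximization at feature weight -1.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field
from typing import Hashable, Mapping, Sequence

from .model import (FeatureNetwork, ModelError, define_function_type)
from . import solvers

INF = float("inf")


@dataclass
class PhyloNetwork:
    """Rooted connected DAG; ``edges`` are (child, parent) pairs."""

    edges: list[tuple[Hashable, Hashable]]
    nodes: list[Hashable] = field(default_factory=list)

    def __post_init__(self):
        seen: list[Hashable] = list(self.nodes)
        for c, p in self.edges:
            for v in (c, p):
                if v not in seen:
                    seen.append(v)
        self.nodes = seen
        self.parents = {v: [] for v in self.nodes}
        self.children = {v: [] for v in self.nodes}
        for c, p in self.edges:
            self.parents[c].append(p)
            self.children[p].append(c)
        roots = [v for v in self.nodes if not self.parents[v]]
        if len(roots) != 1:
            raise ModelError(f"network must have exactly one root, found {roots}")
        self.root = roots[0]
        self._check_dag_connected()

    def _check_dag_connected(self):
        order, state = [], {}
        def visit(v):
            state[v] = 1
            for p in self.parents[v]:
                if state.get(p) == 1:
                    raise ModelError("network contains a directed cycle")
                if p not in state:
                    visit(p)
            state[v] = 2
            order.append(v)
        for v in self.nodes:
            if v not in state:
                visit(v)
        reach = {self.root}
        stack = [self.root]
        while stack:
            u = stack.pop()
            for c in self.children[u]:
                if c not in reach:
                    reach.add(c)
                    stack.append(c)
        if reach != set(self.nodes):
            raise ModelError("network is not connected")

    @property
    def leaves(self) -> list[Hashable]:
        return [v for v in self.nodes if not self.children[v]]

    @property
    def reticulations(self) -> list[Hashable]:
        return [v for v in self.nodes if len(self.parents[v]) > 1]

    @property
    def is_tree(self) -> bool:
        return not self.reticulations

    @property
    def is_binary(self) -> bool:
        return all(len(self.children[v]) <= 2 and len(self.parents[v]) <= 2
                   for v in self.nodes)


def _check_labels(net: PhyloNetwork, alphabet: Sequence, labels: Mapping) -> None:
    for leaf in net.leaves:
        if leaf not in labels:
            raise ModelError(f"leaf {leaf!r} is unlabeled")
        if labels[leaf] not in alphabet:
            raise ModelError(f"label {labels[leaf]!r} of leaf {leaf!r} not in alphabet")


Distance = define_function_type(
    "Distance",
    lambda i, j: (i, j),
    lambda vals, i, j: 0.0 if vals[0] == vals[1] else 1.0,
)

RDistance = define_function_type(
    # selector-gated distance on a reticulation edge: the edge is charged iff
    # the selector picks it (y == r); the non-selected parent edge of the
    # reticulation contributes nothing, realizing min over parents
    "RDistance",
    lambda i, j, y, r: (i, j, y),
    lambda vals, i, j, y, r:
        (0.0 if vals[0] == vals[1] else 1.0) if vals[2] == r else 0.0,
)


def _node_variables(phylo: PhyloNetwork, alphabet, labels) -> tuple[FeatureNetwork, dict]:
    net = FeatureNetwork()
    var_of = {}
    codes = {ch: i for i, ch in enumerate(alphabet)}
    for v in phylo.nodes:
        if not phylo.children[v]:
            dom = [codes[labels[v]]]
        else:
            dom = list(range(len(alphabet)))
        var_of[v] = net.add_variables(1, dom)[0]
    net.meta.update({"kind": "parsimony", "var_of": var_of,
                     "alphabet": list(alphabet)})
    return net, var_of


def hardwired_model(phylo: PhyloNetwork, alphabet: Sequence,
                    labels: Mapping) -> FeatureNetwork:
    """One variable per node, one 0/1 distance function per edge, no constraints."""
    _check_labels(phylo, alphabet, labels)
    net, var_of = _node_variables(phylo, alphabet, labels)
    for c, p in phylo.edges:
        net.add_function(Distance(var_of[c], var_of[p]), "parsimony")
    return net


def softwired_model(phylo: PhyloNetwork, alphabet: Sequence,
                    labels: Mapping) -> FeatureNetwork:
    """Hardwired model plus one Boolean selector per reticulation node.

    The selector value picks which parent edge of the reticulation is
    charged; the other edge's gated distance is +inf, which drops out of the
    minimization.  Requires a binary network.  'Left'/'right' parent follows
    first appearance in the edge list.
    """
    if not phylo.is_binary:
        raise ModelError("softwired model requires a binary network")
    _check_labels(phylo, alphabet, labels)
    net, var_of = _node_variables(phylo, alphabet, labels)
    retic = set(phylo.reticulations)
    selector_of = {}
    for v in sorted(retic, key=str):
        selector_of[v] = net.add_variables(1, [0, 1])[0]
    for c, p in phylo.edges:
        if c in retic:
            r = 0 if p == phylo.parents[c][0] else 1
            net.add_function(RDistance(var_of[c], var_of[p], selector_of[c], r),
                             "parsimony")
        else:
            net.add_function(Distance(var_of[c], var_of[p]), "parsimony")
    net.meta["selector_of"] = selector_of
    return net


def _labeling_from_assignment(phylo, alphabet, assignment, var_of):
    return {v: alphabet[assignment[var_of[v]]] for v in phylo.nodes}


def hardwired_parsimony(phylo: PhyloNetwork, alphabet: Sequence, labels: Mapping,
                        seed: int = 0):
    """Minimal hardwired parsimony score and one optimal full labeling."""
    net = hardwired_model(phylo, alphabet, labels)
    value, assignment = solvers.optimize(net, {"parsimony": -1.0}, seed=seed)
    return -value, _labeling_from_assignment(phylo, alphabet, assignment,
                                             net.meta["var_of"])


def softwired_parsimony(phylo: PhyloNetwork, alphabet: Sequence, labels: Mapping,
                        seed: int = 0):
    """Minimal softwired parsimony score and one optimal full labeling."""
    net = softwired_model(phylo, alphabet, labels)
    value, assignment = solvers.optimize(net, {"parsimony": -1.0}, seed=seed)
    return -value, _labeling_from_assignment(phylo, alphabet, assignment,
                                             net.meta["var_of"])


def parsimony_score(phylo: PhyloNetwork, labeling: Mapping, mode: str = "hardwired",
                    leaf_labels: Mapping | None = None) -> float:
    """Direct score of a total labeling (no optimization).

    hardwired: sum of 0/1 distances over all edges; softwired: per node, the
    distance to the most favorable parent.  If ``leaf_labels`` is given the
    labeling must extend it.
    """
    if leaf_labels is not None:
        for leaf, ch in leaf_labels.items():
            if labeling.get(leaf) != ch:
                raise ModelError(f"labeling conflicts with leaf label at {leaf!r}")
    for v in phylo.nodes:
        if v not in labeling:
            raise ModelError(f"labeling misses node {v!r}")
    if mode == "hardwired":
        return float(sum(1 for c, p in phylo.edges if labeling[c] != labeling[p]))
    if mode == "softwired":
        total = 0
        for v in phylo.nodes:
            if phylo.parents[v]:
                total += min(1 if labeling[v] != labeling[p] else 0
                             for p in phylo.parents[v])
        return float(total)
    raise ModelError(f"unknown mode {mode!r}")


def sankoff_oracle(phylo: PhyloNetwork, alphabet: Sequence, labels: Mapping,
                   distance=None, allow_unlabeled: bool = False) -> float:
    """Classic bottom-up Sankoff DP minimum parsimony score; trees only.

    With ``allow_unlabeled`` an unlabeled leaf is free (zero cost for every
    character) -- needed for displayed trees whose leaves include former
    internal nodes.
    """
    if not phylo.is_tree:
        raise ModelError("sankoff_oracle requires a tree (no reticulations)")
    if not allow_unlabeled:
        _check_labels(phylo, alphabet, labels)
    if distance is None:
        distance = lambda x, y: 0.0 if x == y else 1.0
    cost: dict[Hashable, dict] = {}

    def visit(v):
        if not phylo.children[v]:
            if v in labels:
                cost[v] = {ch: (0.0 if ch == labels[v] else INF) for ch in alphabet}
            else:
                cost[v] = {ch: 0.0 for ch in alphabet}
            return
        for c in phylo.children[v]:
            visit(c)
        cost[v] = {
            ch: sum(min(cost[c][ch2] + distance(ch, ch2) for ch2 in alphabet)
                    for c in phylo.children[v])
            for ch in alphabet
        }

    visit(phylo.root)
    return min(cost[phylo.root].values())


def softwired_brute_force(phylo: PhyloNetwork, alphabet: Sequence,
                          labels: Mapping) -> float:
    """Exhaustive softwired minimum over all 2^r displayed parent choices.

    For each fixing of one parent edge per reticulation, the displayed graph
    is a tree and is scored with the Sankoff oracle; independent test oracle
    for the selector-variable model.
    """
    retic = phylo.reticulations
    best = INF
    for choice in itertools.product(*(range(len(phylo.parents[v])) for v in retic)):
        edges = []
        for c, p in phylo.edges:
            if c in retic:
                keep = phylo.parents[c][choice[retic.index(c)]]
                if p != keep:
                    continue
            edges.append((c, p))
        displayed = PhyloNetwork(edges, nodes=list(phylo.nodes))
        best = min(best, sankoff_oracle(displayed, alphabet, labels,
                                        allow_unlabeled=True))
    return best


def random_tree(n_leaves: int, alphabet: Sequence, seed: int = 0):
    """Random rooted binary tree plus random leaf labels (test fixture)."""
    rng = random.Random(seed)
    if n_leaves < 2:
        raise ModelError("need at least two leaves")
    edges = []
    next_internal = 0
    subtrees = [f"L{i}" for i in range(n_leaves)]
    while len(subtrees) > 1:
        a, b = rng.sample(range(len(subtrees)), 2)
        u, v = subtrees[a], subtrees[b]
        parent = f"I{next_internal}"
        next_internal += 1
        edges.append((u, parent))
        edges.append((v, parent))
        subtrees = [s for k, s in enumerate(subtrees) if k not in (a, b)]
        subtrees.append(parent)
    phylo = PhyloNetwork(edges)
    labels = {leaf: rng.choice(list(alphabet)) for leaf in phylo.leaves}
    return phylo, labels
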