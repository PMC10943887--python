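"""Cluster-tree elimination: algebra-generic forward pass and tracebacks.

The same message-passing recursion solves optimization and partition-function
computation; only the *algebra* changes:

* ``MAX_PLUS``  -- (max, +, Id): messages are conditional optimal subtree
  evaluations; the root value is the optimum E_max.
* ``SUM_PRODUCT`` -- (+, *, exp): messages are conditional subtree partition
  functions; the root value is Z = sum_x exp(E(x, alpha)).

Messages are dense tables with one entry per assignment of the node's
separator (mixed-radix layout, last variable fastest), so a gentle
decomposition of width w with domains of size d costs O(d^(w+1)) time per bag
and O(d^w) space per message.  The deterministic traceback recovers an
optimal assignment; the stochastic traceback draws exact Boltzmann samples.
"""

from __future__ import annotations

import itertools
import logging
import math
import operator
from dataclasses import dataclass, field
from typing import Callable, Mapping

from .model import FeatureNetwork, InfeasibleError, ModelError, weighted_value
from .treedecomp import TreeDecomposition, validate

logger = logging.getLogger(__name__)


class EngineError(ModelError):
    pass


class EngineOverflowError(EngineError):
    """Partition-function overflow; rescale feature weights (e.g. divide
    energies by a temperature-like constant) and retry."""


def _exp(v: float) -> float:
    try:
        return math.exp(v)
    except OverflowError:
        raise EngineOverflowError(
            f"exp({v}) overflows; rescale feature weights"
        ) from None


@dataclass(frozen=True)
class Algebra:
    """Semiring-like evaluation policy: choose across alternatives, combine
    across parts, lift weighted function values into the carrier."""

    name: str
    choose: Callable[[float, float], float]
    combine: Callable[[float, float], float]
    lift: Callable[[float], float]
    neutral_choose: float
    neutral_combine: float
    excluded: float


MAX_PLUS = Algebra("max_plus", max, operator.add, lambda v: v,
                   float("-inf"), 0.0, float("-inf"))
SUM_PRODUCT = Algebra("sum_product", operator.add, operator.mul, _exp,
                      0.0, 1.0, 0.0)


class _Placed:
    """A constraint or function placed at a bag, optionally materialized.

    Materialization tabulates the item over the domain product of its scope
    (mixed-radix index, last scope variable fastest); semantics are unchanged
    since items are referentially transparent.
    """

    __slots__ = ("item", "scope", "table", "strides", "vindex")

    def __init__(self, item, vindex):
        self.item = item
        self.scope = item.scope
        self.table = None
        self.vindex = [vindex[v] for v in item.scope]
        self.strides = None

    def materialize(self, domains) -> int:
        doms = [domains[v] for v in self.scope]
        strides = [0] * len(doms)
        acc = 1
        for i in range(len(doms) - 1, -1, -1):
            strides[i] = acc
            acc *= len(doms[i])
        self.strides = strides
        self.table = [self.item(*vals) for vals in itertools.product(*doms)]
        return len(self.table)

    def eval(self, values):
        if self.table is None:
            return self.item(*(values[v] for v in self.scope))
        idx = 0
        for v, stride, vx in zip(self.scope, self.strides, self.vindex):
            idx += vx[values[v]] * stride
        return self.table[idx]


class _CTNode:
    __slots__ = (
        "id", "parent", "children", "bag", "sep_vars", "diff_var",
        "constraints", "functions", "msg_size", "sep_strides",
    )

    def __init__(self, uid, parent):
        self.id = uid
        self.parent = parent
        self.children: list[int] = []
        self.constraints: list[_Placed] = []
        self.functions: list[tuple[_Placed, str]] = []


class ClusterTree:
    """A gentle tree decomposition annotated with constraint/function placement.

    Every constraint and function is placed at exactly one node whose bag
    covers its scope -- the deepest such node, so items are evaluated as early
    as possible during the bottom-up pass.
    """

    def __init__(self, network: FeatureNetwork, td: TreeDecomposition,
                 precompute: bool = True, table_cap: int = 2_000_000):
        if not td.is_gentle:
            raise EngineError("cluster trees require a gentle tree decomposition")
        report = validate(td, network.dependency_graph())
        if not report.ok:
            raise EngineError(f"tree decomposition invalid for this network: {report}")
        self.network = network
        self.td = td
        self.root = td.root
        self.vindex = [
            {val: i for i, val in enumerate(dom)} for dom in network.domains
        ]
        self.values: list[int | None] = [None] * network.n_variables

        depth = {td.root: 0}
        for u in td.preorder():
            for c in td.children(u):
                depth[c] = depth[u] + 1
        self.preorder = td.preorder()
        self.postorder = td.postorder()

        self.nodes: dict[int, _CTNode] = {}
        for u in self.preorder:
            node = _CTNode(u, td.parent[u])
            node.bag = tuple(sorted(td.bags[u]))
            node.sep_vars = tuple(sorted(td.sep(u)))
            d = td.diff(u)
            node.diff_var = next(iter(d)) if d else None
            sizes = [len(network.domains[v]) for v in node.sep_vars]
            node.msg_size = math.prod(sizes) if sizes else 1
            strides = [0] * len(sizes)
            acc = 1
            for i in range(len(sizes) - 1, -1, -1):
                strides[i] = acc
                acc *= sizes[i]
            node.sep_strides = strides
            self.nodes[u] = node
        for u in self.preorder:
            p = td.parent[u]
            if p is not None:
                self.nodes[p].children.append(u)

        cover = {}
        for u in self.preorder:
            cover[u] = frozenset(td.bags[u])

        def place(item) -> int:
            best, best_key = None, None
            for u in self.preorder:
                if frozenset(item.scope) <= cover[u]:
                    key = (depth[u], -u)
                    if best_key is None or key > best_key:
                        best, best_key = u, key
            if best is None:
                raise EngineError(
                    f"no bag covers scope {item.scope} of {item.name!r}"
                )
            return best

        for c in network.constraints:
            self.nodes[place(c)].constraints.append(_Placed(c, self.vindex))
        for fname, feat in network.features.items():
            for f in feat.functions:
                self.nodes[place(f)].functions.append((_Placed(f, self.vindex), fname))

        self.table_entries = 0
        if precompute:
            self.table_entries = precompute_tables(self, table_cap=table_cap)

    @property
    def width(self) -> int:
        return self.td.width()

    def placed_count(self) -> int:
        return sum(
            len(n.constraints) + len(n.functions) for n in self.nodes.values()
        )

    def _sep_index(self, node: _CTNode, values) -> int:
        idx = 0
        for v, stride in zip(node.sep_vars, node.sep_strides):
            idx += self.vindex[v][values[v]] * stride
        return idx


def build_cluster_tree(network: FeatureNetwork, td: TreeDecomposition,
                       precompute: bool = True,
                       table_cap: int = 2_000_000) -> ClusterTree:
    return ClusterTree(network, td, precompute=precompute, table_cap=table_cap)


def precompute_tables(ct: ClusterTree, table_cap: int = 2_000_000) -> int:
    """Materialize all placed constraints/functions into lookup tables.

    Items whose table would push the total entry count over ``table_cap``
    stay un-materialized and are evaluated on the fly (logged).
    """
    total = 0
    for node in ct.nodes.values():
        for placed in node.constraints + [p for p, _ in node.functions]:
            size = math.prod(len(ct.network.domains[v]) for v in placed.scope)
            if total + size > table_cap:
                logger.info(
                    "table cap %d reached; %r evaluated on the fly",
                    table_cap, placed.item.name,
                )
                continue
            total += placed.materialize(ct.network.domains)
    return total


@dataclass
class ForwardResult:
    """Messages of a completed bottom-up pass plus the root aggregate."""

    messages: dict[int, list[float]]
    root_value: float
    algebra: Algebra
    weights: dict[str, float]
    cluster_tree: ClusterTree = field(repr=False, default=None)


def forward(ct: ClusterTree, weights: Mapping[str, float] | None = None,
            algebra: Algebra = MAX_PLUS) -> ForwardResult:
    """Bottom-up message passing over the cluster tree.

    For each node u and each assignment of sep(u), the message entry is the
    choose-combination over values of the introduced variable (invalid
    extensions contribute the algebra's excluded value) of the lifted local
    function values combined with the children's messages.
    """
    w = ct.network.resolve_weights(weights)
    domains = ct.network.domains
    messages: dict[int, list[float]] = {}
    check_overflow = algebra is SUM_PRODUCT

    for u in ct.postorder:
        if u == ct.root:
            continue
        node = ct.nodes[u]
        node_funcs = [(p, w[fname]) for p, fname in node.functions]
        diff = node.diff_var
        ddom = domains[diff]
        sep_domains = [domains[v] for v in node.sep_vars]
        msg = [algebra.neutral_choose] * node.msg_size
        values = ct.values
        combine, choose, lift = algebra.combine, algebra.choose, algebra.lift
        for sep_idx, sep_vals in enumerate(itertools.product(*sep_domains)):
            for v, val in zip(node.sep_vars, sep_vals):
                values[v] = val
            acc = algebra.neutral_choose
            for dval in ddom:
                values[diff] = dval
                ok = True
                for placed in node.constraints:
                    if not placed.eval(values):
                        ok = False
                        break
                if not ok:
                    continue
                t = algebra.neutral_combine
                for placed, fw in node_funcs:
                    t = combine(t, lift(weighted_value(fw, placed.eval(values))))
                for c in node.children:
                    child = ct.nodes[c]
                    t = combine(t, messages[c][ct._sep_index(child, values)])
                acc = choose(acc, t)
            if check_overflow and math.isinf(acc):
                raise EngineOverflowError(
                    "partition-function message overflowed; rescale feature weights"
                )
            msg[sep_idx] = acc
        messages[u] = msg

    root_value = algebra.neutral_combine
    for c in ct.nodes[ct.root].children:
        root_value = algebra.combine(root_value, messages[c][0])
    if check_overflow and math.isinf(root_value):
        raise EngineOverflowError("partition function overflowed; rescale feature weights")
    return ForwardResult(messages, root_value, algebra, w, ct)


def optimal_traceback(ct: ClusterTree, fr: ForwardResult) -> dict[int, int]:
    """Recover one optimal total assignment from a max-plus forward pass.

    Traverses the tree in preorder; at each node the first introduced-variable
    value (ascending domain order) whose bag evaluation reproduces the stored
    message is selected, so co-optimal ties resolve deterministically.
    """
    if fr.algebra is not MAX_PLUS:
        raise EngineError("optimal_traceback requires a max-plus forward result")
    if fr.root_value == float("-inf"):
        raise InfeasibleError("no valid assignment exists")
    assignment: dict[int, int] = {}
    values = ct.values
    for u in ct.preorder:
        if u == ct.root:
            continue
        node = ct.nodes[u]
        for v in node.sep_vars:
            values[v] = assignment[v]
        target = fr.messages[u][ct._sep_index(node, values)]
        fweights = [(p, fr.weights[fname]) for p, fname in node.functions]
        chosen = None
        for dval in ct.network.domains[node.diff_var]:
            values[node.diff_var] = dval
            t = _eval_bag(ct, node, fweights, fr)
            if t is None:
                continue
            if t == target or abs(t - target) <= 1e-9 * (1.0 + abs(target)):
                chosen = dval
                break
        if chosen is None:
            raise EngineError(
                f"traceback failed to reproduce message at node {u}"
            )
        assignment[node.diff_var] = chosen
        values[node.diff_var] = chosen
    return assignment


def stochastic_traceback(ct: ClusterTree, fr: ForwardResult, rng) -> dict[int, int]:
    """Draw one valid total assignment with probability exp(E(x,alpha))/Z.

    At each node a tracking value t is drawn uniformly in [0, message);
    iterating over the introduced variable's values, t is decremented by each
    value's partial Boltzmann mass, and the value is selected once t drops
    below zero.
    """
    if fr.algebra is not SUM_PRODUCT:
        raise EngineError("stochastic_traceback requires a sum-product forward result")
    if fr.root_value <= 0.0:
        raise InfeasibleError("no valid assignment exists (partition function is 0)")
    assignment: dict[int, int] = {}
    values = ct.values
    for u in ct.preorder:
        if u == ct.root:
            continue
        node = ct.nodes[u]
        for v in node.sep_vars:
            values[v] = assignment[v]
        total = fr.messages[u][ct._sep_index(node, values)]
        fweights = [(p, fr.weights[fname]) for p, fname in node.functions]
        t = rng.random() * total
        chosen = None
        last_positive = None
        for dval in ct.network.domains[node.diff_var]:
            values[node.diff_var] = dval
            b = _eval_bag(ct, node, fweights, fr)
            if b is None or b <= 0.0:
                continue
            last_positive = dval
            t -= b
            if t < 0.0:
                chosen = dval
                break
        if chosen is None:
            chosen = last_positive  # guard against roundoff at the upper edge
        if chosen is None:
            raise EngineError(f"stochastic traceback found no mass at node {u}")
        assignment[node.diff_var] = chosen
        values[node.diff_var] = chosen
    return assignment


def _eval_bag(ct, node, fweights, fr):
    algebra = fr.algebra
    values = ct.values
    for placed in node.constraints:
        if not placed.eval(values):
            return None
    t = algebra.neutral_combine
    for placed, w in fweights:
        t = algebra.combine(t, algebra.lift(weighted_value(w, placed.eval(values))))
    for c in node.children:
        child = ct.nodes[c]
        t = algebra.combine(t, fr.messages[c][ct._sep_index(child, values)])
    return t


def dump_messages(fr: ForwardResult) -> str:
    """Message tables as TSV (node, separator assignment, value); debug aid."""
    ct = fr.cluster_tree
    lines = ["node\tseparator\tvalue"]
    for u, msg in fr.messages.items():
        node = ct.nodes[u]
        sep_domains = [ct.network.domains[v] for v in node.sep_vars]
        for vals, entry in zip(itertools.product(*sep_domains), msg):
            sep = ",".join(f"X{v}={x}" for v, x in zip(node.sep_vars, vals)) or "-"
            lines.append(f"{u}\t{sep}\t{entry!r}")
    return "\n".join(lines) + "\n"
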