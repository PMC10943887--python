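"""Independent brute-force oracles used by the test suite.

These enumerate total assignments directly (vectorized over the full domain
product) and never touch the cluster-tree engine, so they can serve as
ground truth for optimization values, partition functions, and Boltzmann
probabilities on small networks.
"""

from __future__ import annotations

import itertools
import math
import random

import numpy as np

from treefeat.model import (Constraint, FeatureNetwork, NetworkFunction,
                            weighted_value)


def enumerate_scores(net: FeatureNetwork, weights=None):
    """(E, valid, index_of) over all total assignments.

    ``E`` and ``valid`` are arrays over the mixed-radix enumeration of the
    domain product (variable 0 slowest); ``index_of(assignment)`` maps an
    assignment dict to its flat index.
    """
    w = net.resolve_weights(weights)
    doms = net.domains
    sizes = [len(d) for d in doms]
    n_total = math.prod(sizes)
    vidx = [{val: k for k, val in enumerate(d)} for d in doms]

    idx = []
    stride = n_total
    for sz in sizes:
        stride //= sz
        idx.append((np.arange(n_total) // stride) % sz)

    def flat_of(scope):
        flat = np.zeros(n_total, dtype=np.int64)
        st = 1
        for v in reversed(scope):
            flat += idx[v] * st
            st *= sizes[v]
        return flat

    valid = np.ones(n_total, dtype=bool)
    for c in net.constraints:
        table = np.array(
            [bool(c(*vals)) for vals in itertools.product(*(doms[v] for v in c.scope))]
        )
        valid &= table[flat_of(c.scope)]

    energy = np.zeros(n_total)
    for fname, feat in net.features.items():
        if w[fname] == 0.0:
            continue
        for f in feat.functions:
            table = np.array(
                [weighted_value(w[fname], f(*vals))
                 for vals in itertools.product(*(doms[v] for v in f.scope))]
            )
            energy = energy + table[flat_of(f.scope)]

    var_strides = []
    st = n_total
    for sz in sizes:
        st //= sz
        var_strides.append(st)

    def index_of(assignment):
        return sum(var_strides[v] * vidx[v][assignment[v]] for v in range(len(doms)))

    return energy, valid, index_of


def brute_force_max(net: FeatureNetwork, weights=None) -> float:
    energy, valid, _ = enumerate_scores(net, weights)
    if not valid.any():
        return float("-inf")
    return float(energy[valid].max())


def brute_force_partition(net: FeatureNetwork, weights=None) -> float:
    energy, valid, _ = enumerate_scores(net, weights)
    if not valid.any():
        return 0.0
    return float(np.exp(energy[valid]).sum())


def boltzmann_probabilities(net: FeatureNetwork, weights=None):
    """(probabilities over valid flat indices, index_of) for chi-square tests."""
    energy, valid, index_of = enumerate_scores(net, weights)
    mass = np.where(valid, np.exp(energy), 0.0)
    z = mass.sum()
    return mass / z, index_of


def random_network(seed: int, max_vars: int = 8, max_domain: int = 4,
                   max_items: int = 12, max_arity: int = 3) -> FeatureNetwork:
    """Seeded random feature network with table-based constraints/functions."""
    rng = random.Random(seed)
    net = FeatureNetwork()
    n = rng.randint(3, max_vars)
    for _ in range(n):
        size = rng.randint(2, max_domain)
        lo = rng.randint(-2, 2)
        net.add_variables(1, range(lo, lo + size))
    n_items = rng.randint(2, max_items)
    n_constraints = rng.randint(0, n_items // 2)
    for i in range(n_items):
        arity = rng.randint(1, min(max_arity, n))
        scope = tuple(sorted(rng.sample(range(n), arity)))
        combos = list(itertools.product(*(net.domains[v] for v in scope)))
        if i < n_constraints:
            table = {vals: rng.random() < 0.8 for vals in combos}
            net.add_constraint(Constraint(
                scope, lambda *vals, t=table: t[vals], name=f"C{i}"))
        else:
            table = {vals: float(rng.randint(-3, 3)) for vals in combos}
            feature = rng.choice(["f1", "f2"])
            net.add_function(NetworkFunction(
                scope, lambda *vals, t=table: t[vals], name=f"F{i}"), feature)
    return net


def merge_small_bins(observed, expected, min_expected=5.0):
    """Pool low-expectation cells so the chi-square approximation is sound."""
    pairs = sorted(zip(expected, observed), reverse=True)
    obs_out, exp_out = [], []
    acc_o = acc_e = 0.0
    for e, o in pairs:
        acc_e += e
        acc_o += o
        if acc_e >= min_expected:
            exp_out.append(acc_e)
            obs_out.append(acc_o)
            acc_o = acc_e = 0.0
    if acc_e > 0 and exp_out:
        exp_out[-1] += acc_e
        obs_out[-1] += acc_o
    return obs_out, exp_out


def random_weights(seed: int, net: FeatureNetwork) -> dict:
    rng = random.Random(seed + 10_000)
    return {name: rng.choice([-2.0, -1.0, -0.5, 0.0, 0.5, 1.0])
            for name in net.features}
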