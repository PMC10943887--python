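"""User-facing solvers: optimize, partition function, Boltzmann sampling,
and multidimensional Boltzmann sampling (MDBS) for feature targeting.

MDBS draws k samples per round at the current feature weights, estimates the
mean of each targeted feature, and nudges the weights so the sampling means
move toward the targets (increasing a feature's weight increases its
expectation under the Boltzmann distribution).  Samples within tolerance of
every target -- |F(x) - tau_F| <= delta_F -- are collected across rounds
until K of them exist.  An annealing scheme shrinks the update step whenever
the round's root-mean-square deviation from the targets fails to improve on
the best seen so far.
"""

from __future__ import annotations

import logging
import math
import random
import statistics
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .engine import (MAX_PLUS, SUM_PRODUCT, ClusterTree, build_cluster_tree,
                     forward, optimal_traceback, stochastic_traceback)
from .model import FeatureNetwork, ModelError
from .treedecomp import decompose, TreeDecomposition, make_gentle

logger = logging.getLogger(__name__)

__all__ = [
    "TreeSolver", "optimize", "partition", "sample",
    "FeatureTarget", "MDBSConfig", "MDBSRound", "MDBSError",
    "rmsd", "is_admissible", "targeted_sample",
]


class TreeSolver:
    """Pipeline facade: dependency graph -> min-fill -> gentle -> cluster tree.

    The cluster tree is built once and reused across weight settings; only
    the forward pass depends on the weights.
    """

    def __init__(self, network: FeatureNetwork, seed: int = 0, restarts: int = 20,
                 td: TreeDecomposition | None = None, precompute: bool = True):
        if network.n_variables == 0:
            raise ModelError("cannot solve a network without variables")
        if td is None:
            td = decompose(network.dependency_graph(), seed=seed, restarts=restarts)
        elif not td.is_gentle:
            td = make_gentle(td)
        self.network = network
        self.ct: ClusterTree = build_cluster_tree(network, td, precompute=precompute)
        logger.info("solving with tree decomposition of width %d", self.width)

    @property
    def width(self) -> int:
        return self.ct.width

    def optimize(self, weights: Mapping[str, float] | None = None):
        """Maximal weighted evaluation and one optimal valid assignment."""
        fr = forward(self.ct, weights, MAX_PLUS)
        assignment = optimal_traceback(self.ct, fr)
        return fr.root_value, assignment

    def partition(self, weights: Mapping[str, float] | None = None) -> float:
        return forward(self.ct, weights, SUM_PRODUCT).root_value

    def sample(self, weights: Mapping[str, float] | None = None, n: int = 1,
               seed: int | None = None, rng: random.Random | None = None):
        """n i.i.d. Boltzmann samples from one forward pass."""
        if rng is None:
            rng = random.Random(0 if seed is None else seed)
        fr = forward(self.ct, weights, SUM_PRODUCT)
        return [stochastic_traceback(self.ct, fr, rng) for _ in range(n)]


def optimize(network: FeatureNetwork, weights=None, seed: int = 0, restarts: int = 20):
    return TreeSolver(network, seed=seed, restarts=restarts).optimize(weights)


def partition(network: FeatureNetwork, weights=None, seed: int = 0, restarts: int = 20) -> float:
    return TreeSolver(network, seed=seed, restarts=restarts).partition(weights)


def sample(network: FeatureNetwork, weights=None, n: int = 1, seed: int = 0,
           restarts: int = 20):
    return TreeSolver(network, seed=seed, restarts=restarts).sample(weights, n=n, seed=seed + 1)


# -- multidimensional Boltzmann sampling --------------------------------------


@dataclass(frozen=True)
class FeatureTarget:
    """Target value tau with tolerance delta for one feature."""

    feature: str
    tau: float
    delta: float

    def __post_init__(self):
        if self.delta < 0:
            raise ModelError("target tolerance delta must be >= 0")


@dataclass
class MDBSConfig:
    """Tuning constants of the MDBS loop (tunable, not canonical).

    samples_per_round (k) samples are drawn each round; gamma scales the
    weight update, cooling (Gamma, in (0,1]) shrinks gamma on non-improving
    rounds; normalize divides each update by the feature's per-round sample
    standard deviation so gamma is dimensionless across features.
    """

    samples_per_round: int = 100
    gamma: float = 0.5
    cooling: float = 0.8
    max_rounds: int = 1000
    initial_weights: dict[str, float] = field(default_factory=dict)
    normalize: bool = True

    def __post_init__(self):
        if self.samples_per_round < 1:
            raise ModelError("samples_per_round must be >= 1")
        if not (self.gamma > 0):
            raise ModelError("gamma must be > 0")
        if not (0 < self.cooling <= 1):
            raise ModelError("cooling factor must be in (0, 1]")


@dataclass
class MDBSRound:
    """Per-round trace record of a targeted-sampling run."""

    round: int
    weights: dict[str, float]
    means: dict[str, float]
    rmsd: float
    gamma: float
    admissible_new: int
    admissible_total: int


class MDBSError(ModelError):
    """Round budget exhausted before K admissible samples were found."""


def rmsd(means: Mapping[str, float], targets: Sequence[FeatureTarget]) -> float:
    """Root-mean-square deviation of estimated means from target values."""
    if not targets:
        raise ModelError("rmsd of an empty target set is undefined")
    return math.sqrt(
        sum((means[t.feature] - t.tau) ** 2 for t in targets) / len(targets)
    )


def feature_observable(network: FeatureNetwork, feature: str, assignment) -> float:
    """Feature value used for targeting: the proxy if declared, else F(x)."""
    if feature not in network.features:
        raise ModelError(f"unknown feature {feature!r}")
    return network.features[feature].observable(network.as_assignment(assignment))


def is_admissible(network: FeatureNetwork, assignment,
                  targets: Sequence[FeatureTarget]) -> bool:
    """True iff |F(x) - tau_F| <= delta_F for every target (boundary inclusive)."""
    a = network.as_assignment(assignment)
    for t in targets:
        if abs(feature_observable(network, t.feature, a) - t.tau) > t.delta:
            return False
    return True


def targeted_sample(network: FeatureNetwork, targets: Sequence[FeatureTarget],
                    K: int, config: MDBSConfig | None = None, seed: int = 0,
                    solver: TreeSolver | None = None):
    """Collect K (tau, delta)-admissible samples by MDBS weight learning.

    Returns ``(samples, trace)`` where trace is the list of per-round
    :class:`MDBSRound` records.  Weights start at the configured initial
    weights (default 0 for every feature, i.e. uniform over valid
    assignments).  Admissible samples from every round count toward K.
    """
    if K < 1:
        raise ModelError("K must be >= 1")
    config = config or MDBSConfig()
    for t in targets:
        if t.feature not in network.features:
            raise ModelError(f"target references unknown feature {t.feature!r}")
    if solver is None:
        solver = TreeSolver(network, seed=seed)
    rng = random.Random(seed)
    weights = {name: 0.0 for name in network.features}
    weights.update(config.initial_weights)

    admissible: list[dict[int, int]] = []
    trace: list[MDBSRound] = []
    gamma = config.gamma
    best_rmsd = math.inf

    for rnd in range(1, config.max_rounds + 1):
        samples = solver.sample(weights, n=config.samples_per_round, rng=rng)
        observed = {
            t.feature: [feature_observable(network, t.feature, s) for s in samples]
            for t in targets
        }
        new = [
            s for i, s in enumerate(samples)
            if all(abs(observed[t.feature][i] - t.tau) <= t.delta for t in targets)
        ]
        admissible.extend(new)
        means = {f: statistics.fmean(vals) for f, vals in observed.items()}
        r = rmsd(means, targets)
        trace.append(MDBSRound(rnd, dict(weights), means, r, gamma,
                               len(new), len(admissible)))
        if len(admissible) >= K:
            return admissible[:K], trace
        if r < best_rmsd:
            best_rmsd = r
        else:
            gamma *= config.cooling
        for t in targets:
            step = gamma * (t.tau - means[t.feature])
            if config.normalize:
                sd = statistics.pstdev(observed[t.feature]) if len(observed[t.feature]) > 1 else 0.0
                step /= max(sd, 1e-6)
            weights[t.feature] += step
    raise MDBSError(
        f"collected {len(admissible)}/{K} admissible samples in "
        f"{config.max_rounds} rounds"
    )
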