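"""Alignment as a feature network, up to pseudoknot sequence-structure alignment.

Positions i of the first sequence ``a`` get one variable X_i whose value is
the position of ``b`` that i is matched to; deletions are encoded by
repeating the previous value (x_{i-1} = x_i), which keeps values
non-decreasing and makes the encoding a bijection onto alignments.  Sentinel
variables X_0 = 0 and X_{n+1} = m+1 close the ends.  Scores decompose into
binary Match/Deletion/Insertion functions; affine gap cost adds Boolean
match-state variables Y_i (ternary deletion functions), and sequence-structure
alignment adds a 4-ary arc-match bonus per (possibly crossing) base pair of
the arc annotation of ``a``.

Positions are 1-based throughout this module, matching the encoding above;
the X variable of position i has network index i.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .model import (FeatureNetwork, ModelError, define_constraint_type,
                    define_function_type)
from .rna import CANONICAL_PAIRS, SecondaryStructure, _BASE_INDEX


@dataclass(frozen=True)
class ScoringScheme:
    """Elementwise scores sigma plus gap scores (scores, not costs: gaps are
    typically negative).

    ``sigma`` maps two-character strings like ``"AU"`` to scores and overrides
    the match/mismatch scalars where present.  ``gap_open_beta`` switches on
    affine gap scoring g(l) = beta + gamma*l; ``arc_bonus_tau`` is the
    structure-alignment arc-match bonus.
    """

    match: float = 2.0
    mismatch: float = 0.0
    gap_gamma: float = -1.0
    gap_open_beta: float | None = None
    arc_bonus_tau: float | None = None
    sigma: Mapping[str, float] | None = None

    def score(self, x: str, y: str) -> float:
        if self.sigma is not None and x + y in self.sigma:
            return float(self.sigma[x + y])
        return self.match if x == y else self.mismatch

    def _spec(self) -> dict:
        return {"match": self.match, "mismatch": self.mismatch,
                "sigma": dict(self.sigma) if self.sigma else None}


def _sigma(spec: dict, x: str, y: str) -> float:
    if spec.get("sigma") and x + y in spec["sigma"]:
        return float(spec["sigma"][x + y])
    return float(spec["match"] if x == y else spec["mismatch"])


# -- constraint / function types ------------------------------------------------

Leq = define_constraint_type(
    "Leq", lambda i: (i - 1, i), lambda vals, i: vals[0] <= vals[1])

Match = define_function_type(
    "Match",
    lambda i, a_char, b, spec: (i - 1, i),
    lambda vals, i, a_char, b, spec:
        _sigma(spec, a_char, b[vals[1] - 1]) if vals[0] < vals[1] else 0.0,
)

Deletion = define_function_type(
    "Deletion",
    lambda i, gamma: (i - 1, i),
    lambda vals, i, gamma: gamma if vals[0] == vals[1] else 0.0,
)

AffineDeletion = define_function_type(
    # opening a deletion run (previous position matched) costs beta+gamma,
    # extending one (previous position deleted) costs gamma
    "AffineDeletion",
    lambda i, yprev, beta, gamma: (i - 1, i, yprev),
    lambda vals, i, yprev, beta, gamma:
        ((beta + gamma) if vals[2] == 1 else gamma) if vals[0] == vals[1] else 0.0,
)

Insertion = define_function_type(
    # run of l = x_i - x_{i-1} - 1 insertions before matched position i;
    # beta (if affine) is charged once per nonempty run
    "Insertion",
    lambda i, gamma, beta: (i - 1, i),
    lambda vals, i, gamma, beta:
        0.0 if vals[0] == vals[1] or vals[1] - vals[0] == 1
        else (0.0 if beta is None else beta) + gamma * (vals[1] - vals[0] - 1),
)

RelXY = define_constraint_type(
    "RelXY",
    lambda i, y: (i - 1, i, y),
    lambda vals, i, y: (vals[2] == 1) == (vals[0] < vals[1]),
)

BPMatch = define_function_type(
    "BPMatch",
    lambda i, j, yi, yj, b, tau: (i, j, yi, yj),
    lambda vals, i, j, yi, yj, b, tau:
        tau if (vals[2] == 1 and vals[3] == 1
                and 1 <= vals[0] <= len(b) and 1 <= vals[1] <= len(b)
                and (_BASE_INDEX.get(b[vals[0] - 1]), _BASE_INDEX.get(b[vals[1] - 1]))
                in CANONICAL_PAIRS)
        else 0.0,
)


# -- model builders --------------------------------------------------------------


def _banded_domain(i: int, n: int, m: int, band: int | None):
    if band is None:
        return range(0, m + 1)
    anchor = round(i * m / n)
    return range(max(0, anchor - band), min(m, anchor + band) + 1)


def _base_model(a: str, b: str, scheme: ScoringScheme, band: int | None):
    if not a or not b:
        raise ModelError("sequences must be non-empty")
    n, m = len(a), len(b)
    net = FeatureNetwork()
    net.add_variables(1, [0])                       # X_0 sentinel
    for i in range(1, n + 1):
        net.add_variables(1, _banded_domain(i, n, m, band))
    net.add_variables(1, [m + 1])                   # X_{n+1} sentinel
    for i in range(2, n + 1):
        net.add_constraint(Leq(i))
    spec = scheme._spec()
    for i in range(1, n + 1):
        net.add_function(Match(i, a[i - 1], b, spec), "match")
    beta = scheme.gap_open_beta
    for i in range(1, n + 2):
        net.add_function(Insertion(i, scheme.gap_gamma, beta), "insertion")
    net.meta.update({"kind": "alignment", "a": a, "b": b, "n": n, "m": m,
                     "x_vars": list(range(n + 2)), "band": band})
    return net


def linear_model(a: str, b: str, scheme: ScoringScheme | None = None,
                 band: int | None = None) -> FeatureNetwork:
    """Linear-gap alignment network: features match / deletion / insertion."""
    scheme = scheme or ScoringScheme()
    if scheme.gap_open_beta is not None:
        raise ModelError("linear_model requires a scheme without gap_open_beta")
    net = _base_model(a, b, scheme, band)
    for i in range(1, net.meta["n"] + 1):
        net.add_function(Deletion(i, scheme.gap_gamma), "deletion")
    net.meta["mode"] = "linear"
    return net


def affine_model(a: str, b: str, scheme: ScoringScheme,
                 band: int | None = None) -> FeatureNetwork:
    """Affine-gap alignment via Boolean match-state variables Y_0..Y_n.

    Y_i = 1 iff position i is matched (tied to the X variables by ternary
    constraints); the ternary deletion function reads Y_{i-1} to distinguish
    opening (beta+gamma) from extension (gamma).  Insertion runs charge beta
    once per run inside the generalized insertion function.
    """
    if scheme.gap_open_beta is None:
        raise ModelError("affine_model requires gap_open_beta")
    net = _base_model(a, b, scheme, band)
    n = net.meta["n"]
    y = {0: net.add_variables(1, [1])[0]}           # sentinel: position 0 "matched"
    for i in range(1, n + 1):
        y[i] = net.add_variables(1, [0, 1])[0]
        net.add_constraint(RelXY(i, y[i]))
    for i in range(1, n + 1):
        net.add_function(
            AffineDeletion(i, y[i - 1], scheme.gap_open_beta, scheme.gap_gamma),
            "deletion")
    net.meta.update({"mode": "affine", "y_vars": [y[i] for i in range(n + 1)]})
    return net


XDeletion = define_function_type(
    # ternary X-only affine deletion: reads x_{i-2} to detect run opening
    "XDeletion",
    lambda i, beta, gamma: (i - 2, i - 1, i),
    lambda vals, i, beta, gamma:
        ((beta + gamma) if vals[0] < vals[1] else gamma)
        if vals[1] == vals[2] else 0.0,
)


def affine_model_xonly(a: str, b: str, scheme: ScoringScheme,
                       band: int | None = None) -> FeatureNetwork:
    """Affine gaps via ternary deletion functions over X variables only.

    Alternative to :func:`affine_model` without Boolean match-state
    variables; the ternary scopes (X_{i-2}, X_{i-1}, X_i) raise the treewidth
    by one (an extra factor m in the solving cost), which is why the
    Y-variable model is the default.  Kept for benchmarking the width
    difference.
    """
    if scheme.gap_open_beta is None:
        raise ModelError("affine_model_xonly requires gap_open_beta")
    net = _base_model(a, b, scheme, band)
    n = net.meta["n"]
    for i in range(1, n + 1):
        # X_0 = 0 means position 0 counts as matched: a leading deletion opens
        net.add_function(XDeletion(i, scheme.gap_open_beta, scheme.gap_gamma)
                         if i >= 2 else
                         Deletion(i, scheme.gap_open_beta + scheme.gap_gamma),
                         "deletion")
    net.meta["mode"] = "affine_xonly"
    return net


def structure_model(a: str, structure: SecondaryStructure, b: str,
                    scheme: ScoringScheme, band: int | None = None) -> FeatureNetwork:
    """Sequence-structure alignment: linear gap score plus an arc-match bonus.

    One 4-ary BPMatch function per arc (i, j) of the annotation of ``a`` pays
    tau when both endpoints are matched (Y_i = Y_j = 1) to a canonical base
    pair of ``b``; a deleted endpoint never earns the bonus.  Crossing
    (pseudoknotted) annotations are allowed; they raise the treewidth, not an
    error.
    """
    if scheme.arc_bonus_tau is None:
        raise ModelError("structure_model requires arc_bonus_tau")
    if structure.length != len(a):
        raise ModelError("arc annotation length differs from sequence a")
    net = _base_model(a, b, scheme, band)
    n = net.meta["n"]
    for i in range(1, n + 1):
        net.add_function(Deletion(i, scheme.gap_gamma), "deletion")
    y = {}
    for i in range(1, n + 1):
        y[i] = net.add_variables(1, [0, 1])[0]
        net.add_constraint(RelXY(i, y[i]))
    for i, j in sorted(structure.pairs):
        net.add_function(BPMatch(i, j, y[i], y[j], b, scheme.arc_bonus_tau),
                         "bpmatch")
    if not structure.pairs:
        from .model import Feature
        net.features.setdefault("bpmatch", Feature("bpmatch"))
    net.meta.update({"mode": "structure",
                     "structure": sorted(structure.pairs),
                     "y_vars": [y[i] for i in range(1, n + 1)]})
    return net


# -- decoding and direct scoring --------------------------------------------------

GAP = "-"


def decode(assignment, a: str, b: str) -> list[tuple[str, str]]:
    """Turn a valid alignment-model assignment into alignment columns."""
    n, m = len(a), len(b)
    if isinstance(assignment, Mapping):
        x = [assignment[i] for i in range(n + 2)]
    else:
        x = list(assignment)[: n + 2]
    if x[0] != 0 or x[n + 1] != m + 1:
        raise ModelError("assignment lacks the sentinel values 0 and m+1")
    cols: list[tuple[str, str]] = []
    prev = 0
    for i in range(1, n + 1):
        xi = x[i]
        if xi < prev:
            raise ModelError("assignment violates the non-decreasing (Leq) condition")
        if xi == prev:
            cols.append((a[i - 1], GAP))
        else:
            for j in range(prev + 1, xi):
                cols.append((GAP, b[j - 1]))
            cols.append((a[i - 1], b[xi - 1]))
            prev = xi
    for j in range(prev + 1, m + 1):
        cols.append((GAP, b[j - 1]))
    return cols


def encode(columns: Sequence[tuple[str, str]], a: str, b: str) -> dict[int, int]:
    """Inverse of :func:`decode`; verifies the columns spell out a and b."""
    n, m = len(a), len(b)
    if "".join(ca for ca, _ in columns if ca != GAP) != a:
        raise ModelError("columns do not spell sequence a")
    if "".join(cb for _, cb in columns if cb != GAP) != b:
        raise ModelError("columns do not spell sequence b")
    x = {0: 0, n + 1: m + 1}
    i = j = 0
    for ca, cb in columns:
        if ca == GAP and cb == GAP:
            raise ModelError("empty alignment column")
        if cb != GAP:
            j += 1
        if ca != GAP:
            i += 1
            x[i] = j if cb != GAP else x[i - 1]
    return x


def score_columns(columns: Sequence[tuple[str, str]],
                  scheme: ScoringScheme | None = None) -> float:
    """Direct alignment score: sigma over aligned pairs plus gap scores.

    Gap runs are maximal blocks of insertion columns or of deletion columns;
    with affine scoring each run of length l contributes beta + gamma*l,
    otherwise gamma per gapped position.
    """
    scheme = scheme or ScoringScheme()
    total = 0.0
    runs: list[int] = []
    kind = None  # None | "ins" | "del"
    run = 0
    for ca, cb in columns:
        if ca == GAP and cb == GAP:
            raise ModelError("empty alignment column")
        col_kind = "ins" if ca == GAP else ("del" if cb == GAP else None)
        if col_kind is None:
            total += scheme.score(ca, cb)
        if col_kind != kind and run:
            runs.append(run)
            run = 0
        kind = col_kind
        if col_kind is not None:
            run += 1
    if run:
        runs.append(run)
    beta = scheme.gap_open_beta
    for length in runs:
        total += (0.0 if beta is None else beta) + scheme.gap_gamma * length
    return total


# -- independent DP oracles -------------------------------------------------------


def nw_score(a: str, b: str, scheme: ScoringScheme | None = None) -> float:
    """Needleman-Wunsch-style optimum under the linear-gap column score."""
    scheme = scheme or ScoringScheme()
    g = scheme.gap_gamma
    n, m = len(a), len(b)
    prev = [g * j for j in range(m + 1)]
    for i in range(1, n + 1):
        cur = [g * i] + [0.0] * m
        for j in range(1, m + 1):
            cur[j] = max(prev[j - 1] + scheme.score(a[i - 1], b[j - 1]),
                         prev[j] + g, cur[j - 1] + g)
        prev = cur
    return prev[m]


def gotoh_score(a: str, b: str, scheme: ScoringScheme) -> float:
    """Gotoh-style three-state optimum for affine gap score g(l) = beta + gamma*l."""
    if scheme.gap_open_beta is None:
        raise ModelError("gotoh_score requires gap_open_beta")
    beta, g = scheme.gap_open_beta, scheme.gap_gamma
    n, m = len(a), len(b)
    NEG = float("-inf")
    D = [[NEG] * (m + 1) for _ in range(n + 1)]   # overall best
    P = [[NEG] * (m + 1) for _ in range(n + 1)]   # ends in deletion run
    Q = [[NEG] * (m + 1) for _ in range(n + 1)]   # ends in insertion run
    D[0][0] = 0.0
    for i in range(1, n + 1):
        P[i][0] = beta + g * i
        D[i][0] = P[i][0]
    for j in range(1, m + 1):
        Q[0][j] = beta + g * j
        D[0][j] = Q[0][j]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            P[i][j] = max(D[i - 1][j] + beta + g, P[i - 1][j] + g)
            Q[i][j] = max(D[i][j - 1] + beta + g, Q[i][j - 1] + g)
            D[i][j] = max(D[i - 1][j - 1] + scheme.score(a[i - 1], b[j - 1]),
                          P[i][j], Q[i][j])
    return D[n][m]
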