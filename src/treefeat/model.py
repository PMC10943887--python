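"""Declarative feature networks.

A feature network is a constraint network extended by *features*: named sets
of real-valued local functions whose sum defines a global property of an
assignment.  Variables have finite integer domains; Boolean constraints carve
out the space of valid assignments; the weighted sum of feature values,

    E(x, alpha) = sum_F alpha_F * F(x),      F(x) = sum_{f in F} f(x),

is the quantity that the solvers maximize (optimization) or exponentiate
(Boltzmann sampling).  Networks are compositional: variables, constraints and
functions are added step by step and never mutated afterwards.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence


class ModelError(Exception):
    """Malformed model construction or use."""


class DomainError(ModelError):
    """A value lies outside its variable's domain."""


class InvalidAssignmentError(ModelError):
    """A total assignment violates a constraint where validity is required."""


class InfeasibleError(ModelError):
    """The network admits no valid total assignment."""


def _check_scope(scope: Sequence[int]) -> tuple[int, ...]:
    scope = tuple(int(i) for i in scope)
    if len(scope) < 1:
        raise ModelError("constraint/function scope must contain at least one variable")
    return scope


@dataclass(frozen=True)
class Constraint:
    """Boolean predicate over an ordered variable scope.

    ``type_name``/``params`` identify the registered constraint type the
    instance was built from, enabling JSON round trips.
    """

    scope: tuple[int, ...]
    predicate: Callable[..., bool]
    name: str = "constraint"
    type_name: str | None = None
    params: tuple = ()

    def __call__(self, *values) -> bool:
        return bool(self.predicate(*values))


@dataclass(frozen=True)
class NetworkFunction:
    """Real-valued local function over an ordered variable scope.

    Evaluators may return ``+inf``/``-inf`` (used e.g. to exclude branches
    under minimization); they must be referentially transparent.
    """

    scope: tuple[int, ...]
    evaluator: Callable[..., float]
    name: str = "function"
    type_name: str | None = None
    params: tuple = ()

    def __call__(self, *values) -> float:
        return float(self.evaluator(*values))


@dataclass
class Feature:
    """A named set of network functions, optionally with a proxy evaluator.

    The proxy, when present, replaces the induced evaluation F(x) only where
    an *observable* feature value is needed (admissibility checks and mean
    estimation in targeted sampling); the sampling distribution itself is
    always driven by the member functions.
    """

    name: str
    functions: list[NetworkFunction] = field(default_factory=list)
    proxy: Callable[[Mapping[int, int]], float] | None = None

    def value(self, assignment: Mapping[int, int]) -> float:
        total = 0.0
        for f in self.functions:
            total += f(*(assignment[v] for v in f.scope))
        return total

    def observable(self, assignment: Mapping[int, int]) -> float:
        if self.proxy is not None:
            return float(self.proxy(assignment))
        return self.value(assignment)


@dataclass(frozen=True)
class DependencyHypergraph:
    """Variables plus one hyperedge per constraint/function dependency."""

    variables: frozenset[int]
    hyperedges: frozenset[frozenset[int]]

    @property
    def n_variables(self) -> int:
        return len(self.variables)


def weighted_value(weight: float, value: float) -> float:
    """alpha_f * f(x) with the convention that weight 0 nullifies +-inf."""
    if weight == 0.0:
        return 0.0
    return weight * value


class FeatureNetwork:
    """Variables with finite integer domains, constraints, and features."""

    def __init__(self) -> None:
        self.domains: list[tuple[int, ...]] = []
        self.constraints: list[Constraint] = []
        self.features: dict[str, Feature] = {}
        #: free-form metadata set by model builders (e.g. variable roles)
        self.meta: dict = {}

    # -- construction ------------------------------------------------------

    @property
    def n_variables(self) -> int:
        return len(self.domains)

    def add_variables(self, count: int, domain: Iterable[int]) -> list[int]:
        """Append ``count`` fresh variables sharing ``domain``; return their indices."""
        if count < 1:
            raise ModelError(f"count must be >= 1, got {count}")
        dom = tuple(int(v) for v in domain)
        if not dom:
            raise DomainError("domain must be non-empty")
        if len(set(dom)) != len(dom):
            raise DomainError(f"domain has duplicate values: {dom}")
        dom = tuple(sorted(dom))
        start = len(self.domains)
        self.domains.extend([dom] * count)
        return list(range(start, start + count))

    def domain(self, var: int) -> tuple[int, ...]:
        return self.domains[var]

    def _require_scope(self, scope: tuple[int, ...]) -> None:
        for v in scope:
            if not (0 <= v < self.n_variables):
                raise ModelError(f"scope references unknown variable {v}")

    def add_constraint(self, constraint: Constraint) -> None:
        self._require_scope(constraint.scope)
        self.constraints.append(constraint)

    def add_constraints(self, constraints: Iterable[Constraint]) -> None:
        for c in constraints:
            self.add_constraint(c)

    def add_function(self, function: NetworkFunction, feature: str) -> None:
        """Add ``function`` as a member of the feature named ``feature``."""
        self._require_scope(function.scope)
        self.features.setdefault(feature, Feature(feature)).functions.append(function)

    def add_functions(self, functions: Iterable[NetworkFunction], feature: str) -> None:
        for f in functions:
            self.add_function(f, feature)

    def set_feature_proxy(self, feature: str, proxy: Callable[[Mapping[int, int]], float]) -> None:
        if feature not in self.features:
            self.features[feature] = Feature(feature)
        self.features[feature].proxy = proxy

    # -- assignments -------------------------------------------------------

    def as_assignment(self, x) -> dict[int, int]:
        """Accept a mapping or a value sequence (one value per variable)."""
        if isinstance(x, Mapping):
            return {int(k): int(v) for k, v in x.items()}
        values = list(x)
        if len(values) != self.n_variables:
            raise ModelError(
                f"sequence assignment must bind all {self.n_variables} variables, got {len(values)}"
            )
        return {i: int(v) for i, v in enumerate(values)}

    def _check_domains(self, assignment: Mapping[int, int]) -> None:
        for v, val in assignment.items():
            if not (0 <= v < self.n_variables):
                raise ModelError(f"assignment binds unknown variable {v}")
            if val not in self.domains[v]:
                raise DomainError(f"value {val} not in domain of variable {v}: {self.domains[v]}")

    def is_total(self, assignment: Mapping[int, int]) -> bool:
        return len(assignment) == self.n_variables

    def is_valid(self, assignment) -> bool:
        """True iff every constraint whose scope is fully bound is satisfied.

        Constraints with unbound scope variables are skipped, so the empty
        assignment is always valid and validity is monotone: an invalid
        partial assignment has no valid extension.
        """
        a = self.as_assignment(assignment)
        self._check_domains(a)
        for c in self.constraints:
            if all(v in a for v in c.scope):
                if not c(*(a[v] for v in c.scope)):
                    return False
        return True

    def feature_value(self, feature: str, assignment) -> float:
        a = self.as_assignment(assignment)
        if feature not in self.features:
            raise ModelError(f"unknown feature {feature!r}")
        if not self.is_total(a):
            raise ModelError("feature_value requires a total assignment")
        self._check_domains(a)
        return self.features[feature].value(a)

    def resolve_weights(self, weights: Mapping[str, float] | None = None) -> dict[str, float]:
        """Complete a weight vector with the default weight 1.0 per feature."""
        w = dict(weights or {})
        for name in w:
            if name not in self.features:
                raise ModelError(f"weight given for unknown feature {name!r}")
        return {name: float(w.get(name, 1.0)) for name in self.features}

    def evaluate(self, assignment, weights: Mapping[str, float] | None = None) -> float:
        """Weighted evaluation E(x, alpha) of a valid total assignment."""
        a = self.as_assignment(assignment)
        self._check_domains(a)
        if not self.is_total(a):
            raise ModelError("evaluate requires a total assignment")
        if not self.is_valid(a):
            raise InvalidAssignmentError("assignment violates a constraint")
        w = self.resolve_weights(weights)
        total = 0.0
        for name, feat in self.features.items():
            total += weighted_value(w[name], feat.value(a))
        return total

    # -- structure ---------------------------------------------------------

    def dependency_graph(self) -> DependencyHypergraph:
        edges = {frozenset(c.scope) for c in self.constraints}
        for feat in self.features.values():
            edges.update(frozenset(f.scope) for f in feat.functions)
        return DependencyHypergraph(
            variables=frozenset(range(self.n_variables)), hyperedges=frozenset(edges)
        )

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        def item_dict(item):
            if item.type_name is None:
                raise ModelError(
                    f"cannot serialize ad-hoc constraint/function {item.name!r}; "
                    "use define_constraint_type/define_function_type"
                )
            return {"type": item.type_name, "params": list(item.params)}

        return {
            "variables": [list(d) for d in self.domains],
            "constraints": [item_dict(c) for c in self.constraints],
            "features": {
                name: {"functions": [item_dict(f) for f in feat.functions]}
                for name, feat in self.features.items()
            },
        }

    @classmethod
    def from_dict(cls, data: dict) -> "FeatureNetwork":
        net = cls()
        for dom in data.get("variables", []):
            net.add_variables(1, dom)
        for c in data.get("constraints", []):
            factory = _CONSTRAINT_TYPES.get(c["type"])
            if factory is None:
                raise ModelError(f"unknown constraint type {c['type']!r}")
            net.add_constraint(factory(*_revive(c["params"])))
        for name, feat in data.get("features", {}).items():
            net.features.setdefault(name, Feature(name))
            for f in feat.get("functions", []):
                factory = _FUNCTION_TYPES.get(f["type"])
                if factory is None:
                    raise ModelError(f"unknown function type {f['type']!r}")
                net.add_function(factory(*_revive(f["params"])), name)
        return net

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_json(cls, text: str) -> "FeatureNetwork":
        return cls.from_dict(json.loads(text))


def _revive(params):
    """JSON represents tuples as lists; constraint params are positional."""
    return list(params)


# -- constraint/function type factories -------------------------------------

_CONSTRAINT_TYPES: dict[str, Callable] = {}
_FUNCTION_TYPES: dict[str, Callable] = {}


def define_constraint_type(name, scope_builder, value_rule, register: bool = True):
    """Create a factory for a parameterized constraint type.

    ``scope_builder(*params)`` returns the variable scope;
    ``value_rule(values, *params)`` maps the tuple of scope values to a truth
    value.  Both must be referentially transparent.  Registered types can be
    serialized to and revived from JSON by their name and parameters.
    """

    def factory(*params):
        scope = _check_scope(scope_builder(*params))

        def predicate(*values):
            return bool(value_rule(values, *params))

        return Constraint(scope, predicate, name=name, type_name=name, params=tuple(params))

    factory.type_name = name
    if register:
        _CONSTRAINT_TYPES[name] = factory
    return factory


def define_function_type(name, scope_builder, value_rule, register: bool = True):
    """Like :func:`define_constraint_type` for real-valued network functions."""

    def factory(*params):
        scope = _check_scope(scope_builder(*params))

        def evaluator(*values):
            return float(value_rule(values, *params))

        return NetworkFunction(scope, evaluator, name=name, type_name=name, params=tuple(params))

    factory.type_name = name
    if register:
        _FUNCTION_TYPES[name] = factory
    return factory
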