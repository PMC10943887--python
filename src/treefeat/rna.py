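"""Multitarget RNA design models and DFA-controlled sequence models.

The design model places one variable per sequence position (domain = the
four nucleotides), a complementarity constraint per base pair in the union
of the target structures, a GC-content feature (one unary indicator per
position), and one base-pair-energy feature per target structure.  Sampling
at weights (alpha_gc, alpha_1, ..., alpha_k) then draws sequences s with

    P(s)  prop.  exp(alpha_gc * #GC(s)) * prod_l exp(alpha_l * E_bp(s, S_l)).

Motif avoidance/enforcement is expressed by running a deterministic finite
automaton alongside the sequence: one state variable per position plus a
ternary transition constraint, built here from motif lists via Aho-Corasick.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .model import (Feature, FeatureNetwork, ModelError,
                    define_constraint_type, define_function_type)

RNA_ALPHABET: tuple[str, ...] = ("A", "C", "G", "U")
_BASE_INDEX = {b: i for i, b in enumerate(RNA_ALPHABET)}

#: canonical base pairs (Watson-Crick plus wobble), as nucleotide-code pairs
CANONICAL_PAIRS: frozenset[tuple[int, int]] = frozenset(
    (_BASE_INDEX[a], _BASE_INDEX[b])
    for a, b in [("A", "U"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "A"), ("U", "G")]
)

#: placeholder base-pair energy table (NOT a fitted or published parameter
#: set; pass an explicit table for any quantitative use)
DEFAULT_BP_TABLE: dict[str, float] = {
    "GC": -3.0, "CG": -3.0, "AU": -2.0, "UA": -2.0, "GU": -1.0, "UG": -1.0,
}


def encode_sequence(seq: str) -> list[int]:
    try:
        return [_BASE_INDEX[c] for c in seq.upper().replace("T", "U")]
    except KeyError as e:
        raise ModelError(f"not an RNA nucleotide: {e.args[0]!r}") from None


def decode_sequence(codes: Iterable[int]) -> str:
    return "".join(RNA_ALPHABET[c] for c in codes)


# -- secondary structures ------------------------------------------------------


@dataclass(frozen=True)
class SecondaryStructure:
    """Base pairs (i, j), 1 <= i < j <= length, free of base triplets."""

    length: int
    pairs: frozenset[tuple[int, int]]

    def __post_init__(self):
        seen: set[int] = set()
        for i, j in self.pairs:
            if not (1 <= i < j <= self.length):
                raise ModelError(f"pair {(i, j)} out of range for length {self.length}")
            for p in (i, j):
                if p in seen:
                    raise ModelError(f"position {p} paired twice (base triplet)")
                seen.add(p)

    @property
    def crossing(self) -> bool:
        ps = sorted(self.pairs)
        for a in range(len(ps)):
            i, j = ps[a]
            for k, l in ps[a + 1:]:
                if i < k < j < l:
                    return True
        return False


_BRACKETS = {"(": ")", "[": "]", "{": "}", "<": ">"}
_CLOSERS = {v: k for k, v in _BRACKETS.items()}


def parse_dotbracket(text: str) -> SecondaryStructure:
    """Parse dot-bracket notation; extra bracket layers encode pseudoknots."""
    text = text.strip()
    stacks: dict[str, list[int]] = {k: [] for k in _BRACKETS}
    pairs: set[tuple[int, int]] = set()
    for pos, c in enumerate(text, start=1):
        if c == ".":
            continue
        if c in _BRACKETS:
            stacks[c].append(pos)
        elif c in _CLOSERS:
            opener = _CLOSERS[c]
            if not stacks[opener]:
                raise ModelError(f"unbalanced {c!r} at position {pos}")
            pairs.add((stacks[opener].pop(), pos))
        else:
            raise ModelError(f"unexpected character {c!r} in dot-bracket string")
    for k, st in stacks.items():
        if st:
            raise ModelError(f"unbalanced {k!r} at position {st[-1]}")
    return SecondaryStructure(len(text), frozenset(pairs))


def to_dotbracket(structure: SecondaryStructure) -> str:
    """Render a structure, assigning crossing pairs to deeper bracket layers."""
    layers: list[list[tuple[int, int]]] = []
    for pair in sorted(structure.pairs):
        for layer in layers:
            if not any(a < pair[0] < b < pair[1] or pair[0] < a < pair[1] < b
                       for a, b in layer):
                layer.append(pair)
                break
        else:
            layers.append([pair])
    if len(layers) > len(_BRACKETS):
        raise ModelError("structure needs more bracket layers than supported")
    out = ["."] * structure.length
    for layer, opener in zip(layers, _BRACKETS):
        for i, j in layer:
            out[i - 1] = opener
            out[j - 1] = _BRACKETS[opener]
    return "".join(out)


# -- sequence-level scores -----------------------------------------------------


def gc_count(sequence: str) -> int:
    """Number of G and C characters, #GC(w)."""
    codes = encode_sequence(sequence)
    return sum(1 for c in codes if RNA_ALPHABET[c] in ("G", "C"))


def _table_lookup(table: Mapping[str, float], a: int, b: int) -> float:
    key = RNA_ALPHABET[a] + RNA_ALPHABET[b]
    if key not in table:
        raise ModelError(f"energy table lacks canonical pair {key}")
    return float(table[key])


def bp_energy(sequence: str, structure: SecondaryStructure,
              table: Mapping[str, float] | None = None) -> float:
    """E_bp(s, S) = sum of per-pair energies; +inf if any pair is non-canonical."""
    table = DEFAULT_BP_TABLE if table is None else table
    codes = encode_sequence(sequence)
    if len(codes) != structure.length:
        raise ModelError("sequence/structure length mismatch")
    total = 0.0
    for i, j in structure.pairs:
        if (codes[i - 1], codes[j - 1]) not in CANONICAL_PAIRS:
            return float("inf")
        total += _table_lookup(table, codes[i - 1], codes[j - 1])
    return total


# -- design model --------------------------------------------------------------

BPCompl = define_constraint_type(
    "BPCompl",
    lambda i, j: (i, j),
    lambda vals, i, j: (vals[0], vals[1]) in CANONICAL_PAIRS,
)

GC = define_function_type(
    "GC",
    lambda i: (i,),
    lambda vals, i: 1.0 if RNA_ALPHABET[vals[0]] in ("G", "C") else 0.0,
)

BPEnergy = define_function_type(
    # +inf on non-canonical pairs (those assignments are excluded by the
    # BPCompl constraints anyway, but the function is total over the domains)
    "BPEnergy",
    lambda i, j, table: (i, j),
    lambda vals, i, j, table:
        _table_lookup(table, vals[0], vals[1])
        if (vals[0], vals[1]) in CANONICAL_PAIRS else float("inf"),
)


def design_model(structures: Sequence[SecondaryStructure],
                 table: Mapping[str, float] | None = None,
                 allow_crossing: bool = False) -> FeatureNetwork:
    """Feature network for multitarget design over k target structures.

    Variables 0..n-1 carry nucleotide codes; feature ``gc`` counts G/C
    positions; feature ``E<l>`` sums the pair energies of structure l.
    Crossing targets are rejected unless ``allow_crossing`` (the engine
    itself has no noncrossing requirement).
    """
    if not structures:
        raise ModelError("need at least one target structure")
    n = structures[0].length
    if any(s.length != n for s in structures):
        raise ModelError("all target structures must have equal length")
    if not allow_crossing and any(s.crossing for s in structures):
        raise ModelError("crossing target structure; pass allow_crossing=True to permit")
    table = dict(DEFAULT_BP_TABLE if table is None else table)

    net = FeatureNetwork()
    xs = net.add_variables(n, range(len(RNA_ALPHABET)))
    union = sorted(set().union(*(s.pairs for s in structures)))
    for i, j in union:
        net.add_constraint(BPCompl(xs[i - 1], xs[j - 1]))
    for i in xs:
        net.add_function(GC(i), "gc")
    for l, s in enumerate(structures, start=1):
        name = f"E{l}"
        net.features.setdefault(name, Feature(name))  # keep unpaired targets visible
        for i, j in sorted(s.pairs):
            net.add_function(BPEnergy(xs[i - 1], xs[j - 1], table), name)
    net.meta.update({
        "kind": "rna_design", "n": n, "x_vars": xs,
        "structures": [to_dotbracket(s) for s in structures],
    })
    return net


def sequence_of(network: FeatureNetwork, assignment) -> str:
    """Decode a design-model assignment back into an RNA string."""
    a = network.as_assignment(assignment)
    xs = network.meta.get("x_vars")
    if xs is None:
        raise ModelError("network is not a design/DFA sequence model")
    return decode_sequence(a[v] for v in xs)


# -- deterministic finite automata ---------------------------------------------


@dataclass(frozen=True)
class DFA:
    """Total-transition DFA over a symbol alphabet (states are 0..n-1)."""

    alphabet: tuple[str, ...]
    transitions: tuple[tuple[int, ...], ...]  # [state][symbol code] -> state
    initial: int
    accepting: frozenset[int]

    @property
    def n_states(self) -> int:
        return len(self.transitions)

    def step(self, state: int, symbol: str) -> int:
        if symbol not in self.alphabet:
            raise ModelError(f"symbol {symbol!r} not in automaton alphabet")
        return self.transitions[state][self.alphabet.index(symbol)]


def accepts(dfa: DFA, word: str) -> bool:
    state = dfa.initial
    for ch in word:
        state = dfa.step(state, ch)
    return state in dfa.accepting


def aho_corasick_dfa(motifs: Sequence[str], alphabet: Sequence[str] = RNA_ALPHABET,
                     mode: str = "accept", word_length: int | None = None) -> DFA:
    """Aho-Corasick substring automaton for a motif set.

    ``accept`` mode accepts exactly the words containing at least one motif
    occurrence (an absorbing accept state collects all matches); for
    equal-length motifs and words of that same length this is exact-word
    acceptance.  ``forbid`` complements the language by making every state
    but the absorbing one accepting.
    """
    if mode not in ("accept", "forbid"):
        raise ModelError(f"mode must be 'accept' or 'forbid', got {mode!r}")
    alphabet = tuple(alphabet)
    if not motifs:
        raise ModelError("need at least one motif")
    for m in motifs:
        if not m:
            raise ModelError("empty motif")
        if any(c not in alphabet for c in m):
            raise ModelError(f"motif {m!r} uses symbols outside the alphabet")
        if word_length is not None and len(m) != word_length:
            raise ModelError(f"motif {m!r} does not have declared length {word_length}")

    # trie over motif prefixes; any node at/past a full motif collapses to the sink
    prefixes = {""}
    for m in motifs:
        for k in range(1, len(m) + 1):
            prefixes.add(m[:k])
    is_hit = {p for p in prefixes if any(p.endswith(m) for m in motifs)}
    live = sorted((p for p in prefixes if p not in is_hit),
                  key=lambda p: (len(p), p))
    state_of = {p: i for i, p in enumerate(live)}
    sink = len(live)

    def goto(prefix: str, ch: str) -> int:
        s = prefix + ch
        while True:
            if any(s.endswith(m) for m in motifs):
                return sink
            if s in state_of:
                return state_of[s]
            s = s[1:]

    transitions = [
        tuple(goto(p, ch) for ch in alphabet) for p in live
    ]
    transitions.append(tuple(sink for _ in alphabet))  # absorbing
    if mode == "accept":
        accepting = frozenset([sink])
    else:
        accepting = frozenset(range(len(live)))
    return DFA(alphabet, tuple(transitions), state_of[""], accepting)


Transition = define_constraint_type(
    "Transition",
    lambda xi, yprev, yi, delta: (xi, yprev, yi),
    lambda vals, xi, yprev, yi, delta: vals[2] == delta[vals[1]][vals[0]],
)


def dfa_model(dfa: DFA, n: int) -> FeatureNetwork:
    """Pure-CSP network whose valid assignments are the accepted length-n runs.

    Symbol variables X_1..X_n carry alphabet codes; state variables Y_0..Y_n
    carry automaton states, with Y_0 pinned to the initial state and Y_n
    restricted to the accepting set.  Position i contributes the ternary
    transition constraint y_i = delta(y_{i-1}, x_i).
    """
    if n < 1:
        raise ModelError("n must be >= 1")
    if not dfa.accepting:
        raise ModelError("automaton has no accepting states")
    net = FeatureNetwork()
    delta = [list(row) for row in dfa.transitions]
    y0 = net.add_variables(1, [dfa.initial])[0]
    xs, ys = [], [y0]
    for i in range(1, n + 1):
        x = net.add_variables(1, range(len(dfa.alphabet)))[0]
        dom = sorted(dfa.accepting) if i == n else range(dfa.n_states)
        y = net.add_variables(1, dom)[0]
        net.add_constraint(Transition(x, ys[-1], y, delta))
        xs.append(x)
        ys.append(y)
    net.meta.update({"kind": "dfa", "n": n, "x_vars": xs, "y_vars": ys,
                     "alphabet": list(dfa.alphabet)})
    return net


def add_dfa_track(network: FeatureNetwork, dfa: DFA,
                  x_vars: Sequence[int] | None = None) -> list[int]:
    """Merge an automaton into an existing sequence model (e.g. a design
    network): adds state variables and transition constraints over the given
    symbol variables.  Returns the new state-variable indices."""
    xs = list(x_vars if x_vars is not None else network.meta.get("x_vars", []))
    if not xs:
        raise ModelError("no symbol variables to attach the automaton to")
    for x in xs:
        if len(network.domains[x]) > len(dfa.alphabet):
            raise ModelError("symbol variable domain exceeds automaton alphabet")
    if not dfa.accepting:
        raise ModelError("automaton has no accepting states")
    delta = [list(row) for row in dfa.transitions]
    ys = network.add_variables(1, [dfa.initial])
    for i, x in enumerate(xs):
        dom = sorted(dfa.accepting) if i == len(xs) - 1 else range(dfa.n_states)
        y = network.add_variables(1, dom)[0]
        network.add_constraint(Transition(x, ys[-1], y, delta))
        ys.append(y)
    network.meta.setdefault("y_vars", ys)
    return ys
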