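# treefeat

Exact optimization and exact Boltzmann sampling over **feature networks**,
solved by dynamic programming on tree decompositions — with ready-made models
for multitarget RNA design, motif-controlled sequence generation, (pseudoknot)
sequence–structure alignment, and small parsimony on phylogenetic networks.

## Who this is for

Many bioinformatics problems are naturally stated as "find the best solution
under hard constraints and weighted scores" or "draw solutions from the
Boltzmann distribution of those scores".  Writing the dynamic program for each
such problem by hand is tedious and error-prone.  `treefeat` lets you state
the problem declaratively — variables over finite integer domains, Boolean
constraints, and *features* (named sets of real-valued local functions) — and
solves it with generic cluster-tree elimination whose cost is exponential only
in the **treewidth** of the model's dependency graph, not in the number of
variables.

## The model and the algorithms

A feature network is a tuple (X, D, C, F).  A total assignment x is *valid*
if it satisfies every constraint in C; its evaluation under feature weights α
is

    E(x, α) = Σ_{F ∈ F} α_F · F(x),    F(x) = Σ_{f ∈ F} f(x).

Two problems are solved over the valid assignments:

* **Optimization** — find x\* maximizing E(x, α);
* **Sampling** — draw x with probability exp(E(x, α)) / Z, where
  Z = Σ_x exp(E(x, α)) is the partition function.

Both are solved by the same message-passing recursion over a rooted ("gentle")
tree decomposition of the dependency graph, differing only in the algebra:
(max, +, Id) for optimization, (+, ×, exp) for partition functions.  Messages
are tables of conditional subtree values keyed by separator assignments; a
deterministic traceback recovers one optimal assignment, a stochastic
traceback draws exact Boltzmann samples.  For width w, n variables, m
constraints/functions and domain size d, the forward pass costs
O(d^(w+1)·(n+m)) time and O(d^w·n) space; each traceback costs O(d·(n+m)).
Tree decompositions come from a seeded, restarted min-fill heuristic (an exact
small-instance treewidth routine is included for validation).

**Targeted sampling** (multidimensional Boltzmann sampling) collects samples
whose feature values land within tolerances of prescribed targets,
|F(x) − τ_F| ≤ δ_F, by iteratively learning the weights α that move the
sampling means onto the targets, with RMSD-based annealing of the step size.

## A worked example

The classic demonstration: color a 9-vertex graph with 4 colors (inequality
constraints along edges) while minimizing a feature that counts the distinct
colors on three 4-cycles.

```python
from treefeat import FeatureNetwork, define_constraint_type, define_function_type
from treefeat.solvers import TreeSolver

NotEquals = define_constraint_type(
    "NE", lambda i, j: (i, j), lambda vals, i, j: vals[0] != vals[1], register=False)
Card = define_function_type(
    "CardX", lambda *ijkl: ijkl, lambda vals, *ijkl: len(set(vals)), register=False)

net = FeatureNetwork()
net.add_variables(9, [1, 2, 3, 4])                      # one color per vertex
edges = [(1,2),(1,4),(2,3),(2,5),(2,8),(3,6),(4,5),(5,6),(5,7),
         (5,8),(5,9),(6,7),(6,8),(7,8),(8,9)]
for i, j in edges:
    net.add_constraint(NotEquals(i - 1, j - 1))
for cycle in [(2,3,5,6), (2,5,7,8), (5,6,7,8)]:
    net.add_function(Card(*(v - 1 for v in cycle)), "card")

solver = TreeSolver(net, seed=1)
print("width:", solver.width)
value, best = solver.optimize({"card": -1.0})           # minimize via weight -1
print("minimal total cycle cardinality:", -value)
print("one optimal coloring:", [best[i] for i in range(9)])
print("number of proper colorings:", solver.partition({"card": 0.0}))
```

This prints:

```
width: 4
minimal total cycle cardinality: 10.0
one optimal coloring: [1, 2, 1, 2, 1, 4, 2, 3, 2]
number of proper colorings: 1680.0
```

The solver decomposed the problem at width 4 (bags of at most 5 of the 9
variables), found a proper coloring using only 10 distinct colors across the
three scored cycles (the minimum; e.g. cycle (2,3,5,6) gets colors 2,1,1,4 —
three distinct), and counted exactly 1680 proper colorings by running the same
recursion in the sum–product algebra at weight 0.  `solver.sample(...)` draws
colorings from the corresponding Boltzmann distribution; negative weights
concentrate it on few-colored cycles.

The application modules construct such networks for you: `treefeat.rna`
(multitarget design and motif automata), `treefeat.align` (linear, affine and
arc-annotated alignment), `treefeat.phylo` (hardwired/softwired parsimony),
with matching `treefeat` CLI subcommands (`design`, `align`, `parsimony`,
`motif`, plus generic `optimize`/`sample`/`target` on JSON models).  For
instance,

```
treefeat motif --motif UGA --motif UUA --motif UUG --mode accept \
        --length 3 --count --seed 0
```

reports `"count": 3.0` — the three stop codons are the only length-3 words
accepted by their Aho–Corasick automaton.

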