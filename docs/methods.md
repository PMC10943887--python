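# Methods

## Feature networks

A model consists of variables X_1..X_n with finite integer domains, Boolean
constraints over small variable scopes, and *features*: named sets of
real-valued local functions.  A total assignment x is valid iff every
constraint is satisfied; for a partial assignment only constraints whose
scope is fully bound are checked, which makes validity monotone (an invalid
partial assignment has no valid extension).  The evaluation of a valid total
assignment under feature weights α is E(x, α) = Σ_F α_F Σ_{f∈F} f(x).

Functions may return ±∞; this is how a model excludes combinations under
maximization without adding a constraint (after weighting, −∞ maps to the
optimization algebra's excluded value and to Boltzmann factor 0).  One
convention is worth stating explicitly: a feature with weight 0 contributes
exactly 0, even where one of its functions is ±∞.  This keeps "all weights 0"
meaning "uniform over valid assignments" regardless of infinite-valued
functions, and avoids 0·∞ indeterminacy.  Evaluating an *invalid* total
assignment raises an error rather than returning −∞, because both solver
problems quantify over valid assignments only.

Constraint and function *types* are declared once (a scope builder plus a
value rule, both referentially transparent) and instantiated with parameters;
instances built from registered types serialize to JSON together with the
variables and domains, and the CLI consumes such model files.  Feature
proxies (used by targeted sampling, below) are code and do not serialize.

## Tree decompositions

The dependency graph has one hyperedge per constraint/function scope.
Decompositions are computed on the primal graph (each hyperedge cliquified,
which preserves the hyperedge-coverage condition) by a randomized min-fill
elimination heuristic: at each step a vertex with the fewest fill-in edges is
eliminated, ties broken uniformly at random under the run's seeded generator;
the best of `restarts` runs (default 20) is kept.  The result is deterministic
for a fixed seed.

Before solving, a decomposition is normalized to *gentle* form: an empty root
bag, and exactly one variable introduced per non-root node.  Oversized
difference sets are expanded into chains of bags (introducing variables in
ascending index order, for deterministic output); edges that introduce
nothing are contracted.  Width is preserved exactly, and a gentle
decomposition has exactly one tree edge per variable, so each traceback step
decides one variable.

`exact_treewidth` implements the O(2^n) dynamic program over vertex subsets
(minimum over elimination orders of the maximum degree-through-eliminated-set)
and is guarded to ≤ 14 vertices.  It exists to validate the heuristic: on the
random partial-k-tree instances used in the tests the heuristic matches the
exact width in well over 80% of cases and never beats it.

## Cluster-tree elimination

Constraints and functions are placed at the *deepest* bag containing their
scope (ties by lowest node id), so they prune and score partial assignments
as early as possible.  The forward pass visits nodes bottom-up; for each
assignment of a node's separator it combines, over the values of the node's
introduced variable, the lifted weighted local function values with the
children's messages, skipping extensions that violate a placed constraint.
The algebra is a parameter: (max, +, Id) yields optimal subtree evaluations
and E_max at the root; (+, ×, exp) yields conditional partition functions and
Z.  Messages are dense tables indexed by a mixed-radix encoding of the
separator assignment (last variable fastest), matching the d^|sep| space
bound.  An infeasible model yields −∞ (or Z = 0) rather than an error in the
forward pass; tracebacks raise an infeasibility error.

Placed items are precomputed into lookup tables over their scope's domain
product (d^k entries per k-ary item) unless a configurable total-entry cap
would be exceeded, in which case the remaining items are evaluated on the
fly (logged); results are bit-identical either way since items are
referentially transparent.

**Optimal traceback** walks the tree in preorder and, per node, selects the
first introduced-variable value (ascending domain order) whose bag evaluation
reproduces the stored message — a deterministic co-optimal tie-break.
Equality is exact for integer-valued scores and uses the tolerance
1e-9·(1+|value|) otherwise, since floating-point re-derivation need not be
bit-exact.

**Stochastic traceback** draws, per node, a tracking value t uniformly in
[0, message) and decrements it by each value's partial Boltzmann mass until
it turns negative; the resulting total assignment has probability
exp(E(x, α))/Z exactly (verified by chi-square against full enumeration).
Partition functions are computed in ordinary double precision — not in log
space, because the traceback needs additive partial masses — so strongly
positive weights can overflow; this raises a dedicated error that suggests
rescaling the weights.  All sampling randomness flows from one seedable
generator per run.

## Targeted sampling (multidimensional Boltzmann sampling)

Given targets (τ_F, δ_F), the sampler repeatedly draws k samples per round at
the current weights, keeps every (τ, δ)-admissible sample across rounds (the
inequality is non-strict, |F(x)−τ_F| ≤ δ_F), and stops once K admissible
samples exist.  After each incomplete round the targeted weights are updated

    α_F ← α_F + γ·(τ_F − μ̂_F) / s_F,

where μ̂_F is the round's sample mean and s_F its sample standard deviation
floored at 1e-6 (the normalization makes γ dimensionless across
heterogeneous features, e.g. counts vs. energies; an unnormalized variant is
configurable).  Increasing α_F provably increases the Boltzmann expectation
of F, which motivates the sign of the update.  If a round's RMSD to the
targets fails to improve on the best seen, γ is cooled by the factor Γ.
Defaults k=100, γ=0.5, Γ=0.8, max 1000 rounds are pragmatic tuning constants,
not canonical values.  On a separable model (independent binary variables
with a counting feature) the learned weight converges to the closed-form
exponential tilt log(p/(1−p)), which the tests check.

A feature may declare a *proxy* evaluator (e.g. an external folding energy
for a design model whose network functions are simple pair energies).  The
proxy is used for admissibility and for the means that drive the weight
updates; the sampling distribution itself always comes from the network
functions.  No efficiency guarantee is claimed for the loop — it is a
heuristic around exact per-round sampling; the hard guarantee is only that
every returned sample is admissible and valid.

## Application models

**RNA design.**  One variable per position over {A, C, G, U} (encoded 0–3); a
complementarity constraint per base pair in the union of the target
structures restricts pairs to the canonical set {AU, CG, GC, GU, UA, UG};
feature `gc` is a unary G/C indicator per position (so its weight controls
expected GC *count*; the CLI converts percentage targets); feature `E<l>` sums
a per-pair energy table over structure l.  The shipped default table
(GC/CG −3, AU/UA −2, GU/UG −1) is a placeholder on a plausible relative scale,
*not* a fitted parameter set — pass an explicit table for quantitative work.
Crossing (pseudoknotted) targets are accepted behind a flag since the engine
is indifferent to crossing; the strict mode rejects them to match the
noncrossing multitarget problem statement.  Dot-bracket input supports four
bracket layers for pseudoknots; structures must be free of base triplets.

**Motif automata.**  Aho–Corasick over the motif set, with every state at or
past a full motif occurrence collapsed into one absorbing state: `accept`
mode accepts words containing at least one motif occurrence (for equal-length
motifs and words of that length this is exact-word acceptance), `forbid`
makes every state but the absorbing one accepting.  The DFA is run alongside
any sequence model via one state variable per position (the last restricted
to accepting states) and a ternary transition constraint per position; with
no features this is a pure CSP whose partition function at weight 0 counts
accepted words.

**Alignment.**  Positions i of sequence a map to variables X_i whose value is
the matched position of b; deletion of i is encoded by x_i = x_{i−1}, which
keeps values non-decreasing (enforced by binary ≤ constraints) and gives a
bijection between valid assignments and alignments.  Sentinels X_0 = 0 and
X_{n+1} = m+1 are explicit singleton-domain variables.  Match functions apply
the elementwise score σ to *any* aligned pair — mismatch scores live in the σ
table (the default mismatch score 0 makes the total a sum over matches, as in
the worked example).  Linear gap score is γ per gapped position.  Affine gap
score g(ℓ) = β + γℓ adds Boolean match-state variables Y_i tied to the X
variables by ternary constraints; the ternary deletion function charges β+γ
when a deletion run opens (previous position matched) and γ when it extends,
and the insertion function charges β once per nonempty insertion run — with
β = 0 this degenerates exactly to the linear model.  Sequence–structure
alignment adds one 4-ary arc-match function per (possibly crossing) arc of
a's annotation, paying τ only when both endpoints are matched to a canonical
base pair of b — the match-state variables are what make "matched" expressible,
since an arc endpoint may be deleted while b's letters still happen to pair.
Banding restricts X_i's domain to round(i·m/n) ± band around the main
diagonal; a too-tight band surfaces as infeasibility at solve time, and the
band anchoring is the plain diagonal (no guide alignment).  Independent
Needleman–Wunsch- and Gotoh-style DP oracles are included for testing only.

**Network parsimony.**  One variable per node of the rooted DAG (leaf domains
pinned to the observed character, no constraints), one 0/1 distance function
per edge; minimization runs as maximization at feature weight −1 and the
score is reported negated.  Softwired parsimony (binary networks only) adds a
Boolean selector per reticulation node; the selector-gated distance charges
the selected parent edge and contributes 0 on the other, so optimizing over
selectors realizes the min-over-parents score.  "Left/right" parent follows
first appearance in the edge list and affects nothing but selector semantics.
A Sankoff dynamic program (trees) and an exhaustive displayed-tree
enumeration (networks, 2^r selector fixings) serve as independent oracles.

## Synthetic instance generators

All generators are deterministic under their seed.  `random_partial_ktree`
builds a k-tree and drops edges independently, certifying treewidth ≤ k by
construction.  `random_structures` inserts random compatible pairs until a
target count (≈ density·n/2) is reached, rejecting crossings in noncrossing
mode and enforcing a minimum loop span of 3 (the usual steric minimum for
RNA hairpins); densities are therefore exact up to insertion failures.
`random_binary_network` grows a random binary tree and adds each reticulation
by subdividing two edges and linking the new nodes, rejecting combinations
that would close a directed cycle.  What these generators do *not* emulate:
real base-pair statistics or energy landscapes, realistic branch lengths or
character-evolution models, and biologically structured alignment instances.
Passing tests therefore certify algorithmic correctness (agreement with
exact oracles at the stated sizes), not predictive performance on biological
data.

## Problem sizes used by the checks

The test battery compares against exhaustive enumeration wherever that is
exact and cheap: 200 random networks of ≤ 8 variables and domains ≤ 4 for the
engine, 50,000 samples for the chi-square tests of the sampling law (cells
pooled to expected counts ≥ 5), 100 random pairs of length ≤ 8 per alignment
oracle, 50 random trees and 20 random binary networks (≤ 4 reticulations) for
parsimony, 100 random graphs of ≤ 10 vertices for the decomposition
invariants, and a 20-variable counting model targeting 15 ± 1 for targeted
sampling.  These sizes keep the enumeration oracles exact; the engine itself
has no such limits beyond the treewidth dependence.

## Known limitations

* No constraint propagation, arc consistency, or branch-and-bound: dense
  models (large treewidth) are solved essentially by enumeration, which is by
  design out of scope.
* Partition functions in linear space limit usable weight magnitudes; the
  overflow error suggests rescaling but no automatic log-space fallback
  exists (stochastic traceback relies on additive partial masses).
* The alignment models carry the generic engine's extra linear factor in m
  compared to specialized alignment DPs (mitigated in practice by banding);
  local/semiglobal variants and the per-bag DP shortcut are not implemented.
* Softwired parsimony is restricted to binary networks; parental parsimony is
  not implemented.
* Turner/nearest-neighbor RNA energies are not computed; they can be attached
  as feature proxies for targeted sampling.
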