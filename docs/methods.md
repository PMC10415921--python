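# Methods

## The recognition problem

An edge-labeled digraph G = (N, E) with n = |N| nodes, e = |E| edges and
alphabet Σ (σ = |Σ|) is a *Wheeler graph* iff a total order over N exists
with (a) 0-indegree nodes before all others, (b) `a ≺ a' ⇒ v < v'` for every
edge pair (u,v)/a, (u',v')/a', and (c) `a = a' ∧ u < u' ⇒ v ≤ v'`. Ranks are
1-based throughout; labels compare by code point, and multi-character labels
are permitted. Recognition is NP-complete in general (the hard regime being
graphs where some node has d ≥ 5 same-label out-edges), so the toolkit
combines a polynomial pruning heuristic with two exact solvers.

## Renaming heuristic

Condition (b) plus the root rule force a partition into ordered blocks:
roots, then the destination set of each label in alphabet order (after the
conflict check every non-root has a single incoming label; a node with two
distinct incoming labels is an immediate non-Wheeler certificate, since its
rank would have to be smaller than itself). Each block gets a consecutive
rank interval and every member the interval's upper endpoint as its
*temporary order* — the "largest possible order" representative.

Refinement then repeatedly splits tie groups: members are sorted by their
*in-node list*, the sorted distinct temporary orders of their predecessors,
compared lexicographically with shorter-list-first on shared prefixes (a
self-loop contributes the node's own temporary order). This comparison is
*necessary*: whenever two same-label nodes' in-node lists differ under the
current (coarse) orders, every valid Wheeler ordering must place the
lexicographically smaller list first. Splitting therefore never discards a
valid ordering (soundness), tie groups never merge, and at most n rounds are
needed; the iteration cap n is a safety net only, because downstream solvers
verify every outcome. When refinement reaches all-singleton intervals, the
induced total order is the unique ordering consistent with a set of
necessary constraints, so a final check either confirms the graph Wheeler or
proves it is not — the heuristic alone can never produce a false negative.

## Solvers

**Wheelie-Pr** enumerates the Cartesian product of permutations within tie
groups (groups in rank order, permutations lexicographic by node
identifier). Same-label edge pairs are bucketed by the first decision level
at which all four endpoints are placed, and each partial assignment is
checked only against its newly completed pairs; conditions (a) and (b) are
structural after the conflict check. The first complete assignment passing
a full verification is returned; an `exhaustive` flag disables early
stopping (the verdict is unchanged, only the work differs). The timeout is
polled between tie-group assignments.

**Wheelie-SMT** encodes the residual problem in integer difference logic
(QF_IDL): one integer variable per node plus a designated zero, every atom
of the form `x_i − x_j ≤ c` with strict inequalities as `≤ −1`. In *range
mode* the per-node heuristic intervals become range constraints, condition
(b) clauses are implied by the intervals and omitted, and all-different
constraints — encoded pairwise as `(x−y ≤ −1) ∨ (y−x ≤ −1)` — shrink to
pairs inside one tie group. Condition (c) contributes, per ordered pair of
distinct same-label edges, the clause `¬(u−u' ≤ −1) ∨ (v−v' ≤ 0)` (pairs
sharing a source are vacuous but kept, so clause counts are comparable
across modes). *Pure mode* encodes everything from scratch: full 1..n
ranges, one condition-(b) unit per cross-label edge pair, all-node
all-different, and — a necessary addition the bare clause list would miss —
one unit `root − w ≤ −1` per (root, non-root) pair, without which a
satisfying model could order an otherwise unconstrained 0-indegree node too
late and a Wheeler graph would be rejected.

Satisfiability is decided by a DPLL search over a difference-constraint
theory core: asserted atoms are edges `j → i` of weight c in a constraint
graph, consistency is the absence of a negative cycle, and the all-pairs
shortest-path closure D both certifies consistency and evaluates literals
(atom (i,j,c) is entailed iff `D[j,i] ≤ c`, refuted iff `D[i,j] ≤ −c−1`).
Clause families are stored as integer index arrays and evaluated vectorized
against D; implied units are asserted in batches, with the closure
maintained either by per-edge O(n²) relaxations or a full Floyd–Warshall
recomputation when the batch is large. After root-level propagation the
clause set is compacted to the undecided residue; the search then branches
deterministically on the first undecided all-different (then condition-(c))
literal with chronological backtracking, rewinding a weight-matrix trail.
Models are read off the shortest distances from the zero variable; ranges
plus all-different make the decoded assignment a bijection, and every model
is re-verified with the reference checker before a wheeler verdict is
reported. Unsatisfiability of the (complete) encoding is a proof of
non-Wheelerness; timeout maps to a distinct `timeout` verdict. Formulas can
be exported as SMT-LIB 2 (`--dump-smt2`, logic QF_IDL) for cross-checking
with external solvers.

Defaults: solver `smt`, timeout 30 s.

## Oracles and search-space arithmetic

The brute-force recognizer tries all bijections in identifier-lexicographic
order and is capped at n ≤ 9; it is the reference for the cross-solver
equivalence suites. The enumeration baseline counts candidate (O, I, L)
triples — O and I bitstrings of length n+e with n ones that parse as unary
degree codes, L arrangements of the edge-label multiset, and label blocks
aligned to node boundaries in I — and deliberately omits the
graph-isomorphism inner loop of the full algorithm, so it never reaches a
verdict; its count depends only on n, e and the label multiset.
`search_space_C(n)` computes the largest integer C with `2^(2n+C) ≤ n!` by
exact big-integer comparison (floating-point logs are used only for report
fields); all logarithms are base 2.

## Generators

Sequence generators strip `-` gaps per row after any 1-based inclusive
column truncation. The trie inserts prefixes of every row (nodes named by
BFS order, children in label order). The De Bruijn generator takes one node
per distinct (k−1)-mer and labels each edge with the *last* character of
its destination, which gives every node a single incoming label and ≤ 1
same-label out-edge (a 1-NFA). By default every row is first padded with
k−1 `$` sentinels (code point below all residues, never an edge label): all
rows then enter through the single 0-indegree node `$`^(k−1), and the
co-lexicographic node order is a valid Wheeler ordering — provably, since
dropping a (k−1)-mer's first character preserves co-lex order. Without
padding, rows beginning with distinct (k−1)-mers yield several 0-indegree
nodes whose forced placement at the front of the order frequently
contradicts condition (c): roughly half of 4-row random-DNA graphs are then
genuinely non-Wheeler (brute-force verified), so the unpadded variant
(`sentinel=False`) exists for exploration but carries no guarantee. The
labeling variant `first` (label = destination's first character) is
likewise provided for comparison; it makes all out-edges of a node share
one label and breaks both the 1-NFA and the Wheeler guarantee. The
pseudo-De Bruijn generator keeps one node per (row, position) occurrence
and the reverse deterministic generator builds column-wise nodes
right-to-left with the destination column's character as label; neither is
guaranteed Wheeler.

Random generators fix the ordering up front (node `v<rank>`). The complete
generator realizes, per label block of size n_i, a seeded random monotone
lattice path over sources 1..n and the block's destinations — n−1 source
steps and n_i−1 destination steps — giving exactly `n + n_i − 1` edges per
label and `e_max = n·σ + n − σ − r` in total, with block sizes
`n_i ≈ (n−r)/σ` (remainders to alphabetically earlier labels). The output
is maximal at its root count: no edge whose destination already has an
in-edge can be added without violating the returned ordering; an edge into
a root is a different regime, since it lowers r and thereby raises the
bound itself. Random Wheeler graphs subsample a complete graph's edges
(r = 1), force-keeping each destination's first staircase in-edge so no
mid-rank node becomes a spurious root. The d-NFA generator solves the
per-label multiplicity profile (all x_k equal to `⌊e_i/(d(d+1)/2)⌋`,
residual to x_1; feasibility requires `Σ k·x_k = e_i`,
`n_min = 1 + Σ_{k≥2}(k−1)x_k ≤ n_i`, `e_i ≥ n_i` and enough distinct
sources), deals the multiplicities to randomly sampled sources, and maps
the rank-ordered slot sequence onto the destination block by a seeded
random monotone surjection that is strictly increasing within one source's
slots. Note the printed grid n=1000, e=3000, σ=4 admits only d=1 under
these equations (d=2 already needs n_min = 251 > n_i = 250); the validity
sweeps therefore use e = 1200 for d up to 4 at n = 1000.

All generator randomness flows from one `random.Random(seed)` stream per
call; identical parameters and seed give byte-identical DOT output.

`random_dna_msa` supplies uniform i.i.d. A/C/G/T rows as synthetic inputs.
It emulates the *sizes and alphabet* of real alignment-derived inputs, not
their biology: real ortholog rows are highly similar, so their De Bruijn
and trie graphs share far more structure than independent random rows do.
Passing suites on these inputs demonstrates the algorithms' correctness
contracts, not performance on any particular organism's data.

## Visualization

Nodes are drawn twice (source row / destination row) at x = rank × 60 px;
edges are straight lines colored by an 8-color palette assigned in alphabet
order (cycling beyond σ = 8). The crossing count is computed from ranks —
two distinct same-label edges cross iff `(rank u − rank u')(rank v − rank
v') < 0` — so it is exactly the condition-(c) violation count and
independent of styling. SVG output is deterministic. Non-Wheeler orderings
are drawn as-is with their crossing count reported; the CLI refuses to pick
an ordering itself for a non-Wheeler graph.

## Problem sizes and numerical choices

The equivalence suites run all four recognition routes on 200+ graphs with
n ≤ 8 (the brute-force oracle's comfortable range); generator-validity
sweeps go up to n = 1000 / e = 3000; the heuristic-effect comparison uses
twenty ~600-node De Bruijn graphs, where pure-mode formulas are ~0.5M
clauses and solve in about a second each. Degenerate inputs are defined:
the empty graph is Wheeler with the empty ordering; a lone self-loop is
Wheeler (no roots exist, edge-pair conditions are vacuous); duplicate DOT
edge triples collapse with a warning rather than an error. All floating
point is confined to reporting; every decision (closure weights, factorial
comparisons, profile arithmetic) is integral.

## Known limitations

* The built-in QF_IDL engine targets desk-scale formulas; it recomputes an
  O(n³) closure rather than maintaining sparse incremental potentials, so
  graphs beyond ~10⁴ nodes are out of scope.
* Non-Wheeler certificates from the SMT route report unsatisfiability, not
  a minimal conflicting clause set.
* The enumeration baseline cannot confirm Wheelerness (no isomorphism
  check) — it exists for search-space comparison only.
* Heuristic worst cases exist: refinement may stall with large tie groups
  (e.g. many nodes sharing one predecessor), leaving factorial or
  exponential work to the solvers; the d ≥ 5 regime is NP-complete and no
  polynomial guarantee is claimed.
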