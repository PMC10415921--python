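# wgt — Wheeler graph toolkit

A Wheeler graph is an edge-labeled directed graph whose nodes admit a total
order reflecting the co-lexicographic order of the strings spelled into each
node. Such graphs generalize the Burrows–Wheeler transform / FM-index to
graph-shaped text collections — De Bruijn graphs, tries and other pangenome
representations — and can be stored and queried through three succinct arrays
(O, I, L). Deciding whether an arbitrary graph has the Wheeler property is
NP-complete in general, and practical tooling for checking, generating and
visualizing such graphs is what this package provides, aimed at researchers
working on graph-based pangenome indexes.

Formally, a graph is Wheeler iff there is a total order `<` on nodes such
that 0-indegree nodes come first and for every pair of edges (u, v) labeled
`a` and (u', v') labeled `a'`:

* (i) `a ≺ a'  ⇒  v < v'`
* (ii) `a = a' ∧ u < u'  ⇒  v ≤ v'`

## What is inside

* **Recognition (“Wheelie”)** — a *renaming heuristic* partitions nodes into
  rank intervals (0-indegree nodes first, then destination blocks per label,
  iteratively refined by sorting nodes on the lists of their predecessors'
  temporary orders). Residual tie groups go to one of two exact solvers:
  * *Wheelie-Pr*: exhaustive search over within-group permutations with
    incremental pruning;
  * *Wheelie-SMT*: an integer-difference-logic (QF_IDL) encoding — one
    integer per node, atoms `x_i − x_j ≤ c` — decided by a built-in DPLL
    search over a Bellman-Ford/shortest-path theory core. A *pure SMT* mode
    encodes the whole definition without heuristic ranges, and any formula
    can be exported as SMT-LIB 2 for external solvers.
* **Indexing** — a recognized graph is emitted as the O/I/L arrays (unary
  out-/in-degree codes plus edge labels in O order).
* **Generators** — tries, De Bruijn and pseudo-De Bruijn graphs, reverse
  deterministic graphs from gapped FASTA alignments, plus random *complete*
  Wheeler graphs attaining the edge bound
  `e_max = n·σ + n − σ − r`, uniformly subsampled Wheeler graphs, and
  *d*-NFA Wheeler graphs (every node has ≤ d same-label out-edges, at least
  one attains d).
* **Oracles** — a brute-force permutation recognizer, the reduced
  enumeration baseline over candidate O/I/L arrays, and exact search-space
  arithmetic (the largest `C` with `2^(2n+C) ≤ n!`).
* **Visualization** — a two-row bipartite SVG in which a valid Wheeler
  ordering shows zero same-color edge crossings.

## Worked example

Build a De Bruijn graph (k=3) from two sequences and check it:

```sh
$ cat ex.fa
>seq1
ACGTACGT
>seq2
ACGTAGGT
$ wgt generate debruijn -f ex.fa -k 3 -o ex.dot
$ wgt recognize ex.dot
verdict: wheeler
  heuristic_iterations: 1
  largest_tie_group: 0
  solver_backend: heuristic-only
  tie_group_count: 0
ordering (node	rank):
$$	1
$A	2
TA	3
AC	4
AG	5
CG	6
GG	7
GT	8
O:01010010101010101
I:10101001010101001
L:ACCGGGTTA
```

The rows are padded with `$` sentinels so all sequences enter through the
single 0-indegree node `$$`, which is what guarantees the De Bruijn output
is Wheeler; the exit code is 0 (1 = not Wheeler, 2 = timeout). The ordering
is the co-lexicographic witness, and O/I/L encode the graph: e.g. `O`
concatenates one `0` per out-edge and a closing `1` for each node in rank
order, and `L` lists edge labels in that order. A two-row diagram of the
ordering comes from `wgt visualize ex.dot -o ex.svg`.

Comparing the exhaustive search spaces of array enumeration versus node
permutations:

```sh
$ wgt spacecmp -n 100 -e 100 -s 4
n          100
e          100
sigma      4
gt_log2    600.000
wheelie_log2 524.765
C          324
smaller    wheelie
```

i.e. at n=100 the enumeration baseline explores 2^600 candidate arrays while
permutation search explores 100! ≈ 2^524.8; C = 324 is the exact crossover
exponent.

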