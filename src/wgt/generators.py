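"""Graph generators: tries, (pseudo-)De Bruijn graphs, reverse deterministic
graphs from multiple sequence alignments, and random Wheeler graphs.

The random constructions fix a node ordering up front (node ``v<rank>`` has
rank <rank>) and then place edges so the Wheeler conditions hold by
construction: ranks 1..r are 0-indegree roots and the remaining ranks split
into per-label destination blocks in alphabet order.  A *complete* Wheeler
graph attains the edge-count bound e_max = n*sigma + n - sigma - r; random
Wheeler graphs subsample its edges; d-NFA graphs distribute per-label
out-multiplicities 1..d over shuffled source nodes.

All randomness flows from a single integer seed per call, so identical
parameters reproduce byte-identical DOT output.
"""

from __future__ import annotations

import io
import random
from collections import deque
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from Bio import SeqIO

from .graph import Edge, FormatError, LabeledDigraph, NodeOrdering

GAP = "-"
#: Row-start padding character for De Bruijn construction; sorts before all
#: residue characters, so padded (k-1)-mers take the low co-lex ranks.
SENTINEL = "$"
_DNA = "ACGT"


# ---------------------------------------------------------------------------
# Multiple sequence alignments
# ---------------------------------------------------------------------------


@dataclass
class MSA:
    """A gapped multiple sequence alignment (DNA or protein)."""

    records: List[Tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.records:
            raise FormatError("alignment has no records")
        lengths = {len(seq) for _, seq in self.records}
        if len(lengths) != 1:
            raise FormatError(
                f"aligned sequences have unequal lengths: {sorted(lengths)}"
            )

    @property
    def length(self) -> int:
        return len(self.records[0][1])

    def rows(self) -> List[str]:
        return [seq for _, seq in self.records]

    def ungapped_rows(self) -> List[str]:
        return [seq.replace(GAP, "") for _, seq in self.records]


def read_msa(text: str) -> MSA:
    """Parse a gapped FASTA alignment; residues are uppercased."""
    records = [
        (rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(io.StringIO(text), "fasta")
    ]
    if not records:
        raise FormatError("no FASTA records found")
    return MSA(records=records)


def write_msa(msa: MSA) -> str:
    return "".join(f">{name}\n{seq}\n" for name, seq in msa.records)


def truncate_columns(msa: MSA, first: int, last: int) -> MSA:
    """Keep alignment columns ``first..last`` (1-based, inclusive), pre-gap-removal."""
    if not (1 <= first <= last <= msa.length):
        raise ValueError(
            f"column range {first}..{last} outside alignment of length {msa.length}"
        )
    return MSA(records=[(name, seq[first - 1 : last]) for name, seq in msa.records])


def take_rows(msa: MSA, count: int) -> MSA:
    """Keep the first ``count`` records."""
    if count < 1:
        raise ValueError("need at least one row")
    return MSA(records=msa.records[:count])


def random_dna_msa(rows: int, length: int, seed: int, gap_prob: float = 0.0) -> MSA:
    """Seeded random DNA alignment (uniform A/C/G/T, optional gap columns)."""
    rng = random.Random(seed)
    records = []
    for i in range(rows):
        seq = "".join(
            GAP if gap_prob and rng.random() < gap_prob else rng.choice(_DNA)
            for _ in range(length)
        )
        records.append((f"seq{i + 1}", seq))
    return MSA(records=records)


# ---------------------------------------------------------------------------
# Sequence-derived graphs
# ---------------------------------------------------------------------------


def gen_trie(msa: MSA) -> LabeledDigraph:
    """Prefix trie over the gap-stripped rows; node names are BFS orders.

    One node per distinct prefix; the edge (prefix, prefix+c) is labeled c.
    Outputs are Wheeler 1-NFAs.
    """
    children: List[Dict[str, int]] = [{}]  # node id -> {char: child id}
    for row in msa.ungapped_rows():
        cur = 0
        for ch in row:
            nxt = children[cur].get(ch)
            if nxt is None:
                nxt = len(children)
                children.append({})
                children[cur][ch] = nxt
            cur = nxt
    # BFS naming, children visited in label order
    name: Dict[int, str] = {}
    order = 0
    queue = deque([0])
    while queue:
        node = queue.popleft()
        order += 1
        name[node] = str(order)
        for ch in sorted(children[node]):
            queue.append(children[node][ch])
    edges: List[Edge] = []
    queue = deque([0])
    while queue:
        node = queue.popleft()
        for ch in sorted(children[node]):
            child = children[node][ch]
            edges.append((name[node], name[child], ch))
            queue.append(child)
    return LabeledDigraph(nodes=set(name.values()), edges=edges)


def _check_kmer_rows(rows: Sequence[str], k: int) -> None:
    if k < 2:
        raise ValueError("k must be at least 2")
    for i, row in enumerate(rows):
        if len(row) < k - 1:
            raise ValueError(
                f"row {i + 1} has only {len(row)} residues after gap removal; "
                f"need at least k-1 = {k - 1}"
            )


def gen_debruijn(
    msa: MSA, k: int, label_convention: str = "last", sentinel: bool = True
) -> LabeledDigraph:
    """De Bruijn graph: one node per distinct (k-1)-mer of the gap-stripped rows.

    Adjacent (k-1)-mers within a row are connected once; the edge label is the
    last character of the destination (k-1)-mer by default, which makes the
    output a Wheeler 1-NFA under co-lexicographic node order.  The
    ``label_convention="first"`` variant labels with the destination's first
    character instead and carries no such guarantee.

    With ``sentinel=True`` (the default) every row is prefixed with k-1 '$'
    characters, so all rows enter the graph through the single 0-indegree
    node '$'*(k-1).  Without it, rows starting with distinct (k-1)-mers
    produce several 0-indegree nodes whose forced placement at the front of
    the ordering frequently contradicts the same-label condition: the
    Wheeler guarantee holds only for the padded construction.  Sentinels pad
    node names but never appear as edge labels.
    """
    if label_convention not in ("last", "first"):
        raise ValueError("label_convention must be 'last' or 'first'")
    rows = msa.ungapped_rows()
    _check_kmer_rows(rows, k)
    if sentinel:
        rows = [SENTINEL * (k - 1) + row for row in rows]
    nodes: List[str] = []
    seen = set()
    edges: List[Edge] = []
    eseen = set()
    for row in rows:
        kmers = [row[i : i + k - 1] for i in range(len(row) - k + 2)]
        for w in kmers:
            if w not in seen:
                seen.add(w)
                nodes.append(w)
        for a, b in zip(kmers, kmers[1:]):
            lab = b[-1] if label_convention == "last" else b[0]
            if (a, b, lab) not in eseen:
                eseen.add((a, b, lab))
                edges.append((a, b, lab))
    return LabeledDigraph(nodes=set(nodes), edges=edges)


def gen_pseudo_debruijn(
    msa: MSA, k: int, label_convention: str = "last"
) -> LabeledDigraph:
    """De Bruijn-like graph that never merges identical (k-1)-mers.

    One node per (row, position) occurrence, chained within each row; the
    output is not guaranteed to be a Wheeler graph.
    """
    if label_convention not in ("last", "first"):
        raise ValueError("label_convention must be 'last' or 'first'")
    rows = msa.ungapped_rows()
    _check_kmer_rows(rows, k)
    nodes = set()
    edges: List[Edge] = []
    for r, row in enumerate(rows, start=1):
        kmers = [row[i : i + k - 1] for i in range(len(row) - k + 2)]
        names = [f"{w}.r{r}p{i + 1}" for i, w in enumerate(kmers)]
        nodes.update(names)
        for i in range(len(kmers) - 1):
            b = kmers[i + 1]
            lab = b[-1] if label_convention == "last" else b[0]
            edges.append((names[i], names[i + 1], lab))
    return LabeledDigraph(nodes=nodes, edges=edges)


def gen_revdet(msa: MSA) -> LabeledDigraph:
    """Reverse deterministic graph built column by column, right to left.

    Each column contributes one node per distinct non-gap character; each
    row's consecutive ungapped characters c_i (column i) and c_j (next
    ungapped column j) contribute the deduplicated edge
    node(i, c_i) -> node(j, c_j) labeled c_j.  Not guaranteed Wheeler.
    """
    nodes = set()
    edges: List[Edge] = []
    eseen = set()
    for _, seq in msa.records:
        positions = [(col + 1, ch) for col, ch in enumerate(seq) if ch != GAP]
        for col, ch in positions:
            nodes.add(f"c{col}{ch}")
        for (ci, chi), (cj, chj) in zip(positions, positions[1:]):
            ed = (f"c{ci}{chi}", f"c{cj}{chj}", chj)
            if ed not in eseen:
                eseen.add(ed)
                edges.append(ed)
    return LabeledDigraph(nodes=nodes, edges=edges)


# ---------------------------------------------------------------------------
# Random Wheeler graphs
# ---------------------------------------------------------------------------


def _label_alphabet(sigma: int) -> List[str]:
    if sigma <= 26:
        return [chr(ord("A") + i) for i in range(sigma)]
    return [f"L{i:04d}" for i in range(sigma)]


def _block_sizes(total: int, parts: int) -> List[int]:
    """Split ``total`` into ``parts`` near-equal sizes, remainder to the front."""
    base, rem = divmod(total, parts)
    return [base + (1 if i < rem else 0) for i in range(parts)]


def e_max(n: int, sigma: int, r: int) -> int:
    """Upper bound on the edge count of a Wheeler graph: n*sigma + n - sigma - r."""
    if n < 1 or sigma < 1 or not (0 <= r <= n):
        raise ValueError("need n >= 1, sigma >= 1, 0 <= r <= n")
    return n * sigma + n - sigma - r


def _node(rank: int) -> str:
    return f"v{rank}"


def _complete_edges(
    n: int, sigma: int, r: int, rng: random.Random
) -> List[Tuple[int, int, str]]:
    """Edges of a random complete Wheeler graph as (source rank, dest rank, label).

    Per label block of size n_i, a random monotone staircase: sources 1..n in
    rank order, destinations stepping through the block, one step (new source
    or next destination) at a time.  This yields n + n_i - 1 edges per label
    with every source emitting and every block node receiving at least one.
    """
    alphabet = _label_alphabet(sigma)
    sizes = _block_sizes(n - r, sigma)
    edges: List[Tuple[int, int, str]] = []
    lo = r + 1
    for lab, ni in zip(alphabet, sizes):
        steps = ["R"] * (n - 1) + ["U"] * (ni - 1)
        rng.shuffle(steps)
        s, d = 1, lo
        edges.append((s, d, lab))
        for step in steps:
            if step == "R":
                s += 1
            else:
                d += 1
            edges.append((s, d, lab))
        lo += ni
    return edges


def gen_complete_wg(
    n: int, sigma: int, r: int, seed: int
) -> Tuple[LabeledDigraph, NodeOrdering]:
    """A complete Wheeler graph with exactly e_max(n, sigma, r) edges.

    Node ``v<rank>`` has rank <rank>; ranks 1..r are roots.  No further
    labeled edge can be added without breaking the Wheeler conditions under
    the returned ordering.
    """
    if n - r < sigma:
        raise ValueError("infeasible: need n - r >= sigma (one destination per label)")
    e_max(n, sigma, r)  # validates n, sigma, r
    rng = random.Random(seed)
    edges = [(_node(s), _node(d), lab) for s, d, lab in _complete_edges(n, sigma, r, rng)]
    g = LabeledDigraph(nodes={_node(i) for i in range(1, n + 1)}, edges=edges)
    ordering = {_node(i): i for i in range(1, n + 1)}
    return g, ordering


def gen_random_wg(n: int, e: int, sigma: int, seed: int) -> LabeledDigraph:
    """Random Wheeler graph with e < e_max edges, sampled from a complete one.

    One root (rank 1).  Each non-root keeps its first staircase in-edge so no
    mid-rank node is orphaned into a spurious root, then the remaining
    e - (n-1) edges are sampled uniformly without replacement.
    """
    r = 1
    emax = e_max(n, sigma, r)
    if not (n - r <= e < emax):
        raise ValueError(f"need n-1 <= e < e_max = {emax}, got e={e}")
    if n - r < sigma:
        raise ValueError("infeasible: need n - r >= sigma")
    rng = random.Random(seed)
    staircase = _complete_edges(n, sigma, r, rng)
    forced_idx: List[int] = []
    seen_dest = set()
    for i, (_, d, _) in enumerate(staircase):
        if d not in seen_dest:
            seen_dest.add(d)
            forced_idx.append(i)
    pool = [i for i in range(len(staircase)) if i not in set(forced_idx)]
    extra = rng.sample(pool, e - len(forced_idx))
    keep = sorted(set(forced_idx) | set(extra))
    edges = [
        (_node(s), _node(d), lab) for s, d, lab in (staircase[i] for i in keep)
    ]
    return LabeledDigraph(nodes={_node(i) for i in range(1, n + 1)}, edges=edges)


# ---------------------------------------------------------------------------
# d-NFA Wheeler graphs
# ---------------------------------------------------------------------------


@dataclass
class DnfaProfile:
    """Per-label out-multiplicity profile of a d-NFA Wheeler graph.

    For each label i, x[k] is the number of source nodes emitting exactly k
    same-label edges; sum_k k*x[k] = e_i, and the destinations fit iff
    n_min = 1 + sum_{k>=2} (k-1)*x[k] <= n_i.
    """

    d: int
    labels: List[str]
    n_i: List[int]
    e_i: List[int]
    x: List[Dict[int, int]]

    def n_min(self, label_index: int) -> int:
        return 1 + sum((k - 1) * cnt for k, cnt in self.x[label_index].items() if k >= 2)


def solve_dnfa_profile(n: int, e: int, sigma: int, d: int) -> DnfaProfile:
    """Split edges into per-label multiplicity profiles x_k.

    All x_k are set equal (floor(e_i / (d(d+1)/2))) with the residual added to
    x_1.  Errors name the violated feasibility condition.
    """
    if d < 1:
        raise ValueError("d must be at least 1")
    r = 1
    if n - r < sigma:
        raise ValueError("infeasible: need n - r >= sigma")
    labels = _label_alphabet(sigma)
    n_sizes = _block_sizes(n - r, sigma)
    e_sizes = _block_sizes(e, sigma)
    tri = d * (d + 1) // 2
    xs: List[Dict[int, int]] = []
    any_xd = False
    for lab, ni, ei in zip(labels, n_sizes, e_sizes):
        if ei < 1:
            raise ValueError(f"label {lab}: no edges to place (e_i = 0)")
        base = ei // tri
        x = {k: base for k in range(1, d + 1)}
        x[1] += ei - tri * base
        if sum(k * cnt for k, cnt in x.items()) != ei:
            raise AssertionError("multiplicity conservation violated")
        n_min = 1 + sum((k - 1) * cnt for k, cnt in x.items() if k >= 2)
        if n_min > ni:
            raise ValueError(
                f"label {lab}: minimum destinations n_min = {n_min} exceeds n_i = {ni}"
            )
        if ei < ni:
            raise ValueError(
                f"label {lab}: e_i = {ei} < n_i = {ni}; cannot cover every destination"
            )
        if sum(x.values()) > n:
            raise ValueError(
                f"label {lab}: profile needs {sum(x.values())} distinct sources > n = {n}"
            )
        if x.get(d, 0) >= 1:
            any_xd = True
        xs.append(x)
    if not any_xd:
        raise ValueError(
            f"infeasible: no label can host a node with {d} same-label out-edges "
            f"(all x_d = 0); lower d or raise e"
        )
    return DnfaProfile(d=d, labels=labels, n_i=n_sizes, e_i=e_sizes, x=xs)


def gen_dnfa_wg(n: int, e: int, sigma: int, d: int, seed: int) -> LabeledDigraph:
    """Random Wheeler d-NFA: max same-label outdegree is exactly d.

    Per label, the profile's out-multiplicities are dealt to randomly chosen
    source nodes; listing those sources in rank order with repetition, a
    random monotone surjection onto the destination block (strictly
    increasing within one source's slots) places the edges, so the fixed
    rank order remains a valid Wheeler ordering.
    """
    profile = solve_dnfa_profile(n, e, sigma, d)
    r = 1
    rng = random.Random(seed)
    edges: List[Tuple[int, int, str]] = []
    lo = r + 1
    for li, lab in enumerate(profile.labels):
        ni = profile.n_i[li]
        x = profile.x[li]
        mults: List[int] = []
        for k, cnt in sorted(x.items()):
            mults.extend([k] * cnt)
        rng.shuffle(mults)
        sources = sorted(rng.sample(range(1, n + 1), len(mults)))
        n_min = profile.n_min(li)
        # choose which between-source transitions advance the destination
        advance = set(rng.sample(range(len(sources) - 1), ni - n_min)) if len(sources) > 1 else set()
        dest = lo
        for j, (s, k) in enumerate(zip(sources, mults)):
            edges.append((s, dest, lab))
            for _ in range(k - 1):
                dest += 1
                edges.append((s, dest, lab))
            if j < len(sources) - 1 and j in advance:
                dest += 1
        if dest != lo + ni - 1:
            raise AssertionError("destination block not exactly covered")
        lo += ni
    g = LabeledDigraph(
        nodes={_node(i) for i in range(1, n + 1)},
        edges=[(_node(s), _node(t), lab) for s, t, lab in edges],
    )
    return g
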