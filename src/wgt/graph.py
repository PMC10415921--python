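"""Core data model for edge-labeled directed graphs and the Wheeler property.

A Wheeler graph is an edge-labeled digraph whose nodes admit a total order
``<`` such that 0-indegree nodes come first and, for every pair of edges
(u, v) labeled ``a`` and (u', v') labeled ``a'``:

  (i)  a < a'             implies  v < v'
  (ii) a = a' and u < u'  implies  v <= v'

This module houses the graph container, DOT round-tripping, checking a
candidate ordering against the definition, and building the O/I/L succinct
index of a recognized graph.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Set, Tuple

logger = logging.getLogger("wgt")

#: A candidate (or witness) Wheeler ordering: bijection node -> rank in 1..n.
NodeOrdering = Dict[str, int]

Edge = Tuple[str, str, str]  # (source, destination, label)


class FormatError(ValueError):
    """Malformed input document (DOT or FASTA)."""


@dataclass
class LabeledDigraph:
    """An edge-labeled directed graph.

    Parameters
    ----------
    nodes
        Node identifiers (strings).
    edges
        Ordered list of ``(source, destination, label)`` triples. Duplicate
        identical triples are not allowed; parallel edges with distinct labels
        are.
    """

    nodes: Set[str] = field(default_factory=set)
    edges: List[Edge] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.nodes = set(self.nodes)
        self.edges = list(self.edges)
        seen = set()
        for u, v, a in self.edges:
            if u not in self.nodes or v not in self.nodes:
                raise ValueError(f"edge {u}->{v} has an endpoint outside the node set")
            if (u, v, a) in seen:
                raise ValueError(f"duplicate edge triple {u}->{v} [{a}]")
            seen.add((u, v, a))

    @property
    def alphabet(self) -> List[str]:
        """Sorted list of distinct edge labels (code-point order)."""
        return sorted({a for _, _, a in self.edges})

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def e(self) -> int:
        return len(self.edges)

    @property
    def sigma(self) -> int:
        return len(self.alphabet)

    def in_edges(self, v: str) -> List[Edge]:
        return [ed for ed in self.edges if ed[1] == v]

    def out_edges(self, u: str) -> List[Edge]:
        return [ed for ed in self.edges if ed[0] == u]

    def indegree(self) -> Dict[str, int]:
        deg = {v: 0 for v in self.nodes}
        for _, v, _ in self.edges:
            deg[v] += 1
        return deg

    def outdegree(self) -> Dict[str, int]:
        deg = {v: 0 for v in self.nodes}
        for u, _, _ in self.edges:
            deg[u] += 1
        return deg

    def predecessors(self) -> Dict[str, List[str]]:
        pred: Dict[str, List[str]] = {v: [] for v in self.nodes}
        for u, v, _ in self.edges:
            pred[v].append(u)
        return pred

    def in_labels(self) -> Dict[str, Set[str]]:
        """Distinct labels on the incoming edges of each node."""
        lab: Dict[str, Set[str]] = {v: set() for v in self.nodes}
        for _, v, a in self.edges:
            lab[v].add(a)
        return lab


@dataclass
class OrderRanges:
    """Per-node inclusive 1-based rank interval from the renaming heuristic.

    Intervals either coincide exactly (a *tie group*) or are disjoint, and
    together (with tie-group multiplicity) tile 1..n.
    """

    range: Dict[str, Tuple[int, int]] = field(default_factory=dict)

    def tie_groups(self) -> List[List[str]]:
        """Tie groups in rank order; members sorted by identifier."""
        by_range: Dict[Tuple[int, int], List[str]] = {}
        for node, rng in self.range.items():
            by_range.setdefault(rng, []).append(node)
        groups = []
        for rng in sorted(by_range):
            groups.append(sorted(by_range[rng]))
        return groups

    def dump(self) -> str:
        """Debug dump: one ``node<TAB>lo<TAB>hi`` line per node, by (lo, node)."""
        lines = [
            f"{node}\t{lo}\t{hi}"
            for node, (lo, hi) in sorted(self.range.items(), key=lambda kv: (kv[1], kv[0]))
        ]
        return "\n".join(lines) + ("\n" if lines else "")


@dataclass
class WheelerIndex:
    """The O/I/L succinct index of a Wheeler graph.

    O and I are concatenations of unary codes, one per node in rank order:
    '0' per out-edge (resp. in-edge) followed by a terminating '1'.  L lists
    the edge labels in O order.
    """

    O: str
    I: str
    L: str

    def dump(self) -> str:
        return f"O:{self.O}\nI:{self.I}\nL:{self.L}\n"


@dataclass
class RecognitionResult:
    """Outcome of a recognition run."""

    verdict: str  # "wheeler" | "not_wheeler" | "timeout"
    ordering: Optional[NodeOrdering] = None
    violation: Optional[str] = None
    index: Optional[WheelerIndex] = None
    stats: Dict[str, object] = field(default_factory=dict)

    @property
    def is_wheeler(self) -> bool:
        return self.verdict == "wheeler"


# ---------------------------------------------------------------------------
# DOT I/O
#
# Only the restricted directed-DOT dialect used for these graphs is supported:
# node statements, edge statements with a mandatory label attribute, and
# comments.  Other attributes are ignored on read and never written.
# ---------------------------------------------------------------------------

_DOT_ID = r'(?:"(?:[^"\\]|\\.)*"|[A-Za-z0-9_.\-]+)'
_EDGE_RE = re.compile(
    rf"^({_DOT_ID})\s*(->|--)\s*({_DOT_ID})\s*(?:\[([^\]]*)\])?\s*;?$"
)
_NODE_RE = re.compile(rf"^({_DOT_ID})\s*(?:\[([^\]]*)\])?\s*;?$")
_LABEL_RE = re.compile(rf'label\s*=\s*({_DOT_ID})', re.IGNORECASE)


def _unquote(tok: str) -> str:
    if tok.startswith('"') and tok.endswith('"'):
        body = tok[1:-1]
        return re.sub(r"\\(.)", r"\1", body)
    return tok


def _quote(tok: str) -> str:
    if re.fullmatch(r"[A-Za-z_][A-Za-z0-9_]*|[0-9]+", tok):
        return tok
    return '"' + tok.replace("\\", "\\\\").replace('"', '\\"') + '"'


def _strip_comments(text: str) -> str:
    text = re.sub(r"/\*.*?\*/", " ", text, flags=re.S)
    text = re.sub(r"//[^\n]*", "", text)
    text = re.sub(r"(?m)^\s*#[^\n]*", "", text)
    return text


def parse_dot(text: str) -> LabeledDigraph:
    """Parse a directed-graph DOT document into a :class:`LabeledDigraph`.

    Every edge must carry a ``label`` attribute.  Duplicate identical
    (source, destination, label) triples are collapsed with a warning; node
    statements without edges yield isolated nodes.

    Raises
    ------
    FormatError
        If the document is not a ``digraph`` or an edge lacks a label.
    """
    text = _strip_comments(text)
    m = re.search(r"\b(digraph|graph)\b[^{]*\{", text)
    if m is None:
        raise FormatError("not a DOT graph document")
    if m.group(1) != "digraph":
        raise FormatError("undirected DOT graphs are not supported (need digraph)")
    body_start = m.end()
    body_end = text.rfind("}")
    if body_end < body_start:
        raise FormatError("unterminated DOT graph body")
    body = text[body_start:body_end]

    nodes: Set[str] = set()
    edges: List[Edge] = []
    seen: Set[Edge] = set()
    # split on ; and newlines -- statements in this dialect never span both
    for raw in re.split(r"[;\n]+", body):
        stmt = raw.strip()
        if not stmt:
            continue
        em = _EDGE_RE.match(stmt)
        if em:
            if em.group(2) == "--":
                raise FormatError("undirected edge statement in digraph")
            u, v = _unquote(em.group(1)), _unquote(em.group(3))
            attrs = em.group(4) or ""
            lm = _LABEL_RE.search(attrs)
            if lm is None:
                raise FormatError(f"edge {u}->{v} has no label")
            a = _unquote(lm.group(1))
            nodes.add(u)
            nodes.add(v)
            if (u, v, a) in seen:
                logger.warning("duplicate edge %s->%s [%s] collapsed", u, v, a)
                continue
            seen.add((u, v, a))
            edges.append((u, v, a))
            continue
        nm = _NODE_RE.match(stmt)
        if nm:
            name = _unquote(nm.group(1))
            if name not in ("node", "edge", "graph"):  # default-attr statements
                nodes.add(name)
            continue
        raise FormatError(f"unparseable DOT statement: {stmt!r}")
    return LabeledDigraph(nodes=nodes, edges=edges)


def write_dot(g: LabeledDigraph) -> str:
    """Serialize deterministically: isolated nodes sorted, edges in stored order.

    ``parse_dot(write_dot(g))`` reproduces ``g`` (same node set, same edge
    list) for any canonical graph.
    """
    lines = ["digraph {"]
    with_edges = {u for u, _, _ in g.edges} | {v for _, v, _ in g.edges}
    for node in sorted(g.nodes - with_edges):
        lines.append(f"  {_quote(node)};")
    for u, v, a in g.edges:
        lines.append(f'  {_quote(u)} -> {_quote(v)} [label="{a}"];')
    lines.append("}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Wheeler-property checking
# ---------------------------------------------------------------------------


def find_roots(g: LabeledDigraph) -> List[str]:
    """All 0-indegree nodes, sorted by identifier."""
    deg = g.indegree()
    return sorted(v for v in g.nodes if deg[v] == 0)


def _require_bijection(g: LabeledDigraph, ordering: NodeOrdering) -> None:
    if set(ordering) != g.nodes or sorted(ordering.values()) != list(
        range(1, g.n + 1)
    ):
        raise ValueError("ordering is not a bijection of the node set onto 1..n")


def check_wheeler(
    g: LabeledDigraph, ordering: NodeOrdering
) -> Tuple[bool, Optional[str]]:
    """Check a candidate ordering against the Wheeler definition.

    Returns ``(True, None)`` if valid, else ``(False, certificate)`` where the
    certificate names the first violated condition under a deterministic scan:
    condition (a) (roots first), then (b) (label order on destinations), then
    (c) (same-label source order preserved on destinations); edge pairs are
    scanned lexicographically in stored-edge order.
    """
    _require_bijection(g, ordering)
    rank = ordering

    # Fast monotone checks first; the quadratic certificate scan only runs
    # when a violation is known to exist.
    deg = g.indegree()
    roots = [v for v in g.nodes if deg[v] == 0]
    nonroots = [v for v in g.nodes if deg[v] > 0]
    ok_a = not roots or not nonroots or max(rank[v] for v in roots) < min(
        rank[v] for v in nonroots
    )
    if not ok_a:
        bad_nonroot = min(nonroots, key=lambda v: rank[v])
        bad_root = max(roots, key=lambda v: rank[v])
        return (
            False,
            "condition (a): 0-indegree node "
            f"{bad_root!r} (rank {rank[bad_root]}) does not precede node "
            f"{bad_nonroot!r} (rank {rank[bad_nonroot]})",
        )

    by_label: Dict[str, List[Edge]] = {}
    for ed in g.edges:
        by_label.setdefault(ed[2], []).append(ed)
    labels = sorted(by_label)

    # (b): max destination rank of label a < min destination rank of a' > a
    running_max = None
    ok_b = True
    for a in labels:
        ranks = [rank[v] for _, v, _ in by_label[a]]
        if running_max is not None and min(ranks) <= running_max:
            ok_b = False
            break
        running_max = max(ranks) if running_max is None else max(running_max, max(ranks))
    if not ok_b:
        for i, (u, v, a) in enumerate(g.edges):
            for u2, v2, a2 in g.edges[i + 1 :]:
                if a == a2:
                    continue
                lo, hi = ((u, v, a), (u2, v2, a2)) if a < a2 else ((u2, v2, a2), (u, v, a))
                if rank[lo[1]] >= rank[hi[1]]:
                    return (
                        False,
                        "condition (b): edges "
                        f"{lo[0]}->{lo[1]} [{lo[2]}] and {hi[0]}->{hi[1]} [{hi[2]}] "
                        f"have destination ranks {rank[lo[1]]} >= {rank[hi[1]]}",
                    )

    # (c): per label, scanning sources in rank order, destination ranks of a
    # later source may never drop below an earlier source's destinations.
    ok_c = True
    for a in labels:
        pairs = sorted((rank[u], rank[v]) for u, v, _ in by_label[a])
        running = 0
        cur_src = None
        cur_min = None
        prev_max = 0
        for ru, rv in pairs:
            if ru != cur_src:
                prev_max = max(prev_max, running)
                cur_src = ru
            running = max(running, rv)
            if rv < prev_max:
                ok_c = False
                break
        if not ok_c:
            break
    if not ok_c:
        for i, (u, v, a) in enumerate(g.edges):
            for u2, v2, a2 in g.edges[i + 1 :]:
                if a != a2:
                    continue
                if rank[u] < rank[u2] and rank[v] > rank[v2]:
                    return (
                        False,
                        "condition (c): same-label edges "
                        f"{u}->{v} [{a}] and {u2}->{v2} [{a}] invert destination order",
                    )
                if rank[u2] < rank[u] and rank[v2] > rank[v]:
                    return (
                        False,
                        "condition (c): same-label edges "
                        f"{u}->{v} [{a}] and {u2}->{v2} [{a}] invert destination order",
                    )
    return True, None


def build_index(g: LabeledDigraph, ordering: NodeOrdering) -> WheelerIndex:
    """Build the O/I/L index of ``g`` under a *valid* Wheeler ordering.

    O (resp. I) concatenates, over nodes in rank order, '0' per out-edge
    (in-edge) followed by '1'.  L lists edge labels sorted by
    (source rank, label, destination rank).
    """
    valid, cert = check_wheeler(g, ordering)
    if not valid:
        raise ValueError(f"ordering is not a Wheeler ordering: {cert}")
    by_rank = sorted(g.nodes, key=lambda v: ordering[v])
    outd = g.outdegree()
    ind = g.indegree()
    O = "".join("0" * outd[v] + "1" for v in by_rank)
    I = "".join("0" * ind[v] + "1" for v in by_rank)
    L = "".join(
        a
        for _, a, _ in sorted(
            (ordering[u], a, ordering[v]) for u, v, a in g.edges
        )
    )
    return WheelerIndex(O=O, I=I, L=L)


def max_same_label_outdegree(g: LabeledDigraph) -> int:
    """Largest number of same-label out-edges of any node (the d of a d-NFA)."""
    counts: Dict[Tuple[str, str], int] = {}
    for u, _, a in g.edges:
        counts[(u, a)] = counts.get((u, a), 0) + 1
    return max(counts.values(), default=0)


def ordering_dump(ordering: NodeOrdering) -> str:
    """One ``node<TAB>rank`` line per node, sorted by rank."""
    lines = [f"{node}\t{r}" for node, r in sorted(ordering.items(), key=lambda kv: kv[1])]
    return "\n".join(lines) + ("\n" if lines else "")
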