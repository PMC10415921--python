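"""The renaming heuristic: rough rank ranges by iterative partition refinement.

Nodes are first partitioned into blocks -- 0-indegree roots, then the
destinations of each label in alphabet order -- which is forced by the
Wheeler definition (roots first; smaller labels enter smaller nodes).  Each
block receives a consecutive rank interval.  The heuristic then repeatedly
splits blocks by sorting members on their *in-node lists* (the sorted
distinct temporary orders of their predecessors), a comparison that any
valid Wheeler ordering must respect.  Iteration stops at convergence, when
every interval is a singleton, or after n rounds.

Nodes left sharing an interval form *tie groups*; a downstream solver
decides their relative order.  A node with two distinctly-labeled incoming
edges is a certificate that no Wheeler ordering exists at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .graph import LabeledDigraph, OrderRanges, find_roots


@dataclass
class HeuristicState:
    """Mutable state of the renaming heuristic."""

    ranges: OrderRanges = field(default_factory=OrderRanges)
    temp_order: Dict[str, int] = field(default_factory=dict)
    iteration: int = 0
    converged: bool = False
    conflict: Optional[str] = None

    def tie_groups(self) -> List[List[str]]:
        return self.ranges.tie_groups()

    def is_totally_resolved(self) -> bool:
        """True iff every rank interval is a singleton (total order found)."""
        return all(lo == hi for lo, hi in self.ranges.range.values())

    def induced_ordering(self) -> Dict[str, int]:
        if not self.is_totally_resolved():
            raise ValueError("heuristic state has unresolved tie groups")
        return {node: lo for node, (lo, _) in self.ranges.range.items()}


def group_edges_by_label(g: LabeledDigraph) -> Dict[str, List[Tuple[str, str]]]:
    """Map label -> list of (source, destination), keys in alphabet order."""
    grouped: Dict[str, List[Tuple[str, str]]] = {a: [] for a in g.alphabet}
    for u, v, a in g.edges:
        grouped[a].append((u, v))
    return grouped


def detect_label_conflict(g: LabeledDigraph) -> Optional[str]:
    """First node (identifier order) with >= 2 distinct incoming labels.

    Such a node makes the graph non-Wheeler outright: two edges with labels
    a < a' entering the same node v would need rank(v) < rank(v).
    """
    in_labels = g.in_labels()
    for v in sorted(g.nodes):
        if len(in_labels[v]) >= 2:
            labs = ",".join(sorted(in_labels[v]))
            return f"node {v!r} has incoming edges with distinct labels {{{labs}}}"
    return None


def _initial_blocks(g: LabeledDigraph) -> List[List[str]]:
    """Root block then per-label destination blocks, alphabet order."""
    blocks: List[List[str]] = []
    roots = find_roots(g)
    if roots:
        blocks.append(roots)
    grouped = group_edges_by_label(g)
    for a in g.alphabet:
        dests = sorted({v for _, v in grouped[a]})
        if dests:
            blocks.append(dests)
    return blocks


def initialize_rough_order(g: LabeledDigraph) -> HeuristicState:
    """Assign each block a consecutive rank interval; temp order = interval hi.

    The "largest possible order" representative: every member of a block of
    size s starting at rank lo gets temporary order lo+s-1.
    """
    conflict = detect_label_conflict(g)
    state = HeuristicState(conflict=conflict)
    if conflict is not None:
        return state
    accum = 0
    for block in _initial_blocks(g):
        lo, hi = accum + 1, accum + len(block)
        for node in block:
            state.ranges.range[node] = (lo, hi)
            state.temp_order[node] = hi
        accum = hi
    return state


def get_innodelist(
    g: LabeledDigraph, state: HeuristicState, node: str, _pred: Optional[Dict[str, List[str]]] = None
) -> List[int]:
    """Sorted distinct temporary orders of the node's predecessors.

    Empty for roots; a self-loop contributes the node's own temporary order.
    """
    preds = _pred[node] if _pred is not None else g.predecessors()[node]
    return sorted({state.temp_order[p] for p in preds})


def _innodelist_key(lst: List[int]) -> Tuple:
    # lexicographic with shorter-list-first on shared prefixes: Python's
    # tuple comparison already does exactly this.
    return tuple(lst)


def renaming_heuristic(g: LabeledDigraph, max_iterations: Optional[int] = None) -> HeuristicState:
    """Run initialization plus refinement to convergence.

    Returns the final state; ``state.conflict`` is set when a label conflict
    proves the graph non-Wheeler.  Tie groups only ever split across
    iterations (never merge), so at most n rounds are needed; the cap is a
    safety net, since any residual tie is resolved by a downstream solver.
    """
    state = initialize_rough_order(g)
    if state.conflict is not None:
        return state
    if not g.nodes:
        state.converged = True
        return state
    pred = g.predecessors()
    cap = g.n if max_iterations is None else max_iterations

    groups = state.ranges.tie_groups()
    while state.iteration < cap:
        state.iteration += 1
        new_groups: List[List[str]] = []
        changed = False
        for group in groups:
            if len(group) == 1:
                new_groups.append(group)
                continue
            keyed = sorted(
                (( _innodelist_key(get_innodelist(g, state, v, pred)), v) for v in group),
            )
            # split into runs of equal in-node lists
            lo = state.ranges.range[group[0]][0]
            run: List[str] = []
            run_key = None
            subgroups: List[List[str]] = []
            for key, v in keyed:
                if run and key != run_key:
                    subgroups.append(run)
                    run = []
                run.append(v)
                run_key = key
            if run:
                subgroups.append(run)
            if len(subgroups) > 1:
                changed = True
            for sub in subgroups:
                hi = lo + len(sub) - 1
                for v in sub:
                    state.ranges.range[v] = (lo, hi)
                new_groups.append(sorted(sub))
                lo = hi + 1
        # refresh representatives after the full sweep
        for v, (_, hi) in state.ranges.range.items():
            state.temp_order[v] = hi
        groups = new_groups
        if not changed:
            state.converged = True
            break
        if all(len(grp) == 1 for grp in groups):
            state.converged = True
            break
    else:
        state.converged = True  # cap reached; solvers verify downstream
    return state


def is_totally_resolved(state: HeuristicState) -> bool:
    """True iff the converged state assigns every node a singleton range."""
    return state.is_totally_resolved()
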