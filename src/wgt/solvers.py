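"""Recognition solvers: Wheelie-Pr, Wheelie-SMT, pure SMT, and the dispatcher.

The renaming heuristic leaves tie groups -- sets of nodes sharing one rank
interval.  Wheelie-Pr resolves them by exhaustive search over the Cartesian
product of within-group permutations, pruning with the same-label order
condition as soon as a pair of edges has all four endpoints placed.
Wheelie-SMT encodes the residual problem in integer difference logic: with
heuristic ranges the label-order constraints (condition (i)) are implied and
all-different constraints shrink to within-group pairs, which is the entire
benefit of running the heuristic first.  The pure-SMT mode encodes the whole
definition from scratch for comparison.
"""

from __future__ import annotations

import itertools
import time
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .graph import (
    LabeledDigraph,
    NodeOrdering,
    RecognitionResult,
    build_index,
    check_wheeler,
    find_roots,
)
from .renaming import HeuristicState, renaming_heuristic
from .smt import SmtFormula, _empty_pairs, _empty_quads, solve_idl

_SOLVERS = ("pr", "smt", "pure-smt", "brute")


@dataclass
class SolverConfig:
    """Recognition run configuration."""

    solver: str = "smt"
    timeout: float = 30.0
    exhaustive: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.timeout <= 0:
            raise ValueError("timeout must be positive")
        if self.solver not in _SOLVERS:
            raise ValueError(
                f"unknown solver {self.solver!r}; expected one of {', '.join(_SOLVERS)}"
            )


def _heuristic_stats(state: HeuristicState) -> Dict[str, object]:
    groups = state.tie_groups()
    multi = [g for g in groups if len(g) > 1]
    return {
        "heuristic_iterations": state.iteration,
        "tie_group_count": len(multi),
        "largest_tie_group": max((len(g) for g in multi), default=0),
    }


# ---------------------------------------------------------------------------
# Wheelie-Pr: permutations within tie groups
# ---------------------------------------------------------------------------


def wheelie_pr(
    g: LabeledDigraph, state: HeuristicState, cfg: SolverConfig
) -> RecognitionResult:
    """Resolve tie groups by exhaustive permutation search.

    Assignments enumerate the Cartesian product of within-group permutations
    (groups in rank order, permutations in lexicographic order of node
    identifiers); a partial assignment is abandoned as soon as a same-label
    edge pair with all endpoints placed inverts destination order.  With
    ``cfg.exhaustive`` the search always runs to completion and reports the
    first witness found, mirroring a benchmark mode without early stopping.
    """
    if state.conflict is not None:
        return RecognitionResult(
            verdict="not_wheeler", violation=state.conflict, stats=_heuristic_stats(state)
        )
    stats = _heuristic_stats(state)
    stats["solver_backend"] = "wheelie-pr"
    if not g.nodes:
        return RecognitionResult(verdict="wheeler", ordering={}, stats=stats)

    groups = state.ranges.tie_groups()
    rank: Dict[str, int] = {}
    level_of: Dict[str, int] = {}
    multi_groups: List[Tuple[int, List[str]]] = []  # (base rank lo, members)
    for grp in groups:
        lo, _ = state.ranges.range[grp[0]]
        if len(grp) == 1:
            rank[grp[0]] = lo
            level_of[grp[0]] = 0
        else:
            multi_groups.append((lo, grp))
            for v in grp:
                level_of[v] = len(multi_groups)

    # same-label edge pairs bucketed by the decision level completing them
    buckets: List[List[Tuple[str, str, str, str]]] = [
        [] for _ in range(len(multi_groups) + 1)
    ]
    by_label: Dict[str, List[Tuple[str, str]]] = {}
    for u, v, a in g.edges:
        by_label.setdefault(a, []).append((u, v))
    for a in sorted(by_label):
        pairs = by_label[a]
        for x in range(len(pairs)):
            u, v = pairs[x]
            for y in range(x + 1, len(pairs)):
                u2, v2 = pairs[y]
                if u == u2:
                    continue
                lvl = max(level_of[u], level_of[v], level_of[u2], level_of[v2])
                buckets[lvl].append((u, v, u2, v2))

    def violates(u: str, v: str, u2: str, v2: str) -> bool:
        return (rank[u] - rank[u2]) * (rank[v] - rank[v2]) < 0

    for quad in buckets[0]:
        if violates(*quad):
            # the heuristic's own (necessary) constraints are already
            # contradictory: no permutation of the tie groups can help
            return RecognitionResult(
                verdict="not_wheeler",
                violation=(
                    "same-label edges "
                    f"{quad[0]}->{quad[1]} and {quad[2]}->{quad[3]} invert "
                    "destination order for every ordering within heuristic ranges"
                ),
                stats=stats,
            )

    deadline = time.monotonic() + cfg.timeout
    found: List[NodeOrdering] = []
    assignments = 0

    def search(level: int) -> bool:
        """True to stop the whole search (success in early-stop mode)."""
        nonlocal assignments
        if time.monotonic() > deadline:
            raise TimeoutError
        if level == len(multi_groups):
            assignments += 1
            if not found:
                found.append(dict(rank))
            return not cfg.exhaustive
        lo, members = multi_groups[level]
        for perm in itertools.permutations(members):
            for offset, v in enumerate(perm):
                rank[v] = lo + offset
            if all(not violates(*q) for q in buckets[level + 1]):
                if search(level + 1):
                    return True
        for v in multi_groups[level][1]:
            rank.pop(v, None)
        return False

    try:
        search(0)
    except TimeoutError:
        return RecognitionResult(verdict="timeout", stats=stats)

    stats["assignments_tested"] = assignments
    if found:
        ordering = found[0]
        valid, cert = check_wheeler(g, ordering)
        if not valid:
            return RecognitionResult(verdict="not_wheeler", violation=cert, stats=stats)
        return RecognitionResult(verdict="wheeler", ordering=ordering, stats=stats)
    return RecognitionResult(
        verdict="not_wheeler",
        violation="exhausted permutation search without finding a valid ordering",
        stats=stats,
    )


# ---------------------------------------------------------------------------
# SMT encoding
# ---------------------------------------------------------------------------


def encode_smt(
    g: LabeledDigraph, state: Optional[HeuristicState] = None
) -> SmtFormula:
    """Encode Wheeler recognition over ``g`` as a QF_IDL formula.

    Pure mode (``state`` absent): ranges 1..n, a condition-(i) unit clause per
    edge pair with labels a < a', root-before-nonroot unit clauses, a
    condition-(ii) clause per ordered pair of distinct same-label edges, and
    pairwise all-different over all nodes.

    Range mode (``state`` given): per-node ranges from the heuristic;
    condition-(i) and root clauses are implied by the ranges and omitted;
    all-different shrinks to pairs within tie groups.
    """
    nodes = sorted(g.nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)

    by_label: Dict[str, List[Tuple[int, int]]] = {}
    for u, v, a in g.edges:
        by_label.setdefault(a, []).append((idx[u], idx[v]))
    labels = sorted(by_label)

    # condition (ii): ordered pairs of distinct same-label edges
    quads: List[np.ndarray] = []
    for a in labels:
        arr = np.asarray(by_label[a], dtype=np.int64)
        m = len(arr)
        if m < 2:
            continue
        left = np.repeat(np.arange(m), m)
        right = np.tile(np.arange(m), m)
        mask = left != right
        left, right = left[mask], right[mask]
        quads.append(
            np.column_stack(
                [arr[left, 0], arr[right, 0], arr[left, 1], arr[right, 1]]
            )
        )
    cond2 = np.concatenate(quads) if quads else _empty_quads()

    if state is None:
        lo = np.ones(n, dtype=np.int64)
        hi = np.full(n, n, dtype=np.int64)
        # condition (i): one unit clause per edge pair with labels a < a'
        pairs: List[np.ndarray] = []
        dests = {a: np.asarray([v for _, v in by_label[a]], dtype=np.int64) for a in labels}
        for x in range(len(labels)):
            for y in range(x + 1, len(labels)):
                dv = dests[labels[x]]
                dvp = dests[labels[y]]
                pairs.append(
                    np.column_stack(
                        [np.repeat(dv, len(dvp)), np.tile(dvp, len(dv))]
                    )
                )
        cond1 = np.concatenate(pairs) if pairs else _empty_pairs()
        roots = find_roots(g)
        root_idx = np.asarray([idx[v] for v in roots], dtype=np.int64)
        nonroot_idx = np.asarray(
            [idx[v] for v in nodes if v not in set(roots)], dtype=np.int64
        )
        if len(root_idx) and len(nonroot_idx):
            root_pairs = np.column_stack(
                [
                    np.repeat(root_idx, len(nonroot_idx)),
                    np.tile(nonroot_idx, len(root_idx)),
                ]
            )
        else:
            root_pairs = _empty_pairs()
        if n >= 2:
            ii, jj = np.triu_indices(n, k=1)
            alldiff = np.column_stack([ii, jj])
        else:
            alldiff = _empty_pairs()
        return SmtFormula(
            nodes=nodes, lo=lo, hi=hi, cond1=cond1, roots=root_pairs,
            cond2=cond2, alldiff=alldiff, mode="pure",
        )

    if state.conflict is not None:
        raise ValueError("cannot encode a graph with a label conflict")
    lo = np.empty(n, dtype=np.int64)
    hi = np.empty(n, dtype=np.int64)
    for v, (a, b) in state.ranges.range.items():
        lo[idx[v]] = a
        hi[idx[v]] = b
    ad: List[np.ndarray] = []
    for grp in state.ranges.tie_groups():
        if len(grp) < 2:
            continue
        gi = np.asarray(sorted(idx[v] for v in grp), dtype=np.int64)
        ii, jj = np.triu_indices(len(gi), k=1)
        ad.append(np.column_stack([gi[ii], gi[jj]]))
    alldiff = np.concatenate(ad) if ad else _empty_pairs()
    return SmtFormula(
        nodes=nodes, lo=lo, hi=hi, cond1=_empty_pairs(), roots=_empty_pairs(),
        cond2=cond2, alldiff=alldiff, mode="range",
    )


def solve_smt(
    formula: SmtFormula, cfg: SolverConfig
) -> Tuple[Optional[bool], Optional[NodeOrdering]]:
    """Decide a formula with the built-in IDL engine.

    Returns ``(True, model)`` on sat, ``(False, None)`` on unsat, and
    ``(None, None)`` when the timeout expires ("unknown").
    """
    status, model = solve_idl(formula, timeout=cfg.timeout)
    if status == "sat":
        return True, model
    if status == "unsat":
        return False, None
    return None, None


# ---------------------------------------------------------------------------
# Top-level recognizers
# ---------------------------------------------------------------------------


def _smt_result(
    g: LabeledDigraph,
    cfg: SolverConfig,
    state: Optional[HeuristicState],
    backend: str,
    stats: Dict[str, object],
) -> RecognitionResult:
    formula = encode_smt(g, state)
    stats["solver_backend"] = backend
    stats.update(formula.metadata)
    sat, model = solve_smt(formula, cfg)
    if sat is None:
        return RecognitionResult(verdict="timeout", stats=stats)
    if not sat:
        return RecognitionResult(
            verdict="not_wheeler",
            violation="difference-logic formula is unsatisfiable",
            stats=stats,
        )
    valid, cert = check_wheeler(g, model)
    if not valid:  # the encoding is complete; a bad model is an internal error
        raise RuntimeError(f"SMT model failed verification: {cert}")
    return RecognitionResult(verdict="wheeler", ordering=model, stats=stats)


def wheelie_smt(g: LabeledDigraph, cfg: SolverConfig) -> RecognitionResult:
    """Renaming heuristic plus difference-logic solving (the default mode)."""
    state = renaming_heuristic(g)
    stats = _heuristic_stats(state)
    if state.conflict is not None:
        return RecognitionResult(
            verdict="not_wheeler", violation=state.conflict, stats=stats
        )
    if state.is_totally_resolved():
        ordering = state.induced_ordering()
        stats["solver_backend"] = "heuristic-only"
        valid, cert = check_wheeler(g, ordering)
        if valid:
            return RecognitionResult(verdict="wheeler", ordering=ordering, stats=stats)
        # every heuristic constraint is necessary, so the unique consistent
        # ordering failing the check proves the graph non-Wheeler
        return RecognitionResult(verdict="not_wheeler", violation=cert, stats=stats)
    return _smt_result(g, cfg, state, "wheelie-smt", stats)


def pure_smt(g: LabeledDigraph, cfg: SolverConfig) -> RecognitionResult:
    """Encode the full definition from scratch, without heuristic ranges."""
    return _smt_result(g, cfg, None, "pure-smt", {})


def recognize(g: LabeledDigraph, cfg: Optional[SolverConfig] = None) -> RecognitionResult:
    """Dispatch on ``cfg.solver`` and attach the O/I/L index on success."""
    from .oracle import brute_force_recognize  # local import: oracle uses graph only

    cfg = cfg or SolverConfig()
    if cfg.solver == "pr":
        state = renaming_heuristic(g)
        result = wheelie_pr(g, state, cfg)
    elif cfg.solver == "smt":
        result = wheelie_smt(g, cfg)
    elif cfg.solver == "pure-smt":
        result = pure_smt(g, cfg)
    elif cfg.solver == "brute":
        result = brute_force_recognize(g)
    else:  # unreachable: SolverConfig validates
        raise ValueError(f"unknown solver {cfg.solver!r}")
    if result.verdict == "wheeler" and result.ordering is not None:
        result.index = build_index(g, result.ordering)
    return result
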