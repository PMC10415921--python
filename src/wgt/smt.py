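"""Integer difference logic (QF_IDL) formulas and a decision procedure.

The Wheeler recognition constraints are encoded with one integer variable per
node plus a designated zero variable; every atom has the form
``x_i - x_j <= c`` (strict inequalities become ``<= -1``).  Satisfiability of
a conjunction of such atoms reduces to the absence of a negative cycle in a
weighted digraph (an edge j -> i of weight c per atom), which is decided here
with all-pairs shortest paths.  Disjunctive clauses are handled by a DPLL
search on top of that theory core:

* the shortest-path closure D entails atom (i, j, c) iff D[j, i] <= c and
  refutes it iff D[i, j] <= -c - 1, which evaluates whole clause families at
  once (vectorized);
* implied unit literals are asserted as new graph edges and the closure is
  maintained incrementally;
* when propagation reaches a fixpoint with undecided clauses, the search
  branches on the first undecided literal and backtracks chronologically.

Models are read off the shortest-path distances from the zero variable.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from typing import Dict, Iterator, List, Optional, Tuple

import numpy as np
from scipy.sparse.csgraph import (
    NegativeCycleError,
    csgraph_from_dense,
    floyd_warshall,
)

from .graph import NodeOrdering

_INF = np.inf


@dataclass
class SmtFormula:
    """A QF_IDL formula over one variable per node (plus an implicit zero).

    Clause families are stored as integer index arrays rather than an explicit
    clause list; ``iter_clauses`` materializes them in a fixed order.  All
    constraints below use variable indices into ``nodes``.

    * ``lo``/``hi``: per-node range, lo_i <= x_i <= hi_i (two atoms, counted
      as one range clause).
    * ``cond1``: rows (v, v') -> unit clause x_v - x_v' <= -1 (label-order
      constraint; one row per edge pair with labels a < a').
    * ``roots``: rows (root, w) -> unit clause x_root - x_w <= -1 (0-indegree
      nodes precede positive-indegree nodes; pure mode only).
    * ``cond2``: rows (u, u', v, v') -> clause
      NOT(x_u - x_u' <= -1) OR (x_v - x_v' <= 0), one row per ordered pair of
      distinct same-label edges (u,v), (u',v').
    * ``alldiff``: rows (i, j) -> clause (x_i - x_j <= -1) OR (x_j - x_i <= -1).
    """

    nodes: List[str]
    lo: np.ndarray
    hi: np.ndarray
    cond1: np.ndarray  # (m1, 2) int
    roots: np.ndarray  # (m0, 2) int
    cond2: np.ndarray  # (m2, 4) int
    alldiff: np.ndarray  # (m3, 2) int
    mode: str = "pure"  # "pure" | "range"

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def metadata(self) -> Dict[str, int]:
        return {
            "range_clauses": self.n,
            "condition_i_clauses": int(len(self.cond1)),
            "root_clauses": int(len(self.roots)),
            "condition_ii_clauses": int(len(self.cond2)),
            "alldiff_clauses": int(len(self.alldiff)),
        }

    @property
    def num_clauses(self) -> int:
        return sum(self.metadata.values())

    # -- SMT-LIB 2 export ---------------------------------------------------

    def _var(self, i: int) -> str:
        return f"x{i}"

    def iter_clauses(self) -> Iterator[str]:
        """Clauses as SMT-LIB 2 assertion bodies, in family order."""

        def le(i: int, j: int, c: int) -> str:
            return f"(<= (- {self._var(i)} {self._var(j)}) {c})"

        zero = "x_zero"
        for i in range(self.n):
            yield (
                f"(and (<= (- {zero} {self._var(i)}) {-int(self.lo[i])}) "
                f"(<= (- {self._var(i)} {zero}) {int(self.hi[i])}))"
            )
        for v, vp in self.cond1:
            yield le(int(v), int(vp), -1)
        for rt, w in self.roots:
            yield le(int(rt), int(w), -1)
        for u, up, v, vp in self.cond2:
            yield f"(or (not {le(int(u), int(up), -1)}) {le(int(v), int(vp), 0)})"
        for i, j in self.alldiff:
            yield f"(or {le(int(i), int(j), -1)} {le(int(j), int(i), -1)})"

    def to_smt2(self) -> str:
        out = ["(set-logic QF_IDL)", "(declare-fun x_zero () Int)"]
        out += [f"(declare-fun {self._var(i)} () Int)" for i in range(self.n)]
        out += [f"(assert {c})" for c in self.iter_clauses()]
        out += ["(check-sat)", "(get-model)"]
        return "\n".join(out) + "\n"


def _empty_pairs() -> np.ndarray:
    return np.empty((0, 2), dtype=np.int64)


def _empty_quads() -> np.ndarray:
    return np.empty((0, 4), dtype=np.int64)


# ---------------------------------------------------------------------------
# DPLL(IDL) engine
# ---------------------------------------------------------------------------


class _Timeout(Exception):
    pass


class _IdlSolver:
    """Chronological-backtracking DPLL over the difference-constraint core.

    W is the dense edge-weight matrix (W[j, i] = c for atom x_i - x_j <= c);
    D its shortest-path closure.  Assertions are trailed so the matrix can be
    rewound on backtrack; D is then recomputed from W.
    """

    # full closure recompute beats per-edge incremental updates beyond this
    _BATCH_FULL = 64

    def __init__(self, f: SmtFormula, deadline: Optional[float]):
        self.f = f
        self.deadline = deadline
        n = f.n
        self.zero = n
        W = np.full((n + 1, n + 1), _INF)
        W[self.zero, np.arange(n)] = f.hi  # x_i - zero <= hi_i
        W[np.arange(n), self.zero] = -f.lo  # zero - x_i <= -lo_i
        if len(f.cond1):
            W[f.cond1[:, 1], f.cond1[:, 0]] = np.minimum(
                W[f.cond1[:, 1], f.cond1[:, 0]], -1
            )
        if len(f.roots):
            W[f.roots[:, 1], f.roots[:, 0]] = np.minimum(
                W[f.roots[:, 1], f.roots[:, 0]], -1
            )
        self.W = W
        self.D: Optional[np.ndarray] = None
        self.trail: List[Tuple[int, int, float]] = []
        # undecided clause views (compacted after root-level propagation)
        self.cond2 = f.cond2
        self.alldiff = f.alldiff

    def _check_time(self) -> None:
        if self.deadline is not None and time.monotonic() > self.deadline:
            raise _Timeout

    def _full_closure(self) -> bool:
        """Recompute D from W; False on negative cycle."""
        self._check_time()
        if np.diag(self.W).min() < 0:  # negative self-loop, e.g. v - v <= -1
            self.D = None
            return False
        try:
            self.D = floyd_warshall(
                csgraph_from_dense(self.W, null_value=_INF), directed=True
            )
        except NegativeCycleError:
            self.D = None
            return False
        return True

    def _assert_edge(self, j: int, i: int, c: float) -> None:
        """Record atom x_i - x_j <= c (edge j -> i, weight c) on the trail."""
        if c < self.W[j, i]:
            self.trail.append((j, i, self.W[j, i]))
            self.W[j, i] = c

    def _apply_edges(self, edges: List[Tuple[int, int, float]]) -> bool:
        """Assert a batch and maintain D; False on inconsistency."""
        new = [(j, i, c) for (j, i, c) in edges if c < self.W[j, i]]
        for j, i, c in new:
            self._assert_edge(j, i, c)
        if not new:
            return True
        if self.D is None or len(new) > self._BATCH_FULL:
            return self._full_closure()
        D = self.D
        for j, i, c in new:
            # relax every pair through the new edge j -> i
            cand = np.add.outer(D[:, j] + c, D[i, :])
            np.minimum(D, cand, out=D)
        if np.diag(D).min() < 0:
            return False
        return True

    # -- clause evaluation (vectorized) -------------------------------------

    def _eval(self):
        """Classify cond2/alldiff clauses against D.

        Returns (conflict, implied_edges, undecided2, undecidedA) where the
        undecided arrays index into self.cond2 / self.alldiff.
        """
        D = self.D
        implied: List[Tuple[int, int, float]] = []
        conflict = False

        c2 = self.cond2
        if len(c2):
            u, up, v, vp = c2[:, 0], c2[:, 1], c2[:, 2], c2[:, 3]
            a_true = D[up, u] <= -1  # u < u' entailed
            a_false = D[u, up] <= 0  # u >= u' entailed
            c_true = D[vp, v] <= 0  # v <= v' entailed
            c_false = D[v, vp] <= -1  # v > v' entailed
            sat = a_false | c_true
            if np.any(a_true & c_false & ~sat):
                conflict = True
            unit_c = a_true & ~c_true & ~c_false & ~sat  # assert v <= v'
            unit_a = c_false & ~a_true & ~a_false & ~sat  # assert u >= u'
            for k in np.nonzero(unit_c)[0]:
                implied.append((int(vp[k]), int(v[k]), 0.0))
            for k in np.nonzero(unit_a)[0]:
                implied.append((int(u[k]), int(up[k]), 0.0))
            und2 = np.nonzero(~sat & ~a_true & ~a_false & ~c_true & ~c_false)[0]
        else:
            und2 = np.empty(0, dtype=np.int64)

        ad = self.alldiff
        if len(ad):
            i, j = ad[:, 0], ad[:, 1]
            l1_true = D[j, i] <= -1
            l1_false = D[i, j] <= 0
            l2_true = D[i, j] <= -1
            l2_false = D[j, i] <= 0
            sat = l1_true | l2_true
            if np.any(l1_false & l2_false & ~sat):
                conflict = True
            unit1 = l2_false & ~l1_true & ~l1_false & ~sat
            unit2 = l1_false & ~l2_true & ~l2_false & ~sat
            for k in np.nonzero(unit1)[0]:
                implied.append((int(j[k]), int(i[k]), -1.0))
            for k in np.nonzero(unit2)[0]:
                implied.append((int(i[k]), int(j[k]), -1.0))
            undA = np.nonzero(~sat & ~(l1_true | l1_false) & ~(l2_true | l2_false))[0]
        else:
            undA = np.empty(0, dtype=np.int64)
        return conflict, implied, und2, undA

    def _propagate(self):
        """Run unit/theory propagation to fixpoint.

        Returns (ok, und2, undA); ok False on conflict.
        """
        while True:
            self._check_time()
            if self.D is None and not self._full_closure():
                return False, None, None
            conflict, implied, und2, undA = self._eval()
            if conflict:
                return False, None, None
            if not implied:
                return True, und2, undA
            if not self._apply_edges(implied):
                return False, None, None

    def solve(self) -> Tuple[str, Optional[np.ndarray]]:
        """Returns ("sat", model-values), ("unsat", None) or ("unknown", None)."""
        try:
            if not self._full_closure():
                return "unsat", None
            ok, und2, undA = self._propagate()
            if not ok:
                return "unsat", None
            # root-level statuses are permanent: drop decided clauses
            self.cond2 = self.cond2[und2]
            self.alldiff = self.alldiff[undA]
            und2 = np.arange(len(self.cond2))
            undA = np.arange(len(self.alldiff))

            # decisions: (trail_mark, branch_edges_remaining)
            stack: List[Tuple[int, List[Tuple[int, int, float]]]] = []
            while True:
                self._check_time()
                if ok:
                    if len(und2) == 0 and len(undA) == 0:
                        return "sat", self._model()
                    lit, neg = self._pick(und2, undA)
                    stack.append((len(self.trail), [neg]))
                    ok = self._apply_edges([lit])
                    if ok:
                        ok, und2, undA = self._propagate()
                else:
                    # conflict: rewind to the most recent decision with an
                    # untried branch
                    while stack and not stack[-1][1]:
                        mark, _ = stack.pop()
                        self._rewind(mark)
                    if not stack:
                        return "unsat", None
                    mark, alts = stack[-1]
                    self._rewind(mark)
                    lit = alts.pop()
                    ok = self._apply_edges([lit])
                    if ok:
                        ok, und2, undA = self._propagate()
        except _Timeout:
            return "unknown", None

    def _pick(self, und2, undA):
        """Deterministic branch literal: first undecided alldiff, else cond2."""
        if len(undA):
            i, j = self.alldiff[undA[0]]
            return (int(j), int(i), -1.0), (int(i), int(j), -1.0)
        u, up, v, vp = self.cond2[und2[0]]
        # branch on the antecedent atom u < u'; negation is u >= u'
        return (int(up), int(u), -1.0), (int(u), int(up), 0.0)

    def _rewind(self, mark: int) -> None:
        while len(self.trail) > mark:
            j, i, old = self.trail.pop()
            self.W[j, i] = old
        self.D = None  # stale; recomputed lazily

    def _model(self) -> np.ndarray:
        if self.D is None:
            self._full_closure()
        vals = self.D[self.zero, : self.f.n]
        return np.asarray(np.round(vals), dtype=np.int64)


def solve_idl(
    formula: SmtFormula, timeout: Optional[float] = None
) -> Tuple[str, Optional[NodeOrdering]]:
    """Decide a formula; on sat, decode the model into a node -> rank map."""
    if formula.n == 0:
        return "sat", {}
    deadline = None if timeout is None else time.monotonic() + timeout
    status, vals = _IdlSolver(formula, deadline).solve()
    if status != "sat":
        return status, None
    model = {node: int(vals[i]) for i, node in enumerate(formula.nodes)}
    return "sat", model
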