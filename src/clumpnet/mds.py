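"""Exact minimum dominating sets and control-node classification.

A dominating set covers every vertex through its closed neighborhood; the
minimum dominating set (MDS) is found exactly with a binary integer program
(minimize sum x_v subject to x_v + sum_{u in N(v)} x_u >= 1). Alternative
optima are enumerated by adding no-good cuts and re-solving while the
objective stays optimal. Vertices in every optimum are *critical* control
nodes; vertices in at least one but not all optima are *intermittent*.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .io import Graph, ValidationError


@dataclass(frozen=True)
class ControlSet:
    """Enumerated optimal MDSs and the derived control-node classes."""

    solutions: tuple          # tuple of frozensets, each an optimal MDS
    mds_size: int
    critical: frozenset       # in every enumerated optimum
    intermittent: frozenset   # in at least one, but not all

    @classmethod
    def from_solutions(cls, solutions) -> "ControlSet":
        sols = tuple(frozenset(s) for s in solutions)
        if not sols:
            raise ValidationError("no solutions to classify")
        sizes = {len(s) for s in sols}
        if len(sizes) != 1:
            raise ValidationError("solutions have differing sizes")
        critical = frozenset.intersection(*sols)
        union = frozenset.union(*sols)
        return cls(sols, sizes.pop(), critical, union - critical)

    @property
    def control_nodes(self) -> frozenset:
        return self.critical | self.intermittent


def _closed_neighborhood(g: Graph):
    verts, adj = g.adjacency()
    a = adj.astype(np.float64)
    np.fill_diagonal(a, 1.0)
    return verts, a


def is_dominating(g: Graph, s) -> bool:
    """True when every vertex is in ``s`` or adjacent to a member of ``s``."""
    s = set(s)
    return all(v in s or g.neighbors(v) & s for v in g.vertices)


def _solve(c: np.ndarray, constraints) -> np.ndarray | None:
    res = milp(c=c, constraints=constraints, integrality=np.ones_like(c),
               bounds=Bounds(0, 1))
    if res.status == 2:  # infeasible (only reachable with no-good cuts)
        return None
    if not res.success:
        raise RuntimeError(f"MILP solver failed: status={res.status} {res.message}")
    return np.round(res.x).astype(int)


def mds_ilp(g: Graph):
    """One exact minimum dominating set of ``g`` (set of vertex names)."""
    if g.n_vertices == 0:
        raise ValidationError("graph is empty")
    verts, a = _closed_neighborhood(g)
    n = len(verts)
    x = _solve(np.ones(n), [LinearConstraint(sparse.csr_matrix(a), lb=np.ones(n))])
    return {verts[i] for i in np.flatnonzero(x)}


def enumerate_optimal_mds(g: Graph, n_solutions: int = 15) -> ControlSet:
    """Enumerate up to ``n_solutions`` distinct optimal MDSs.

    After each optimum S, the no-good cut ``sum_{v in S} x_v <= |S| - 1``
    is added and the program re-solved; enumeration stops when the
    objective exceeds the optimum, the cuts make the program infeasible
    (all optima found), or the requested number of solutions is reached.
    """
    if n_solutions < 1:
        raise ValidationError("n_solutions must be >= 1")
    verts, a = _closed_neighborhood(g)
    n = len(verts)
    base = [LinearConstraint(sparse.csr_matrix(a), lb=np.ones(n))]
    cuts: list = []
    solutions = []
    best = None
    while len(solutions) < n_solutions:
        x = _solve(np.ones(n), base + cuts)
        if x is None:
            break
        size = int(x.sum())
        if best is None:
            best = size
        elif size > best:
            break
        solutions.append(frozenset(verts[i] for i in np.flatnonzero(x)))
        cuts.append(LinearConstraint(x.astype(float), ub=size - 1))
    return ControlSet.from_solutions(solutions)


def brute_force_mds(g: Graph):
    """Exhaustive MDS search (test oracle): minimal size and ALL optima.

    Refuses graphs with more than 20 vertices.
    """
    n = g.n_vertices
    if n == 0:
        raise ValidationError("graph is empty")
    if n > 20:
        raise ValidationError("brute force limited to 20 vertices")
    verts, adj = g.adjacency()
    closed = []
    for i in range(n):
        mask = 1 << i
        for j in np.flatnonzero(adj[i]):
            mask |= 1 << int(j)
        closed.append(mask)
    full = (1 << n) - 1
    for size in range(1, n + 1):
        optima = []
        for combo in combinations(range(n), size):
            cover = 0
            for i in combo:
                cover |= closed[i]
            if cover == full:
                optima.append(frozenset(verts[i] for i in combo))
        if optima:
            return size, optima
    raise AssertionError("unreachable: the full vertex set always dominates")
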