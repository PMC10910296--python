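"""Certified exact solvers for the p-median objective on small instances.

Two independent routes:

* :func:`solve_exact` enumerates every K-subset of cells and is therefore
  correct by construction — the test oracle for the metaheuristic.  Guarded
  by a subset-count limit (default 2,000,000): above it the caller should
  shrink the instance, not the oracle approximate.
* :func:`solve_ilp` solves the integer linear program — minimise
  sum_ij x_ij D(i, j) subject to each cell assigned to exactly one open
  centroid (sum_j x_ij = 1, x_ij <= y_j), exactly K centroids open
  (sum_j y_j = K), all indicators binary — through scipy's HiGHS MILP
  backend.  It must agree with the enumeration wherever both run.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import scipy.sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .distance import _BaseDistance
from .errors import ConfigError, OracleScaleError
from .vns import evaluate

__all__ = ["ExactResult", "solve_exact", "solve_ilp", "DEFAULT_SUBSET_LIMIT"]

DEFAULT_SUBSET_LIMIT = 2_000_000


@dataclass
class ExactResult:
    """Optimal centroid set, its objective, and how many candidates were seen."""

    best_Y: np.ndarray
    best_F: float
    n_evaluated: int


def solve_exact(
    D: _BaseDistance, k: int, limit: int = DEFAULT_SUBSET_LIMIT
) -> ExactResult:
    """Exhaustive minimisation of F over all C(n, K) centroid subsets.

    Ties resolve to the lexicographically smallest subset (combinations are
    enumerated in lexicographic order and kept only on strict improvement).
    """
    n = D.n
    if not 1 <= k <= n:
        raise ConfigError(f"need 1 <= K <= n, got K={k}, n={n}")
    n_subsets = math.comb(n, k)
    if n_subsets > limit:
        raise OracleScaleError(
            f"C({n}, {k}) = {n_subsets} exceeds the enumeration limit {limit}"
        )
    # full matrix once: every subset objective is a column-slice min-sum
    full = D.columns(np.arange(n))
    best_Y: np.ndarray | None = None
    best_F = math.inf
    for comb in itertools.combinations(range(n), k):
        F = full[:, comb].min(axis=1).sum()
        if F < best_F:
            best_F = float(F)
            best_Y = np.asarray(comb, dtype=int)
    assert best_Y is not None
    return ExactResult(best_Y=best_Y, best_F=best_F, n_evaluated=n_subsets)


def solve_ilp(D: _BaseDistance, k: int) -> ExactResult:
    """Integer-programming route to the same optimum (HiGHS via scipy).

    Variables are y_j (centroid open) and x_ij (cell i served by j).
    Suitable only for small instances: n^2 + n binaries.
    """
    n = D.n
    if not 1 <= k <= n:
        raise ConfigError(f"need 1 <= K <= n, got K={k}, n={n}")
    full = np.asarray(D.columns(np.arange(n)), dtype=float)

    # variable layout: [y_0..y_{n-1}, x_00, x_01, ..., x_{n-1,n-1}]
    n_y = n
    n_x = n * n
    c = np.concatenate([np.zeros(n_y), full.ravel()])

    rows, cols, vals = [], [], []
    lb, ub = [], []
    r = 0
    for i in range(n):  # each cell in exactly one cluster
        for j in range(n):
            rows.append(r)
            cols.append(n_y + i * n + j)
            vals.append(1.0)
        lb.append(1.0)
        ub.append(1.0)
        r += 1
    for i in range(n):  # x_ij <= y_j
        for j in range(n):
            rows.append(r)
            cols.append(n_y + i * n + j)
            vals.append(1.0)
            rows.append(r)
            cols.append(j)
            vals.append(-1.0)
            lb.append(-math.inf)
            ub.append(0.0)
            r += 1
    for j in range(n):  # exactly K open centroids
        rows.append(r)
        cols.append(j)
        vals.append(1.0)
    lb.append(float(k))
    ub.append(float(k))
    r += 1

    A = scipy.sparse.csr_matrix((vals, (rows, cols)), shape=(r, n_y + n_x))
    res = milp(
        c=c,
        constraints=LinearConstraint(A, lb, ub),
        integrality=np.ones(n_y + n_x),
        bounds=Bounds(0.0, 1.0),
    )
    if res is None or not res.success:  # pragma: no cover - solver failure
        raise RuntimeError(f"MILP solver failed: {getattr(res, 'message', 'no result')}")
    y = np.flatnonzero(np.round(res.x[:n_y]) == 1)
    sol = evaluate(y, D)
    return ExactResult(best_Y=np.sort(y), best_F=sol.F, n_evaluated=0)
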