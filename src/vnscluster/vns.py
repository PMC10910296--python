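"""Variable neighborhood search for the p-median cell clustering problem.

The solution vector ``Y`` holds K distinct cell indices chosen as cluster
representatives (medoids, called *centroids* here: representative cells, not
mean points).  The derived assignment ``X`` maps every cell to its nearest
centroid under the blended distance D, and the objective

    F(Y) = sum_i D(i, X[i])

is the total distance of all cells to their representatives.  VNS escapes
local minima by *shaking* the incumbent — replacing k of the K centroids with
random outside cells — and re-descending with a randomized first-improvement
local search; k sweeps k_min..k_max (step k_step), resetting to k_min on every
improvement and wrapping around at k_max.

One iteration = one shake + local-search cycle; the run stops after
``max_iter`` iterations and returns the best solution found together with the
trace of incumbent objective values (non-increasing by construction).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .distance import _BaseDistance
from .errors import ConfigError, ShakeError, SolutionError

__all__ = [
    "VNSConfig",
    "CentroidSolution",
    "assign",
    "objective",
    "initial_solution",
    "shake",
    "local_search",
    "neighbor_order",
    "vns_run",
]


@dataclass(frozen=True)
class VNSConfig:
    """All solver tunables.

    Parameters
    ----------
    k : int
        Number of clusters K (1 <= K <= n).
    alpha : float in [0, 1]
        Weight of the embedding (cosine) term in the blended distance.
    k_min, k_max, k_step : int
        Shake-neighborhood schedule; k_min and k_step default to 1, k_max
        defaults to min(10, K) when left as None.  k_max may not exceed K.
    max_iter : int
        Number of shake + local-search iterations.
    m : int
        Local-search breadth: per centroid, a candidate-list size is drawn
        uniformly from {0..m} (1 is redrawn); 0 keeps the centroid.
    p : int
        Local-search persistence: maximum number of full passes without
        improvement before giving up.
    seed : int
        Base seed; run r of a batch uses seed + r.
    n_runs : int
        Batch size for multi-seed statistics.
    """

    k: int
    alpha: float = 1.0
    k_min: int = 1
    k_max: Optional[int] = None
    k_step: int = 1
    max_iter: int = 500
    m: int = 10
    p: int = 10
    seed: int = 0
    n_runs: int = 20
    normalize_coords: bool = False

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ConfigError(f"k must be >= 1, got {self.k}")
        if not 0.0 <= self.alpha <= 1.0:
            raise ConfigError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.k_min < 1 or self.k_step < 1:
            raise ConfigError("k_min and k_step must be >= 1")
        if self.k_max is not None:
            if self.k_max < self.k_min:
                raise ConfigError("k_max must be >= k_min")
            if self.k_max > self.k:
                raise ConfigError("k_max cannot exceed the number of centroids K")
        if self.max_iter < 0:
            raise ConfigError("max_iter must be >= 0")
        if self.m < 0:
            raise ConfigError("m must be >= 0")
        if self.p < 1:
            raise ConfigError("p must be >= 1")
        if self.n_runs < 1:
            raise ConfigError("n_runs must be >= 1")

    def resolved_k_max(self) -> int:
        return min(10, self.k) if self.k_max is None else self.k_max

    def validate_against(self, n: int) -> None:
        if self.k > n:
            raise ConfigError(f"K={self.k} exceeds the number of cells n={n}")
        if self.resolved_k_max() < self.k_min:
            raise ConfigError("resolved k_max < k_min")


@dataclass
class CentroidSolution:
    """A feasible solution: centroid indices Y, assignment X, objective F.

    Invariants: Y has K distinct entries in [0, n); X[i] is the element of Y
    nearest to cell i (ties to the lowest centroid index); X[y] = y for every
    centroid; F = sum_i D(i, X[i]) >= 0.
    """

    Y: np.ndarray
    X: np.ndarray
    F: float

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=int)
        self.X = np.asarray(self.X, dtype=int)

    @property
    def k(self) -> int:
        return self.Y.size

    def check(self, D: _BaseDistance) -> None:
        """Structural feasibility: the ILP constraints in assignment form.

        Every cell is assigned to exactly one centroid (X is a total map),
        assignments point only at chosen centroids (X[i] in Y), exactly K
        distinct centroids are open, and each centroid represents itself.
        """
        n = D.n
        if np.unique(self.Y).size != self.k:
            raise SolutionError("duplicate centroid indices")
        if self.Y.min() < 0 or self.Y.max() >= n:
            raise SolutionError("centroid index out of range")
        if self.X.shape != (n,):
            raise SolutionError("assignment X must cover every cell exactly once")
        yset = set(self.Y.tolist())
        if not set(self.X.tolist()) <= yset:
            raise SolutionError("assignment to a non-centroid cell")
        if any(self.X[y] != y for y in self.Y):
            raise SolutionError("a centroid is not assigned to itself")
        Ys = np.sort(self.Y)
        cols = D.columns(Ys)
        best = cols.min(axis=1)
        got = cols[np.arange(n), np.searchsorted(Ys, self.X)]
        if not np.allclose(got, best, rtol=0.0, atol=1e-9):
            raise SolutionError("X does not map every cell to its nearest centroid")


def _validate_Y(Y: np.ndarray, n: int) -> np.ndarray:
    Y = np.asarray(Y, dtype=int)
    if Y.ndim != 1 or Y.size < 1:
        raise SolutionError("Y must be a nonempty 1-D index vector")
    if np.unique(Y).size != Y.size:
        raise SolutionError("duplicate entries in Y")
    if Y.min() < 0 or Y.max() >= n:
        raise SolutionError("centroid index out of range")
    return Y


def assign(Y: Sequence[int], D: _BaseDistance) -> np.ndarray:
    """Nearest-centroid assignment X for centroid vector Y.

    ``X[i]`` is the centroid (cell index) minimising D(i, y) over y in Y;
    ties break to the lowest centroid index.  Deterministic.
    """
    Y = _validate_Y(np.asarray(Y), D.n)
    Ys = np.sort(Y)
    cols = D.columns(Ys)
    return Ys[np.argmin(cols, axis=1)]  # argmin takes first min -> lowest index


def objective(Y: Sequence[int], D: _BaseDistance) -> float:
    """F(Y) = total distance of every cell to its nearest centroid."""
    Y = _validate_Y(np.asarray(Y), D.n)
    return float(D.columns(Y).min(axis=1).sum())


def evaluate(Y: Sequence[int], D: _BaseDistance) -> CentroidSolution:
    """Bundle Y with its derived assignment and objective."""
    Y = _validate_Y(np.asarray(Y), D.n)
    Ys = np.sort(Y)
    cols = D.columns(Ys)
    pos = np.argmin(cols, axis=1)
    return CentroidSolution(
        Y=Y, X=Ys[pos], F=float(cols[np.arange(D.n), pos].sum())
    )


def initial_solution(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Uniformly sampled K-subset of {0..n-1}, as a vector."""
    if not 1 <= k <= n:
        raise ConfigError(f"need 1 <= K <= n, got K={k}, n={n}")
    return rng.choice(n, size=k, replace=False)


def shake(
    Y: Sequence[int], k: int, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Replace k randomly chosen centroids with k random outside cells.

    The entrants are drawn without replacement from {0..n-1} \\ Y, so the
    result again has K mutually distinct entries and shares exactly K - k of
    them with Y.
    """
    Y = _validate_Y(np.asarray(Y), n)
    K = Y.size
    if not 1 <= k <= K:
        raise ShakeError(f"need 1 <= k <= K, got k={k}, K={K}")
    if n - K < k:
        raise ShakeError(
            f"replacement pool has {n - K} cells, cannot draw {k} entrants"
        )
    pool = np.setdiff1d(np.arange(n), Y, assume_unique=False)
    entrants = rng.choice(pool, size=k, replace=False)
    positions = rng.choice(K, size=k, replace=False)
    out = Y.copy()
    out[positions] = entrants
    return out


def neighbor_order(D: _BaseDistance) -> np.ndarray:
    """Per-cell candidate order: cells sorted by (distance, index).

    Row i lists all n cells from nearest to farthest from cell i; cell i
    itself sits first at distance 0.  Precomputed once per dataset since D is
    fixed for the whole search.
    """
    n = D.n
    order = np.empty((n, n), dtype=int)
    for i in range(n):
        # stable sort on distance keeps ties in ascending index order
        order[i] = np.argsort(D.row(i), kind="stable")
    return order


def local_search(
    Y_prime: Sequence[int],
    D: _BaseDistance,
    m: int,
    p: int,
    F_star: float,
    rng: np.random.Generator,
    nn_order: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Randomized first-improvement descent around Y'.

    Each pass walks the positions of Y' in order.  For each centroid it draws
    ``ind`` uniformly from {0..m}, redrawing while ind == 1 (a candidate list
    of size 1 would contain only the centroid itself, at distance 0).  With
    ind == 0 the centroid is kept; with ind >= 2 the ``ind`` cells nearest to
    the current centroid form the candidate list, cells already in the working
    vector are removed, and one survivor is chosen uniformly at random — or,
    if none survive, a uniform random cell outside the working vector.  A pass
    yields Y''; if F(Y'') < F_star the pass's result is returned immediately
    (first improvement).  Otherwise the pass restarts from Y', at most p
    times; with no improvement after p passes, Y' is returned unchanged.
    """
    n = D.n
    Y_prime = _validate_Y(np.asarray(Y_prime), n)
    if m < 0:
        raise ConfigError("m must be >= 0")
    if p < 1:
        raise ConfigError("p must be >= 1")
    if m == 0:
        return Y_prime  # ind is always 0: every pass reproduces Y'
    if nn_order is None:
        nn_order = neighbor_order(D)
    K = Y_prime.size
    all_cells = np.arange(n)
    for _ in range(p):
        work = Y_prime.copy()
        members = set(work.tolist())
        for pos in range(K):
            ind = int(rng.integers(0, m + 1))
            while ind == 1:
                ind = int(rng.integers(0, m + 1))
            if ind == 0:
                continue
            cur = work[pos]
            cand = [c for c in nn_order[cur, :ind] if c not in members]
            if cand:
                new = int(cand[rng.integers(len(cand))])
            else:
                pool = np.setdiff1d(all_cells, work)
                new = int(pool[rng.integers(pool.size)])
            members.discard(int(cur))
            members.add(new)
            work[pos] = new
        if objective(work, D) < F_star:
            return work
    return Y_prime


@dataclass
class VNSTrace:
    """Per-iteration record of the search: k used and incumbent F after."""

    iterations: List[int] = field(default_factory=list)
    k_values: List[int] = field(default_factory=list)
    F_star: List[float] = field(default_factory=list)

    def append(self, iteration: int, k: int, F: float) -> None:
        self.iterations.append(iteration)
        self.k_values.append(k)
        self.F_star.append(F)


def vns_run(
    D: _BaseDistance,
    config: VNSConfig,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[CentroidSolution, VNSTrace]:
    """One seeded VNS run: initial solution, then max_iter shake/descend
    cycles with the k_min..k_max neighborhood schedule.

    Returns the best solution found and the incumbent trace (index 0 is the
    initial solution; the F_star sequence never increases).  Identical seed,
    config and distance model give bit-identical output.
    """
    config.validate_against(D.n)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n, K = D.n, config.k
    best = evaluate(initial_solution(n, K, rng), D)
    trace = VNSTrace()
    trace.append(0, 0, best.F)
    # shake needs at least one outside cell; K == n has a unique (optimal)
    # solution anyway, so the initial evaluation is returned as-is
    k_cap = min(config.resolved_k_max(), n - K)
    if k_cap < config.k_min:
        return best, trace
    nn = neighbor_order(D)
    k = config.k_min
    F_star = best.F
    for it in range(1, config.max_iter + 1):
        Y1 = shake(best.Y, k, n, rng)
        Y2 = local_search(Y1, D, config.m, config.p, F_star, rng, nn)
        F2 = objective(Y2, D)
        if F2 < F_star:
            best = evaluate(Y2, D)
            F_star = best.F
            k = config.k_min
        else:
            k += config.k_step
            if k > k_cap:
                k = config.k_min
        trace.append(it, k, F_star)
    return best, trace
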