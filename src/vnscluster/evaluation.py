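"""Multi-seed run statistics and partition agreement (ARI).

Because the search is stochastic, a configuration is characterised by a batch
of R independently seeded runs (R = 20 by convention).  The batch summary
mirrors the usual metaheuristic reporting:

* ``f_VNS`` — the smallest objective over the R runs;
* ``err``  — the mean relative gap of each run to that best,
  err = (1/R) sum_i err_i with err_i = |F_i - f_VNS| / |F_i|;
* ``sigma`` — the (population) standard deviation of the err_i.

Partition agreement against ground truth uses the Hubert-Arabie adjusted
Rand index: +1 for identical partitions (up to relabeling), approximately 0
for independent random partitions, negative for less-than-chance agreement.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .distance import _BaseDistance
from .errors import ValidationError
from .vns import CentroidSolution, VNSConfig, VNSTrace, vns_run

__all__ = ["RunStats", "adjusted_rand_index", "run_stats", "run_batch"]


def adjusted_rand_index(labels_a: Sequence, labels_b: Sequence) -> float:
    """Chance-corrected agreement between two partitions, in [-1, 1].

    Invariant to any bijective relabeling of either argument and symmetric
    in its arguments.
    """
    labels_a = list(labels_a)
    labels_b = list(labels_b)
    if len(labels_a) != len(labels_b):
        raise ValidationError(
            f"label sequences differ in length: {len(labels_a)} vs {len(labels_b)}"
        )
    if len(labels_a) < 2:
        raise ValidationError("ARI needs at least two items")
    return float(adjusted_rand_score(labels_a, labels_b))


@dataclass
class RunStats:
    """Summary of R seeded runs of one configuration."""

    per_run_F: List[float]
    per_run_time: List[float]
    seeds: List[int]
    f_VNS: float = field(init=False)
    t_VNS: float = field(init=False)
    err: float = field(init=False)
    sigma: float = field(init=False)
    per_run_err: List[float] = field(init=False)

    def __post_init__(self) -> None:
        if not self.per_run_F:
            raise ValidationError("at least one run is required")
        F = np.asarray(self.per_run_F, dtype=float)
        self.f_VNS = float(F.min())
        best = int(np.argmin(F))  # earliest seed on ties
        self.t_VNS = float(self.per_run_time[best])
        with np.errstate(invalid="ignore", divide="ignore"):
            err_i = np.abs(F - self.f_VNS) / np.abs(F)
        err_i = np.where(F == 0.0, 0.0, err_i)  # F_i = 0 forces f_VNS = 0
        self.per_run_err = err_i.tolist()
        self.err = float(err_i.mean())
        self.sigma = float(np.sqrt(np.mean((err_i - self.err) ** 2)))

    @property
    def best_index(self) -> int:
        return int(np.argmin(self.per_run_F))

    @property
    def n_runs(self) -> int:
        return len(self.per_run_F)

    def to_dict(self) -> dict:
        return {
            "f_VNS": self.f_VNS,
            "t_VNS": self.t_VNS,
            "err": self.err,
            "sigma": self.sigma,
            "per_run_F": list(self.per_run_F),
            "seeds": list(self.seeds),
        }


def run_stats(
    per_run_F: Sequence[float],
    per_run_time: Optional[Sequence[float]] = None,
    seeds: Optional[Sequence[int]] = None,
) -> RunStats:
    """Build a :class:`RunStats` from raw per-run objective values."""
    R = len(per_run_F)
    return RunStats(
        per_run_F=[float(v) for v in per_run_F],
        per_run_time=list(per_run_time) if per_run_time is not None else [0.0] * R,
        seeds=list(seeds) if seeds is not None else list(range(R)),
    )


def run_batch(
    D: _BaseDistance,
    config: VNSConfig,
    collect_traces: bool = False,
) -> Tuple[RunStats, CentroidSolution, List[VNSTrace]]:
    """Run the search for seeds seed, seed+1, ..., seed+n_runs-1.

    Returns the batch statistics, the solution achieving f_VNS (earliest
    seed on ties), and the per-run traces (empty unless requested).
    """
    solutions: List[CentroidSolution] = []
    traces: List[VNSTrace] = []
    F_list: List[float] = []
    t_list: List[float] = []
    seeds = [config.seed + r for r in range(config.n_runs)]
    for s in seeds:
        cfg = replace(config, seed=s)
        t0 = time.perf_counter()
        sol, trace = vns_run(D, cfg)
        t_list.append(time.perf_counter() - t0)
        solutions.append(sol)
        F_list.append(sol.F)
        if collect_traces:
            traces.append(trace)
    stats = RunStats(per_run_F=F_list, per_run_time=t_list, seeds=seeds)
    return stats, solutions[stats.best_index], traces
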