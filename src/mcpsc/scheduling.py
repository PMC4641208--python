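"""Job-farm generation, partitioning, dispatch and cost modelling.

The pairwise comparison workload is a list of jobs, one per
(query, database, method) triple: K_Q x K_D pairs per method, self-pairs
included. Methods flagged ``sequential`` (fast ones) run in the
coordinating process; ``parallel`` methods are spread over workers either
by static partitioning (random, greedy LPT on a length attribute) or by
dynamic round-robin dispatch to the next free worker. Schedules are
simulated with explicit per-job costs so load-balancing comparisons are
reproducible without wall-clock measurement; costs can come from a fitted
polynomial model of comparison time versus pair-length attributes.
"""

from __future__ import annotations

import heapq
import random
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from mcpsc.methods import (
    AlignmentCache,
    ContactMapCache,
    DomainStore,
    MethodRegistry,
    MethodScore,
    run_method,
)
from mcpsc.structio import ProteinDomain

__all__ = [
    "PSCJob",
    "Schedule",
    "CostModel",
    "generate_jobs",
    "partition_random",
    "partition_greedy_lpt",
    "sort_jobs_desc",
    "dispatch_round_robin",
    "simulate_partition_schedule",
    "execute_parallel",
    "fit_cost_model",
    "select_cost_model",
    "job_attribute",
]


@dataclass(frozen=True)
class PSCJob:
    """One pairwise comparison task."""

    query_id: str
    db_id: str
    method: str
    routing: str  # "sequential" | "parallel"
    len_q: int
    len_d: int

    def __post_init__(self) -> None:
        if self.routing not in ("sequential", "parallel"):
            raise ValueError(f"invalid routing {self.routing!r}")
        if self.len_q < 1 or self.len_d < 1:
            raise ValueError("domain lengths must be >= 1")

    @property
    def attr_sum(self) -> int:
        return self.len_q + self.len_d

    @property
    def attr_product(self) -> int:
        return self.len_q * self.len_d

    @property
    def sort_key(self) -> tuple[str, str, str]:
        return (self.query_id, self.db_id, self.method)


def job_attribute(job: PSCJob, attribute: str) -> int:
    if attribute == "sum":
        return job.attr_sum
    if attribute == "product":
        return job.attr_product
    raise ValueError(f"unknown attribute {attribute!r} (expected 'sum' or 'product')")


@dataclass(frozen=True)
class Schedule:
    """Assignment of jobs to workers with the derived timing summary."""

    assignments: tuple  # per-worker tuples of jobs
    finish_times: tuple  # per-worker totals, cost units
    makespan: float
    serial_time: float
    speedup: float
    efficiency: float
    idle: tuple  # per-worker makespan - finish_time

    @classmethod
    def from_assignments(
        cls, assignments: Sequence[Sequence[PSCJob]], costs: Mapping[PSCJob, float]
    ) -> "Schedule":
        finish = tuple(float(sum(costs[j] for j in part)) for part in assignments)
        makespan = max(finish) if finish else 0.0
        serial = float(sum(finish))
        speedup = serial / makespan if makespan > 0 else 1.0
        n = len(assignments)
        return cls(
            assignments=tuple(tuple(p) for p in assignments),
            finish_times=finish,
            makespan=makespan,
            serial_time=serial,
            speedup=speedup,
            efficiency=speedup / n if n else 0.0,
            idle=tuple(makespan - f for f in finish),
        )


def _as_cost_map(jobs: Sequence[PSCJob], costs) -> dict[PSCJob, float]:
    if isinstance(costs, Mapping):
        missing = [j for j in jobs if j not in costs]
        if missing:
            raise ValueError(f"no cost for job {missing[0].sort_key}")
        return {j: float(costs[j]) for j in jobs}
    costs = list(costs)
    if len(costs) != len(jobs):
        raise ValueError(f"{len(costs)} costs for {len(jobs)} jobs")
    return {j: float(c) for j, c in zip(jobs, costs)}


def generate_jobs(
    queries: Sequence[ProteinDomain],
    database: Sequence[ProteinDomain],
    methods: Mapping[str, str] | Iterable[tuple[str, str]],
) -> list[PSCJob]:
    """Build the K_Q x K_D x M job farm.

    ``methods`` maps method name -> routing flag. One job is emitted per
    (query, db, method) triple, covering all-to-all (Q == D) and
    many-to-many runs; self-pairs are included.
    """
    if not queries or not database:
        raise ValueError("query and database sets must be non-empty")
    method_items = list(methods.items()) if isinstance(methods, Mapping) else list(methods)
    jobs = [
        PSCJob(
            query_id=q.id,
            db_id=d.id,
            method=name,
            routing=routing,
            len_q=q.length,
            len_d=d.length,
        )
        for q in queries
        for d in database
        for name, routing in method_items
    ]
    return jobs


def partition_random(jobs: Sequence[PSCJob], n_parts: int, seed: int) -> list[list[PSCJob]]:
    """Shuffle jobs with the given seed and deal them out evenly.

    Part sizes differ by at most one; empty parts are allowed when there
    are fewer jobs than parts.
    """
    if n_parts < 1:
        raise ValueError("n_parts must be >= 1")
    shuffled = list(jobs)
    random.Random(seed).shuffle(shuffled)
    parts: list[list[PSCJob]] = [[] for _ in range(n_parts)]
    for k, job in enumerate(shuffled):
        parts[k % n_parts].append(job)
    return parts


def partition_greedy_lpt(
    jobs: Sequence[PSCJob], n_parts: int, attribute: str = "product"
) -> list[list[PSCJob]]:
    """Longest-processing-time greedy partitioning.

    Jobs are sorted in descending order of the chosen length attribute and
    each is assigned to the partition with the smallest running sum. Sorting
    ties break by (query_id, db_id, method); running-sum ties go to the
    lowest partition index.
    """
    if n_parts < 1:
        raise ValueError("n_parts must be >= 1")
    ordered = sort_jobs_desc(jobs, attribute)
    parts: list[list[PSCJob]] = [[] for _ in range(n_parts)]
    heap = [(0.0, i) for i in range(n_parts)]
    heapq.heapify(heap)
    for job in ordered:
        total, idx = heapq.heappop(heap)
        parts[idx].append(job)
        heapq.heappush(heap, (total + job_attribute(job, attribute), idx))
    return parts


def sort_jobs_desc(jobs: Sequence[PSCJob], attribute: str = "product") -> list[PSCJob]:
    """Descending sort on the length attribute; ties by (query, db, method)."""
    return sorted(jobs, key=lambda j: (-job_attribute(j, attribute), j.sort_key))


def dispatch_round_robin(
    ordered_jobs: Sequence[PSCJob], n_workers: int, costs
) -> Schedule:
    """Dynamic dispatch: hand the next job to the next free worker.

    Event-driven simulation: each job goes to the worker with the earliest
    current finish time, ties resolved to the lowest worker index.
    """
    if n_workers < 1:
        raise ValueError("n_workers must be >= 1")
    cost_map = _as_cost_map(list(ordered_jobs), costs)
    if any(c < 0 for c in cost_map.values()):
        raise ValueError("costs must be non-negative")
    assignments: list[list[PSCJob]] = [[] for _ in range(n_workers)]
    heap = [(0.0, i) for i in range(n_workers)]
    heapq.heapify(heap)
    for job in ordered_jobs:
        t, idx = heapq.heappop(heap)
        assignments[idx].append(job)
        heapq.heappush(heap, (t + cost_map[job], idx))
    return Schedule.from_assignments(assignments, cost_map)


def simulate_partition_schedule(partitions: Sequence[Sequence[PSCJob]], costs) -> Schedule:
    """Schedule implied by static partitions: one partition per worker."""
    all_jobs = [j for part in partitions for j in part]
    cost_map = _as_cost_map(all_jobs, costs)
    return Schedule.from_assignments(partitions, cost_map)


def execute_parallel(
    jobs: Sequence[PSCJob],
    n_workers: int,
    registry: MethodRegistry,
    domain_store: DomainStore,
    cmap_cache: ContactMapCache | None = None,
    alignment_cache: AlignmentCache | None = None,
) -> list[MethodScore]:
    """Run the job farm: sequential-routed jobs first in the coordinating
    process, then parallel-routed jobs on a pool of ``n_workers`` workers.

    The returned score list is ordered by the input job order, so results
    are identical for any worker count (scheduling never affects values).
    Worker failures are re-raised naming the offending job.
    """
    if n_workers < 1:
        raise ValueError("n_workers must be >= 1")
    if cmap_cache is None:
        cmap_cache = ContactMapCache(domain_store)
    if alignment_cache is None:
        alignment_cache = AlignmentCache(domain_store)

    results: dict[int, MethodScore] = {}

    def run_one(k: int, job: PSCJob) -> None:
        try:
            results[k] = run_method(job, registry, domain_store, cmap_cache, alignment_cache)
        except Exception as exc:
            raise RuntimeError(
                f"job ({job.query_id}, {job.db_id}, {job.method}) failed: {exc}"
            ) from exc

    sequential = [(k, j) for k, j in enumerate(jobs) if j.routing == "sequential"]
    parallel = [(k, j) for k, j in enumerate(jobs) if j.routing == "parallel"]

    for k, job in sequential:
        run_one(k, job)

    if parallel:
        if n_workers == 1:
            for k, job in parallel:
                run_one(k, job)
        else:
            with ThreadPoolExecutor(max_workers=n_workers) as pool:
                futures = [pool.submit(run_one, k, job) for k, job in parallel]
                for fut in futures:
                    fut.result()

    return [results[k] for k in range(len(jobs))]


@dataclass(frozen=True)
class CostModel:
    """Polynomial model of per-job cost versus a pair-length attribute.

    ``coefficients`` are in descending powers (numpy polyval convention):
    linear (a, b) -> a*x + b; quadratic (a, b, c) -> a*x^2 + b*x + c.
    """

    form: str  # "linear" | "quadratic"
    attribute: str  # "sum" | "product"
    coefficients: tuple
    residual_ss: float

    def __post_init__(self) -> None:
        if self.form not in ("linear", "quadratic"):
            raise ValueError(f"unknown form {self.form!r}")
        expected = 2 if self.form == "linear" else 3
        if len(self.coefficients) != expected:
            raise ValueError(f"{self.form} model needs {expected} coefficients")
        if self.residual_ss < 0:
            raise ValueError("residual_ss must be >= 0")

    def predict(self, attrs) -> np.ndarray:
        return np.polyval(self.coefficients, np.asarray(attrs, dtype=float))


def fit_cost_model(attrs, times, form: str = "quadratic",
                   attribute: str = "product") -> CostModel:
    """Least-squares fit of observed job times against a length attribute."""
    x = np.asarray(attrs, dtype=float)
    t = np.asarray(times, dtype=float)
    if x.shape != t.shape or x.ndim != 1:
        raise ValueError("attrs and times must be 1-D arrays of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.any(x <= 0):
        raise ValueError("attributes must be positive")
    if np.ptp(x) == 0:
        raise ValueError("singular design: all attribute values equal")
    deg = 1 if form == "linear" else 2
    if form not in ("linear", "quadratic"):
        raise ValueError(f"unknown form {form!r}")
    coeffs = np.polyfit(x, t, deg)
    resid = float(((np.polyval(coeffs, x) - t) ** 2).sum())
    return CostModel(form=form, attribute=attribute,
                     coefficients=tuple(coeffs), residual_ss=resid)


def select_cost_model(jobs: Sequence[PSCJob], times,
                      forms: Sequence[str] = ("linear", "quadratic"),
                      attributes: Sequence[str] = ("sum", "product")) -> CostModel:
    """Fit every (form, attribute) combination; return the lowest-residual fit."""
    t = np.asarray(times, dtype=float)
    best: CostModel | None = None
    for attribute in attributes:
        x = np.array([job_attribute(j, attribute) for j in jobs], dtype=float)
        for form in forms:
            model = fit_cost_model(x, t, form=form, attribute=attribute)
            if best is None or model.residual_ss < best.residual_ss:
                best = model
    return best
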