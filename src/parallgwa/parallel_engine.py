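"""Task-pull execution of partitioned work with deterministic merging.

The contract mirrors a frontend/compute-node cluster: a plan (from
:mod:`parallgwa.partitioner`) becomes a list of :class:`Task` objects, an
executor runs each task exactly once — idle workers pulling the next
unassigned task until none remain — and the frontend merges the results
into the same table or matrix a sequential run would produce. Merging is
a pure function of the results and the plan, keyed by task id, so the
output is bit-identical for every processor count and every completion
order. A failing task yields a failed-status result carrying its
diagnostic; the remaining tasks still run.

Two executors satisfy the contract: ``"serial"`` (a plain loop, also used
whenever P == 1) and ``"processes"`` (a local fork-based process pool).
The statistics code never knows which executor runs it.

The overhead model quantifies the cost of parallelism itself:
``overhead(t1, tP, P) = tP - t1/P`` (measured parallel time minus ideal
time), and ``predict_time(t1, ohead, P) = t1/P + ohead`` extrapolates
run time to other processor counts holding the overhead constant.
"""

from __future__ import annotations

import logging
import traceback
from concurrent.futures import FIRST_COMPLETED, ProcessPoolExecutor, wait
from dataclasses import dataclass, field
from functools import partial
from multiprocessing import get_context
from typing import Any, Callable, Sequence

import numpy as np
import pandas as pd

from . import ind_stats, pairwise_stats, snp_stats
from .errors import ConsistencyError, MergeError, ParameterError
from .genotype_io import GenotypeMatrix, PhenotypeTable
from .pairwise_stats import DEFAULT_MIN_SHARED, PairMatrix
from .partitioner import (
    DEFAULT_SIDE_MAX,
    IndexRange,
    LinearPartition,
    PairBlock,
    PairwisePlan,
    partition_linear,
    plan_pairwise,
)

logger = logging.getLogger(__name__)

EXECUTORS = ("serial", "processes")

#: symmetric duplicate blocks must agree to this absolute tolerance
SYMMETRY_TOL = 1e-12


@dataclass(frozen=True)
class Task:
    """One unit of schedulable work: a block of a partition plan."""

    task_id: int
    block: IndexRange | PairBlock
    kind: str  # "type1" | "type2" | "type3" | "type4"
    payload_ref: str = ""


@dataclass
class TaskResult:
    task_id: int
    body: Any = None
    status: str = "ok"  # "ok" | "failed"
    diagnostic: str | None = None

    @property
    def ok(self) -> bool:
        return self.status == "ok"


def _safe_call(worker: Callable[[Task], Any], task: Task) -> TaskResult:
    """Run one task, capturing any exception as a failed result."""
    try:
        return TaskResult(task_id=task.task_id, body=worker(task))
    except Exception:
        return TaskResult(
            task_id=task.task_id,
            status="failed",
            diagnostic=traceback.format_exc(limit=10),
        )


def run_tasks(
    tasks: Sequence[Task],
    worker: Callable[[Task], Any],
    P: int = 1,
    executor: str = "serial",
    retries: int = 0,
) -> list[TaskResult]:
    """Execute every task exactly once; return results ordered by task id.

    ``P == 1`` (or ``executor="serial"``) runs a plain sequential loop.
    With ``executor="processes"`` at most P worker processes each pull the
    next unassigned task as they go idle. Failed tasks are retried up to
    ``retries`` times (default 0: deterministic single attempt).
    """
    if not tasks:
        raise ParameterError("task list is empty")
    if P < 1:
        raise ParameterError(f"P must be >= 1, got {P}")
    if executor not in EXECUTORS:
        raise ParameterError(f"executor must be one of {EXECUTORS}, got {executor!r}")
    ids = [t.task_id for t in tasks]
    if sorted(ids) != list(range(len(tasks))):
        raise ParameterError("task ids must be unique and dense from 0")

    pending = list(tasks)
    results: dict[int, TaskResult] = {}
    for attempt in range(retries + 1):
        if executor == "serial" or P == 1:
            got = [_safe_call(worker, t) for t in pending]
        else:
            got = _run_process_pool(pending, worker, P)
        for r in got:
            results[r.task_id] = r
        pending = [t for t in pending if not results[t.task_id].ok]
        if not pending:
            break
        if attempt < retries:
            logger.warning("retrying %d failed tasks (attempt %d)", len(pending), attempt + 2)
    n_failed = sum(0 if r.ok else 1 for r in results.values())
    logger.info(
        "run_tasks: %d tasks, %d ok, %d failed (P=%d, executor=%s)",
        len(tasks), len(tasks) - n_failed, n_failed, P, executor,
    )
    return [results[i] for i in range(len(tasks))]


def _run_process_pool(tasks: Sequence[Task], worker, P: int) -> list[TaskResult]:
    # task pull: seed each worker with one task, hand out the rest as
    # workers come free, so a slow task never blocks the queue behind it
    ctx = get_context("fork")
    out: list[TaskResult] = []
    queue = list(tasks)
    with ProcessPoolExecutor(max_workers=P, mp_context=ctx) as pool:
        running = set()
        while queue and len(running) < P:
            running.add(pool.submit(_safe_call, worker, queue.pop(0)))
        while running:
            done, running = wait(running, return_when=FIRST_COMPLETED)
            for fut in done:
                out.append(fut.result())
            while queue and len(running) < P:
                running.add(pool.submit(_safe_call, worker, queue.pop(0)))
    return out


# ---------------------------------------------------------------------------
# Merging

def _require_all_ok(results: Sequence[TaskResult]) -> None:
    failed = [r.task_id for r in results if not r.ok]
    if failed:
        detail = next(r.diagnostic for r in results if not r.ok)
        raise MergeError(f"cannot merge: tasks {failed} failed; first diagnostic:\n{detail}")


def merge_linear(results: Sequence[TaskResult], partition: LinearPartition) -> pd.DataFrame:
    """Concatenate per-range tables in range order (== sequential row order)."""
    _require_all_ok(results)
    if len(results) != len(partition.ranges):
        raise MergeError(
            f"expected {len(partition.ranges)} results, got {len(results)}"
        )
    ordered = sorted(results, key=lambda r: r.task_id)
    for r, rng in zip(ordered, partition.ranges):
        if len(r.body) != rng.size:
            raise MergeError(
                f"task {r.task_id} returned {len(r.body)} rows for range of {rng.size}"
            )
    return pd.concat([r.body for r in ordered], ignore_index=True)


def merge_pairwise(
    results: Sequence[TaskResult],
    plan: PairwisePlan,
    tol: float = SYMMETRY_TOL,
) -> tuple[np.ndarray, np.ndarray]:
    """Assemble block results into full symmetric (values, n_shared) matrices.

    Each result body is ``(values, n_shared)`` for its block. Where the
    plan computed both (i, k) and (k, i), the two values must agree within
    ``tol`` (anything worse signals a worker bug) and the upper-triangle
    value is kept. Blocks strictly below the diagonal may be omitted
    (symmetry-exploiting schedules); their cells are filled by mirroring.
    """
    _require_all_ok(results)
    by_id = {r.task_id: r for r in results}
    n = plan.n
    values = np.full((n, n), np.nan)
    counts = np.zeros((n, n), dtype=np.int64)
    covered = np.zeros((n, n), dtype=bool)
    for tid, block in enumerate(plan.blocks):
        if tid not in by_id:
            if block.rows.start >= block.cols.stop:  # strictly below diagonal
                continue
            raise MergeError(f"missing result for block {tid} ({block.rows} x {block.cols})")
        v, c = by_id[tid].body
        sl = (slice(block.rows.start, block.rows.stop), slice(block.cols.start, block.cols.stop))
        if v.shape != (block.rows.size, block.cols.size):
            raise MergeError(
                f"block {tid}: result shape {v.shape} != "
                f"({block.rows.size}, {block.cols.size})"
            )
        values[sl] = v
        counts[sl] = c
        covered[sl] = True
    both = covered & covered.T
    upper = np.triu(both, k=1)
    diff = np.abs(values - values.T)
    bad = upper & ~(np.isnan(values) & np.isnan(values.T)) & ~(diff <= tol)
    if bad.any():
        i, k = np.argwhere(bad)[0]
        raise ConsistencyError(
            f"symmetric duplicates disagree at ({i}, {k}): "
            f"{values[i, k]!r} vs {values[k, i]!r}"
        )
    only_lower = covered.T & ~covered
    values[only_lower] = values.T[only_lower]
    counts[only_lower] = counts.T[only_lower]
    if not (covered | covered.T).all():
        i, k = np.argwhere(~(covered | covered.T))[0]
        raise MergeError(f"pair grid cell ({i}, {k}) not covered by any block")
    # keep the upper-triangle copy of duplicated cells
    iu = np.triu_indices(n, k=1)
    lower = (iu[1], iu[0])
    values[lower] = values[iu]
    counts[lower] = counts[iu]
    return values, counts


# ---------------------------------------------------------------------------
# Overhead model

def overhead(time_a_cpu: float, time_P_cpus: float, P: int) -> float:
    """Parallel overhead: measured P-processor time minus ideal time t1/P."""
    if time_a_cpu < 0 or time_P_cpus < 0:
        raise ParameterError("durations must be >= 0")
    if P < 1:
        raise ParameterError(f"P must be >= 1, got {P}")
    return time_P_cpus - time_a_cpu / P


def predict_time(time_a_cpu: float, overhead_ref: float, P: int) -> float:
    """Extrapolated P-processor run time: t1/P plus a constant overhead."""
    if time_a_cpu < 0 or overhead_ref < 0:
        raise ParameterError("durations must be >= 0")
    if P < 1:
        raise ParameterError(f"P must be >= 1, got {P}")
    return time_a_cpu / P + overhead_ref


@dataclass(frozen=True)
class OverheadModel:
    """Constant-overhead extrapolation anchored at a reference measurement."""

    time_a_cpu: float
    P_ref: int
    overhead_ref: float

    @classmethod
    def from_measurements(cls, time_a_cpu: float, time_P_cpus: float, P_ref: int) -> "OverheadModel":
        return cls(time_a_cpu, P_ref, overhead(time_a_cpu, time_P_cpus, P_ref))

    def predict(self, P: int) -> float:
        return predict_time(self.time_a_cpu, self.overhead_ref, P)


# ---------------------------------------------------------------------------
# Module-level workers (picklable for the process executor). Each receives
# the shared dataset bound into a partial plus the task naming its slice.

def _type1_worker(task: Task, G: GenotypeMatrix, fn_name: str, kwargs: dict) -> pd.DataFrame:
    sub = G.subset_snps(list(task.block.indices()))
    fn = getattr(snp_stats, fn_name)
    return fn(sub, **kwargs)


def _type2_worker(task: Task, G: GenotypeMatrix, fn_name: str, freqs: np.ndarray) -> pd.DataFrame:
    rows = list(task.block.indices())
    codes = G.codes[rows, :]
    ids = [G.sample_ids[i] for i in rows]
    if fn_name == "per_individual_summary":
        return ind_stats._summary_rows(codes, ids)
    if fn_name == "homozygosity":
        return ind_stats._homozygosity_rows(codes, ids, freqs)
    raise ParameterError(f"unknown type-2 function {fn_name!r}")


def _type3_worker(
    task: Task, G: GenotypeMatrix, weight: str,
    freqs: np.ndarray | None, diag_vals: np.ndarray, diag_n: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    b: PairBlock = task.block
    return pairwise_stats.ibs_block(
        G, list(b.rows.indices()), list(b.cols.indices()),
        weight=weight, freqs=freqs, diag_vals=diag_vals, diag_n=diag_n,
    )


def _type4_worker(
    task: Task, G: GenotypeMatrix, statistic: str,
    max_bp_window: int | None, min_shared: int,
) -> tuple[np.ndarray, np.ndarray]:
    b: PairBlock = task.block
    attr = "Dprime" if statistic == "dprime" else statistic
    vals = np.empty((b.rows.size, b.cols.size))
    ns = np.empty((b.rows.size, b.cols.size), dtype=np.int64)
    for a, i in enumerate(b.rows.indices()):
        for c, k in enumerate(b.cols.indices()):
            res = pairwise_stats.ld_cell(
                G, i, k, max_bp_window=max_bp_window, min_shared=min_shared
            )
            vals[a, c] = getattr(res, attr)
            ns[a, c] = res.n
    return vals, ns


def _linear_tasks(total: int, nprocs: int, kind: str, what: str) -> tuple[list[Task], LinearPartition]:
    part = partition_linear(total, min(nprocs, total))
    tasks = [
        Task(task_id=i, block=r, kind=kind, payload_ref=f"{what}[{r.start}:{r.stop}]")
        for i, r in enumerate(part.ranges)
    ]
    return tasks, part


def _pairwise_tasks(
    n: int, nprocs: int, kind: str, what: str,
    side_max: int, exploit_symmetry: bool,
) -> tuple[list[Task], PairwisePlan]:
    plan = plan_pairwise(n, nprocs, side_max=side_max)
    tasks = []
    for i, b in enumerate(plan.blocks):
        if exploit_symmetry and b.rows.start >= b.cols.stop:
            continue  # strictly below the diagonal; merge mirrors it
        tasks.append(
            Task(task_id=i, block=b, kind=kind,
                 payload_ref=f"{what}[{b.rows.start}:{b.rows.stop})x[{b.cols.start}:{b.cols.stop})")
        )
    # task ids must be dense for run_tasks; remap but remember plan index
    remapped = [
        Task(task_id=j, block=t.block, kind=t.kind, payload_ref=t.payload_ref)
        for j, t in enumerate(tasks)
    ]
    return remapped, plan


def _restore_plan_ids(results: list[TaskResult], tasks: list[Task], plan: PairwisePlan) -> list[TaskResult]:
    """Re-key results from dense task ids back to plan block indices."""
    block_index = {id(b): i for i, b in enumerate(plan.blocks)}
    out = []
    for r, t in zip(sorted(results, key=lambda r: r.task_id), tasks):
        out.append(TaskResult(task_id=block_index[id(t.block)], body=r.body,
                              status=r.status, diagnostic=r.diagnostic))
    return out


# ---------------------------------------------------------------------------
# High-level parallel drivers (the paper's four computation types)

def parallel_snp_summary(
    G: GenotypeMatrix, nprocs: int = 1, executor: str = "serial"
) -> pd.DataFrame:
    """Type-1 driver: per-SNP summaries over a linear SNP partition."""
    tasks, part = _linear_tasks(G.n_snps, nprocs, "type1", "snps")
    worker = partial(_type1_worker, G=G, fn_name="snp_summary", kwargs={})
    return merge_linear(run_tasks(tasks, worker, P=nprocs, executor=executor), part)


def parallel_score_test(
    G: GenotypeMatrix, y: Sequence[float], nprocs: int = 1, executor: str = "serial"
) -> pd.DataFrame:
    """Type-1 driver: score association test over a linear SNP partition."""
    tasks, part = _linear_tasks(G.n_snps, nprocs, "type1", "snps")
    worker = partial(_type1_worker, G=G, fn_name="score_test",
                     kwargs={"y": np.asarray(y, dtype=np.float64)})
    return merge_linear(run_tasks(tasks, worker, P=nprocs, executor=executor), part)


def parallel_ml_regression(
    G: GenotypeMatrix,
    pheno: PhenotypeTable,
    trait: str,
    covariates: Sequence[str] = (),
    model: str = "linear",
    nprocs: int = 1,
    executor: str = "serial",
) -> pd.DataFrame:
    """Type-1 driver: per-SNP regression over a linear SNP partition."""
    tasks, part = _linear_tasks(G.n_snps, nprocs, "type1", "snps")
    worker = partial(
        _type1_worker, G=G, fn_name="ml_regression",
        kwargs={"pheno": pheno, "trait": trait,
                "covariates": tuple(covariates), "model": model},
    )
    return merge_linear(run_tasks(tasks, worker, P=nprocs, executor=executor), part)


def parallel_individual_summary(
    G: GenotypeMatrix, nprocs: int = 1, executor: str = "serial"
) -> pd.DataFrame:
    """Type-2 driver: per-individual call rate/heterozygosity."""
    tasks, part = _linear_tasks(G.n_samples, nprocs, "type2", "individuals")
    worker = partial(_type2_worker, G=G, fn_name="per_individual_summary",
                     freqs=np.empty(0))
    return merge_linear(run_tasks(tasks, worker, P=nprocs, executor=executor), part)


def parallel_homozygosity(
    G: GenotypeMatrix, nprocs: int = 1, executor: str = "serial"
) -> pd.DataFrame:
    """Type-2 driver: per-individual homozygosity/inbreeding.

    Sample allele frequencies are computed once on the frontend and shared
    with every worker, exactly as the sequential path uses them.
    """
    tasks, part = _linear_tasks(G.n_samples, nprocs, "type2", "individuals")
    freqs = snp_stats.alt_allele_freqs(G)
    worker = partial(_type2_worker, G=G, fn_name="homozygosity", freqs=freqs)
    return merge_linear(run_tasks(tasks, worker, P=nprocs, executor=executor), part)


def parallel_ibs_matrix(
    G: GenotypeMatrix,
    weight: str = "none",
    nprocs: int = 1,
    executor: str = "serial",
    side_max: int = DEFAULT_SIDE_MAX,
    exploit_symmetry: bool = False,
) -> PairMatrix:
    """Type-3 driver: IBS/kinship matrix over the recursive pairwise plan."""
    if G.n_samples < 2:
        raise ParameterError("need at least 2 individuals")
    freqs = snp_stats.alt_allele_freqs(G) if weight == "freq" else None
    diag_vals, diag_n = pairwise_stats._ibs_diagonal(
        G, weight, freqs if freqs is not None else np.empty(0)
    )
    tasks, plan = _pairwise_tasks(G.n_samples, nprocs, "type3", "individuals",
                                  side_max, exploit_symmetry)
    worker = partial(_type3_worker, G=G, weight=weight, freqs=freqs,
                     diag_vals=diag_vals, diag_n=diag_n)
    results = run_tasks(tasks, worker, P=nprocs, executor=executor)
    values, counts = merge_pairwise(_restore_plan_ids(results, tasks, plan), plan)
    statistic = "ibs" if weight == "none" else "kinship"
    return PairMatrix(ids=list(G.sample_ids), values=values,
                      statistic=statistic, n_shared=counts)


def parallel_ld_matrix(
    G: GenotypeMatrix,
    statistic: str = "r2",
    snp_subset: Sequence[str] | Sequence[int] | None = None,
    max_bp_window: int | None = None,
    min_shared: int = DEFAULT_MIN_SHARED,
    nprocs: int = 1,
    executor: str = "serial",
    side_max: int = DEFAULT_SIDE_MAX,
    exploit_symmetry: bool = False,
) -> PairMatrix:
    """Type-4 driver: one LD statistic matrix over the pairwise plan."""
    if statistic not in pairwise_stats.LD_STATISTICS:
        raise ParameterError(f"unknown LD statistic {statistic!r}")
    idx = pairwise_stats.resolve_snp_subset(G, snp_subset)
    if len(idx) < 2:
        raise ParameterError("need at least 2 SNPs after subsetting")
    sub = G.subset_snps(idx)
    tasks, plan = _pairwise_tasks(sub.n_snps, nprocs, "type4", "snps",
                                  side_max, exploit_symmetry)
    worker = partial(_type4_worker, G=sub, statistic=statistic,
                     max_bp_window=max_bp_window, min_shared=min_shared)
    results = run_tasks(tasks, worker, P=nprocs, executor=executor)
    values, counts = merge_pairwise(_restore_plan_ids(results, tasks, plan), plan)
    return PairMatrix(ids=sub.snp_names, values=values,
                      statistic=statistic, n_shared=counts)
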