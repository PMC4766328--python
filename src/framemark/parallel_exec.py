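"""Order-preserving data-parallel execution of per-frame operations.

A stack is split into contiguous frame chunks — near-equal sizes differing by
at most one, e.g. 30 frames on 4 workers -> 8,8,7,7 and 15 -> 4,4,4,3 — and
each chunk runs the frame operation sequentially on its own worker process.
Results are keyed by frame number and reassembled strictly in frame order,
so parallel output is bit-identical to a plain sequential loop.

Jobs move through an explicit life cycle,

    pending -> queued -> running -> finished | failed -> deleted,

mirroring how batch schedulers manage work even though a local process pool
dequeues immediately. Every transition emits a structured log line
(job id, state, timestamp). A job may be deleted only once finished or
failed, and results are retrievable only in the finished state.
"""

from __future__ import annotations

import itertools
import logging
import os
import time
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from typing import Any, Callable, Optional, Sequence

import numpy as np

from .dicom_io import ImageStack
from .embedder import ConfigurationError

__all__ = [
    "PENDING", "QUEUED", "RUNNING", "FINISHED", "FAILED", "DELETED",
    "StateError", "FrameOperationError",
    "TaskRecord", "JobRecord",
    "partition_frames", "create_job", "submit_and_run", "fetch_outputs",
    "delete_job", "work_profile", "resolve_workers",
]

logger = logging.getLogger("framemark.parallel")

PENDING = "pending"
QUEUED = "queued"
RUNNING = "running"
FINISHED = "finished"
FAILED = "failed"
DELETED = "deleted"

_TRANSITIONS = {
    PENDING: {QUEUED},
    QUEUED: {RUNNING},
    RUNNING: {FINISHED, FAILED},
    FINISHED: {DELETED},
    FAILED: {DELETED},
    DELETED: set(),
}

_job_counter = itertools.count(1)


class StateError(RuntimeError):
    """An operation was attempted in a job state where it is not legal."""


class FrameOperationError(RuntimeError):
    """The frame operation raised; carries the 1-based frame number."""

    def __init__(self, frame_number: int, message: str):
        super().__init__(f"frame {frame_number}: {message}")
        self.frame_number = frame_number


@dataclass
class TaskRecord:
    task_id: int
    frame_range: tuple[int, int]  # half-open, 0-based
    worker_id: int
    state: str = PENDING


@dataclass
class JobRecord:
    job_id: int
    operation: Callable[[np.ndarray, int], tuple[np.ndarray, Any]]
    frames: Optional[np.ndarray]
    meta: dict
    tasks: list[TaskRecord]
    state: str = PENDING
    results: dict[int, tuple[np.ndarray, Any]] = field(default_factory=dict)
    error: Optional[str] = None

    def _transition(self, new_state: str) -> None:
        if new_state not in _TRANSITIONS[self.state]:
            raise StateError(f"job {self.job_id}: illegal transition {self.state} -> {new_state}")
        self.state = new_state
        logger.info("job=%d state=%s time=%.6f", self.job_id, new_state, time.time())


def partition_frames(frame_count: int, workers: int) -> list[tuple[int, int]]:
    """Contiguous near-equal chunks of ``range(frame_count)``.

    The first ``frame_count mod chunks`` chunks get the ceiling size, the
    rest the floor; sizes differ by at most one and sum to the frame count.
    Returns half-open (start, stop) ranges in frame order.
    """
    if frame_count < 1 or workers < 1:
        raise ConfigurationError("frame_count and workers must be positive")
    chunks = min(workers, frame_count)
    size, extra = divmod(frame_count, chunks)
    ranges: list[tuple[int, int]] = []
    start = 0
    for i in range(chunks):
        stop = start + size + (1 if i < extra else 0)
        ranges.append((start, stop))
        start = stop
    return ranges


def chunk_sizes(frame_count: int, workers: int) -> list[int]:
    """The chunk sizes produced by :func:`partition_frames`."""
    return [stop - start for start, stop in partition_frames(frame_count, workers)]


def resolve_workers(workers: int | str, frame_count: int) -> int:
    """Resolve a worker request; ``"auto"`` means the detected core count,
    capped at the frame count (parallel width cannot usefully exceed it)."""
    if workers == "auto":
        workers = os.cpu_count() or 1
    if not isinstance(workers, int) or workers < 1:
        raise ConfigurationError(f"workers must be a positive integer or 'auto', got {workers!r}")
    return min(workers, frame_count)


def create_job(
    stack: ImageStack,
    operation: Callable[[np.ndarray, int], tuple[np.ndarray, Any]],
    workers: int | str,
) -> JobRecord:
    """Create a pending job whose tasks cover the stack's frames."""
    if not isinstance(stack, ImageStack) or stack.frame_count < 1:
        raise ConfigurationError("a job requires a non-empty ImageStack")
    n = resolve_workers(workers, stack.frame_count)
    ranges = partition_frames(stack.frame_count, n)
    tasks = [TaskRecord(task_id=i, frame_range=rng, worker_id=i) for i, rng in enumerate(ranges)]
    job = JobRecord(
        job_id=next(_job_counter),
        operation=operation,
        frames=stack.frames,
        meta=dict(stack.meta),
        tasks=tasks,
    )
    logger.info("job=%d state=%s time=%.6f", job.job_id, PENDING, time.time())
    return job


def _run_chunk(
    operation: Callable[[np.ndarray, int], tuple[np.ndarray, Any]],
    frames: np.ndarray,
    start: int,
) -> list[tuple[np.ndarray, Any]]:
    """Worker body: run the operation sequentially over one contiguous chunk."""
    out: list[tuple[np.ndarray, Any]] = []
    for offset in range(frames.shape[0]):
        frame_idx = start + offset
        try:
            out.append(operation(frames[offset], frame_idx))
        except Exception as exc:
            raise FrameOperationError(frame_idx + 1, str(exc)) from exc
    return out


def submit_and_run(job: JobRecord) -> JobRecord:
    """Submit a pending job and run its tasks to completion on a process pool.

    On success the job is ``finished`` with per-frame results recorded; if
    any task's operation raises, the job is ``failed`` and ``job.error``
    names the failing 1-based frame number.
    """
    if job.state != PENDING:
        raise StateError(f"job {job.job_id}: submit requires pending state, is {job.state}")
    job._transition(QUEUED)
    job._transition(RUNNING)
    assert job.frames is not None
    try:
        if len(job.tasks) == 1:
            # degenerate parallelism: run in-process, same code path as workers
            task = job.tasks[0]
            task.state = RUNNING
            start, stop = task.frame_range
            chunk = _run_chunk(job.operation, job.frames[start:stop], start)
            for offset, payload in enumerate(chunk):
                job.results[start + offset] = payload
            task.state = FINISHED
        else:
            with ProcessPoolExecutor(max_workers=len(job.tasks)) as pool:
                futures = {}
                for task in job.tasks:
                    task.state = RUNNING
                    start, stop = task.frame_range
                    futures[pool.submit(_run_chunk, job.operation, job.frames[start:stop], start)] = task
                for future, task in futures.items():
                    chunk = future.result()
                    start = task.frame_range[0]
                    for offset, payload in enumerate(chunk):
                        job.results[start + offset] = payload
                    task.state = FINISHED
    except Exception as exc:
        for task in job.tasks:
            if task.state != FINISHED:
                task.state = FAILED
        job.error = str(exc)
        job._transition(FAILED)
        return job
    job._transition(FINISHED)
    return job


def fetch_outputs(job: JobRecord) -> tuple[ImageStack, list[Any]]:
    """Concatenate per-frame outputs strictly by frame number.

    Legal only in the finished state; auxiliary per-frame outputs (metrics,
    tamper results) are returned in the same order.
    """
    if job.state != FINISHED:
        raise StateError(f"job {job.job_id}: outputs retrievable only when finished, is {job.state}")
    assert job.frames is not None
    order = sorted(job.results)
    if order != list(range(job.frames.shape[0])):
        raise StateError(f"job {job.job_id}: incomplete results")
    frames = np.stack([job.results[i][0] for i in order])
    aux = [job.results[i][1] for i in order]
    return ImageStack(frames.astype(np.uint8), dict(job.meta)), aux


def delete_job(job: JobRecord) -> JobRecord:
    """Delete a finished or failed job and release its resources."""
    job._transition(DELETED)
    job.results = {}
    job.frames = None
    return job


def work_profile(
    job: JobRecord, tamper_flags: Sequence[bool]
) -> list[dict[str, int]]:
    """Per-worker load: assigned frames and tampered frames in each chunk.

    The maximum per-worker tampered count is the load-balance statistic —
    tampered frames cost more to process, so packing them into one chunk
    leaves other workers idle.
    """
    if job.state not in (FINISHED, DELETED):
        raise StateError(f"job {job.job_id}: work profile requires a finished job")
    flags = np.asarray(tamper_flags, dtype=bool)
    profile = []
    for task in job.tasks:
        start, stop = task.frame_range
        profile.append(
            {
                "worker_id": task.worker_id,
                "frames": stop - start,
                "tampered": int(flags[start:stop].sum()),
            }
        )
    return profile


def max_tampered_per_worker(profile: list[dict[str, int]]) -> int:
    return max(entry["tampered"] for entry in profile)
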