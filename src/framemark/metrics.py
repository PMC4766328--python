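"""Fidelity metrics (MSE, PSNR), empirical speedup, and scaling models.

MSE accumulates in exact integer arithmetic before the single final division,
so sequential and parallel metric computation cannot drift apart through
floating-point summation order. PSNR uses the bit-depth peak (255 for 8-bit
images) rather than the observed frame maximum.

The scaling models describe the limits of data-parallel frame processing:
Amdahl's law, S(P) = 1 / ((1 - a)/P + a), fixes the total work and bounds the
speedup by 1/a where a is the serial fraction of the runtime; Gustafson's
law, S(P) = P - a(P - 1), lets the work grow with the processor count and is
linear in P with slope 1 - a.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "MetricRecord",
    "SpeedupModel",
    "mse",
    "psnr",
    "speedup",
    "amdahl_speedup",
    "amdahl_limit",
    "gustafson_speedup",
]


@dataclass(frozen=True)
class MetricRecord:
    """Per-frame fidelity record; ``frame_number`` is 1-based."""

    frame_number: int
    mse: float
    psnr: float
    n: int

    def __post_init__(self) -> None:
        if self.mse < 0:
            raise ValueError("mse must be non-negative")
        if math.isinf(self.psnr) != (self.mse == 0):
            raise ValueError("psnr is infinite iff mse is zero")


@dataclass(frozen=True)
class SpeedupModel:
    """A predicted speedup ``s`` for serial fraction ``alpha`` on ``p`` cores."""

    alpha: float
    p: int
    s: float


def _as_arrays(frame_a, frame_b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(frame_a)
    b = np.asarray(frame_b)
    if a.shape != b.shape:
        raise ValueError(f"frame dimensions differ: {a.shape} vs {b.shape}")
    return a, b


def mse(frame_a, frame_b) -> float:
    """Mean squared error (1/n) * sum((a_i - b_i)^2) over all n pixels."""
    a, b = _as_arrays(frame_a, frame_b)
    diff = a.astype(np.int64) - b.astype(np.int64)
    return int(np.sum(diff * diff)) / diff.size


def psnr(frame_a, frame_b, peak: int = 255) -> float:
    """Peak signal-to-noise ratio, 10*log10(peak^2 / MSE), in dB.

    Returns ``math.inf`` when the frames are identical (MSE = 0).
    """
    err = mse(frame_a, frame_b)
    if err == 0:
        return math.inf
    return 10.0 * math.log10(peak * peak / err)


def speedup(elapsed_sequential: float, elapsed_parallel: float) -> float:
    """Ratio of sequential to parallel elapsed time (unrounded)."""
    if elapsed_sequential <= 0 or elapsed_parallel <= 0:
        raise ValueError("elapsed times must be positive")
    return elapsed_sequential / elapsed_parallel


def amdahl_speedup(alpha: float, p: float) -> float:
    """Fixed-workload speedup 1 / ((1 - alpha)/p + alpha) on p processors."""
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must be in [0, 1]")
    if p < 1:
        raise ValueError("p must be >= 1")
    return 1.0 / ((1.0 - alpha) / p + alpha)


def amdahl_limit(alpha: float) -> float:
    """Asymptotic speedup bound 1/alpha as the processor count grows."""
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]; the bound is infinite at 0")
    return 1.0 / alpha


def gustafson_speedup(alpha: float, p: float) -> float:
    """Scaled-workload speedup p - alpha*(p - 1) on p processors."""
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must be in [0, 1]")
    if p < 1:
        raise ValueError("p must be >= 1")
    return p - alpha * (p - 1.0)
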