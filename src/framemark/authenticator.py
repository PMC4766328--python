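"""Tamper detection, localization and recovery for watermarked stacks.

A block is flagged exactly when the CRC-16 recomputed over its current 6-MSB
content (plus frame index, block index and key) differs from the code stored
in its LSB planes — so any edit of a block's visible content, or of the
stored code bits themselves, trips the check, and untouched blocks are never
flagged (the codes are deterministic).

Recovery is two-layered:

* a flagged block is approximately rebuilt from the quantized 2x2 sub-block
  means stored in its holder block (the block i with pi(i) = j); if the
  holder is itself flagged the block is reported unrecoverable and left
  as-is;
* if the RONI archive verifies (magic, version, frame index, CRC-32), every
  LSB plane of the frame is then restored to its pre-embedding bits, which
  makes authenticate-after-embed on an untampered stack return the original
  stack bit-exactly.

Frame numbers in reports are 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import embedder as emb
from .dicom_io import ImageStack
from .embedder import ConfigurationError, WatermarkConfig

__all__ = [
    "FrameAuthResult",
    "AuthReport",
    "authenticate_frame",
    "recover_frame",
    "authenticate_stack_sequential",
    "authenticate_stack",
]


@dataclass
class FrameAuthResult:
    """Per-frame verdict: ``tampered`` is true iff any block is flagged or
    the LSB archive failed verification."""

    tampered: bool
    tampered_blocks: list[int]
    recovered_frame: np.ndarray
    archive_intact: bool
    unrecoverable_blocks: list[int] = field(default_factory=list)
    # carried so recover_frame can run after authenticate_frame
    _stored_means: Optional[np.ndarray] = field(default=None, repr=False)
    _archive_bits: Optional[np.ndarray] = field(default=None, repr=False)


@dataclass
class AuthReport:
    """Stack-level outcome: the (strictly increasing, 1-based) tampered frame
    numbers and the recovered stack in original frame order."""

    tampered_frame_numbers: list[int]
    recovered_stack: ImageStack
    frame_results: list[FrameAuthResult] = field(default_factory=list)


def authenticate_frame(
    frame: np.ndarray, config: WatermarkConfig, frame_idx: int
) -> FrameAuthResult:
    """Verify one frame and produce its recovered version.

    An unreadable or corrupted archive is a detection outcome
    (``archive_intact`` false), never an exception.
    """
    frame = np.asarray(frame, dtype=np.uint8)
    if frame.shape != config.roi.shape:
        raise ConfigurationError(
            f"frame shape {frame.shape} does not match ROI mask {config.roi.shape}"
        )
    stored_codes, msbs, stored_means = emb.extract_block_payloads(frame, config)
    recomputed = emb._codes_for_blocks(msbs, frame_idx, config.key)
    flagged = np.flatnonzero(stored_codes != recomputed).tolist()

    archive_bits = emb.read_roni_archive(frame, config, frame_idx)
    result = FrameAuthResult(
        tampered=bool(flagged) or archive_bits is None,
        tampered_blocks=flagged,
        recovered_frame=frame.copy(),
        archive_intact=archive_bits is not None,
        _stored_means=stored_means,
        _archive_bits=archive_bits,
    )
    result.recovered_frame = recover_frame(frame, result, config)
    return result


def recover_frame(
    frame: np.ndarray, result: FrameAuthResult, config: WatermarkConfig
) -> np.ndarray:
    """Rebuild flagged blocks from their holders' stored means, then restore
    all LSB planes from the archive when it verified."""
    frame = np.asarray(frame, dtype=np.uint8)
    grid = emb.grid_for(config)
    out = frame.copy()
    flagged = set(result.tampered_blocks)
    unrecoverable: list[int] = []
    bs = config.block_size
    for j in result.tampered_blocks:
        holder = int(grid.inverse[j])
        if holder in flagged or result._stored_means is None:
            unrecoverable.append(j)
            continue
        means = result._stored_means[holder]  # (bs/2, bs/2) six-bit means
        msb_block = np.kron(means, np.ones((2, 2), dtype=np.uint8))
        r, c = grid.origins[j]
        lsbs = out[r : r + bs, c : c + bs] & ((1 << config.lsb_count) - 1)
        out[r : r + bs, c : c + bs] = (msb_block << config.lsb_count) | lsbs
    result.unrecoverable_blocks = unrecoverable
    if result._archive_bits is not None:
        out = emb.restore_lsb_planes(out, config, result._archive_bits)
    return out


def authenticate_stack_sequential(stack: ImageStack, config: WatermarkConfig) -> AuthReport:
    """Authenticate and recover frame by frame with a plain loop."""
    recovered = np.empty_like(stack.frames)
    results: list[FrameAuthResult] = []
    tampered: list[int] = []
    for i in range(stack.frame_count):
        res = authenticate_frame(stack.frames[i], config, i)
        recovered[i] = res.recovered_frame
        results.append(res)
        if res.tampered:
            tampered.append(i + 1)
    return AuthReport(tampered, ImageStack(recovered, dict(stack.meta)), results)


def _auth_op(frame: np.ndarray, frame_idx: int, config: WatermarkConfig):
    res = authenticate_frame(frame, config, frame_idx)
    return res.recovered_frame, res


def authenticate_stack(
    stack: ImageStack, config: WatermarkConfig, workers: int | str = 1
) -> AuthReport:
    """Authenticate a stack sequentially (workers=1) or on a worker pool;
    the report is identical across modes."""
    if workers == 1:
        return authenticate_stack_sequential(stack, config)
    from functools import partial

    from . import parallel_exec as px

    job = px.create_job(stack, partial(_auth_op, config=config), workers)
    px.submit_and_run(job)
    if job.state == px.FAILED:
        raise RuntimeError(job.error)
    recovered, results = px.fetch_outputs(job)
    px.delete_job(job)
    results = list(results)
    tampered = [i + 1 for i, r in enumerate(results) if r.tampered]
    return AuthReport(tampered, recovered, results)
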