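"""Fragile watermark embedding with reversible LSB archival.

The frame is split into an ROI (the diagnostically significant region, where
tampering must be detected, localized and approximately recovered) and the
RONI (everything else, typically the dark border of an ultrasound scan).

Per 8x8 ROI block, the two LSB planes (128 bits at the defaults) carry:

    16 bits   CRC-16/CCITT over the block's own 6-MSB content plus the frame
              index, block index and watermark key
    96 bits   recovery field for the partner block pi(i): sixteen 6-bit
              quantized means of its 2x2 sub-blocks' 6-MSB values
    16 bits   zero padding

pi is a keyed, fixed-point-free permutation of the block indices (Sattolo
cycle driven by the 32-bit key), so a block never stores its own recovery
data. The bit stream is serialized LSB-plane-first in raster order.

Reversibility comes from the RONI archive: the original LSB planes of the
whole frame (ROI section first, then RONI, plane-major in raster order) are
deflate-compressed and written, behind a small header with a CRC-32, into the
RONI's LSB planes. Embedding fails with a capacity error — it never silently
truncates — when header + compressed archive exceed the RONI capacity.

All 6-MSB planes are left untouched everywhere, which bounds the per-pixel
distortion by 2**lsb_count - 1 and the frame MSE by (2**lsb_count - 1)**2.
"""

from __future__ import annotations

import binascii
import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .dicom_io import ImageStack
from .metrics import MetricRecord, mse, psnr

__all__ = [
    "ConfigurationError",
    "CapacityError",
    "RegionSpec",
    "WatermarkConfig",
    "BlockGrid",
    "partition_regions",
    "build_block_grid",
    "block_auth_code",
    "embed_frame",
    "embed_stack_sequential",
    "embed_stack",
]

AUTH_BITS = 16
MEAN_BITS = 6  # quantized sub-block mean width == MSB width at lsb_count=2
ARCHIVE_MAGIC = b"FWMA"
ARCHIVE_VERSION = 1
HEADER_BYTES = len(ARCHIVE_MAGIC) + 1 + 4 + 4 + 4  # magic, version, frame, bitlen, crc32


class ConfigurationError(ValueError):
    """The watermark configuration is inconsistent with the frame or itself."""


class CapacityError(ConfigurationError):
    """A payload does not fit the region that must carry it."""


# ---------------------------------------------------------------------------
# regions and configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionSpec:
    """ROI mask over a frame; the RONI is its complement."""

    roi_mask: np.ndarray

    def __post_init__(self) -> None:
        mask = np.ascontiguousarray(np.asarray(self.roi_mask, dtype=bool))
        mask.setflags(write=False)
        object.__setattr__(self, "roi_mask", mask)
        if mask.ndim != 2:
            raise ConfigurationError("roi_mask must be a 2-D boolean grid")
        if not mask.any():
            raise ConfigurationError("ROI is empty")
        if mask.all():
            raise CapacityError("ROI covers the entire frame; RONI must be non-empty")

    @property
    def roni_mask(self) -> np.ndarray:
        return ~self.roi_mask

    @property
    def shape(self) -> tuple[int, int]:
        return self.roi_mask.shape  # type: ignore[return-value]

    @classmethod
    def from_rect(cls, height: int, width: int, x: int, y: int, w: int, h: int) -> "RegionSpec":
        """Rectangular ROI with top-left corner (x, y) — x is the column."""
        if x < 0 or y < 0 or w <= 0 or h <= 0 or x + w > width or y + h > height:
            raise ConfigurationError(
                f"rectangle {x},{y},{w},{h} does not fit a {height}x{width} frame"
            )
        mask = np.zeros((height, width), dtype=bool)
        mask[y : y + h, x : x + w] = True
        return cls(mask)


@dataclass(frozen=True)
class WatermarkConfig:
    """Everything the embedder and authenticator must share.

    ``key`` is a 32-bit integer seeding the block mapping and entering every
    block authentication code; the identical config must be supplied to both
    embed and authenticate.
    """

    roi: RegionSpec
    key: int
    lsb_count: int = 2
    block_size: int = 8

    def __post_init__(self) -> None:
        if self.lsb_count not in (1, 2):
            raise ConfigurationError("lsb_count must be 1 or 2")
        if self.block_size < 2 or self.block_size % 2:
            raise ConfigurationError("block_size must be even and >= 2")
        if not 0 <= self.key < 2**32:
            raise ConfigurationError("key must be an unsigned 32-bit integer")
        cap = self.lsb_count * self.block_size**2
        if cap < AUTH_BITS:
            raise ConfigurationError(
                f"block capacity {cap} bits cannot hold a {AUTH_BITS}-bit auth code"
            )

    @property
    def block_capacity_bits(self) -> int:
        return self.lsb_count * self.block_size**2

    @property
    def recovery_bits(self) -> int:
        """Bits of the per-block recovery field; 0 when it does not fit."""
        rec = MEAN_BITS * (self.block_size // 2) ** 2
        return rec if AUTH_BITS + rec <= self.block_capacity_bits else 0


def partition_regions(
    height: int, width: int, roi: RegionSpec, block_size: Optional[int] = None
) -> tuple[np.ndarray, np.ndarray]:
    """Split a frame into disjoint, jointly covering ROI and RONI masks."""
    if roi.shape != (height, width):
        raise ConfigurationError(
            f"ROI mask shape {roi.shape} does not match frame {height}x{width}"
        )
    if block_size is not None and not _tile_origins(roi.roi_mask, block_size).size:
        raise ConfigurationError("ROI does not contain a single full block")
    return roi.roi_mask, roi.roni_mask


# ---------------------------------------------------------------------------
# block grid and keyed mapping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BlockGrid:
    """Raster-ordered tiling of the ROI into full blocks, plus the keyed
    fixed-point-free partner mapping pi (block i carries the recovery data of
    block pi[i])."""

    block_size: int
    origins: np.ndarray  # (n, 2) top-left (row, col) of each block
    mapping: np.ndarray  # pi, a permutation of range(n)
    inverse: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        inv = np.empty_like(self.mapping)
        inv[self.mapping] = np.arange(self.mapping.size)
        object.__setattr__(self, "inverse", inv)

    @property
    def n_blocks(self) -> int:
        return int(self.origins.shape[0])


def _tile_origins(roi_mask: np.ndarray, block_size: int) -> np.ndarray:
    """Origins of the regular block_size tiles lying wholly inside the ROI,
    in raster order."""
    h, w = roi_mask.shape
    bh, bw = h // block_size, w // block_size
    if bh == 0 or bw == 0:
        return np.empty((0, 2), dtype=np.intp)
    trimmed = roi_mask[: bh * block_size, : bw * block_size]
    full = trimmed.reshape(bh, block_size, bw, block_size).all(axis=(1, 3))
    rows, cols = np.nonzero(full)
    return np.column_stack((rows, cols)).astype(np.intp) * block_size


def _sattolo_permutation(n: int, key: int) -> np.ndarray:
    """A single-cycle (hence fixed-point-free for n > 1) permutation drawn
    deterministically from the key."""
    perm = np.arange(n)
    if n > 1:
        rng = np.random.Generator(np.random.PCG64(key))
        for i in range(n - 1, 0, -1):
            j = int(rng.integers(0, i))
            perm[i], perm[j] = perm[j], perm[i]
    return perm


def build_block_grid(roi_mask: np.ndarray, block_size: int, key: int) -> BlockGrid:
    """Tile the ROI into full blocks (raster order) and derive pi from the key."""
    origins = _tile_origins(np.asarray(roi_mask, dtype=bool), block_size)
    if origins.shape[0] == 0:
        raise ConfigurationError(
            f"ROI admits no full {block_size}x{block_size} block"
        )
    return BlockGrid(block_size, origins, _sattolo_permutation(origins.shape[0], key))


def grid_for(config: WatermarkConfig) -> BlockGrid:
    return build_block_grid(config.roi.roi_mask, config.block_size, config.key)


# ---------------------------------------------------------------------------
# authentication codes
# ---------------------------------------------------------------------------

def block_auth_code(
    block_msbs: Sequence[int] | np.ndarray, frame_idx: int, block_idx: int, key: int
) -> int:
    """CRC-16/CCITT over the block's 6-MSB values followed by frame index,
    block index and key, each as a 32-bit big-endian word."""
    msbs = np.asarray(block_msbs, dtype=np.uint8).reshape(-1)
    buf = msbs.tobytes() + b"".join(
        int(v).to_bytes(4, "big") for v in (frame_idx, block_idx, key)
    )
    return binascii.crc_hqx(buf, 0xFFFF)


def _codes_for_blocks(msbs: np.ndarray, frame_idx: int, key: int) -> np.ndarray:
    n = msbs.shape[0]
    flat = msbs.reshape(n, -1)
    tail_prefix = int(frame_idx).to_bytes(4, "big")
    key_b = int(key).to_bytes(4, "big")
    codes = np.empty(n, dtype=np.uint16)
    for i in range(n):
        buf = flat[i].tobytes() + tail_prefix + int(i).to_bytes(4, "big") + key_b
        codes[i] = binascii.crc_hqx(buf, 0xFFFF)
    return codes


# ---------------------------------------------------------------------------
# bit plumbing
# ---------------------------------------------------------------------------

def _int_to_bits(values: np.ndarray, width: int) -> np.ndarray:
    """(n,) ints -> (n, width) bits, most significant first."""
    shifts = np.arange(width - 1, -1, -1)
    return ((values[:, None].astype(np.uint32) >> shifts) & 1).astype(np.uint8)


def _bits_to_int(bits: np.ndarray) -> np.ndarray:
    """(n, width) bits -> (n,) ints, most significant first."""
    width = bits.shape[-1]
    weights = (1 << np.arange(width - 1, -1, -1)).astype(np.uint32)
    return (bits.astype(np.uint32) * weights).sum(axis=-1)


def _extract_blocks(frame: np.ndarray, grid: BlockGrid) -> np.ndarray:
    bs = grid.block_size
    r = grid.origins[:, 0, None, None] + np.arange(bs)[None, :, None]
    c = grid.origins[:, 1, None, None] + np.arange(bs)[None, None, :]
    return frame[r, c]


def _scatter_blocks(frame: np.ndarray, grid: BlockGrid, blocks: np.ndarray) -> None:
    bs = grid.block_size
    r = grid.origins[:, 0, None, None] + np.arange(bs)[None, :, None]
    c = grid.origins[:, 1, None, None] + np.arange(bs)[None, None, :]
    frame[r, c] = blocks


def _subblock_means(msbs: np.ndarray, block_size: int) -> np.ndarray:
    """Quantized (floor) means of each 2x2 sub-block's MSB values.

    Input (n, bs, bs); output (n, bs/2, bs/2) values in [0, 63].
    """
    n = msbs.shape[0]
    sb = block_size // 2
    grouped = msbs.reshape(n, sb, 2, sb, 2).astype(np.uint16)
    return (grouped.sum(axis=(2, 4)) // 4).astype(np.uint8)


def _payload_bits(config: WatermarkConfig, codes: np.ndarray, partner_means: np.ndarray) -> np.ndarray:
    """Assemble per-block payload bits: auth code, recovery field, padding."""
    n = codes.shape[0]
    parts = [_int_to_bits(codes.astype(np.uint32), AUTH_BITS)]
    if config.recovery_bits:
        mean_bits = _int_to_bits(
            partner_means.reshape(n, -1).reshape(-1), MEAN_BITS
        ).reshape(n, -1)
        parts.append(mean_bits)
    pad = config.block_capacity_bits - sum(p.shape[1] for p in parts)
    if pad:
        parts.append(np.zeros((n, pad), dtype=np.uint8))
    return np.concatenate(parts, axis=1)


def _write_block_lsbs(blocks: np.ndarray, bits: np.ndarray, lsb_count: int) -> np.ndarray:
    """Overwrite the LSB planes of (n, bs, bs) blocks with payload bits,
    LSB-plane-first in raster order."""
    n, bs, _ = blocks.shape
    out = (blocks >> lsb_count) << lsb_count
    for p in range(lsb_count):
        plane = bits[:, p * bs * bs : (p + 1) * bs * bs].reshape(n, bs, bs)
        out |= plane << p
    return out.astype(np.uint8)


def _read_block_lsbs(blocks: np.ndarray, lsb_count: int) -> np.ndarray:
    n, bs, _ = blocks.shape
    planes = [((blocks >> p) & 1).reshape(n, bs * bs) for p in range(lsb_count)]
    return np.concatenate(planes, axis=1).astype(np.uint8)


# ---------------------------------------------------------------------------
# RONI archive (reversibility)
# ---------------------------------------------------------------------------

def _region_indices(config: WatermarkConfig) -> tuple[np.ndarray, np.ndarray]:
    flat_roi = config.roi.roi_mask.ravel()
    return np.flatnonzero(flat_roi), np.flatnonzero(~flat_roi)


def _original_lsb_bits(frame: np.ndarray, config: WatermarkConfig) -> np.ndarray:
    """Original LSB planes of the whole frame: ROI section then RONI,
    plane-major in raster order."""
    roi_idx, roni_idx = _region_indices(config)
    flat = frame.ravel()
    sections = []
    for idx in (roi_idx, roni_idx):
        vals = flat[idx]
        for p in range(config.lsb_count):
            sections.append((vals >> p) & 1)
    return np.concatenate(sections).astype(np.uint8)


def _build_archive(frame: np.ndarray, config: WatermarkConfig, frame_idx: int) -> bytes:
    payload = np.packbits(_original_lsb_bits(frame, config)).tobytes()
    comp = zlib.compress(payload, 9)
    header = (
        ARCHIVE_MAGIC
        + bytes([ARCHIVE_VERSION])
        + int(frame_idx).to_bytes(4, "big")
        + (8 * len(comp)).to_bytes(4, "big")
        + (zlib.crc32(comp) & 0xFFFFFFFF).to_bytes(4, "big")
    )
    return header + comp


def _write_roni_archive(frame: np.ndarray, config: WatermarkConfig, archive: bytes) -> None:
    """Write the archive stream into the RONI LSB planes in place,
    LSB-plane-first in raster order; surplus capacity is zero-filled."""
    _, roni_idx = _region_indices(config)
    capacity = config.lsb_count * roni_idx.size
    nbits = 8 * len(archive)
    if nbits > capacity:
        raise CapacityError(
            f"RONI archive needs {nbits} bits but only {capacity} are available; "
            "enlarge the RONI or reduce the ROI"
        )
    bits = np.zeros(capacity, dtype=np.uint8)
    bits[:nbits] = np.unpackbits(np.frombuffer(archive, dtype=np.uint8))
    flat = frame.ravel()
    vals = (flat[roni_idx] >> config.lsb_count) << config.lsb_count
    for p in range(config.lsb_count):
        vals |= bits[p * roni_idx.size : (p + 1) * roni_idx.size] << p
    flat[roni_idx] = vals


def read_roni_archive(
    frame: np.ndarray, config: WatermarkConfig, frame_idx: int
) -> Optional[np.ndarray]:
    """Parse and verify the RONI archive; return the original LSB bit vector
    (frame order as written by :func:`_original_lsb_bits`) or None when the
    header or CRC-32 does not verify."""
    _, roni_idx = _region_indices(config)
    flat = frame.ravel()
    planes = [((flat[roni_idx] >> p) & 1).astype(np.uint8) for p in range(config.lsb_count)]
    stream = np.packbits(np.concatenate(planes)).tobytes()
    if len(stream) < HEADER_BYTES or stream[:4] != ARCHIVE_MAGIC:
        return None
    if stream[4] != ARCHIVE_VERSION:
        return None
    if int.from_bytes(stream[5:9], "big") != frame_idx:
        return None
    bitlen = int.from_bytes(stream[9:13], "big")
    crc = int.from_bytes(stream[13:17], "big")
    nbytes = (bitlen + 7) // 8
    comp = stream[HEADER_BYTES : HEADER_BYTES + nbytes]
    if len(comp) < nbytes or (zlib.crc32(comp) & 0xFFFFFFFF) != crc:
        return None
    try:
        payload = zlib.decompress(comp)
    except zlib.error:
        return None
    total = config.lsb_count * frame.size
    bits = np.unpackbits(np.frombuffer(payload, dtype=np.uint8))
    if bits.size < total:
        return None
    return bits[:total]


def restore_lsb_planes(frame: np.ndarray, config: WatermarkConfig, bits: np.ndarray) -> np.ndarray:
    """Replace every LSB plane of *frame* with the archived original bits."""
    roi_idx, roni_idx = _region_indices(config)
    out = frame.copy()
    flat = out.ravel()
    pos = 0
    for idx in (roi_idx, roni_idx):
        vals = (flat[idx] >> config.lsb_count) << config.lsb_count
        for p in range(config.lsb_count):
            vals |= bits[pos : pos + idx.size].astype(np.uint8) << p
            pos += idx.size
        flat[idx] = vals
    return out


# ---------------------------------------------------------------------------
# embedding
# ---------------------------------------------------------------------------

def extract_block_payloads(
    frame: np.ndarray, config: WatermarkConfig, grid: Optional[BlockGrid] = None
) -> tuple[np.ndarray, np.ndarray, Optional[np.ndarray]]:
    """Read each ROI block's stored payload.

    Returns ``(stored_codes, recomputed_codes, stored_partner_means)`` where
    the means are ``(n, sb, sb)`` or None when the config carries no recovery
    field. Shared by the authenticator.
    """
    grid = grid or grid_for(config)
    blocks = _extract_blocks(frame, grid)
    bits = _read_block_lsbs(blocks, config.lsb_count)
    stored_codes = _bits_to_int(bits[:, :AUTH_BITS]).astype(np.uint16)
    means = None
    if config.recovery_bits:
        sb = config.block_size // 2
        mean_bits = bits[:, AUTH_BITS : AUTH_BITS + config.recovery_bits]
        means = _bits_to_int(mean_bits.reshape(-1, MEAN_BITS)).reshape(
            grid.n_blocks, sb, sb
        ).astype(np.uint8)
    return stored_codes, blocks >> config.lsb_count, means


def embed_frame(frame: np.ndarray, config: WatermarkConfig, frame_idx: int) -> np.ndarray:
    """Watermark a single frame; returns a new array, the input is untouched."""
    frame = np.asarray(frame, dtype=np.uint8)
    if frame.shape != config.roi.shape:
        raise ConfigurationError(
            f"frame shape {frame.shape} does not match ROI mask {config.roi.shape}"
        )
    grid = grid_for(config)
    archive = _build_archive(frame, config, frame_idx)

    blocks = _extract_blocks(frame, grid)
    msbs = blocks >> config.lsb_count
    codes = _codes_for_blocks(msbs, frame_idx, config.key)
    partner_means = _subblock_means(msbs, config.block_size)[grid.mapping]
    bits = _payload_bits(config, codes, partner_means)

    out = frame.copy()
    _scatter_blocks(out, grid, _write_block_lsbs(blocks, bits, config.lsb_count))
    _write_roni_archive(out, config, archive)
    return out


def embed_stack_sequential(
    stack: ImageStack, config: WatermarkConfig
) -> tuple[ImageStack, list[MetricRecord]]:
    """Embed every frame in order with a plain loop; per-frame fidelity
    metrics are computed against the originals."""
    out_frames = np.empty_like(stack.frames)
    records: list[MetricRecord] = []
    for i in range(stack.frame_count):
        try:
            out_frames[i] = embed_frame(stack.frames[i], config, i)
        except Exception as exc:
            raise type(exc)(f"frame {i + 1}: {exc}") from exc
        err = mse(stack.frames[i], out_frames[i])
        records.append(
            MetricRecord(i + 1, err, psnr(stack.frames[i], out_frames[i]), out_frames[i].size)
        )
    return ImageStack(out_frames, dict(stack.meta)), records


def _embed_op(frame: np.ndarray, frame_idx: int, config: WatermarkConfig):
    """Per-frame operation for the parallel executor."""
    out = embed_frame(frame, config, frame_idx)
    rec = MetricRecord(frame_idx + 1, mse(frame, out), psnr(frame, out), out.size)
    return out, rec


def embed_stack(
    stack: ImageStack, config: WatermarkConfig, workers: int | str = 1
) -> tuple[ImageStack, list[MetricRecord]]:
    """Embed a stack, sequentially (workers=1) or on a worker pool.

    Parallel output is bit-identical to the sequential loop: frames are
    independent and chunk results are reassembled in frame order.
    """
    if workers == 1:
        return embed_stack_sequential(stack, config)
    from . import parallel_exec as px
    from functools import partial

    job = px.create_job(stack, partial(_embed_op, config=config), workers)
    px.submit_and_run(job)
    if job.state == px.FAILED:
        raise RuntimeError(job.error)
    out, aux = px.fetch_outputs(job)
    px.delete_job(job)
    return out, list(aux)
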