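# Methods

## Model and assumptions

`framemark` implements block-based fragile watermarking for stacks of 8-bit
grayscale frames. The core assumptions are:

* **Lossless storage.** The watermark lives in the LSB planes, so any
  requantization, filtering or lossy compression destroys it by design
  (that is what makes it *fragile*). DICOM output is therefore always
  written with an uncompressed transfer syntax, and only 8-bit
  single-sample grayscale is accepted.
* **ROI/RONI separability.** The diagnostically significant region (ROI)
  must be declared up front — a mask or rectangle; ultrasound's fan-shaped
  sector is the packaged default. The same region spec, together with the
  key, block size and LSB count, must be presented at embedding and at
  authentication; they are one configuration object.
* **Compressible RONI.** Reversibility requires archiving the frame's
  original LSB planes inside the RONI's LSB capacity. For an L-LSB scheme
  with ROI fraction f, the raw archive is L·H·W bits against a capacity of
  L·(1−f)·H·W bits, so embedding is feasible only because RONI LSBs (dark,
  near-constant background) compress to almost nothing while ROI LSBs
  (speckle) are nearly incompressible. The capacity condition is *checked*
  per frame — a frame whose archive does not fit raises a capacity error
  naming required vs. available bits; nothing is silently truncated.

## Embedding

Per ROI block of `block_size`² pixels (default 8×8) the `lsb_count` LSB
planes (default 2, i.e. 128 bits) carry, serialized LSB-plane-first in
raster order:

1. a 16-bit CRC-16/CCITT over the block's 6-MSB values followed by the
   frame index, block index and 32-bit key (each big-endian 32-bit), so
   codes cannot be transplanted across blocks, frames or keys;
2. the recovery field of the partner block π(i): one 6-bit floor-quantized
   mean per 2×2 sub-block of its 6-MSB values (96 bits at the defaults);
3. zero padding to fill the capacity exactly (16 bits at the defaults).

π is drawn from the key by Sattolo's algorithm, which yields a single cycle
and hence a fixed-point-free permutation for any block count > 1 — a block
never stores its own recovery data, otherwise one localized edit could
destroy both the content and its backup.

The RONI archive is `magic ‖ version ‖ frame_idx ‖ bit-length ‖ CRC-32`
(17 bytes) followed by the deflate-compressed original LSB planes of the
whole frame, ROI section first then RONI, plane-major in raster order.
Surplus RONI capacity is zero-filled so embedding is a pure function of
(frame, config, frame index); sequential and parallel runs are bit-identical
by construction.

Degenerate configurations: `lsb_count = 1` cannot fit the recovery field for
any even block size (16 + 1.5·bs² > bs² always), so such configs embed the
auth code only — detection and archive-based reversibility remain, partner
recovery is unavailable and tampered blocks are reported unrecoverable. A
block capacity below 16 bits is rejected outright.

## Authentication and recovery

A block is flagged **iff** the CRC recomputed over its current 6-MSB content
differs from the stored code. Single-value and short-burst edits are
detected deterministically (CRC-16 catches all bursts ≤ 16 bits); an
arbitrary multi-pixel edit is missed with probability ≈ 2⁻¹⁶. Untouched
blocks are never flagged (codes are deterministic). LSB-only edits are
flagged when they corrupt the stored code bits themselves (raster
positions 0–15 of the block's first LSB plane). An LSB edit confined to the
recovery/padding bits corrupts that block's backup payload but not its
verdict — a deliberate trade-off: the code cannot checksum the planes it is
stored in.

The frame verdict is `any block flagged OR archive failed verification`
(magic/version/frame-index/CRC-32). A corrupt archive is a detection
outcome, never an exception.

Recovery is layered: flagged block j is rebuilt from the means stored in its
holder π⁻¹(j) when the holder is unflagged (each pixel's 6 MSBs become its
sub-block's stored mean — approximate by construction; exact MSB recovery
cannot fit the embedding capacity); blocks whose holder is also flagged are
listed unrecoverable and left as-is. Finally, if the archive verified, every
LSB plane is restored to its pre-embedding bits — which is why
authenticate∘embed on an untampered stack is the bit-exact identity.

## Parallel execution

Frames are independent, so the stack is an embarrassingly parallel workload:
`partition_frames` cuts F frames into min(workers, F) contiguous chunks
whose sizes are ⌈F/C⌉ for the first F mod C chunks and ⌊F/C⌋ for the rest
(30 on 4 → 8,8,7,7; 15 on 4 → 4,4,4,3). Each chunk runs the frame operation
sequentially on its own process; results are keyed by frame number and
reassembled strictly in frame order, making parallel output bit-identical to
the sequential loop for every worker count — a property the test suite
asserts rather than assumes. Jobs follow an explicit
pending → queued → running → finished/failed → deleted life cycle with
logged transitions; `queued` is retained for fidelity to batch schedulers
even though the local pool dequeues immediately, and multi-job queues with
promote/demote are out of scope (one job at a time). "auto" workers means
the detected core count capped at the frame count. `work_profile` exposes
per-worker frame and tampered-frame counts: tampered frames cost extra
recovery work, so the maximum per-worker tampered count is the
load-balance statistic for contiguous chunking (an even placement of 9
tampered frames over 4,4,4,3 chunks gives max 3; packing them into the
first 9 positions gives max 4).

## Metrics

MSE accumulates the squared differences in exact integer arithmetic before
one final division, so metric values cannot depend on summation order
across execution modes. PSNR uses peak = 255 — the bit-depth maximum, not
the observed frame maximum — because every self-consistent published
(MSE, PSNR) pair this package checks against satisfies
10·log₁₀(255²/MSE) exactly; PSNR is +∞ iff MSE = 0. Speedup is the plain
elapsed-time ratio (displayed rounded to 2 decimals); Amdahl's and
Gustafson's laws are provided as model curves. Wall-clock speedups are
hardware-bound and are deliberately not asserted anywhere.

## Synthetic data

The generator emulates a B-mode cine loop: a fan sector (apex top-centre,
default ≈ 40% of a 480×640 frame) containing a smooth phantom — background
echogenicity ≈ 130 with one hypoechoic and one hyperechoic ellipse that
drift sinusoidally across frames — multiplied by unit-mean gamma speckle
whose shape parameter is set so the ROI intensity variance is ≈ 1600
(σ ≈ 40); the RONI is constant near-black (level 4). These defaults were
chosen once as a realistic B-mode texture and, more importantly, to
reproduce the two statistics the design depends on: high-entropy ROI LSBs
and a perfectly compressible RONI. What the generator does **not** emulate:
beam-physics (attenuation, shadowing, side lobes), vendor overlays and
annotations burned into the RONI, or interlaced/compressed acquisitions. A
vendor stack with a busy RONI would compress worse and could legitimately
fail the capacity check — passing tests on the phantom demonstrate the
mechanism, not universal capacity headroom.

Tamper modes emulate manual edits: constant fill, noise, copy-from-frame,
and an LSB-only mode for payload-corruption experiments. A tamper that
would leave the listed region unchanged is forced to differ (or rejected),
so "k frames tampered" always means k frames actually differ.

## Numerical and design choices

* CRC-16/CCITT (poly 0x1021, init 0xFFFF) for block codes; CRC-32 for the
  archive; deflate level 9 for the archive body. Any consistent choice
  would work; these are fixed for interoperability.
* Quantized means use floor division (sum // 4): deterministic, bias < 1
  LSB of the 6-bit scale.
* Block tiling is the regular block_size grid intersected with the ROI
  (tiles wholly inside, raster order); ROI pixels outside full blocks keep
  their original LSBs and are covered by the archive only.
* All randomness derives from named seeds: the watermark key drives π; the
  fixture seed drives phantom and speckle. There is no hidden global state.
* Problem sizes in the test suite: the full study condition (15 frames of
  480×640) is used for the detection ladder, reversibility and fidelity
  checks; mode-equivalence across worker counts runs on a 15-frame 320×240
  stack, and unit tests use 6-frame 96×128 stacks — the properties checked
  are size-invariant.

## Known limitations

* Recovery is approximate (2×2 means of 6-MSB content) and fails for a
  block whose holder is also tampered; wholesale ROI destruction leaves
  only detection plus archive-based LSB restoration.
* A forger knowing key, config and scheme could re-embed consistently;
  fragile watermarking is integrity protection against editing, not a
  cryptographic signature scheme.
* Detection is per-block (8×8 granularity); sub-pixel provenance and
  forensic attribution are out of scope.
* Only 8-bit grayscale uncompressed DICOM is supported.
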