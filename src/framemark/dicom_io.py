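"""Read and write multiframe 8-bit grayscale DICOM image stacks.

Pixel data is stored uncompressed (Explicit VR Little Endian) so that the
least-significant bit planes — which carry the fragile watermark — survive a
write/read round trip bit-exactly. Only ``PixelData`` and the geometry
attributes that describe it are rewritten; every other attribute of a source
dataset is passed through untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, UltrasoundMultiFrameImageStorage, generate_uid

__all__ = [
    "ImageStack",
    "FormatError",
    "UnsupportedFormatError",
    "read_stack",
    "write_stack",
]


class FormatError(ValueError):
    """The file is not decodable as multiframe grayscale pixel data."""


class UnsupportedFormatError(FormatError):
    """The file decodes but is not 8-bit single-sample grayscale."""


@dataclass
class ImageStack:
    """An ordered stack of equally sized 8-bit grayscale frames.

    ``frames`` is a ``(frame_count, height, width)`` uint8 array; ``meta``
    carries opaque pass-through attributes (for stacks read from DICOM it
    holds the source :class:`pydicom.dataset.Dataset` under ``"dataset"``).
    Frames are indexed 0-based internally; user-facing reports are 1-based.
    """

    frames: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.asarray(self.frames)
        if arr.ndim == 2:
            arr = arr[np.newaxis]
        if arr.ndim != 3:
            raise ValueError(f"frames must be (F, H, W), got shape {arr.shape}")
        if arr.shape[0] < 1:
            raise ValueError("a stack must contain at least one frame")
        if arr.size == 0:
            raise ValueError("frames must be non-empty")
        if arr.dtype != np.uint8:
            if np.issubdtype(arr.dtype, np.integer) and arr.min() >= 0 and arr.max() <= 255:
                arr = arr.astype(np.uint8)
            else:
                raise ValueError("pixel values must be integers in [0, 255]")
        self.frames = arr

    @property
    def frame_count(self) -> int:
        return int(self.frames.shape[0])

    @property
    def height(self) -> int:
        return int(self.frames.shape[1])

    @property
    def width(self) -> int:
        return int(self.frames.shape[2])

    @property
    def bits_per_pixel(self) -> int:
        return 8

    def copy(self) -> "ImageStack":
        return ImageStack(self.frames.copy(), dict(self.meta))

    def __eq__(self, other: object) -> bool:  # bit-exact comparison
        if not isinstance(other, ImageStack):
            return NotImplemented
        return self.frames.shape == other.frames.shape and bool(
            np.array_equal(self.frames, other.frames)
        )


def read_stack(path: str | Path) -> ImageStack:
    """Read a multiframe 8-bit grayscale DICOM file into an :class:`ImageStack`.

    Raises :class:`FormatError` if pixel data is missing or undecodable and
    :class:`UnsupportedFormatError` for non-8-bit or non-grayscale images.
    """
    try:
        ds = pydicom.dcmread(str(path))
    except Exception as exc:  # pydicom raises several unrelated types here
        raise FormatError(f"cannot read DICOM file {path!r}: {exc}") from exc
    if "PixelData" not in ds:
        raise FormatError(f"{path!r} contains no pixel data")
    if int(ds.get("BitsAllocated", 0)) != 8 or int(ds.get("BitsStored", 8)) != 8:
        raise UnsupportedFormatError(
            f"{path!r}: only 8 bits allocated/stored supported, "
            f"got {ds.get('BitsAllocated')}/{ds.get('BitsStored')}"
        )
    if int(ds.get("SamplesPerPixel", 1)) != 1 or not str(
        ds.get("PhotometricInterpretation", "MONOCHROME2")
    ).startswith("MONOCHROME"):
        raise UnsupportedFormatError(f"{path!r}: only single-sample grayscale supported")
    try:
        arr = ds.pixel_array
    except Exception as exc:
        raise FormatError(f"{path!r}: undecodable pixel data: {exc}") from exc
    if arr.ndim == 2:
        arr = arr[np.newaxis]
    return ImageStack(arr.astype(np.uint8), meta={"dataset": ds, "path": str(path)})


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write *stack* as an uncompressed multiframe grayscale DICOM file.

    If the stack was read from DICOM, all non-pixel attributes of the source
    dataset are preserved; otherwise a minimal ultrasound multiframe dataset
    is created. Returns the path written.
    """
    if not isinstance(stack, ImageStack):
        stack = ImageStack(np.asarray(stack))
    path = Path(path)

    src = stack.meta.get("dataset")
    if isinstance(src, Dataset):
        ds = src.copy()
        file_meta = FileMetaDataset()
        if getattr(src, "file_meta", None) is not None:
            for elem in src.file_meta:
                file_meta.add(elem)
    else:
        file_meta = FileMetaDataset()
        ds = FileDataset(str(path), {}, file_meta=file_meta, preamble=b"\0" * 128)
        ds.SOPClassUID = UltrasoundMultiFrameImageStorage
        ds.SOPInstanceUID = generate_uid()
        ds.Modality = "US"
        ds.PatientName = ""
        ds.PatientID = ""
    file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
    file_meta.MediaStorageSOPClassUID = ds.get("SOPClassUID", UltrasoundMultiFrameImageStorage)
    file_meta.MediaStorageSOPInstanceUID = ds.get("SOPInstanceUID", generate_uid())

    ds.file_meta = file_meta
    ds.Rows = stack.height
    ds.Columns = stack.width
    ds.NumberOfFrames = stack.frame_count
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 8
    ds.BitsStored = 8
    ds.HighBit = 7
    ds.PixelRepresentation = 0
    payload = stack.frames.tobytes()
    if len(payload) % 2:  # DICOM values must have even length
        payload += b"\0"
    ds.PixelData = payload
    ds["PixelData"].VR = "OB"
    ds.save_as(str(path), enforce_file_format=True)
    return path
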