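"""Readers and writers for the pipeline's on-disk artifacts.

Everything the pipeline touches on disk goes through this module: grayscale
channel TIFFs (one file per fluorescence plane), integer label-mask TIFFs
(the digitized cell boundaries), the study manifest CSV, and measurement
tables. Readers validate strictly and never rescale intensities — a ratio
computed before a save/load cycle must equal the ratio computed after it.

Coordinates are 0-based ``(row, col)`` throughout.
"""

from __future__ import annotations

import dataclasses
import enum
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

#: Column order of the study manifest CSV.
MANIFEST_COLUMNS = [
    "sample_id",
    "group",
    "image_index",
    "green_path",
    "red_path",
    "mask_path",
]


class Channel(str, enum.Enum):
    """Fluorescence plane identity: FITC/green carries the target protein
    (NAIP), Texas Red carries the housekeeping reference (GAPDH)."""

    GREEN_NAIP = "green_NAIP"
    RED_GAPDH = "red_GAPDH"


@dataclass
class ChannelImage:
    """One grayscale plane of one microscope field.

    Parameters
    ----------
    pixels
        2-D nonnegative integer array (uint8 or uint16).
    channel
        Which plane this is (:class:`Channel`).
    bit_depth
        8 or 16; all pixels must be ≤ ``2**bit_depth - 1``.
    field_id, sample_id
        Provenance tags; free text.
    """

    pixels: np.ndarray
    channel: Channel
    bit_depth: int = 16
    field_id: str = ""
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        self.channel = Channel(self.channel)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError(
                f"pixels must be a non-empty 2-D array, got shape {self.pixels.shape}"
            )
        if not np.issubdtype(self.pixels.dtype, np.integer):
            raise ValueError(f"pixels must be integer-valued, got {self.pixels.dtype}")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if self.pixels.min() < 0:
            raise ValueError("pixel values must be nonnegative")
        maxval = (1 << self.bit_depth) - 1
        if self.pixels.max() > maxval:
            raise ValueError(
                f"pixel value {self.pixels.max()} exceeds {self.bit_depth}-bit range"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class LabelMask:
    """Integer cell-label image: 0 is background, k > 0 is cell k.

    Labels may be any positive integers; gaps are allowed (cells excluded
    upstream simply leave holes in the label set).
    """

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2 or self.labels.size == 0:
            raise ValueError(
                f"labels must be a non-empty 2-D array, got shape {self.labels.shape}"
            )
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError(f"labels must be integer-valued, got {self.labels.dtype}")
        if self.labels.min() < 0:
            raise ValueError("labels must be nonnegative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def cell_ids(self) -> list[int]:
        """Sorted distinct nonzero labels."""
        ids = np.unique(self.labels)
        return [int(i) for i in ids if i != 0]


def read_channel_image(
    path: str | Path,
    expected_channel: Channel | str,
    *,
    sample_id: str = "",
    field_id: str = "",
) -> ChannelImage:
    """Load a single-plane grayscale TIFF without rescaling.

    Bit depth is inferred from the file's dtype; the channel tag comes from
    the caller (the file itself carries no channel metadata).
    """
    path = Path(path)
    try:
        arr = tifffile.imread(path)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read TIFF {path}: {exc}") from exc
    if arr.ndim != 2:
        raise ValueError(
            f"{path}: expected single-plane grayscale, got array of shape {arr.shape}"
        )
    if arr.dtype == np.uint8:
        bit_depth = 8
    elif arr.dtype == np.uint16:
        bit_depth = 16
    else:
        raise ValueError(f"{path}: unsupported pixel dtype {arr.dtype} (need uint8/uint16)")
    return ChannelImage(
        pixels=arr,
        channel=Channel(expected_channel),
        bit_depth=bit_depth,
        sample_id=sample_id,
        field_id=field_id,
    )


def write_channel_image(image: ChannelImage, path: str | Path) -> None:
    """Write a channel plane as plain grayscale TIFF (uint8/uint16)."""
    dtype = np.uint8 if image.bit_depth == 8 else np.uint16
    tifffile.imwrite(Path(path), image.pixels.astype(dtype))


def read_label_mask(path: str | Path, expected_shape: tuple[int, int] | None = None) -> LabelMask:
    """Load an integer label mask, checking its shape against the paired images."""
    path = Path(path)
    arr = tifffile.imread(path)
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected single-plane label mask, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError(f"{path}: label mask must be integer-valued, got {arr.dtype}")
    if arr.min() < 0:
        raise ValueError(f"{path}: label mask contains negative labels")
    if expected_shape is not None and tuple(arr.shape) != tuple(expected_shape):
        raise ValueError(
            f"{path}: mask shape {tuple(arr.shape)} does not match expected {tuple(expected_shape)}"
        )
    return LabelMask(labels=arr.astype(np.int64))


def write_label_mask(mask: LabelMask, path: str | Path) -> None:
    if mask.labels.max(initial=0) > np.iinfo(np.uint16).max:
        raise ValueError("label ids exceed uint16 range")
    tifffile.imwrite(Path(path), mask.labels.astype(np.uint16))


# ---------------------------------------------------------------------------
# study manifest


def write_manifest(rows: pd.DataFrame, path: str | Path) -> None:
    """Write the manifest CSV with the canonical column order."""
    missing = [c for c in MANIFEST_COLUMNS if c not in rows.columns]
    if missing:
        raise ValueError(f"manifest is missing columns {missing}")
    rows[MANIFEST_COLUMNS].to_csv(path, index=False)


def read_manifest(path: str | Path, *, check_paths: bool = True) -> pd.DataFrame:
    """Load a study manifest; path columns are resolved relative to the
    manifest's own directory and (optionally) checked for existence."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"sample_id": str, "group": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: manifest missing columns {missing}")
    dup = df.duplicated(subset=["sample_id", "image_index"])
    if dup.any():
        bad = df.loc[dup, ["sample_id", "image_index"]].iloc[0]
        raise ValueError(
            f"{path}: duplicate (sample_id, image_index) = "
            f"({bad['sample_id']}, {bad['image_index']})"
        )
    root = path.parent
    for col in ("green_path", "red_path", "mask_path"):
        resolved = df[col].map(lambda p: str((root / p).resolve()) if not Path(p).is_absolute() else p)
        if check_paths:
            for p in resolved:
                if not Path(p).exists():
                    raise FileNotFoundError(f"{path}: manifest references missing file {p}")
        df[col] = resolved
    return df


# ---------------------------------------------------------------------------
# measurement tables

#: 17 significant digits: lossless round-trip for IEEE doubles.
_FLOAT_FORMAT = "%.17g"


def write_measurements(rows: list, path: str | Path, *, kind: str = "cells") -> None:
    """Write per-cell measurements or sample summaries as CSV.

    ``rows`` must be homogeneous dataclass instances (CellMeasurement or
    SampleSummary). For an empty list, ``kind`` ("cells" or "samples")
    selects which header to emit. Floats are written with full precision so
    a read-back reproduces every ratio bit-for-bit.
    """
    from . import quantify  # local import: quantify depends on this module

    headers = {
        "cells": [f.name for f in dataclasses.fields(quantify.CellMeasurement)],
        "samples": [f.name for f in dataclasses.fields(quantify.SampleSummary)],
    }
    if rows:
        first_type = type(rows[0])
        if any(type(r) is not first_type for r in rows):
            raise ValueError("mixed row types in measurement table")
        if not dataclasses.is_dataclass(rows[0]):
            raise ValueError(f"rows must be dataclasses, got {first_type.__name__}")
        df = pd.DataFrame([dataclasses.asdict(r) for r in rows])
    else:
        if kind not in headers:
            raise ValueError(f"kind must be 'cells' or 'samples', got {kind!r}")
        df = pd.DataFrame(columns=headers[kind])
    df.to_csv(path, index=False, float_format=_FLOAT_FORMAT)


def read_measurements(path: str | Path) -> pd.DataFrame:
    """Read back a measurement table written by :func:`write_measurements`."""
    return pd.read_csv(
        path,
        dtype={"sample_id": str, "field_id": str, "group_label": str},
        float_precision="round_trip",
    )
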