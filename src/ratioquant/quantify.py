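"""Per-cell ratio measurement and per-sample summaries.

The core quantity is the per-cell expression ratio

    ratio = mean green (NAIP) pixel intensity over the cell
            -----------------------------------------------
            mean red (GAPDH) pixel intensity over the same cell

computed over exactly the pixels carrying that cell's label, with no
background subtraction by default. Dividing by the housekeeping channel
makes the ratio invariant to any common multiplicative gain (illumination,
exposure); an additive offset on both channels, by contrast, pulls ratios
toward 1 — which is why synthetic fixtures default to zero background.

A sample is summarized by the mean ratio (M.R) and sample standard
deviation (n−1 denominator) of a fixed-size random cell collection
(default 30 cells) pooled across all of the sample's fields.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as _cc_label

from .io import Channel, ChannelImage, LabelMask

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CellMeasurement:
    """One cell's channel means and ratio."""

    sample_id: str
    field_id: str
    cell_id: int
    green_mean: float
    red_mean: float
    ratio: float
    n_pixels: int


@dataclass(frozen=True)
class SampleSummary:
    """A sample's cell-collection mean ratio (M.R) and SD."""

    sample_id: str
    group_label: str
    n_cells: int
    mean_ratio: float
    sd_ratio: float


def measure_cell(
    green: ChannelImage,
    red: ChannelImage,
    mask: LabelMask,
    cell_id: int,
    *,
    min_cell_area: int = 1,
) -> CellMeasurement | None:
    """Measure one labelled cell; returns None if the cell is excluded.

    Exclusion (with a logged warning) happens when the red (housekeeping)
    mean is zero — the cell carries no reference signal — or when the cell
    is smaller than ``min_cell_area`` pixels. A ``cell_id`` absent from the
    mask is a caller error and raises.
    """
    if green.shape != red.shape or green.shape != mask.shape:
        raise ValueError(
            f"shape mismatch: green {green.shape}, red {red.shape}, mask {mask.shape}"
        )
    sel = mask.labels == cell_id
    n_pixels = int(sel.sum())
    if n_pixels == 0:
        raise ValueError(f"cell_id {cell_id} not present in mask")
    if n_pixels < min_cell_area:
        logger.warning(
            "sample %s field %s cell %d excluded: area %d < min_cell_area %d",
            green.sample_id, green.field_id, cell_id, n_pixels, min_cell_area,
        )
        return None
    green_mean = float(green.pixels[sel].mean(dtype=np.float64))
    red_mean = float(red.pixels[sel].mean(dtype=np.float64))
    if red_mean == 0.0:
        logger.warning(
            "sample %s field %s cell %d excluded: red (housekeeping) mean is zero",
            green.sample_id, green.field_id, cell_id,
        )
        return None
    return CellMeasurement(
        sample_id=green.sample_id,
        field_id=green.field_id,
        cell_id=cell_id,
        green_mean=green_mean,
        red_mean=red_mean,
        ratio=green_mean / red_mean,
        n_pixels=n_pixels,
    )


def measure_field(
    green: ChannelImage,
    red: ChannelImage,
    mask: LabelMask,
    *,
    min_cell_area: int = 1,
    exclude_border: bool = True,
) -> list[CellMeasurement]:
    """Measure every labelled cell in a field (vectorized over labels).

    Cells touching the image border are excluded by default: their pixel
    means are biased by truncation of the cell footprint.
    """
    if green.shape != red.shape or green.shape != mask.shape:
        raise ValueError(
            f"shape mismatch: green {green.shape}, red {red.shape}, mask {mask.shape}"
        )
    lab = mask.labels
    border_ids: set[int] = set()
    if exclude_border:
        border = np.concatenate([lab[0, :], lab[-1, :], lab[:, 0], lab[:, -1]])
        border_ids = {int(i) for i in np.unique(border) if i != 0}
        if border_ids:
            logger.warning(
                "sample %s field %s: excluding %d border-touching cell(s)",
                green.sample_id, green.field_id, len(border_ids),
            )
    flat = lab.ravel()
    counts = np.bincount(flat)
    gsums = np.bincount(flat, weights=green.pixels.ravel().astype(np.float64))
    rsums = np.bincount(flat, weights=red.pixels.ravel().astype(np.float64))
    out: list[CellMeasurement] = []
    for cid in np.nonzero(counts)[0]:
        cid = int(cid)
        if cid == 0 or cid in border_ids:
            continue
        n = int(counts[cid])
        if n < min_cell_area:
            logger.warning(
                "sample %s field %s cell %d excluded: area %d < min_cell_area %d",
                green.sample_id, green.field_id, cid, n, min_cell_area,
            )
            continue
        rmean = rsums[cid] / n
        if rmean == 0.0:
            logger.warning(
                "sample %s field %s cell %d excluded: red (housekeeping) mean is zero",
                green.sample_id, green.field_id, cid,
            )
            continue
        gmean = gsums[cid] / n
        out.append(
            CellMeasurement(
                sample_id=green.sample_id,
                field_id=green.field_id,
                cell_id=cid,
                green_mean=float(gmean),
                red_mean=float(rmean),
                ratio=float(gmean / rmean),
                n_pixels=n,
            )
        )
    return out


def segment_cells(red: ChannelImage, *, min_cell_area: int = 20) -> LabelMask:
    """Automated stand-in for manual cell delineation.

    Global Otsu threshold on the red (housekeeping) plane — present in every
    cell by assumption — then 8-connected components, removal of components
    below ``min_cell_area``, and relabelling in raster order. A blank field
    yields an empty mask, not an error.
    """
    arr = red.pixels
    if arr.min() == arr.max():
        return LabelMask(np.zeros(arr.shape, dtype=np.int64))
    thr = threshold_otsu(arr)
    binary = arr > thr
    lab = _cc_label(binary, connectivity=2)
    counts = np.bincount(lab.ravel())
    keep = np.nonzero(counts >= min_cell_area)[0]
    keep = keep[keep != 0]
    out = np.zeros_like(lab, dtype=np.int64)
    # raster-order relabelling: sort surviving components by first pixel
    flat = lab.ravel()
    order = []
    for cid in keep:
        order.append((int(np.argmax(flat == cid)), int(cid)))
    for new_id, (_, old_id) in enumerate(sorted(order), start=1):
        out[lab == old_id] = new_id
    return LabelMask(out)


def subtract_background(image: ChannelImage, *, size: int = 50) -> ChannelImage:
    """Optional rolling-minimum background subtraction (off by default)."""
    from scipy.ndimage import minimum_filter

    bg = minimum_filter(image.pixels, size=size)
    pixels = (image.pixels.astype(np.int64) - bg).clip(min=0)
    dtype = np.uint8 if image.bit_depth == 8 else np.uint16
    return ChannelImage(
        pixels.astype(dtype), image.channel, image.bit_depth, image.field_id, image.sample_id
    )


def select_cell_collection(
    measurements: list[CellMeasurement],
    k: int = 30,
    seed: int | np.random.Generator = 0,
) -> list[CellMeasurement]:
    """Draw the fixed-size cell collection for a sample.

    Uniform random subset of size ``k`` without replacement across all the
    sample's fields, reproducible from ``seed``. With fewer than ``k`` cells
    available, all cells are returned and a shortfall warning is logged.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if not measurements:
        raise ValueError("no measurements to select from: sample unanalyzable")
    if len(measurements) <= k:
        if len(measurements) < k:
            logger.warning(
                "sample %s: only %d cells available for a %d-cell collection",
                measurements[0].sample_id, len(measurements), k,
            )
        return list(measurements)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.choice(len(measurements), size=k, replace=False)
    return [measurements[i] for i in sorted(int(i) for i in idx)]


def summarize_sample(
    collection: list[CellMeasurement], group_label: str = ""
) -> SampleSummary:
    """Sample summary: M.R (arithmetic mean of ratios) and SD (n−1).

    A single-cell collection gets SD 0 by convention (with a warning);
    mixing cells from multiple samples is an error.
    """
    if not collection:
        raise ValueError("cannot summarize an empty collection")
    sample_ids = {m.sample_id for m in collection}
    if len(sample_ids) > 1:
        raise ValueError(f"collection mixes cells from samples {sorted(sample_ids)}")
    ratios = np.array([m.ratio for m in collection], dtype=np.float64)
    n = len(ratios)
    if n == 1:
        logger.warning("sample %s: single-cell collection, SD set to 0", collection[0].sample_id)
        sd = 0.0
    else:
        sd = float(ratios.std(ddof=1))
    return SampleSummary(
        sample_id=collection[0].sample_id,
        group_label=group_label,
        n_cells=n,
        mean_ratio=float(ratios.mean()),
        sd_ratio=sd,
    )
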