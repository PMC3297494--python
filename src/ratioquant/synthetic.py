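"""Synthetic two-channel micrograph generator with per-cell ground truth.

The forward model emulates dual-stained lymph-node fields: elliptical cells
on a dark background, a red (Texas Red / GAPDH) plane whose in-cell level is
approximately constant across cells of a sample (housekeeping assumption),
and a green (FITC / NAIP) plane whose in-cell level equals a per-cell true
expression ratio times that cell's red level. Per-pixel noise is additive
Gaussian by default (an optional Poisson mode models shot noise). Every
draw is reproducible from ``(seed, sample_id, image_index)``, so samples
are independent and order-insensitive.

Because output images are integer-valued (8/16-bit TIFF), each cell's
levels are quantized at generation time: the red level is rounded to an
integer ``r`` and the green level to ``g = round(ratio_draw * r)``, and the
stored ground truth is ``true_ratio = g / r``. On a noise-free, zero-offset
field the measured per-cell ratio then equals the stored truth to floating-
point rounding.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.draw import ellipse as _draw_ellipse

from .io import (
    Channel,
    ChannelImage,
    LabelMask,
    write_channel_image,
    write_label_mask,
    write_manifest,
)

logger = logging.getLogger(__name__)

#: rejection-sampling budget per cell before declaring the field too crowded
_MAX_PLACEMENT_ATTEMPTS = 500

# sub-stream tags, so truth draws, pixel noise and collection sampling are
# independent streams under the same (seed, sample_id, image_index) key
_STAGE_TRUTHS = 0
_STAGE_RENDER = 1
_STAGE_COLLECTION = 2


@dataclass(frozen=True)
class SyntheticSampleSpec:
    """Generator parameters for one sample (one tissue block).

    ``true_mean_ratio`` / ``between_cell_sd`` define the truncated-normal
    distribution of per-cell expression ratios; ``red_mean_level`` /
    ``red_cell_cv`` the housekeeping channel level and its cell-to-cell
    coefficient of variation. ``background_level`` (both channels) and
    ``pixel_noise_sd`` are in intensity units of the chosen bit depth.
    """

    sample_id: str
    group_label: str = ""
    n_images: int = 20
    cells_per_image: int = 10
    true_mean_ratio: float = 0.6
    between_cell_sd: float = 0.05
    red_mean_level: float = 1000.0
    red_cell_cv: float = 0.10
    background_level: float = 0.0
    pixel_noise_sd: float = 20.0
    image_shape: tuple[int, int] = (256, 256)
    cell_radius_range: tuple[float, float] = (6.0, 12.0)
    bit_depth: int = 16
    noise_model: str = "gaussian"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")
        if self.n_images < 1:
            raise ValueError("n_images must be a positive integer")
        if self.cells_per_image < 0:
            raise ValueError("cells_per_image must be >= 0")
        if self.true_mean_ratio <= 0:
            raise ValueError("true_mean_ratio must be positive")
        for name in ("between_cell_sd", "red_cell_cv", "background_level", "pixel_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.between_cell_sd >= self.true_mean_ratio:
            raise ValueError(
                "between_cell_sd must be < true_mean_ratio (keeps truncated draws positive)"
            )
        if self.red_mean_level <= 0:
            raise ValueError("red_mean_level must be positive")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if self.noise_model not in ("gaussian", "poisson"):
            raise ValueError("noise_model must be 'gaussian' or 'poisson'")
        rmin, rmax = self.cell_radius_range
        if not (0 < rmin <= rmax):
            raise ValueError("cell_radius_range must satisfy 0 < min <= max")
        h, w = self.image_shape
        if 2 * rmax + 2 >= min(h, w):
            raise ValueError(
                f"cell_radius_range {self.cell_radius_range} does not fit inside "
                f"image_shape {self.image_shape}"
            )

    def replace(self, **changes) -> "SyntheticSampleSpec":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class CellTruth:
    """Ground truth for one rendered cell (unobservable in real slides)."""

    cell_id: int
    center: tuple[float, float]  # (row, col)
    radii: tuple[float, float]  # (r_row, r_col)
    true_ratio: float
    true_red_level: float


def _sample_key(sample_id: str) -> int:
    """Stable 32-bit hash of the sample id (platform-independent)."""
    return int.from_bytes(hashlib.sha256(sample_id.encode()).digest()[:4], "big")


def _rng(spec: SyntheticSampleSpec, image_index: int, stage: int) -> np.random.Generator:
    ss = np.random.SeedSequence(
        [spec.seed % (1 << 32), _sample_key(spec.sample_id), image_index, stage]
    )
    return np.random.default_rng(ss)


def sample_rng(spec: SyntheticSampleSpec, stage: int = _STAGE_COLLECTION) -> np.random.Generator:
    """Per-sample stream (not tied to any one image); used for collection draws."""
    return _rng(spec, image_index=1 << 20, stage=stage)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    """Normal(mean, sd) truncated at 0 by redraw; exact point mass if sd == 0."""
    if sd == 0:
        return np.full(n, mean, dtype=float)
    out = rng.normal(mean, sd, size=n)
    bad = out <= 0
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = out <= 0
    return out


def draw_cell_truths(spec: SyntheticSampleSpec, image_index: int) -> list[CellTruth]:
    """Draw per-cell ground truth for one field and place the cells.

    Cells are non-overlapping ellipses placed by rejection sampling, fully
    inside the image. Per-cell ratios come from a truncated normal
    ``N(true_mean_ratio, between_cell_sd)``, red levels from
    ``N(red_mean_level, red_cell_cv * red_mean_level)``, both truncated at 0
    and then quantized to the integer pixel grid (see module docstring).
    """
    if image_index < 0 or image_index >= spec.n_images:
        raise ValueError(f"image_index {image_index} out of range [0, {spec.n_images})")
    n = spec.cells_per_image
    if n == 0:
        return []
    rng = _rng(spec, image_index, _STAGE_TRUTHS)
    h, w = spec.image_shape
    rmin, rmax = spec.cell_radius_range

    ratios = _truncated_normal(rng, spec.true_mean_ratio, spec.between_cell_sd, n)
    reds = _truncated_normal(
        rng, spec.red_mean_level, spec.red_cell_cv * spec.red_mean_level, n
    )
    # quantize to the integer pixel grid so stored truth == rendered signal
    red_int = np.maximum(1, np.rint(reds)).astype(int)
    green_int = np.rint(ratios * red_int).astype(int)
    true_ratios = green_int / red_int
    radii = rng.uniform(rmin, rmax, size=(n, 2))

    truths: list[CellTruth] = []
    placed: list[tuple[float, float, float]] = []  # (row, col, bounding radius)
    for i in range(n):
        r_row, r_col = radii[i]
        bound = max(r_row, r_col)
        ok = False
        for _ in range(_MAX_PLACEMENT_ATTEMPTS):
            cr = rng.uniform(r_row + 1, h - 1 - r_row - 1)
            cc = rng.uniform(r_col + 1, w - 1 - r_col - 1)
            if all(
                (cr - pr) ** 2 + (cc - pc) ** 2 > (bound + pb + 1.0) ** 2
                for pr, pc, pb in placed
            ):
                ok = True
                break
        if not ok:
            raise RuntimeError(
                f"could not place cell {i + 1}/{n} after {_MAX_PLACEMENT_ATTEMPTS} "
                f"attempts for sample {spec.sample_id!r} image {image_index} "
                f"(image_shape={spec.image_shape}, cell_radius_range="
                f"{spec.cell_radius_range}); the field is too crowded"
            )
        placed.append((cr, cc, bound))
        truths.append(
            CellTruth(
                cell_id=i + 1,
                center=(float(cr), float(cc)),
                radii=(float(r_row), float(r_col)),
                true_ratio=float(true_ratios[i]),
                true_red_level=float(red_int[i]),
            )
        )
    return truths


def render_field(
    truths: list[CellTruth],
    spec: SyntheticSampleSpec,
    *,
    image_index: int = 0,
) -> tuple[ChannelImage, ChannelImage, LabelMask]:
    """Render one field: (green plane, red plane, label mask).

    Inside cell i the noise-free red value is ``true_red_level_i +
    background_level`` and the green value ``true_ratio_i * true_red_level_i
    + background_level``; outside cells both planes sit at
    ``background_level``. Per-pixel noise is then added (Gaussian SD
    ``pixel_noise_sd``, or Poisson when ``noise_model='poisson'``) and the
    result is clipped to the bit-depth range and rounded. Clipping logs a
    warning with the clipped-pixel fraction.
    """
    h, w = spec.image_shape
    green = np.full((h, w), float(spec.background_level))
    red = np.full((h, w), float(spec.background_level))
    labels = np.zeros((h, w), dtype=np.int64)

    for t in truths:
        rr, cc = _draw_ellipse(t.center[0], t.center[1], t.radii[0], t.radii[1], shape=(h, w))
        red[rr, cc] = t.true_red_level + spec.background_level
        green[rr, cc] = t.true_ratio * t.true_red_level + spec.background_level
        labels[rr, cc] = t.cell_id

    rng = _rng(spec, image_index, _STAGE_RENDER)
    if spec.noise_model == "poisson":
        green = rng.poisson(np.maximum(green, 0)).astype(float)
        red = rng.poisson(np.maximum(red, 0)).astype(float)
    elif spec.pixel_noise_sd > 0:
        green = green + rng.normal(0.0, spec.pixel_noise_sd, size=(h, w))
        red = red + rng.normal(0.0, spec.pixel_noise_sd, size=(h, w))

    maxval = (1 << spec.bit_depth) - 1
    # negative excursions floor at the sensor's dark level silently; only
    # saturation above the bit-depth maximum distorts in-cell means
    n_overflow = int((green > maxval).sum() + (red > maxval).sum())
    if n_overflow:
        frac = n_overflow / (2 * h * w)
        logger.warning(
            "sample %s image %d: %.3f%% of pixels overflow the %d-bit range (clipped)",
            spec.sample_id,
            image_index,
            100 * frac,
            spec.bit_depth,
        )
    dtype = np.uint8 if spec.bit_depth == 8 else np.uint16
    green_q = np.rint(np.clip(green, 0, maxval)).astype(dtype)
    red_q = np.rint(np.clip(red, 0, maxval)).astype(dtype)

    fid = f"{image_index:03d}"
    return (
        ChannelImage(green_q, Channel.GREEN_NAIP, spec.bit_depth, fid, spec.sample_id),
        ChannelImage(red_q, Channel.RED_GAPDH, spec.bit_depth, fid, spec.sample_id),
        LabelMask(labels),
    )


def generate_field(
    spec: SyntheticSampleSpec, image_index: int
) -> tuple[list[CellTruth], ChannelImage, ChannelImage, LabelMask]:
    """Convenience: draw truths and render, for one field."""
    truths = draw_cell_truths(spec, image_index)
    green, red, mask = render_field(truths, spec, image_index=image_index)
    return truths, green, red, mask


def generate_study(specs: list[SyntheticSampleSpec], output_dir: str | Path) -> pd.DataFrame:
    """Write a full synthetic study to disk and return its manifest.

    Per sample, ``n_images`` triples ``<sample>_<image#>_{green|red|mask}.tif``
    are written, plus ``manifest.csv`` and ``study_config.json`` (every spec
    parameter including seeds) so the study can be regenerated exactly.
    """
    ids = [s.sample_id for s in specs]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise ValueError(f"duplicate sample_id(s): {sorted(dupes)}")

    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for spec in specs:
        for idx in range(spec.n_images):
            truths = draw_cell_truths(spec, idx)
            green, red, mask = render_field(truths, spec, image_index=idx)
            gname = f"{spec.sample_id}_{idx:03d}_green.tif"
            rname = f"{spec.sample_id}_{idx:03d}_red.tif"
            mname = f"{spec.sample_id}_{idx:03d}_mask.tif"
            write_channel_image(green, outdir / gname)
            write_channel_image(red, outdir / rname)
            write_label_mask(mask, outdir / mname)
            rows.append(
                {
                    "sample_id": spec.sample_id,
                    "group": spec.group_label,
                    "image_index": idx,
                    "green_path": gname,
                    "red_path": rname,
                    "mask_path": mname,
                }
            )
    manifest = pd.DataFrame(rows)
    write_manifest(manifest, outdir / "manifest.csv")
    config = [
        {
            **dataclasses.asdict(s),
            "image_shape": list(s.image_shape),
            "cell_radius_range": list(s.cell_radius_range),
        }
        for s in specs
    ]
    (outdir / "study_config.json").write_text(json.dumps(config, indent=2))
    logger.info("wrote %d field triples for %d samples to %s", len(rows), len(specs), outdir)
    return manifest


def build_group_specs(
    groups: list[dict],
    *,
    seed: int,
    sample_defaults: dict | None = None,
) -> list[SyntheticSampleSpec]:
    """Expand group-level definitions into per-sample specs.

    Each group dict has ``label``, ``n_samples``, ``mean_ratio`` and
    ``between_sample_sd``; per-sample true mean ratios are drawn (seeded)
    from ``N(mean_ratio, between_sample_sd)`` truncated at 0, modelling
    biological variation between tissue blocks of the same diagnostic group.
    ``sample_defaults`` overrides any :class:`SyntheticSampleSpec` field.
    """
    defaults = dict(sample_defaults or {})
    specs: list[SyntheticSampleSpec] = []
    for grp in groups:
        label = grp["label"]
        n_samples = int(grp["n_samples"])
        mean = float(grp["mean_ratio"])
        sd = float(grp.get("between_sample_sd", 0.0))
        rng = np.random.default_rng(
            np.random.SeedSequence([seed % (1 << 32), _sample_key(label), 0])
        )
        means = _truncated_normal(rng, mean, sd, n_samples)
        for i in range(n_samples):
            kwargs = dict(defaults)
            kwargs.update(grp.get("sample_overrides", {}))
            if "image_shape" in kwargs:
                kwargs["image_shape"] = tuple(kwargs["image_shape"])
            if "cell_radius_range" in kwargs:
                kwargs["cell_radius_range"] = tuple(kwargs["cell_radius_range"])
            specs.append(
                SyntheticSampleSpec(
                    sample_id=f"{label}_{i:03d}",
                    group_label=label,
                    true_mean_ratio=float(means[i]),
                    seed=seed,
                    **kwargs,
                )
            )
    return specs
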