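"""Published study layout used as default simulation conditions.

The source study measured NAIP/GAPDH mean ratios (M.R ± SD over samples)
in 101 FFPE lymph-node blocks: 39 Hodgkin lymphoma (HL), 23 non-Hodgkin
lymphoma (NHL: 6 follicular, 17 high-grade DLBCL/ALCL), 30 normal and 9
reactive lymphoid hyperplasia (RLH) nodes, with 20–30 fields per sample
and a 30-cell collection per sample. These printed numbers are inputs: the
synthetic generator uses them as group-level truths, and the summary-level
t-tests consume them directly.
"""

from __future__ import annotations

import numpy as np

from .stats import ContingencyTable

#: Printed group summaries: label -> (n_samples, mean M.R, between-sample SD).
PRINTED_GROUPS: dict[str, tuple[int, float, float]] = {
    "HL": (39, 0.5834, 0.021),
    "NHL": (23, 0.6040, 0.026),
    "FL": (6, 0.5886, 0.012),
    "NHL_high_grade": (17, 0.6095, 0.028),
    "normal": (30, 0.5882, 0.047),
    "RLH": (9, 0.6365, 0.017),
    "control": (39, 0.5987, 0.045),  # 30 normal + 9 RLH pooled
}

#: Clinical-feature count tables (rows HL, NHL).
TABLE_SEX = ContingencyTable(
    row_labels=["HL", "NHL"],
    col_labels=["male", "female"],
    counts=np.array([[21, 18], [17, 5]]),
)
TABLE_B_SYMPTOM = ContingencyTable(
    row_labels=["HL", "NHL"],
    col_labels=["positive", "negative"],
    counts=np.array([[14, 17], [11, 10]]),
)


def group_def(label: str, *, n_samples: int | None = None) -> dict:
    """Group definition for :func:`ratioquant.build_group_specs`."""
    n, mean, sd = PRINTED_GROUPS[label]
    return {
        "label": label,
        "n_samples": n_samples if n_samples is not None else n,
        "mean_ratio": mean,
        "between_sample_sd": sd,
    }


#: Per-sample generator conditions for the default synthetic studies:
#: 30-cell collections built from 3 fields x 10 cells, moderate noise
#: (pixel SD 30 against an in-cell red level of 1000, i.e. SNR ~ 33),
#: cell-to-cell ratio spread 0.05, zero background.
SIM_SAMPLE_DEFAULTS: dict = {
    "n_images": 3,
    "cells_per_image": 10,
    "between_cell_sd": 0.05,
    "red_mean_level": 1000.0,
    "red_cell_cv": 0.10,
    "background_level": 0.0,
    "pixel_noise_sd": 30.0,
    "image_shape": (128, 128),
    "cell_radius_range": (4.0, 8.0),
}
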