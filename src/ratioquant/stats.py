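"""Group-level hypothesis tests on sample mean ratios and clinical tables.

Two-sample t-tests (pooled by default, Welch optional), one-way ANOVA
across diagnostic groups, and χ²/Fisher tests on clinical-feature
contingency tables. All tests are two-sided and no multiple-testing
correction is applied; callers see raw p values plus the number of tests
performed. Tests can run either on raw sample M.R collections or directly
on printed summary statistics (n, mean, SD per group).

A null-calibration simulation (`type_one_error_sim`) checks the pooled t
layer against its nominal size using the synthetic generator's per-cell
ratio distribution.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .quantify import SampleSummary
from .synthetic import SyntheticSampleSpec, _truncated_normal

logger = logging.getLogger(__name__)

_T_METHODS = ("t_pooled", "t_welch")


@dataclass
class GroupComparison:
    """Result of one two-group or k-group test."""

    group_a: str
    group_b: str  # empty for k-group tests
    method: str  # t_pooled | t_welch | anova | chi_square | fisher_exact
    statistic: float
    df: float | tuple[float, float] | None
    p_value: float
    n_a: int
    n_b: int = 0


@dataclass
class ContingencyTable:
    """Labelled nonnegative-integer count grid (at least 2×2)."""

    row_labels: list[str]
    col_labels: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or min(self.counts.shape) < 2:
            raise ValueError(f"contingency table must be at least 2×2, got {self.counts.shape}")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.rint(self.counts)):
                raise ValueError("contingency counts must be integers")
            self.counts = np.rint(self.counts).astype(int)
        if self.counts.min() < 0:
            raise ValueError("contingency counts must be nonnegative")
        if len(self.row_labels) != self.counts.shape[0] or len(self.col_labels) != self.counts.shape[1]:
            raise ValueError("label lengths do not match table shape")


def read_contingency_csv(path: str | Path) -> ContingencyTable:
    """Read a labelled count grid: header row = column labels, first column = row labels."""
    df = pd.read_csv(path, index_col=0)
    return ContingencyTable(
        row_labels=[str(r) for r in df.index],
        col_labels=[str(c) for c in df.columns],
        counts=df.to_numpy(),
    )


def _values(side: Sequence) -> np.ndarray:
    vals = [v.mean_ratio if isinstance(v, SampleSummary) else float(v) for v in side]
    arr = np.asarray(vals, dtype=np.float64)
    if not np.isfinite(arr).all():
        raise ValueError("non-finite values in group")
    return arr


def _welch_df(s1: float, n1: int, s2: float, n2: int) -> float:
    v1, v2 = s1**2 / n1, s2**2 / n2
    return (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))


def t_test_groups(
    a: Sequence,
    b: Sequence,
    method: str = "t_pooled",
    *,
    group_a: str = "A",
    group_b: str = "B",
) -> GroupComparison:
    """Two-sided two-sample t-test on raw values or SampleSummary M.R values.

    ``t_pooled`` assumes a common variance (df = n_a + n_b − 2); ``t_welch``
    uses the Satterthwaite df. Two groups with zero variance and equal means
    give statistic 0, p 1 by convention.
    """
    if method not in _T_METHODS:
        raise ValueError(f"method must be one of {_T_METHODS}")
    x, y = _values(a), _values(b)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs n >= 2")
    df: float = len(x) + len(y) - 2 if method == "t_pooled" else _welch_df(
        x.std(ddof=1), len(x), y.std(ddof=1), len(y)
    )
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        if x.mean() == y.mean():
            return GroupComparison(group_a, group_b, method, 0.0, df, 1.0, len(x), len(y))
        logger.warning("zero variance in both groups with unequal means: p set to 0")
        return GroupComparison(group_a, group_b, method, float("inf"), df, 0.0, len(x), len(y))
    res = sps.ttest_ind(x, y, equal_var=(method == "t_pooled"))
    return GroupComparison(
        group_a, group_b, method,
        float(res.statistic), float(res.df), float(res.pvalue), len(x), len(y),
    )


def t_test_from_summaries(
    n1: int, m1: float, s1: float,
    n2: int, m2: float, s2: float,
    method: str = "t_pooled",
    *,
    group_a: str = "A",
    group_b: str = "B",
) -> GroupComparison:
    """t-test directly from printed summaries (n, mean, SD per group).

    Identical to :func:`t_test_groups` on any raw data with those exact
    summaries. ``±`` values printed in study reports are taken as SDs; a
    caller holding SEMs must convert (multiply by √n) first.
    """
    if method not in _T_METHODS:
        raise ValueError(f"method must be one of {_T_METHODS}")
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if s1 < 0 or s2 < 0:
        raise ValueError("SDs must be nonnegative")
    df: float = n1 + n2 - 2 if method == "t_pooled" else _welch_df(s1, n1, s2, n2)
    if s1 == 0 and s2 == 0:
        if m1 == m2:
            return GroupComparison(group_a, group_b, method, 0.0, df, 1.0, n1, n2)
        logger.warning("zero SDs with unequal means: infinite statistic, p set to 0")
        return GroupComparison(group_a, group_b, method, float("inf"), df, 0.0, n1, n2)
    res = sps.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=(method == "t_pooled"))
    return GroupComparison(
        group_a, group_b, method, float(res.statistic), df, float(res.pvalue), n1, n2
    )


def one_way_anova(
    groups: Sequence[Sequence], labels: Sequence[str] | None = None
) -> GroupComparison:
    """One-way fixed-effects ANOVA across k ≥ 2 groups of sample M.R values."""
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    arrs = [_values(g) for g in groups]
    for i, g in enumerate(arrs):
        if len(g) < 2:
            raise ValueError(f"group {i} has n < 2")
    pooled = np.concatenate(arrs)
    if pooled.std(ddof=0) == 0:
        raise ValueError("degenerate: zero total variance across all groups")
    res = sps.f_oneway(*arrs)
    k, n = len(arrs), len(pooled)
    name = "|".join(labels) if labels else f"{k} groups"
    return GroupComparison(
        group_a=name, group_b="", method="anova",
        statistic=float(res.statistic), df=(float(k - 1), float(n - k)),
        p_value=float(res.pvalue), n_a=n, n_b=0,
    )


def _as_counts(table: ContingencyTable | np.ndarray) -> tuple[np.ndarray, list[str], list[str]]:
    if isinstance(table, ContingencyTable):
        return table.counts, table.row_labels, table.col_labels
    arr = np.asarray(table)
    t = ContingencyTable(
        row_labels=[f"r{i}" for i in range(arr.shape[0])] if arr.ndim == 2 else [],
        col_labels=[f"c{j}" for j in range(arr.shape[1])] if arr.ndim == 2 else [],
        counts=arr,
    )
    return t.counts, t.row_labels, t.col_labels


def fisher_exact(table: ContingencyTable | np.ndarray) -> GroupComparison:
    """Two-sided Fisher exact test on a 2×2 table.

    p is the sum of hypergeometric probabilities (at fixed margins) no
    larger than that of the observed table. A zero margin admits only one
    table, so p = 1. Larger tables should use :func:`chi_square`.
    """
    counts, rows, cols = _as_counts(table)
    if counts.shape != (2, 2):
        raise ValueError(
            f"fisher_exact requires a 2×2 table (got {counts.shape}); use chi_square"
        )
    odds, p = sps.fisher_exact(counts, alternative="two-sided")
    statistic = float(odds) if np.isfinite(odds) else 1.0  # odds ratio undefined at a zero margin
    return GroupComparison(
        group_a=rows[0], group_b=rows[1], method="fisher_exact",
        statistic=statistic, df=None, p_value=float(p),
        n_a=int(counts[0].sum()), n_b=int(counts[1].sum()),
    )


def chi_square(table: ContingencyTable | np.ndarray) -> GroupComparison:
    """Pearson χ² test of independence (no continuity correction).

    Warns when any expected count is below 5 and recommends the exact test.
    """
    counts, rows, cols = _as_counts(table)
    if counts.sum(axis=1).min() == 0 or counts.sum(axis=0).min() == 0:
        raise ValueError("chi_square: table has a zero row or column sum")
    stat, p, df, expected = sps.chi2_contingency(counts, correction=False)
    if expected.min() < 5:
        warnings.warn(
            f"expected count {expected.min():.2f} < 5; consider fisher_exact",
            UserWarning,
            stacklevel=2,
        )
    return GroupComparison(
        group_a="|".join(rows), group_b="|".join(cols), method="chi_square",
        statistic=float(stat), df=float(df), p_value=float(p),
        n_a=int(counts.sum()), n_b=0,
    )


def _pooled_t_p(a: np.ndarray, b: np.ndarray, axis: int = -1) -> np.ndarray:
    """Vectorized two-sided pooled-t p values along ``axis``."""
    res = sps.ttest_ind(a, b, axis=axis, equal_var=True)
    return np.asarray(res.pvalue)


def type_one_error_sim(
    n_per_group: int,
    true_spec: SyntheticSampleSpec,
    reps: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
    *,
    k_cells: int = 30,
) -> float:
    """Null rejection rate of the pooled t at level ``alpha``.

    Both groups are generated from the same :class:`SyntheticSampleSpec`:
    each replicate draws ``n_per_group`` samples per group, each sample's
    M.R being the mean of ``k_cells`` per-cell ratios from the generator's
    truncated-normal ratio distribution, then applies the pooled t to the
    two M.R vectors. Under the null the rate should match ``alpha``.
    """
    if reps < 100:
        raise ValueError("reps must be >= 100")
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must be in [0, 1]")
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    rng = np.random.default_rng(seed)
    shape = (reps, n_per_group, k_cells)
    draws_a = _truncated_normal(
        rng, true_spec.true_mean_ratio, true_spec.between_cell_sd, int(np.prod(shape))
    ).reshape(shape)
    draws_b = _truncated_normal(
        rng, true_spec.true_mean_ratio, true_spec.between_cell_sd, int(np.prod(shape))
    ).reshape(shape)
    mr_a = draws_a.mean(axis=2)
    mr_b = draws_b.mean(axis=2)
    p = _pooled_t_p(mr_a, mr_b, axis=1)
    return float(np.mean(p < alpha))
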