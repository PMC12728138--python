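"""Evaluation statistics: absolute-agreement ICC and two-part alpha.

Both operate on paired per-subject series (e.g. latencies from two raters
or from odd/even trial halves).  Missing entries are removed pairwise.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "icc_absolute_agreement",
    "two_part_alpha",
    "bootstrap_ci",
    "UndefinedStatisticError",
]


class UndefinedStatisticError(ValueError):
    """The statistic is undefined (zero variance or too few pairs)."""


def _paired(values_1, values_2, min_n: int) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(values_1, dtype=float)
    y = np.asarray(values_2, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired series must be 1-D and of equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < min_n:
        raise UndefinedStatisticError(
            f"need at least {min_n} complete pairs, got {x.size}"
        )
    return x, y


def icc_absolute_agreement(values_1, values_2) -> float:
    """ICC(A,1): two-way model, single rater, absolute agreement.

    Computed from the explicit two-way mean-squares decomposition
    (McGraw & Wong): with rows = subjects (n) and columns = raters (k = 2),

        ICC(A,1) = (MS_R − MS_E) / (MS_R + (k−1) MS_E + (k/n)(MS_C − MS_E)).

    Unlike a Pearson correlation this penalizes systematic offsets between
    the two series, not just scatter.
    """
    x, y = _paired(values_1, values_2, min_n=2)
    data = np.column_stack([x, y])
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    resid = data - row_means[:, None] - col_means[None, :] + grand
    ss_err = (resid**2).sum()
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    denom = ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e)
    if denom <= 0:
        raise UndefinedStatisticError("zero total variance; ICC undefined")
    return float((ms_r - ms_e) / denom)


def two_part_alpha(values_1, values_2, *, standardized: bool = False) -> float:
    """Coefficient alpha over two parts (split-half reliability).

    For k = 2 parts, α = 2 (1 − (var(p1) + var(p2)) / var(p1 + p2)).
    With ``standardized=True`` both parts are z-standardized first, which
    makes α equal the Spearman–Brown stepped-up correlation 2r / (1 + r).
    """
    x, y = _paired(values_1, values_2, min_n=3)
    if standardized:
        if x.std(ddof=1) == 0 or y.std(ddof=1) == 0:
            raise UndefinedStatisticError("zero part variance")
        x = (x - x.mean()) / x.std(ddof=1)
        y = (y - y.mean()) / y.std(ddof=1)
    var_sum = np.var(x + y, ddof=1)
    if var_sum <= 0:
        raise UndefinedStatisticError("zero variance of the part sum")
    return float(2.0 * (1.0 - (np.var(x, ddof=1) + np.var(y, ddof=1)) / var_sum))


def bootstrap_ci(
    values_1,
    values_2,
    statistic,
    *,
    n_boot: int = 5000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI for a paired statistic, resampling subjects."""
    x, y = _paired(values_1, values_2, min_n=2)
    rng = np.random.default_rng(seed)
    stats = []
    for _ in range(n_boot):
        idx = rng.integers(0, x.size, size=x.size)
        try:
            stats.append(statistic(x[idx], y[idx]))
        except UndefinedStatisticError:
            continue
    if not stats:
        raise UndefinedStatisticError("statistic undefined in every resample")
    lo = (1.0 - level) / 2.0
    return tuple(np.quantile(stats, [lo, 1.0 - lo]))  # type: ignore[return-value]
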