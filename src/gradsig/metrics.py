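"""Accuracy metrics for signal extraction and the paired Wilcoxon test.

RMSE, MAE and MAPE score an extracted signal against the known truth curve
of a simulated replicate.  RRMSE is the ratio of an alternate method's RMSE
to the SDD benchmark's: values below 1 mean the alternate outperforms the
benchmark, and ``improvement_pct`` converts that ratio into the familiar
"outperformed by X%" statement.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import stats


def _pair(estimate, truth) -> tuple[np.ndarray, np.ndarray]:
    e = np.asarray(estimate, dtype=float)
    t = np.asarray(truth, dtype=float)
    if e.shape != t.shape or e.ndim != 1 or e.size < 1:
        raise ValueError("estimate and truth must be equal-length 1-D sequences")
    return e, t


def rmse(estimate: Sequence[float], truth: Sequence[float]) -> float:
    """Root mean squared error."""
    e, t = _pair(estimate, truth)
    return float(np.sqrt(np.mean((e - t) ** 2)))


def mae(estimate: Sequence[float], truth: Sequence[float]) -> float:
    """Mean absolute error."""
    e, t = _pair(estimate, truth)
    return float(np.mean(np.abs(e - t)))


def mape(estimate: Sequence[float], truth: Sequence[float]) -> float:
    """Mean absolute percentage error, in percent; truth must be nonzero."""
    e, t = _pair(estimate, truth)
    if np.any(t == 0):
        raise ValueError("MAPE undefined: truth contains zeros")
    return float(100.0 * np.mean(np.abs((t - e) / t)))


def rrmse(
    rmse_alt: Sequence[float],
    rmse_sdd: Sequence[float],
    mode: str = "ratio_of_means",
) -> float:
    """Relative RMSE of an alternate method against the SDD benchmark.

    ``ratio_of_means`` divides the replicate-mean RMSEs (the default);
    ``mean_of_ratios`` averages the per-replicate ratios.  RRMSE < 1 means
    the alternate outperforms the benchmark.
    """
    a = np.atleast_1d(np.asarray(rmse_alt, dtype=float))
    s = np.atleast_1d(np.asarray(rmse_sdd, dtype=float))
    if a.size != s.size or a.size < 1:
        raise ValueError("replicate RMSE sequences must have equal nonzero length")
    if np.any(s <= 0):
        raise ValueError("benchmark RMSEs must be positive")
    if mode == "ratio_of_means":
        return float(np.mean(a) / np.mean(s))
    if mode == "mean_of_ratios":
        return float(np.mean(a / s))
    raise ValueError(f"unknown mode {mode!r}")


def improvement_pct(rrmse_value: float) -> float:
    """Percent by which the alternate outperforms the benchmark: (1 - RRMSE) * 100."""
    return float((1.0 - rrmse_value) * 100.0)


def wilcoxon_compare(rmse_a: Sequence[float], rmse_b: Sequence[float]) -> float:
    """Two-sided two-sample Wilcoxon rank-sum p-value on two RMSE samples.

    Uses the exact null distribution for small samples without ties and the
    normal approximation otherwise.
    """
    a = np.asarray(rmse_a, dtype=float)
    b = np.asarray(rmse_b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("both samples must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.pvalue)
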