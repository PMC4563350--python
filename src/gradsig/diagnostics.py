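"""Residual and separability diagnostics for extracted signals.

A good extraction leaves residuals that look like stationary white noise
(ADF rejects a unit root, Ljung-Box fails to reject independence) and a
signal uncorrelated with its residual under Pearson, Kendall and Spearman
correlation — near-zero coefficients mean signal and noise separate well.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .profiles import SignalExtraction

CORRELATION_METHODS = ("pearson", "kendall", "spearman")


def residual_diagnostics(extraction: SignalExtraction, lags: int | None = None) -> dict:
    """ADF unit-root and Ljung-Box whiteness tests on a residual series.

    Returns a dict with ``adf_stat``, ``adf_p``, ``ljungbox_stat``,
    ``ljungbox_p`` and the Ljung-Box ``lags`` used (default
    min(10, N // 5)).  Needs at least 20 residuals.
    """
    from statsmodels.stats.diagnostic import acorr_ljungbox
    from statsmodels.tsa.stattools import adfuller

    resid = np.asarray(extraction.residual, dtype=float)
    n = resid.size
    if n < 20:
        raise ValueError("need at least 20 residuals for diagnostics")
    if lags is None:
        lags = max(1, min(10, n // 5))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        adf_stat, adf_p, *_ = adfuller(resid, autolag="AIC")
        lb = acorr_ljungbox(resid, lags=[lags], return_df=True)
    return {
        "adf_stat": float(adf_stat),
        "adf_p": float(adf_p),
        "ljungbox_stat": float(lb["lb_stat"].iloc[0]),
        "ljungbox_p": float(lb["lb_pvalue"].iloc[0]),
        "lags": int(lags),
    }


def signal_noise_correlations(
    extraction: SignalExtraction,
    methods: Iterable[str] = CORRELATION_METHODS,
) -> dict[str, float]:
    """Correlation between extracted signal and residual, per coefficient."""
    sig = extraction.signal
    res = extraction.residual
    out: dict[str, float] = {}
    for m in methods:
        if m == "pearson":
            out[m] = float(stats.pearsonr(sig, res).statistic)
        elif m == "kendall":
            out[m] = float(stats.kendalltau(sig, res).statistic)
        elif m == "spearman":
            out[m] = float(stats.spearmanr(sig, res).statistic)
        else:
            raise ValueError(f"unknown correlation method {m!r}")
    return out


def correlation_table(
    extractions: Sequence[tuple[str, SignalExtraction]],
    methods: Iterable[str] = CORRELATION_METHODS,
) -> pd.DataFrame:
    """Long-format signal-noise correlation table keyed (series, model, method)."""
    rows = []
    for series_id, extraction in extractions:
        coefs = signal_noise_correlations(extraction, methods)
        for m, v in coefs.items():
            rows.append({"series": series_id, "model": extraction.method,
                         "method": m, "value": v})
    return pd.DataFrame(rows, columns=["series", "model", "method", "value"])
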