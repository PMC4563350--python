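"""The Monte-Carlo simulation study: many noisy replicates, many extractors.

Each replicate draws one noisy gradient; every requested method extracts a
signal from the *same* noisy series (common random numbers sharpen the
paired comparisons); signals are scored against the known truth by RMSE,
MAE and MAPE.  The summary mirrors the usual benchmark table: per-model
mean errors, min/max RMSE across replicates, and RRMSE against the SDD
benchmark, plus pairwise two-sample Wilcoxon tests on the RMSE samples.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics
from .baselines import fit_arfima, fit_arima_auto, fit_ets, fit_nn_autoregression
from .profiles import ExpressionProfile, SignalExtraction
from .sdd import extract_signal_sdd
from .simulate import SimulationSpec, generate_replicate
from .ssa import extract_signal_ssa

logger = logging.getLogger("gradsig")

DEFAULT_METHODS = ("ssa", "sdd_anterior_efold", "arima", "arfima", "ets", "nn")
KNOWN_METHODS = DEFAULT_METHODS + ("sdd_least_squares",)
DEFAULT_BENCHMARK = "sdd_anterior_efold"


def _run_method(name: str, profile: ExpressionProfile, seed: int, cfg: dict) -> SignalExtraction:
    if name == "ssa":
        return extract_signal_ssa(profile, **cfg)
    if name == "sdd_anterior_efold":
        return extract_signal_sdd(profile, "anterior_efold")
    if name == "sdd_least_squares":
        return extract_signal_sdd(profile, "least_squares")
    if name == "arima":
        return fit_arima_auto(profile, **cfg).extraction
    if name == "arfima":
        return fit_arfima(profile, **cfg).extraction
    if name == "ets":
        return fit_ets(profile, **cfg).extraction
    if name == "nn":
        return fit_nn_autoregression(profile, seed=seed, **cfg).extraction
    raise ValueError(f"unknown method {name!r}")


@dataclass(frozen=True)
class MetricsRow:
    """One benchmark-table row: per-model mean errors across replicates."""

    model: str
    rmse: float
    mape: float
    mae: float
    rrmse: float
    min_rmse: float
    max_rmse: float


@dataclass(frozen=True)
class StudyResult:
    rmse_matrix: pd.DataFrame  # replicate x model
    mae_matrix: pd.DataFrame
    mape_matrix: pd.DataFrame
    summary: tuple[MetricsRow, ...]
    wilcoxon_p: dict[tuple[str, str], float]
    spec: SimulationSpec
    benchmark: str
    method_seeds: dict[str, int] = field(default_factory=dict)
    warnings_: tuple[str, ...] = ()

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "model": r.model, "rmse": r.rmse, "mape": r.mape, "mae": r.mae,
                    "rrmse": r.rrmse, "min": r.min_rmse, "max": r.max_rmse,
                }
                for r in self.summary
            ]
        )


def run_simulation_study(
    spec: SimulationSpec,
    methods: tuple[str, ...] = DEFAULT_METHODS,
    method_configs: dict[str, dict] | None = None,
    benchmark: str = DEFAULT_BENCHMARK,
    rrmse_mode: str = "ratio_of_means",
) -> StudyResult:
    """Run the replicate-by-method benchmark described in the module docstring.

    Every method sees the same noisy series in each replicate.  A method
    failing on more than 1% of replicates aborts the study; isolated
    failures are logged and the affected replicate is dropped for *all*
    methods, so replicate alignment is preserved.  The whole study is
    reproducible from ``spec.seed``.
    """
    methods = tuple(methods)
    unknown = [m for m in methods if m not in KNOWN_METHODS]
    if unknown:
        raise ValueError(f"unknown method(s) {unknown}; choose from {KNOWN_METHODS}")
    cfgs = {m: dict((method_configs or {}).get(m, {})) for m in methods}
    n_reps = spec.n_reps
    rmse_m = np.full((n_reps, len(methods)), np.nan)
    mae_m = np.full_like(rmse_m, np.nan)
    mape_m = np.full_like(rmse_m, np.nan)
    fail_counts = {m: 0 for m in methods}
    method_seeds = {
        m: int((spec.seed * 7919 + 13 * j + 1) % (2**31 - 1)) for j, m in enumerate(methods)
    }

    for rep in range(n_reps):
        truth, noisy = generate_replicate(spec, rep)
        for j, m in enumerate(methods):
            seed = int((method_seeds[m] + rep) % (2**31 - 1))
            try:
                extraction = _run_method(m, noisy, seed, cfgs[m])
            except Exception as exc:  # noqa: BLE001 - individual failures are data
                fail_counts[m] += 1
                logger.warning("replicate %d: method %s failed: %s", rep, m, exc)
                continue
            rmse_m[rep, j] = metrics.rmse(extraction.signal, truth.intensities)
            mae_m[rep, j] = metrics.mae(extraction.signal, truth.intensities)
            mape_m[rep, j] = metrics.mape(extraction.signal, truth.intensities)

    for m, nfail in fail_counts.items():
        if nfail > 0.01 * n_reps:
            raise RuntimeError(
                f"method {m!r} failed on {nfail}/{n_reps} replicates (> 1%); aborting"
            )

    keep = ~np.isnan(rmse_m).any(axis=1)
    notes: list[str] = []
    if not np.all(keep):
        notes.append(f"dropped {int(np.sum(~keep))} replicates with failures (pairwise)")
    rmse_df = pd.DataFrame(rmse_m[keep], columns=list(methods))
    mae_df = pd.DataFrame(mae_m[keep], columns=list(methods))
    mape_df = pd.DataFrame(mape_m[keep], columns=list(methods))

    bench_col = rmse_df[benchmark].to_numpy() if benchmark in methods else None
    degenerate = bench_col is not None and float(np.mean(bench_col)) < 1e-9
    if degenerate:
        notes.append("degenerate-noise study: benchmark RMSE ~ 0, RRMSE undefined")
        warnings.warn(notes[-1], stacklevel=2)

    rows = []
    for m in methods:
        col = rmse_df[m].to_numpy()
        if bench_col is None or degenerate:
            rr = np.nan
        else:
            rr = metrics.rrmse(col, bench_col, mode=rrmse_mode)
        rows.append(
            MetricsRow(
                model=m,
                rmse=float(np.mean(col)),
                mape=float(np.mean(mape_df[m])),
                mae=float(np.mean(mae_df[m])),
                rrmse=float(rr),
                min_rmse=float(np.min(col)),
                max_rmse=float(np.max(col)),
            )
        )

    wp: dict[tuple[str, str], float] = {}
    if rmse_df.shape[0] >= 2:
        for a, b in combinations(methods, 2):
            wp[(a, b)] = metrics.wilcoxon_compare(rmse_df[a], rmse_df[b])

    return StudyResult(
        rmse_matrix=rmse_df, mae_matrix=mae_df, mape_matrix=mape_df,
        summary=tuple(rows), wilcoxon_p=wp, spec=spec, benchmark=benchmark,
        method_seeds=method_seeds, warnings_=tuple(notes),
    )


def render_report(study: StudyResult, outdir: str | Path, plots: bool = False) -> dict[str, Path]:
    """Write the benchmark table, Wilcoxon table and a JSON run manifest.

    ``summary.csv`` has the fixed column order
    model, rmse, mape, mae, rrmse, min, max.  The manifest records the
    simulation spec, methods, per-method seeds and package versions so a
    run can be reproduced exactly.
    """
    if not study.summary:
        raise ValueError("empty study result")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["summary"] = outdir / "summary.csv"
    study.summary_frame().to_csv(paths["summary"], index=False)

    paths["rmse_matrix"] = outdir / "rmse_matrix.csv"
    study.rmse_matrix.to_csv(paths["rmse_matrix"], index=False)

    wdf = pd.DataFrame(
        [{"model_a": a, "model_b": b, "p_value": p} for (a, b), p in study.wilcoxon_p.items()]
    )
    paths["wilcoxon"] = outdir / "wilcoxon.csv"
    wdf.to_csv(paths["wilcoxon"], index=False)

    import statsmodels

    manifest = {
        "spec": study.spec.to_dict(),
        "methods": [r.model for r in study.summary],
        "benchmark": study.benchmark,
        "method_seeds": study.method_seeds,
        "n_replicates_used": int(study.rmse_matrix.shape[0]),
        "warnings": list(study.warnings_),
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "statsmodels": statsmodels.__version__,
        },
    }
    paths["manifest"] = outdir / "manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=2))

    if plots:
        paths["rmse_plot"] = outdir / "rmse_distribution.png"
        plot_rmse_distributions(study, paths["rmse_plot"])
    return paths


def plot_rmse_distributions(study: StudyResult, path: str | Path) -> None:
    """Box plot of per-replicate RMSE by model."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    study.rmse_matrix.boxplot(ax=ax)
    ax.set_ylabel("RMSE vs truth (intensity AU)")
    ax.set_xlabel("model")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_extraction(extraction: SignalExtraction, path: str | Path) -> None:
    """Observed series with the extracted signal overlaid."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(extraction.positions, extraction.observed, "k.", ms=3, label="observed")
    ax.plot(extraction.positions, extraction.signal, "r-", lw=1.5, label=extraction.method)
    ax.set_xlabel("position (% egg length)")
    ax.set_ylabel("intensity (AU)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
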