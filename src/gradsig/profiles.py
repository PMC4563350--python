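"""One-dimensional expression profiles: containers, readers, writers.

An expression profile pairs positions along the anterior--posterior (AP)
axis of an embryo, in percent egg length, with fluorescence intensities in
arbitrary units.  Profiles are the common currency of the package: measured
data (e.g. FlyEx-style exports), simulated noise-free gradients, and noisy
simulated replicates all share the same container.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("gradsig")

PROVENANCES = ("measured", "simulated_truth", "simulated_noisy")


@dataclass(frozen=True)
class ExpressionProfile:
    """An ordered 1-D expression profile along the AP axis.

    Parameters
    ----------
    series_id
        Text label identifying the embryo or simulated replicate.
    positions
        Positions along the AP axis in percent egg length, strictly
        increasing, length N >= 3.
    intensities
        Fluorescence intensities (arbitrary units), finite, same length.
    provenance
        One of ``measured``, ``simulated_truth``, ``simulated_noisy``.
    """

    series_id: str
    positions: np.ndarray
    intensities: np.ndarray
    provenance: str = "measured"

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        ints = np.asarray(self.intensities, dtype=float)
        if pos.ndim != 1 or ints.ndim != 1 or pos.size != ints.size:
            raise ValueError("positions and intensities must be equal-length 1-D sequences")
        if pos.size < 3:
            raise ValueError(f"profile needs at least 3 points, got {pos.size}")
        if not np.all(np.isfinite(pos)):
            raise ValueError("positions must be finite")
        if not np.all(np.diff(pos) > 0):
            raise ValueError("positions must be strictly increasing")
        if not np.all(np.isfinite(ints)):
            raise ValueError("intensities must be finite (no missing values)")
        if self.provenance not in PROVENANCES:
            raise ValueError(f"provenance must be one of {PROVENANCES}")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "intensities", ints)

    def __len__(self) -> int:
        return int(self.positions.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionProfile):
            return NotImplemented
        return (
            self.series_id == other.series_id
            and self.provenance == other.provenance
            and np.array_equal(self.positions, other.positions)
            and np.array_equal(self.intensities, other.intensities)
        )


@dataclass(frozen=True)
class SignalExtraction:
    """Result of a signal-extraction method on one profile.

    ``signal + residual`` equals the observed series element-wise; the
    residual is whatever the method left behind as noise.
    """

    method: str
    positions: np.ndarray
    observed: np.ndarray
    signal: np.ndarray
    residual: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        obs = np.asarray(self.observed, dtype=float)
        sig = np.asarray(self.signal, dtype=float)
        res = np.asarray(self.residual, dtype=float)
        n = pos.size
        if not (obs.size == sig.size == res.size == n):
            raise ValueError("positions, observed, signal, residual must have equal length")
        if n == 0:
            raise ValueError("empty extraction")
        scale = max(1.0, float(np.max(np.abs(obs))))
        if np.max(np.abs(obs - (sig + res))) > 1e-8 * scale:
            raise ValueError("signal + residual must equal the observed series")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "observed", obs)
        object.__setattr__(self, "signal", sig)
        object.__setattr__(self, "residual", res)


def _finalize_rows(series_id: str, pos: np.ndarray, ints: np.ndarray) -> ExpressionProfile:
    """Sort, drop non-finite intensities, average duplicate positions."""
    finite = np.isfinite(ints) & np.isfinite(pos)
    n_dropped = int(np.sum(~finite))
    if n_dropped:
        logger.warning("%s: dropped %d rows with non-finite values", series_id, n_dropped)
    pos, ints = pos[finite], ints[finite]
    order = np.argsort(pos, kind="stable")
    pos, ints = pos[order], ints[order]
    uniq, inverse, counts = np.unique(pos, return_inverse=True, return_counts=True)
    if uniq.size != pos.size:
        warnings.warn(
            f"{series_id}: averaged intensities at {int(np.sum(counts > 1))} duplicated positions",
            stacklevel=3,
        )
        sums = np.zeros(uniq.size)
        np.add.at(sums, inverse, ints)
        ints = sums / counts
        pos = uniq
    if pos.size < 3:
        raise ValueError(f"{series_id}: fewer than 3 valid rows after cleaning")
    return ExpressionProfile(series_id, pos, ints)


def read_profile(
    path: str | Path,
    dialect: str = "two_column",
    *,
    position_column: int = 1,
    intensity_column: int = 3,
    series_id: str | None = None,
) -> ExpressionProfile:
    """Read an expression profile from a delimited text file.

    Two dialects are supported.  ``two_column`` is a CSV with header
    ``position,intensity``.  ``flyex_like`` is a whitespace-delimited table
    in the style of FlyEx quantitative exports (per-nucleus rows); the AP
    coordinate and intensity column indices are configurable because the
    exact export layout varies (defaults: columns 1 and 3 of an
    ``id x y intensity`` table).

    Rows with non-finite intensities are dropped (and logged); rows sharing
    an identical position are averaged with a warning so that downstream
    methods always receive a single-valued sequence.
    """
    path = Path(path)
    sid = series_id if series_id is not None else path.stem
    if dialect == "two_column":
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
        cols = [c.strip().lower() for c in df.columns]
        if "position" in cols and "intensity" in cols:
            pos = df[df.columns[cols.index("position")]].to_numpy(float)
            ints = df[df.columns[cols.index("intensity")]].to_numpy(float)
        else:
            # headerless two-column file: re-read taking the first two columns
            df = pd.read_csv(path, comment="#", header=None, float_precision="round_trip")
            pos = df.iloc[:, 0].to_numpy(float)
            ints = df.iloc[:, 1].to_numpy(float)
    elif dialect == "flyex_like":
        df = pd.read_csv(path, sep=r"\s+", comment="#", header=None, float_precision="round_trip")
        ncol = df.shape[1]
        pc = position_column if position_column < ncol else 0
        ic = intensity_column if intensity_column < ncol else ncol - 1
        # tolerate a header line of non-numeric tokens
        df = df.apply(pd.to_numeric, errors="coerce")
        pos = df.iloc[:, pc].to_numpy(float)
        ints = df.iloc[:, ic].to_numpy(float)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return _finalize_rows(sid, pos, ints)


def crop_to_ap_window(
    profile: ExpressionProfile, lo: float = 20.0, hi: float = 80.0
) -> ExpressionProfile:
    """Restrict a profile to the AP window [lo, hi] percent egg length.

    Measured Bicoid series are conventionally analysed between 20% and 80%
    egg length, where nuclear quantification is reliable.  Boundaries are
    inclusive; an empty result is an error.
    """
    if not lo < hi:
        raise ValueError("lo must be < hi")
    mask = (profile.positions >= lo) & (profile.positions <= hi)
    if not np.any(mask):
        raise ValueError(f"no positions of {profile.series_id!r} fall inside [{lo}, {hi}]")
    if np.all(mask):
        return profile
    return replace(
        profile,
        positions=profile.positions[mask],
        intensities=profile.intensities[mask],
    )


def write_profile(profile: ExpressionProfile, path: str | Path) -> None:
    """Write a profile as two-column CSV ``position,intensity`` at full precision."""
    pd.DataFrame({"position": profile.positions, "intensity": profile.intensities}).to_csv(
        path, index=False
    )


def write_extraction(result: SignalExtraction, path: str | Path) -> None:
    """Write an extraction as CSV ``position,observed,signal,residual``.

    Values are written at full float precision so that a read round-trips
    bit-exactly.
    """
    if len(result.positions) == 0:
        raise ValueError("cannot write an empty extraction")
    df = pd.DataFrame(
        {
            "position": result.positions,
            "observed": result.observed,
            "signal": result.signal,
            "residual": result.residual,
        }
    )
    df.to_csv(path, index=False)


def read_extraction(path: str | Path, method: str = "unknown") -> SignalExtraction:
    """Read back a CSV written by :func:`write_extraction`."""
    df = pd.read_csv(path, float_precision="round_trip")
    return SignalExtraction(
        method=method,
        positions=df["position"].to_numpy(float),
        observed=df["observed"].to_numpy(float),
        signal=df["signal"].to_numpy(float),
        residual=df["residual"].to_numpy(float),
    )
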