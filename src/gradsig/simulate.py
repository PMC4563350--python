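"""Synthetic morphogen gradients from the SDD model, plus noisy replicates.

At steady state the synthesis--diffusion--degradation (SDD) model yields an
exponential concentration profile ``B = A * exp(-x / lambda)`` with amplitude
``A`` at the anterior (x = 0) and length constant ``lambda = sqrt(D * tau_p)``
set by the diffusion constant and the protein lifetime.  Real fluorescence
profiles are this curve buried in heteroscedastic measurement noise, so the
generator adds zero-mean Gaussian noise whose standard deviation differs
between segments of the AP axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .profiles import ExpressionProfile


@dataclass(frozen=True)
class NoiseSegment:
    """Gaussian noise level on one stretch of the AP axis (percent egg length)."""

    start: float
    end: float
    sigma: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("segment start must be < end")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


def default_segments(x_start: float = 0.0, x_end: float = 100.0) -> tuple[NoiseSegment, ...]:
    """Three equal-width segments with noise s.d. (8, 12, 8) intensity units."""
    edges = np.linspace(x_start, x_end, 4)
    sigmas = (8.0, 12.0, 8.0)
    return tuple(
        NoiseSegment(float(edges[i]), float(edges[i + 1]), sigmas[i]) for i in range(3)
    )


@dataclass(frozen=True)
class SimulationSpec:
    """Full description of one simulation study's data-generating process.

    Defaults: amplitude 255 (an 8-bit-like intensity ceiling), length
    constant 20 %EL, 101 equally spaced points on 0--100 %EL, three
    equal-width noise segments with s.d. (8, 12, 8), 1000 replicates.
    """

    amplitude_A: float = 255.0
    lambda_: float = 20.0
    n_points: int = 101
    x_start: float = 0.0
    x_end: float = 100.0
    segments: tuple[NoiseSegment, ...] = ()
    n_reps: int = 1000
    seed: int = 42

    def __post_init__(self) -> None:
        if self.amplitude_A <= 0 or self.lambda_ <= 0:
            raise ValueError("amplitude_A and lambda_ must be positive")
        if self.n_points < 3:
            raise ValueError("n_points must be >= 3")
        if not self.x_start < self.x_end:
            raise ValueError("x_start must be < x_end")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        segs = tuple(self.segments) or default_segments(self.x_start, self.x_end)
        segs = tuple(sorted(segs, key=lambda s: s.start))
        tol = 1e-9 * (self.x_end - self.x_start)
        if abs(segs[0].start - self.x_start) > tol or abs(segs[-1].end - self.x_end) > tol:
            raise ValueError("segments must jointly cover [x_start, x_end]")
        for a, b in zip(segs, segs[1:]):
            if abs(a.end - b.start) > tol:
                raise ValueError("segments must be contiguous and non-overlapping")
        object.__setattr__(self, "segments", segs)

    def grid(self) -> np.ndarray:
        return np.linspace(self.x_start, self.x_end, self.n_points)

    def sigma_at(self, positions: np.ndarray) -> np.ndarray:
        """Noise standard deviation at each position (segment lookup)."""
        positions = np.asarray(positions, dtype=float)
        sigma = np.full(positions.shape, np.nan)
        for seg in self.segments:
            mask = (positions >= seg.start) & (positions <= seg.end)
            sigma[np.where(mask & np.isnan(sigma))] = seg.sigma
            # interior boundaries: the later segment wins nothing; first match kept
        if np.any(np.isnan(sigma)):
            bad = positions[np.isnan(sigma)]
            raise ValueError(f"positions not covered by any noise segment: {bad[:5]}")
        return sigma

    def to_dict(self) -> dict:
        d = asdict(self)
        d["segments"] = [asdict(s) for s in self.segments]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationSpec":
        d = dict(d)
        segs = tuple(NoiseSegment(**s) for s in d.pop("segments", []))
        return cls(segments=segs, **d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationSpec":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def sdd_curve(
    amplitude_A: float, lambda_: float, positions: Sequence[float] | np.ndarray
) -> np.ndarray:
    """Steady-state SDD gradient A * exp(-x / lambda) at the given positions.

    Positions are measured from the anterior (x = 0 at the anterior pole);
    the curve drops to 1/e of its anterior value at x = lambda.
    """
    if amplitude_A <= 0:
        raise ValueError("amplitude_A must be positive")
    if lambda_ <= 0:
        raise ValueError("lambda_ must be positive")
    x = np.asarray(positions, dtype=float)
    return amplitude_A * np.exp(-x / lambda_)


def steady_state_length_constant(D: float, tau_p: float) -> float:
    """Length constant sqrt(D * tau_p) implied by diffusion and lifetime.

    Substituting m(x) = A exp(-x/lambda) into the SDD reaction--diffusion
    equation with dm/dt = 0 and no source away from the anterior gives
    D/lambda^2 = 1/tau_p.
    """
    if D < 0:
        raise ValueError("D must be >= 0")
    if tau_p <= 0:
        raise ValueError("tau_p must be positive")
    return math.sqrt(D * tau_p)


def generate_replicate(
    spec: SimulationSpec, rep_index: int
) -> tuple[ExpressionProfile, ExpressionProfile]:
    """Generate the (truth, noisy) profile pair for one replicate.

    The truth curve depends only on the spec, never on the seed.  The noise
    stream is fully determined by ``(spec.seed, rep_index)``: each replicate
    has its own independent substream, so replicates can be generated in any
    order (or in parallel) with identical results.
    """
    if not 0 <= rep_index < spec.n_reps:
        raise ValueError(f"rep_index {rep_index} outside [0, {spec.n_reps})")
    x = spec.grid()
    truth_vals = sdd_curve(spec.amplitude_A, spec.lambda_, x)
    sigma = spec.sigma_at(x)
    rng = np.random.default_rng([spec.seed, rep_index])
    noise = rng.normal(0.0, 1.0, size=x.size) * sigma
    truth = ExpressionProfile(f"rep{rep_index}_truth", x, truth_vals, "simulated_truth")
    noisy = ExpressionProfile(f"rep{rep_index}", x, truth_vals + noise, "simulated_noisy")
    return truth, noisy
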