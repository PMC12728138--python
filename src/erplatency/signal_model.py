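"""Core time-series representation and the time/amplitude transformations.

An ERP waveform is a uniformly sampled voltage series with an explicit time
axis in milliseconds and a stimulus-onset origin (t = 0 ms).  The dynamic
template is obtained from a grand-average waveform by two linear
transformations: an amplitude scale ``a`` (multiply every value) and a
time-stretch ``b`` (the signal value at time ``t`` becomes the
spline-interpolated value of the original at ``t / b``, with the origin
fixed at stimulus onset).  Time points whose preimage falls outside the
input's support receive no extrapolated value; they are flagged invalid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = [
    "SampledSignal",
    "TransformParams",
    "stretch_signal",
    "scale_amplitude",
    "grand_average",
    "GridError",
    "InterpolationError",
]

#: Tolerance for checking that the time grid is uniform, in ms.
GRID_TOL = 1e-9


class GridError(ValueError):
    """Raised when a time grid is non-uniform, misaligned or lacks t = 0."""


class InterpolationError(ValueError):
    """Raised when a signal has too few valid samples to interpolate."""


@dataclass(frozen=True)
class SampledSignal:
    """A uniformly sampled voltage series with a stimulus-onset origin.

    Parameters
    ----------
    times
        Strictly increasing, uniformly spaced time axis in milliseconds.
        Must contain t = 0 ms exactly (the stimulus onset).
    values
        Voltage in microvolts, one per time point.  Invalid samples hold NaN.
    valid_mask
        Per-timepoint flag marking samples with interpolation support.
        Defaults to ``isfinite(values)``.
    """

    times: np.ndarray
    values: np.ndarray
    valid_mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if times.ndim != 1 or times.size < 2:
            raise GridError("time axis must be 1-D with at least 2 samples")
        steps = np.diff(times)
        if np.any(steps <= 0):
            raise GridError("times must be strictly increasing")
        if np.any(np.abs(steps - steps[0]) > GRID_TOL):
            raise GridError("times must be uniformly spaced")
        if values.shape != times.shape:
            raise GridError("values and times must have the same length")
        if self.valid_mask is None:
            mask = np.isfinite(values)
        else:
            mask = np.asarray(self.valid_mask, dtype=bool)
            if mask.shape != times.shape:
                raise GridError("valid_mask and times must have the same length")
            mask = mask & np.isfinite(values)
        onset = int(np.argmin(np.abs(times)))
        if abs(times[onset]) > GRID_TOL:
            raise GridError("time axis must contain t = 0 ms (stimulus onset)")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "valid_mask", mask)
        object.__setattr__(self, "_onset_index", onset)

    @property
    def onset_index(self) -> int:
        """Index of t = 0 ms."""
        return self._onset_index  # type: ignore[attr-defined]

    @property
    def step(self) -> float:
        """Sampling step in ms."""
        return float(self.times[1] - self.times[0])

    @property
    def n(self) -> int:
        return self.times.size

    def interpolator(self) -> CubicSpline:
        """Natural cubic spline through the valid samples.

        Knot values are reproduced exactly; no extrapolation is intended —
        callers must mask evaluations outside :meth:`support`.
        """
        t, v = self.times[self.valid_mask], self.values[self.valid_mask]
        if t.size < 4:
            raise InterpolationError(
                f"need at least 4 valid samples for cubic interpolation, got {t.size}"
            )
        return CubicSpline(t, v, bc_type="natural", extrapolate=False)

    def support(self) -> tuple[float, float]:
        """Time range (ms) covered by valid samples."""
        t = self.times[self.valid_mask]
        if t.size == 0:
            raise InterpolationError("signal has no valid samples")
        return float(t[0]), float(t[-1])

    def same_grid(self, other: "SampledSignal", tol: float = GRID_TOL) -> bool:
        return self.times.shape == other.times.shape and bool(
            np.all(np.abs(self.times - other.times) <= tol)
        )


@dataclass(frozen=True)
class TransformParams:
    """Template transformation parameters.

    ``a`` scales the amplitude; ``b`` stretches the time axis (component
    latencies are multiplied by ``b``).  Bounds follow the optimization box.
    """

    a: float = 1.0
    b: float = 1.0

    A_BOUNDS = (0.2, 20.0)
    B_BOUNDS = (0.3, 2.0)

    def __post_init__(self) -> None:
        if not (self.A_BOUNDS[0] <= self.a <= self.A_BOUNDS[1]):
            raise ValueError(f"a = {self.a} outside bounds {self.A_BOUNDS}")
        if not (self.B_BOUNDS[0] <= self.b <= self.B_BOUNDS[1]):
            raise ValueError(f"b = {self.b} outside bounds {self.B_BOUNDS}")


def stretch_signal(signal: SampledSignal, b: float) -> SampledSignal:
    """Stretch (b > 1) or compress (b < 1) a signal along the time axis.

    The output lives on the same grid; its value at time ``t`` is the cubic
    spline interpolation of the input at ``t / b``.  The fixed point is
    t = 0 ms.  Samples whose preimage falls outside the input's valid
    support become invalid (NaN) — no extrapolation.
    """
    if not (b > 0):
        raise ValueError(f"stretch factor must be positive, got {b}")
    spline = signal.interpolator()
    lo, hi = signal.support()
    pre = signal.times / b
    mask = (pre >= lo - GRID_TOL) & (pre <= hi + GRID_TOL)
    values = np.full_like(signal.values, np.nan)
    values[mask] = spline(np.clip(pre[mask], lo, hi))
    return SampledSignal(signal.times, values, mask)


def scale_amplitude(signal: SampledSignal, a: float) -> SampledSignal:
    """Multiply every value by ``a``; times and validity are unchanged."""
    return SampledSignal(signal.times, signal.values * a, signal.valid_mask.copy())


def transform_template(
    template: SampledSignal, params: TransformParams
) -> SampledSignal:
    """Apply the dynamic-template transformation: stretch by b, scale by a."""
    return scale_amplitude(stretch_signal(template, params.b), params.a)


def grand_average(signals: Sequence[SampledSignal]) -> SampledSignal:
    """Pointwise mean of waveforms sharing one grid.

    A time point is valid only where it is valid in every input (the grand
    average is used as a template and must be interpolation-supported
    everywhere it is defined).
    """
    signals = list(signals)
    if not signals:
        raise ValueError("need at least one signal")
    ref = signals[0]
    for s in signals[1:]:
        if not ref.same_grid(s):
            raise GridError("all signals must share the same time grid")
    stack = np.vstack([s.values for s in signals])
    mask = np.all(np.vstack([s.valid_mask for s in signals]), axis=0)
    values = np.where(mask, np.mean(np.where(mask, stack, 0.0), axis=0), np.nan)
    return SampledSignal(ref.times, values, mask)
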