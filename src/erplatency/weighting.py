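"""Per-timepoint weight vectors for the template-matching objectives.

A weighting window (e.g. 250–700 ms) marks where the component of interest
lives in the grand average; a weighting function turns the window into a
weight vector over the template grid.  Weights are attached to the static
template grid and are never warped.  All outputs are max-normalized to 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import windows as _windows

from .signal_model import SampledSignal

__all__ = ["WeightingWindow", "WeightVector", "make_weights", "WEIGHT_FUNCTIONS"]

#: Window presets (ms) commonly used for the parietal P3.
WINDOW_PRESETS: dict[str, tuple[float, float]] = {
    "wide_early": (200.0, 700.0),
    "standard": (250.0, 700.0),
    "wide_late": (250.0, 900.0),
    "tight": (300.0, 600.0),
}

WEIGHT_FUNCTIONS = ("none", "rectangular", "hamming", "tukey25", "normalized")


class DegenerateTemplateError(ValueError):
    """Template has no positive amplitude inside the weighting window."""


@dataclass(frozen=True)
class WeightingWindow:
    """Closed time interval [lower, upper] in ms."""

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"window must satisfy lower < upper, got {self}")

    def contains(self, times: np.ndarray) -> np.ndarray:
        return (times >= self.lower) & (times <= self.upper)


@dataclass(frozen=True)
class WeightVector:
    """Nonnegative weights, one per template time point, max-normalized to 1."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0) or not np.any(w > 0):
            raise ValueError("weights must be nonnegative and not all zero")
        object.__setattr__(self, "weights", w)

    @property
    def total(self) -> float:
        return float(self.weights.sum())


def make_weights(
    template: SampledSignal,
    window: WeightingWindow,
    function: str = "normalized",
    *,
    use_abs: bool = False,
) -> WeightVector:
    """Build the weight vector ω from a window and a weighting function.

    ``none``
        Weight 1 everywhere, ignoring the window.
    ``rectangular``
        1 inside the window, 0 outside (a Tukey window with α = 0).
    ``hamming`` / ``tukey25``
        The standard Hamming / Tukey(α = 0.25) taper spanning exactly the
        window's samples; 0 outside.
    ``normalized``
        Inside the window, the template amplitude divided by its in-window
        maximum, floored at 0 (``use_abs=True`` uses |amplitude| instead);
        0 outside.  Weight is maximal at the component peak and shrinks
        with amplitude.
    """
    times = template.times
    inside = window.contains(times)
    if not inside.any():
        raise ValueError(
            f"window {window} contains no samples of the epoch "
            f"[{times[0]}, {times[-1]}] ms"
        )
    if window.lower < times[0] or window.upper > times[-1]:
        raise ValueError(f"window {window} extends outside the epoch")

    w = np.zeros_like(times)
    m = int(inside.sum())
    if function == "none":
        w = np.ones_like(times)
    elif function == "rectangular":
        w[inside] = 1.0
    elif function == "hamming":
        w[inside] = _windows.hamming(m, sym=True)
    elif function == "tukey25":
        w[inside] = _windows.tukey(m, alpha=0.25, sym=True)
    elif function == "normalized":
        amp = np.abs(template.values) if use_abs else template.values
        peak = np.nanmax(amp[inside])
        if not np.isfinite(peak) or peak <= 0:
            raise DegenerateTemplateError(
                "template has no positive amplitude inside the weighting window"
            )
        w[inside] = np.clip(amp[inside] / peak, 0.0, None)
        w[~np.isfinite(w)] = 0.0
    else:
        raise ValueError(
            f"unknown weighting function {function!r}; choose from {WEIGHT_FUNCTIONS}"
        )
    return WeightVector(w / w.max())
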