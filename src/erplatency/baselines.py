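"""Reference latency extractors: peak latency and fractional-area variants.

All extractors assume a positive-going component (the P3); pass
``polarity=-1`` for negative components.  Latencies are returned in ms;
``nan`` marks a missing estimate (no qualifying peak, no positive area).
"""

from __future__ import annotations

import math

import numpy as np

from .signal_model import SampledSignal
from .weighting import WeightingWindow

__all__ = [
    "MeasurementWindow",
    "peak_latency",
    "area_latency_50",
    "liesefeld_a_latency",
    "liesefeld_b_latency",
]

# A measurement window is the same [lower, upper] interval type used for
# weighting windows; the distinction is only in how it is applied (directly
# to each subject waveform here, to the template in the matcher).
MeasurementWindow = WeightingWindow


def _window_arrays(
    signal: SampledSignal, window: MeasurementWindow, polarity: int
) -> tuple[np.ndarray, np.ndarray]:
    inside = window.contains(signal.times)
    t = signal.times[inside]
    v = polarity * signal.values[inside]
    v = np.where(signal.valid_mask[inside], v, np.nan)
    return t, v


def peak_latency(
    signal: SampledSignal, window: MeasurementWindow, *, polarity: int = 1
) -> float:
    """Time of the largest in-window deflection exceeding its neighborhood.

    A sample qualifies when it has three neighbors on each side inside the
    epoch and its value is strictly larger than the mean of the three left
    neighbors and the mean of the three right neighbors.  Among qualifying
    samples the largest wins; ties go to the earliest.  Returns nan when no
    sample qualifies.
    """
    times = signal.times
    values = polarity * np.where(signal.valid_mask, signal.values, np.nan)
    inside = window.contains(times)
    best_v, best_t = -math.inf, math.nan
    for i in np.flatnonzero(inside):
        if i < 3 or i + 3 >= times.size:
            continue
        v = values[i]
        left = values[i - 3 : i]
        right = values[i + 1 : i + 4]
        if not (np.isfinite(v) and np.all(np.isfinite(left)) and np.all(np.isfinite(right))):
            continue
        if v > left.mean() and v > right.mean() and v > best_v:
            best_v, best_t = v, float(times[i])
    return best_t


def _fractional_area_time(t: np.ndarray, v: np.ndarray, fraction: float) -> float:
    """Time splitting the cumulative sum of ``v`` at ``fraction`` of its total.

    ``v`` must be nonnegative (NaN treated as 0).  The crossing is located
    by linear interpolation between the two samples bracketing the target.
    """
    v = np.where(np.isfinite(v), v, 0.0)
    total = v.sum()
    if total <= 0:
        return math.nan
    target = fraction * total
    cum = np.cumsum(v)
    k = int(np.searchsorted(cum, target))
    if k == 0:
        return float(t[0])
    c_prev, c_k = cum[k - 1], cum[k]
    if c_k == c_prev:  # flat stretch: take its left edge
        return float(t[k - 1])
    return float(t[k - 1] + (target - c_prev) / (c_k - c_prev) * (t[k] - t[k - 1]))


def area_latency_50(
    signal: SampledSignal,
    window: MeasurementWindow,
    *,
    fraction: float = 0.5,
    polarity: int = 1,
) -> float:
    """50% fractional-area latency with the time axis as baseline.

    Values below 0 μV are set to 0, the in-window samples are cumulated,
    and the time where the cumulative signal crosses ``fraction`` of the
    total is found by linear interpolation.  nan when the clipped area
    is zero.
    """
    t, v = _window_arrays(signal, window, polarity)
    if t.size == 0:
        return math.nan
    return _fractional_area_time(t, np.clip(v, 0.0, None), fraction)


def liesefeld_a_latency(
    signal: SampledSignal,
    window: MeasurementWindow,
    *,
    fraction: float = 0.5,
    rel_baseline: float = 0.5,
    polarity: int = 1,
) -> float:
    """Fractional-area latency with a relative baseline at 50% of the peak.

    Half of the in-window maximum amplitude is subtracted from the signal
    and negative remainders are clipped to 0 before the cumulative-area
    step; this suppresses sub-half-maximum activity such as neighboring
    components.  nan when the in-window maximum is not positive.
    """
    t, v = _window_arrays(signal, window, polarity)
    if t.size == 0 or not np.any(np.isfinite(v)):
        return math.nan
    m = np.nanmax(v)
    if m <= 0:
        return math.nan
    shifted = np.clip(v - rel_baseline * m, 0.0, None)
    return _fractional_area_time(t, shifted, fraction)


def liesefeld_b_latency(
    signal: SampledSignal,
    window: MeasurementWindow,
    *,
    fraction: float = 0.5,
    rel_baseline: float = 0.3,
    polarity: int = 1,
) -> float:
    """Fractional-area latency with a 30%-of-peak baseline and a window
    constrained to the baseline crossings flanking the component peak.

    The last sub-baseline crossing before the in-window peak and the first
    after it bound the measurement interval (clamped to the window edge
    when a side never crosses); within that interval the fractional-area
    latency of the baseline-subtracted, clipped signal is computed.
    """
    t, v = _window_arrays(signal, window, polarity)
    if t.size == 0 or not np.any(np.isfinite(v)):
        return math.nan
    i_peak = int(np.nanargmax(v))
    m = v[i_peak]
    if m <= 0:
        return math.nan
    beta = rel_baseline * m

    # onset: walk left from the peak to the last sample below baseline
    t_on = t[0]
    for i in range(i_peak, 0, -1):
        lo, hi = v[i - 1], v[i]
        if np.isfinite(lo) and lo < beta <= hi:
            t_on = t[i - 1] + (beta - lo) / (hi - lo) * (t[i] - t[i - 1])
            break
    # offset: walk right from the peak to the first sample below baseline
    t_off = t[-1]
    for i in range(i_peak, t.size - 1):
        hi, lo = v[i], v[i + 1]
        if np.isfinite(lo) and lo < beta <= hi:
            t_off = t[i] + (hi - beta) / (hi - lo) * (t[i + 1] - t[i])
            break

    keep = (t >= t_on) & (t <= t_off)
    shifted = np.clip(v[keep] - beta, 0.0, None)
    return _fractional_area_time(t[keep], shifted, fraction)
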