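"""Synthetic ERP generation with known ground-truth latency scaling.

Waveforms emulate a parietal stimulus-locked average: a dominant positive
P3-like deflection around 300–500 ms preceded by a negative N2-like trough,
on an epoch from −200 to just under 1000 ms.  Each synthetic subject owns a
true time-stretch ``b_true`` and amplitude scale ``a_true`` applied to a
population template; single trials add stationary AR(1) noise so that the
noise carries low-frequency structure like filtered EEG rather than being
white.  Everything is seeded and bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .signal_model import SampledSignal, scale_amplitude, stretch_signal

__all__ = [
    "ComponentSpec",
    "SyntheticSubject",
    "default_epoch",
    "make_population_template",
    "generate_subject_erp",
    "generate_noise_trials",
    "DEFAULT_COMPONENTS",
]

#: AR(1) coefficient of the trial noise at the default 2 ms step.
AR_PHI = 0.9


@dataclass(frozen=True)
class ComponentSpec:
    """A Gaussian bump: signed amplitude (μV), center and SD (ms)."""

    center: float
    width: float
    amplitude: float

    def __post_init__(self) -> None:
        if not self.width > 0:
            raise ValueError("component width must be positive")


#: N2-like trough followed by a P3-like deflection peaking near 9.4 μV.
DEFAULT_COMPONENTS: tuple[ComponentSpec, ...] = (
    ComponentSpec(center=250.0, width=30.0, amplitude=-2.5),
    ComponentSpec(center=370.0, width=80.0, amplitude=9.4),
)


@dataclass(frozen=True)
class SyntheticSubject:
    """Ground truth for one simulated subject."""

    b_true: float = 1.0
    a_true: float = 1.0
    noise_sd: float = 3.0
    n_trials: int = 80
    seed: int = 0
    ar_phi: float = AR_PHI
    jitter_sd: float = 0.0  # optional trial-level latency jitter (SD of b)

    def __post_init__(self) -> None:
        if not 0.3 <= self.b_true <= 2.0:
            raise ValueError("b_true must lie in [0.3, 2]")
        if self.n_trials < 2:
            raise ValueError("need at least 2 trials")
        if self.noise_sd < 0 or self.jitter_sd < 0:
            raise ValueError("noise_sd and jitter_sd must be nonnegative")


def default_epoch(step: float = 2.0) -> np.ndarray:
    """Time axis −200 … <1000 ms (500 Hz at the default 2 ms step)."""
    return np.arange(-200.0, 1000.0, step)


def make_population_template(
    components=DEFAULT_COMPONENTS, epoch: np.ndarray | None = None
) -> SampledSignal:
    """Sum of Gaussian components evaluated on the epoch grid."""
    components = tuple(components)
    if not components:
        raise ValueError("need at least one component")
    times = default_epoch() if epoch is None else np.asarray(epoch, dtype=float)
    values = np.zeros_like(times)
    for c in components:
        values += c.amplitude * np.exp(-0.5 * ((times - c.center) / c.width) ** 2)
    return SampledSignal(times, values)


def _ar1_noise(rng: np.random.Generator, n: int, sd: float, phi: float) -> np.ndarray:
    """Stationary AR(1) series with marginal SD ``sd``."""
    if sd == 0:
        return np.zeros(n)
    eps = rng.normal(0.0, sd * np.sqrt(1.0 - phi**2), size=n)
    eps[0] = rng.normal(0.0, sd)  # stationary initial condition
    return lfilter([1.0], [1.0, -phi], eps)


def generate_subject_erp(
    template: SampledSignal, subject: SyntheticSubject
) -> tuple[SampledSignal, list[SampledSignal]]:
    """Simulate one subject's trials and their average.

    Each trial is ``a_true · stretch(template, b_true)`` plus AR(1) noise,
    seeded deterministically from ``(seed, trial index)``; with jitter
    enabled the trial's stretch is additionally perturbed.  The subject ERP
    is the trial average; a sample is valid only where every trial is.
    """
    base = scale_amplitude(stretch_signal(template, subject.b_true), subject.a_true)
    trials: list[SampledSignal] = []
    for k in range(subject.n_trials):
        rng = np.random.default_rng([subject.seed, k])
        if subject.jitter_sd > 0:
            b_k = float(np.clip(rng.normal(subject.b_true, subject.jitter_sd), 0.3, 2.0))
            trial_base = scale_amplitude(stretch_signal(template, b_k), subject.a_true)
        else:
            trial_base = base
        noise = _ar1_noise(rng, template.n, subject.noise_sd, subject.ar_phi)
        values = np.where(trial_base.valid_mask, trial_base.values + noise, np.nan)
        trials.append(SampledSignal(template.times, values, trial_base.valid_mask))
    mask = np.all(np.vstack([t.valid_mask for t in trials]), axis=0)
    mean = np.where(mask, np.mean(np.vstack([t.values for t in trials]), axis=0), np.nan)
    return SampledSignal(template.times, mean, mask), trials


def make_battery(
    n_subjects: int,
    *,
    n_trials: int = 80,
    noise_sd: float = 3.0,
    seed: int = 0,
    b_range: tuple[float, float] = (0.85, 1.15),
    a_range: tuple[float, float] = (0.6, 1.6),
    components=DEFAULT_COMPONENTS,
    epoch: np.ndarray | None = None,
) -> tuple[list[SyntheticSubject], list[SampledSignal], list[list[SampledSignal]]]:
    """A population of synthetic subjects with realistic between-subject
    variation in component latency and amplitude.

    Each subject's time scale is drawn uniformly from ``b_range`` and
    amplitude scale from ``a_range`` — individual latencies rarely deviate
    from the grand average by much more than 15%, amplitudes vary more
    freely.  Returns (subjects, subject ERPs, per-subject trial lists).
    """
    template = make_population_template(components, epoch)
    rng = np.random.default_rng([seed, 104729])
    subjects, erps, trials_all = [], [], []
    for j in range(n_subjects):
        subject = SyntheticSubject(
            b_true=float(rng.uniform(*b_range)),
            a_true=float(rng.uniform(*a_range)),
            noise_sd=noise_sd,
            n_trials=n_trials,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        erp, trials = generate_subject_erp(template, subject)
        subjects.append(subject)
        erps.append(erp)
        trials_all.append(trials)
    return subjects, erps, trials_all


def generate_noise_trials(
    epoch: np.ndarray,
    n_trials: int,
    noise_sd: float,
    seed: int,
    ar_phi: float = 0.0,
) -> tuple[SampledSignal, list[SampledSignal]]:
    """Component-free trials (pure noise) and their average.

    ``ar_phi=0`` gives white noise; these subjects should be rejected by
    the fit screening because no template transformation resembles them.
    """
    times = np.asarray(epoch, dtype=float)
    trials = []
    for k in range(n_trials):
        rng = np.random.default_rng([seed, k])
        trials.append(SampledSignal(times, _ar1_noise(rng, times.size, noise_sd, ar_phi)))
    mean = np.mean(np.vstack([t.values for t in trials]), axis=0)
    return SampledSignal(times, mean), trials
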