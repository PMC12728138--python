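# Methods

## The model

`erplatency` estimates the latency of the parietal P3 component in
subject-level event-related potentials (ERPs) by **dynamic template
matching**. The grand-average waveform over all subjects serves as a
template containing an idealized version of the component; two free
parameters turn it into a dynamic template:

- **a** — amplitude scale: every template value is multiplied by *a*
  (dimensionless, box `[0.2, 20]`);
- **b** — time stretch: the template value at time *t* becomes the
  cubic-spline–interpolated value of the original at *t / b*
  (dimensionless, box `[0.3, 2]`), with the fixed point at stimulus onset
  (*t* = 0 ms).

The transformation that best fits a subject's ERP is found by optimizing
one of two similarity measures over the box:

- **MINSQ** minimizes the weighted sum of squared distances
  `Σ_i ω_i (t_i^{a,b} − s_i)²` between the transformed template `t^{a,b}`
  and the signal `s`;
- **MAXCOR** maximizes the weighted Pearson correlation
  `cov_ω(t^{a,b}, s) / sqrt(cov_ω(t^{a,b}, t^{a,b}) cov_ω(s, s))`, with
  `cov_ω(x, y) = Σ ω_i (x_i − m_x(ω)) (y_i − m_y(ω)) / Σ ω_i`. Because
  correlation is invariant to linear amplitude transformations, *a* is
  fixed at 1 and only *b* is optimized.

The subject's latency is `b_opt × l_GA`, where `l_GA` is the component
latency of the grand average, computed here with the relative-baseline
(50 %-of-peak) fractional-area extractor over the active weighting window
— the grand average's high signal-to-noise ratio makes that reading
stable.

## Weighting vectors

A weighting window (presets 200–700, 250–700, 250–900, 300–600 ms;
default 250–700 ms) marks where the component lives in the grand average.
A weighting function maps the window to per-sample weights `ω_i`
(max-normalized to 1, zero outside the window):

| function | shape |
|---|---|
| `none` | 1 everywhere, window ignored |
| `rectangular` | indicator of the window (Tukey α = 0) |
| `hamming`, `tukey25` | standard tapers spanning the window's samples |
| `normalized` (default) | template amplitude / in-window maximum, negative lobes floored at 0 |

`normalized` concentrates weight at the component peak — the closest
formalization of how a human rater reads a waveform — and is the default.
Negative template lobes receive zero weight by default; `use_abs=True`
weights by magnitude instead, which lets a pronounced neighboring trough
(the N2) contribute. Weights attach to the static template grid and are
never warped.

## Penalty and screening

Occasionally the optimizer is drawn to extreme stretches by spurious
matches with early or late signal. A penalty multiplies a minimized
objective (divides a maximized one) by `e^b` for `b ≥ 1.5` and by
`e^(1/b)` for `b ≤ 2/3`; inside the open band `(2/3, 1.5)` no penalty
applies, so plausible stretches are not biased toward 1.

The weighted correlation at the optimum is the **fit statistic** for both
objectives (a distance is amplitude-sensitive and harder to interpret).
Estimates with `r < 0.3` (strictly below; the boundary passes) are flagged
invalid — waveforms this dissimilar rarely contain an identifiable
component. Downstream, latencies more than 3 SD from their condition ×
method group mean are flagged as outliers (single pass, groups of < 3 left
alone).

## Optimization

The optimum is found by a deterministic multistart: `n_starts = 16` points
— one at the center `(a, b) = (1, 1)` plus a seeded Latin-hypercube sample
over the box, with *a* sampled log-uniformly because its box spans two
decades — each refined by bounded Powell search (derivative-free; a rare
boundary failure of Powell's line search falls back to bounded
Nelder-Mead). Among final objectives agreeing to 1e-9, the candidate with
*b* closest to 1 wins, matching the penalty's conservatism. The multistart
optimum is verified against a dense 41 × 41 grid in the tests.

Publicly the model transforms the template; internally the default
(`direction="inverse"`) warps the subject signal by `1/b` onto the static
template grid so the weights never move. Samples without interpolation
support after warping (compression pushes the preimage past the epoch
edge) are dropped from both sums and the remaining weight is renormalized
to the all-valid total, keeping objectives comparable across *b* —
otherwise shrinking support would spuriously favor large stretches. No
value is ever extrapolated. The fit statistic is always evaluated in the
forward frame (transformed template vs. signal), so it is identical for
both directions at a given optimum; the recovered *b* agrees between
directions to ~0.01 on noisy synthetic ERPs.

## Baseline extractors

- **Peak latency**: the largest in-window sample exceeding the mean of its
  three neighbors on each side (window default 250–900 ms); ties go to the
  earliest sample; no qualifying sample → missing.
- **50 % fractional-area latency**: clip negative values to 0, cumulate
  in-window samples, and interpolate linearly where the cumulative mass
  crosses 50 % (window default 250–700 ms).
- **Relative-baseline variant ("Liesefeld A")**: subtract 50 % of the
  in-window peak and clip at 0 before the area step, suppressing
  sub-half-maximum activity.
- **Crossing-constrained variant ("Liesefeld B")**: baseline at 30 % of
  the peak; the measurement interval is constrained to the last
  sub-baseline crossing before the peak and the first after it (clamped to
  the window edge when a side never crosses); the 50 %-area latency of the
  baseline-subtracted, clipped signal is computed inside that interval.
  With several supra-baseline lobes, the lobe holding the global in-window
  maximum defines the crossings.

All extractors assume a positive component; `polarity=-1` negates the
signal first. All are equivariant to amplitude scaling and shift with the
signal under translation.

## Synthetic data

The generator emulates a parietal stimulus-locked average on a −200 … 998
ms epoch at 2 ms steps: an N2-like trough (−2.5 μV at 250 ms, SD 30 ms)
followed by a P3-like deflection (+9.4 μV at 370 ms, SD 80 ms). Each
subject owns a true stretch `b_true` and amplitude scale `a_true` applied
to this template; each of `n_trials` trials (default 80, matching typical
retained-trial counts in speeded tasks) adds stationary AR(1) noise
(φ = 0.9 at the 2 ms step, marginal SD `noise_sd`, default 3 μV) so the
noise carries low-frequency structure like filtered EEG — white noise
would make matching unrealistically easy. The default battery draws
`b_true ~ U(0.85, 1.15)` and `a_true ~ U(0.6, 1.6)`: a latency spread
comparable to the shifts the simulation injects and a wider amplitude
spread, as typical for parietal P3 datasets. Optional trial-level latency
jitter exists for robustness probes and is off by default so ground truth
stays interpretable.

What the generator does **not** emulate: overlapping components with
independent latencies, trial-level amplitude fluctuation, non-stationary
noise, multi-channel topography, and real artifact structure. Passing
tests therefore demonstrate correctness of the algorithmics and parameter
recovery under the stated noise model, not performance on recorded EEG.

A note on the noise model and screening: AR(1) noise at φ = 0.9 leaves few
effective degrees of freedom inside a 450 ms window, so a *component-free*
waveform made of such noise can reach weighted correlations well above
0.3 by chance. The screening properties (≥ 95 % rejection of pure-noise
subjects at the 0.3 cutoff) are therefore stated and tested for white
component-free noise; correlated noise superimposed on a real component —
the situation the battery simulates — does not suffer this ambiguity.

## Shift-recovery simulation

Per subject, a true shift `λ_j ~ N(0.9, 0.05)` is drawn once. Each
iteration splits the subject's trials into disjoint random halves (50/50,
equalizing the signal-to-noise ratio of the two averages), stretches the
experimental half-average by `λ_j` with the same spline transform the
matcher uses, extracts latencies from both averages, and forms
`λ̂ = l_exp / l_control`. Under the stretch convention used throughout
(latency times are multiplied by the factor), the experimental latency
equals `λ` times the control latency, so this ratio estimates `λ`
directly; `invert_ratio=True` reports the reciprocal convention instead.
Estimates are screened by fit (`r < 0.3`), implausible stretch
(`b ∉ (0.5, 1.9)` for template methods), and a single-pass 3-SD rule over
the pooled estimates; subjects with fewer than 50 % valid iterations are
excluded; remaining estimates are averaged per subject and compared to
truth with the absolute-agreement ICC.

The reference configuration (60 subjects, 80 trials, noise SD 3 μV, 20
iterations, MINSQ + normalized weights + penalty, window 250–700 ms) runs
in about five minutes on one CPU and achieves ICC ≈ 0.99 on the bundled
battery. Twenty iterations suffice here because split-half variability is
the only iteration-level noise source; the protocol accepts any count.

## Evaluation statistics

- **ICC(A,1)** — two-way model, single rater, absolute agreement, from
  the explicit mean-squares decomposition
  `(MS_R − MS_E) / (MS_R + (k−1) MS_E + (k/n)(MS_C − MS_E))` with k = 2.
  Agreement is stricter than consistency: a constant offset between the
  series lowers it even when the Pearson r is 1.
- **Two-part coefficient alpha** — Cronbach's alpha for two parts,
  `α = 2 (1 − (var p₁ + var p₂) / var(p₁ + p₂))`, the split-half
  reliability of latencies from odd/even trial halves (odd/even balances
  slow drifts); a standardized variant equals the Spearman–Brown stepped-up
  correlation.

Missing entries are deleted pairwise. A percentile bootstrap over subjects
is available as a generic utility.

## Numerical choices and degenerate inputs

- Cubic splines use natural boundary conditions; knot values are exact.
- Uniform-grid checks use a 1e-9 ms tolerance; the epoch must contain
  *t* = 0 exactly.
- A flat (zero-variance) waveform under the weights cannot be correlated
  with the template: the result carries `reject_reason="degenerate"`
  rather than raising.
- In the peak search, ties go to the earliest qualifying sample.
- Fractional-area crossings interpolate linearly between adjacent
  cumulative sums; a zero-mass window yields a missing value.
- Sharp features near the sampling limit (e.g. a 30 ms-SD trough at 2 ms
  steps) accumulate ~1e-6 μV interpolation error per double warp; all
  equivalence tolerances account for this.

## Known limitations

- Validated on synthetic P3-like morphologies only; components with less
  distinct shapes or lower prominence may need different weighting.
- Positive-going components are the default; polarity is a flag, mixed
  polarities within one window are not modeled.
- The penalty's exponential form is pragmatic, not derived; alternative
  penalties can be supplied through the library API.
- Single-trial latencies, difference-wave onsets and jackknife-based
  estimation are out of scope.
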