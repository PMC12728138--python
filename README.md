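# erplatency

Automatic extraction of subject-level ERP (P3) latencies by **dynamic
template matching**, for ERP researchers who need latency estimates that
are objective, reproducible and screenable at scale.

Individual latencies of the P3 — the positive parietal deflection around
300–500 ms after stimulus onset — carry real information about the speed
of neurocognitive processing, but classical automatic extractors (peak
latency, fractional-area latency) are often unreliable on noisy
subject-level averages, and manual extraction does not scale. This package
implements a matcher that works the way an expert does: it treats the
grand average as a template of the component and asks how that template
must be deformed to resemble each subject's waveform.

The template `t` is transformed with two parameters — an amplitude scale
*a* (`a·t`) and a time stretch *b* (value at time *t* becomes the
spline-interpolated value at *t/b*, origin at stimulus onset) — and the
transformation is optimized against the subject ERP `s` under per-sample
weights ω derived from the grand average:

- **MINSQ**: minimize `Σ_i ω_i (t_i^{a,b} − s_i)²` over `a ∈ [0.2, 20]`,
  `b ∈ [0.3, 2]`;
- **MAXCOR**: maximize the weighted correlation `cov_ω(t^{a,b}, s) /
  √(cov_ω(t^{a,b}, t^{a,b}) · cov_ω(s, s))` over *b* (a is irrelevant to a
  correlation).

The subject's latency is `b_opt × l_GA`, with `l_GA` the grand-average
component latency. An optional penalty (`e^b` for `b ≥ 1.5`, `e^{1/b}` for
`b ≤ 2/3`) discourages extreme stretches, and the weighted correlation at
the optimum is a fit statistic: estimates with `r < 0.3` are flagged as
showing no identifiable component, which enables automatic rejection or
targeted manual review.

Also included: the classical extractors (peak with a 3-neighbor rule, 50 %
fractional-area, and two relative-baseline area variants), a latency-shift
recovery simulation with known ground truth, absolute-agreement ICC and
two-part coefficient alpha, and a synthetic-ERP generator — so the whole
pipeline is testable without any recorded EEG. See `docs/methods.md` for
the full model description.

## Worked example

```python
import erplatency as e

template = e.make_population_template()          # N2 + P3 preset, -200..998 ms
window = e.WeightingWindow(250, 700)
l_ga = e.template_latency(template, window)      # grand-average latency
print(f"grand-average latency: {l_ga:.1f} ms")

subject = e.SyntheticSubject(b_true=1.10, a_true=0.80, noise_sd=3.0,
                             n_trials=80, seed=42)
erp, _ = e.generate_subject_erp(template, subject)

result = e.fit_template(erp, template, l_ga, e.MatchConfig(method="minsq"))
print(f"a_opt={result.a_opt:.3f}  b_opt={result.b_opt:.3f}  "
      f"fit_r={result.fit_r:.3f}  latency={result.latency_ms:.1f} ms  "
      f"valid={result.valid}")
print(f"peak latency:      {e.peak_latency(erp, e.MeasurementWindow(250, 900)):.1f} ms")
print(f"50% area latency:  {e.area_latency_50(erp, window):.1f} ms")
```

prints

```
grand-average latency: 371.6 ms
a_opt=0.806  b_opt=1.109  fit_r=0.991  latency=412.0 ms  valid=True
peak latency:      422.0 ms
50% area latency:  422.6 ms
```

The subject was simulated with a true stretch of 1.10 and amplitude scale
0.80 on top of 3 μV autocorrelated trial noise; the matcher recovers both
parameters to within 0.01 from the 80-trial average and assigns a latency
of 1.109 × 371.6 ≈ 412 ms, with a fit statistic of 0.991 (far above the
0.3 rejection cutoff). The classical extractors read the same waveform
some 10 ms later because they respond to the waveform's shape inside a
fixed window rather than to the component's displacement as a whole.

## Command line

```sh
erplatency synth --subjects 20 --trials 80 --noise-sd 3 --seed 7 \
    --out erps.csv --truth truth.csv
erplatency extract --erps erps.csv --method minsq \
    --weight-function normalized --window 250 700 --penalty \
    --out latencies.csv --review-list review.csv
erplatency simulate --subjects 60 --iterations 20 --extractor minsq \
    --seed 7 --out recovery.csv
erplatency evaluate --pred latencies.csv --ref other.csv --stat icc
```

ERP matrices are plain delimited text (header row = time axis in ms, one
row per subject); every run writes a JSON manifest with the configuration,
seed and missing-value percentage.

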