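# Methods

This note records the model the package implements, the parameter defaults
and why they were chosen, and the numerical conventions that affect results.

## 1. Stimulation protocol and dose metrics

A `StimulusProtocol` is a pulsed-ultrasound stimulus: a sinusoidal carrier at
fundamental frequency `f0` gated into tone bursts of duration `tbd`, repeated
at pulse repetition frequency `prf` for a total pulse duration `pd`; stimuli
recur every `isi` seconds with multiplicative uniform jitter `±jitter_frac`,
for `n_trials` triggers. Defaults (SI units):

| parameter | default | meaning |
|---|---|---|
| `f0` | 1.5 MHz | carrier frequency |
| `prf` | 1500 Hz | pulse repetition frequency |
| `tbd` | 200 µs | tone-burst duration |
| `pd` | 67 ms | stimulus (pulse) duration |
| `isi` | 2.5 s | inter-stimulus interval |
| `jitter_frac` | 0.10 | uniform ISI jitter, ±10% |
| `n_trials` | 505 | triggers per session |
| `p_p2p` | 114 kPa | peak-to-peak pressure |
| `z0` | 1.62 MRayl | acoustic impedance of brain tissue |

Construction validates the invariants `tbd × prf ≤ 1` (bursts cannot overlap),
`pd < isi(1 − jitter_frac)` (stimuli cannot overlap), and positivity of all
quantities; violations raise `ProtocolError`.

Dose metrics follow the standard exposimetry definitions:

- duty cycle `DC = tbd × prf` (dimensionless);
- pulse intensity integral `PII = ∫ p(t)²/z0 dt` over one burst, computed by
  trapezoidal integration of a synthesized burst and converted from SI
  (J m⁻²) to J cm⁻² (÷10⁴);
- `I_SPTA = PII × prf` (converted W cm⁻² → mW cm⁻², ×10³) and, equivalently,
  `I_SPTA = I_SPPA × DC` with `I_SPPA = PII / tbd`.

`synthesize_burst` enforces ≥20 samples per carrier cycle; `dose_metrics`
uses 50. The trapezoid rule on a sampled sinusoid agrees with the closed form
`p0²·tbd/(2 z0)` to better than 0.1% at that density (tested). The two
`I_SPTA` pathways agree to 0.5% across protocols (tested). Trial triggers
place the first stimulus at t = 0 with successive gaps drawn uniformly from
`isi(1 ± jitter_frac)`.

## 2. Synthetic unit generator

Each unit is an inhomogeneous Poisson process realized by thinning against
the per-trial rate profile, followed by greedy enforcement of a 1.5 ms
absolute refractory period (earliest spike kept, subsequent spikes closer
than 1.5 ms deleted). The refractory period is biophysically mandatory here:
without it a 15 Hz Poisson train carries ~1.6% sub-millisecond
inter-spike intervals and is correctly rejected by the package's own
refractory quality-control rule.

Rate profiles by `response_kind`:

- `none` — constant `baseline_rate`;
- `time_locked` — rate multiplied by `gain` during `[0, pd]` after each
  trigger;
- `delayed` — rate multiplied by `gain` during `[onset, onset + response_dur]`,
  where `onset` is drawn **once per unit** from a truncated Normal
  `N(onset_mean, onset_sd²)` on `onset_trunc` (rejection sampling);
- `inhibited` — as `time_locked` with `gain < 1`.

Waveform templates are biphasic raised-cosine lobes: a negative initial
phase of duration `ip_dur` (ms) and a positive after-hyperpolarization of
duration `ahp_dur` (ms) at 35% of the trough amplitude, with exact zero
crossings at the phase boundaries so that feature extraction has a defined
ground truth.

Frozen presets (the package's modeled study conditions; these defaults were
fixed before validation and never adjusted afterwards):

| preset | type | rate (Hz) | response | gain | onset (s) | truncation (s) | IP/AHP (ms) |
|---|---|---|---|---|---|---|---|
| `awake_rsu` | RSU | 5 | time-locked | 2.0 | — | — | 0.35 / 0.60 |
| `anesth_rsu` | RSU | 5 | time-locked | 1.5 | — | — | 0.35 / 0.60 |
| `awake_fsu` | FSU | 15 | delayed | 1.8 | N(0.51, 0.14²) | (0.10, 1.20) | 0.15 / 0.25 |
| `anesth_fsu` | FSU | 15 | delayed | 1.4 | N(0.24, 0.08²) | (0.068, 0.80) | 0.15 / 0.25 |
| `sham` | RSU | 5 | none | — | — | — | 0.35 / 0.60 |

Rates (5 Hz regular-spiking, 15 Hz fast-spiking) and gains are field-typical
magnitudes; the latency distributions are the modeled population parameters.
`generate_session` derives one independent stream per unit from a single
session seed via `numpy.random.SeedSequence.spawn`, so sessions are exactly
reproducible and units are order-independent. Optional additive artifact
epochs (merged if overlapping) and rendered extracellular traces
(template convolution plus white noise, one channel per unit) are available.

**What the generator emulates / does not emulate.** It captures baseline
rates, time-locked and delayed rate modulation, waveform shape differences,
refractoriness, ISI jitter, and artifacts. It does not model bursting,
rate drift or nonstationarity, multi-unit channels or spike overlap,
trial-to-trial latency variability (onset is per-unit, not per-trial), or
waveform variability beyond additive noise.

## 3. Spike processing

- **Filtering**: 4th-order Butterworth band-pass 300–5000 Hz, applied
  forward–backward (`sosfiltfilt`) for zero phase distortion.
- **Noise estimate**: `σ = MAD / 0.6745` (median absolute deviation), robust
  to the spikes themselves.
- **Detection**: negative threshold crossings at `−k·σ` (default k = 5),
  1 ms lockout, spike time at the local minimum, snippets −0.5/+1.5 ms.
- **Features**: from the mean waveform, a baseline band (mean ± 3 SD of the
  first 0.2 ms) defines "at baseline"; the initial-phase duration `ip_ms`
  runs from the last in-band sample before the trough (found by a backward
  walk from the trough) to the post-trough zero crossing, and `ahp_ms` spans
  the positive phase; sub-sample boundaries are linearly interpolated.
  Templates without a defined biphasic structure raise
  `FeatureUndefinedError`.
- **Quality control** (`qc_units`): units are removed, with reasons, for
  `"amplitude"` (no positive phase above the baseline band), `"presence"`
  (no spikes in ≥1 of 10 equal recording segments), or `"refractory"`
  (>1% of ISIs below 1 ms).
- **Artifact masking**: spikes inside artifact epochs are removed and any
  trial whose analysis window [−0.5, +1.5] s overlaps an epoch is excluded.

## 4. PSTH and response detection

PSTHs span −0.5 to +1.5 s around each trigger in 35.7 ms bins. Only full
bins are kept — `floor(2.0 / 0.0357) = 56` bins, of which the first
`floor(0.5 / 0.0357) = 14` are baseline. The first 5 trials are dropped
(default), so a 505-trigger session yields 500 analyzed trials. Bin values
are mean spikes per bin per trial. All bin and window comparisons use
half-open intervals `[a, b)`.

**Baseline SEM.** Two estimators are provided (`sem_mode`):

- `"trials"` (default): SD of per-trial baseline spike counts, pooled across
  baseline bins, divided by √n_trials — the uncertainty of the baseline mean
  as estimated from trials;
- `"bins"`: SD across the 14 baseline bin values divided by √14.

The default is `"trials"`. With `"bins"`, the detector threshold
(mean + 1 SEM) sits only ≈ SD/√14 ≈ 0.27 bin-SDs above the baseline mean, so
a pure-noise PSTH produces a 3-consecutive-bin excursion somewhere in a
1.4 s search window roughly 45% of the time, contaminating population
latency estimates with false early onsets. With `"trials"` at 500 trials the
threshold sits near one bin-SD and the false-positive rate is low.

**Detector.** A response is significant when ≥3 consecutive bins (within an
optional search window, selected by bin left edge) are ≥ baseline mean +
1 SEM. The latency is reported at the **bin center** of the earliest run's
first bin (`latency_at="center"`, default); left-edge reporting is available
but carries a systematic −bin_width/2 ≈ −18 ms bias for onsets uniform
within a bin. A zero SEM (e.g. silent baseline) is flagged as
`degenerate_sem` rather than silently trusted. `classify_response` labels a
detection `time_locked` if latency ≤ pd, else `delayed`.

**Structural note.** At 35.7 ms bins, at most two bins overlap a 67 ms
stimulus, so a 3-bin run can never lie entirely inside it: responses strictly
confined to the stimulus cannot be detected by the run rule. Time-locked
effects are therefore quantified by the **normalized response** — the
time-weighted mean rate in a window (partial bins weighted by overlap) as a
percentage of the baseline rate. A zero baseline raises `NormalizationError`.
`baseline_stability` screens PSTHs whose baseline coefficient of variation
exceeds 0.5.

## 5. Cell-type classification

k-means (k = 2, scikit-learn, `n_init=10`, seeded) on the unstandardized
`(ip_ms, ahp_ms)` plane; the cluster with the smaller feature sum is
fast-spiking. Both features are in milliseconds and of the same scale, so no
standardization is applied. Per-unit ambiguity is the ratio of distances to
the nearer and farther centroid; units with ratio > 0.8 are tie-broken by
firing rate (≥10 Hz → FSU, else RSU). Degenerate inputs (fewer than two
distinct feature points) raise `ClassificationError`.

## 6. Statistics

Shapiro–Wilk per group (`normality`), Kruskal–Wallis omnibus (`omnibus`),
Wilcoxon rank-sum pairwise (`rank_sum`: exact when both n ≤ 10 and there are
no ties, asymptotic otherwise) with Bonferroni correction over all
k(k−1)/2 pairs (`pairwise`), and a two-factor ANOVA via statsmodels
(`two_factor`, type-II sums of squares, optionally on ranks; empty cells are
an error). `compare_latencies` is the rank-sum applied to two latency
samples. The test suite cross-checks the exact rank-sum p-value against a
brute-force enumeration over all label assignments and calibrates
Kruskal–Wallis type-I error by simulation.

## 7. Problem sizes and runtime

Package validation uses 200 units per condition at full session scale
(505 triggers, 500 analyzed trials) for latency recovery, 100 units for
normalization calibration, 2000 simulations for type-I error calibration,
and 40 seeds for distribution-separability checks. These sizes keep the full
test suite under ~15 s on one CPU while giving Monte-Carlo error well below
the stated tolerances.

## 8. Known limitations

- The run-rule detector cannot see sub-67 ms time-locked responses (see the
  structural note above); use the normalized response for those.
- Detected latency is quantized to the bin grid; bin-center reporting removes
  the systematic edge bias but not the quantization.
- The generator's per-unit (not per-trial) onset makes delayed responses
  sharper than real data; recovered population latency SDs are accordingly
  optimistic.
- `load_nwb_session` is a documented loader contract (raises
  `NotImplementedError`); NWB support requires pynwb, which is deliberately
  not a dependency.
- Spike detection assumes negative-going spikes on single-unit channels; no
  clustering/sorting of overlapping units is attempted.
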