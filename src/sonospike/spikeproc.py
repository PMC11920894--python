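"""Continuous-trace spike processing and unit-level quality control.

Covers the standard extracellular chain: zero-phase bandpass filtering
(300 Hz - 5 kHz), threshold spike detection against a robust noise
estimate, extraction of the two waveform-duration features used for
cell-type classification (initial-phase and after-hyperpolarization
durations), unit quality filters, and artifact-epoch masking.

The detector assumes one putative unit per channel; it is a deliberately
simple single-threshold detector intended for synthetic traces with known
ground truth, not a full multi-unit spike sorter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, sosfiltfilt


class FeatureUndefinedError(ValueError):
    """Waveform features cannot be extracted (e.g. no biphasic structure)."""


@dataclass
class UnitRecording:
    """Spike times and mean waveform for one sorted unit.

    ``spike_times`` are sorted ascending, in seconds from session start.
    ``template`` is the mean extracellular waveform (one row of samples at
    ``sample_rate``). ``truth`` optionally carries ground-truth generator
    metadata (cell type, response kind, drawn onset) for synthetic units.
    """

    unit_id: str
    spike_times: np.ndarray
    template: np.ndarray
    sample_rate: float
    duration: float
    channel: int = 0
    truth: dict = field(default_factory=dict)

    @property
    def mean_rate(self) -> float:
        """Session-wide mean firing rate, Hz."""
        return len(self.spike_times) / self.duration


@dataclass(frozen=True)
class WaveformFeatures:
    """Phase durations and amplitudes of a biphasic action potential."""

    ip_ms: float
    ahp_ms: float
    peak_pos_amp: float
    trough_amp: float


def bandpass(
    trace: np.ndarray,
    sample_rate: float,
    low: float = 300.0,
    high: float = 5000.0,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth bandpass (forward-backward filtering).

    Output has the same length as the input; the double pass cancels the
    filter's phase delay so spike shapes are not skewed.
    """
    if high >= sample_rate / 2:
        raise ValueError(
            f"high edge {high} Hz must be below Nyquist {sample_rate / 2} Hz"
        )
    if not 0 < low < high:
        raise ValueError("band edges must satisfy 0 < low < high")
    sos = butter(order, [low, high], btype="bandpass", fs=sample_rate, output="sos")
    return sosfiltfilt(sos, np.asarray(trace, dtype=float))


def mad_noise_sd(trace: np.ndarray) -> float:
    """Robust noise SD estimate: median absolute deviation / 0.6745.

    Insensitive to the spikes themselves, unlike the raw SD.
    """
    med = np.median(trace)
    return float(np.median(np.abs(trace - med)) / 0.6745)


def detect_spikes(
    trace: np.ndarray,
    sample_rate: float,
    k_thresh: float = 5.0,
    lockout_ms: float = 1.0,
    snippet_ms: tuple[float, float] = (0.5, 1.5),
) -> tuple[np.ndarray, np.ndarray]:
    """Threshold detection of negative-going spikes on a filtered trace.

    The threshold is ``-k_thresh`` times the MAD noise estimate. Each
    sub-threshold excursion yields one event at its trough, with a
    refractory lockout of ``lockout_ms`` between accepted troughs. Snippets
    span ``-snippet_ms[0]`` to ``+snippet_ms[1]`` around the trough.

    Returns ``(spike_times_s, snippets)``; a flat or spike-free trace
    returns empty arrays rather than raising.
    """
    trace = np.asarray(trace, dtype=float)
    sd = mad_noise_sd(trace)
    if sd == 0.0 and np.all(trace == trace[0] if len(trace) else True):
        n_pre = int(round(snippet_ms[0] * 1e-3 * sample_rate))
        n_post = int(round(snippet_ms[1] * 1e-3 * sample_rate))
        return np.array([]), np.empty((0, n_pre + n_post + 1))
    thresh = -k_thresh * sd
    below = trace < thresh
    if not below.any():
        n_pre = int(round(snippet_ms[0] * 1e-3 * sample_rate))
        n_post = int(round(snippet_ms[1] * 1e-3 * sample_rate))
        return np.array([]), np.empty((0, n_pre + n_post + 1))

    # contiguous sub-threshold runs -> candidate troughs
    idx = np.flatnonzero(below)
    run_breaks = np.flatnonzero(np.diff(idx) > 1)
    run_starts = np.concatenate([[0], run_breaks + 1])
    run_ends = np.concatenate([run_breaks, [len(idx) - 1]])
    troughs = np.array(
        [idx[s] + np.argmin(trace[idx[s] : idx[e] + 1]) for s, e in zip(run_starts, run_ends)]
    )

    lockout = int(round(lockout_ms * 1e-3 * sample_rate))
    accepted: list[int] = []
    last = -lockout - 1
    for tr in troughs:
        if tr - last > lockout:
            accepted.append(int(tr))
            last = tr
    troughs = np.array(accepted)

    n_pre = int(round(snippet_ms[0] * 1e-3 * sample_rate))
    n_post = int(round(snippet_ms[1] * 1e-3 * sample_rate))
    keep = (troughs >= n_pre) & (troughs + n_post < len(trace))
    troughs = troughs[keep]
    snippets = np.stack(
        [trace[t - n_pre : t + n_post + 1] for t in troughs], axis=0
    ) if len(troughs) else np.empty((0, n_pre + n_post + 1))
    return troughs / sample_rate, snippets


def extract_features(
    template: np.ndarray,
    sample_rate: float,
    baseline_ms: float = 0.2,
) -> WaveformFeatures:
    """Phase durations of a biphasic (trough-then-hump) waveform.

    Baseline is the mean of the first ``baseline_ms`` of the template, with
    a tolerance band of +/- 3 SD of that segment. The waveform onset is the
    last in-band sample before the trough (i.e. where the trace leaves the
    baseline band on its way down). The initial phase (IP) runs from onset
    to the first baseline crossing after the trough; the
    after-hyperpolarization phase (AHP) runs from that crossing to the next
    recrossing of baseline. Crossing times are linearly interpolated between
    samples so feature precision is not locked to the sample grid.

    Raises
    ------
    FeatureUndefinedError
        If the template has no trough below the baseline band, never
        recrosses baseline after the trough, or has no positive phase.
    """
    x = np.asarray(template, dtype=float)
    n0 = max(2, int(round(baseline_ms * 1e-3 * sample_rate)))
    if len(x) < n0 + 4:
        raise FeatureUndefinedError("template too short for feature extraction")
    base = x[:n0]
    mu = float(base.mean())
    band = 3.0 * float(base.std())

    trough_idx = int(np.argmin(x))
    trough_amp = mu - x[trough_idx]
    if x[trough_idx] >= mu - band or trough_amp <= 0:
        raise FeatureUndefinedError("no trough below baseline band")

    # onset: walk back from the trough to the last sample inside the band
    onset_idx = trough_idx
    while onset_idx > 0 and abs(x[onset_idx - 1] - mu) > band:
        onset_idx -= 1
    onset_idx = max(onset_idx - 1, 0)
    t_onset = onset_idx / sample_rate

    def _crossing_up(start: int) -> float | None:
        for i in range(start, len(x)):
            if x[i] >= mu:
                if i == 0 or x[i] == mu:
                    return i / sample_rate
                frac = (mu - x[i - 1]) / (x[i] - x[i - 1])
                return (i - 1 + frac) / sample_rate
        return None

    def _crossing_down(start: int) -> float | None:
        for i in range(start, len(x)):
            if x[i] <= mu:
                if x[i] == mu or x[i - 1] == x[i]:
                    return i / sample_rate
                frac = (x[i - 1] - mu) / (x[i - 1] - x[i])
                return (i - 1 + frac) / sample_rate
        return None

    t_cross1 = _crossing_up(trough_idx + 1)
    if t_cross1 is None:
        raise FeatureUndefinedError("waveform never returns to baseline after trough")

    after = x[int(np.ceil(t_cross1 * sample_rate)) :]
    if len(after) == 0 or after.max() <= mu:
        raise FeatureUndefinedError("no positive after-hyperpolarization phase")
    peak_rel = int(np.argmax(after)) + int(np.ceil(t_cross1 * sample_rate))
    t_cross2 = _crossing_down(peak_rel + 1)
    if t_cross2 is None:
        raise FeatureUndefinedError("after-hyperpolarization never recrosses baseline")

    ip_ms = (t_cross1 - t_onset) * 1e3
    ahp_ms = (t_cross2 - t_cross1) * 1e3
    peak_pos_amp = float(x[peak_rel] - mu)
    return WaveformFeatures(
        ip_ms=ip_ms, ahp_ms=ahp_ms, peak_pos_amp=peak_pos_amp, trough_amp=trough_amp
    )


def qc_units(
    units: list[UnitRecording],
    duration: float,
    n_presence_segments: int = 10,
    refractory_ms: float = 1.0,
    max_refractory_frac: float = 0.01,
    baseline_ms: float = 0.2,
) -> tuple[list[UnitRecording], list[tuple[UnitRecording, list[str]]]]:
    """Apply unit-level quality filters; return (kept, removed-with-reasons).

    Removal reasons:

    - ``"amplitude"``: template peak positive amplitude does not exceed the
      baseline band (mean +/- 3 SD of the first 0.2 ms).
    - ``"presence"``: no spike in at least one of ``n_presence_segments``
      equal segments of the session (unit not present throughout).
    - ``"refractory"``: more than ``max_refractory_frac`` of inter-spike
      intervals are shorter than ``refractory_ms`` (contaminated cluster).
    """
    kept: list[UnitRecording] = []
    removed: list[tuple[UnitRecording, list[str]]] = []
    for u in units:
        reasons: list[str] = []

        x = np.asarray(u.template, dtype=float)
        n0 = max(2, int(round(baseline_ms * 1e-3 * u.sample_rate)))
        mu = x[:n0].mean()
        band = 3.0 * x[:n0].std()
        if len(x) < n0 or x.max() <= mu + band:
            reasons.append("amplitude")

        seg = duration / n_presence_segments
        seg_idx = np.minimum(
            (np.asarray(u.spike_times) / seg).astype(int), n_presence_segments - 1
        )
        if len(np.unique(seg_idx)) < n_presence_segments:
            reasons.append("presence")

        if len(u.spike_times) >= 2:
            isi = np.diff(u.spike_times)
            if np.mean(isi < refractory_ms * 1e-3) > max_refractory_frac:
                reasons.append("refractory")

        if reasons:
            removed.append((u, reasons))
        else:
            kept.append(u)
    return kept, removed


def mask_artifacts(
    spike_times: np.ndarray,
    artifact_epochs: list[tuple[float, float]],
    triggers: np.ndarray,
    t_pre: float = 0.5,
    t_post: float = 1.5,
) -> tuple[np.ndarray, list[int]]:
    """Remove spikes inside artifact epochs and flag contaminated trials.

    A trial is excluded when its analysis window ``[trigger - t_pre,
    trigger + t_post]`` overlaps any epoch. Returns the cleaned spike times
    and the excluded trial indices (into ``triggers``).
    """
    spike_times = np.asarray(spike_times, dtype=float)
    triggers = np.asarray(triggers, dtype=float)
    keep = np.ones(len(spike_times), dtype=bool)
    excluded: set[int] = set()
    for start, end in artifact_epochs:
        if end < start:
            raise ValueError("artifact epoch with end < start")
        keep &= ~((spike_times >= start) & (spike_times <= end))
        overlap = (triggers - t_pre <= end) & (triggers + t_post >= start)
        excluded.update(np.flatnonzero(overlap).tolist())
    return spike_times[keep], sorted(excluded)
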