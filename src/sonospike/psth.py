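"""Trial-aligned PSTHs, baseline-normalized responses, and latency detection.

The peristimulus time histogram (PSTH) spans 0.5 s before to 1.5 s after
stimulus onset in 35.7 ms bins; per-bin values are mean spikes per bin per
trial after dropping the first five trials of a session. Baseline
statistics come from the bins entirely before onset. A unit responds
significantly when at least ``min_consec`` (default 3) consecutive bins
sit at or above baseline mean + 1 SEM; the response latency is the left
edge of the first bin of the earliest qualifying run. A response is
*time-locked* when that latency falls within the stimulus duration and
*delayed* when it falls after it.

The baseline SEM can be estimated two ways (``sem_mode``):

- ``"trials"`` (default): pooled SD of single-trial baseline bin counts
  divided by sqrt(n_trials) — the sampling error of one trial-averaged
  bin. This keeps the false-positive rate of the 3-bin run rule low.
- ``"bins"``: SD of the ~14 trial-averaged baseline bin values divided by
  sqrt(n_bins) — the sampling error of the baseline mean itself, a much
  smaller number that makes the run rule very permissive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_BIN_WIDTH = 0.0357  # s
DEFAULT_T_PRE = 0.5
DEFAULT_T_POST = 1.5


class NormalizationError(ValueError):
    """Baseline rate is zero; percent-of-baseline response is undefined."""


@dataclass
class Psth:
    """Trial-averaged binned spike counts for one unit.

    ``values[k]`` is the mean spike count in bin ``k`` per trial; bin ``k``
    spans ``[-t_pre + k*bin_width, -t_pre + (k+1)*bin_width)`` relative to
    stimulus onset. The trailing partial bin is discarded.
    """

    bin_width: float
    t_pre: float
    t_post: float
    values: np.ndarray
    n_trials_used: int
    baseline_mean: float
    baseline_sem: float
    n_baseline_bins: int

    @property
    def left_edges(self) -> np.ndarray:
        return -self.t_pre + np.arange(len(self.values)) * self.bin_width

    @property
    def baseline_values(self) -> np.ndarray:
        return self.values[: self.n_baseline_bins]

    @property
    def baseline_sd(self) -> float:
        """SD of the trial-averaged baseline bin values."""
        if self.n_baseline_bins < 2:
            return 0.0
        return float(np.std(self.baseline_values, ddof=1))


@dataclass(frozen=True)
class ResponseDetection:
    """Outcome of the consecutive-bin significance rule."""

    significant: bool
    latency: float | None
    degenerate_sem: bool = False  # baseline SEM was zero; rule fires trivially


@dataclass(frozen=True)
class ResponseResult:
    """Normalized response of one unit in one analysis window."""

    unit_id: str
    window: tuple[float, float]
    normalized_rate: float  # percent of baseline
    significant: bool
    latency: float | None
    response_class: str  # "time_locked" | "delayed" | "none"


def compute_psth(
    spike_times: np.ndarray,
    triggers: np.ndarray,
    excluded_trials: list[int] | None = None,
    bin_width: float = DEFAULT_BIN_WIDTH,
    t_pre: float = DEFAULT_T_PRE,
    t_post: float = DEFAULT_T_POST,
    drop_first: int = 5,
    sem_mode: str = "trials",
) -> Psth:
    """Trial-aligned PSTH with baseline statistics.

    The first ``drop_first`` triggers are discarded (settling period), then
    any ``excluded_trials`` (indices into the original trigger list). Bins
    cover ``[-t_pre, t_post)``; only the ``floor((t_pre+t_post)/bin_width)``
    full bins are kept. Baseline bins are those entirely before onset.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    triggers = np.asarray(triggers, dtype=float)
    spike_times = np.sort(np.asarray(spike_times, dtype=float))
    excluded = set(excluded_trials or ())
    use = [
        i for i in range(len(triggers)) if i >= drop_first and i not in excluded
    ]
    n_used = len(use)
    if n_used == 0:
        raise ValueError("no trials remain after drop_first and exclusions")

    n_bins = int(np.floor((t_pre + t_post) / bin_width + 1e-9))
    edges = -t_pre + np.arange(n_bins + 1) * bin_width
    counts = np.zeros((n_used, n_bins))
    for row, i in enumerate(use):
        t0 = triggers[i]
        lo = np.searchsorted(spike_times, t0 + edges[0])
        hi = np.searchsorted(spike_times, t0 + edges[-1])
        rel = spike_times[lo:hi] - t0
        counts[row], _ = np.histogram(rel, bins=edges)

    values = counts.mean(axis=0)
    n_base = int(np.floor(t_pre / bin_width + 1e-9))
    base_vals = values[:n_base]
    baseline_mean = float(base_vals.mean()) if n_base else 0.0
    if sem_mode == "bins":
        sem = (
            float(np.std(base_vals, ddof=1)) / np.sqrt(n_base)
            if n_base >= 2
            else 0.0
        )
    elif sem_mode == "trials":
        base_counts = counts[:, :n_base].ravel()
        sem = (
            float(np.std(base_counts, ddof=1)) / np.sqrt(n_used)
            if len(base_counts) >= 2
            else 0.0
        )
    else:
        raise ValueError(f"unknown sem_mode {sem_mode!r}")

    return Psth(
        bin_width=bin_width,
        t_pre=t_pre,
        t_post=t_post,
        values=values,
        n_trials_used=n_used,
        baseline_mean=baseline_mean,
        baseline_sem=sem,
        n_baseline_bins=n_base,
    )


def normalized_response(psth: Psth, window: tuple[float, float]) -> float:
    """Mean spike rate in ``window`` as a percent of the baseline rate.

    Bins partially overlapping the window contribute time-weighted rates,
    so window edges need not align with the bin grid.
    """
    start, end = window
    if end <= start:
        raise ValueError("window end must exceed start")
    if start < -psth.t_pre - 1e-9 or end > psth.t_post + 1e-9:
        raise ValueError("window outside PSTH span")
    if psth.baseline_mean <= 0:
        raise NormalizationError("baseline rate is zero; response undefined")

    edges = np.concatenate([psth.left_edges, [psth.left_edges[-1] + psth.bin_width]])
    overlap = np.minimum(edges[1:], end) - np.maximum(edges[:-1], start)
    overlap = np.clip(overlap, 0.0, None)
    rates = psth.values / psth.bin_width
    window_rate = float(np.sum(rates * overlap) / overlap.sum())
    baseline_rate = psth.baseline_mean / psth.bin_width
    return 100.0 * window_rate / baseline_rate


def detect_response(
    psth: Psth,
    search_window: tuple[float, float] | None = None,
    min_consec: int = 3,
    latency_at: str = "center",
) -> ResponseDetection:
    """Consecutive-bin significance rule with run-onset latency.

    Scans bins whose left edge lies in ``search_window`` (half-open,
    default ``[0, t_post)``). Significant iff at least ``min_consec``
    consecutive bins have value >= baseline mean + baseline SEM; latency is
    reported from the first bin of the earliest qualifying run. With
    ``latency_at="center"`` (default) the bin center is reported — the
    unbiased estimate of an onset uniformly positioned within the bin;
    ``"left_edge"`` reports the bin's left edge instead. A zero baseline
    SEM with elevated bins still fires the rule (>= comparison) and is
    flagged ``degenerate_sem``.
    """
    if latency_at not in ("center", "left_edge"):
        raise ValueError("latency_at must be 'center' or 'left_edge'")
    if search_window is None:
        search_window = (0.0, psth.t_post)
    start, end = search_window
    edges = psth.left_edges
    mask = (edges >= start - 1e-12) & (edges < end - 1e-12)
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        return ResponseDetection(False, None)
    thresh = psth.baseline_mean + psth.baseline_sem
    above = psth.values[idx] >= thresh

    offset = 0.5 * psth.bin_width if latency_at == "center" else 0.0
    run = 0
    for j, ok in enumerate(above):
        run = run + 1 if ok else 0
        if run == min_consec:
            first = idx[j - min_consec + 1]
            return ResponseDetection(
                True,
                float(edges[first] + offset),
                degenerate_sem=(psth.baseline_sem == 0.0),
            )
    return ResponseDetection(False, None)


def classify_response(detection: ResponseDetection, pd: float) -> str:
    """Classify a detection as time-locked, delayed, or none.

    Time-locked: the qualifying run starts at or before the end of the
    stimulus (latency <= pd). Delayed: the earliest run starts after the
    stimulus. At the 35.7 ms bin width a 3-bin run cannot fit inside a
    67 ms stimulus, so classification keys on the run start, not its span.
    """
    if not detection.significant or detection.latency is None:
        return "none"
    return "time_locked" if detection.latency <= pd else "delayed"


def baseline_stability(psth: Psth, cv_thresh: float = 0.5) -> bool:
    """Automated screen for fluctuating/artifact-contaminated baselines.

    Fails when the coefficient of variation of the baseline bins exceeds
    ``cv_thresh`` or any baseline bin exceeds mean + 5 SD. An all-zero
    baseline (undefined CV) also fails.
    """
    if psth.n_baseline_bins < 5:
        raise ValueError("need at least 5 baseline bins")
    vals = psth.baseline_values
    if psth.baseline_mean <= 0:
        return False
    sd = psth.baseline_sd
    if sd / psth.baseline_mean > cv_thresh:
        return False
    if np.any(vals > psth.baseline_mean + 5.0 * sd):
        return False
    return True


def latency_summary(
    latencies: np.ndarray | list[float],
    hist_bin: float = 0.05,
    hist_range: tuple[float, float] = (0.0, 1.5),
) -> tuple[float, float, tuple[np.ndarray, np.ndarray]]:
    """Mean, SD and histogram of per-unit response-onset latencies."""
    lat = np.asarray(latencies, dtype=float)
    if len(lat) == 0:
        raise ValueError("no latencies to summarize")
    mean = float(lat.mean())
    sd = float(lat.std(ddof=1)) if len(lat) > 1 else 0.0
    n_bins = int(round((hist_range[1] - hist_range[0]) / hist_bin))
    hist, edges = np.histogram(lat, bins=n_bins, range=hist_range)
    return mean, sd, (hist, edges)
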