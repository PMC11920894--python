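"""Basic diagnostic plots: PSTH, raster, latency histogram."""

from __future__ import annotations

import numpy as np

from .psth import Psth


def plot_psth(psth: Psth, ax=None, stim_dur: float | None = None):
    """Bar PSTH with the baseline mean +/- 1 SEM band and stimulus onset."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.bar(psth.left_edges, psth.values, width=psth.bin_width, align="edge",
           color="0.3")
    ax.axhline(psth.baseline_mean, color="tab:blue", lw=1, label="baseline")
    ax.axhline(psth.baseline_mean + psth.baseline_sem, color="tab:blue",
               lw=0.8, ls="--", label="baseline + 1 SEM")
    ax.axvline(0.0, color="tab:red", lw=1)
    if stim_dur:
        ax.axvspan(0.0, stim_dur, color="tab:red", alpha=0.15)
    ax.set_xlabel("time from stimulus onset (s)")
    ax.set_ylabel("spikes / bin / trial")
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_raster(spike_times, triggers, t_pre=0.5, t_post=1.5, ax=None):
    """Trial raster aligned to stimulus onset."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    spike_times = np.asarray(spike_times)
    for i, t0 in enumerate(triggers):
        rel = spike_times[(spike_times >= t0 - t_pre) & (spike_times < t0 + t_post)] - t0
        ax.plot(rel, np.full(len(rel), i), "|", color="k", ms=2)
    ax.axvline(0.0, color="tab:red", lw=1)
    ax.set_xlabel("time from stimulus onset (s)")
    ax.set_ylabel("trial")
    return ax


def plot_latency_hist(latencies_by_condition: dict, bin_width=0.05, ax=None):
    """Overlaid onset-latency histograms per condition."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    bins = np.arange(0.0, 1.5 + bin_width, bin_width)
    for name, lat in latencies_by_condition.items():
        ax.hist(lat, bins=bins, alpha=0.5, label=name)
    ax.set_xlabel("delayed-response onset latency (s)")
    ax.set_ylabel("units")
    ax.legend(frameon=False)
    return ax
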