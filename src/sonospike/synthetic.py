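"""Ground-truth-labeled synthetic sessions of ultrasound-stimulation spiking.

Spike trains are inhomogeneous Poisson processes generated by thinning,
with an absolute refractory period imposed afterwards: a unit fires at its
baseline rate everywhere except inside a per-trial response window, where
the rate is multiplied by ``gain``. Two response
motifs are modeled, matching the structure reported for somatosensory
units under pulsed focused ultrasound:

- *time-locked* (regular-spiking units): elevation during the stimulus
  itself, window ``[trigger, trigger + pd]``;
- *delayed* (fast-spiking units): elevation starting after the stimulus,
  window ``[trigger + onset, trigger + onset + response_dur]`` where the
  onset is drawn once per unit from a truncated Normal. Awake fast-spiking
  onsets are Normal(0.51 s, 0.14 s); anesthetized onsets are
  Normal(0.24 s, 0.08 s).

Waveform templates are biphasic piecewise raised-cosine lobes (negative
trough then positive after-hyperpolarization hump) whose baseline
crossings fall exactly at the requested initial-phase and AHP durations,
so feature extraction can be validated by round-trip.

Baseline rates and response gains are fixture choices (5 Hz regular /
15 Hz fast-spiking; gains below); they set detection comfortably above
threshold at full session scale and are configurable per UnitSpec.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .acoustics import StimulusProtocol, trial_triggers
from .spikeproc import UnitRecording

TEMPLATE_SAMPLE_RATE = 30_000.0
AHP_AMP_FRAC = 0.35  # positive hump amplitude relative to trough depth


@dataclass(frozen=True)
class UnitSpec:
    """Generative parameters for one synthetic unit.

    ``gain`` multiplies the baseline rate inside the response window
    (values < 1 encode inhibition); ``onset_*`` parameterize the truncated
    Normal from which a delayed unit's onset latency is drawn once per
    unit. ``ip_dur``/``ahp_dur`` (ms) shape the waveform template.
    """

    cell_type: str  # "RSU" | "FSU"
    baseline_rate: float
    response_kind: str  # "time_locked" | "delayed" | "inhibited" | "none"
    gain: float = 1.0
    onset_mean: float = 0.0
    onset_sd: float = 0.0
    onset_trunc: tuple[float, float] = (0.0, 0.0)
    response_dur: float = 0.3
    ip_dur: float = 0.35
    ahp_dur: float = 0.60
    amp: float = 10.0
    refractory: float = 0.0015  # absolute refractory period, s

    def __post_init__(self) -> None:
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be positive")
        if self.gain <= 0:
            raise ValueError("gain must be positive")
        if self.onset_trunc[0] < 0:
            raise ValueError("onset truncation lower bound must be >= 0")
        if self.ip_dur <= 0 or self.ahp_dur <= 0:
            raise ValueError("phase durations must be positive")
        if self.response_dur <= 0:
            raise ValueError("response_dur must be positive")


# Frozen presets. Onset-latency distributions are the reported awake /
# anesthetized fast-spiking values; truncation keeps every delayed onset
# after the 67 ms stimulus. Rates, gains and waveform durations are
# fixture choices (no magnitudes are reported for either cell class).
_PRESETS: dict[str, UnitSpec] = {
    "awake_rsu": UnitSpec(
        cell_type="RSU", baseline_rate=5.0, response_kind="time_locked",
        gain=2.0, ip_dur=0.35, ahp_dur=0.60, amp=10.0,
    ),
    "anesth_rsu": UnitSpec(
        cell_type="RSU", baseline_rate=5.0, response_kind="time_locked",
        gain=1.5, ip_dur=0.35, ahp_dur=0.60, amp=10.0,
    ),
    "awake_fsu": UnitSpec(
        cell_type="FSU", baseline_rate=15.0, response_kind="delayed",
        gain=1.8, onset_mean=0.51, onset_sd=0.14, onset_trunc=(0.10, 1.20),
        ip_dur=0.15, ahp_dur=0.25, amp=10.0,
    ),
    "anesth_fsu": UnitSpec(
        cell_type="FSU", baseline_rate=15.0, response_kind="delayed",
        gain=1.4, onset_mean=0.24, onset_sd=0.08, onset_trunc=(0.068, 0.80),
        ip_dur=0.15, ahp_dur=0.25, amp=10.0,
    ),
    "sham": UnitSpec(
        cell_type="RSU", baseline_rate=5.0, response_kind="none",
        ip_dur=0.35, ahp_dur=0.60, amp=10.0,
    ),
}


def preset(name: str) -> UnitSpec:
    """Return one of the frozen unit presets.

    Available: ``awake_rsu``, ``anesth_rsu``, ``awake_fsu``, ``anesth_fsu``,
    ``sham``.
    """
    try:
        return _PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(_PRESETS)}"
        ) from None


@dataclass
class SessionFixture:
    """A complete synthetic recording session with ground truth."""

    protocol: StimulusProtocol
    triggers: np.ndarray
    units: list[UnitRecording]
    artifact_epochs: list[tuple[float, float]]
    seed: int
    traces: np.ndarray | None = None  # (n_units, n_samples) float32
    trace_sample_rate: float | None = None

    @property
    def duration(self) -> float:
        return float(self.triggers[-1] + self.protocol.isi)


def generate_template(
    ip_ms: float,
    ahp_ms: float,
    amp: float,
    sample_rate: float = TEMPLATE_SAMPLE_RATE,
    pre_pad_ms: float = 0.5,
    post_pad_ms: float = 0.5,
    ahp_amp_frac: float = AHP_AMP_FRAC,
) -> np.ndarray:
    """Biphasic action-potential template with exact phase durations.

    The waveform is zero during the pre-pad, then a negative raised-cosine
    lobe of duration ``ip_ms`` (the initial phase, trough at its midpoint),
    then a positive raised-cosine lobe of duration ``ahp_ms`` (the
    after-hyperpolarization hump, amplitude ``ahp_amp_frac * amp``), then
    zero. Baseline crossings therefore sit exactly at the lobe boundaries.
    """
    if sample_rate < 20_000:
        raise ValueError("sample_rate must be >= 20 kHz for waveform templates")
    if amp <= 0:
        raise ValueError("amp must be positive (degenerate template)")
    n_ip = int(round(ip_ms * 1e-3 * sample_rate))
    n_ahp = int(round(ahp_ms * 1e-3 * sample_rate))
    if n_ip < 2 or n_ahp < 2:
        raise ValueError("phase durations must span at least 2 samples")
    n_pre = int(round(pre_pad_ms * 1e-3 * sample_rate))
    n_post = int(round(post_pad_ms * 1e-3 * sample_rate))
    t_ip = np.arange(n_ip) / n_ip
    t_ahp = np.arange(n_ahp) / n_ahp
    lobe_neg = -amp * 0.5 * (1.0 - np.cos(2.0 * np.pi * t_ip))
    lobe_pos = ahp_amp_frac * amp * 0.5 * (1.0 - np.cos(2.0 * np.pi * t_ahp))
    return np.concatenate(
        [np.zeros(n_pre), lobe_neg, lobe_pos, np.zeros(n_post)]
    )


def _response_windows(
    spec: UnitSpec, protocol: StimulusProtocol, triggers: np.ndarray, onset: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial (start, end) of the rate-modulation window, absolute time."""
    if spec.response_kind == "time_locked":
        return triggers, triggers + protocol.pd
    if spec.response_kind in ("delayed", "inhibited"):
        return triggers + onset, triggers + onset + spec.response_dur
    return np.empty(0), np.empty(0)


def draw_onset(spec: UnitSpec, rng: np.random.Generator) -> float:
    """Draw a unit's delayed-response onset from its truncated Normal."""
    lo, hi = spec.onset_trunc
    for _ in range(10_000):
        x = rng.normal(spec.onset_mean, spec.onset_sd)
        if lo <= x <= hi:
            return float(x)
    raise RuntimeError("onset truncation bounds reject essentially all draws")


def generate_unit(
    spec: UnitSpec,
    protocol: StimulusProtocol,
    triggers: np.ndarray,
    seed: int | np.random.SeedSequence,
    unit_id: str = "u0",
    channel: int = 0,
) -> UnitRecording:
    """Simulate one unit's spike train by Poisson thinning.

    The instantaneous rate is ``baseline_rate`` outside response windows
    and ``baseline_rate * gain`` inside them. For delayed units the onset
    is drawn once (stored in ``truth["onset"]``); the window repeats on
    every trial. Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    duration = float(triggers[-1] + protocol.isi)
    onset = 0.0
    if spec.response_kind in ("delayed", "inhibited"):
        onset = draw_onset(spec, rng)
    starts, ends = _response_windows(spec, protocol, triggers, onset)

    rate_max = spec.baseline_rate * max(spec.gain, 1.0)
    n_cand = rng.poisson(rate_max * duration)
    t_cand = np.sort(rng.uniform(0.0, duration, size=n_cand))
    in_window = np.zeros(n_cand, dtype=bool)
    if len(starts):
        k = np.searchsorted(starts, t_cand, side="right") - 1
        valid = k >= 0
        in_window[valid] = t_cand[valid] <= ends[k[valid]]
    rate = np.where(in_window, spec.baseline_rate * spec.gain, spec.baseline_rate)
    accept = rng.uniform(0.0, 1.0, size=n_cand) < rate / rate_max
    spikes = t_cand[accept]
    if spec.refractory > 0 and len(spikes) > 1:
        # absolute refractory period: greedily drop spikes too close to the
        # previous accepted spike, as real units cannot fire within it
        keep = [0]
        last = spikes[0]
        for j in range(1, len(spikes)):
            if spikes[j] - last >= spec.refractory:
                keep.append(j)
                last = spikes[j]
        spikes = spikes[keep]

    template = generate_template(spec.ip_dur, spec.ahp_dur, spec.amp)
    truth = {
        "cell_type": spec.cell_type,
        "response_kind": spec.response_kind,
        "onset": onset if spec.response_kind in ("delayed", "inhibited") else None,
        "spec": asdict(spec),
    }
    return UnitRecording(
        unit_id=unit_id,
        spike_times=spikes,
        template=template,
        sample_rate=TEMPLATE_SAMPLE_RATE,
        duration=duration,
        channel=channel,
        truth=truth,
    )


def _render_trace(
    unit: UnitRecording,
    duration: float,
    sample_rate: float,
    artifact_epochs: list[tuple[float, float]],
    rng: np.random.Generator,
    noise_sd: float = 1.0,
    artifact_amp: float = 20.0,
) -> np.ndarray:
    """Continuous voltage trace: templates at spike times + noise + artifacts."""
    n = int(round(duration * sample_rate))
    trace = rng.normal(0.0, noise_sd, size=n).astype(np.float32)
    tpl = unit.template.astype(np.float32)
    trough = int(np.argmin(tpl))
    for t in unit.spike_times:
        i0 = int(round(t * sample_rate)) - trough
        if i0 < 0 or i0 + len(tpl) > n:
            continue
        trace[i0 : i0 + len(tpl)] += tpl
    for start, end in artifact_epochs:
        a, b = int(start * sample_rate), min(int(end * sample_rate), n)
        trace[a:b] += rng.normal(0.0, artifact_amp, size=b - a).astype(np.float32)
    return trace


def generate_session(
    population: list[tuple[UnitSpec, int]],
    protocol: StimulusProtocol,
    seed: int,
    with_trace: bool = False,
    artifact_rate: float = 0.0,
    artifact_dur: float = 0.5,
    trace_sample_rate: float = TEMPLATE_SAMPLE_RATE,
) -> SessionFixture:
    """Generate a full labeled session.

    ``population`` is a list of ``(UnitSpec, count)``; each unit gets its
    own independent random stream (spawned from ``seed``) and its own
    channel. ``artifact_rate`` is the expected number of movement-artifact
    epochs per second (each ``artifact_dur`` long, merged if overlapping).
    With ``with_trace`` a continuous noisy voltage trace is rendered per
    unit channel (memory scales with session length; intended for short
    test sessions).
    """
    triggers = trial_triggers(protocol, seed)
    duration = float(triggers[-1] + protocol.isi)
    ss = np.random.SeedSequence(seed)
    n_units = sum(c for _, c in population)
    children = ss.spawn(n_units + 2)
    art_rng = np.random.default_rng(children[n_units])
    trace_rng = np.random.default_rng(children[n_units + 1])

    epochs: list[tuple[float, float]] = []
    if artifact_rate > 0:
        n_art = art_rng.poisson(artifact_rate * duration)
        starts = np.sort(art_rng.uniform(0.0, duration - artifact_dur, size=n_art))
        for s in starts:
            e = s + artifact_dur
            if epochs and s <= epochs[-1][1]:
                epochs[-1] = (epochs[-1][0], max(epochs[-1][1], e))
            else:
                epochs.append((float(s), float(e)))

    units: list[UnitRecording] = []
    i = 0
    for spec, count in population:
        for _ in range(count):
            units.append(
                generate_unit(
                    spec, protocol, triggers, children[i],
                    unit_id=f"u{i:03d}", channel=i,
                )
            )
            i += 1

    traces = None
    if with_trace:
        traces = np.stack(
            [
                _render_trace(u, duration, trace_sample_rate, epochs, trace_rng)
                for u in units
            ]
        )
    return SessionFixture(
        protocol=protocol,
        triggers=triggers,
        units=units,
        artifact_epochs=epochs,
        seed=seed,
        traces=traces,
        trace_sample_rate=trace_sample_rate if with_trace else None,
    )
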