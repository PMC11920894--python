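"""Pulsed focused-ultrasound protocols and acoustic dose metrics.

A stimulation trial delivers a train of sinusoidal tone bursts: the carrier
at fundamental frequency ``f0`` is gated into bursts of duration ``tbd``
repeated at the pulse repetition frequency ``prf`` for a total stimulus
(pulse) duration ``pd``; trials recur every ``isi`` seconds with optional
timing jitter. Dose is summarized by the duty cycle DC = TBD x PRF, the
pulse intensity integral PII = integral of p^2(t)/Z0 dt over one burst
(energy fluence per burst), and the derived intensities

    I_SPPA = PII / TBD        (pulse-average)
    I_SPTA = PII x PRF        (temporal-average) = I_SPPA x DC

All internal quantities are SI (Pa, s, W m^-2); the reported intensities
use the conventional mW cm^-2 and PII uses J cm^-2.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np


class ProtocolError(ValueError):
    """Raised when stimulus-protocol parameters are physically inconsistent."""


@dataclass(frozen=True)
class StimulusProtocol:
    """Full parameterization of a pulsed ultrasound delivery schedule.

    Parameters
    ----------
    f0 : float
        Carrier (fundamental) frequency, Hz.
    prf : float
        Pulse repetition frequency, Hz.
    tbd : float
        Tone-burst duration, s. Must fit within one PRF period.
    pd : float
        Stimulus (pulse) duration per trial, s.
    isi : float
        Inter-stimulus interval between trial onsets, s.
    jitter_frac : float
        Fractional uniform jitter applied to each inter-onset gap.
    n_trials : int
        Number of stimulation trials in a session.
    p_p2p : float
        Peak-to-peak acoustic pressure at the focus, Pa.
    z0 : float
        Acoustic impedance of the medium, Rayl (kg m^-2 s^-1). Default is
        a soft-tissue/brain convention of 1.62 MRayl.
    """

    f0: float = 1.5e6
    prf: float = 1500.0
    tbd: float = 200e-6
    pd: float = 0.067
    isi: float = 2.5
    jitter_frac: float = 0.10
    n_trials: int = 505
    p_p2p: float = 114e3
    z0: float = 1.62e6

    def __post_init__(self) -> None:
        if self.f0 <= 0:
            raise ProtocolError("f0 must be positive")
        if self.prf <= 0:
            raise ProtocolError("prf must be positive")
        if not (0 < self.tbd <= 1.0 / self.prf + 1e-15):
            raise ProtocolError(
                "tone-burst duration must be positive and fit within one PRF "
                f"period (tbd={self.tbd} s, 1/prf={1.0 / self.prf} s); "
                "bursts would overlap"
            )
        if not (0 < self.pd <= self.isi):
            raise ProtocolError("pulse duration must satisfy 0 < pd <= isi")
        if not (0 <= self.jitter_frac < 1):
            raise ProtocolError("jitter_frac must be in [0, 1)")
        if self.n_trials < 1:
            raise ProtocolError("n_trials must be >= 1")
        if self.p_p2p < 0:
            raise ProtocolError("p_p2p must be non-negative")
        if self.z0 <= 0:
            raise ProtocolError("z0 must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class DoseMetrics:
    """Acoustic dose summary for one protocol.

    Attributes
    ----------
    duty_cycle : float
        TBD x PRF, fraction of stimulus-on time with acoustic output.
    pii : float
        Pulse intensity integral per tone burst, J cm^-2.
    i_sppa : float
        Spatial-peak pulse-average intensity, mW cm^-2.
    i_spta : float
        Spatial-peak temporal-average intensity, mW cm^-2.
    """

    duty_cycle: float
    pii: float
    i_sppa: float
    i_spta: float

    def to_dict(self) -> dict:
        return asdict(self)


def duty_cycle(protocol: StimulusProtocol) -> float:
    """Duty cycle DC = TBD x PRF of a pulsed protocol, in [0, 1]."""
    dc = protocol.tbd * protocol.prf
    if dc > 1 + 1e-12:
        raise ProtocolError(f"tbd * prf = {dc} > 1: bursts would overlap")
    return min(dc, 1.0)


def synthesize_burst(
    protocol: StimulusProtocol, sample_rate: float
) -> tuple[np.ndarray, np.ndarray]:
    """Synthesize one sinusoidal tone burst as a sampled pressure series.

    Returns ``(t, p)`` with ``t`` in seconds and ``p`` in Pa. The burst is a
    pure carrier sinusoid of amplitude ``p_p2p / 2`` lasting ``tbd``.

    Raises
    ------
    ProtocolError
        If ``sample_rate`` is below 20 samples per carrier cycle.
    """
    min_rate = 20.0 * protocol.f0
    if sample_rate < min_rate:
        raise ProtocolError(
            f"sample_rate {sample_rate:g} Hz undersamples the carrier; "
            f"need at least {min_rate:g} Hz (20 x f0)"
        )
    n = int(round(protocol.tbd * sample_rate))
    t = np.arange(n) / sample_rate
    p = (protocol.p_p2p / 2.0) * np.sin(2.0 * np.pi * protocol.f0 * t)
    return t, p


def pulse_intensity_integral(
    t: np.ndarray, p: np.ndarray, z0: float
) -> float:
    """Pulse intensity integral PII = integral p^2(t)/Z0 dt, in J cm^-2.

    Trapezoidal integration of the instantaneous intensity over the burst;
    the SI result (J m^-2) is divided by 1e4 to give J cm^-2.
    """
    if len(p) == 0:
        raise ValueError("empty pressure series")
    if z0 <= 0:
        raise ValueError("z0 must be positive")
    return float(np.trapezoid(np.asarray(p, dtype=float) ** 2 / z0, t)) / 1e4


def i_spta_from_pii(pii: float, prf: float) -> float:
    """Temporal-average intensity I_SPTA = PII x PRF, in mW cm^-2.

    ``pii`` is in J cm^-2 and ``prf`` in Hz, so the product is W cm^-2;
    the factor 1e3 converts to mW cm^-2.
    """
    if pii < 0:
        raise ValueError("pii must be non-negative")
    if prf <= 0:
        raise ValueError("prf must be positive")
    return pii * prf * 1e3


def i_spta_from_i_sppa(i_sppa: float, duty_cycle: float) -> float:
    """Temporal-average intensity from pulse-average intensity and duty cycle.

    I_SPTA = I_SPPA x DC; units follow the input (mW cm^-2 in, mW cm^-2 out).
    """
    if i_sppa < 0 or duty_cycle < 0:
        raise ValueError("inputs must be non-negative")
    if duty_cycle > 1 + 1e-12:
        raise ValueError("duty_cycle must be <= 1")
    return i_sppa * duty_cycle


def dose_metrics(
    protocol: StimulusProtocol, samples_per_cycle: int = 50
) -> DoseMetrics:
    """Compute the full dose summary for a sinusoidal-burst protocol."""
    dc = duty_cycle(protocol)
    t, p = synthesize_burst(protocol, samples_per_cycle * protocol.f0)
    pii = pulse_intensity_integral(t, p, protocol.z0)
    i_spta = i_spta_from_pii(pii, protocol.prf)
    i_sppa = pii / protocol.tbd * 1e3
    return DoseMetrics(duty_cycle=dc, pii=pii, i_sppa=i_sppa, i_spta=i_spta)


def trial_triggers(protocol: StimulusProtocol, seed: int) -> np.ndarray:
    """Trial onset times for a session, s.

    The first onset is at t = 0; each subsequent inter-onset gap is drawn
    uniformly from ``isi * (1 +/- jitter_frac)``. Jitter decorrelates the
    stimulus from slow rhythms and limits adaptation. Reproducible per seed.
    """
    rng = np.random.default_rng(seed)
    lo = protocol.isi * (1.0 - protocol.jitter_frac)
    hi = protocol.isi * (1.0 + protocol.jitter_frac)
    gaps = rng.uniform(lo, hi, size=protocol.n_trials - 1)
    return np.concatenate([[0.0], np.cumsum(gaps)])
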