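"""Filtering, detection, waveform features, QC, artifact masking."""

import numpy as np
import pytest

from sonospike import (
    StimulusProtocol,
    bandpass,
    detect_spikes,
    extract_features,
    generate_session,
    generate_template,
    mask_artifacts,
    preset,
    qc_units,
)
from sonospike.spikeproc import FeatureUndefinedError, UnitRecording

SR = 30_000.0


class TestBandpass:
    def test_removes_dc_offset(self, rng):
        x = rng.normal(0, 1, 30_000) + 100.0
        y = bandpass(x, SR)
        assert abs(y.mean()) < 0.1  # 1e-3 of the 100-unit offset

    def test_inband_tone_preserved(self):
        t = np.arange(0, 1, 1 / SR)
        x = np.sin(2 * np.pi * 1000 * t)
        y = bandpass(x, SR)
        mid = slice(5000, 25000)  # avoid filter edges
        assert y[mid].max() == pytest.approx(1.0, rel=0.05)

    def test_stopband_tone_attenuated(self):
        t = np.arange(0, 1, 1 / SR)
        x = np.sin(2 * np.pi * 50 * t)
        y = bandpass(x, SR)
        assert y[5000:25000].max() < 0.1  # >= 20 dB down

    def test_linearity(self, rng):
        a = rng.normal(0, 1, 10_000)
        b = rng.normal(0, 1, 10_000)
        assert np.allclose(bandpass(a + b, SR), bandpass(a, SR) + bandpass(b, SR),
                           atol=1e-9)

    def test_length_preserved_and_bad_band_rejected(self, rng):
        x = rng.normal(0, 1, 5000)
        assert len(bandpass(x, SR)) == len(x)
        with pytest.raises(ValueError):
            bandpass(x, 8000.0)  # high edge above Nyquist


class TestDetectSpikes:
    def test_noise_only_low_false_positive_rate(self, rng):
        dur = 20.0
        x = rng.normal(0, 1, int(dur * SR))
        times, _ = detect_spikes(x, SR, k_thresh=5.0)
        assert len(times) / dur < 1.0  # Gaussian 5-sigma tail

    def test_flat_trace_returns_empty(self):
        times, snips = detect_spikes(np.zeros(30_000), SR)
        assert len(times) == 0 and len(snips) == 0

    def test_recovers_injected_spikes(self, rng):
        tpl = generate_template(0.3, 0.7, amp=10.0, sample_rate=SR)  # SNR 10
        trough = np.argmin(tpl)
        dur = 20.0
        x = rng.normal(0, 1, int(dur * SR))
        true_times = np.arange(0.5, dur - 0.5, 0.05)
        for t in true_times:
            i0 = int(round(t * SR)) - trough
            x[i0:i0 + len(tpl)] += tpl
        det, snips = detect_spikes(bandpass(x, SR), SR)
        matched = sum(np.min(np.abs(det - t)) < 5e-4 for t in true_times)
        assert matched / len(true_times) >= 0.95
        assert snips.shape[1] == int(round(2e-3 * SR)) + 1

    def test_refractory_lockout(self):
        x = np.zeros(30_000)
        tpl = generate_template(0.2, 0.3, amp=10.0, sample_rate=SR)
        for t in (0.5, 0.5004):  # 0.4 ms apart -> one detection
            i0 = int(round(t * SR)) - np.argmin(tpl)
            x[i0:i0 + len(tpl)] += tpl
        x += np.random.default_rng(0).normal(0, 0.5, len(x))
        times, _ = detect_spikes(x, SR, k_thresh=5.0)
        near = times[(times > 0.498) & (times < 0.503)]
        assert len(near) == 1


class TestExtractFeatures:
    def test_duration_sweep_accuracy(self):
        """Mean absolute error below 2 samples across the physiological range."""
        errs = []
        for ip in np.arange(0.2, 1.21, 0.2):
            for ahp in np.arange(0.2, 1.21, 0.2):
                f = extract_features(generate_template(ip, ahp, 10.0, SR), SR)
                errs += [abs(f.ip_ms - ip), abs(f.ahp_ms - ahp)]
        assert np.mean(errs) < 2 * 1e3 / SR

    def test_amplitude_invariance(self):
        tpl = generate_template(0.3, 0.7, amp=5.0)
        a = extract_features(tpl, SR)
        b = extract_features(2 * tpl, SR)
        assert a.ip_ms == pytest.approx(b.ip_ms)
        assert a.ahp_ms == pytest.approx(b.ahp_ms)

    def test_monophasic_template_rejected(self):
        tpl = np.concatenate([np.zeros(15), -np.sin(np.pi * np.arange(30) / 30), np.zeros(15)])
        with pytest.raises(FeatureUndefinedError):
            extract_features(tpl, SR)

    def test_robust_to_template_noise(self, rng):
        # mean-of-snippets templates carry residual noise ~ sd/sqrt(n)
        tpl = generate_template(0.4, 0.6, amp=10.0, sample_rate=SR)
        noisy = tpl + rng.normal(0, 0.05, len(tpl))
        f = extract_features(noisy, SR)
        assert f.ip_ms == pytest.approx(0.4, abs=3e3 / SR)
        assert f.ahp_ms == pytest.approx(0.6, abs=3e3 / SR)


def _unit(uid, spikes, tpl=None, duration=100.0):
    if tpl is None:
        tpl = generate_template(0.3, 0.7, amp=10.0, sample_rate=SR)
    return UnitRecording(
        unit_id=uid, spike_times=np.asarray(spikes, dtype=float),
        template=tpl, sample_rate=SR, duration=duration,
    )


class TestQcUnits:
    def test_constructed_violations(self, rng):
        dur = 100.0
        good = np.sort(rng.uniform(0, dur, 500))
        # (a) no positive phase above baseline band
        mono = np.concatenate([np.zeros(15), -10 * np.sin(np.pi * np.arange(30) / 30),
                               np.zeros(15)])
        # (c) refractory contamination: many sub-ms intervals
        bursty = np.sort(np.concatenate([good, good + 2e-4]))
        units = [
            _unit("ok1", good),
            _unit("ok2", np.sort(rng.uniform(0, dur, 800))),
            _unit("ok3", np.sort(rng.uniform(0, dur, 300))),
            _unit("amp_bad", good, tpl=mono),
            _unit("ref_bad", bursty),
        ]
        kept, removed = qc_units(units, dur)
        assert {u.unit_id for u in kept} == {"ok1", "ok2", "ok3"}
        reasons = {u.unit_id: r for u, r in removed}
        assert "amplitude" in reasons["amp_bad"]
        assert "refractory" in reasons["ref_bad"]

    def test_all_pass_identity(self, rng):
        units = [_unit(f"u{i}", np.sort(rng.uniform(0, 100, 400))) for i in range(4)]
        kept, removed = qc_units(units, 100.0)
        assert len(kept) == 4 and removed == []

    def test_silent_tail_removed_for_presence(self, rng):
        spikes = np.sort(rng.uniform(0, 80, 400))  # silent in last 20%
        kept, removed = qc_units([_unit("u", spikes)], 100.0)
        assert kept == []
        assert removed[0][1] == ["presence"]

    def test_idempotent(self, rng):
        units = [_unit(f"u{i}", np.sort(rng.uniform(0, 100, 300))) for i in range(3)]
        once, _ = qc_units(units, 100.0)
        twice, _ = qc_units(once, 100.0)
        assert [u.unit_id for u in once] == [u.unit_id for u in twice]


class TestMaskArtifacts:
    def test_no_epochs_identity(self):
        spikes = np.array([1.0, 2.0, 3.0])
        triggers = np.array([0.5, 3.0])
        out, excluded = mask_artifacts(spikes, [], triggers)
        assert np.array_equal(out, spikes) and excluded == []

    def test_epoch_covering_one_trial_window(self):
        triggers = np.array([10.0, 20.0, 30.0])
        spikes = np.array([9.0, 19.5, 29.0])
        out, excluded = mask_artifacts(spikes, [(19.0, 21.0)], triggers)
        assert excluded == [1]
        assert np.array_equal(out, [9.0, 29.0])

    def test_epoch_in_dead_time_excludes_no_trials(self):
        # trials every 10 s; epoch between trial windows removes spikes only
        triggers = np.array([10.0, 20.0])
        spikes = np.array([13.0, 14.0, 20.5])
        out, excluded = mask_artifacts(spikes, [(12.5, 14.5)], triggers)
        assert excluded == []
        assert np.array_equal(out, [20.5])


def test_detection_pipeline_recovers_generator_features():
    """End-to-end on a rendered trace: detect, average snippets, extract
    features; recovered durations match the generating spec."""
    proto = StimulusProtocol(n_trials=12)
    fix = generate_session([(preset("awake_rsu"), 1)], proto, seed=17,
                           with_trace=True)
    spec = preset("awake_rsu")
    trace = bandpass(fix.traces[0], fix.trace_sample_rate)
    times, snips = detect_spikes(trace, fix.trace_sample_rate)
    true_times = fix.units[0].spike_times
    matched = sum(np.min(np.abs(times - t)) < 5e-4 for t in true_times)
    assert matched / len(true_times) >= 0.9
    f = extract_features(snips.mean(axis=0), fix.trace_sample_rate)
    assert f.ip_ms == pytest.approx(spec.ip_dur, abs=0.1)
    assert f.ahp_ms == pytest.approx(spec.ahp_dur, abs=0.1)
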