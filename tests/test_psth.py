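"""PSTH construction, normalized response, and the consecutive-bin detector."""

import numpy as np
import pytest

from sonospike import (
    baseline_stability,
    classify_response,
    compute_psth,
    detect_response,
    generate_unit,
    latency_summary,
    normalized_response,
    trial_triggers,
)
from sonospike.psth import NormalizationError, Psth
from sonospike.synthetic import UnitSpec

BIN = 0.0357


def poisson_spikes(rate, duration, seed):
    rng = np.random.default_rng(seed)
    n = rng.poisson(rate * duration)
    return np.sort(rng.uniform(0, duration, n))


def make_psth(values, n_trials=500, sem=None):
    """Hand-constructed PSTH for detector arithmetic."""
    values = np.asarray(values, dtype=float)
    n_base = int(np.floor(0.5 / BIN + 1e-9))
    base = values[:n_base]
    if sem is None:
        sem = float(np.std(base, ddof=1)) / np.sqrt(n_base)
    return Psth(
        bin_width=BIN, t_pre=0.5, t_post=1.5, values=values,
        n_trials_used=n_trials, baseline_mean=float(base.mean()),
        baseline_sem=sem, n_baseline_bins=n_base,
    )


class TestComputePsth:
    def test_trial_accounting(self, protocol):
        triggers = trial_triggers(protocol, seed=1)
        psth = compute_psth(poisson_spikes(5, 1300, 1), triggers, drop_first=5)
        assert psth.n_trials_used == 500

    def test_bin_count_and_baseline_bins(self, protocol):
        triggers = trial_triggers(protocol, seed=1)
        psth = compute_psth(poisson_spikes(5, 1300, 2), triggers)
        assert len(psth.values) == 56  # floor(2.0 / 0.0357)
        assert psth.n_baseline_bins == 14

    def test_homogeneous_poisson_bin_values(self, short_protocol):
        triggers = trial_triggers(short_protocol, seed=3)
        duration = triggers[-1] + 2.5
        psth = compute_psth(poisson_spikes(10, duration, 3), triggers)
        expected = 10 * BIN
        per_bin_sem = np.sqrt(expected / psth.n_trials_used)
        assert np.all(np.abs(psth.values - expected) < 5 * per_bin_sem)
        assert psth.baseline_mean == pytest.approx(expected, abs=4 * per_bin_sem)

    def test_no_spikes(self, short_protocol):
        triggers = trial_triggers(short_protocol, seed=4)
        psth = compute_psth(np.array([]), triggers)
        assert np.all(psth.values == 0)
        assert psth.baseline_sem == 0.0

    def test_count_conservation(self, short_protocol):
        triggers = trial_triggers(short_protocol, seed=5)
        spikes = poisson_spikes(8, triggers[-1] + 2.5, 5)
        psth = compute_psth(spikes, triggers, drop_first=5)
        total = 0
        edges = (-0.5, -0.5 + 56 * BIN)
        for t0 in triggers[5:]:
            total += np.sum((spikes >= t0 + edges[0]) & (spikes < t0 + edges[1]))
        assert psth.values.sum() * psth.n_trials_used == pytest.approx(total)

    def test_excluded_trials_reduce_n(self, short_protocol):
        triggers = trial_triggers(short_protocol, seed=6)
        spikes = poisson_spikes(5, triggers[-1] + 2.5, 6)
        psth = compute_psth(spikes, triggers, excluded_trials=[10, 11])
        assert psth.n_trials_used == len(triggers) - 5 - 2

    def test_all_trials_excluded_rejected(self, short_protocol):
        triggers = trial_triggers(short_protocol, seed=7)
        with pytest.raises(ValueError):
            compute_psth(np.array([1.0]), triggers,
                         excluded_trials=list(range(len(triggers))))


class TestNormalizedResponse:
    def test_unmodulated_unit_near_100pct(self, short_protocol):
        triggers = trial_triggers(short_protocol, seed=8)
        psth = compute_psth(poisson_spikes(10, triggers[-1] + 2.5, 8), triggers)
        for window in [(0.0, 0.067), (0.5, 1.0), (0.2, 0.7)]:
            assert normalized_response(psth, window) == pytest.approx(100, abs=15)

    def test_gain_two_time_locked_unit(self, protocol):
        spec = UnitSpec(cell_type="RSU", baseline_rate=10.0,
                        response_kind="time_locked", gain=2.0)
        triggers = trial_triggers(protocol, seed=9)
        u = generate_unit(spec, protocol, triggers, seed=9)
        psth = compute_psth(u.spike_times, triggers)
        assert normalized_response(psth, (0.0, 0.067)) == pytest.approx(200, abs=12)

    def test_partial_bin_weighting(self):
        # constant-rate PSTH: any window, aligned or not, returns 100%
        psth = make_psth(np.full(56, 0.4))
        assert normalized_response(psth, (0.01, 0.05)) == pytest.approx(100)

    def test_zero_baseline_rejected(self):
        psth = make_psth(np.concatenate([np.zeros(14), np.full(42, 0.3)]))
        with pytest.raises(NormalizationError):
            normalized_response(psth, (0.0, 0.067))

    def test_window_outside_span_rejected(self):
        psth = make_psth(np.full(56, 0.4))
        with pytest.raises(ValueError):
            normalized_response(psth, (1.0, 2.0))


class TestDetectResponse:
    def test_flat_psth_not_significant(self, rng):
        vals = rng.normal(0.5, 0.01, 56)
        psth = make_psth(vals, sem=0.05)  # threshold above all noise
        det = detect_response(psth)
        assert not det.significant and det.latency is None

    def test_three_elevated_bins_latency_arithmetic(self):
        vals = np.full(56, 0.35)
        vals[20:23] = 0.5
        psth = make_psth(vals, sem=0.05)
        det = detect_response(psth)
        assert det.significant
        # run starts at bin 20: left edge 20*0.0357 - 0.5 = 0.214 s
        assert det.latency == pytest.approx(0.214 + BIN / 2, abs=1e-9)
        left = detect_response(psth, latency_at="left_edge")
        assert left.latency == pytest.approx(0.214, abs=1e-9)

    def test_two_elevated_bins_not_significant(self):
        vals = np.full(56, 0.35)
        vals[20:22] = 0.8
        psth = make_psth(vals, sem=0.05)
        assert not detect_response(psth).significant

    def test_search_window_restricts_bins(self):
        vals = np.full(56, 0.35)
        vals[20:23] = 0.5
        psth = make_psth(vals, sem=0.05)
        # searching only after the run's bins finds nothing
        assert not detect_response(psth, (0.9, 1.5)).significant

    def test_zero_sem_fires_and_flags(self):
        vals = np.concatenate([np.full(14, 0.35), np.full(42, 0.36)])
        psth = make_psth(vals, sem=0.0)
        det = detect_response(psth)
        assert det.significant and det.degenerate_sem


class TestClassifyResponse:
    def test_during_stimulus_is_time_locked(self):
        vals = np.full(56, 0.35)
        vals[14:18] = 0.6  # run starts in the bin straddling onset
        det = detect_response(make_psth(vals, sem=0.05))
        assert classify_response(det, pd=0.067) == "time_locked"
        assert det.latency <= 0.067

    def test_after_stimulus_is_delayed(self):
        vals = np.full(56, 0.35)
        vals[28:32] = 0.6  # run starts ~0.5 s after onset
        det = detect_response(make_psth(vals, sem=0.05))
        assert classify_response(det, pd=0.067) == "delayed"
        assert det.latency == pytest.approx(0.51, abs=0.02)

    def test_no_run_is_none(self):
        det = detect_response(make_psth(np.full(56, 0.35), sem=0.05))
        assert classify_response(det, pd=0.067) == "none"


class TestBaselineStability:
    def test_poisson_baseline_passes(self, short_protocol):
        triggers = trial_triggers(short_protocol, seed=10)
        psth = compute_psth(poisson_spikes(10, triggers[-1] + 2.5, 10), triggers)
        assert baseline_stability(psth)

    def test_artifact_bin_fails(self):
        vals = np.full(56, 0.35)
        vals[5] = 3.5  # 10x artifact bin in the baseline
        assert not baseline_stability(make_psth(vals))

    def test_all_zero_baseline_fails(self):
        vals = np.concatenate([np.zeros(14), np.full(42, 0.3)])
        assert not baseline_stability(make_psth(vals, sem=0.0))


class TestLatencySummary:
    def test_single_latency(self):
        mean, sd, _ = latency_summary([0.24])
        assert mean == 0.24 and sd == 0.0

    def test_histogram_covers_range(self):
        lat = [0.1, 0.2, 0.3, 1.4]
        mean, sd, (hist, edges) = latency_summary(lat)
        assert hist.sum() == 4
        assert edges[0] == 0.0 and edges[-1] == pytest.approx(1.5)
        assert len(hist) == 30

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            latency_summary([])


def test_response_monotone_in_gain(protocol):
    """Mean normalized time-locked response never decreases with gain."""
    triggers = trial_triggers(protocol, seed=11)
    means = []
    for gain in (1.0, 1.5, 2.0, 3.0):
        spec = UnitSpec(cell_type="RSU", baseline_rate=10.0,
                        response_kind="time_locked", gain=gain)
        vals = []
        for s in range(5):
            u = generate_unit(spec, protocol, triggers, seed=200 + s)
            psth = compute_psth(u.spike_times, triggers)
            vals.append(normalized_response(psth, (0.0, protocol.pd)))
        means.append(np.mean(vals))
    assert all(b > a - 5 for a, b in zip(means, means[1:]))
    assert means[-1] > means[0]
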