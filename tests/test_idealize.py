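"""Idealization: post-filter, baseline, event detection, segmentation."""

import itertools

import numpy as np
import pytest
from scipy import signal as sig

from poregram import idealize, synth
from poregram.idealize import (
    EventWindow,
    _pelt,
    default_penalty,
    detect_events,
    estimate_baseline,
    postfilter,
    segment_levels,
)
from poregram.trace_io import Trace

FS = 50_000.0


class TestPostfilter:
    def test_dc_invariance(self):
        tr = Trace(np.full(5000, 87.3), FS)
        out = postfilter(tr, 2000.0)
        np.testing.assert_allclose(out.samples, 87.3, atol=1e-9)
        assert out.metadata["postfilter_hz"] == 2000.0

    def test_white_noise_energy_removed(self):
        rng = np.random.default_rng(0)
        tr = Trace(rng.normal(0, 1, 50_000), FS)
        assert postfilter(tr, 2000.0).samples.std() < tr.samples.std()

    def test_passband_tone_barely_attenuated(self):
        """500 Hz through the 2 kHz filter: <5% loss, matching |H|^2 analytically."""
        t = np.arange(int(FS)) / FS
        tr = Trace(np.sin(2 * np.pi * 500 * t), FS)
        out = postfilter(tr, 2000.0).samples[12_500:-12_500]
        measured = out.max()
        sos = sig.bessel(4, 2000.0, fs=FS, output="sos", norm="mag")
        w, h = sig.sosfreqz(sos, worN=[2 * np.pi * 500 / FS])
        analytic = np.abs(h[0]) ** 2  # forward+backward pass
        assert 1 - measured < 0.05
        assert measured == pytest.approx(analytic, abs=0.005)

    def test_cutoff_above_nyquist_rejected(self):
        tr = Trace(np.zeros(100), FS)
        with pytest.raises(ValueError, match="Nyquist"):
            postfilter(tr, 30_000.0)


class TestBaseline:
    def test_event_free_trace_within_0p2_pA(self, unit_model, octamer_plan):
        ch = synth.ChannelModel(capture_rate_per_uM=0.0)
        tr, _ = synth.simulate_trace(ch, unit_model, octamer_plan, duration=1.0, seed=2)
        est = estimate_baseline(tr)
        assert abs(est - tr.samples[500:].mean()) < 0.2
        assert abs(est - ch.open_current) < 0.2

    def test_occupied_trace_within_0p5_pA(self):
        """~30% of samples inside deep blockades must not bias the estimate."""
        rng = np.random.default_rng(5)
        x = 100.0 + rng.normal(0, 1.5, 100_000)
        for s in range(0, 100_000, 10_000):
            x[s : s + 3000] = 15.0 + rng.normal(0, 1.5, 3000)
        est = estimate_baseline(Trace(x, FS))
        assert abs(est - 100.0) < 0.5

    def test_all_zero_trace_is_an_error(self):
        with pytest.raises(ValueError):
            estimate_baseline(Trace(np.zeros(1000), FS))


class TestDetectEvents:
    def test_constant_trace_has_no_events(self):
        rng = np.random.default_rng(1)
        tr = Trace(100 + rng.normal(0, 1.5, 20_000), FS)
        assert detect_events(tr, 100.0) == []

    def test_planted_events_recovered_with_high_overlap(self, octamer_recording):
        trace, gt = octamer_recording
        baseline = estimate_baseline(trace)
        windows = [w for w in detect_events(trace, baseline)]
        truth = [
            (ev.levels[0].start_idx, ev.levels[-1].end_idx) for ev in gt.events if ev.levels
        ]
        assert len(windows) == len(truth)
        for w, (s, e) in zip(windows, truth):
            inter = max(0, min(w.end_idx, e) - max(w.start_idx, s))
            assert inter / (e - s) > 0.95

    def test_truncated_event_flagged_incomplete(self):
        rng = np.random.default_rng(3)
        x = 100 + rng.normal(0, 1.5, 10_000)
        x[8000:] = 15.0 + rng.normal(0, 1.5, 2000)
        windows = detect_events(Trace(x, FS), 100.0)
        assert len(windows) == 1
        assert not windows[0].complete

    def test_threshold_ordering_enforced(self):
        tr = Trace(np.full(100, 100.0), FS)
        with pytest.raises(ValueError):
            detect_events(tr, 100.0, threshold_frac=0.95, min_return_frac=0.9)


def _staircase(rng, n, k, lo=5, sep=5):
    cps = np.sort(rng.choice(np.arange(lo, n - lo), size=k, replace=False)) if k else np.array([], int)
    while k > 1 and np.any(np.diff(cps) < sep):
        cps = np.sort(rng.choice(np.arange(lo, n - lo), size=k, replace=False))
    means = rng.uniform(-8, 8, k + 1)
    x = np.empty(n)
    for m, (a, b) in zip(means, zip([0, *cps], [*cps, n])):
        x[a:b] = m
    return x, cps


def _brute_force(x, pen, kmax):
    n = len(x)
    s1 = np.concatenate(([0.0], np.cumsum(x)))
    s2 = np.concatenate(([0.0], np.cumsum(x * x)))

    def cost(cps):
        bounds = (0, *cps, n)
        return sum(
            (s2[b] - s2[a]) - (s1[b] - s1[a]) ** 2 / (b - a)
            for a, b in zip(bounds, bounds[1:])
        ) + pen * len(cps)

    best = (np.inf, ())
    for k in range(kmax + 1):
        for cps in itertools.combinations(range(1, n), k):
            c = cost(cps)
            if c < best[0] - 1e-12:
                best = (c, cps)
    return best


class TestSegmentation:
    def test_noiseless_staircase_recovered_exactly(self):
        x = np.concatenate([np.full(300, 100.0), np.full(200, 15.0), np.full(250, 30.0)])
        tr = Trace(x + 0.0, FS)
        segs = segment_levels(tr, (0, len(x)), penalty=1.0, mergeable_delta_pA=0.5)
        assert [s.start_idx for s in segs] == [0, 300, 500]
        assert segs[1].mean_pA == pytest.approx(15.0)

    @pytest.mark.parametrize("trial", range(6))
    def test_matches_exhaustive_optimum_on_small_traces(self, trial):
        """Penalized optimum equals brute-force enumeration (<=3 change points)."""
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(40, 140))
        k = int(rng.integers(0, 4))
        x, _ = _staircase(rng, n, k)
        x += rng.normal(0, 1.0, n)
        # penalty high enough that noise-only splits are never optimal, so
        # the global optimum stays within the brute-force enumeration range
        pen = 25.0
        best_cost, _ = _brute_force(x, pen, kmax=3)
        cps = _pelt(x, pen)
        s1 = np.concatenate(([0.0], np.cumsum(x)))
        s2 = np.concatenate(([0.0], np.cumsum(x * x)))
        bounds = (0, *cps, n)
        pelt_cost = sum(
            (s2[b] - s2[a]) - (s1[b] - s1[a]) ** 2 / (b - a)
            for a, b in zip(bounds, bounds[1:])
        ) + pen * len(cps)
        assert pelt_cost == pytest.approx(best_cost, abs=1e-9)

    def test_high_snr_change_points_within_200us(self):
        """SNR>=5 steps with >=1 ms dwells: >=99% recovered within 0.2 ms."""
        rng = np.random.default_rng(77)
        found = total = 0
        for _ in range(100):
            k = int(rng.integers(1, 4))
            dwells = rng.uniform(1.0, 6.0, k + 1)  # ms
            lengths = (dwells * FS / 1000).astype(int)
            means = np.cumsum(rng.choice([-1, 1], k + 1) * rng.uniform(5, 12, k + 1))
            x = np.concatenate([np.full(n, m) for n, m in zip(lengths, means)])
            x += rng.normal(0, 1.0, x.size)
            true_cps = np.cumsum(lengths)[:-1]
            got = np.array(_pelt(x, default_penalty(x)))
            for tc in true_cps:
                total += 1
                if got.size and np.min(np.abs(got - tc)) <= 0.2e-3 * FS:
                    found += 1
        assert found / total >= 0.99

    def test_more_penalty_never_more_segments(self):
        """Monotonicity: smaller penalty => cost no higher, never fewer segments."""
        rng = np.random.default_rng(9)
        x, _ = _staircase(rng, 400, 3)
        x += rng.normal(0, 1.0, 400)
        counts = [len(_pelt(x, pen)) for pen in (200.0, 50.0, 10.0, 2.0)]
        assert counts == sorted(counts)

    def test_window_too_short_rejected(self):
        tr = Trace(np.zeros(100), FS)
        with pytest.raises(ValueError):
            segment_levels(tr, (5, 6))

    def test_sub_dead_time_segments_flagged_not_dropped(self):
        x = np.concatenate([np.full(500, 100.0), np.full(4, 50.0), np.full(500, 15.0)])
        tr = Trace(x, FS)
        segs = segment_levels(tr, (0, len(x)), penalty=1.0, mergeable_delta_pA=0.5)
        assert any(s.sub_dead_time for s in segs)
        assert sum(s.end_idx - s.start_idx for s in segs) == len(x)


class TestIdealizeTrace:
    def test_recovers_configured_levels_via_stats(self, octamer_analysis, channel, unit_model):
        """End-to-end: I_res% of >=1 ms levels within 0.5 points of configured."""
        _, _, stats = octamer_analysis
        for label, conf in (("A1", unit_model.ires_A1), ("A2", unit_model.ires_A2)):
            sel = stats[(stats.level_label == label) & (stats.dwell_ms >= 1.0)]
            assert len(sel) > 20
            assert abs(sel.ires_pct.mean() - conf) < 0.5
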