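"""Parameter-based detector: peaks, S allocation, the full sweep, snapping."""

import numpy as np
import pytest
from reference_detection import ref_detect, ref_local_maxima

import catrans
from catrans import (
    CalciumTraceSet,
    DetectionParams,
    allocate_rise_segment,
    detect_transients,
    find_candidate_peaks,
    snap_point,
)
from catrans.signal_processing import compute_snr


class TestFindCandidatePeaks:
    def test_monotone_trace_has_no_peaks(self):
        assert find_candidate_peaks(np.arange(50.0)) == []
        assert find_candidate_peaks(np.arange(50.0)[::-1].copy()) == []

    def test_direct_inspection(self):
        assert find_candidate_peaks(
            np.array([0, 1, 3, 1, 0, 2, 5, 2.0])
        ) == [2, 6]

    def test_plateau_counts_once_at_leftmost_frame(self):
        assert find_candidate_peaks(np.array([0, 2, 2, 2, 1, 0.0])) == [1]
        # plateau running into the trace end is not a peak
        assert find_candidate_peaks(np.array([0, 2, 2.0])) == []

    def test_matches_bruteforce_scan_on_random_traces(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            # quantized values make plateaus common
            x = rng.integers(0, 4, size=500).astype(float)
            assert find_candidate_peaks(x) == ref_local_maxima(x)


class TestAllocateRiseSegment:
    def test_zero_s_removes_peak(self):
        assert allocate_rise_segment(np.zeros(50), 25) is None

    def test_containing_run(self):
        S = np.zeros(200)
        S[100:111] = 1.0
        assert allocate_rise_segment(S, 110) == (100, 110)
        assert allocate_rise_segment(S, 105) == (100, 110)

    def test_lookback_tolerance(self):
        S = np.zeros(200)
        S[100:111] = 1.0  # S > 0 on frames 100..110
        assert allocate_rise_segment(S, 112, lookback=5) == (100, 110)
        assert allocate_rise_segment(S, 112, lookback=1) is None


class TestDetectTransients:
    def test_zero_s_gives_no_events(self):
        n = 1000
        C = np.abs(np.sin(np.arange(n) / 25.0))
        ts = CalciumTraceSet(
            [0], C=C[None, :], S=np.zeros((1, n)), dff=C[None, :] * 3
        )
        assert detect_transients(ts, 0, DetectionParams()) == []

    def test_single_clean_transient_recovered(self):
        cfg = catrans.GeneratorConfig(n_cells=1, n_frames=2000, noise_sigma=0.0)
        C, S, raw, dff, events, labels = catrans.generate_cell(
            cfg, cell_seed=0, forced_events=[(100, 110)]
        )
        ts = CalciumTraceSet([0], C=C[None], S=S[None], dff=dff[None])
        got = detect_transients(
            ts, 0, DetectionParams(peak_threshold=0.5, interval_threshold=10,
                                   snr_threshold=2.0)
        )
        assert [(e.rise_start, e.rise_stop) for e in got] == [(100, 110)]

    def test_interval_threshold_controls_merging(self):
        cfg = catrans.GeneratorConfig(n_cells=1, n_frames=2000, noise_sigma=0.0)
        # two rises whose onsets are 8 frames apart
        C, S, raw, dff, events, labels = catrans.generate_cell(
            cfg, cell_seed=1, forced_events=[(100, 104), (108, 113)]
        )
        ts = CalciumTraceSet([0], C=C[None], S=S[None], dff=dff[None])
        loose = DetectionParams(peak_threshold=0.2, interval_threshold=10,
                                snr_threshold=1.0)
        tight = DetectionParams(peak_threshold=0.2, interval_threshold=5,
                                snr_threshold=1.0)
        assert len(detect_transients(ts, 0, loose)) == 1
        assert len(detect_transients(ts, 0, tight)) == 2

    def test_unknown_cell_is_fatal(self):
        ts = CalciumTraceSet([0], C=np.zeros((1, 100)), S=np.zeros((1, 100)),
                             dff=np.zeros((1, 100)))
        with pytest.raises(KeyError):
            detect_transients(ts, "nope", DetectionParams())

    def test_every_event_satisfies_acceptance_conditions(self, small_noisy_ts):
        ts, _, _ = small_noisy_ts
        params = DetectionParams(peak_threshold=0.6, interval_threshold=15,
                                 snr_threshold=4.0)
        for cid in ts.cell_ids:
            row = ts.cell_index(cid)
            snr = compute_snr(ts.dff[row], params)
            for e in detect_transients(ts, cid, params):
                seg = slice(e.rise_start, e.rise_stop + 1)
                assert ts.S[row, seg].max() > 0
                assert ts.dff[row, seg].max() >= params.peak_threshold
                assert snr[seg].max() >= params.snr_threshold

    def test_matches_independent_bruteforce_sweep(self):
        """Full equivalence with a separately written reference sweep."""
        from catrans.signal_processing import ensure_dff

        rng = np.random.default_rng(99)
        for trial in range(20):
            cfg = catrans.GeneratorConfig(
                n_cells=1, n_frames=2000, seed=int(rng.integers(1 << 30))
            )
            ts, _, _ = catrans.generate_traceset(cfg)
            for peak_thr, interval_thr, snr_thr in [
                (0.2, 5, 1.0), (0.8, 20, 5.0), (1.6, 60, 12.0)
            ]:
                params = DetectionParams(
                    peak_threshold=peak_thr,
                    interval_threshold=interval_thr,
                    snr_threshold=snr_thr,
                )
                dff = ensure_dff(ts, params)[0]
                snr = compute_snr(dff, params)
                expected = ref_detect(
                    ts.C[0], ts.S[0], dff, snr, peak_thr, interval_thr, snr_thr
                )
                got = detect_transients(ts, 0, params)
                assert [(e.rise_start, e.rise_stop) for e in got] == [
                    (e["rise_start"], e["rise_stop"]) for e in expected
                ]
                assert np.allclose(
                    [e.peak_amplitude for e in got],
                    [e["peak_amp"] for e in expected],
                )
                assert np.allclose(
                    [e.total_amplitude for e in got],
                    [e["total_amp"] for e in expected],
                )


class TestThresholdMonotonicity:
    def test_event_set_shrinks_as_thresholds_rise(self, small_noisy_ts):
        ts, _, _ = small_noisy_ts

        def boundaries(params):
            return {
                (e.rise_start, e.rise_stop)
                for e in detect_transients(ts, 1, params)
            }

        base = dict(peak_threshold=0.2, interval_threshold=8, snr_threshold=1.0)
        for key, grid in [
            ("peak_threshold", [0.2, 0.6, 1.2, 2.4]),
            ("snr_threshold", [1.0, 4.0, 8.0, 16.0]),
        ]:
            prev = None
            for v in grid:
                cur = boundaries(DetectionParams(**{**base, key: v}))
                if prev is not None:
                    assert cur <= prev  # raising a threshold never adds events
                prev = cur

    def test_event_count_nonincreasing_in_interval_threshold(
        self, small_noisy_ts
    ):
        ts, _, _ = small_noisy_ts
        counts = [
            len(
                detect_transients(
                    ts, 0,
                    DetectionParams(peak_threshold=0.2, snr_threshold=1.0,
                                    interval_threshold=iv),
                )
            )
            for iv in [1, 5, 15, 40, 120]
        ]
        assert counts == sorted(counts, reverse=True)


class TestSnapPoint:
    def test_already_at_extremum(self):
        x = np.zeros(100)
        x[50] = 5.0
        assert snap_point(x, 50, "max") == 50

    def test_snaps_to_unique_max(self):
        x = np.zeros(100)
        x[57] = 3.0
        assert snap_point(x, 50, "max") == 57

    def test_matches_bruteforce_with_tie_rule(self):
        rng = np.random.default_rng(8)
        x = rng.integers(0, 3, size=300).astype(float)
        for frame in rng.integers(0, 300, size=100):
            frame = int(frame)
            for mode in ("max", "min"):
                lo, hi = max(0, frame - 10), min(300, frame + 11)
                win = x[lo:hi]
                target = win.max() if mode == "max" else win.min()
                cands = [i for i in range(lo, hi) if x[i] == target]
                best = min(cands, key=lambda i: (abs(i - frame), i))
                assert snap_point(x, frame, mode) == best
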