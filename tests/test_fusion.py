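"""Fusion-event detection: ROI placement, F/F0 traces, the amplitude and
rise-time criteria, and per-neuron summaries.

The detection oracle used here is a brute-force frame scan that applies the
stated criteria literally to a constructed trace; it is independent of the
vectorized implementation it checks.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dcvpipe.core import Movie, StimProtocol
from dcvpipe.fusion import (
    FusionEvent,
    RoiTrace,
    detect_events,
    extract_trace,
    place_rois,
    summarize_events,
)
from dcvpipe.simulate import EventSpec, SimConfig, generate_fusion_movie


def make_trace(R, frame_interval=0.5):
    """Wrap a ratio trace as a RoiTrace with F0 = 1."""
    return RoiTrace(
        roi_center=(1, 1),
        roi_size=3,
        F=np.asarray(R, dtype=float),
        F0=1.0,
        frame_interval=frame_interval,
    )


def brute_force_events(R, frame_interval=0.5, threshold_sd=2.0, max_rise=1.0, min_run=3):
    """Independent oracle: literal frame scan of the detection criteria.

    Valid for traces whose baseline (first 60 frames) carries the noise and
    whose events are clean steps; uses the same run/threshold definitions
    but no median filter, so apply it only to spike-free traces.
    """
    R = np.asarray(R, dtype=float)
    base = R[:60]
    mu, sig = base.mean(), max(base.std(ddof=1), 0.01)
    thr = mu + threshold_sd * sig
    events = []
    i, armed = 0, True
    while i < len(R):
        if R[i] <= thr:
            if R[i] < mu + sig:
                armed = True
            i += 1
            continue
        j = i
        while j < len(R) and R[j] > thr:
            j += 1
        peak = i + int(np.argmax(R[i:j]))
        rise_frame = i + int(np.argmax(R[i:j] >= R[i:j].max() - 3 * sig))
        rise = (rise_frame - (i - 1)) * frame_interval
        if armed and j - i >= min_run and rise < max_rise and R[peak] - mu >= threshold_sd * sig:
            events.append((peak, R[peak]))
        armed = False
        i = j
    return events


class TestPlaceRois:
    def test_single_event_yields_single_centered_roi(self, clean_event_movie):
        cfg, movie, truth = clean_event_movie
        rois = place_rois(movie, cfg.stim_protocol)
        assert len(rois) == 1
        r, c = truth.puncta_positions[0]
        assert abs(rois[0][0] - r) <= 1 and abs(rois[0][1] - c) <= 1

    def test_no_events_no_noise_yields_empty_list(self):
        cfg = SimConfig(n_puncta=4, punctum_min_separation=12.0, rng_seed=31)
        movie, _ = generate_fusion_movie(cfg)
        assert place_rois(movie, cfg.stim_protocol) == []

    def test_three_separated_events_found_within_one_pixel(self):
        cfg = SimConfig(
            n_puncta=3,
            punctum_min_separation=18.0,
            background_level=0.0,
            events=tuple(EventSpec(i, 35.0 + 5 * i, 3.0, 0.25, 5.0) for i in range(3)),
            rng_seed=32,
        )
        movie, truth = generate_fusion_movie(cfg)
        rois = place_rois(movie, cfg.stim_protocol)
        assert len(rois) == 3
        for pos in truth.puncta_positions:
            assert any(
                abs(rr - pos[0]) <= 1 and abs(cc - pos[1]) <= 1 for rr, cc in rois
            )

    def test_stimulation_outside_recording_raises(self, clean_event_movie):
        _, movie, _ = clean_event_movie
        late = StimProtocol(start_time=1e4)
        with pytest.raises(ValueError):
            place_rois(movie, late)


class TestExtractTrace:
    def test_constant_movie_gives_unit_ratio(self):
        movie = Movie(np.full((20, 9, 9), 100.0), frame_interval=0.5)
        trace = extract_trace(movie, (4, 4))
        assert np.allclose(trace.R, 1.0)

    def test_step_ratio_is_step_over_baseline(self):
        data = np.full((12, 9, 9), 10.0)
        data[10:] = 30.0
        movie = Movie(data, frame_interval=0.5)
        trace = extract_trace(movie, (4, 4))
        assert trace.F0 == pytest.approx(10.0)
        assert trace.R[-1] == pytest.approx(3.0)

    def test_simulated_event_peak_ratio_round_trip(self, clean_event_movie):
        cfg, movie, truth = clean_event_movie
        r, c = (int(round(v)) for v in truth.puncta_positions[0])
        trace = extract_trace(movie, (r, c))
        assert trace.R.max() == pytest.approx(3.0, abs=0.01)

    def test_edge_clipped_roi_raises(self):
        movie = Movie(np.zeros((12, 9, 9)) + 1, frame_interval=0.5)
        with pytest.raises(ValueError, match="clipped"):
            extract_trace(movie, (0, 4))


class TestDetectEvents:
    def test_single_step_event_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        R = rng.normal(1.0, 0.05, 240)
        R[100:104] = 2.0  # 1-frame rise, 4-frame duration
        trace = make_trace(R)
        events = detect_events(trace)
        oracle = brute_force_events(R)
        assert len(events) == len(oracle) == 1
        assert events[0].peak_frame == oracle[0][0]
        assert events[0].rise_time == pytest.approx(0.5)
        assert events[0].peak_ratio == pytest.approx(2.0)

    def test_slow_four_frame_rise_rejected(self):
        rng = np.random.default_rng(1)
        R = rng.normal(1.0, 0.05, 240)
        R[100:104] = [1.25, 1.5, 1.75, 2.0]  # ramp spread over 2 s
        R[104:108] = 2.0
        assert detect_events(make_trace(R)) == []

    def test_flat_trace_yields_nothing(self):
        assert detect_events(make_trace(np.ones(240))) == []

    def test_short_spike_rejected_by_duration(self):
        rng = np.random.default_rng(2)
        R = rng.normal(1.0, 0.05, 240)
        R[120] = 2.0  # single-frame spike: curation artifact, not an event
        assert detect_events(make_trace(R)) == []

    def test_two_events_separated_by_baseline_return(self):
        rng = np.random.default_rng(3)
        R = rng.normal(1.0, 0.05, 240)
        R[100:105] = 2.0
        R[150:155] = 2.0
        events = detect_events(make_trace(R))
        assert [e.peak_frame for e in events] == [
            100 + int(np.argmax(R[100:105])),
            150 + int(np.argmax(R[150:155])),
        ]

    def test_hovering_decay_not_fragmented(self):
        # slow decay oscillating around the threshold must stay one event
        rng = np.random.default_rng(4)
        R = rng.normal(1.0, 0.05, 240)
        decay = 1.0 + 1.0 * np.exp(-np.arange(60) / 12.0)
        R[100:160] = decay + rng.normal(0, 0.05, 60)
        events = detect_events(make_trace(R))
        assert len(events) == 1

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(scale=st.floats(min_value=0.1, max_value=100.0))
    def test_detection_invariant_to_intensity_scaling(self, scale):
        rng = np.random.default_rng(5)
        F = rng.normal(100.0, 5.0, 240)
        F[100:105] = 220.0
        base = detect_events(
            RoiTrace((1, 1), 3, F, float(F[:10].mean()), 0.5)
        )
        scaled = detect_events(
            RoiTrace((1, 1), 3, F * scale, float(F[:10].mean() * scale), 0.5)
        )
        assert [e.peak_frame for e in scaled] == [e.peak_frame for e in base]
        assert [e.rise_time for e in scaled] == [e.rise_time for e in base]

    def test_noise_free_baseline_uses_sigma_floor(self, caplog):
        R = np.ones(240)
        R[100:105] = 2.0
        events = detect_events(make_trace(R))
        assert len(events) == 1


class TestSummarizeEvents:
    def test_empty_summary(self):
        s = summarize_events([], 240, StimProtocol())
        assert s.n_events == 0
        assert s.mean_peak_ratio is None
        assert np.all(s.cumulative_counts == 0)

    def test_cumulative_steps_at_peak_frames(self):
        events = [
            FusionEvent(0, 69, 70, 2.0, 1.0, 0.5),
            FusionEvent(0, 79, 80, 3.0, 2.0, 0.5),
            FusionEvent(1, 89, 90, 2.5, 1.5, 0.5),
        ]
        s = summarize_events(events, 240, StimProtocol())
        assert s.cumulative_counts[-1] == s.n_events == 3
        assert s.cumulative_counts[69] == 0 and s.cumulative_counts[70] == 1
        assert np.all(np.diff(s.cumulative_counts) >= 0)
        assert s.mean_peak_ratio == pytest.approx(2.5)
        assert s.events_per_window == {"pre": 0, "stim": 3, "post": 0}

    def test_poisson_event_counts_average_to_rate(self):
        rng = np.random.default_rng(6)
        counts = []
        for _ in range(100):
            n = rng.poisson(5)
            events = [
                FusionEvent(0, f, f + 1, 2.0, 1.0, 0.5)
                for f in sorted(rng.integers(60, 200, size=n))
            ]
            counts.append(summarize_events(events, 240, StimProtocol()).n_events)
        assert np.mean(counts) == pytest.approx(5.0, abs=0.5)
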