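"""Synthetic-experiment generator: layout, wave statistics, rendering, ephys."""

import numpy as np
import pytest

from gliawave.config import SimulationConfig
from gliawave.core import GroundTruth, roi_circularity
from gliawave.simulate import (
    generate_experiment,
    make_layout,
    render_movie,
    simulate_ephys,
    simulate_waves,
    transient_kernel,
)
from gliawave.traces import compute_dff, extract_traces

from conftest import make_single_event_experiment


class TestLayout:
    def test_empty_layout(self):
        cfg = SimulationConfig(n_stalks=0, n_lateral=0)
        lay = make_layout(cfg, 0)
        assert lay.n_rois == 0
        assert lay.labels.max() == 0

    def test_counts_and_disjointness(self):
        cfg = SimulationConfig(n_stalks=10, n_lateral=10)
        lay = make_layout(cfg, 1)
        assert lay.n_rois == 20
        # label image is consistent with pixel sets and sets are disjoint
        total = sum(r.area for r in lay.rois)
        assert (lay.labels > 0).sum() == total
        for r in lay.rois:
            assert (lay.labels[r.pixels[:, 0], r.pixels[:, 1]] == r.id).all()

    def test_shape_classes_separate_by_circularity(self):
        """Rendered stalks sit above the 0.7 circularity cutoff, lateral
        processes below it (circularity recomputed from the masks)."""
        cfg = SimulationConfig(n_stalks=8, n_lateral=8)
        lay = make_layout(cfg, 2)
        for r in lay.rois:
            circ = roi_circularity(lay.labels == r.id)
            if r.shape_class == "stalk":
                assert circ >= 0.7
            else:
                assert circ < 0.7

    def test_overcrowded_field_raises(self):
        cfg = SimulationConfig(field_size=(40, 40), n_stalks=30, n_lateral=30)
        with pytest.raises(RuntimeError, match="crowd|small"):
            make_layout(cfg, 0)


class TestWaves:
    def test_full_participation(self):
        cfg = SimulationConfig(participation_p=1.0, n_frames=300)
        truth = simulate_waves(cfg, 0)
        assert truth.n_waves >= 1
        assert all(len(s) == cfg.n_rois for s in truth.recruited)

    def test_zero_participation(self):
        cfg = SimulationConfig(participation_p=0.0, n_frames=300)
        truth = simulate_waves(cfg, 0)
        assert all(len(s) == 0 for s in truth.recruited)
        assert truth.n_events == 0

    def test_mean_participation_matches_binomial(self):
        """participation_p=0.5, 40 ROIs, ~200 waves: mean within 3 binomial SE."""
        cfg = SimulationConfig(participation_p=0.5, n_frames=6200)  # ~8378 s
        truth = simulate_waves(cfg, 123)
        assert truth.n_waves > 150
        frac = np.mean(truth.true_participation_per_wave)
        se = np.sqrt(0.5 * 0.5 / 40) / np.sqrt(truth.n_waves)
        assert abs(frac - 0.5) < 3 * se

    def test_event_lags_within_glial_window(self):
        cfg = SimulationConfig(seed=5)
        truth = simulate_waves(cfg, 5)
        for w, rec in enumerate(truth.recruited):
            onset = truth.wave_onsets_s[w]
            for rid in rec:
                lags = [t - onset for t in truth.event_onsets[rid] if 0 <= t - onset <= cfg.glial_lag_s]
                assert lags, f"ROI {rid} has no event within the lag window of wave {w}"

    def test_events_inside_recording(self):
        cfg = SimulationConfig(seed=8)
        truth = simulate_waves(cfg, 8)
        for ts in truth.event_onsets.values():
            for t in ts:
                assert 0 <= t <= cfg.duration_s

    def test_recruitment_monotone_in_p(self):
        means = []
        for p in (0.2, 0.5, 0.8):
            cfg = SimulationConfig(participation_p=p, n_frames=600)
            fracs = [
                np.mean(simulate_waves(cfg, s).true_participation_per_wave) for s in range(5)
            ]
            means.append(np.mean(fracs))
        assert means[0] < means[1] < means[2]


class TestRender:
    def test_no_events_constant_movie(self):
        cfg = SimulationConfig(
            n_frames=20, field_size=(64, 64), n_stalks=3, n_lateral=3, noise_sd=0.0
        )
        lay = make_layout(cfg, 0)
        truth = GroundTruth(np.array([]), [], {r.id: [] for r in lay.rois}, lay.n_rois)
        movie = render_movie(lay, truth, cfg, 0)
        assert (movie.data == movie.data[0]).all()
        for r in lay.rois:
            assert movie.data[0][r.pixels[:, 0], r.pixels[:, 1]].mean() == cfg.baseline_f0

    def test_single_event_peak_matches_sampled_kernel(self):
        """Noiseless single transient: max ROI-mean dF/F equals the kernel
        evaluated at the frame times (brute-force oracle)."""
        cfg, layout, truth, movie = make_single_event_experiment(onset_s=50.0)
        expected = transient_kernel(
            movie.times - 50.0, cfg.rise_s, cfg.decay_s, cfg.peak_dff
        ).max()
        traces = extract_traces(movie, layout)
        dff = compute_dff(
            traces, f0_method="external", f0=np.array([cfg.baseline_f0])
        )
        # uint16 quantisation adds up to 0.5/100 per pixel
        assert dff.dff.max() == pytest.approx(expected, abs=0.02)

    def test_calcium_kernel_width_in_3_to_5_s(self):
        """Full width at 10% of peak of the default calcium kernel, brute force."""
        cfg = SimulationConfig()
        t = np.arange(0, 30, 0.001)
        k = transient_kernel(t, cfg.rise_s, cfg.decay_s, cfg.peak_dff)
        above = t[k > 0.1 * cfg.peak_dff]
        width = above[-1] - above[0]
        assert 3.0 <= width <= 5.0

    def test_glutamate_kernel_faster_than_calcium(self):
        cal = SimulationConfig(sensor="calcium")
        glu = SimulationConfig(sensor="glutamate")
        t = np.arange(0, 30, 0.001)
        for cfg_ in (cal, glu):
            k = transient_kernel(t, cfg_.rise_s, cfg_.decay_s, 1.0)
            cfg_._w = np.ptp(t[k > 0.1])
        assert glu._w < cal._w

    def test_noiseless_trace_reproduces_kernel(self):
        """ROI-mean trace -> dF/F with known F0 recovers the injected kernel."""
        cfg, layout, truth, movie = make_single_event_experiment(onset_s=40.0)
        traces = compute_dff(
            extract_traces(movie, layout), f0_method="external", f0=np.array([cfg.baseline_f0])
        )
        expected = transient_kernel(movie.times - 40.0, cfg.rise_s, cfg.decay_s, cfg.peak_dff)
        assert np.allclose(traces.dff[0], expected, atol=0.02)


class TestEphys:
    def _truth(self, onsets, n_rois=4):
        return GroundTruth(np.asarray(onsets, dtype=float), [set() for _ in onsets], {}, n_rois)

    def test_no_waves_baseline_only(self):
        cfg = SimulationConfig(n_frames=74)  # 100 s
        trace = simulate_ephys(self._truth([]), cfg, 0)
        se = cfg.ephys_noise_sd_pA / np.sqrt(len(trace.current_pA))
        assert abs(trace.current_pA.mean()) < 3 * se

    def test_two_noiseless_epscs_scan_oracle(self):
        """Threshold-scan oracle finds exactly 2 sub-baseline excursions with
        onsets at the injected wave times."""
        cfg = SimulationConfig(n_frames=74, ephys_noise_sd_pA=0.0)
        trace = simulate_ephys(self._truth([10.0, 60.0]), cfg, 0)
        below = trace.current_pA < -1.0
        edges = np.flatnonzero(np.diff(below.astype(int)) == 1) + 1
        assert len(edges) == 2
        assert trace.time_s[edges] == pytest.approx([10.0, 60.0], abs=0.05)

    def test_inward_sign_convention(self):
        cfg = SimulationConfig(n_frames=74)
        trace = simulate_ephys(self._truth([30.0]), cfg, 1)
        assert trace.current_pA.min() < 0


class TestGenerate:
    def test_seeded_determinism(self):
        cfg = SimulationConfig(
            n_frames=30, field_size=(64, 64), n_stalks=3, n_lateral=3, seed=42
        )
        m1, e1, l1, t1 = generate_experiment(cfg)
        m2, e2, l2, t2 = generate_experiment(cfg)
        assert (m1.data == m2.data).all()
        assert (e1.current_pA == e2.current_pA).all()
        assert (l1.labels == l2.labels).all()
        assert np.array_equal(t1.wave_onsets_s, t2.wave_onsets_s)

    def test_duration_arithmetic(self, small_experiment):
        movie, ephys, _, _ = small_experiment
        cfg = SimulationConfig(n_frames=120, frame_rate_hz=0.74)
        assert cfg.duration_s == pytest.approx(162.2, abs=0.2)
        assert ephys.time_s[-1] <= movie.duration_s
        assert ephys.time_s[-1] > movie.duration_s - 1.0

    def test_event_count_bookkeeping(self, small_experiment):
        _, _, _, truth = small_experiment
        assert truth.n_events == sum(len(s) for s in truth.recruited)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"participation_p": 1.5},
            {"participation_p": -0.1},
            {"n_frames": 0},
            {"frame_rate_hz": 0.0},
            {"sensor": "voltage"},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)
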