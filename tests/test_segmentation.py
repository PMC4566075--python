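"""Registration, Laplacian segmentation, shape classification, grid partition."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gliawave.config import SimulationConfig
from gliawave.core import GroundTruth
from gliawave.segmentation import (
    classify_roi_shape,
    grid_roi_masks,
    laplacian_roi_masks,
    register_movie,
)
from gliawave.core import MovieStack
from gliawave.simulate import generate_experiment, make_layout, render_movie


def _noiseless_movie(seed=0, drift=0.0, n_frames=40, field=128, n_stalks=5, n_lateral=5):
    cfg = SimulationConfig(
        n_frames=n_frames,
        field_size=(field, field),
        n_stalks=n_stalks,
        n_lateral=n_lateral,
        noise_sd=0.0,
        drift_px_per_frame=drift,
        seed=seed,
    )
    layout = make_layout(cfg, seed)
    truth = GroundTruth(np.array([]), [], {}, layout.n_rois)
    return cfg, layout, render_movie(layout, truth, cfg, seed)


def _exhaustive_shift(reference, frame, max_shift=12):
    """Brute-force integer-shift oracle: displacement minimising SSD."""
    best, best_err = (0, 0), np.inf
    for dy in range(-max_shift, max_shift + 1):
        for dx in range(-max_shift, max_shift + 1):
            err = np.sum(
                (np.roll(frame, (-dy, -dx), axis=(0, 1)).astype(float) - reference) ** 2
            )
            if err < best_err:
                best, best_err = (dy, dx), err
    return best


class TestRegistration:
    def test_zero_drift_zero_shifts(self):
        _, _, movie = _noiseless_movie(drift=0.0, n_frames=10)
        reg = register_movie(movie)
        assert (reg.shifts == 0).all()
        assert not reg.rejected

    def test_constant_drift_recovered_exactly(self):
        """Noiseless 0.25 px/frame drift: shifts equal the injected cumulative
        displacement, cross-checked against an exhaustive-search oracle."""
        cfg, _, movie = _noiseless_movie(drift=0.25, n_frames=30)
        reg = register_movie(movie)
        expected = np.array([[int(round(0.25 * i)), 0] for i in range(30)])
        assert (reg.shifts == expected).all()
        ref = movie.data[0].astype(float)
        for i in (7, 21, 29):
            assert tuple(reg.shifts[i]) == _exhaustive_shift(ref, movie.data[i])

    def test_reregistration_is_identity(self):
        _, _, movie = _noiseless_movie(drift=0.25, n_frames=20)
        reg = register_movie(movie)
        reg2 = register_movie(reg.movie)
        assert (reg2.shifts == 0).all()

    def test_single_frame_identity(self):
        movie = MovieStack(np.zeros((1, 16, 16)), 1.0)
        reg = register_movie(movie)
        assert reg.shifts.shape == (1, 2) and (reg.shifts == 0).all()

    def test_nonfinite_pixels_rejected(self):
        data = np.zeros((3, 16, 16))
        data[1, 2, 2] = np.nan
        with pytest.raises(ValueError, match="finite"):
            register_movie(MovieStack(data, 1.0))

    def test_large_shift_sets_rejection_flag(self):
        _, _, movie = _noiseless_movie(drift=1.0, n_frames=30)
        reg = register_movie(movie, reject_shift_px=10)
        assert reg.rejected


class TestLaplacianSegmentation:
    def test_blank_image_gives_zero_rois(self):
        rois = laplacian_roi_masks(np.full((64, 64), 7.0))
        assert rois.n_rois == 0

    def test_recovers_noiseless_layout(self):
        """20 bright shapes, noiseless: exactly 20 ROIs, each overlapping its
        ground-truth mask with Jaccard >= 0.8 (maximal-overlap matching)."""
        _, layout, movie = _noiseless_movie(field=256, n_stalks=10, n_lateral=10, n_frames=10)
        rois = laplacian_roi_masks(movie)
        assert rois.n_rois == 20
        for r in rois.rois:
            true_ids = layout.labels[r.pixels[:, 0], r.pixels[:, 1]]
            vals, counts = np.unique(true_ids[true_ids > 0], return_counts=True)
            assert len(vals) > 0
            tid = vals[np.argmax(counts)]
            true_mask = layout.labels == tid
            det_mask = rois.labels == r.id
            jaccard = (true_mask & det_mask).sum() / (true_mask | det_mask).sum()
            assert jaccard >= 0.8

    def test_roi_count_stable_under_noise(self):
        """At SNR ~10 the ROI count stays within 10% of the noiseless count
        over 10 seeds."""
        counts = []
        for seed in range(10):
            cfg = SimulationConfig(
                n_frames=40,
                field_size=(256, 256),
                n_stalks=10,
                n_lateral=10,
                noise_sd=5.0,  # peak_dff*baseline/noise = 10
                seed=seed,
            )
            layout = make_layout(cfg, seed)
            truth = GroundTruth(np.array([]), [], {}, layout.n_rois)
            movie = render_movie(layout, truth, cfg, seed)
            counts.append(laplacian_roi_masks(movie).n_rois)
        assert all(abs(c - 20) <= 2 for c in counts)

    def test_translation_equivariance(self):
        _, _, movie = _noiseless_movie(field=128, n_frames=5)
        img = movie.data.mean(axis=0)
        rois_a = laplacian_roi_masks(img)
        rois_b = laplacian_roi_masks(np.roll(img, (9, 5), axis=(0, 1)))
        assert rois_b.n_rois == rois_a.n_rois
        shifted = np.roll(rois_a.labels != 0, (9, 5), axis=(0, 1))
        assert ((rois_b.labels != 0) == shifted).all()

    def test_registration_then_segmentation_matches_driftfree(self):
        """A drifting noiseless movie, once registered, segments identically
        to the drift-free movie of the same layout."""
        _, _, still = _noiseless_movie(seed=4, drift=0.0, n_frames=30)
        _, _, drifting = _noiseless_movie(seed=4, drift=0.25, n_frames=30)
        reg = register_movie(drifting)
        rois_still = laplacian_roi_masks(still)
        rois_reg = laplacian_roi_masks(reg.movie)
        assert (rois_reg.labels != 0).sum() == (rois_still.labels != 0).sum()
        assert ((rois_reg.labels != 0) == (rois_still.labels != 0)).all()


class TestShapeClassification:
    def test_disk_is_stalk(self):
        mask = np.zeros((20, 20), dtype=bool)
        rr, cc = np.ogrid[:20, :20]
        mask[(rr - 10) ** 2 + (cc - 10) ** 2 <= 25] = True
        assert classify_roi_shape(mask) == "stalk"

    def test_bar_is_lateral_process(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[10:13, 5:23] = True  # 3 x 18 bar
        assert classify_roi_shape(mask) == "lateral_process"

    def test_degenerate_roi_raises(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 2] = True
        with pytest.raises(ValueError, match="degenerate"):
            classify_roi_shape(mask)

    def test_agreement_with_generator_classes(self):
        """Classification recovers the generator's true class for >= 95% of
        ROIs over 10 seeded layouts."""
        agree = total = 0
        for seed in range(10):
            layout = make_layout(SimulationConfig(seed=seed), seed)
            for r in layout.rois:
                agree += classify_roi_shape(layout.labels == r.id) == r.shape_class
                total += 1
        assert agree / total >= 0.95


class TestGridPartition:
    def test_standard_field(self):
        rois = grid_roi_masks(256, 256, 16)
        assert rois.n_rois == 16
        assert all(r.area == 64 * 64 for r in rois.rois)
        assert all(r.shape_class == "grid" for r in rois.rois)

    def test_minimal_field(self):
        rois = grid_roi_masks(4, 4, 16)
        assert rois.n_rois == 16
        assert all(r.area == 1 for r in rois.rois)

    def test_indivisible_field_raises(self):
        with pytest.raises(ValueError, match="divisible"):
            grid_roi_masks(250, 256, 16)

    def test_nonsquare_count_raises(self):
        with pytest.raises(ValueError, match="square"):
            grid_roi_masks(256, 256, 12)

    @given(
        k=st.sampled_from([1, 2, 3, 4]),
        mr=st.integers(min_value=1, max_value=6),
        mc=st.integers(min_value=1, max_value=6),
    )
    def test_partition_property(self, k, mr, mc):
        """Grid ROIs always cover the field exactly once (cover + disjoint)."""
        rois = grid_roi_masks(k * mr, k * mc, k * k)
        assert (rois.labels > 0).all()
        assert sum(r.area for r in rois.rois) == k * mr * k * mc
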