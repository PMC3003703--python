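import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aquaskinner.arena import ArenaGeometry, Quadrant, dish_mask
from aquaskinner.tracking import (
    BackgroundModel,
    QCFlag,
    TrackState,
    TrackingParams,
    binarize,
    heal_background,
    init_background,
    qc_frame,
    select_blobs,
    smooth,
    subtract_and_stretch,
    track_frame,
)

SHAPE = (240, 240)


def flat(value, dtype=np.uint8):
    return np.full(SHAPE, value, dtype=dtype)


class TestInitBackground:
    def test_identical_frames_reproduce_frame(self):
        frames = [flat(57)] * 5
        model = init_background(frames)
        assert np.array_equal(model.background, flat(57).astype(float))
        assert (model.per_quadrant_age == 0).all()

    def test_median_rejects_transient_speck(self):
        frames = [flat(10) for _ in range(5)]
        frames[3] = frames[3].copy()
        frames[3][100, 100] = 200
        model = init_background(frames)
        assert model.background[100, 100] == 10

    def test_single_frame(self):
        model = init_background([flat(80)])
        assert np.array_equal(model.background, flat(80).astype(float))

    def test_empty_and_mismatched_inputs_rejected(self):
        with pytest.raises(ValueError):
            init_background([])
        with pytest.raises(ValueError):
            init_background([flat(10), np.zeros((120, 120), np.uint8)])


class TestHealBackground:
    def test_all_quadrants_occupied_leaves_model_unchanged(self, geometry):
        model = init_background([flat(100)])
        healed = heal_background(model, flat(200), set(Quadrant), geometry)
        assert np.array_equal(healed.background, model.background)
        assert (healed.per_quadrant_age == 1).all()

    def test_full_weight_with_no_occupancy_copies_frame(self, geometry):
        model = init_background([flat(100)], update_weight=1.0)
        healed = heal_background(model, flat(200), set(), geometry)
        assert np.array_equal(healed.background, flat(200).astype(float))
        assert (healed.per_quadrant_age == 0).all()

    def test_healed_background_follows_drift_where_frozen_lags(self, geometry):
        # linear ramp over 1000 frames; animal pinned in Q1, so only
        # Q2..Q4 may update
        model = init_background([flat(100)])
        frozen = model.background.copy()
        frame = None
        for tick in range(1000):
            frame = flat(100).astype(float) + 20.0 * tick / 1000.0
            model = heal_background(model, frame, {Quadrant.Q1}, geometry)
        labels_err = np.abs(model.background - frame)
        from aquaskinner.arena import quadrant_label_image

        labels = quadrant_label_image(geometry)
        for q in (1, 2, 3):  # Q2..Q4 healed
            assert labels_err[labels == q].max() < 2.0
        assert np.abs(frozen - frame).max() >= 19.0


class TestSubtractAndStretch:
    def test_frame_equal_background_gives_zero(self):
        model = init_background([flat(120)])
        out = subtract_and_stretch(flat(120), model, expected_area_px=100)
        assert out.max() == 0

    def test_isolated_square_saturates(self):
        model = init_background([flat(0)])
        frame = flat(0)
        frame[50:60, 50:60] = 50  # 100 px at difference 50
        out = subtract_and_stretch(frame, model, expected_area_px=100)
        assert out[50:60, 50:60].min() >= 0.99 * 255

    def test_stretch_is_scale_invariant_through_binarization(self):
        model = init_background([flat(0)])
        frame1 = flat(0)
        frame1[50:62, 50:62] = 40
        frame2 = flat(0)
        frame2[50:62, 50:62] = 80  # doubled difference
        out1 = subtract_and_stretch(frame1, model, expected_area_px=144)
        out2 = subtract_and_stretch(frame2, model, expected_area_px=144)
        b1 = binarize(out1, noise_k=3.0)
        b2 = binarize(out2, noise_k=3.0)
        assert np.array_equal(b1, b2)

    def test_oversized_expected_area_rejected(self):
        model = init_background([flat(0)])
        with pytest.raises(ValueError):
            subtract_and_stretch(flat(0), model, expected_area_px=240 * 240)


class TestBinarize:
    def test_zero_image_stays_zero(self):
        assert not binarize(flat(0), noise_k=3.0).any()

    def test_sparse_bright_pixels_selected_exactly(self):
        img = flat(0)
        img[10:20, 10:20] = 255  # 100 px bright
        out = binarize(img, noise_k=3.0)
        # threshold = mean + 3*std of the constructed image is far below 255
        p = 100 / img.size
        t = 255 * p + 3.0 * 255 * math.sqrt(p * (1 - p))
        assert t < 255
        assert out.sum() == 100
        assert out[10:20, 10:20].all()

    @given(k_lo=st.floats(0.5, 3.0), k_hi=st.floats(3.0, 8.0))
    @settings(max_examples=25, deadline=None)
    def test_raising_noise_k_never_adds_pixels(self, k_lo, k_hi):
        rng = np.random.default_rng(11)
        img = (rng.random(SHAPE) * 255).astype(np.uint8)
        lo = binarize(img, noise_k=k_lo)
        hi = binarize(img, noise_k=k_hi)
        assert not (hi & ~lo).any()


class TestSelectBlobs:
    def test_single_component_kept(self):
        img = np.zeros(SHAPE, bool)
        img[10:20, 10:22] = True  # 120 px
        blobs = select_blobs(img, min_area_px=50)
        assert len(blobs) == 1 and blobs[0].area_px == 120

    def test_small_component_dropped(self):
        img = np.zeros(SHAPE, bool)
        img[10:20, 10:22] = True
        img[100:102, 100:105] = True  # 10 px of noise
        blobs = select_blobs(img, min_area_px=50)
        assert [b.area_px for b in blobs] == [120]

    def test_empty_image_gives_empty_list(self):
        assert select_blobs(np.zeros(SHAPE, bool), min_area_px=1) == []

    def test_diagonal_fragments_join_under_8_connectivity(self):
        img = np.zeros(SHAPE, bool)
        for i in range(60):  # 1-px-wide diagonal line
            img[50 + i, 50 + i] = True
        assert len(select_blobs(img, min_area_px=50)) == 1

    def test_monotone_in_min_area(self):
        rng = np.random.default_rng(3)
        img = rng.random(SHAPE) > 0.7
        n_small = len(select_blobs(img, min_area_px=5))
        n_large = len(select_blobs(img, min_area_px=20))
        assert n_large <= n_small


class TestQCFrame:
    def _blob_at(self, px, py, area=150):
        from aquaskinner.tracking import Blob

        return Blob(centroid_px=(px, py), area_px=area,
                    bbox=(int(py) - 6, int(px) - 6, int(py) + 6, int(px) + 6),
                    perimeter_px=40.0)

    def test_large_jump_rejected(self, geometry):
        prev = TrackState(level=(0.0, 0.0), last_raw=(0.0, 0.0), qc_flag=QCFlag.ACCEPTED)
        # 0.6 of a diameter = 36 mm = 144 px to the right of centre
        blob = self._blob_at(119.5 + 110, 119.5)  # 27.5 mm, 0.458 diam
        assert qc_frame(blob, prev, 0.5, (60, 500), geometry) is QCFlag.ACCEPTED
        assert qc_frame(blob, prev, 0.2, (60, 500), geometry) is QCFlag.REJECTED_JUMP

    def test_small_move_accepted(self, geometry):
        prev = TrackState(level=(0.0, 0.0), last_raw=(0.0, 0.0), qc_flag=QCFlag.ACCEPTED)
        blob = self._blob_at(119.5 + 24, 119.5)  # 6 mm = 0.1 diameter
        assert qc_frame(blob, prev, 0.5, (60, 500), geometry) is QCFlag.ACCEPTED

    def test_missing_blob_flags_no_blob(self, geometry):
        prev = TrackState()
        assert qc_frame(None, prev, 0.5, (60, 500), geometry) is QCFlag.NO_BLOB

    def test_area_out_of_bounds_rejected(self, geometry):
        prev = TrackState(level=(0.0, 0.0), last_raw=(0.0, 0.0))
        assert (
            qc_frame(self._blob_at(119.5, 119.5, area=10), prev, 0.5, (60, 500), geometry)
            is QCFlag.REJECTED_AREA
        )


class TestSmoothing:
    def test_constant_input_is_fixed_point(self):
        st_ = TrackState(level=(5.0, -3.0), trend=(0.0, 0.0), last_raw=(5.0, -3.0))
        for _ in range(20):
            st_ = smooth(st_, (5.0, -3.0))
        assert st_.level == (5.0, -3.0)
        assert st_.trend == (0.0, 0.0)

    def test_linear_input_recovers_slope(self):
        # Holt recurrence tracks a linear ramp: trend converges to the slope
        a, b = 2.0, 0.03
        st_ = TrackState(alpha=0.5, beta=0.5)
        for t in range(1000):
            st_ = smooth(st_, (a + b * t, 0.0))
        assert abs(st_.trend[0] - b) < 1e-6
        assert abs(st_.trend[1]) < 1e-12

    def test_alpha_one_beta_zero_passes_through(self):
        st_ = TrackState(alpha=1.0, beta=1e-12)
        for raw in [(1.0, 2.0), (3.0, -1.0), (0.5, 0.5)]:
            st_ = smooth(st_, raw)
            assert st_.level == pytest.approx(raw)
            assert st_.trend == pytest.approx((0.0, 0.0), abs=1e-9)

    @given(vx=st.floats(-10, 10), vy=st.floats(-10, 10))
    @settings(max_examples=25, deadline=None)
    def test_shift_equivariance(self, vx, vy):
        raws = [(1.0, 0.5), (2.0, 1.5), (2.5, 0.0), (4.0, -1.0)]
        s1 = TrackState()
        s2 = TrackState()
        for r in raws:
            s1 = smooth(s1, r)
            s2 = smooth(s2, (r[0] + vx, r[1] + vy))
        assert s2.level[0] - s1.level[0] == pytest.approx(vx, abs=1e-9)
        assert s2.level[1] - s1.level[1] == pytest.approx(vy, abs=1e-9)
        assert s2.trend == pytest.approx(s1.trend, abs=1e-9)


class TestTrackFramePipeline:
    def test_empty_dish_coasts_with_no_blob(self, geometry, tracking_params):
        from aquaskinner.synthdata import RenderParams, empty_frame

        rp = RenderParams(sensor_noise_sd=0.0)
        frame = empty_frame(rp, geometry)
        model = init_background([frame])
        state = TrackState()
        for _ in range(5):
            state, model, blob = track_frame(frame, model, state, tracking_params, geometry)
            assert state.qc_flag is QCFlag.NO_BLOB
            assert blob is None
        assert not state.initialized

    def test_deterministic_given_identical_frames(self, geometry, tracking_params):
        from aquaskinner.synthdata import RenderParams, circle_trajectory, render_frame, empty_frame

        rp = RenderParams(sensor_noise_sd=0.0)
        traj = circle_trajectory(15.0, 3.0, 5.0)
        frames = [
            render_frame(traj(i * 0.1), traj.heading(i * 0.1), rp, geometry, i)[0]
            for i in range(30)
        ]
        runs = []
        for _ in range(2):
            model = init_background([empty_frame(rp, geometry)])
            state = TrackState()
            levels = []
            for f in frames:
                state, model, _ = track_frame(f, model, state, tracking_params, geometry)
                levels.append(state.level)
            runs.append(levels)
        assert runs[0] == runs[1]
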