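"""The five gaze metrics against brute-force oracles and their invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import build_recording
from oracles import covered_tiles_geometric, dwell_oracle, path_oracle

from gazecad.geometry import PixelBox
from gazecad.metrics import (
    GazeRecording,
    LesionAOI,
    MetricRecord,
    RecordingError,
    covered_lung_tiles,
    dwell_time,
    interpretation_time,
    lung_coverage,
    lung_tiles,
    path_length,
    render_overlay,
    time_to_first_fixation,
    visual_angle,
)

AOI = LesionAOI(PixelBox(200, 200, 300, 280), margin=50)


def random_recording(rng, n=120, width=640, height=480, p_valid=0.8):
    pts = rng.uniform([0, 0], [width - 1, height - 1], size=(n, 2))
    valid = rng.random(n) < p_valid
    return build_recording(pts, valid=valid, width=width, height=height)


class TestInterpretationTime:
    def test_equals_duration(self):
        rec = build_recording(np.zeros((10, 2)), duration=14.6)
        assert interpretation_time(rec) == pytest.approx(14.6)

    def test_empty_recording_zero(self):
        rec = build_recording(np.empty((0, 2)), duration=0.0)
        assert interpretation_time(rec) == 0.0

    def test_independent_of_validity(self):
        pts = np.random.default_rng(0).uniform(0, 400, size=(50, 2))
        with_samples = build_recording(pts, duration=5.0)
        none_valid = build_recording(pts, valid=np.zeros(50, bool), duration=5.0)
        assert interpretation_time(with_samples) == interpretation_time(none_valid)


class TestDwell:
    def test_ninety_consecutive_in_aoi_samples(self):
        pts = np.tile([250.0, 240.0], (90, 1))
        assert dwell_time(build_recording(pts), AOI) == pytest.approx(1.5)

    def test_no_samples_inside(self):
        pts = np.tile([10.0, 10.0], (40, 1))
        assert dwell_time(build_recording(pts), AOI) == 0.0

    def test_invalid_samples_do_not_count(self):
        pts = np.tile([250.0, 240.0], (60, 1))
        valid = np.zeros(60, bool)
        valid[:30] = True
        assert dwell_time(build_recording(pts, valid=valid), AOI) == pytest.approx(0.5)

    def test_matches_membership_loop_on_random_tracks(self):
        rng = np.random.default_rng(21)
        for _ in range(100):
            rec = random_recording(rng, n=60)
            assert dwell_time(rec, AOI) == pytest.approx(dwell_oracle(rec, AOI.region(640, 480)))


class TestTimeToFirstFixation:
    def test_first_entry_timestamp(self):
        pts = np.vstack([np.tile([10.0, 10.0], (60, 1)), np.tile([250.0, 240.0], (10, 1))])
        assert time_to_first_fixation(build_recording(pts), AOI) == pytest.approx(1.0)

    def test_first_sample_already_inside(self):
        rec = build_recording(np.tile([250.0, 240.0], (5, 1)))
        assert time_to_first_fixation(rec, AOI) == 0.0

    def test_never_entering_gives_absent(self):
        rec = build_recording(np.tile([5.0, 5.0], (30, 1)))
        assert time_to_first_fixation(rec, AOI) is None

    def test_invalid_entries_skipped(self):
        pts = np.vstack([np.tile([250.0, 240.0], (30, 1)), np.tile([250.0, 240.0], (30, 1))])
        valid = np.concatenate([np.zeros(30, bool), np.ones(30, bool)])
        assert time_to_first_fixation(build_recording(pts, valid=valid), AOI) == pytest.approx(0.5)


class TestPathLength:
    def test_three_four_five_triangle(self):
        assert path_length(build_recording([[0, 0], [3, 4]])) == pytest.approx(5.0)

    def test_single_valid_sample(self):
        rec = build_recording([[100, 100], [200, 200]], valid=[True, False])
        assert path_length(rec) == 0.0

    def test_bridges_dropout_gaps(self):
        pts = [[0, 0], [50, 50], [3, 4]]
        rec = build_recording(pts, valid=[True, False, True])
        assert path_length(rec) == pytest.approx(5.0)

    def test_matches_pairwise_summation_on_random_walks(self):
        rng = np.random.default_rng(22)
        for _ in range(100):
            rec = random_recording(rng, n=200)
            assert path_length(rec) == pytest.approx(path_oracle(rec), rel=1e-12)


class TestCoverage:
    def test_band_containing_whole_image(self, small_mask):
        # a dense sweep with a buffer larger than the frame reaches every tile
        pts = [[i, 240] for i in range(0, 640, 10)]
        rec = build_recording(pts)
        assert lung_coverage(rec, small_mask, cell=50, buffer=700.0) == 1.0

    def test_no_valid_samples_gives_zero(self, small_mask):
        rec = build_recording(np.tile([300.0, 200.0], (20, 1)), valid=np.zeros(20, bool))
        assert lung_coverage(rec, small_mask) == 0.0

    def test_dimension_mismatch_rejected(self, small_mask):
        rec = build_recording([[10, 10]], width=500, height=480)
        with pytest.raises(RecordingError):
            lung_coverage(rec, small_mask)

    def test_empty_lung_raises(self):
        rec = build_recording([[10, 10]], width=100, height=100)
        with pytest.raises(RecordingError):
            lung_coverage(rec, np.zeros((100, 100), bool))

    def test_tile_centre_rule(self):
        mask = np.zeros((100, 100), bool)
        mask[20:30, 20:30] = True          # covers the (0, 0) tile centre (25, 25)
        mask[60:70, 10:20] = True          # off-centre blob: no tile centre inside
        tiles = lung_tiles(mask, cell=50)
        assert tiles.tolist() == [[0, 0]]

    def test_matches_geometric_brute_force(self, small_mask):
        rng = np.random.default_rng(23)
        tiles = lung_tiles(small_mask, cell=50)
        for _ in range(100)            :
            n = int(rng.integers(1, 12))
            pts = rng.uniform([0, 0], [639, 479], size=(n, 2))
            got = covered_lung_tiles(pts, tiles, 50, 50.0)
            want = covered_tiles_geometric(pts, tiles, 50, 50.0)
            assert got.tolist() == want


class TestVisualAngle:
    def test_margin_subtends_about_one_degree(self):
        assert round(visual_angle(50, 0.233, 60.0), 1) == 1.1

    def test_zero_extent(self):
        assert visual_angle(0, 0.233, 60.0) == 0.0

    def test_small_angle_halves_with_doubled_distance(self):
        a1 = visual_angle(50, 0.233, 60.0)
        a2 = visual_angle(50, 0.233, 120.0)
        assert a1 / a2 == pytest.approx(2.0, rel=1e-2)

    def test_rejects_nonpositive_geometry(self):
        with pytest.raises(ValueError):
            visual_angle(50, 0.0, 60.0)
        with pytest.raises(ValueError):
            visual_angle(50, 0.233, -1.0)


class TestOverlay:
    def test_dimensions_and_determinism(self, small_mask):
        rng = np.random.default_rng(3)
        rec = random_recording(rng, n=40)
        img1 = render_overlay(rec, small_mask, buffer=50)
        img2 = render_overlay(rec, small_mask, buffer=50)
        assert img1.shape == (480, 640, 3)
        assert np.array_equal(img1, img2)

    def test_empty_recording_is_mask_only(self, small_mask):
        rec = build_recording(np.empty((0, 2)), duration=1.0)
        img = render_overlay(rec, small_mask)
        assert set(map(tuple, np.unique(img.reshape(-1, 3), axis=0))) <= {
            (0, 0, 0), (0, 90, 90)
        }


class TestRecordingValidation:
    def test_non_monotone_timestamps_rejected(self):
        with pytest.raises(RecordingError):
            GazeRecording(
                t=[0.0, 0.2, 0.1], x=[0, 0, 0], y=[0, 0, 0], valid=[1, 1, 1],
                sampling_rate=60, duration=1.0, image_width=10, image_height=10,
            )

    def test_duration_must_cover_samples(self):
        with pytest.raises(RecordingError):
            build_recording(np.zeros((60, 2)), duration=0.5)

    def test_metric_record_invariants(self):
        with pytest.raises(ValueError):
            MetricRecord(5.0, 6.0, None, 0.0, 0.5, 1.0)
        with pytest.raises(ValueError):
            MetricRecord(5.0, 1.0, None, 0.0, 1.2, 1.0)


class TestMetricProperties:
    @settings(max_examples=40, deadline=None)
    @given(seed=st.integers(0, 10_000), margin=st.floats(0, 80))
    def test_dwell_bounded_and_monotone_in_margin(self, seed, margin):
        rng = np.random.default_rng(seed)
        rec = random_recording(rng)
        aoi_small = LesionAOI(AOI.box, margin=0.0)
        aoi = LesionAOI(AOI.box, margin=margin)
        assert dwell_time(rec, aoi) <= interpretation_time(rec) + 1e-9
        assert dwell_time(rec, aoi_small) <= dwell_time(rec, aoi)

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000), buffer=st.floats(5, 60))
    def test_coverage_in_unit_interval_and_monotone_in_buffer(self, seed, buffer, small_mask):
        rng = np.random.default_rng(seed)
        rec = random_recording(rng, n=25)
        c1 = lung_coverage(rec, small_mask, buffer=buffer)
        c2 = lung_coverage(rec, small_mask, buffer=buffer + 20)
        assert 0.0 <= c1 <= c2 <= 1.0

    @settings(max_examples=40, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_ttff_bounded_and_insensitive_to_later_samples(self, seed):
        rng = np.random.default_rng(seed)
        rec = random_recording(rng)
        ttff = time_to_first_fixation(rec, AOI)
        if ttff is None:
            return
        assert ttff <= interpretation_time(rec) + 1e-9
        cut = int(np.searchsorted(rec.t, ttff, side="right"))
        truncated = GazeRecording(
            t=rec.t[:cut], x=rec.x[:cut], y=rec.y[:cut], valid=rec.valid[:cut],
            sampling_rate=rec.sampling_rate, duration=rec.duration,
            image_width=rec.image_width, image_height=rec.image_height,
        )
        assert time_to_first_fixation(truncated, AOI) == ttff

    @settings(max_examples=40, deadline=None)
    @given(seed=st.integers(0, 10_000), dx=st.floats(-200, 200), scale=st.floats(0.1, 5))
    def test_path_translation_invariance_and_scaling(self, seed, dx, scale):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 300, size=(40, 2))
        base = path_length(build_recording(pts, width=2000, height=2000))
        shifted = path_length(build_recording(pts + [dx, 0], width=2000, height=2000))
        scaled = path_length(build_recording(pts * scale, width=2000, height=2000))
        assert shifted == pytest.approx(base, rel=1e-9, abs=1e-7)
        assert scaled == pytest.approx(scale * base, rel=1e-9, abs=1e-7)
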