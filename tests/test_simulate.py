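"""The synthetic study generator: masks, boxes, scanpaths, full studies."""

import numpy as np
import pytest
from skimage.measure import label

from gazecad.design import CaseSpec, Group
from gazecad.metrics import (
    LesionAOI,
    dwell_time,
    interpretation_time,
    lung_coverage,
    lung_tiles,
    path_length,
    time_to_first_fixation,
)
from gazecad.simulate import (
    ConditionEffects,
    PlacementError,
    ReaderProfile,
    WITH_BB,
    WITHOUT_BB,
    make_lung_mask,
    sample_lesion_box,
    simulate_metric_values,
    simulate_scanpath,
    simulate_study,
)
from gazecad.validity import capture_ratio


class TestLungMask:
    def test_two_connected_components(self):
        mask = make_lung_mask(512, 512, seed=1)
        assert label(mask).max() == 2

    def test_area_fraction_matches_display_layout(self):
        # portrait radiograph pillarboxed on a landscape frame: lungs
        # occupy a modest share of the full frame
        for seed in range(5):
            frac = make_lung_mask(2560, 1440, seed).mean()
            assert 0.13 <= frac <= 0.22

    def test_bit_identical_per_seed(self):
        a = make_lung_mask(512, 512, seed=9)
        b = make_lung_mask(512, 512, seed=9)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, make_lung_mask(512, 512, seed=10))

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            make_lung_mask(63, 512, seed=0)


class TestLesionBox:
    def test_exact_size_centred_on_mask_pixel(self, small_mask):
        rng = np.random.default_rng(0)
        box = sample_lesion_box(small_mask, (20, 20), rng)
        assert box.width == 20 and box.height == 20
        cx, cy = box.center
        assert small_mask[int(cy), int(cx)]

    def test_centres_always_inside_mask(self, small_mask):
        rng = np.random.default_rng(1)
        for _ in range(1000):
            box = sample_lesion_box(small_mask, (10, 40), rng)
            cx, cy = box.center
            assert small_mask[int(cy), int(cx)]

    def test_empty_mask_raises(self):
        with pytest.raises(PlacementError):
            sample_lesion_box(np.zeros((100, 100), bool), (10, 10),
                              np.random.default_rng(0))


def tp_case_on(mask, rng, size=(25, 45)):
    box = sample_lesion_box(mask, size, rng)
    return CaseSpec("c0", True, Group.TP, lesion_box=box, displayed_box=box,
                    image_width=mask.shape[1], image_height=mask.shape[0])


PROFILE = ReaderProfile("A", 6.0, 0.8, 1.2, 2000.0, 0.55)
EFFECTS = ConditionEffects(1.5, 0.4, -0.4, 500.0, 6.0)


class TestScanpath:
    def test_zero_dropout_capture_ratio_exactly_one(self, small_mask, tp_case):
        rng = np.random.default_rng(2)
        rec, _ = simulate_scanpath(tp_case, WITHOUT_BB, PROFILE, EFFECTS, rng,
                                   mask=small_mask)
        assert capture_ratio(rec) == 1.0

    def test_fixed_duration_yields_rate_times_duration_samples(self, small_mask, tp_case):
        from gazecad.simulate import MetricDispersion

        prof = ReaderProfile("A", 10.0, 0.8, 1.2, 2000.0, 0.55)
        disp = MetricDispersion(sigma_time=0.0)
        rng = np.random.default_rng(3)
        rec, _ = simulate_scanpath(tp_case, WITHOUT_BB, prof, EFFECTS, rng,
                                   mask=small_mask, dispersion=disp)
        assert rec.n_samples == 600
        assert interpretation_time(rec) == pytest.approx(10.0)

    def test_samples_stay_inside_image(self, small_mask, tp_case):
        for seed in range(6):
            rng = np.random.default_rng(seed)
            cond = WITH_BB if seed % 2 else WITHOUT_BB
            rec, _ = simulate_scanpath(tp_case, cond, PROFILE, EFFECTS, rng,
                                       mask=small_mask)
            assert rec.x.min() >= 0 and rec.x.max() <= 639
            assert rec.y.min() >= 0 and rec.y.max() <= 479

    def test_metric_recovery_against_latent_targets(self, small_mask, tp_case):
        """Metrics recomputed from the emitted samples must land on the
        latent targets: duration exactly, dwell/TTFF within two sampling
        intervals, path and coverage within the generator's stated
        construction tolerances (10% of the path; 3 grid tiles or 0.06 of
        coverage, whichever is larger) on unflagged reads."""
        aoi = LesionAOI(tp_case.lesion_box, 50.0)
        n_tiles = len(lung_tiles(small_mask, cell=50))
        cov_tol = max(0.06, 3.0 / n_tiles)
        checked = 0
        for seed in range(12):
            rng = np.random.default_rng(100 + seed)
            cond = WITH_BB if seed % 2 else WITHOUT_BB
            rec, la = simulate_scanpath(tp_case, cond, PROFILE, EFFECTS, rng,
                                        mask=small_mask)
            assert interpretation_time(rec) == pytest.approx(la.duration_s)
            two_ticks = 2.0 / rec.sampling_rate
            assert dwell_time(rec, aoi) == pytest.approx(la.achieved_dwell_s, abs=two_ticks)
            assert time_to_first_fixation(rec, aoi) == pytest.approx(
                la.achieved_ttff_s, abs=two_ticks
            )
            assert path_length(rec) == pytest.approx(la.achieved_path_px, rel=1e-9)
            assert lung_coverage(rec, small_mask) == pytest.approx(
                la.achieved_coverage, abs=1e-12
            )
            if not la.flags:
                assert la.achieved_path_px == pytest.approx(la.path_px, rel=0.10)
                assert abs(la.achieved_coverage - la.coverage) <= cov_tol
                checked += 1
        assert checked >= 4

    def test_dropout_capture_expectation(self, small_mask, tp_case):
        prof = ReaderProfile("A", 4.0, 0.8, 1.2, 1500.0, 0.5,
                             dropout_rate=0.2, dropout_concentration=50.0)
        rng = np.random.default_rng(5)
        ratios = [
            capture_ratio(simulate_scanpath(tp_case, WITHOUT_BB, prof, EFFECTS,
                                            rng, mask=small_mask)[0])
            for _ in range(100)
        ]
        se = np.std(ratios, ddof=1) / 10
        assert abs(np.mean(ratios) - 0.8) < 3 * se

    def test_ttff_effect_propagates_to_measurements(self, small_mask):
        """Across replicate cases, the measured with-box vs without-box
        TTFF difference tracks the configured shift within Monte-Carlo
        error."""
        rng = np.random.default_rng(6)
        aoi_margin = 50.0
        diffs = []
        for _ in range(200):
            case = tp_case_on(small_mask, rng)
            aoi = LesionAOI(case.lesion_box, aoi_margin)
            out = {}
            for cond in (WITH_BB, WITHOUT_BB):
                rec, _ = simulate_scanpath(case, cond, PROFILE, EFFECTS, rng,
                                           mask=small_mask)
                out[cond] = time_to_first_fixation(rec, aoi)
            if out[WITH_BB] is not None and out[WITHOUT_BB] is not None:
                diffs.append(out[WITH_BB] - out[WITHOUT_BB])
        mean = np.mean(diffs)
        mc_se = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
        # truncation at the 0.05 s floor attenuates the shift slightly,
        # so allow the Monte-Carlo band plus a one-tick attenuation margin
        assert abs(mean - EFFECTS.delta_ttff_s) < 3 * mc_se + 0.05


class TestStudy:
    def test_read_count_and_conditions(self, tiny_config):
        bundle = simulate_study(tiny_config)
        assert len(bundle.reads) == 2 * 2 * tiny_config.design.n_total
        for read in bundle.reads:
            case = next(c for c in bundle.cases if c.case_id == read.case_id)
            expected = (
                WITH_BB if read.session == 1 and case.displayed_box is not None
                else WITHOUT_BB
            )
            assert read.condition == expected

    def test_case_boxes_respect_group_invariants(self, tiny_config):
        bundle = simulate_study(tiny_config)
        for case in bundle.cases:
            case.validate(aoi_margin=tiny_config.aoi_margin)

    def test_deterministic_per_seed(self, tiny_config):
        a = simulate_study(tiny_config)
        b = simulate_study(tiny_config)
        for ra, rb in zip(a.reads, b.reads):
            assert np.array_equal(ra.recording.x, rb.recording.x)
            assert np.array_equal(ra.recording.valid, rb.recording.valid)
            assert ra.decision == rb.decision
        assert a.latent_table.equals(b.latent_table)

    def test_different_seed_differs(self, tiny_config):
        from dataclasses import replace

        a = simulate_study(tiny_config)
        b = simulate_study(replace(tiny_config, seed=tiny_config.seed + 1))
        assert not a.latent_table.equals(b.latent_table)

    def test_zero_effects_give_null_condition_contrast(self, tiny_config):
        from dataclasses import replace
        from scipy import stats

        cfg = replace(tiny_config, effects=ConditionEffects(), seed=17)
        bundle = simulate_study(cfg)
        lat = bundle.latent_table
        tp = {c.case_id for c in bundle.cases if c.group is Group.TP}
        sub = lat[lat.case_id.isin(tp)]
        piv = sub.pivot_table(index=["reader", "case_id"], columns="session",
                              values="duration_s")
        _, p = stats.ttest_rel(piv[1], piv[2])
        assert p > 0.005


class TestMetricModel:
    def test_null_draws_have_no_session_shift(self):
        rng = np.random.default_rng(30)
        df = simulate_metric_values([PROFILE], ConditionEffects(), 400, rng)
        s1 = df[df.session == 1]["interpretation_time_s"]
        s2 = df[df.session == 2]["interpretation_time_s"]
        se = np.sqrt(s1.var() / len(s1) + s2.var() / len(s2))
        assert abs(s1.mean() - s2.mean()) < 3 * se

    def test_additive_shift_moves_the_mean(self):
        rng = np.random.default_rng(31)
        eff = ConditionEffects(delta_interpretation_time_s=2.0)
        df = simulate_metric_values([PROFILE], eff, 2000, rng)
        s1 = df[df.session == 1]["interpretation_time_s"]
        s2 = df[df.session == 2]["interpretation_time_s"]
        assert s1.mean() - s2.mean() == pytest.approx(2.0, abs=0.35)
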