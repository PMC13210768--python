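"""Detector: segmentation, morphometry, criteria, metrics, bookkeeping."""

import numpy as np
import pandas as pd
import pytest

from fibersense import detect, edf, synth
from fibersense.detect import ComponentMetrics, CountingCriteria, DetectorConfig, MatchResult
from fibersense.errors import InputError, ParameterError
from fibersense.synth import TruthLabel

from conftest import make_fiber, quiet_scene


def render_composite(scene, n_planes=9):
    stack = synth.render_zstack(scene, synth.StackSpec(n_planes=n_planes))
    return edf.focus_stack(stack)


def metrics(length, width, endpoints=2):
    return ComponentMetrics(length, width, length / width, endpoints)


class TestSegment:
    def test_blank_noiseless_image_has_no_components(self):
        comp = render_composite(quiet_scene(noise=False))
        labels = detect.segment(comp, DetectorConfig(pixel_size=0.5))
        assert labels.max() == 0

    def test_single_fiber_gives_one_component(self):
        comp = render_composite(quiet_scene([make_fiber(50, 40)]))
        labels = detect.segment(comp, DetectorConfig(pixel_size=0.5))
        assert labels.max() == 1

    def test_two_separated_fibers_give_two_components(self):
        scene = quiet_scene([make_fiber(25, 40), make_fiber(75, 40)])
        labels = detect.segment(render_composite(scene), DetectorConfig(pixel_size=0.5))
        assert labels.max() == 2


class TestMeasureComponent:
    def test_rectangle_bar_geometry(self):
        # 30 x 3 px bar at 0.33 µm/px: length ~9.9 µm, width ~1.0 µm (±1 px).
        mask = np.zeros((20, 40), bool)
        mask[8:11, 5:35] = True
        m = detect.measure_component(mask, 0.33)
        assert abs(m.skeleton_length - 9.9) <= 0.34
        assert abs(m.width - 1.0) <= 0.34
        assert m.n_skeleton_endpoints == 2

    def test_one_pixel_line(self):
        mask = np.zeros((11, 40), bool)
        mask[5, 5:35] = True
        m = detect.measure_component(mask, 0.33)
        assert abs(m.skeleton_length - 9.9) <= 0.34
        assert abs(m.width - 0.33) <= 0.34

    def test_square_blob_is_isotropic(self):
        mask = np.zeros((30, 30), bool)
        mask[5:25, 5:25] = True
        m = detect.measure_component(mask, 0.33)
        assert m.aspect_ratio < 3

    def test_x_cross_has_four_endpoints(self):
        from scipy import ndimage as ndi

        mask = np.zeros((41, 41), bool)
        for i in range(41):
            mask[i, i] = True
            mask[i, 40 - i] = True
        mask = ndi.binary_dilation(mask)
        m = detect.measure_component(mask, 0.33, spur_prune_um=2.0)
        assert m.n_skeleton_endpoints == 4

    def test_short_spurs_are_pruned(self):
        # A long bar with a 3-px side branch: pruning removes the branch.
        mask = np.zeros((21, 50), bool)
        mask[10, 5:45] = True
        mask[7:10, 20] = True
        pruned = detect.measure_component(mask, 0.33, spur_prune_um=2.0)
        kept = detect.measure_component(mask, 0.33, spur_prune_um=0.0)
        assert pruned.n_skeleton_endpoints == 2
        assert kept.n_skeleton_endpoints == 3

    def test_scale_covariance(self):
        """Doubling pixel_size doubles lengths/widths, fixes aspect ratio."""
        mask = np.zeros((20, 60), bool)
        mask[9:12, 5:55] = True
        m1 = detect.measure_component(mask, 0.33)
        m2 = detect.measure_component(mask, 0.66)
        assert m2.skeleton_length == pytest.approx(2 * m1.skeleton_length)
        assert m2.width == pytest.approx(2 * m1.width)
        assert m2.aspect_ratio == pytest.approx(m1.aspect_ratio)

    def test_empty_mask_rejected(self):
        with pytest.raises(InputError):
            detect.measure_component(np.zeros((5, 5), bool), 0.33)

    def test_aspect_ratio_consistency(self):
        mask = np.zeros((15, 40), bool)
        mask[7, 3:37] = True
        m = detect.measure_component(mask, 0.5)
        assert m.aspect_ratio == pytest.approx(m.skeleton_length / m.width, abs=1e-6)


class TestClassifyFiber:
    @pytest.mark.parametrize(
        "length,width,endpoints,status,reason",
        [
            (10.0, 1.0, 2, "countable", "none"),
            (4.0, 1.0, 2, "rejected", "too_short"),
            (12.0, 1.0, 4, "rejected", "aggregate"),
            (5.0, 1.0, 2, "rejected", "too_short"),  # exact boundary, strict
            (10.0, 3.0, 2, "rejected", "too_thick"),  # exact boundary, strict
            (9.0, 3.0, 2, "rejected", "too_thick"),
            (10.0, 4.0, 2, "rejected", "too_thick"),
            (4.0, 4.0, 5, "rejected", "too_short"),  # reason order: length first
        ],
    )
    def test_rule_order_and_boundaries(self, criteria, length, width, endpoints, status, reason):
        got = detect.classify_fiber(metrics(length, width, endpoints), criteria)
        assert got == (status, reason)

    def test_exact_aspect_ratio_boundary_rejected(self, criteria):
        m = ComponentMetrics(9.0, 3.0 - 1e-9, 3.0, 2)
        assert detect.classify_fiber(m, criteria) == ("rejected", "low_AR")

    def test_conjunction_over_grid(self, criteria):
        """Flipping any single criterion from pass to fail rejects the fiber."""
        passing = dict(length=10.0, width=1.0, endpoints=2)
        failing = dict(length=4.0, width=3.5, endpoints=4)
        assert detect.classify_fiber(metrics(**passing), criteria)[0] == "countable"
        for key in passing:
            kw = dict(passing, **{key: failing[key]})
            assert detect.classify_fiber(metrics(**kw), criteria)[0] == "rejected", key
        # Failing the aspect ratio alone (length and width both passing).
        low_ar = ComponentMetrics(6.0, 2.5, 2.4, 2)
        assert detect.classify_fiber(low_ar, criteria) == ("rejected", "low_AR")

    def test_aggregates_kept_when_rule_disabled(self):
        crit = CountingCriteria(exclude_aggregates=False)
        assert detect.classify_fiber(metrics(12.0, 1.0, 4), crit)[0] == "countable"


class TestConfidence:
    def test_strong_margins_saturate_to_one(self, criteria):
        c = detect.confidence_score(metrics(30.0, 0.5), criteria, contrast_snr=50.0)
        assert c > 0.98

    def test_length_factor_is_half_at_boundary(self, criteria):
        f = detect.confidence_factors(metrics(5.0, 0.5), criteria, contrast_snr=50.0)
        assert f["length"] == pytest.approx(0.5)

    def test_contrast_never_increases_confidence_when_decreasing(self, criteria):
        m = metrics(10.0, 1.0)
        grid = [detect.confidence_score(m, criteria, contrast_snr=s) for s in
                np.linspace(20.0, 0.0, 15)]
        assert all(a >= b for a, b in zip(grid, grid[1:]))


class TestDetectFibers:
    def test_blank_image_counts_zero(self):
        comp = render_composite(quiet_scene())
        dets, n = detect.detect_fibers(comp, DetectorConfig(pixel_size=0.5))
        assert n == 0

    def test_recovers_well_separated_fibers(self):
        fibers = [
            make_fiber(30, 25, orientation=0.3),
            make_fiber(90, 25, orientation=1.2),
            make_fiber(150, 25, orientation=2.0),
            make_fiber(60, 75, orientation=0.9),
            make_fiber(130, 75, orientation=2.7),
        ]
        scene = quiet_scene(fibers, field=(180.0, 100.0))
        dets, n = detect.detect_fibers(render_composite(scene), DetectorConfig(pixel_size=0.5))
        assert n == 5

    def test_confidence_threshold_one_counts_nothing(self):
        scene = quiet_scene([make_fiber(50, 40)])
        cfg = DetectorConfig(pixel_size=0.5, confidence_threshold=1.0)
        dets, n = detect.detect_fibers(render_composite(scene), cfg)
        assert n == 0
        assert any(d.reject_reason == "low_confidence" for d in dets)


class TestMatching:
    def fake_det(self, x, y, status="countable"):
        return detect.DetectedFiber(
            bbox=(int(x / 0.5) - 5, int(y / 0.5) - 5, int(x / 0.5) + 5, int(y / 0.5) + 5),
            centroid_um=(x, y), skeleton_length=10.0, width=1.0, aspect_ratio=10.0,
            confidence=0.9, status=status, reject_reason="none" if status == "countable" else "too_short",
        )

    def fake_truth(self, x, y, countable=True):
        return TruthLabel(make_fiber(x, y), countable, "none" if countable else "too_short")

    def test_perfect_detections(self):
        dets = [self.fake_det(10, 10), self.fake_det(40, 40)]
        truth = [self.fake_truth(10, 10), self.fake_truth(40, 40)]
        m = detect.match_detections(dets, truth, pixel_size=0.5)
        assert (m.tp, m.fp, m.fn) == (2, 0, 0)

    def test_one_truth_two_nearby_detections(self):
        dets = [self.fake_det(10, 10), self.fake_det(11, 10)]
        truth = [self.fake_truth(10, 10)]
        m = detect.match_detections(dets, truth, pixel_size=0.5)
        assert (m.tp, m.fp, m.fn) == (1, 1, 0)

    def test_missed_truths_are_fn(self):
        truth = [self.fake_truth(10, 10), self.fake_truth(40, 40), self.fake_truth(70, 70)]
        m = detect.match_detections([], truth)
        assert (m.tp, m.fp, m.fn) == (0, 0, 3)

    def test_uncovered_particles_are_tn(self):
        particles = [synth.ParticleTruth((60.0, 60.0), 0.5), synth.ParticleTruth((10.0, 10.0), 0.5)]
        dets = [self.fake_det(10, 10)]
        truth = [self.fake_truth(10, 10)]
        m = detect.match_detections(dets, truth, particles, pixel_size=0.5)
        assert m.tn == 1  # the particle at (60, 60); the one under the box is not


class TestDetectionMetrics:
    def test_simple_counts(self):
        dm = detect.detection_metrics(MatchResult(tp=1, fp=1, fn=0, tn=0))
        assert dm.precision == pytest.approx(0.5)
        assert dm.recall == pytest.approx(1.0)
        assert dm.f_score == pytest.approx(2 / 3)

    def test_degenerate_counts_are_absent_not_zero(self):
        dm = detect.detection_metrics(MatchResult(tp=0, fp=0, fn=0, tn=10))
        assert dm.accuracy == pytest.approx(1.0)
        assert dm.precision is None and dm.recall is None and dm.f_score is None

    def test_mixed_counts(self):
        dm = detect.detection_metrics(MatchResult(tp=9, fp=1, fn=1, tn=89))
        assert dm.accuracy == pytest.approx(0.98)
        assert dm.precision == pytest.approx(0.9)
        assert dm.recall == pytest.approx(0.9)
        assert dm.f_score == pytest.approx(0.9)


class TestBackgroundFlag:
    @pytest.mark.parametrize("count,flag", [(0, False), (80, False), (81, True), (200, True)])
    def test_threshold_is_strict(self, count, flag):
        assert detect.background_flag(count) is flag

    def test_negative_count_rejected(self):
        with pytest.raises(ParameterError):
            detect.background_flag(-1)


class TestDatasetBookkeeping:
    def test_per_split_averages(self):
        # Totals mirroring the annotated training corpus.
        rng = np.random.default_rng(0)

        def counts(total, n):
            base = np.full(n, total // n)
            base[: total % n] += 1
            return rng.permutation(base)

        df = pd.concat(
            [
                pd.DataFrame({"split": "train", "n_fibers": counts(6493, 994),
                              "n_particles": counts(85705, 994)}),
                pd.DataFrame({"split": "val", "n_fibers": counts(1341, 110),
                              "n_particles": counts(12396, 110)}),
            ]
        )
        out = detect.summarize_dataset(df)
        assert out.loc["train", "fibers_per_image"] == 6.5
        assert out.loc["train", "particles_per_image"] == 86.2
        assert out.loc["val", "fibers_per_image"] == 12.2
        assert out.loc["val", "particles_per_image"] == 112.7

    def test_zero_fiber_split(self):
        df = pd.DataFrame({"split": "test", "n_fibers": [0] * 19, "n_particles": [1] * 19})
        assert detect.summarize_dataset(df).loc["test", "fibers_per_image"] == 0.0

    def test_empty_table_rejected(self):
        with pytest.raises(InputError):
            detect.summarize_dataset(pd.DataFrame(columns=["split", "n_fibers", "n_particles"]))

    def test_split_fractions(self):
        sp = detect.split_dataset(1123, (994, 110, 19), seed=0)
        assert sp.fractions == (88.5, 9.8, 1.7)
        counts = np.bincount(sp.assignment, minlength=3)
        assert tuple(counts) == (994, 110, 19)

    def test_split_determinism_and_validation(self):
        a = detect.split_dataset(10, (7, 2, 1), seed=5)
        b = detect.split_dataset(10, (7, 2, 1), seed=5)
        np.testing.assert_array_equal(a.assignment, b.assignment)
        assert detect.split_dataset(10, (10, 0, 0), seed=1).fractions[0] == 100.0
        with pytest.raises(InputError):
            detect.split_dataset(10, (5, 4), seed=1)


class TestBackgroundEffect:
    def test_high_particle_load_raises_false_positives(self):
        """Fields above the 80-particle flag level yield at least as many
        spurious fiber detections as sparse fields, and some."""
        from conftest import recovery_params

        crit = CountingCriteria()
        cfg = DetectorConfig(pixel_size=0.66)

        import math

        def total_fp(expected_particles, seeds):
            fp = 0
            for s in seeds:
                params = recovery_params()
                params.expected_fibers = 0.0
                params.expected_particles = expected_particles
                # Coarser particles: contiguous clusters must be able to
                # reach fiber-like dimensions for misclassification to occur.
                params.particle_radius_log_mean = math.log(0.9)
                scene = synth.sample_scene(params, s)
                comp = render_composite(scene)
                dets, _ = detect.detect_fibers(comp, cfg, crit)
                labels = synth.true_countable_fibers(scene, crit)
                m = detect.match_detections(dets, labels, scene.particles, pixel_size=0.66)
                fp += m.fp
            return fp

        seeds = range(1, 7)
        fp_high = total_fp(150.0, seeds)
        fp_low = total_fp(30.0, seeds)
        assert fp_high > fp_low
        assert fp_high > 0
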