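import numpy as np
import pytest

from autobend import (BendingConfig, DIRECTIONS, JointFrame, LandmarkSet,
                      bend_direction, build_segment, eval_centrum_strain,
                      eval_intersection, eval_zyg_strain, run_all_directions)
from autobend.bending_engine import primary_label


def _x_translation(dx):
    m = np.eye(4)
    m[0, 3] = dx
    return m


class TestConfigValidation:
    def test_cap_must_be_multiple_of_increment(self):
        with pytest.raises(ValueError, match="multiple"):
            BendingConfig(increment=0.5, max_angle=45.3)

    def test_bounds_must_straddle_zero(self):
        with pytest.raises(ValueError):
            BendingConfig(zyg_bounds=(0.1, 0.5))

    def test_unknown_constraint_rejected(self):
        with pytest.raises(ValueError):
            BendingConfig(enabled=("intersection", "magic"))


class TestEvalIntersection:
    def test_neutral_pose_not_violated(self, cube_pair_segment):
        s = eval_intersection(cube_pair_segment, np.eye(4), 0.0)
        assert not s.violated
        assert s.measures["intersection_area"] == 0.0

    def test_coincident_cubes_threshold_zero(self, cube_pair_segment):
        # slide the posterior cube onto the anterior one
        s = eval_intersection(cube_pair_segment, _x_translation(-3.0), 0.0)
        assert s.violated and s.labels == {"intersection"}
        assert s.measures["intersection_area"] == pytest.approx(6.0)

    def test_threshold_arithmetic(self, cube_pair_segment):
        # overlap area 4 vs threshold 0.5 * mean_area 6 = 3 -> violated
        pose = _x_translation(-2.5)
        assert eval_intersection(cube_pair_segment, pose, 0.5).violated
        # threshold 0.7 * 6 = 4.2 > 4 -> allowed
        assert not eval_intersection(cube_pair_segment, pose, 0.7).violated


class TestEvalStrains:
    def test_zyg_disarticulation(self, cube_pair_segment):
        # facets overlap in x: pulling the posterior body caudally shrinks
        # the x-separation.  d0 = 2, d = 0.9 -> s = -0.55
        s = eval_zyg_strain(cube_pair_segment, _x_translation(1.1),
                            (-0.5, 0.5))
        assert s.labels == {"zyg-disarticulation"}
        assert s.measures["zyg_strain"] == pytest.approx(-0.55)

    def test_zyg_overlap(self, cube_pair_segment):
        # d0 = 2; d = 3.2 -> s = +0.60
        s = eval_zyg_strain(cube_pair_segment, _x_translation(-1.2),
                            (-0.5, 0.5))
        assert s.labels == {"zyg-overlap"}
        assert s.measures["zyg_strain"] == pytest.approx(0.60)

    def test_centrum_tension_and_tolerated_translation(self, cube_pair_segment):
        # +0.5 mm on a 2 mm gap: all strains +0.25, inside +-0.5
        s = eval_centrum_strain(cube_pair_segment, _x_translation(0.5),
                                (-0.5, 0.5))
        assert not s.violated
        assert all(v == pytest.approx(0.25) for v in s.measures.values())
        # +1.1 mm -> +0.55 -> tension
        s = eval_centrum_strain(cube_pair_segment, _x_translation(1.1),
                                (-0.5, 0.5))
        assert s.labels == {"centrum-tension"}

    def test_centrum_compression(self, cube_pair_segment):
        s = eval_centrum_strain(cube_pair_segment, _x_translation(-1.1),
                                (-0.5, 0.5))
        assert s.labels == {"centrum-compression"}


class TestBendDirection:
    def test_unconstrained_reaches_cap(self, cube_pair_segment):
        cfg = BendingConfig(enabled=())
        for direction in DIRECTIONS:
            r = bend_direction(cube_pair_segment, direction, cfg)
            assert r.stop_angle == 45.0
            assert r.constraint_labels == {"max-angle"}

    def test_invalid_direction(self, cube_pair_segment):
        with pytest.raises(ValueError, match="direction"):
            bend_direction(cube_pair_segment, "sideways", BendingConfig())

    def test_neutral_violation_reports_zero(self, unit_cube):
        a = unit_cube.copy()
        b = unit_cube.copy()
        b.apply_translation([0.5, 0, 0])  # overlapping at neutral
        lm = LandmarkSet({
            "ant_dorsal": (-0.4, 0.5, 0), "ant_ventral": (-0.4, -0.5, 0),
            "ant_left": (-0.4, 0, 0.5), "ant_right": (-0.4, 0, -0.5),
            "post_dorsal": (0.4, 0.5, 0), "post_ventral": (0.4, -0.5, 0),
            "post_left": (0.4, 0, 0.5), "post_right": (0.4, 0, -0.5),
            "zyg_post_caudal": (0.5, 0.5, 0.5),
            "zyg_pre_cranial": (-0.5, 0.5, 0.5)})
        seg = build_segment(a, b, JointFrame.standard(), lm)
        r = bend_direction(seg, "dorsiflexion",
                           BendingConfig(intersection_threshold=0.0,
                                         enabled=("intersection",)))
        assert r.stop_angle == 0.0
        assert r.constraint_labels == {"intersection"}

    def test_stop_angle_is_multiple_of_increment(self, block):
        segment, _ = block
        res = run_all_directions(segment, BendingConfig())
        for r in res.directions.values():
            k = r.stop_angle / 0.5
            assert abs(k - round(k)) < 1e-12

    def test_strains_at_stop_satisfy_bounds(self, block):
        segment, _ = block
        cfg = BendingConfig()
        for direction, (axis, sign) in DIRECTIONS.items():
            r = bend_direction(segment, direction, cfg)
            pose = segment.frame.rotation_matrix(axis, sign * r.stop_angle)
            zyg = eval_zyg_strain(segment, pose, cfg.zyg_bounds)
            cen = eval_centrum_strain(segment, pose, cfg.centrum_bounds)
            assert not zyg.violated and not cen.violated

    def test_determinism(self, block):
        segment, _ = block
        cfg = BendingConfig()
        a = run_all_directions(segment, cfg)
        b = run_all_directions(segment, cfg)
        assert a == b


class TestMonotonicity:
    """Widening any constraint never decreases the attainable angle."""

    def test_intersection_threshold(self, block):
        segment, _ = block
        lo = run_all_directions(segment, BendingConfig(
            intersection_threshold=0.0, enabled=("intersection",)))
        hi = run_all_directions(segment, BendingConfig(
            intersection_threshold=0.01, enabled=("intersection",)))
        for d in DIRECTIONS:
            assert hi[d].stop_angle >= lo[d].stop_angle

    @pytest.mark.parametrize("constraint,field", [
        ("zyg", "zyg_bounds"), ("centrum", "centrum_bounds")])
    def test_strain_bounds(self, block, constraint, field):
        segment, _ = block
        narrow = run_all_directions(segment, BendingConfig(
            enabled=(constraint,), **{field: (-0.3, 0.3)}))
        wide = run_all_directions(segment, BendingConfig(
            enabled=(constraint,), **{field: (-0.6, 0.6)}))
        for d in DIRECTIONS:
            assert wide[d].stop_angle >= narrow[d].stop_angle


class TestTranslationRelief:
    def test_relief_never_reduces_stop_angle(self, block):
        segment, _ = block
        base = BendingConfig(intersection_threshold=0.0,
                             enabled=("intersection",))
        for frac in (0.005, 0.01, 0.05):
            relief = BendingConfig(intersection_threshold=0.0,
                                   enabled=("intersection",),
                                   translation_fraction=frac)
            for d in DIRECTIONS:
                r0 = bend_direction(segment, d, base)
                r1 = bend_direction(segment, d, relief)
                assert r1.stop_angle >= r0.stop_angle
                assert r1.translation_used <= frac * segment.sqrt_area + 1e-12

    def test_budget_respected_with_small_steps(self, block):
        segment, _ = block
        cfg = BendingConfig(intersection_threshold=0.0,
                            enabled=("intersection",),
                            translation_fraction=0.05,
                            translation_step_fraction=0.01)
        for d in DIRECTIONS:
            r = bend_direction(segment, d, cfg)
            assert r.translation_used <= 0.05 * segment.sqrt_area + 1e-12


class TestLabels:
    def test_priority_resolution(self):
        labels = {"centrum-tension", "intersection", "zyg-overlap"}
        assert primary_label(labels) == "intersection"
        assert primary_label({"zyg-overlap", "centrum-tension"}) == "zyg-overlap"
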