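"""Asymmetry indicator formulas, threshold rules and kinematic features."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import strokesym as ss
from strokesym.indicators import (
    AgeNorms,
    AsymmetryIndicators,
    estimate_body_height,
    indicator_series,
    interpolate_low_confidence,
    lift_scale,
    segment_exceedances,
    ANTHROPOMETRIC_RATIOS,
)
from strokesym.keypoints import KeypointSequence
from strokesym.skeleton import KEYPOINT_INDEX


class TestScalarFormulas:
    @pytest.mark.parametrize(
        "right,left,expected",
        [(50.0, 31.7, 18.3), (10.0, 30.0, 20.0), (30.0, 10.0, 20.0), (42.0, 42.0, 0.0)],
    )
    def test_shoulder_rotation_difference(self, right, left, expected):
        assert ss.shoulder_rotation_difference(right, left) == pytest.approx(expected)

    def test_rotation_difference_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            ss.shoulder_rotation_difference(np.nan, 10.0)

    def test_shoulder_height_difference_scale_invariant(self):
        base = ss.shoulder_height_difference(106.0, 100.0, 100.0)
        assert base == pytest.approx(0.06)
        assert base > ss.Thresholds().shoulder_height
        for c in (0.1, 3.0, 250.0):
            assert ss.shoulder_height_difference(106 * c, 100 * c, 100 * c) == \
                pytest.approx(base)

    def test_shoulder_height_difference_requires_positive_height(self):
        with pytest.raises(ValueError):
            ss.shoulder_height_difference(1.0, 2.0, 0.0)

    @pytest.mark.parametrize(
        "pts,expected_angle,expected_b",
        [
            ([(-1, 2), (0, 2), (1, 2)], 0.0, 0.0),        # straight level spine
            ([(-1, 1), (0, 0), (1, -1)], 45.0, -1.0),     # pure lean, a = 0
            ([(-1, 0), (0, 1), (1, 0)], 0.0, 0.0),        # symmetric bow, vertex at 0
        ],
    )
    def test_spinal_lateral_flexion_closed_forms(self, pts, expected_angle, expected_b):
        angle, (a, b, c) = ss.spinal_lateral_flexion(*pts)
        assert angle == pytest.approx(expected_angle, abs=1e-10)
        assert b == pytest.approx(expected_b, abs=1e-10)

    def test_spinal_lateral_flexion_duplicate_abscissae(self):
        with pytest.raises(ValueError, match="degenerate"):
            ss.spinal_lateral_flexion((0, 1), (0, 2), (1, 3))

    @given(
        a=st.floats(-3, 3), b=st.floats(-3, 3), c=st.floats(-3, 3),
        x=st.tuples(st.floats(-5, 5), st.floats(-5, 5), st.floats(-5, 5)),
    )
    def test_vertex_identity_arctan_2a_xvertex_equals_arctan_minus_b(self, a, b, c, x):
        # Eq. identity: for y = ax^2 + bx + c, 2a * x_vertex = -b exactly
        xs = np.asarray(x)
        if len(np.unique(xs)) < 3 or abs(a) < 1e-6:
            return
        ys = a * xs**2 + b * xs + c
        angle, (fa, fb, _) = ss.spinal_lateral_flexion(*zip(xs, ys))
        x_vertex = -fb / (2 * fa)
        assert np.degrees(np.arctan(2 * fa * x_vertex)) == pytest.approx(angle, abs=1e-8)

    @pytest.mark.parametrize(
        "h_r,h_l,expected",
        [(1.0, 1.0, 0.0), (2.0, 1.0, 45.0)],
    )
    def test_pelvic_tilt_closed_forms(self, h_r, h_l, expected):
        gamma = ss.pelvic_tilt(h_r, h_l, (1.0, 0.0), (0.0, 0.0))
        assert gamma == pytest.approx(expected)

    def test_pelvic_tilt_boundary_at_five_degrees(self):
        # tan(5 deg) ~= 0.0875 of the hip separation
        gamma = ss.pelvic_tilt(np.tan(np.radians(5.0)), 0.0, (1.0, 0.0), (0.0, 0.0))
        assert gamma == pytest.approx(5.0, abs=1e-9)

    def test_pelvic_tilt_coincident_hips(self):
        with pytest.raises(ValueError, match="degenerate"):
            ss.pelvic_tilt(1.0, 0.0, (0.0, 0.0), (0.0, 0.0))

    def test_hip_flexion_difference_symmetry(self):
        assert ss.hip_flexion_difference(95, 95) == 0
        assert ss.hip_flexion_difference(100, 89) == pytest.approx(11.0)
        assert ss.hip_flexion_difference(89, 100) == pytest.approx(11.0)

    @pytest.mark.parametrize("angle", [0.0, 12.5, 30.0, 90.0])
    def test_trunk_rotation_recovers_constructed_angle(self, angle):
        hip = [(-1.0, 0.0), (1.0, 0.0)]
        r = np.radians(angle)
        sh = [(-np.cos(r), -np.sin(r)), (np.cos(r), np.sin(r))]
        assert ss.trunk_rotation_angle(sh, hip) == pytest.approx(angle, abs=1e-9)

    def test_trunk_rotation_degenerate_axis(self):
        with pytest.raises(ValueError, match="degenerate"):
            ss.trunk_rotation_angle([(0, 0), (0, 0)], [(0, 0), (1, 0)])


class TestAgeNormalize:
    def test_z_score_values(self):
        norms = AgeNorms({("delta_theta_shoulder", 14): (12.0, 4.0)})
        f = lambda v: ss.age_normalize(v, 14, "delta_theta_shoulder", norms)
        assert f(12.0) == 0.0
        assert f(16.0) == 1.0

    def test_missing_entry_and_zero_sigma_rejected(self):
        norms = AgeNorms({("alpha_spine", 13): (5.0, 0.0)})
        with pytest.raises(ValueError):
            ss.age_normalize(1.0, 13, "alpha_spine", norms)
        with pytest.raises(ValueError):
            ss.age_normalize(1.0, 12, "alpha_spine", norms)


class TestRuleLabels:
    def _ind(self, **kw):
        base = dict(delta_theta_shoulder=0, delta_h_shoulder=0, alpha_spine=0,
                    trunk_rotation=0, delta_theta_hip=0, gamma_pelvis=0)
        base.update(kw)
        return AsymmetryIndicators(**base)

    def test_all_zero_is_normal_and_low(self):
        ind = self._ind()
        assert ss.classify_asymmetry(ind) == ss.AsymmetryLabel.NORMAL
        assert ss.assign_risk_level(ind) == ss.RiskLevel.LOW

    def test_shoulder_rotation_just_over_threshold(self):
        ind = self._ind(delta_theta_shoulder=16.0)
        assert ss.classify_asymmetry(ind) == ss.AsymmetryLabel.SHOULDER
        assert ss.assign_risk_level(ind) == ss.RiskLevel.MEDIUM

    def test_trunk_label_from_spinal_flexion(self):
        ind = self._ind(alpha_spine=14.8)
        assert ss.classify_asymmetry(ind) == ss.AsymmetryLabel.TRUNK

    def test_negative_spine_and_pelvis_use_magnitudes(self):
        assert ss.classify_asymmetry(self._ind(alpha_spine=-14.8)) == \
            ss.AsymmetryLabel.TRUNK
        assert ss.classify_asymmetry(self._ind(gamma_pelvis=-6.0)) == \
            ss.AsymmetryLabel.HIP

    def test_multi_segment_tie_resolved_by_relative_excess(self):
        # hip exceeds by 50 % relative, shoulder by 10 % -> hip wins
        ind = self._ind(delta_theta_shoulder=16.5, delta_theta_hip=15.0)
        assert ss.classify_asymmetry(ind) == ss.AsymmetryLabel.HIP

    def test_compound_exceedance_is_high_risk(self):
        ind = self._ind(delta_theta_shoulder=21.0, alpha_spine=10.5)
        assert ss.assign_risk_level(ind) == ss.RiskLevel.HIGH

    def test_risk_is_monotone_in_exceeding_segments(self):
        lvl0 = ss.assign_risk_level(self._ind())
        lvl1 = ss.assign_risk_level(self._ind(delta_theta_shoulder=20.0))
        lvl2 = ss.assign_risk_level(
            self._ind(delta_theta_shoulder=20.0, gamma_pelvis=7.0))
        lvl3 = ss.assign_risk_level(
            self._ind(delta_theta_shoulder=20.0, gamma_pelvis=7.0, alpha_spine=12.0))
        assert int(lvl0) < int(lvl1) < int(lvl2) <= int(lvl3)

    @pytest.mark.parametrize(
        "field,thr_attr,column",
        [
            ("delta_theta_shoulder", "shoulder_rot", 0),
            ("delta_h_shoulder", "shoulder_height", 1),
            ("delta_theta_hip", "hip_flexion", 4),
            ("gamma_pelvis", "pelvic_tilt", 5),
        ],
    )
    def test_bisection_recovers_switching_point(self, field, thr_attr, column):
        thr = ss.Thresholds()
        target = getattr(thr, thr_attr)

        def fires(v: float) -> bool:
            return ss.classify_asymmetry(self._ind(**{field: v}), thr) != \
                ss.AsymmetryLabel.NORMAL

        lo, hi = 0.0, target * 3
        assert not fires(lo) and fires(hi)
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if fires(mid):
                hi = mid
            else:
                lo = mid
        assert hi == pytest.approx(target, abs=1e-9)
        # strict inequality: the threshold itself does not fire
        assert not fires(target)

    def test_adult_reference_thresholds_are_larger(self):
        thr = ss.Thresholds()
        adult = thr.adult_reference()
        assert adult.shoulder_rot == pytest.approx(thr.shoulder_rot / (1 - 0.125))
        assert adult.pelvic_tilt > thr.pelvic_tilt


class TestKinematicFeatures:
    def test_output_length_and_static_derivatives(self, clean_sample):
        seq = clean_sample.keypoints
        feats = ss.kinematic_features(seq, window=5)
        assert feats.shape == (seq.n_frames - 4, 12)
        static = KeypointSequence(
            coords=np.repeat(seq.coords[:1], 10, axis=0),
            frame_rate=seq.frame_rate,
            coordinate_mode="world3d",
            thoracic=np.repeat(seq.thoracic[:1], 10, axis=0),
        )
        f = ss.kinematic_features(static)
        assert np.allclose(f[:, 6:], 0.0)

    def test_linear_ramp_gives_constant_derivative(self):
        # pelvis height ramp -> gamma ramps; derivative column ~ slope
        t = 20
        base = ss.generate_stroke(
            ss.default_template("backhand_push", duration=t),
            ss.AsymmetryParams(), seed=0,
        ).keypoints
        coords = base.coords.copy()
        slope_per_frame = 0.001
        ramp = slope_per_frame * np.arange(t)
        coords[:, KEYPOINT_INDEX["right_hip"], 1] += ramp
        seq = KeypointSequence(coords=coords, frame_rate=base.frame_rate,
                               coordinate_mode="world3d", thoracic=base.thoracic)
        ind = indicator_series(seq, body_height=1.6)
        gamma = ind[:, 5]
        emp_slope = np.diff(gamma).mean() * seq.frame_rate
        feats = ss.kinematic_features(seq, body_height=1.6)
        # derivative column 11 = gamma rate (deg/s), central difference
        assert np.allclose(feats[:, 11], emp_slope, rtol=0.05)

    def test_window_longer_than_clip_rejected(self, clean_sample):
        with pytest.raises(ValueError):
            ss.kinematic_features(clean_sample.keypoints, window=100)


class TestMirrorAndScaleInvariance:
    def test_indicators_invariant_under_mirror(self, small_cohort):
        samples, _ = small_cohort
        for s in samples[:25]:
            i1 = indicator_series(s.keypoints, body_height=s.body_height)
            i2 = indicator_series(ss.mirror_keypoints(s.keypoints),
                                  body_height=s.body_height)
            assert np.allclose(np.abs(i1), np.abs(i2), atol=1e-9)

    def test_labels_invariant_under_mirror(self, small_cohort):
        samples, _ = small_cohort
        for s in samples[:25]:
            m = ss.mirror_keypoints(s.keypoints)
            lab_m, _ = ss.classify_sequence(m, body_height=s.body_height)
            lab_o, _ = ss.classify_sequence(s.keypoints, body_height=s.body_height)
            assert lab_m == lab_o
            risk_m, _ = ss.risk_level_sequence(m, body_height=s.body_height)
            risk_o, _ = ss.risk_level_sequence(s.keypoints, body_height=s.body_height)
            assert risk_m == risk_o

    def test_scale_invariant_indicators(self, clean_sample):
        seq = clean_sample.keypoints
        h = clean_sample.body_height
        i1 = indicator_series(seq, body_height=h)
        for c in (0.5, 7.0):
            scaled = KeypointSequence(
                coords=seq.coords * c, frame_rate=seq.frame_rate,
                coordinate_mode="world3d", thoracic=seq.thoracic * c,
            )
            i2 = indicator_series(scaled, body_height=h * c)
            # delta_h, alpha, trunk rotation, gamma are dimensionless/angular
            assert np.allclose(i1[:, [1, 2, 3, 5]], i2[:, [1, 2, 3, 5]], atol=1e-9)


class TestLifting:
    def _frontal_2d(self, t=8):
        """Frontal standing pose in pixels, proportions matching the ratio table."""
        h_px = 400.0
        y0 = 450.0
        coords = np.zeros((t, 17, 2))

        def put(name, x, y):
            coords[:, KEYPOINT_INDEX[name]] = [256 + x, y]

        hip_y = y0 - 0.53 * h_px
        sh_y = hip_y - ANTHROPOMETRIC_RATIOS["torso"] * h_px
        put("left_hip", -26, hip_y); put("right_hip", 26, hip_y)
        put("left_knee", -26, hip_y + ANTHROPOMETRIC_RATIOS["thigh"] * h_px)
        put("right_knee", 26, hip_y + ANTHROPOMETRIC_RATIOS["thigh"] * h_px)
        put("left_ankle", -26, hip_y + (ANTHROPOMETRIC_RATIOS["thigh"]
                                        + ANTHROPOMETRIC_RATIOS["shank"]) * h_px)
        put("right_ankle", 26, hip_y + (ANTHROPOMETRIC_RATIOS["thigh"]
                                        + ANTHROPOMETRIC_RATIOS["shank"]) * h_px)
        put("left_shoulder", -46, sh_y); put("right_shoulder", 46, sh_y)
        put("left_elbow", -50, sh_y + ANTHROPOMETRIC_RATIOS["upper_arm"] * h_px)
        put("right_elbow", 50, sh_y + ANTHROPOMETRIC_RATIOS["upper_arm"] * h_px)
        put("left_wrist", -52, sh_y + (ANTHROPOMETRIC_RATIOS["upper_arm"]
                                       + ANTHROPOMETRIC_RATIOS["forearm"]) * h_px)
        put("right_wrist", 52, sh_y + (ANTHROPOMETRIC_RATIOS["upper_arm"]
                                       + ANTHROPOMETRIC_RATIOS["forearm"]) * h_px)
        nose_y = y0 - 0.93 * h_px
        put("nose", 0, nose_y)
        put("left_eye", -8, nose_y - 4); put("right_eye", 8, nose_y - 4)
        put("left_ear", -16, nose_y); put("right_ear", 16, nose_y)
        return KeypointSequence(coords=coords, coordinate_mode="image2d",
                                frame_size=(512, 512))

    def test_frontal_pose_depths_on_reference_plane(self):
        seq = self._frontal_2d()
        lifted = ss.lift_to_3d(seq, body_height=1.6)
        z = lifted.coords[:, :, 2]
        hips = [KEYPOINT_INDEX["left_hip"], KEYPOINT_INDEX["right_hip"]]
        assert np.allclose(z[:, hips], 0.0, atol=1e-9)
        # near-exact proportions: every depth stays within 6 % of stature
        assert np.abs(z).max() < 0.06 * 1.6

    def test_reprojection_reproduces_input(self):
        seq = self._frontal_2d()
        lifted = ss.lift_to_3d(seq, body_height=1.6)
        s = lift_scale(seq, 1.6)
        assert np.allclose(lifted.coords[:, :, 0] / s, seq.coords[:, :, 0])
        assert np.allclose(-lifted.coords[:, :, 1] / s, seq.coords[:, :, 1])

    def test_forearm_length_close_to_anthropometric_ratio(self):
        seq = self._frontal_2d()
        lifted = ss.lift_to_3d(seq, body_height=1.6)
        seg = np.linalg.norm(
            lifted.coords[:, KEYPOINT_INDEX["right_wrist"]]
            - lifted.coords[:, KEYPOINT_INDEX["right_elbow"]],
            axis=-1,
        )
        expected = ANTHROPOMETRIC_RATIOS["forearm"] * 1.6
        assert np.all(np.abs(seg - expected) / expected < 0.05)

    def test_low_confidence_interpolation_and_missing_limit(self, clean_sample):
        seq = clean_sample.keypoints
        conf = seq.confidence.copy()
        conf[10:13, KEYPOINT_INDEX["left_wrist"]] = 0.0
        broken = KeypointSequence(coords=seq.coords.copy(), confidence=conf,
                                  frame_rate=seq.frame_rate,
                                  coordinate_mode="world3d")
        fixed = interpolate_low_confidence(broken)
        j = KEYPOINT_INDEX["left_wrist"]
        interp = np.array([np.interp(
            [10, 11, 12], [9, 13], [seq.coords[9, j, d], seq.coords[13, j, d]]
        ) for d in range(3)]).T
        assert np.allclose(fixed.coords[10:13, j], interp)
        conf[:, j] = 0.0
        with pytest.raises(ValueError, match="missing"):
            interpolate_low_confidence(
                KeypointSequence(coords=seq.coords.copy(), confidence=conf,
                                 frame_rate=seq.frame_rate,
                                 coordinate_mode="world3d")
            )

    def test_lift_requires_image_mode(self, clean_sample):
        with pytest.raises(ValueError, match="image2d"):
            ss.lift_to_3d(clean_sample.keypoints, body_height=1.6)


def test_segment_exceedances_shape_and_meaning():
    arr = np.array([[16.0, 0, 0, 0, 0, 0], [0, 0, 9.0, 0, 0, -6.0]])
    exc = segment_exceedances(arr)
    assert exc.shape == (2, 3)
    assert exc[0].tolist() == [True, False, False]
    assert exc[1].tolist() == [False, True, True]
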