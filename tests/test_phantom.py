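"""Phantom geometry, motion model and camera rendering."""

import math

import numpy as np
import pytest

from motiongate import phantom as ph


def one_ellipse_spec(intensity=1.0, label="abdomen"):
    seg = ph.Segment(label, (15.0, 15.0), (6.0, 4.0), intensity)
    return ph.PhantomSpec(
        segments=(seg,), pivot_mm=(15.0, 15.0), keypoint_mm=(21.0, 15.0)
    )


class TestBuildPhantom:
    def test_empty_segment_list_gives_zero_image(self):
        spec = ph.PhantomSpec(segments=(), pivot_mm=(15, 15), keypoint_mm=(15, 15))
        p = ph.build_phantom(spec, (32, 32), 30.0)
        assert np.all(p.image == 0)

    def test_large_ellipse_interior_equals_intensity(self):
        p = ph.build_phantom(one_ellipse_spec(1.0), (64, 64), 30.0)
        # pixels well inside the ellipse have full coverage
        cy, cx = 32, 32
        assert np.all(p.image[cy - 4 : cy + 4, cx - 4 : cx + 4] == 1.0)
        assert p.image.max() <= 1.0

    def test_superposition_of_disjoint_ellipses(self):
        a = ph.Segment("head", (8.0, 8.0), (3.0, 2.0), 0.7)
        b = ph.Segment("abdomen", (21.0, 21.0), (4.0, 3.0), 0.9)
        mk = lambda segs: ph.PhantomSpec(segs, (15, 15), (24.9, 21.0))
        both = ph.build_phantom(mk((a, b)), (64, 64), 30.0).image
        only_a = ph.build_phantom(mk((a,)), (64, 64), 30.0).image
        only_b = ph.build_phantom(mk((b,)), (64, 64), 30.0).image
        np.testing.assert_allclose(both, only_a + only_b, atol=1e-14)

    def test_linearity_in_intensity(self):
        img1 = ph.build_phantom(one_ellipse_spec(0.4), (48, 48), 30.0).image
        img2 = ph.build_phantom(one_ellipse_spec(0.8), (48, 48), 30.0).image
        np.testing.assert_allclose(img2, 2.0 * img1, atol=1e-14)

    def test_segment_outside_fov_raises_with_name(self):
        seg = ph.Segment("head", (28.0, 15.0), (5.0, 2.0), 0.5)
        spec = ph.PhantomSpec((seg,), (15, 15), (15, 15))
        with pytest.raises(ph.SegmentOutsideFOVError, match="head"):
            ph.build_phantom(spec, (32, 32), 30.0)

    def test_masks_partition_by_label(self, cam_phantom):
        labels = list(cam_phantom.masks)
        stack = np.stack([cam_phantom.masks[l] for l in labels])
        assert np.all(stack.sum(axis=0) <= 1)


class TestMotionModel:
    def test_zero_amplitude_is_identity_for_all_t(self):
        model = ph.MotionModel(
            angular_amplitude_deg=0.0, translation_amplitude_mm=(0.0, 0.0), rng_seed=3
        )
        sampler = ph.MotionSampler(model)
        for t in np.linspace(0, 10, 50):
            assert sampler(t).is_identity

    def test_dwell_window_is_rest_pose(self):
        model = ph.MotionModel(
            base_period_s=1.0, period_jitter_sd_s=0.0, dwell_fraction=0.4, rng_seed=0
        )
        sampler = ph.MotionSampler(model)
        for t in [0.0, 0.1, 0.39, 1.0, 1.2, 2.3999]:
            assert sampler(t).is_identity, t
        assert not sampler(0.7).is_identity

    def test_peak_angle_matches_reconstructed_jittered_cycles(self):
        """Re-generate the jittered cycle boundaries independently from the
        same seed and evaluate the waveform peak of an arbitrary cycle."""
        model = ph.MotionModel(
            angular_amplitude_deg=15.0,
            base_period_s=0.8,
            period_jitter_sd_s=0.1,
            dwell_fraction=0.3,
            rng_seed=77,
        )
        # independent oracle: same stream contract, coded from scratch
        rng = np.random.default_rng(77)
        edges = [0.0]
        while edges[-1] < 10.0:
            p = max(0.8 + rng.normal(0.0, 0.1), 0.08)
            edges.append(edges[-1] + p)
        k = 5
        period = edges[k + 1] - edges[k]
        t_peak = edges[k] + 0.3 * period + 0.5 * (period - 0.3 * period)
        tf = ph.eval_motion(model, t_peak)
        assert tf.rotation_rad == pytest.approx(math.radians(15.0), abs=1e-12)

    def test_determinism_across_samplers(self):
        model = ph.MotionModel(rng_seed=9)
        s1, s2 = ph.MotionSampler(model), ph.MotionSampler(model)
        ts = np.linspace(0, 20, 101)
        for t in ts:
            a, b = s1(t), s2(t)
            assert a.rotation_rad == b.rotation_rad
            assert a.translation_mm == b.translation_mm

    def test_dwell_fraction_conserved_over_many_cycles(self):
        model = ph.MotionModel(
            base_period_s=0.2, period_jitter_sd_s=0.02, dwell_fraction=0.4, rng_seed=5
        )
        sampler = ph.MotionSampler(model)
        ts = np.arange(0, 8.0, 1 / 60)  # ~40 cycles
        frac = np.mean([sampler(t).is_identity for t in ts])
        n = len(ts)
        sigma = math.sqrt(0.4 * 0.6 / n)
        assert abs(frac - 0.4) < 4 * sigma + 1 / (0.2 * 60)


class TestApplyTransform:
    def test_identity_leaves_point(self):
        p = ph.apply_transform(ph.RigidTransform2D(), (3.0, 4.0), (1.0, 1.0))
        np.testing.assert_allclose(p, (3.0, 4.0))

    def test_pivot_is_fixed_point_of_rotation(self):
        tf = ph.RigidTransform2D(rotation_rad=1.234)
        p = ph.apply_transform(tf, (2.0, 5.0), (2.0, 5.0))
        np.testing.assert_allclose(p, (2.0, 5.0), atol=1e-14)

    def test_quarter_turn_handedness(self):
        # positive angle takes +x toward +y
        tf = ph.RigidTransform2D(rotation_rad=math.pi / 2)
        p = ph.apply_transform(tf, (1.0, 0.0), (0.0, 0.0))
        np.testing.assert_allclose(p, (0.0, 1.0), atol=1e-15)

    def test_compose_with_inverse_is_identity(self):
        tf = ph.RigidTransform2D(0.7, (1.5, -0.8))
        pivot = np.array([2.0, 3.0])
        pts = np.random.default_rng(0).normal(size=(20, 2)) * 5
        back = ph.apply_transform(tf.inverse(), ph.apply_transform(tf, pts, pivot), pivot)
        np.testing.assert_allclose(back, pts, atol=1e-12)


class TestRenderFrame:
    def test_identity_noise_free_equals_static_render(self, cam_phantom, spec):
        frame, kp = ph.render_frame(cam_phantom, ph.RigidTransform2D(), 0.0)
        np.testing.assert_array_equal(frame.pixels, cam_phantom.image)
        np.testing.assert_allclose(kp, cam_phantom.mm_to_px(spec.keypoint_mm))

    def test_integer_pixel_translation_matches_array_shift(self, cam_phantom):
        pitch = cam_phantom.pitch_mm
        tf = ph.RigidTransform2D(0.0, (2 * pitch, 3 * pitch))  # +2 px x, +3 px y
        moved = cam_phantom.warp_moving(tf)
        expected = np.zeros_like(cam_phantom.moving_image)
        expected[3:, 2:] = cam_phantom.moving_image[:-3, :-2]
        np.testing.assert_allclose(moved, expected, atol=1e-12)

    def test_noise_is_seeded_and_reproducible(self, cam_phantom):
        f1, _ = ph.render_frame(
            cam_phantom, ph.RigidTransform2D(), 0.0, noise_sd=0.01,
            rng=np.random.default_rng(42),
        )
        f2, _ = ph.render_frame(
            cam_phantom, ph.RigidTransform2D(), 0.0, noise_sd=0.01,
            rng=np.random.default_rng(42),
        )
        np.testing.assert_array_equal(f1.pixels, f2.pixels)


class TestGenerateSequence:
    def test_frame_count_and_timestamps(self, cam_phantom):
        model = ph.MotionModel(angular_amplitude_deg=0, translation_amplitude_mm=(0, 0))
        frames, traj = ph.generate_sequence(model, cam_phantom, 30.0, 1.0)
        assert len(frames) == 31
        np.testing.assert_allclose([f.timestamp for f in frames], np.arange(31) / 30.0)
        assert len(traj) == 31

    def test_zero_amplitude_constant_ground_truth(self, cam_phantom):
        model = ph.MotionModel(angular_amplitude_deg=0, translation_amplitude_mm=(0, 0))
        _, traj = ph.generate_sequence(model, cam_phantom, 30.0, 0.5)
        assert np.ptp(traj.x) == 0 and np.ptp(traj.y) == 0

    def test_peak_excursion_matches_closed_form_rotation(self, cam_phantom, spec):
        """With no jitter, no dwell and no translation a frame lands exactly on
        the waveform peak; the keypoint's peak y matches the closed-form
        rotation of the keypoint about the pivot by the full amplitude."""
        amp = 18.0
        model = ph.MotionModel(
            angular_amplitude_deg=amp,
            base_period_s=1.0,
            period_jitter_sd_s=0.0,
            translation_amplitude_mm=(0.0, 0.0),
            dwell_fraction=0.0,
        )
        _, traj = ph.generate_sequence(model, cam_phantom, 30.0, 1.0)
        kp = np.asarray(spec.keypoint_mm) - np.asarray(spec.pivot_mm)
        a = math.radians(amp)
        peak_mm = np.array(
            [kp[0] * math.cos(a) - kp[1] * math.sin(a),
             kp[0] * math.sin(a) + kp[1] * math.cos(a)]
        ) + np.asarray(spec.pivot_mm)
        expected_peak_y_px = peak_mm[1] / cam_phantom.pitch_mm
        assert traj.y.max() == pytest.approx(expected_peak_y_px, abs=1e-9)

    def test_bit_identical_stacks_for_same_seed(self, cam_phantom):
        model = ph.MotionModel(rng_seed=4)
        f1, t1 = ph.generate_sequence(model, cam_phantom, 30.0, 0.5, 0.02, noise_seed=7)
        f2, t2 = ph.generate_sequence(model, cam_phantom, 30.0, 0.5, 0.02, noise_seed=7)
        for a, b in zip(f1, f2):
            np.testing.assert_array_equal(a.pixels, b.pixels)
        np.testing.assert_array_equal(t1.positions, t2.positions)


def test_ncc_relocation_recovers_ground_truth(cam_phantom):
    """Normalized cross-correlation of a rest-pose patch re-finds the keypoint
    within 0.5 px on noise-free translated frames."""
    from skimage.feature import match_template

    model = ph.MotionModel(
        angular_amplitude_deg=0.0,
        translation_amplitude_mm=(0.9, 0.5),
        base_period_s=1.0,
        period_jitter_sd_s=0.0,
        dwell_fraction=0.2,
    )
    frames, truth = ph.generate_sequence(model, cam_phantom, 30.0, 1.0)
    rest = frames[0].pixels
    kx, ky = truth.x[0], truth.y[0]
    h = 8
    patch = rest[int(ky) - h : int(ky) + h + 1, int(kx) - h : int(kx) + h + 1]
    def parabolic(v_m, v_0, v_p):
        denom = v_m - 2 * v_0 + v_p
        return 0.0 if denom == 0 else 0.5 * (v_m - v_p) / denom

    for i in [5, 10, 15, 20]:
        score = match_template(frames[i].pixels, patch, pad_input=True)
        py, px = np.unravel_index(np.argmax(score), score.shape)
        # quadratic sub-pixel refinement of the correlation peak
        dx = parabolic(score[py, px - 1], score[py, px], score[py, px + 1])
        dy = parabolic(score[py - 1, px], score[py, px], score[py + 1, px])
        found = np.array([px + dx + (kx - int(kx)), py + dy + (ky - int(ky))])
        err = np.linalg.norm(found - truth.positions[i])
        assert err <= 0.5 + 1e-9, (i, err)
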