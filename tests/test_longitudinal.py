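"""Longitudinal trajectories, drift estimation, and joint parameter recovery."""

import numpy as np
import pytest

from nloi import (
    CellSceneConfig,
    DecayModel,
    DegenerateInputError,
    NoiseModel,
    SegmentationMask,
    StsResponse,
    analyze_series,
    compare_timepoints,
    estimate_drift,
    generate_cell_scene,
    generate_time_series,
    intensity_trajectory,
    orr_trajectory,
)

DECAY_FRACTIONS = {"2PF": 0.25, "3PF": 0.60, "SHG": 0.30, "THG": 0.65}


@pytest.fixture(scope="module")
def base_scene():
    config = CellSceneConfig(
        image_size_px=(192, 192),
        orr_targets=(0.72, 0.86, 0.94),
        membrane_thg_level=0.8,
        seed=23,
    )
    frame, truth = generate_cell_scene(config)
    # structural SHG content so the default drift channel has features
    from nloi import FiberSceneConfig, generate_fiber_image

    shg, _ = generate_fiber_image(FiberSceneConfig(
        image_size_px=(192, 192), orientation="uniform", n_fibers=30, seed=23))
    frame.channels["SHG"] = shg
    return config, frame, truth


class TestIntensityTrajectory:
    def test_identical_frames_have_zero_change(self, base_scene):
        _, frame, _ = base_scene
        frames = []
        for t in (0.0, 10.0, 20.0):
            f = frame.copy()
            f.time_min = t
            frames.append(f)
        pct = intensity_trajectory(frames)
        np.testing.assert_allclose(pct.to_numpy(), 0.0, atol=1e-12)

    def test_noise_free_decay_recovered_exactly(self, base_scene):
        _, frame, truth = base_scene
        decay = DecayModel(decay_fractions=DECAY_FRACTIONS,
                           duration_min=62.0, n_frames=5)
        frames, _ = generate_time_series(frame, decay, seed=0,
                                         ground_truth=truth)
        final = intensity_trajectory(frames).iloc[-1]
        for chan, frac in DECAY_FRACTIONS.items():
            assert final[chan] == pytest.approx(-100.0 * frac, abs=1e-9)

    def test_noisy_decay_recovered_within_five_points(self, base_scene):
        _, frame, truth = base_scene
        decay = DecayModel(decay_fractions=DECAY_FRACTIONS,
                           duration_min=62.0, n_frames=5)
        frames, _ = generate_time_series(frame, decay,
                                         NoiseModel(photon_scale=40.0),
                                         seed=29, ground_truth=truth)
        final = intensity_trajectory(frames).iloc[-1]
        for chan, frac in DECAY_FRACTIONS.items():
            assert abs(final[chan] - (-100.0 * frac)) < 5.0

    def test_invariant_to_global_rescaling(self, base_scene):
        _, frame, truth = base_scene
        decay = DecayModel(decay_fractions=DECAY_FRACTIONS, duration_min=30.0,
                           n_frames=4)
        frames, _ = generate_time_series(frame, decay, seed=0)
        scaled = []
        for f in frames:
            g = f.copy()
            g.channels = {k: v * 11.0 for k, v in g.channels.items()}
            scaled.append(g)
        np.testing.assert_allclose(intensity_trajectory(scaled).to_numpy(),
                                   intensity_trajectory(frames).to_numpy(),
                                   atol=1e-9)

    def test_zero_initial_mean_warns_and_isolates_channel(self, base_scene):
        _, frame, _ = base_scene
        f0 = frame.copy()
        f0.channels["THG"] = np.zeros(frame.shape)
        f1 = f0.copy()
        f1.time_min = 10.0
        with pytest.warns(UserWarning):
            pct = intensity_trajectory([f0, f1])
        assert np.isnan(pct["THG"]).all()
        assert np.isfinite(pct["2PF"]).all()


class TestOrrTrajectory:
    def test_unequal_decay_drives_orr_up(self):
        # constant-ORR scene; 3PF fades faster than 2PF -> ORR must rise
        frame, _ = generate_cell_scene(CellSceneConfig(
            image_size_px=(160, 160), orr_targets=(0.8, 0.8, 0.8), seed=31))
        decay = DecayModel(decay_fractions={"2PF": 0.25, "3PF": 0.60},
                           duration_min=60.0, n_frames=6)
        frames, _ = generate_time_series(frame, decay, seed=0)
        means = [s.mean for s in orr_trajectory(frames)]
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_sts_profile_gives_down_then_up_orr(self):
        frame, _ = generate_cell_scene(CellSceneConfig(
            image_size_px=(160, 160), orr_targets=(0.86, 0.86), seed=37))
        decay = DecayModel(
            decay_fractions={"2PF": 0.25, "3PF": 0.60},
            duration_min=60.0, n_frames=13,
            sts_response=StsResponse(amplitude=1.2, rise_end_min=30.0))
        frames, gt = generate_time_series(frame, decay, seed=0)
        means = np.array([s.mean for s in orr_trajectory(frames)])
        k_min = int(np.argmin(means))
        programmed = int(np.argmin(np.abs(gt.times_min - 30.0)))
        assert abs(k_min - programmed) <= 1
        assert means[0] > means[k_min] < means[-1]

    def test_zero_decay_keeps_summaries_constant(self, base_scene):
        _, frame, _ = base_scene
        decay = DecayModel(decay_fractions={}, duration_min=10.0, n_frames=3)
        frames, _ = generate_time_series(frame, decay, seed=0)
        summaries = orr_trajectory(frames)
        for s in summaries[1:]:
            assert s.mean == pytest.approx(summaries[0].mean, abs=1e-12)
            assert s.iqr == pytest.approx(summaries[0].iqr, abs=1e-12)

    def test_masked_trajectory_uses_labeled_pixels_only(self, base_scene):
        _, frame, truth = base_scene
        decay = DecayModel(decay_fractions={"3PF": 0.5}, duration_min=10.0,
                           n_frames=3)
        frames, _ = generate_time_series(frame, decay, seed=0,
                                         ground_truth=truth)
        masks = [SegmentationMask(truth.label_mask, source="ground_truth")] * 3
        masked = orr_trajectory(frames, masks)
        n_fg = (truth.label_mask > 0).sum()
        assert all(s.n == n_fg for s in masked)

    def test_mask_count_mismatch_raises(self, base_scene):
        _, frame, truth = base_scene
        decay = DecayModel(decay_fractions={}, duration_min=10.0, n_frames=3)
        frames, _ = generate_time_series(frame, decay, seed=0)
        with pytest.raises(ValueError):
            orr_trajectory(frames, [SegmentationMask(truth.label_mask)] * 2)


class TestDriftEstimation:
    def test_self_drift_is_zero(self, base_scene):
        _, frame, _ = base_scene
        np.testing.assert_allclose(estimate_drift(frame, frame), 0.0,
                                   atol=1e-9)

    def test_imposed_shift_recovered(self, base_scene):
        # 42 px at 0.35 um/px -> 14.7 um, the "~15 um" drift scale
        _, frame, _ = base_scene
        from scipy import ndimage

        moved = frame.copy()
        moved.channels = {
            k: ndimage.shift(v, (0.0, 42.0), order=1, mode="constant")
            for k, v in frame.channels.items()
        }
        drift = estimate_drift(frame, moved)
        tol_um = 0.5 * frame.pixel_size_um
        assert abs(drift[0] - 14.7) < tol_um
        assert abs(drift[1]) < tol_um

    def test_antisymmetry(self, base_scene):
        _, frame, _ = base_scene
        from scipy import ndimage

        moved = frame.copy()
        moved.channels = {
            k: ndimage.shift(v, (5.0, -11.0), order=1, mode="constant")
            for k, v in frame.channels.items()
        }
        fwd = estimate_drift(frame, moved)
        back = estimate_drift(moved, frame)
        np.testing.assert_allclose(fwd, -back, atol=0.5 * frame.pixel_size_um)

    def test_noisy_shift_recovered_within_one_pixel(self, base_scene):
        _, frame, _ = base_scene
        from scipy import ndimage

        from nloi import apply_noise

        rng = np.random.default_rng(41)
        noise = NoiseModel(photon_scale=40.0)
        moved = frame.copy()
        moved.channels = {
            k: apply_noise(
                ndimage.shift(v, (7.0, 20.0), order=1, mode="constant"),
                noise, rng)
            for k, v in frame.channels.items()
        }
        drift = estimate_drift(frame, moved)
        expected = np.array([20.0, 7.0]) * frame.pixel_size_um
        assert np.all(np.abs(drift - expected) < frame.pixel_size_um)

    def test_featureless_channel_rejected(self):
        from nloi import MultimodalFrame

        flat = MultimodalFrame(channels={"SHG": np.ones((64, 64))},
                               pixel_size_um=0.35)
        with pytest.raises(DegenerateInputError):
            estimate_drift(flat, flat)


class TestJointRecovery:
    def test_decay_drift_and_sts_recovered_from_one_series(self, base_scene):
        """End-to-end: one generated dataset yields all imposed parameters."""
        _, frame, truth = base_scene
        decay = DecayModel(
            decay_fractions={"2PF": 0.25, "3PF": 0.60, "THG": 0.65},
            duration_min=60.0, n_frames=7,
            drift_um_total=(15.0, 0.0),
            sts_response=StsResponse(amplitude=1.2, rise_end_min=30.0))
        frames, gt = generate_time_series(frame, decay,
                                          NoiseModel(photon_scale=200.0),
                                          seed=43, ground_truth=truth)
        result = analyze_series(frames, drift_channel="SHG")

        # decay fractions, excluding the STS-modulated 3PF channel
        final = result.percent_change.iloc[-1]
        assert abs(final["2PF"] - (-25.0)) < 5.0
        assert abs(final["THG"] - (-65.0)) < 5.0

        # imposed drift, within half a pixel equivalent
        tol = 1.0 * frame.pixel_size_um
        assert abs(result.drift_um[-1][0] - 15.0) < tol
        assert abs(result.drift_um[-1][1]) < tol

        # STS turning point from the ORR trajectory
        means = np.array([s.mean for s in result.orr_summaries])
        k_min = int(np.argmin(means))
        programmed = int(np.argmin(np.abs(gt.times_min - 30.0)))
        assert abs(k_min - programmed) <= 1

    def test_comparisons_detect_orr_shift(self, base_scene):
        _, frame, truth = base_scene
        decay = DecayModel(decay_fractions={"3PF": 0.6}, duration_min=60.0,
                           n_frames=5)
        frames, _ = generate_time_series(frame, decay,
                                         NoiseModel(photon_scale=40.0),
                                         seed=47, ground_truth=truth)
        comps = compare_timepoints(frames)
        assert set(comps) == {(0, 2), (0, 4), (2, 4)}
        assert comps[(0, 4)].significant  # large imposed 3PF decay
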