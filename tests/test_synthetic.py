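"""Synthetic scene generators: ground-truth exactness and determinism."""

import numpy as np
import pytest

from nloi import (
    CellSceneConfig,
    DecayModel,
    FiberSceneConfig,
    NoiseModel,
    PlacementError,
    SceneConfigError,
    StsResponse,
    apply_noise,
    generate_cell_scene,
    generate_fiber_image,
    generate_time_series,
)
from nloi.synthetic import sts_factor


class TestFiberScenes:
    def test_fixed_model_records_constant_angles(self, fiber_scene_factory):
        _, truth, _ = fiber_scene_factory(orientation="fixed", theta0=30.0,
                                          n_fibers=50)
        assert np.all(truth.fiber_angles_deg == 30.0)

    def test_von_mises_circular_mean_near_mu(self, fiber_scene_factory):
        _, truth, _ = fiber_scene_factory(orientation="von_mises", theta0=45.0,
                                          kappa=8.0, n_fibers=500, seed=21)
        doubled = np.radians(2.0 * truth.fiber_angles_deg)
        mean_axial = np.degrees(
            np.angle(np.exp(1j * doubled).mean())) / 2.0 % 180.0
        # circular mean of the recorded sample within 2 degrees of mu
        assert min(abs(mean_axial - 45.0), 180 - abs(mean_axial - 45.0)) < 2.0

    def test_uniform_angles_pass_rayleigh_test(self, fiber_scene_factory):
        _, truth, _ = fiber_scene_factory(orientation="uniform", n_fibers=1000,
                                          seed=13)
        doubled = np.radians(2.0 * truth.fiber_angles_deg)
        n = doubled.size
        rbar = np.abs(np.exp(1j * doubled).mean())
        z = n * rbar**2
        p = np.exp(-z) * (1 + (2 * z - z**2) / (4 * n))  # Rayleigh approx
        assert p > 0.01  # fails to reject uniformity

    def test_raster_is_nonnegative_and_textured(self, fiber_scene_factory):
        img, _, _ = fiber_scene_factory()
        assert img.min() >= 0
        assert np.ptp(img) > 0

    def test_bit_reproducible_under_seed(self, fiber_scene_factory):
        a, ta, _ = fiber_scene_factory(orientation="uniform", seed=5)
        b, tb, _ = fiber_scene_factory(orientation="uniform", seed=5)
        np.testing.assert_array_equal(a, b)
        np.testing.assert_array_equal(ta.fiber_angles_deg, tb.fiber_angles_deg)

    def test_fiber_longer_than_diagonal_rejected(self):
        with pytest.raises(SceneConfigError):
            FiberSceneConfig(image_size_px=(64, 64), pixel_size_um=0.35,
                             fiber_length_um=1000.0)


class TestCellScenes:
    def test_half_orr_means_equal_channels(self):
        frame, truth = generate_cell_scene(
            CellSceneConfig(orr_targets=(0.5,), seed=1))
        interior = truth.label_mask == 1
        np.testing.assert_array_equal(frame.channel("2PF")[interior],
                                      frame.channel("3PF")[interior])

    def test_interior_pixels_carry_exact_orr(self, cell_scene):
        config, frame, truth = cell_scene
        pf2, pf3 = frame.channel("2PF"), frame.channel("3PF")
        for i, target in enumerate(config.orr_targets, start=1):
            sel = truth.label_mask == i
            orr = pf2[sel] / (pf2[sel] + pf3[sel])
            np.testing.assert_allclose(orr, target, rtol=0, atol=1e-12)

    def test_thg_confined_to_membranes_and_droplets(self, cell_scene):
        _, frame, truth = cell_scene
        thg = frame.channel("THG")
        assert not thg[truth.label_mask > 0].any()  # interiors are THG-dark
        assert thg.any()  # but membranes exist

    def test_empty_scene(self):
        frame, truth = generate_cell_scene(CellSceneConfig(orr_targets=()))
        assert truth.label_mask.max() == 0
        assert not frame.channel("2PF").any()

    def test_impossible_placement_raises(self):
        with pytest.raises(PlacementError):
            generate_cell_scene(CellSceneConfig(
                image_size_px=(64, 64), pixel_size_um=0.35,
                orr_targets=(0.5,) * 50, cell_radius_um=5.0))


class TestNoise:
    def test_poisson_mean_is_unbiased(self):
        model = NoiseModel(photon_scale=40.0, offset=0.1)
        out = apply_noise(np.ones((100, 100)), model, seed=2)
        se = np.sqrt(1.0 / 40.0 / out.size)  # Poisson var = mean/scale
        assert abs(out.mean() - 1.1) < 3 * se

    def test_high_photon_limit_approaches_input(self):
        rng = np.random.default_rng(4)
        raster = rng.uniform(0.5, 2.0, (50, 50))
        out = apply_noise(raster, NoiseModel(photon_scale=1e6), seed=3)
        assert np.max(np.abs(out - raster)) < 0.01

    def test_deterministic_under_seed(self):
        model = NoiseModel(photon_scale=40.0, read_noise_sd=0.05)
        raster = np.full((20, 20), 0.7)
        np.testing.assert_array_equal(apply_noise(raster, model, 9),
                                      apply_noise(raster, model, 9))

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            apply_noise(np.array([[-1.0]]), NoiseModel())

    def test_output_nonnegative(self):
        model = NoiseModel(photon_scale=40.0, read_noise_sd=0.5)
        out = apply_noise(np.full((50, 50), 0.01), model, seed=1)
        assert out.min() >= 0


class TestTimeSeries:
    def test_decay_endpoints_exact_noise_free(self, cell_scene):
        _, frame, truth = cell_scene
        decay = DecayModel(
            decay_fractions={"2PF": 0.25, "3PF": 0.60, "SHG": 0.30, "THG": 0.65},
            duration_min=62.0, n_frames=5)
        frames, gt = generate_time_series(frame, decay, seed=0,
                                          ground_truth=truth)
        first = gt.expected_channel_means.iloc[0]
        last = gt.expected_channel_means.iloc[-1]
        for chan, frac in decay.decay_fractions.items():
            if first[chan] > 0:
                assert last[chan] / first[chan] == pytest.approx(1 - frac,
                                                                 abs=1e-12)
                # expected means describe the actual rendered frames
                assert frames[-1].channel(chan).mean() == pytest.approx(
                    last[chan], abs=1e-12)

    def test_zero_decay_drift_noise_preserves_frames(self, cell_scene):
        _, frame, _ = cell_scene
        decay = DecayModel(decay_fractions={}, duration_min=10.0, n_frames=3)
        frames, _ = generate_time_series(frame, decay, seed=0)
        for f in frames:
            for name in frame.channel_names:
                np.testing.assert_array_equal(f.channel(name),
                                              frame.channel(name))

    def test_recorded_drift_matches_pixel_conversion(self, cell_scene):
        # 15 um over the series at 0.35 um/px -> 42.857 px cumulative in x
        _, frame, _ = cell_scene
        decay = DecayModel(decay_fractions={}, duration_min=10.0, n_frames=10,
                           drift_um_total=(15.0, 0.0))
        _, gt = generate_time_series(frame, decay, seed=0)
        assert gt.drift_um[-1][0] == pytest.approx(15.0)
        drift_px = gt.drift_um[-1][0] / frame.pixel_size_um
        assert drift_px == pytest.approx(15.0 / 0.35, abs=1e-9)

    def test_decay_trajectories_monotone_and_sts_unimodal(self, cell_scene):
        _, frame, _ = cell_scene
        decay = DecayModel(
            decay_fractions={"2PF": 0.25, "3PF": 0.60},
            duration_min=60.0, n_frames=13,
            sts_response=StsResponse(amplitude=1.0, rise_end_min=30.0))
        _, gt = generate_time_series(frame, decay, seed=0)
        means = gt.expected_channel_means
        diffs2 = np.diff(means["2PF"].to_numpy())
        assert np.all(diffs2 <= 1e-12)  # plain channels decay monotonically
        pf3 = means["3PF"].to_numpy()
        peak = int(np.argmax(pf3))
        assert np.all(np.diff(pf3[:peak + 1]) > 0)  # rises to the turn
        assert np.all(np.diff(pf3[peak:]) < 0)  # then falls
        turn_time = gt.times_min[peak]
        assert abs(turn_time - 30.0) <= 60.0 / 12 + 1e-9

    def test_out_of_frame_drift_rejected(self, cell_scene):
        _, frame, _ = cell_scene
        h, w = frame.shape
        decay = DecayModel(decay_fractions={}, duration_min=10.0, n_frames=3,
                           drift_um_total=(w * frame.pixel_size_um * 2, 0.0))
        with pytest.raises(SceneConfigError):
            generate_time_series(frame, decay)

    def test_series_bit_reproducible_with_noise(self, cell_scene):
        _, frame, _ = cell_scene
        decay = DecayModel(duration_min=20.0, n_frames=3)
        noise = NoiseModel(photon_scale=40.0)
        a, _ = generate_time_series(frame, decay, noise, seed=12)
        b, _ = generate_time_series(frame, decay, noise, seed=12)
        for fa, fb in zip(a, b):
            for name in fa.channel_names:
                np.testing.assert_array_equal(fa.channel(name),
                                              fb.channel(name))


def test_sts_factor_shape():
    sts = StsResponse(amplitude=0.8, rise_end_min=30.0)
    assert sts_factor(0.0, sts, 60.0) == 1.0
    assert sts_factor(30.0, sts, 60.0) == pytest.approx(1.8)
    assert sts_factor(60.0, sts, 60.0) == pytest.approx(1.0)
    assert sts_factor(15.0, sts, 60.0) == pytest.approx(1.4)
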