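"""Stimulus generators: determinism, quantization, spectra, rendering."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dsmotion import (
    GratingProtocol,
    MotionTrajectory,
    expected_speed_um_per_s,
    generate_pink_texture,
    generate_probe_stimuli,
    generate_smoothed_texture,
    generate_trajectory,
    render_moving_texture,
    texture_from_image,
)
from dsmotion.stimulus import (
    TextureOverflowError,
    quantize_steps,
    radial_amplitude_slope,
)


class TestTrajectory:
    def test_steps_are_quantized_to_pixel_raster(self):
        traj = generate_trajectory(3, 5000)
        ratio = traj.steps / 7.5
        assert np.allclose(ratio, np.round(ratio))

    def test_seed_reproducibility(self):
        a = generate_trajectory(5, 1000)
        b = generate_trajectory(5, 1000)
        assert np.array_equal(a.steps, b.steps)
        assert not np.array_equal(a.steps, generate_trajectory(6, 1000).steps)

    def test_rounded_step_sd_matches_analytic_inflation(self):
        """Rounding adds q^2/12 to the per-component step variance."""
        traj = generate_trajectory(8, 200000)
        expected = math.sqrt(22.5**2 + 7.5**2 / 12.0)
        for comp in range(2):
            assert traj.steps[:, comp].std() == pytest.approx(expected, rel=0.01)
        assert expected / 22.5 < 1.05  # spec'd inflation band

    def test_mean_speed_matches_rayleigh_oracle(self):
        traj = generate_trajectory(9, 90000)
        assert traj.mean_speed_um_per_s() == pytest.approx(
            expected_speed_um_per_s(), rel=0.02
        )

    def test_empty_trajectory(self):
        traj = generate_trajectory(1, 0)
        assert traj.n_frames == 0
        assert traj.mean_speed_um_per_s() == 0.0

    def test_invalid_step_sd(self):
        with pytest.raises(ValueError):
            generate_trajectory(1, 10, step_sd=0.0)

    def test_flip_preserves_step_magnitudes(self):
        traj = generate_trajectory(4, 500)
        flipped = traj.flipped()
        assert np.array_equal(np.abs(flipped.steps), np.abs(traj.steps))
        assert np.array_equal(flipped.steps, -traj.steps)

    @given(st.floats(-100, 100))
    @settings(max_examples=50, deadline=None)
    def test_quantization_rounds_half_away_from_zero(self, x):
        q = quantize_steps(np.array([x]), 7.5)[0]
        assert abs(q / 7.5 - round(q / 7.5)) < 1e-9
        assert abs(q - x) <= 3.75 + 1e-9


class TestTextures:
    def test_standard_texture_mean_and_determinism(self, standard_texture):
        tex = standard_texture
        assert tex.luminance.shape == (400, 400)
        assert abs(tex.mean - 0.5) < 0.01  # within 2% of target mean
        assert tex.luminance.min() >= 0.0 and tex.luminance.max() <= 1.0
        again = generate_smoothed_texture(7, (3000.0, 3000.0))
        assert np.array_equal(tex.luminance, again.luminance)

    def test_pink_texture_spectrum_slope(self, standard_texture):
        pink = generate_pink_texture(7, (3000.0, 3000.0), reference=standard_texture)
        assert radial_amplitude_slope(pink) == pytest.approx(-1.0, abs=0.1)

    def test_pink_texture_matches_reference_moments(self, standard_texture):
        pink = generate_pink_texture(7, (3000.0, 3000.0), reference=standard_texture)
        assert pink.mean == pytest.approx(standard_texture.mean, rel=0.02)
        assert pink.sd == pytest.approx(standard_texture.sd, rel=0.02)

    def test_extent_smaller_than_one_square_rejected(self):
        with pytest.raises(ValueError):
            generate_smoothed_texture(1, (20.0, 20.0))

    def test_image_texture_grayscale_conversion(self, standard_texture):
        rgb = np.random.default_rng(0).random((50, 50, 3))
        tex = texture_from_image(rgb, reference=standard_texture)
        assert tex.luminance.shape == (50, 50)
        assert tex.sd == pytest.approx(standard_texture.sd, rel=0.02)


class TestRendering:
    def test_zero_trajectory_gives_static_movie(self, standard_texture):
        traj = MotionTrajectory(np.zeros((5, 2)))
        movie = render_moving_texture(standard_texture, traj, window_um=(300, 300))
        assert movie.frames.shape == (6, 40, 40)
        for t in range(1, 6):
            assert np.array_equal(movie.frames[t], movie.frames[0])

    def test_single_step_shifts_one_pixel(self, standard_texture):
        traj = MotionTrajectory(np.array([[7.5, 0.0]]))
        movie = render_moving_texture(standard_texture, traj, window_um=(300, 300))
        # texture content moves right by one pixel
        assert np.array_equal(movie.frames[1][:, 1:], movie.frames[0][:, :-1])

    def test_flip_equals_negated_steps(self, standard_texture):
        traj = generate_trajectory(11, 50)
        a = render_moving_texture(standard_texture, traj.flipped(), window_um=(300, 300))
        b = render_moving_texture(
            standard_texture,
            MotionTrajectory(-traj.steps, traj.step_sd, traj.quantum),
            window_um=(300, 300),
        )
        assert np.array_equal(a.frames, b.frames)

    def test_overflow_names_the_frame(self, standard_texture):
        steps = np.full((100, 2), 75.0)  # runs off the texture quickly
        traj = MotionTrajectory(steps)
        with pytest.raises(TextureOverflowError) as exc:
            render_moving_texture(standard_texture, traj, window_um=(600, 600))
        assert exc.value.frame > 0


class TestProbeStimuli:
    def test_grating_schedule_duration(self):
        proto = GratingProtocol()
        movie, sched = generate_probe_stimuli(
            "grating", {"protocol": proto, "window_um": (150.0, 150.0)}, seed=1
        )
        gratings = [e for e in sched if e["event"] == "grating"]
        assert len(gratings) == 8 * 5
        total = max(e["t_end"] for e in sched)
        assert total == pytest.approx(8 * 5 * (6.67 + 1.67), rel=1e-3)
        dirs = sorted({e["direction_deg"] for e in gratings})
        assert np.allclose(np.diff(dirs), 45.0)

    def test_checkerboard_long_run_mean(self):
        movie, _ = generate_probe_stimuli(
            "checkerboard", {"n_squares_x": 8, "n_squares_y": 6, "n_frames": 4000},
            seed=2,
        )
        assert movie.pitch_um == 75.0
        assert movie.frames.mean() == pytest.approx(0.5, abs=0.02)
        assert set(np.unique(movie.frames)) == {0.0, 1.0}

    def test_flash_schedule_windows(self):
        movie, sched = generate_probe_stimuli("flash", {"n_cycles": 2}, seed=3)
        ons = [e for e in sched if e["event"] == "flash_on"]
        offs = [e for e in sched if e["event"] == "flash_off"]
        assert len(ons) == len(offs) == 2
        assert ons[0]["t_end"] - ons[0]["t_start"] == pytest.approx(0.5, abs=0.04)
        assert movie.frames.max() == pytest.approx(0.7)
        assert movie.frames.min() == pytest.approx(0.3)

    def test_flicker_moments(self):
        movie, _ = generate_probe_stimuli("flicker", {"n_frames": 30000}, seed=4)
        vals = movie.frames[:, 0, 0]
        assert vals.mean() == pytest.approx(0.5, abs=0.01)
        assert vals.std() == pytest.approx(0.15, abs=0.01)

    def test_omsi_coherent_vs_differential_patch_correlation(self):
        movie, sched = generate_probe_stimuli(
            "omsi_patches",
            {"window_um": (900.0, 900.0), "segment_s": 6.0, "repeats": 1},
            seed=5,
        )
        coh = next(e for e in sched if e["event"] == "coherent")["offsets_um"]
        dif = next(e for e in sched if e["event"] == "differential")["offsets_um"]

        def cross_patch_step_corr(offsets):
            steps = np.diff(offsets, axis=1)
            return np.corrcoef(steps[0], steps[1])[0, 1]

        assert cross_patch_step_corr(coh) == pytest.approx(1.0)
        assert abs(cross_patch_step_corr(dif)) < 0.2
        # jitter steps are +-15 um
        assert set(np.unique(np.diff(dif, axis=1))) <= {-30.0, 0.0, 30.0, -15.0, 15.0}

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            generate_probe_stimuli("sparkle", {}, seed=1)
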