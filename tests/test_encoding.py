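"""Motion STA, shuffle significance, LN nonlinearity, STC, texture STAs."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dsmotion import (
    MotionLNModel,
    build_population,
    compute_motion_sta,
    compute_stc,
    conditional_texture_sta,
    estimate_nonlinearity,
    fit_parametric_nonlinearity,
    generate_smoothed_texture,
    generate_trajectory,
    ln_drive,
    render_moving_texture,
    segment_stimulus,
    simulate_motion_ln_cell,
    simulate_texture_cell,
    sta_significance,
)
from dsmotion.cells import ParametricNonlinearity
from dsmotion.encoding import (
    BinnedNonlinearity,
    _equal_count_partition,
    subspace_angle_deg,
)
from dsmotion.rng import stream


class TestMotionSTA:
    def test_single_spike_recovers_its_window(self):
        traj = generate_trajectory(1, 100)
        counts = np.zeros(100)
        counts[60] = 1  # window is steps 36..59
        seg = segment_stimulus(traj.steps, counts)
        sta = compute_motion_sta(seg)
        expected = np.concatenate([traj.steps[36:60, 0], traj.steps[36:60, 1]])
        assert np.allclose(sta.a, expected)

    def test_sta_invariant_under_count_scaling(self):
        traj = generate_trajectory(2, 2000)
        counts = stream(3, "spikes").poisson(0.2, 2000).astype(float)
        a1 = compute_motion_sta(segment_stimulus(traj.steps, counts)).a
        a3 = compute_motion_sta(segment_stimulus(traj.steps, 3 * counts)).a
        assert np.allclose(a1, a3)

    def test_zero_spikes_rejected(self):
        traj = generate_trajectory(2, 200)
        with pytest.raises(ValueError):
            compute_motion_sta(segment_stimulus(traj.steps, np.zeros(200)))

    def test_sta_magnitude_shrinks_with_spikes_for_null_cell(self):
        traj = generate_trajectory(4, 50000)
        rng = stream(5, "spikes")
        mags = []
        for rate in (0.05, 0.5):
            counts = rng.poisson(rate, 50000).astype(float)
            mags.append(compute_motion_sta(segment_stimulus(traj.steps, counts)).magnitude)
        assert mags[1] < mags[0]

    def test_model_cell_angle_recovery(self, trajectory_10min, exponential_cell,
                                       exponential_counts):
        seg = segment_stimulus(trajectory_10min.steps, exponential_counts)
        sta = compute_motion_sta(seg)
        err = abs(
            (sta.preferred_angle_deg - exponential_cell.preferred_direction_deg + 180)
            % 360 - 180
        )
        assert err < 15.0


class TestShuffleSignificance:
    def test_driven_cell_significant(self, trajectory_10min, exponential_counts):
        seg = segment_stimulus(trajectory_10min.steps, exponential_counts)
        sig, null = sta_significance(seg, n_shuffles=300, seed=1)
        assert sig
        assert null.shape == (300,)

    def test_reproducible_under_fixed_seed(self, trajectory_short):
        counts = stream(7, "spikes").poisson(0.15, 3000).astype(float)
        seg = segment_stimulus(trajectory_short.steps, counts)
        _, null_a = sta_significance(seg, n_shuffles=200, seed=9)
        _, null_b = sta_significance(seg, n_shuffles=200, seed=9)
        assert np.array_equal(null_a, null_b)

    def test_type_one_error_calibrated(self):
        """Null (stimulus-independent) cells are flagged at ~5%."""
        hits = 0
        n_runs = 60
        for r in range(n_runs):
            rng = stream(800, "experiment", r)
            traj = generate_trajectory(int(rng.integers(2**31)), 3000)
            counts = rng.poisson(4 / 30, 3000).astype(float)
            seg = segment_stimulus(traj.steps, counts)
            sig, _ = sta_significance(
                seg, n_shuffles=300, seed=int(rng.integers(2**31))
            )
            hits += sig
        assert 0.0 <= hits / n_runs <= 0.15

    def test_short_recording_rejected(self):
        traj = generate_trajectory(1, 100)
        counts = np.ones(100)
        with pytest.raises(ValueError):
            sta_significance(segment_stimulus(traj.steps, counts), 100, seed=0)


class TestNonlinearity:
    def test_equal_count_bins_differ_by_at_most_one(self):
        for n, b in [(1000, 15), (1003, 15), (47, 15)]:
            sizes = [len(g) for g in _equal_count_partition(n, b)]
            assert sum(sizes) == n
            assert max(sizes) - min(sizes) <= 1

    def test_ushape_index_formula(self):
        """N(gmin)=10, N(0)=1, N(gmax)=10 gives U = 0.9."""
        rates = np.array([10, 5, 3, 2, 1.5, 1.2, 1.1, 1.0, 1.1, 1.2, 1.5, 2, 3, 5, 10])
        nl = BinnedNonlinearity(np.linspace(-2, 2, 15), rates, np.full(15, 10))
        assert nl.ushape_index == pytest.approx(0.9)

    def test_flat_left_tail_gives_zero_index(self):
        rates = np.array([1.0] * 8 + [2, 3, 4, 5, 6, 7, 8.0])
        nl = BinnedNonlinearity(np.linspace(-2, 2, 15), rates, np.full(15, 10))
        assert nl.ushape_index == pytest.approx(0.0)

    def test_monotone_cell_negative_index(self, trajectory_10min, exponential_counts):
        seg = segment_stimulus(trajectory_10min.steps, exponential_counts)
        sta = compute_motion_sta(seg)
        g = ln_drive(seg, sta.a)
        nl = estimate_nonlinearity(g, seg.f)
        assert nl.ushape_index < 0

    def test_ushape_cell_positive_index(self, ushape_cell, trajectory_10min):
        counts = simulate_motion_ln_cell(ushape_cell, trajectory_10min, 13).counts[0, 0]
        seg = segment_stimulus(trajectory_10min.steps, counts)
        res = MotionLNModel(trajectory_10min, counts).fit(n_shuffles=0)
        assert res.ushape_index > 0

    def test_too_many_bins_rejected(self):
        with pytest.raises(ValueError):
            estimate_nonlinearity(np.arange(10.0), np.arange(10.0), n_bins=15)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=10, deadline=None)
    def test_binning_is_equal_count_for_random_drives(self, seed):
        rng = np.random.default_rng(seed)
        g = rng.standard_normal(500)
        f = rng.poisson(0.2, 500)
        nl = estimate_nonlinearity(g, f)
        assert nl.bin_counts.max() - nl.bin_counts.min() <= 1


class TestParametricFits:
    def test_exponential_self_consistency(self):
        x = np.linspace(-2, 2, 15)
        truth = ParametricNonlinearity("exponential", A=2.0, B=1.5)
        fit = fit_parametric_nonlinearity(
            BinnedNonlinearity(x, truth(x), np.full(15, 100)), "exponential"
        )
        assert fit.A == pytest.approx(2.0, rel=0.05)
        assert fit.B == pytest.approx(1.5, rel=0.05)

    def test_ushape_self_consistency(self):
        x = np.linspace(-2.2, 2.2, 15)
        truth = ParametricNonlinearity("ushape", A=3.0, B=0.0, C=1.0)
        fit = fit_parametric_nonlinearity(
            BinnedNonlinearity(x, truth(x), np.full(15, 100)), "ushape"
        )
        assert fit.C == pytest.approx(1.0, rel=0.2)
        assert fit.A == pytest.approx(3.0, rel=0.2)

    def test_all_zero_rates_rejected(self):
        with pytest.raises(ValueError):
            fit_parametric_nonlinearity(
                BinnedNonlinearity(np.linspace(-1, 1, 15), np.zeros(15),
                                   np.full(15, 5)),
                "exponential",
            )


class TestSTC:
    def test_matrix_symmetric_with_real_spectrum(self, trajectory_10min,
                                                 exponential_counts):
        seg = segment_stimulus(trajectory_10min.steps, exponential_counts)
        stc = compute_stc(seg)
        assert np.allclose(stc.stc_matrix, stc.stc_matrix.T)
        assert np.all(np.isreal(stc.eigenvalues))
        assert np.all(np.diff(stc.eigenvalues) <= 1e-12)

    def test_two_filter_cell_subspace_recovery(self):
        traj = generate_trajectory(23, 54000)
        cell = build_population(1, nonlinearity_kind="ushape", two_component=True)[0]
        counts = simulate_motion_ln_cell(cell, traj, 3).counts[0, 0]
        stc = compute_stc(segment_stimulus(traj.steps, counts))
        true_basis = []
        for c in range(2):
            th = math.radians(cell.filter_directions_deg[c])
            true_basis.append(
                np.concatenate(
                    [cell.filters[c] * math.cos(th), cell.filters[c] * math.sin(th)]
                )
            )
        assert subspace_angle_deg(true_basis, [stc.e1, stc.e2]) < 10.0

    def test_ushape_cell_top_eigenvector_matches_filter_axis(self, ushape_cell,
                                                             trajectory_10min):
        """A variance-raising (U-shaped) nonlinearity concentrates the STC
        excess along the cell's filter axis."""
        counts = simulate_motion_ln_cell(ushape_cell, trajectory_10min, 17).counts[0, 0]
        seg = segment_stimulus(trajectory_10min.steps, counts)
        stc = compute_stc(seg)
        th = math.radians(ushape_cell.preferred_direction_deg)
        true = np.concatenate(
            [ushape_cell.filters[0] * math.cos(th),
             ushape_cell.filters[0] * math.sin(th)]
        )
        cosine = abs(np.dot(stc.e1, true))
        assert cosine > 0.9

    def test_null_cell_spectrum_flat(self, trajectory_10min):
        counts = stream(18, "spikes").poisson(0.4, 18000).astype(float)
        stc = compute_stc(segment_stimulus(trajectory_10min.steps, counts))
        # stimulus-independent spikes: spectrum confined to the
        # finite-sample (Marchenko-Pastur) band around 1, no outliers
        n_spk = counts.sum()
        edge = (1 + math.sqrt(48 / n_spk)) ** 2
        assert stc.eigenvalues[0] < 1.2 * edge
        assert stc.eigenvalues[-1] > 0.8 / edge

    def test_zero_spikes_rejected(self, trajectory_short):
        with pytest.raises(ValueError):
            compute_stc(segment_stimulus(trajectory_short.steps, np.zeros(3000)))


class TestConditionalTextureSTA:
    @pytest.fixture(scope="class")
    def texture_movie_and_counts(self):
        tex = generate_smoothed_texture(31, (7500.0, 7500.0))
        traj = generate_trajectory(32, 2500)
        movie = render_moving_texture(tex, traj, window_um=(600.0, 600.0))
        sts = simulate_texture_cell(movie, (300.0, 300.0), 0.0, seed=33)
        counts = sts.counts[0, 0]
        seg = segment_stimulus(traj.steps, counts[: traj.n_frames])
        sta = compute_motion_sta(seg)
        g = np.zeros(traj.n_frames)
        g[seg.L :] = ln_drive(seg, sta.a)
        return movie, counts, g

    def test_off_cell_preferred_condition_dark_biased(self, texture_movie_and_counts):
        movie, counts, g = texture_movie_and_counts
        ct = conditional_texture_sta(movie, counts, g, "preferred")
        assert ct.contrast_bias < 0  # dark-dominated: OFF-type encoder

    def test_random_spikes_fail_inclusion(self, texture_movie_and_counts):
        movie, counts, g = texture_movie_and_counts
        rng = stream(34, "spikes")
        rand_counts = rng.poisson(0.2, counts.shape[0]).astype(float)
        ct = conditional_texture_sta(movie, rand_counts, g, "preferred")
        assert not ct.included
        # mean-corrected frame has little structure relative to raw scale
        assert np.abs(ct.spatial_frame).max() < 4 * ct.pixel_sd

    def test_conditions_partition_drive_range(self, texture_movie_and_counts):
        movie, counts, g = texture_movie_and_counts
        pref = conditional_texture_sta(movie, counts, g, "preferred")
        nonpref = conditional_texture_sta(movie, counts, g, "nonpreferred")
        lag = 6  # 200 ms at 30 Hz
        n = g.size
        eligible = counts[lag:n]
        mid = eligible[np.abs(g[lag:]) <= 0.5].sum()
        # no spike with |g| <= 0.5 contributes to either condition
        assert pref.n_spikes + nonpref.n_spikes + mid == eligible.sum()

    def test_empty_condition_rejected(self, texture_movie_and_counts):
        movie, counts, g = texture_movie_and_counts
        with pytest.raises(ValueError):
            conditional_texture_sta(movie, counts, np.zeros_like(g), "preferred")


class TestModelResults:
    def test_summary_reports_key_quantities(self, trajectory_10min,
                                            exponential_counts):
        res = MotionLNModel(trajectory_10min, exponential_counts).fit(
            n_shuffles=200, seed=2, compute_covariance=True
        )
        text = res.summary()
        assert "preferred direction" in text
        assert "U-shape index" in text
        assert res.sta.significant
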