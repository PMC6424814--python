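"""Optimal linear decoder: design, fitting, reconstruction, reduced codes."""

import math

import numpy as np
import pytest

from dsmotion import (
    LinearMotionDecoder,
    build_design,
    build_population,
    compute_motion_sta,
    fit_decoder,
    generate_trajectory,
    reconstruct,
    reduce_pair,
    segment_stimulus,
    select_opponent_axis,
    simulate_motion_ln_cell,
    simulate_population,
)
from dsmotion.rng import stream


class TestDesign:
    def test_column_counts(self):
        traj = generate_trajectory(1, 500)
        one = build_design(np.zeros((1, 500)), traj.steps)
        assert one.F.shape[1] == 25  # 1 + L
        twenty = build_design(np.zeros((20, 500)), traj.steps)
        assert twenty.F.shape[1] == 481  # 1 + 20*24

    def test_leading_column_is_ones(self):
        traj = generate_trajectory(2, 300)
        d = build_design(np.ones((2, 300)), traj.steps)
        assert np.all(d.F[:, 0] == 1.0)

    def test_chronological_split_no_leakage(self):
        traj = generate_trajectory(3, 1000)
        d = build_design(np.zeros((1, 1000)), traj.steps)
        boundary = int(0.7 * 1000)
        # every training window ends before the boundary
        assert np.all(d.train_idx + d.L - 1 < boundary)
        # every test target is at or after the boundary
        assert np.all(d.test_idx >= boundary)
        assert len(set(d.train_idx) & set(d.test_idx)) == 0

    def test_misaligned_lengths_rejected(self):
        traj = generate_trajectory(4, 300)
        with pytest.raises(ValueError):
            build_design(np.zeros((1, 299)), traj.steps)


class TestFitting:
    def test_noiseless_single_tap_cell_recovers_delta_filter(self):
        """A cell whose count equals the current step decodes perfectly."""
        traj = generate_trajectory(5, 4000)
        counts = traj.steps[:, 0][None, :]  # direct linear readout of dx
        d = build_design(counts, traj.steps[:, 0])
        filt = fit_decoder(d)
        taps = filt.cell_filter(0, 0)
        assert taps[0] == pytest.approx(1.0, abs=1e-8)
        assert np.allclose(taps[1:], 0.0, atol=1e-8)
        rec = reconstruct(d, filt)
        assert rec.correlation(0) > 0.99

    def test_all_zero_counts_offset_only(self):
        traj = generate_trajectory(6, 2000)
        d = build_design(np.zeros((1, 2000)), traj.steps)
        filt = fit_decoder(d)
        train_mean = d.S[d.train_idx].mean(axis=0)
        assert np.allclose(filt.offsets, train_mean)
        rec = reconstruct(d, filt)
        assert np.allclose(rec.U, rec.U[0])  # constant reconstruction

    def test_duplicated_cell_equals_single_cell_reconstruction(self):
        traj = generate_trajectory(7, 6000)
        cell = build_population(1, nonlinearity_kind="exponential")[0]
        counts = simulate_motion_ln_cell(cell, traj, 8).counts[0, 0]
        single = LinearMotionDecoder(counts[None, :], traj.steps).fit()
        dup = LinearMotionDecoder(np.stack([counts, counts]), traj.steps).fit()
        assert np.allclose(
            single.reconstruction.U, dup.reconstruction.U, atol=1e-6
        )

    def test_training_residuals_orthogonal_to_regressors(self):
        traj = generate_trajectory(9, 4000)
        counts = stream(9, "spikes").poisson(0.2, (2, 4000)).astype(float)
        d = build_design(counts, traj.steps)
        filt = fit_decoder(d)
        F = d.F[d.train_idx]
        resid = d.S[d.train_idx] - F @ filt.B
        assert np.allclose(F.T @ resid, 0.0, atol=1e-6)


class TestReconstruction:
    def test_ln_population_reconstruction_is_low_pass(self, mixed_population,
                                                      trajectory_10min):
        """Reconstructed motion concentrates below ~5 Hz."""
        _, counts = mixed_population
        res = LinearMotionDecoder(counts, trajectory_10min.steps).fit()
        U = res.reconstruction.U[:, 0]
        spec = np.abs(np.fft.rfft(U - U.mean())) ** 2
        freqs = np.fft.rfftfreq(U.size, 1 / 30.0)
        low = spec[freqs <= 5.0].sum()
        assert low / spec.sum() > 0.8

    def test_decoder_filters_match_time_reversed_encoders(self):
        """At 30 min of data, decoder filters mirror the encoding kernels.

        The decoder tap at lag d weighs the count d frames after the decoded
        step, which carries the encoding filter's weight at lag d; taps
        1..L-1 therefore reproduce the time-reversed encoding kernel.
        """
        traj = generate_trajectory(22, 54000)
        cells = build_population(3, nonlinearity_kind="exponential")
        counts = simulate_population(cells, traj, 5).counts[:, 0, :]
        res = LinearMotionDecoder(counts, traj.steps).fit()
        for i, c in enumerate(cells):
            th = math.radians(c.preferred_direction_deg)
            reversed_kernel = c.filters[0][::-1]
            for ax, w in ((0, math.cos(th)), (1, math.sin(th))):
                if abs(w) < 0.3:
                    continue
                taps = res.filters.cell_filter(i, ax)
                r = np.corrcoef(taps[1:], (reversed_kernel * w)[:-1])[0, 1]
                assert abs(r) > 0.9

    def test_pure_noise_cell_adds_no_information(self, mixed_population,
                                                 trajectory_10min):
        _, counts = mixed_population
        noise = stream(77, "spikes").poisson(0.15, counts.shape[1])[None, :]
        base = LinearMotionDecoder(counts, trajectory_10min.steps).fit()
        extra = LinearMotionDecoder(
            np.concatenate([counts, noise]), trajectory_10min.steps
        ).fit()
        i_base = base.information().total_rate
        i_extra = extra.information().total_rate
        assert i_extra < i_base * 1.05  # no gain beyond sampling error

    def test_mismatched_filters_rejected(self):
        traj = generate_trajectory(10, 2000)
        d1 = build_design(np.zeros((1, 2000)), traj.steps)
        d2 = build_design(np.zeros((2, 2000)), traj.steps)
        filt = fit_decoder(d1)
        with pytest.raises(ValueError):
            reconstruct(d2, filt)


class TestReducedCodes:
    def test_identical_cells_subtract_is_zero(self):
        c = np.arange(10)
        red = reduce_pair(c, c, "subtract")
        assert np.all(red.sequence == 0)

    def test_add_doubles_and_reconstruction_is_scale_invariant(self):
        traj = generate_trajectory(11, 9000)
        cell = build_population(1, nonlinearity_kind="exponential")[0]
        counts = simulate_motion_ln_cell(cell, traj, 12).counts[0, 0]
        added = reduce_pair(counts, counts, "add")
        assert np.array_equal(added.sequence, 2 * counts)
        single = LinearMotionDecoder(counts[None, :], traj.steps).fit()
        summed = LinearMotionDecoder(added.sequence[None, :], traj.steps).fit()
        assert np.allclose(
            single.reconstruction.U, summed.reconstruction.U, atol=1e-8
        )

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            reduce_pair(np.zeros(5), np.zeros(6), "add")


class TestOpponentAxis:
    @staticmethod
    def _sta_for(cell, traj, seed):
        counts = simulate_motion_ln_cell(cell, traj, seed).counts[0, 0]
        return compute_motion_sta(segment_stimulus(traj.steps, counts))

    def test_pure_axis_pairs(self):
        traj = generate_trajectory(13, 18000)
        cx = build_population(2, direction_groups=(0.0, 180.0),
                              nonlinearity_kind="exponential")
        sx1 = self._sta_for(cx[0], traj, 1)
        sx2 = self._sta_for(cx[1], traj, 2)
        assert select_opponent_axis(sx1, sx2) == "x"
        cy = build_population(2, direction_groups=(90.0, 270.0),
                              nonlinearity_kind="exponential")
        sy1 = self._sta_for(cy[0], traj, 3)
        sy2 = self._sta_for(cy[1], traj, 4)
        assert select_opponent_axis(sy1, sy2) == "y"

    def test_matches_brute_force_for_oblique_pair(self):
        traj = generate_trajectory(14, 18000)
        cells = build_population(2, direction_groups=(60.0, 180.0),
                                 nonlinearity_kind="exponential")
        s1 = self._sta_for(cells[0], traj, 5)
        s2 = self._sta_for(cells[1], traj, 6)
        n = 9  # 300 ms
        diffs = {}
        for name, a, b in (("x", s1.ax, s2.ax), ("y", s1.ay, s2.ay)):
            pa = a[-n:][np.argmax(np.abs(a[-n:]))]
            pb = b[-n:][np.argmax(np.abs(b[-n:]))]
            diffs[name] = abs(pa - pb)
        expected = max(diffs, key=diffs.get)
        assert select_opponent_axis(s1, s2) == expected
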