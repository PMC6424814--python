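"""Optimal linear multi-cell decoding of motion trajectories.

The decoder reconstructs the motion-step sequence from the lagged,
frame-binned spike counts of a cell population by ordinary least squares:
each decoded step s_j is regressed on a constant plus, for every cell, the
L = 24 counts in frames j..j+L-1 (spikes *follow* the stimulus they encode,
so the count window starts at the decoded frame).  Solving the normal
equations B = (F'^T F')^{-1} F'^T S' corrects the filters for the pairwise
correlations between the cells' spike trains.  Filters are fitted on the
chronologically first 70% of the recording and evaluated on the final 30%;
windows straddling the boundary are dropped from both sets.

Reduced population codes -- the per-frame difference or sum of two cells'
counts -- are decoded by the same machinery as a single response sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .stimulus import FILTER_TAPS
from .encoding import MotionSTAResult

DT = 1.0 / 30.0


@dataclass
class DesignMatrices:
    """Lagged-count design matrix and aligned step targets."""

    F: np.ndarray  # (n_rows, 1 + n_cells*L)
    S: np.ndarray  # (n_rows, d)
    train_idx: np.ndarray
    test_idx: np.ndarray
    L: int
    n_cells: int

    @property
    def n_axes(self) -> int:
        return self.S.shape[1]


def build_design(
    counts: np.ndarray,
    steps: np.ndarray,
    L: int = FILTER_TAPS,
    train_frac: float = 0.7,
) -> DesignMatrices:
    """Build the decoding design from per-cell counts and motion steps.

    ``counts`` is (n_cells, M) and ``steps`` (M, d) with d = 1 or 2.  Row j
    of the design holds [1, counts of frames j..j+L-1 per cell] and targets
    steps[j].  The chronological train/test split is applied to the decoded
    frames; rows whose count window crosses the boundary are discarded.
    """
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    steps = np.asarray(steps, dtype=float)
    if steps.ndim == 1:
        steps = steps[:, None]
    M = steps.shape[0]
    if counts.shape[1] != M:
        raise ValueError(
            f"counts ({counts.shape[1]} frames) and steps ({M}) are misaligned"
        )
    if M <= L:
        raise ValueError("need more frames than the filter length")
    n_cells = counts.shape[0]
    n_rows = M - L + 1
    blocks = [np.ones((n_rows, 1))]
    for i in range(n_cells):
        blocks.append(sliding_window_view(counts[i], L))
    F = np.concatenate(blocks, axis=1)
    S = steps[:n_rows]
    boundary = int(np.floor(train_frac * M))
    rows = np.arange(n_rows)
    train_idx = rows[rows + L - 1 < boundary]  # window fully inside train block
    test_idx = rows[rows >= boundary]
    return DesignMatrices(F, S, train_idx, test_idx, L, n_cells)


@dataclass
class DecoderFilters:
    """Fitted reconstruction filters: offsets plus L taps per cell and axis."""

    B: np.ndarray  # (1 + n_cells*L, d)
    L: int
    n_cells: int

    @property
    def offsets(self) -> np.ndarray:
        return self.B[0]

    def cell_filter(self, cell: int, axis: int = 0) -> np.ndarray:
        """L-tap filter of one cell for axis 0 (x) or 1 (y).

        Tap k weighs the count k frames after the decoded step's frame.
        """
        start = 1 + cell * self.L
        return self.B[start : start + self.L, axis]


@dataclass
class Reconstruction:
    """Test-block reconstruction paired with the held-out steps."""

    U: np.ndarray  # (n_test, d)
    S_test: np.ndarray

    def correlation(self, axis: int = 0) -> float:
        return float(np.corrcoef(self.U[:, axis], self.S_test[:, axis])[0, 1])


def fit_decoder(design: DesignMatrices) -> DecoderFilters:
    """Least-squares filters on the training block.

    ``lstsq`` returns the minimum-norm solution, so rank-deficient designs
    (e.g. duplicated cells) fall through to the pseudo-inverse path
    automatically.
    """
    F = design.F[design.train_idx]
    S = design.S[design.train_idx]
    if F.shape[0] == 0:
        raise ValueError("empty training block")
    B, *_ = np.linalg.lstsq(F, S, rcond=None)
    return DecoderFilters(B, design.L, design.n_cells)


def reconstruct(design: DesignMatrices, filters: DecoderFilters) -> Reconstruction:
    """Linear readout U = F'' B on the held-out test block."""
    if filters.B.shape[0] != design.F.shape[1]:
        raise ValueError("filters do not match the design (L or cell set differ)")
    F = design.F[design.test_idx]
    return Reconstruction(F @ filters.B, design.S[design.test_idx])


# ---------------------------------------------------------------------------
# Model / Results wrapper
# ---------------------------------------------------------------------------

class LinearMotionDecoder:
    """Optimal linear decoder of motion steps from population spike counts.

    Examples
    --------
    >>> dec = LinearMotionDecoder(counts, trajectory.steps)      # doctest: +SKIP
    >>> res = dec.fit()                                          # doctest: +SKIP
    >>> res.information().total_rate                             # doctest: +SKIP
    """

    def __init__(
        self,
        counts: np.ndarray,
        steps: np.ndarray,
        L: int = FILTER_TAPS,
        train_frac: float = 0.7,
        dt: float = DT,
    ):
        self.design = build_design(counts, steps, L, train_frac)
        self.dt = dt

    def fit(self) -> "DecoderResults":
        filters = fit_decoder(self.design)
        recon = reconstruct(self.design, filters)
        return DecoderResults(self, filters, recon)


@dataclass
class DecoderResults:
    """Fitted decoder: filters, held-out reconstruction, information."""

    model: LinearMotionDecoder
    filters: DecoderFilters
    reconstruction: Reconstruction

    def information(self, segment_taps: int | None = None):
        """Spectral lower bound on the stimulus information (bits/s)."""
        from .information import info_lower_bound

        L = segment_taps or self.model.design.L
        return info_lower_bound(
            self.reconstruction.S_test,
            self.reconstruction.U,
            segment_taps=L,
            dt=self.model.dt,
        )

    def summary(self) -> str:
        d = self.model.design
        info = self.information()
        lines = [
            "Optimal linear motion decoder",
            "=" * 40,
            f"cells:          {d.n_cells}",
            f"taps per cell:  {d.L}",
            f"train rows:     {d.train_idx.size}",
            f"test rows:      {d.test_idx.size}",
            f"offsets:        {np.array2string(self.filters.offsets, precision=4)}",
            f"test r (x):     {self.reconstruction.correlation(0):.3f}",
            f"information:    {info.total_rate:.3f} bits/s",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Reduced (subtractive / additive) codes
# ---------------------------------------------------------------------------

@dataclass
class ReducedCode:
    """Single response sequence formed from a cell pair."""

    sequence: np.ndarray
    mode: Literal["subtract", "add"]
    opponent_axis: Literal["x", "y"] | None = None


def reduce_pair(
    counts_i: np.ndarray, counts_j: np.ndarray, mode: Literal["subtract", "add"]
) -> ReducedCode:
    """Element-wise difference or sum of two cells' binned counts."""
    ci = np.asarray(counts_i)
    cj = np.asarray(counts_j)
    if ci.shape != cj.shape:
        raise ValueError("count sequences must have equal length")
    if mode == "subtract":
        return ReducedCode(ci - cj, mode)
    if mode == "add":
        return ReducedCode(ci + cj, mode)
    raise ValueError(f"unknown mode {mode!r}")


def select_opponent_axis(
    sta_i: MotionSTAResult,
    sta_j: MotionSTAResult,
    window_ms: float = 300.0,
    dt: float = DT,
) -> Literal["x", "y"]:
    """Motion axis with the larger STA peak difference in the last 300 ms.

    For each axis the peak is the extremal STA value (largest magnitude)
    within ``window_ms`` before the spike; the axis maximizing
    |peak_i - peak_j| is the opponent axis.  Ties go to x.
    """
    n = int(round(window_ms / 1000.0 / dt))

    def peak(v: np.ndarray) -> float:
        tail = v[-n:]
        return float(tail[np.argmax(np.abs(tail))])

    dx = abs(peak(sta_i.ax) - peak(sta_j.ax))
    dy = abs(peak(sta_i.ay) - peak(sta_j.ay))
    return "y" if dy > dx else "x"
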