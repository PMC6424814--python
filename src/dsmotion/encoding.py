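"""Single-cell motion encoding characterization.

Implements the spike-triggered analyses on the motion-step sequence: the
motion STA (average pre-spike trajectory) with a spike-shuffle significance
test, the LN-model nonlinearity estimated by equal-count binning with its
U-shape index, spike-triggered covariance (STC) with conditional
nonlinearities along the leading eigenvectors, parametric nonlinearity fits,
and conditional texture STAs (the average pre-spike spatial pattern for
preferred vs non-preferred motion).

All temporal windows span ``L = 24`` taps of 33 ms (800 ms).  Segment rows
and filter taps are stored in chronological order: index 0 is the oldest
frame of the window and the last index is the frame immediately preceding
the response bin.

:class:`MotionLNModel` packages the whole characterization in a
model/results pair: construct it from a trajectory and a spike-count
sequence, call :meth:`MotionLNModel.fit`, and read the estimates off the
returned :class:`MotionLNResults`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.ndimage import gaussian_filter
from scipy.optimize import curve_fit

from .rng import stream
from .stimulus import FILTER_TAPS, MotionTrajectory, Movie

DT = 1.0 / 30.0


# ---------------------------------------------------------------------------
# Stimulus segmentation
# ---------------------------------------------------------------------------

@dataclass
class SegmentedStimulus:
    """Trailing trajectory windows paired with the following spike count.

    Row j of ``Sseg`` holds steps j..j+L-1 (x taps then y taps, chronological)
    and ``f[j]`` is the spike count in frame j+L.
    """

    Sseg: np.ndarray  # (M - L, d*L)
    f: np.ndarray  # (M - L,)
    L: int
    n_axes: int  # 1 or 2
    step_sd: float  # empirical per-component SD used for normalization

    @property
    def n_segments(self) -> int:
        return self.Sseg.shape[0]


def segment_stimulus(
    steps: np.ndarray, counts: np.ndarray, L: int = FILTER_TAPS
) -> SegmentedStimulus:
    """Arrange motion steps into overlapping windows aligned with responses."""
    steps = np.asarray(steps, dtype=float)
    if steps.ndim == 1:
        steps = steps[:, None]
    counts = np.asarray(counts, dtype=float)
    M = steps.shape[0]
    if counts.shape[0] != M:
        raise ValueError("steps and counts must have equal length")
    if M <= L:
        raise ValueError("trajectory must be longer than the window L")
    windows = sliding_window_view(steps, L, axis=0)[:-1]  # (M-L, d, L)
    Sseg = windows.reshape(M - L, -1)
    sd = float(steps.std(axis=0).mean())
    return SegmentedStimulus(
        np.ascontiguousarray(Sseg), counts[L:].copy(), L, steps.shape[1], sd
    )


# ---------------------------------------------------------------------------
# Motion STA
# ---------------------------------------------------------------------------

@dataclass
class MotionSTAResult:
    """Spike-count-weighted average pre-spike trajectory."""

    a: np.ndarray  # (d*L,) chronological taps, x block then y block
    L: int
    n_axes: int
    n_spikes: float
    magnitude: float = field(init=False)
    significant: bool | None = None
    shuffle_null: np.ndarray | None = None
    dt: float = DT

    def __post_init__(self) -> None:
        self.magnitude = float(np.linalg.norm(self.a))

    @property
    def ax(self) -> np.ndarray:
        return self.a[: self.L]

    @property
    def ay(self) -> np.ndarray:
        if self.n_axes < 2:
            raise ValueError("one-dimensional STA has no y component")
        return self.a[self.L : 2 * self.L]

    @property
    def preferred_vector(self) -> np.ndarray:
        """Direction vector v = (sum ax, sum ay)."""
        vx = float(self.ax.sum())
        vy = float(self.ay.sum()) if self.n_axes == 2 else 0.0
        return np.array([vx, vy])

    @property
    def preferred_angle_deg(self) -> float:
        v = self.preferred_vector
        return math.degrees(math.atan2(v[1], v[0])) % 360.0

    @property
    def lags_ms(self) -> np.ndarray:
        """Time before the response bin for each tap (chronological order)."""
        return (np.arange(self.L, 0, -1) - 0.5) * self.dt * 1000.0


def compute_motion_sta(seg: SegmentedStimulus) -> MotionSTAResult:
    """a = Sseg^T f / sum(f): the mean pre-spike step sequence."""
    n_spikes = seg.f.sum()
    if n_spikes <= 0:
        raise ValueError("cannot compute an STA from zero spikes")
    a = seg.Sseg.T @ seg.f / n_spikes
    return MotionSTAResult(a, seg.L, seg.n_axes, float(n_spikes))


def sta_significance(
    seg: SegmentedStimulus,
    n_shuffles: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[bool, np.ndarray]:
    """Spike-shuffle significance test for the motion STA magnitude.

    The null distribution redraws the observed number of spikes uniformly
    over the recording (equivalently, multinomial reallocation of the binned
    counts) and recomputes |a| per shuffle.  The observed STA is significant
    when its magnitude exceeds the ``level`` quantile of the null.
    """
    if n_shuffles < 100:
        import warnings

        warnings.warn("fewer than 100 shuffles gives a coarse null", stacklevel=2)
    if seg.n_segments < 10 * seg.L:
        raise ValueError("recording too short for the shuffle test (need >= 10 L windows)")
    observed = compute_motion_sta(seg).magnitude
    n_spikes = int(round(seg.f.sum()))
    M = seg.n_segments
    rng = stream(seed, "shuffle")
    mags = np.empty(n_shuffles)
    chunk = max(1, min(n_shuffles, int(2e8 / max(M, 1) / 8)))
    p = np.full(M, 1.0 / M)
    done = 0
    while done < n_shuffles:
        k = min(chunk, n_shuffles - done)
        F = rng.multinomial(n_spikes, p, size=k).astype(float)  # (k, M)
        A = seg.Sseg.T @ F.T  # (dL, k)
        mags[done : done + k] = np.linalg.norm(A, axis=0) / n_spikes
        done += k
    threshold = np.quantile(mags, level)
    return bool(observed > threshold), mags


# ---------------------------------------------------------------------------
# LN nonlinearity
# ---------------------------------------------------------------------------

def ln_drive(seg: SegmentedStimulus, a: np.ndarray) -> np.ndarray:
    """Filtered drive g = Sseg_norm . a_norm.

    The filter is normalized to unit Euclidean norm and the stimulus to unit
    variance, so g is on a dimensionless scale with SD ~ 1.
    """
    a = np.asarray(a, dtype=float)
    return (seg.Sseg / seg.step_sd) @ (a / np.linalg.norm(a))


def _equal_count_partition(n: int, n_bins: int) -> list[np.ndarray]:
    """Split indices 0..n-1 into ``n_bins`` contiguous equal-count groups.

    Remainder samples are assigned to the central bins so the tails keep the
    base occupancy.
    """
    base, extra = divmod(n, n_bins)
    sizes = np.full(n_bins, base, dtype=int)
    if extra:
        center = n_bins // 2
        order = np.argsort(np.abs(np.arange(n_bins) - center), kind="stable")
        sizes[order[:extra]] += 1
    edges = np.concatenate([[0], np.cumsum(sizes)])
    return [np.arange(edges[i], edges[i + 1]) for i in range(n_bins)]


@dataclass
class BinnedNonlinearity:
    """Equal-count-binned rate nonlinearity N(g) in Hz."""

    g_centers: np.ndarray
    rates_hz: np.ndarray
    bin_counts: np.ndarray
    dt: float = DT

    @property
    def ushape_index(self) -> float:
        """U = (N(g_min) - N(0)) / N(g_max).

        Negative for monotonically rising nonlinearities, near zero for a
        flat left tail, and approaching one for a symmetric U-shape.
        """
        n_bins = len(self.rates_hz)
        center = self.rates_hz[n_bins // 2]
        right = self.rates_hz[-1]
        if right == 0:
            raise ZeroDivisionError("U-shape index undefined: N(g_max) = 0")
        return float((self.rates_hz[0] - center) / right)


def estimate_nonlinearity(
    g: np.ndarray, f: np.ndarray, n_bins: int = 15, dt: float = DT
) -> BinnedNonlinearity:
    """Bin (g, f) pairs into equal-count bins and average within each bin."""
    g = np.asarray(g, dtype=float)
    f = np.asarray(f, dtype=float)
    if g.shape != f.shape:
        raise ValueError("g and f must be aligned")
    if n_bins > g.size:
        raise ValueError(f"n_bins={n_bins} exceeds the {g.size} available samples")
    order = np.argsort(g, kind="stable")
    gs, fs = g[order], f[order]
    groups = _equal_count_partition(g.size, n_bins)
    centers = np.array([gs[idx].mean() for idx in groups])
    rates = np.array([fs[idx].mean() / dt for idx in groups])
    counts = np.array([idx.size for idx in groups])
    return BinnedNonlinearity(centers, rates, counts, dt)


def fit_parametric_nonlinearity(
    binned: BinnedNonlinearity, kind: Literal["exponential", "ushape"]
):
    """Least-squares fit of A e^{Bx} or C + A x^2 e^{Bx} to the binned rates."""
    from .cells import ParametricNonlinearity

    x, y = binned.g_centers, binned.rates_hz
    if np.all(y == 0):
        raise ValueError("cannot fit a nonlinearity to all-zero rates")
    if kind == "exponential":
        pos = y > 0
        if pos.sum() >= 2:
            slope, intercept = np.polyfit(x[pos], np.log(y[pos]), 1)
            p0 = [math.exp(intercept), slope]
        else:
            p0 = [max(y.mean(), 1e-3), 1.0]
        popt, _ = curve_fit(
            lambda x, A, B: A * np.exp(B * x), x, y, p0=p0,
            bounds=([1e-9, -20], [np.inf, 20]), maxfev=20000,
        )
        return ParametricNonlinearity("exponential", float(popt[0]), float(popt[1]))
    if kind == "ushape":
        c0 = max(float(y.min()), 1e-6)
        a0 = max((float(y.max()) - c0) / max(float(np.abs(x).max()) ** 2, 1e-6), 1e-6)
        popt, _ = curve_fit(
            lambda x, C, A, B: C + A * x**2 * np.exp(B * x), x, y,
            p0=[c0, a0, 0.0], bounds=([0, 1e-9, -20], [np.inf, np.inf, 20]),
            maxfev=20000,
        )
        return ParametricNonlinearity(
            "ushape", float(popt[1]), float(popt[2]), float(popt[0])
        )
    raise ValueError(f"unknown nonlinearity kind {kind!r}")


# ---------------------------------------------------------------------------
# Spike-triggered covariance
# ---------------------------------------------------------------------------

@dataclass
class STCResult:
    """Spike-triggered covariance and its leading eigenstructure."""

    stc_matrix: np.ndarray  # (dL, dL), symmetric
    eigenvalues: np.ndarray  # descending
    eigenvectors: np.ndarray  # columns, same order
    conditional_nls: list[BinnedNonlinearity] | None = None

    @property
    def e1(self) -> np.ndarray:
        return self.eigenvectors[:, 0]

    @property
    def e2(self) -> np.ndarray:
        return self.eigenvectors[:, 1]


def compute_stc(
    seg: SegmentedStimulus,
    n_bins: int = 15,
    conditional_band: float = 0.5,
    dt: float = DT,
) -> STCResult:
    """Spike-weighted covariance of the pre-spike windows about the STA.

    STC = sum_j f_j (s_j - a)(s_j - a)^T / sum_j f_j on the unit-variance
    normalized stimulus.  Conditional nonlinearities along the two leading
    eigenvectors are computed from segments whose projection on the *other*
    eigenvector lies within ``(-conditional_band, conditional_band)``.
    """
    n_spikes = seg.f.sum()
    if n_spikes <= 0:
        raise ValueError("cannot compute STC from zero spikes")
    S = seg.Sseg / seg.step_sd
    a = S.T @ seg.f / n_spikes
    D = S - a
    stc = (D * seg.f[:, None]).T @ D / n_spikes
    stc = 0.5 * (stc + stc.T)
    if not np.any(stc):
        raise ValueError("degenerate (zero) spike-triggered covariance")
    w, V = np.linalg.eigh(stc)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    g1 = S @ V[:, 0]
    g2 = S @ V[:, 1]
    nls = []
    for g_own, g_other in ((g1, g2), (g2, g1)):
        sel = np.abs(g_other) < conditional_band
        if sel.sum() >= n_bins:
            nls.append(estimate_nonlinearity(g_own[sel], seg.f[sel], n_bins, dt))
        else:
            nls.append(None)
    return STCResult(stc, w, V, nls)


def subspace_angle_deg(basis_a: np.ndarray, basis_b: np.ndarray) -> float:
    """Largest principal angle between two filter subspaces, in degrees."""
    Qa, _ = np.linalg.qr(np.column_stack(basis_a))
    Qb, _ = np.linalg.qr(np.column_stack(basis_b))
    s = np.linalg.svd(Qa.T @ Qb, compute_uv=False)
    s = np.clip(s, -1.0, 1.0)
    return float(np.degrees(np.arccos(s.min())))


# ---------------------------------------------------------------------------
# Conditional texture STAs
# ---------------------------------------------------------------------------

@dataclass
class ConditionalTextureSTA:
    """Mean pre-spike spatial pattern under a motion condition.

    ``spatial_frame`` is the frame 200 ms before the spike, corrected by
    subtracting the all-frame mean pattern.
    """

    spatial_frame: np.ndarray
    condition: Literal["preferred", "nonpreferred"]
    n_spikes: float
    pixel_sd: float
    contrast_bias: float
    dark_spot_um: tuple[float, float]
    included: bool
    pitch_um: float


def conditional_texture_sta(
    movie: Movie,
    counts: np.ndarray,
    g: np.ndarray,
    condition: Literal["preferred", "nonpreferred"],
    frame_lag_ms: float = 200.0,
    threshold: float = 0.5,
    inclusion_sds: float = 4.0,
    smooth_um: float = 30.0,
) -> ConditionalTextureSTA:
    """Average the stimulus frame 200 ms before condition-selected spikes.

    Spikes are selected by the filtered drive: ``g > 0.5`` for preferred
    motion, ``g < -0.5`` for non-preferred.  The all-frame mean pattern is
    subtracted to cancel non-informative structure; the result is included
    only when its absolute peak exceeds ``inclusion_sds`` pixel SDs.  The
    dark spot is the minimum of the corrected frame after a light spatial
    smoothing that suppresses single-pixel noise.
    """
    counts = np.asarray(counts, dtype=float)
    g = np.asarray(g, dtype=float)
    n_frames = movie.frames.shape[0]
    n = min(n_frames, counts.shape[0], g.shape[0])
    lag = int(round(frame_lag_ms / 1000.0 / movie.dt_s))
    if condition == "preferred":
        sel = g[:n] > threshold
    elif condition == "nonpreferred":
        sel = g[:n] < -threshold
    else:
        raise ValueError(f"unknown condition {condition!r}")
    sel &= np.arange(n) >= lag
    weights = counts[:n] * sel
    n_spikes = weights.sum()
    if n_spikes <= 0:
        raise ValueError(f"no spikes satisfy the {condition!r} condition")
    idx = np.nonzero(weights)[0]
    sta = np.tensordot(weights[idx], movie.frames[idx - lag].astype(np.float64), axes=1)
    sta /= n_spikes
    corrected = sta - movie.frames.astype(np.float64).mean(axis=0)
    sd = float(corrected.std())
    peak = float(np.abs(corrected).max())
    included = bool(sd > 0 and peak >= inclusion_sds * sd)
    bias = float((corrected.min() + corrected.max()) / sd) if sd > 0 else float("nan")
    smooth = gaussian_filter(corrected, sigma=smooth_um / movie.pitch_um)
    r, c = np.unravel_index(np.argmin(smooth), smooth.shape)
    rows = corrected.shape[0]
    dark = ((c + 0.5) * movie.pitch_um, (rows - r - 0.5) * movie.pitch_um)
    return ConditionalTextureSTA(
        corrected, condition, float(n_spikes), sd, bias, dark, included, movie.pitch_um
    )


# ---------------------------------------------------------------------------
# Model / Results wrapper
# ---------------------------------------------------------------------------

class MotionLNModel:
    """LN characterization of one cell's motion encoding.

    Parameters
    ----------
    trajectory : MotionTrajectory or array
        Motion steps, (M, 2) in um (or (M,) for one-dimensional stimuli).
    counts : array
        Frame-binned spike counts aligned with the steps.
    L : int
        Window length in taps (default 24 = 800 ms at 30 Hz).
    """

    def __init__(self, trajectory, counts, L: int = FILTER_TAPS, dt: float = DT):
        steps = (
            trajectory.steps
            if isinstance(trajectory, MotionTrajectory)
            else np.asarray(trajectory, dtype=float)
        )
        self.seg = segment_stimulus(steps, np.asarray(counts), L)
        self.L = L
        self.dt = dt

    def fit(
        self,
        n_shuffles: int = 1000,
        significance_level: float = 0.95,
        n_bins: int = 15,
        compute_covariance: bool = False,
        seed: int = 0,
    ) -> "MotionLNResults":
        sta = compute_motion_sta(self.seg)
        if n_shuffles:
            significant, null = sta_significance(
                self.seg, n_shuffles, significance_level, seed
            )
            sta.significant = significant
            sta.shuffle_null = null
        g = ln_drive(self.seg, sta.a)
        nl = estimate_nonlinearity(g, self.seg.f, n_bins, self.dt)
        stc = compute_stc(self.seg, n_bins, dt=self.dt) if compute_covariance else None
        return MotionLNResults(self, sta, nl, g, stc)


@dataclass
class MotionLNResults:
    """Fitted motion-encoding characterization of one cell."""

    model: MotionLNModel
    sta: MotionSTAResult
    nonlinearity: BinnedNonlinearity
    drive: np.ndarray
    stc: STCResult | None = None

    @property
    def preferred_angle_deg(self) -> float:
        return self.sta.preferred_angle_deg

    @property
    def ushape_index(self) -> float:
        return self.nonlinearity.ushape_index

    def summary(self) -> str:
        s = self.sta
        lines = [
            "Motion LN model",
            "=" * 40,
            f"segments:            {self.model.seg.n_segments}",
            f"spikes:              {s.n_spikes:.0f}",
            f"STA magnitude:       {s.magnitude:.4f} um",
            f"significant:         {s.significant}",
            f"preferred direction: {s.preferred_angle_deg:.1f} deg",
            f"U-shape index:       {self.ushape_index:+.3f}",
        ]
        if self.stc is not None:
            ev = self.stc.eigenvalues
            lines.append(f"STC top eigenvalues: {ev[0]:.3f}, {ev[1]:.3f}")
        return "\n".join(lines)
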