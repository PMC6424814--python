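"""Model retina: simulated direction-selective ganglion cells.

Spike trains are generated by linear-nonlinear Poisson (LN-Poisson) cascades
driven by the motion-step sequence: each cell filters the (unit-variance
normalized) motion steps with one or two 800-ms kernels, passes the filtered
drive through a static nonlinearity -- monotonic exponential or non-monotonic
U-shape -- and emits spike counts per 33-ms frame from a Poisson draw.
Populations carry the three preferred-direction groups, separated by 120
degrees, that are characteristic of the global-motion direction-selective
cells this package models.

A separate, explicitly synthetic texture-driven encoder
(:func:`simulate_texture_cell`) provides an OFF-type, contrast- and
direction-sensitive cell operating on rendered movies; it is scaffolding for
testing classification and conditional texture analyses, not a fitted model
of any recorded cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .rng import stream
from .screen import DEFAULT_SCREEN, ScreenModel
from .stimulus import (
    FILTER_TAPS,
    MotionTrajectory,
    Movie,
    Texture,
    TrialProtocol,
    render_moving_texture,
)


# ---------------------------------------------------------------------------
# Nonlinearities
# ---------------------------------------------------------------------------

@dataclass
class ParametricNonlinearity:
    """Static rate nonlinearity N(x), in Hz.

    ``exponential``: N(x) = A exp(B x) -- monotone for B > 0.
    ``ushape``:      N(x) = C + A x^2 exp(B x) -- non-monotonic, elevated for
    strong drive of either sign (the source of direction ambiguity).
    """

    kind: Literal["exponential", "ushape"]
    A: float
    B: float
    C: float = 0.0

    def __post_init__(self) -> None:
        if self.A <= 0:
            raise ValueError("A must be positive")
        if self.kind == "ushape" and self.C < 0:
            raise ValueError("ushape offset C must be non-negative")
        if self.kind not in ("exponential", "ushape"):
            raise ValueError(f"unknown nonlinearity kind {self.kind!r}")

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.kind == "exponential":
            return self.A * np.exp(self.B * x)
        return self.C + self.A * x**2 * np.exp(self.B * x)


# Defaults giving mean rates of a few Hz for unit-variance Gaussian drive
# (exponential ~3.3 Hz, ushape ~4.0 Hz).  The exponential steepness keeps the
# monotonic control in a mildly distorting regime where opponent pairs decode
# redundantly; the near-symmetric U-shape reproduces the strongly compromised
# single-cell information and the synergy of opponent U-shaped pairs.
DEFAULT_EXPONENTIAL = dict(kind="exponential", A=2.0, B=1.0)
DEFAULT_USHAPE = dict(kind="ushape", A=2.75, B=0.25, C=1.0)


def default_nonlinearity(kind: str) -> ParametricNonlinearity:
    if kind == "exponential":
        return ParametricNonlinearity(**DEFAULT_EXPONENTIAL)
    if kind == "ushape":
        return ParametricNonlinearity(**DEFAULT_USHAPE)
    raise ValueError(f"unknown nonlinearity kind {kind!r}")


# ---------------------------------------------------------------------------
# Temporal filter template
# ---------------------------------------------------------------------------

def biphasic_filter_template(
    n_taps: int = FILTER_TAPS,
    dt: float = 1.0 / 30.0,
    peak_ms: float = 175.0,
    zero_crossing_ms: float = 100.0,
) -> np.ndarray:
    """Canonical biphasic motion kernel, unit Euclidean norm.

    Difference of two temporal Gaussians with the main (positive) lobe
    peaking ``peak_ms`` before the spike and the sign change at
    ``zero_crossing_ms``.  Taps are returned in chronological order: index 0
    is the oldest step of the 800-ms window, the last index is the step
    immediately preceding the response bin.
    """
    # time before the response bin, chronological order
    tau_ms = (np.arange(n_taps, 0, -1) - 0.5) * dt * 1000.0
    sd1, sd2 = 45.0, 30.0
    peak2_ms = 60.0
    g1 = np.exp(-((tau_ms - peak_ms) ** 2) / (2 * sd1**2))
    g2 = np.exp(-((tau_ms - peak2_ms) ** 2) / (2 * sd2**2))
    # weight the undershoot so the sign change lands at the requested time
    w = math.exp(-((zero_crossing_ms - peak_ms) ** 2) / (2 * sd1**2)) / math.exp(
        -((zero_crossing_ms - peak2_ms) ** 2) / (2 * sd2**2)
    )
    k = g1 - w * g2
    return k / np.linalg.norm(k)


# ---------------------------------------------------------------------------
# Model cells and spike-train containers
# ---------------------------------------------------------------------------

@dataclass
class ModelCell:
    """An LN-Poisson model cell driven by motion steps.

    ``filters`` holds one or two temporal kernels (chronological taps, unit
    norm each); ``filter_directions_deg`` gives the motion-space axis of each
    kernel, so the full stimulus filter of component ``c`` is
    ``(cos(theta_c), sin(theta_c)) x filters[c]``.  For two-component cells
    the firing rate is the sum ``N1(g1) + N2(g2)``.
    """

    filters: np.ndarray  # (n_components, L)
    filter_directions_deg: np.ndarray  # (n_components,)
    nonlinearities: Sequence[ParametricNonlinearity]
    preferred_direction_deg: float
    rate_scale: float = 1.0
    rf_center_um: tuple[float, float] = (0.0, 0.0)
    group: str = ""

    def __post_init__(self) -> None:
        self.filters = np.atleast_2d(np.asarray(self.filters, dtype=float))
        self.filter_directions_deg = np.atleast_1d(
            np.asarray(self.filter_directions_deg, dtype=float)
        )
        if not np.all(np.isfinite(self.filters)):
            raise ValueError("filter taps must be finite")
        if len(self.nonlinearities) != self.filters.shape[0]:
            raise ValueError("need one nonlinearity per filter component")

    @property
    def n_taps(self) -> int:
        return self.filters.shape[1]

    def drive(self, steps: np.ndarray, step_sd: float) -> np.ndarray:
        """Filtered drive g_c(t) per component for count bins t = 0..M-1.

        ``steps`` is the (M, 2) motion-step table in um; it is normalized to
        unit variance per component using the nominal step SD.  The count in
        bin t is driven by the L steps t-L..t-1; bins with incomplete
        windows (t < L) get zero drive.
        """
        s = np.asarray(steps, dtype=float) / step_sd
        M = s.shape[0]
        L = self.n_taps
        out = np.zeros((self.filters.shape[0], M))
        for c in range(self.filters.shape[0]):
            th = math.radians(self.filter_directions_deg[c])
            proj = s[:, 0] * math.cos(th) + s[:, 1] * math.sin(th)
            # g[t] = sum_i k[i] * proj[t - L + i]; k chronological
            full = np.convolve(proj, self.filters[c][::-1], mode="full")
            out[c, L:] = full[L - 1 : M - 1]
        return out

    def rate(self, steps: np.ndarray, step_sd: float) -> np.ndarray:
        """Firing rate in Hz per count bin."""
        g = self.drive(steps, step_sd)
        r = np.zeros(g.shape[1])
        for c, nl in enumerate(self.nonlinearities):
            r += nl(g[c])
        r *= self.rate_scale
        if np.any(r < 0):
            raise ValueError("nonlinearity produced a negative firing rate")
        return r


@dataclass
class SpikeTrainSet:
    """Frame-binned spike counts with trial structure.

    ``counts`` has shape (n_cells, n_trials, n_frames); entry [i, k, t] is
    the spike count of cell i in trial k during the frame interval
    [t*dt, (t+1)*dt).  Spike times, when materialized, are uniformly placed
    within their bin so that binning round-trips exactly.
    """

    counts: np.ndarray
    dt: float
    cell_meta: list[dict] = field(default_factory=list)
    trial_meta: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim == 2:
            self.counts = self.counts[:, None, :]
        if np.any(self.counts < 0):
            raise ValueError("spike counts must be non-negative")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_trials(self) -> int:
        return self.counts.shape[1]

    @property
    def n_frames(self) -> int:
        return self.counts.shape[2]

    def mean_rates_hz(self) -> np.ndarray:
        return self.counts.mean(axis=(1, 2)) / self.dt

    def spike_times(self, cell: int, trial: int = 0, seed: int = 0) -> np.ndarray:
        """Materialize sorted spike times (s) for one cell and trial."""
        rng = stream(seed, "spikes", index=cell * 10007 + trial)
        c = self.counts[cell, trial]
        bins = np.repeat(np.arange(self.n_frames), c)
        times = (bins + rng.random(bins.size)) * self.dt
        return np.sort(times)


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def _nominal_step_sd(trajectory: MotionTrajectory) -> float:
    """Per-component SD of quantized steps: sqrt(sigma^2 + q^2/12)."""
    return math.sqrt(trajectory.step_sd**2 + trajectory.quantum**2 / 12.0)


def simulate_motion_ln_cell(
    cell: ModelCell,
    trajectory: MotionTrajectory,
    seed: int,
    n_trials: int = 1,
    dt: float = 1.0 / 30.0,
    cell_index: int = 0,
) -> SpikeTrainSet:
    """Simulate Poisson spike counts of one LN cell for a motion trajectory."""
    if trajectory.n_frames <= cell.n_taps:
        raise ValueError("trajectory must be longer than the filter")
    r = cell.rate(trajectory.steps, _nominal_step_sd(trajectory))
    counts = np.empty((1, n_trials, trajectory.n_frames), dtype=np.int64)
    for k in range(n_trials):
        rng = stream(seed, "spikes", index=cell_index * 10007 + k)
        counts[0, k] = rng.poisson(r * dt)
    meta = [
        {
            "preferred_direction_deg": cell.preferred_direction_deg,
            "rf_center_um": cell.rf_center_um,
            "group": cell.group,
        }
    ]
    return SpikeTrainSet(counts, dt, meta, [{"transform": "identity"}] * n_trials)


def simulate_population(
    cells: Sequence[ModelCell],
    trajectory: MotionTrajectory,
    seed: int,
    n_trials: int = 1,
    dt: float = 1.0 / 30.0,
) -> SpikeTrainSet:
    """Simulate a population with independent Poisson noise per cell/trial."""
    sets = [
        simulate_motion_ln_cell(c, trajectory, seed, n_trials, dt, cell_index=i)
        for i, c in enumerate(cells)
    ]
    counts = np.concatenate([s.counts for s in sets], axis=0)
    meta = [s.cell_meta[0] for s in sets]
    return SpikeTrainSet(counts, dt, meta, sets[0].trial_meta)


_GROUP_NAMES = {0: "nasal-dorsal", 1: "temporal", 2: "nasal-ventral"}


def direction_group(angle_deg: float) -> str:
    """Preferred-direction group by angle from the nasal direction.

    0-120 deg: nasal-dorsal; 120-240: temporal; 240-360: nasal-ventral.
    Boundary angles belong to the lower interval.
    """
    a = float(angle_deg) % 360.0
    if a <= 120.0:
        return _GROUP_NAMES[0]
    if a <= 240.0:
        return _GROUP_NAMES[1]
    return _GROUP_NAMES[2]


def build_population(
    n_cells: int,
    direction_groups: Sequence[float] = (60.0, 180.0, 300.0),
    nonlinearity_kind: str = "ushape",
    rf_centers_um: Sequence[tuple[float, float]] | None = None,
    seed: int = 0,
    rate_scale: float = 1.0,
    two_component: bool = False,
) -> list[ModelCell]:
    """Build a population spanning three direction groups 120 deg apart.

    Cells are assigned round-robin to the three group angles, so equal group
    sizes result whenever ``n_cells`` is a multiple of three.  Every cell
    uses the canonical biphasic kernel rotated into its preferred direction.
    With ``two_component=True`` each cell gains an orthogonal second filter
    with a symmetric U-shaped nonlinearity, emulating the luminance-driven
    sensitivity to motion orthogonal to the preferred direction.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    angles = np.asarray(direction_groups, dtype=float)
    diffs = np.diff(np.sort(angles % 360.0))
    if len(angles) == 3 and not np.allclose(diffs, 120.0):
        raise ValueError("three direction groups must be separated by 120 deg")
    template = biphasic_filter_template()
    cells = []
    for i in range(n_cells):
        theta = float(angles[i % len(angles)])
        rf = (
            tuple(rf_centers_um[i])
            if rf_centers_um is not None
            else (0.0, 0.0)
        )
        if two_component:
            filters = np.vstack([template, template])
            dirs = np.array([theta, theta + 90.0])
            nls = [
                default_nonlinearity(nonlinearity_kind),
                ParametricNonlinearity("ushape", A=3.0, B=0.0, C=1.0),
            ]
        else:
            filters = template[None, :]
            dirs = np.array([theta])
            nls = [default_nonlinearity(nonlinearity_kind)]
        cells.append(
            ModelCell(
                filters=filters,
                filter_directions_deg=dirs,
                nonlinearities=nls,
                preferred_direction_deg=theta,
                rate_scale=rate_scale,
                rf_center_um=rf,
                group=direction_group(theta),
            )
        )
    return cells


def opponent_pair(
    nonlinearity_kind: str,
    axis_deg: float = 0.0,
    rate_scale: float = 1.0,
) -> list[ModelCell]:
    """Two LN cells with opposing filters and a shared nonlinearity.

    The pair filters the same step sequence with kernel k and -k (preferred
    directions ``axis_deg`` and ``axis_deg + 180``); used for the
    one-dimensional opponent-pair simulations.
    """
    template = biphasic_filter_template()
    nl = default_nonlinearity(nonlinearity_kind)
    cells = []
    for theta in (axis_deg, axis_deg + 180.0):
        cells.append(
            ModelCell(
                filters=template[None, :],
                filter_directions_deg=np.array([theta]),
                nonlinearities=[
                    ParametricNonlinearity(nl.kind, nl.A, nl.B, nl.C)
                ],
                preferred_direction_deg=theta % 360.0,
                rate_scale=rate_scale,
                group=direction_group(theta),
            )
        )
    return cells


# ---------------------------------------------------------------------------
# Texture-driven cell (synthetic scaffolding)
# ---------------------------------------------------------------------------

def simulate_texture_cell(
    movie: Movie,
    rf_center_um: tuple[float, float],
    preferred_direction_deg: float,
    seed: int,
    rf_sd_um: float = 100.0,
    subunit_sd_um: float = 50.0,
    subunit_sep_um: float = 80.0,
    delay_frames: int = 5,
    baseline_hz: float = 0.5,
    contrast_gain_hz: float = 30.0,
    transient_gain_hz: float = 40.0,
    motion_gain_hz: float = 400.0,
    mean_level: float = 0.5,
    n_trials: int = 1,
    cell_index: int = 0,
) -> SpikeTrainSet:
    """Synthetic OFF-type direction-selective encoder on a rendered movie.

    This is deliberately simple scaffolding, not a model fitted to any
    recording: an OFF-rectified center contrast signal (sustained plus
    transient) is combined with a Barlow-Levick-style motion detector built
    from two spatially offset OFF subunits with an asymmetric temporal
    delay.  Spikes are Poisson.
    """
    frames = movie.frames.astype(np.float64)
    n_frames, rows, cols = frames.shape
    px = movie.pitch_um
    y = (np.arange(rows)[::-1] + 0.5) * px
    x = (np.arange(cols) + 0.5) * px
    X, Y = np.meshgrid(x, y)

    cx, cy = rf_center_um
    if not (x.min() <= cx <= x.max() and y.min() <= cy <= y.max()):
        raise ValueError(f"rf center {rf_center_um} outside movie window")

    def gauss_weights(cx_, cy_, sd):
        w = np.exp(-((X - cx_) ** 2 + (Y - cy_) ** 2) / (2 * sd**2))
        return w / w.sum()

    contrast = (frames - mean_level) / mean_level
    w_center = gauss_weights(cx, cy, rf_sd_um)
    c_center = contrast.reshape(n_frames, -1) @ w_center.ravel()

    th = math.radians(preferred_direction_deg)
    ux, uy = math.cos(th), math.sin(th)
    half = subunit_sep_um / 2.0
    w_lead = gauss_weights(cx - half * ux, cy - half * uy, subunit_sd_um)
    w_trail = gauss_weights(cx + half * ux, cy + half * uy, subunit_sd_um)
    a = np.maximum(-(contrast.reshape(n_frames, -1) @ w_lead.ravel()), 0.0)
    b = np.maximum(-(contrast.reshape(n_frames, -1) @ w_trail.ravel()), 0.0)

    d = delay_frames
    motion = np.zeros(n_frames)
    motion[d:] = a[:-d] * b[d:] - b[:-d] * a[d:]

    dc = np.zeros(n_frames)
    dc[1:] = np.diff(c_center)
    rate = (
        baseline_hz
        + contrast_gain_hz * np.maximum(-c_center, 0.0)
        + transient_gain_hz * np.maximum(-dc, 0.0)
        + motion_gain_hz * np.maximum(motion, 0.0)
    )
    counts = np.empty((1, n_trials, n_frames), dtype=np.int64)
    for k in range(n_trials):
        rng = stream(seed, "spikes", index=cell_index * 10007 + k)
        counts[0, k] = rng.poisson(rate * movie.dt_s)
    meta = [
        {
            "preferred_direction_deg": preferred_direction_deg,
            "rf_center_um": rf_center_um,
            "group": direction_group(preferred_direction_deg),
            "model": "synthetic_texture_cell",
        }
    ]
    return SpikeTrainSet(counts, movie.dt_s, meta, [{"transform": "identity"}] * n_trials)


# ---------------------------------------------------------------------------
# Trial protocols
# ---------------------------------------------------------------------------

def apply_trial_protocol(
    cells: Sequence[ModelCell],
    base_trajectory: MotionTrajectory,
    protocol: TrialProtocol,
    seed: int,
    texture: Texture | None = None,
    screen: ScreenModel = DEFAULT_SCREEN,
    window_um: tuple[float, float] = (600.0, 600.0),
    dt: float = 1.0 / 30.0,
) -> SpikeTrainSet:
    """Simulate repeated trials with per-trial trajectory/texture transforms.

    Motion-LN cells respond to the (possibly flipped) step sequence; texture
    offsets leave them unchanged by construction.  When ``texture`` is
    given, cells are instead driven through :func:`simulate_texture_cell`
    on movies rendered with the per-trial texture offset, so offsets
    decorrelate the local contrast input while the trajectory is repeated.
    """
    n_frames = int(round(protocol.trial_duration_s / dt))
    if n_frames > base_trajectory.n_frames:
        raise ValueError("trial duration exceeds the base trajectory length")
    base = MotionTrajectory(
        base_trajectory.steps[:n_frames],
        base_trajectory.step_sd,
        base_trajectory.quantum,
        base_trajectory.seed,
    )
    all_counts = []
    trial_meta = []
    for k, tf in enumerate(protocol.transforms):
        traj = base.flipped() if tf.kind == "flip_xy" else base
        if texture is None:
            trial_counts = []
            for i, cell in enumerate(cells):
                s = simulate_motion_ln_cell(
                    cell, traj, seed, n_trials=1, dt=dt, cell_index=i * 1009 + k
                )
                trial_counts.append(s.counts[0, 0])
        else:
            offset = tf.offset_vector()
            movie = render_moving_texture(
                texture, traj, screen, window_um, texture_offset_um=tuple(offset)
            )
            trial_counts = []
            for i, cell in enumerate(cells):
                s = simulate_texture_cell(
                    movie,
                    rf_center_um=cell.rf_center_um,
                    preferred_direction_deg=cell.preferred_direction_deg,
                    seed=seed,
                    mean_level=screen.mean_level,
                    cell_index=i * 1009 + k,
                )
                trial_counts.append(s.counts[0, 0, :n_frames])
        all_counts.append(np.stack(trial_counts))
        trial_meta.append({"transform": tf.kind, "offset_axis": tf.offset_axis})
    counts = np.stack(all_counts, axis=1)  # (n_cells, n_trials, n_frames)
    meta = [
        {
            "preferred_direction_deg": c.preferred_direction_deg,
            "rf_center_um": c.rf_center_um,
            "group": c.group,
        }
        for c in cells
    ]
    return SpikeTrainSet(counts, dt, meta, trial_meta)
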