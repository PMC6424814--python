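"""Visual stimulus synthesis.

Generates, bit-reproducibly from a seed, every stimulus class used in the
analyses: smoothed white-noise textures, pink-noise textures, arbitrary
grayscale-image textures, two-dimensional random-walk motion trajectories,
drifting square-wave gratings, checkerboard white noise, full-field flashes
and flicker, and jittering grating patches for object-motion sensitivity
testing.

The central stimulus is a spatially correlated texture that is translated in
a two-dimensional random walk: every 33-ms frame the texture moves by
independent Gaussian steps (SD 22.5 um per component) rounded to the 7.5 um
pixel raster, emulating jitter of the retinal image under fixational eye
movements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .rng import stream
from .screen import DEFAULT_SCREEN, ScreenModel

# Geometry of the standard texture: binary black/white squares of 30 um edge,
# smoothed with an isotropic Gaussian of 60 um SD, contrast scaled by 1.5.
SQUARE_SIZE_UM = 30.0
SMOOTHING_SD_UM = 60.0
CONTRAST_SCALE = 1.5

# Random-walk defaults: Gaussian steps of 22.5 um SD per frame and component,
# quantized to the 7.5 um pixel raster.
STEP_SD_UM = 22.5
STEP_QUANTUM_UM = 7.5

# Temporal filter span used throughout: 24 taps of 33 ms = 800 ms.
FILTER_TAPS = 24


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Texture:
    """A static grayscale texture sampled at ``pitch`` um per texel."""

    luminance: np.ndarray  # (rows, cols)
    pitch: float
    kind: Literal["smoothed_white", "pink", "image"]
    seed: int | None = None

    @property
    def mean(self) -> float:
        return float(self.luminance.mean())

    @property
    def sd(self) -> float:
        return float(self.luminance.std())

    @property
    def extent_um(self) -> tuple[float, float]:
        r, c = self.luminance.shape
        return (r * self.pitch, c * self.pitch)


@dataclass
class MotionTrajectory:
    """Two-dimensional random-walk motion steps.

    ``steps`` holds (dx, dy) in um for each 33-ms frame; every step is an
    integer multiple of ``quantum``.
    """

    steps: np.ndarray  # (n_frames, 2) um
    step_sd: float = STEP_SD_UM
    quantum: float = STEP_QUANTUM_UM
    seed: int | None = None

    @property
    def n_frames(self) -> int:
        return self.steps.shape[0]

    def cumulative(self) -> np.ndarray:
        """Cumulative displacement after each step, (n_frames, 2) um."""
        return np.cumsum(self.steps, axis=0)

    def flipped(self) -> "MotionTrajectory":
        """Trajectory with both step components negated (x/y flip)."""
        return MotionTrajectory(-self.steps, self.step_sd, self.quantum, self.seed)

    def mean_speed_um_per_s(self, frames_per_window: int = 30) -> float:
        """Mean Euclidean displacement over disjoint windows, in um/window.

        With the default 30-frame window this is the net texture displacement
        accumulated per second.
        """
        n = (self.n_frames // frames_per_window) * frames_per_window
        if n == 0:
            return 0.0
        disp = self.steps[:n].reshape(-1, frames_per_window, 2).sum(axis=1)
        return float(np.hypot(disp[:, 0], disp[:, 1]).mean())


@dataclass(frozen=True)
class GratingProtocol:
    """Drifting square-wave grating protocol for direction tuning."""

    spatial_period_um: float = 600.0
    temporal_frequency_hz: float = 0.75
    contrast: float = 1.0
    n_directions: int = 8
    duration_per_direction_s: float = 6.67
    gray_gap_s: float = 1.67
    repeats: int = 5

    @property
    def directions_deg(self) -> np.ndarray:
        return np.arange(self.n_directions) * (360.0 / self.n_directions)


OffsetAxis = Literal["+x", "-x", "+y", "-y"]


@dataclass(frozen=True)
class TrialTransform:
    """Per-trial trajectory/texture transform."""

    kind: Literal["identity", "flip_xy", "offset"]
    offset_axis: OffsetAxis | None = None
    offset_um: float = 1500.0

    def offset_vector(self) -> np.ndarray:
        if self.kind != "offset":
            return np.zeros(2)
        sign = 1.0 if self.offset_axis[0] == "+" else -1.0
        if self.offset_axis[1] == "x":
            return np.array([sign * self.offset_um, 0.0])
        return np.array([0.0, sign * self.offset_um])


@dataclass
class TrialProtocol:
    """Repeated-trial structure with per-trial transforms."""

    transforms: Sequence[TrialTransform]
    trial_duration_s: float

    def __post_init__(self) -> None:
        for t in self.transforms:
            if t.kind == "offset" and t.offset_axis not in ("+x", "-x", "+y", "-y"):
                raise ValueError("offset transform needs offset_axis in {+x,-x,+y,-y}")

    @property
    def n_trials(self) -> int:
        return len(self.transforms)


# ---------------------------------------------------------------------------
# Texture generators
# ---------------------------------------------------------------------------

def _n_texels(extent_um: tuple[float, float], texel_um: float) -> tuple[int, int]:
    w, h = extent_um
    if w < texel_um or h < texel_um:
        raise ValueError(
            f"extent {extent_um} um smaller than one {texel_um} um texel"
        )
    return (math.ceil(h / texel_um), math.ceil(w / texel_um))


def generate_smoothed_texture(
    seed: int,
    extent_um: tuple[float, float] = (3000.0, 3000.0),
    screen: ScreenModel = DEFAULT_SCREEN,
) -> Texture:
    """Standard texture: smoothed binary white noise.

    Binary black/white squares of 30 x 30 um (probability 0.5 each, 100%
    contrast) are convolved with an isotropic Gaussian of 60 um SD; the
    contrast deviations from the mean are then scaled by 1.5 and clipped to
    the displayable range.
    """
    rng = stream(seed, "texture")
    rows, cols = _n_texels(extent_um, SQUARE_SIZE_UM)
    lo, hi = screen.luminance_range
    squares = rng.integers(0, 2, size=(rows, cols)).astype(np.float64)
    squares = squares * (hi - lo) + lo
    up = int(round(SQUARE_SIZE_UM / screen.pixel_pitch))
    grid = np.repeat(np.repeat(squares, up, axis=0), up, axis=1)
    sigma_px = SMOOTHING_SD_UM / screen.pixel_pitch
    smooth = gaussian_filter(grid, sigma=sigma_px, mode="wrap")
    scaled = screen.mean_level + CONTRAST_SCALE * (smooth - screen.mean_level)
    return Texture(np.clip(scaled, lo, hi), screen.pixel_pitch, "smoothed_white", seed)


def generate_pink_texture(
    seed: int,
    extent_um: tuple[float, float] = (3000.0, 3000.0),
    screen: ScreenModel = DEFAULT_SCREEN,
    reference: Texture | None = None,
) -> Texture:
    """Pink-noise texture with a 1/f spatial amplitude spectrum.

    The texture is adjusted to the same mean intensity and SD as the paired
    standard texture (``reference``; generated from the same seed when not
    supplied) before clipping.
    """
    rng = stream(seed, "texture", index=1)
    rows = math.ceil(extent_um[1] / screen.pixel_pitch)
    cols = math.ceil(extent_um[0] / screen.pixel_pitch)
    white = rng.standard_normal((rows, cols))
    fy = np.fft.fftfreq(rows)[:, None]
    fx = np.fft.fftfreq(cols)[None, :]
    f = np.hypot(fy, fx)
    f[0, 0] = np.inf  # zero out DC; mean is set explicitly below
    spectrum = np.fft.fft2(white) / f
    pink = np.fft.ifft2(spectrum).real

    if reference is None:
        reference = generate_smoothed_texture(seed, extent_um, screen)
    pink = (pink - pink.mean()) / pink.std() * reference.sd + reference.mean
    lo, hi = screen.luminance_range
    return Texture(np.clip(pink, lo, hi), screen.pixel_pitch, "pink", seed)


def texture_from_image(
    image: np.ndarray,
    screen: ScreenModel = DEFAULT_SCREEN,
    reference: Texture | None = None,
) -> Texture:
    """Wrap an arbitrary grayscale image array as a texture.

    Color images are converted to grayscale by averaging channels.  When a
    ``reference`` texture is given, mean and SD are matched to it.
    """
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim == 3:
        arr = arr.mean(axis=2)
    if arr.ndim != 2:
        raise ValueError("image must be a 2D grayscale or 3D color array")
    if reference is not None:
        arr = (arr - arr.mean()) / arr.std() * reference.sd + reference.mean
    lo, hi = screen.luminance_range
    return Texture(np.clip(arr, lo, hi), screen.pixel_pitch, "image")


def radial_amplitude_slope(texture: Texture, n_bins: int = 24) -> float:
    """Log-log slope of the radially averaged amplitude spectrum.

    Diagnostic for spectral content: ~ -1 for pink noise.
    """
    amp = np.abs(np.fft.fft2(texture.luminance - texture.luminance.mean()))
    rows, cols = amp.shape
    fy = np.fft.fftfreq(rows)[:, None]
    fx = np.fft.fftfreq(cols)[None, :]
    f = np.hypot(fy, fx).ravel()
    a = amp.ravel()
    # fit over one decade of mid frequencies, away from DC and Nyquist
    mask = (f > 0.01) & (f < 0.25)
    edges = np.geomspace(0.01, 0.25, n_bins + 1)
    idx = np.digitize(f[mask], edges) - 1
    fm, am = f[mask], a[mask]
    centers, means = [], []
    for k in range(n_bins):
        sel = idx == k
        if sel.sum() > 3:
            centers.append(np.exp(np.log(fm[sel]).mean()))
            means.append(am[sel].mean())
    slope = np.polyfit(np.log(centers), np.log(means), 1)[0]
    return float(slope)


# ---------------------------------------------------------------------------
# Motion trajectory
# ---------------------------------------------------------------------------

def quantize_steps(steps: np.ndarray, quantum: float) -> np.ndarray:
    """Round to the nearest multiple of ``quantum``, halves away from zero."""
    scaled = np.asarray(steps) / quantum
    return np.sign(scaled) * np.floor(np.abs(scaled) + 0.5) * quantum


def generate_trajectory(
    seed: int,
    n_frames: int,
    step_sd: float = STEP_SD_UM,
    quantum: float = STEP_QUANTUM_UM,
) -> MotionTrajectory:
    """Two-dimensional random-walk motion steps.

    Independent Gaussian draws of SD ``step_sd`` per frame and component,
    rounded to multiples of ``quantum`` (the pixel raster).  Rounding
    inflates the per-component SD to sqrt(step_sd^2 + quantum^2/12).
    """
    if step_sd <= 0:
        raise ValueError(f"step_sd must be positive, got {step_sd}")
    if n_frames < 0:
        raise ValueError("n_frames must be >= 0")
    rng = stream(seed, "trajectory")
    raw = rng.normal(0.0, step_sd, size=(n_frames, 2))
    return MotionTrajectory(quantize_steps(raw, quantum), step_sd, quantum, seed)


def expected_speed_um_per_s(
    step_sd: float = STEP_SD_UM,
    quantum: float = STEP_QUANTUM_UM,
    frames_per_s: int = 30,
) -> float:
    """Analytic mean 1-s displacement of the quantized random walk.

    The summed displacement over one second is 2D Gaussian with
    per-component SD sqrt(frames) * sigma_r, where the rounded single-step
    SD is sigma_r = sqrt(step_sd^2 + quantum^2/12); its Euclidean norm is
    Rayleigh with mean sigma * sqrt(pi/2).
    """
    sigma_r = math.sqrt(step_sd**2 + quantum**2 / 12.0)
    return math.sqrt(frames_per_s) * sigma_r * math.sqrt(math.pi / 2.0)


# ---------------------------------------------------------------------------
# Movie rendering
# ---------------------------------------------------------------------------

@dataclass
class Movie:
    """A luminance movie at the stimulus update rate."""

    frames: np.ndarray  # (n_frames, rows, cols), float32
    pitch_um: float
    dt_s: float
    seed: int | None = None


class TextureOverflowError(ValueError):
    """Trajectory excursion left the texture extent."""

    def __init__(self, frame: int, msg: str) -> None:
        super().__init__(msg)
        self.frame = frame


def render_moving_texture(
    texture: Texture,
    trajectory: MotionTrajectory,
    screen: ScreenModel = DEFAULT_SCREEN,
    window_um: tuple[float, float] = (600.0, 600.0),
    window_center_um: tuple[float, float] | None = None,
    texture_offset_um: tuple[float, float] = (0.0, 0.0),
) -> Movie:
    """Render the texture translated along a motion trajectory.

    Frame ``t`` (0-based; ``n_frames + 1`` frames in total) shows the texture
    translated by the cumulative sum of steps ``1..t``, sampled through a
    fixed window of ``window_um`` centered on the texture (or on
    ``window_center_um`` in texture coordinates).  Because steps are
    quantized to the pixel raster, translation is an exact integer pixel
    shift; no interpolation is involved.  ``texture_offset_um`` shifts the
    texture layout itself (used by the offset-trial protocol).

    A positive step (dx, dy) moves the texture content rightward/upward on
    the screen; the y axis of the returned arrays points down (row order).
    """
    px = screen.pixel_pitch
    if abs(trajectory.quantum / px - round(trajectory.quantum / px)) > 1e-9:
        raise ValueError("trajectory quantum must be a multiple of the pixel pitch")
    rows_t, cols_t = texture.luminance.shape
    wr = int(round(window_um[1] / px))
    wc = int(round(window_um[0] / px))
    if window_center_um is None:
        center = np.array([cols_t * px / 2.0, rows_t * px / 2.0])
    else:
        center = np.asarray(window_center_um, dtype=float)

    cum = np.vstack([np.zeros(2), trajectory.cumulative()])  # frame 0 unshifted
    shift = cum + np.asarray(texture_offset_um)
    # window origin (top-left) in texture pixels for each frame
    col0 = np.rint((center[0] - wc * px / 2.0 - shift[:, 0]) / px).astype(int)
    # screen-up = decreasing row index
    row0 = np.rint((rows_t * px - (center[1] + wr * px / 2.0 - shift[:, 1])) / px).astype(int)

    frames = np.empty((shift.shape[0], wr, wc), dtype=np.float32)
    for t in range(shift.shape[0]):
        r, c = row0[t], col0[t]
        if r < 0 or c < 0 or r + wr > rows_t or c + wc > cols_t:
            raise TextureOverflowError(
                t, f"frame {t}: window leaves texture extent (row {r}, col {c})"
            )
        frames[t] = texture.luminance[r : r + wr, c : c + wc]
    return Movie(frames, px, screen.frame_dt, trajectory.seed)


# ---------------------------------------------------------------------------
# Probe stimuli
# ---------------------------------------------------------------------------

def _grating_frame(
    shape: tuple[int, int],
    pitch: float,
    angle_deg: float,
    period_um: float,
    phase: float,
    contrast: float,
    mean: float,
) -> np.ndarray:
    rows, cols = shape
    y = (np.arange(rows)[::-1, None] + 0.5) * pitch
    x = (np.arange(cols)[None, :] + 0.5) * pitch
    th = math.radians(angle_deg)
    proj = x * math.cos(th) + y * math.sin(th)
    wave = np.sign(np.sin(2.0 * np.pi * (proj / period_um - phase)))
    return mean * (1.0 + contrast * wave)


def generate_probe_stimuli(
    kind: Literal["grating", "checkerboard", "flash", "flicker", "omsi_patches"],
    params: dict | None = None,
    seed: int = 0,
    screen: ScreenModel = DEFAULT_SCREEN,
):
    """Generate one of the probe stimuli together with its event schedule.

    Returns ``(movie, schedule)`` where ``schedule`` is a list of event dicts
    with ``t_start``/``t_end`` seconds and stimulus-specific keys.

    kinds
    -----
    grating
        Drifting square-wave gratings per :class:`GratingProtocol` (8
        directions x 5 repeats, 6.67 s each, 1.67 s gray gaps).
    checkerboard
        Spatiotemporal binary white noise: 80 x 60 squares of 75 um edge,
        each black or white with probability 0.5, updated at 30 Hz.  The
        movie is returned at square resolution (pitch 75 um).
    flash
        Full-field 500-ms steps of +-40% contrast with 1.5-s gray gaps.
    flicker
        Full-field Gaussian luminance flicker, SD 30% of mean, 30 Hz.
    omsi_patches
        Circular 750-um grating patches on a hexagonal grid, gratings of
        300 um period jittered by +-15 um steps at 30 Hz; segments of
        coherent (shared jitter) and differential (independent jitter)
        motion separated by gray gaps.
    """
    p = dict(params or {})
    rng = stream(seed, "probe")
    dt = screen.frame_dt
    mean = screen.mean_level

    if kind == "grating":
        proto: GratingProtocol = p.get("protocol", GratingProtocol())
        window = p.get("window_um", (600.0, 600.0))
        rows = int(round(window[1] / screen.pixel_pitch))
        cols = int(round(window[0] / screen.pixel_pitch))
        frames_dir = int(round(proto.duration_per_direction_s / dt))
        frames_gap = int(round(proto.gray_gap_s / dt))
        chunks, schedule, t = [], [], 0.0
        for rep in range(proto.repeats):
            for angle in proto.directions_deg:
                seg = np.empty((frames_dir, rows, cols), dtype=np.float32)
                for i in range(frames_dir):
                    phase = proto.temporal_frequency_hz * i * dt
                    seg[i] = _grating_frame(
                        (rows, cols), screen.pixel_pitch, angle,
                        proto.spatial_period_um, phase, proto.contrast, mean,
                    )
                chunks.append(seg)
                schedule.append(
                    {"event": "grating", "direction_deg": float(angle),
                     "repeat": rep, "t_start": t, "t_end": t + frames_dir * dt}
                )
                t += frames_dir * dt
                chunks.append(np.full((frames_gap, rows, cols), mean, np.float32))
                schedule.append({"event": "gray", "t_start": t, "t_end": t + frames_gap * dt})
                t += frames_gap * dt
        movie = Movie(np.concatenate(chunks), screen.pixel_pitch, dt, seed)
        return movie, schedule

    if kind == "checkerboard":
        nx = int(p.get("n_squares_x", 80))
        ny = int(p.get("n_squares_y", 60))
        square_um = float(p.get("square_um", 75.0))
        n_frames = int(p.get("n_frames", int(round(p.get("duration_s", 60.0) / dt))))
        lo, hi = screen.luminance_range
        frames = rng.integers(0, 2, size=(n_frames, ny, nx)).astype(np.float32)
        frames = frames * (hi - lo) + lo
        movie = Movie(frames, square_um, dt, seed)
        return movie, [{"event": "checkerboard", "t_start": 0.0, "t_end": n_frames * dt}]

    if kind == "flash":
        step = float(p.get("contrast_step", 0.4))
        n_cycles = int(p.get("n_cycles", 20))
        flash_s, gap_s = 0.5, 1.5
        f_flash = int(round(flash_s / dt))
        f_gap = int(round(gap_s / dt))
        vals, schedule, t = [], [], 0.0
        for c in range(n_cycles):
            for polarity in (+1, -1):
                vals.extend([mean * (1 + polarity * step)] * f_flash)
                schedule.append(
                    {"event": "flash_on" if polarity > 0 else "flash_off",
                     "t_start": t, "t_end": t + f_flash * dt}
                )
                t += f_flash * dt
                vals.extend([mean] * f_gap)
                t += f_gap * dt
        frames = np.asarray(vals, np.float32)[:, None, None]
        return Movie(frames, screen.pixel_pitch, dt, seed), schedule

    if kind == "flicker":
        n_frames = int(p.get("n_frames", int(round(p.get("duration_s", 300.0) / dt))))
        sd = float(p.get("sd_fraction", 0.3)) * mean
        lo, hi = screen.luminance_range
        vals = np.clip(rng.normal(mean, sd, size=n_frames), lo, hi)
        frames = vals.astype(np.float32)[:, None, None]
        return (
            Movie(frames, screen.pixel_pitch, dt, seed),
            [{"event": "flicker", "t_start": 0.0, "t_end": n_frames * dt}],
        )

    if kind == "omsi_patches":
        window = p.get("window_um", (1500.0, 1500.0))
        patch_d = float(p.get("patch_diameter_um", 750.0))
        period = float(p.get("grating_period_um", 300.0))
        jitter = float(p.get("jitter_um", 15.0))
        seg_s = float(p.get("segment_s", 23.33))
        gap_s = float(p.get("gray_gap_s", 1.67))
        n_repeats = int(p.get("repeats", 1))
        rows = int(round(window[1] / screen.pixel_pitch))
        cols = int(round(window[0] / screen.pixel_pitch))
        y = (np.arange(rows)[::-1, None] + 0.5) * screen.pixel_pitch
        x = (np.arange(cols)[None, :] + 0.5) * screen.pixel_pitch
        # hexagonal patch centers covering the window
        centers = []
        pitch_h = patch_d
        pitch_v = patch_d * math.sqrt(3) / 2.0
        nrow = int(window[1] / pitch_v) + 2
        ncol = int(window[0] / pitch_h) + 2
        for i in range(nrow):
            for j in range(ncol):
                cx = j * pitch_h + (i % 2) * pitch_h / 2.0
                cy = i * pitch_v
                centers.append((cx, cy))
        masks = [
            (x - cx) ** 2 + (y - cy) ** 2 <= (patch_d / 2.0) ** 2
            for cx, cy in centers
        ]
        f_seg = int(round(seg_s / dt))
        f_gap = int(round(gap_s / dt))
        chunks, schedule, t = [], [], 0.0
        for rep in range(n_repeats):
            for mode in ("coherent", "differential"):
                if mode == "coherent":
                    shared = rng.choice([-jitter, jitter], size=f_seg)
                    offsets = np.tile(np.cumsum(shared), (len(centers), 1))
                else:
                    steps = rng.choice([-jitter, jitter], size=(len(centers), f_seg))
                    offsets = np.cumsum(steps, axis=1)
                seg = np.full((f_seg, rows, cols), mean, np.float32)
                for i in range(f_seg):
                    frame = np.full((rows, cols), mean, np.float64)
                    for m, mask in enumerate(masks):
                        wave = np.broadcast_to(
                            np.sign(np.sin(2 * np.pi * (x + offsets[m, i]) / period)),
                            (rows, cols),
                        )
                        frame[mask] = mean * (1.0 + wave[mask])
                    seg[i] = frame
                chunks.append(seg)
                schedule.append(
                    {"event": mode, "repeat": rep, "t_start": t,
                     "t_end": t + f_seg * dt, "offsets_um": offsets}
                )
                t += f_seg * dt
                chunks.append(np.full((f_gap, rows, cols), mean, np.float32))
                schedule.append({"event": "gray", "t_start": t, "t_end": t + f_gap * dt})
                t += f_gap * dt
        return Movie(np.concatenate(chunks), screen.pixel_pitch, dt, seed), schedule

    raise ValueError(f"unknown probe stimulus kind {kind!r}")
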