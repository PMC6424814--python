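"""Identification of standard direction-selective cells.

Classification follows the probe-stimulus battery: direction tuning to
drifting gratings (direction-selectivity index, DSI), object-motion
sensitivity (OMSI) from coherently vs differentially jittering grating
patches, receptive fields from checkerboard white noise (spike-triggered
average factorized by SVD, spatial component fitted with a 2D Gaussian),
and contrast tuning from full-field flashes and Gaussian flicker.

A standard (global-motion) direction-selective cell satisfies DSI > 0.3
with a grating firing rate above 1 Hz, and OMSI < 0.7 with an adequate rate
under the patch stimulus.  Preferred directions are expressed in the
retinal convention (angle from the nasal direction, counterclockwise
positive for the left eye) and grouped into the three 120-degree sectors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .cells import direction_group
from .stimulus import Movie

DT = 1.0 / 30.0


# ---------------------------------------------------------------------------
# Direction tuning
# ---------------------------------------------------------------------------

@dataclass
class DirectionTuning:
    angles_deg: np.ndarray
    counts: np.ndarray
    dsi: float
    preferred_angle_deg: float


def compute_dsi(
    counts_by_direction: np.ndarray, angles_deg: Sequence[float] | None = None
) -> DirectionTuning:
    """Vector-sum direction-selectivity index.

    DSI = |sum_theta f_theta e^{i theta}| / sum_theta f_theta, with the
    preferred angle given by the argument of the complex sum.
    """
    counts = np.asarray(counts_by_direction, dtype=float)
    if angles_deg is None:
        angles_deg = np.arange(counts.size) * (360.0 / counts.size)
    angles = np.asarray(angles_deg, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("DSI undefined: all direction counts are zero")
    z = np.sum(counts * np.exp(1j * np.radians(angles)))
    dsi = float(abs(z) / total)
    angle = math.degrees(np.angle(z)) % 360.0
    return DirectionTuning(angles, counts, dsi, angle)


def grating_direction_counts(
    counts: np.ndarray,
    schedule: Sequence[dict],
    dt: float = DT,
    skip_onset_s: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-direction spike counts from a grating run.

    The onset response (first second of each direction presentation) is
    excluded.  Returns (angles, counts, mean_rate_hz over grating periods).
    """
    by_dir: dict[float, float] = {}
    total_spikes = 0.0
    total_time = 0.0
    for ev in schedule:
        if ev["event"] != "grating":
            continue
        i0 = int(round((ev["t_start"] + skip_onset_s) / dt))
        i1 = int(round(ev["t_end"] / dt))
        c = float(counts[i0:i1].sum())
        by_dir[ev["direction_deg"]] = by_dir.get(ev["direction_deg"], 0.0) + c
        j0 = int(round(ev["t_start"] / dt))
        total_spikes += float(counts[j0:i1].sum())
        total_time += (i1 - j0) * dt
    angles = np.array(sorted(by_dir))
    vals = np.array([by_dir[a] for a in angles])
    rate = total_spikes / total_time if total_time > 0 else 0.0
    return angles, vals, rate


def compute_omsi(coherent_count: float, differential_count: float) -> float:
    """Object-motion-sensitivity index (f_d - f_c) / (f_d + f_c)."""
    fc, fd = float(coherent_count), float(differential_count)
    if fc < 0 or fd < 0:
        raise ValueError("counts must be non-negative")
    if fc + fd == 0:
        raise ValueError("OMSI undefined: no spikes in either condition")
    return (fd - fc) / (fd + fc)


def omsi_condition_counts(
    counts: np.ndarray, schedule: Sequence[dict], dt: float = DT
) -> tuple[float, float, float]:
    """(coherent, differential) spike counts and mean rate from a patch run."""
    fc = fd = 0.0
    total_time = 0.0
    for ev in schedule:
        i0 = int(round(ev["t_start"] / dt))
        i1 = int(round(ev["t_end"] / dt))
        c = float(counts[i0:i1].sum())
        if ev["event"] == "coherent":
            fc += c
            total_time += (i1 - i0) * dt
        elif ev["event"] == "differential":
            fd += c
            total_time += (i1 - i0) * dt
    rate = (fc + fd) / total_time if total_time > 0 else 0.0
    return fc, fd, rate


# ---------------------------------------------------------------------------
# Receptive fields from checkerboard noise
# ---------------------------------------------------------------------------

@dataclass
class ReceptiveFieldFit:
    spatial_sta: np.ndarray
    temporal_sta: np.ndarray
    center_um: tuple[float, float]
    sds_um: tuple[float, float]
    orientation_deg: float
    polarity: int  # +1 ON-dominated, -1 OFF-dominated
    reliable: bool
    excluded: bool = False

    def ellipse_points(self, n: int = 100, n_sd: float = 1.5) -> np.ndarray:
        """Points on the n_sd-SD contour of the Gaussian fit, (n, 2) um."""
        t = np.linspace(0, 2 * np.pi, n)
        th = math.radians(self.orientation_deg)
        sx, sy = self.sds_um
        x = n_sd * sx * np.cos(t)
        y = n_sd * sy * np.sin(t)
        xr = x * math.cos(th) - y * math.sin(th) + self.center_um[0]
        yr = x * math.sin(th) + y * math.cos(th) + self.center_um[1]
        return np.column_stack([xr, yr])


def rf_distance_um(fit_a: ReceptiveFieldFit, fit_b: ReceptiveFieldFit) -> float:
    """Euclidean distance between fitted receptive field centers."""
    (xa, ya), (xb, yb) = fit_a.center_um, fit_b.center_um
    return math.hypot(xa - xb, ya - yb)


def _gauss2d(coords, amp, x0, y0, sx, sy, theta, offset):
    x, y = coords
    ct, st = np.cos(theta), np.sin(theta)
    xr = (x - x0) * ct + (y - y0) * st
    yr = -(x - x0) * st + (y - y0) * ct
    return offset + amp * np.exp(-(xr**2 / (2 * sx**2) + yr**2 / (2 * sy**2)))


def estimate_receptive_field(
    movie: Movie,
    counts: np.ndarray,
    window_taps: int = 15,
    min_rate_hz: float = 0.3,
    reliability_sds: float = 4.0,
) -> ReceptiveFieldFit:
    """Receptive field from checkerboard white noise.

    Computes the spatiotemporal STA over a trailing ``window_taps``-frame
    window (500 ms by default), factorizes it into spatial x temporal
    components by SVD, auto-detects polarity, and fits the spatial
    component with a 2D Gaussian.  Cells below ``min_rate_hz`` are flagged
    excluded without a fit; spatially structureless STAs (peak below
    ``reliability_sds`` map SDs) are flagged unreliable.
    """
    counts = np.asarray(counts, dtype=float)
    frames = movie.frames.astype(np.float64)
    n = min(frames.shape[0], counts.shape[0])
    rate = counts[:n].sum() / (n * movie.dt_s)
    rows, cols = frames.shape[1:]
    if rate < min_rate_hz:
        return ReceptiveFieldFit(
            np.zeros((rows, cols)), np.zeros(window_taps), (np.nan, np.nan),
            (np.nan, np.nan), 0.0, 0, False, excluded=True,
        )
    dev = frames[:n] - frames[:n].mean()
    L = window_taps
    sta = np.zeros((L, rows, cols))
    spike_bins = np.nonzero(counts[:n])[0]
    spike_bins = spike_bins[spike_bins >= L]
    n_spk = counts[spike_bins].sum()
    for lag in range(L):
        # tap `lag` is chronological: lag 0 oldest (L frames before the bin)
        sta[lag] = np.tensordot(
            counts[spike_bins], dev[spike_bins - L + 1 + lag], axes=1
        ) / n_spk
    flat = sta.reshape(L, -1)
    U, sv, Vt = np.linalg.svd(flat, full_matrices=False)
    temporal, spatial = U[:, 0] * sv[0], Vt[0].reshape(rows, cols)
    # polarity: sign of the extremal spatial weight; flip so the spatial
    # lobe is positive for fitting
    peak_idx = np.unravel_index(np.argmax(np.abs(spatial)), spatial.shape)
    polarity = int(np.sign(spatial[peak_idx] * temporal[np.argmax(np.abs(temporal))]))
    if spatial[peak_idx] < 0:
        spatial, temporal = -spatial, -temporal
    sd_map = spatial.std()
    reliable = bool(np.abs(spatial[peak_idx]) >= reliability_sds * sd_map)
    px = movie.pitch_um
    y = (np.arange(rows)[::-1] + 0.5) * px
    x = (np.arange(cols) + 0.5) * px
    X, Y = np.meshgrid(x, y)
    p0 = [
        float(spatial[peak_idx]), float(X[peak_idx]), float(Y[peak_idx]),
        2 * px, 2 * px, 0.0, float(np.median(spatial)),
    ]
    try:
        popt, _ = curve_fit(
            _gauss2d, (X.ravel(), Y.ravel()), spatial.ravel(), p0=p0, maxfev=5000
        )
        amp, x0, y0, sx, sy, theta, _ = popt
        sx, sy = abs(sx), abs(sy)
    except RuntimeError:
        x0, y0, sx, sy, theta = p0[1], p0[2], p0[3], p0[4], 0.0
        reliable = False
    return ReceptiveFieldFit(
        spatial, temporal, (float(x0), float(y0)), (float(sx), float(sy)),
        math.degrees(theta) % 180.0, polarity, reliable,
    )


# ---------------------------------------------------------------------------
# Contrast tuning
# ---------------------------------------------------------------------------

@dataclass
class ContrastIndices:
    flash_onoff: float | None
    flicker_onoff: float | None
    flash_included: bool
    flicker_included: bool


def contrast_indices(
    flash_counts: np.ndarray,
    flash_schedule: Sequence[dict],
    flicker_values: np.ndarray,
    flicker_counts: np.ndarray,
    dt: float = DT,
    sta_taps: int = 24,
) -> ContrastIndices:
    """ON-OFF indices from full-field flashes and Gaussian flicker.

    Flash index: (f_on - f_off)/(f_on + f_off) from counts 50-550 ms after
    each flash onset; requires a mean rate of at least 1 Hz.  Flicker
    index: sum of the last 200 ms of the luminance STA normalized by the
    summed absolute values in that range (-1 pure OFF, +1 pure ON);
    requires an STA peak at least 7 tail SDs (tail = 800-500 ms pre-spike).
    """
    counts = np.asarray(flash_counts, dtype=float)
    fon = foff = 0.0
    total_t = 0.0
    for ev in flash_schedule:
        if ev["event"] not in ("flash_on", "flash_off"):
            continue
        i0 = int(round((ev["t_start"] + 0.05) / dt))
        i1 = int(round((ev["t_start"] + 0.55) / dt))
        c = float(counts[i0:i1].sum())
        if ev["event"] == "flash_on":
            fon += c
        else:
            foff += c
        total_t += 0.5
    if total_t == 0:
        raise ValueError("flash schedule contains no flash events")
    flash_rate = (fon + foff) / total_t
    flash_included = flash_rate >= 1.0
    flash_idx = (fon - foff) / (fon + foff) if (fon + foff) > 0 else None

    vals = np.asarray(flicker_values, dtype=float)
    fc = np.asarray(flicker_counts, dtype=float)
    n = min(vals.size, fc.size)
    dev = vals[:n] - vals[:n].mean()
    L = sta_taps
    sta = np.zeros(L)
    spikes = fc[:n].copy()
    spikes[: L - 1] = 0
    tot = spikes.sum()
    if tot > 0:
        # trailing window t-L+1..t: the last tap is the spike's own frame
        for lag in range(L):
            sta[lag] = np.dot(spikes[L - 1 :], dev[lag : n - L + 1 + lag]) / tot
    # chronological taps: last 6 (200 ms) closest to the spike
    n200 = int(round(0.2 / dt))
    head = sta[-n200:]
    tail = sta[: int(round(0.3 / dt))]  # 800 to 500 ms pre-spike
    denom = np.abs(head).sum()
    flicker_idx = float(head.sum() / denom) if denom > 0 else None
    peak = np.abs(sta).max()
    flicker_included = bool(tail.std() > 0 and peak >= 7.0 * tail.std())
    return ContrastIndices(flash_idx, flicker_idx, flash_included, flicker_included)


# ---------------------------------------------------------------------------
# Cell classification
# ---------------------------------------------------------------------------

Label = Literal["standard_DS", "object_motion_DS", "non_DS", "unclassified"]


@dataclass
class CellClassification:
    label: Label
    group: str | None
    reason: str = ""


def classify_cell(
    dsi: float,
    grating_rate_hz: float,
    omsi: float | None,
    omsi_rate_hz: float | None,
    preferred_angle_deg: float,
    eye: Literal["left", "right"] = "left",
) -> CellClassification:
    """Label a cell as standard DS, object-motion DS, or non-DS.

    Standard DS requires DSI > 0.3, grating rate > 1 Hz, OMSI < 0.7 and a
    patch-stimulus rate > 1 Hz.  The preferred-direction group uses the
    retinal angle convention: for the right eye the angle sign is mirrored.
    """
    if not (dsi > 0.3 and grating_rate_hz > 1.0):
        return CellClassification("non_DS", None)
    if omsi is None or omsi_rate_hz is None:
        return CellClassification(
            "unclassified", None, reason="OMSI unavailable for a DS cell"
        )
    if omsi_rate_hz <= 1.0:
        return CellClassification(
            "unclassified", None, reason="patch-stimulus rate too low for OMSI"
        )
    angle = preferred_angle_deg % 360.0
    if eye == "right":
        angle = (-angle) % 360.0
    if omsi >= 0.7:
        return CellClassification("object_motion_DS", direction_group(angle))
    return CellClassification("standard_DS", direction_group(angle))
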