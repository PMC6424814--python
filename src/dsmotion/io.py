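"""Plain-text and HDF5 I/O for trajectories, spikes, filters and reports.

Formats
-------
Trajectory: CSV with header ``frame,dx_um,dy_um``, one row per frame,
0-based frame index; round-trips bit-exactly.

Spikes: CSV with header ``cell_id,trial,spike_time_s``; readers tolerate
unsorted rows and sort them (with a warning).

Decoder filters: CSV ``cell_id,axis,tap,coef`` plus offset rows
(``cell_id = -1``).

Movies: HDF5 container with dataset ``frames`` and attributes ``pitch_um``,
``dt_s``, ``seed``.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .decoding import DecoderFilters
from .stimulus import MotionTrajectory, Movie


def write_trajectory(trajectory: MotionTrajectory, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "frame": np.arange(trajectory.n_frames),
            "dx_um": trajectory.steps[:, 0],
            "dy_um": trajectory.steps[:, 1],
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_trajectory(
    path: str | Path, step_sd: float = 22.5, quantum: float = 7.5
) -> MotionTrajectory:
    df = pd.read_csv(path)
    required = {"frame", "dx_um", "dy_um"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    df = df.sort_values("frame")
    steps = df[["dx_um", "dy_um"]].to_numpy(dtype=float)
    return MotionTrajectory(steps, step_sd, quantum)


def write_spikes(spike_times: dict[tuple[int, int], np.ndarray], path: str | Path) -> None:
    """Write per-(cell, trial) spike-time arrays to a sorted CSV table."""
    rows = []
    for (cell, trial), times in sorted(spike_times.items()):
        for t in np.sort(np.asarray(times, dtype=float)):
            rows.append((cell, trial, t))
    pd.DataFrame(rows, columns=["cell_id", "trial", "spike_time_s"]).to_csv(
        path, index=False, float_format="%.9f"
    )


def read_spikes(path: str | Path) -> dict[tuple[int, int], np.ndarray]:
    df = pd.read_csv(path)
    required = {"cell_id", "trial", "spike_time_s"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    out: dict[tuple[int, int], np.ndarray] = {}
    for (cell, trial), grp in df.groupby(["cell_id", "trial"]):
        times = grp["spike_time_s"].to_numpy(dtype=float)
        if np.any(np.diff(times) < 0):
            warnings.warn(f"{path}: unsorted spike times; sorting", stacklevel=2)
            times = np.sort(times)
        out[(int(cell), int(trial))] = times
    return out


def bin_spike_times(times: np.ndarray, n_frames: int, dt: float) -> np.ndarray:
    """Frame-binned counts using the interval convention [t*dt, (t+1)*dt)."""
    idx = np.floor(np.asarray(times, dtype=float) / dt).astype(int)
    idx = idx[(idx >= 0) & (idx < n_frames)]
    return np.bincount(idx, minlength=n_frames)


def write_decoder_filters(filters: DecoderFilters, path: str | Path) -> None:
    rows = []
    axes = filters.B.shape[1]
    for ax in range(axes):
        rows.append((-1, "xy"[ax], -1, filters.B[0, ax]))
        for cell in range(filters.n_cells):
            for tap, coef in enumerate(filters.cell_filter(cell, ax)):
                rows.append((cell, "xy"[ax], tap, coef))
    pd.DataFrame(rows, columns=["cell_id", "axis", "tap", "coef"]).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_decoder_filters(path: str | Path) -> DecoderFilters:
    df = pd.read_csv(path)
    axes = sorted(df["axis"].unique())
    n_cells = int(df["cell_id"].max()) + 1
    L = int(df[df["cell_id"] >= 0]["tap"].max()) + 1
    B = np.zeros((1 + n_cells * L, len(axes)))
    for ai, ax in enumerate(axes):
        sub = df[df["axis"] == ax]
        off = sub[sub["cell_id"] == -1]
        B[0, ai] = float(off["coef"].iloc[0])
        body = sub[sub["cell_id"] >= 0].sort_values(["cell_id", "tap"])
        B[1:, ai] = body["coef"].to_numpy(dtype=float)
    return DecoderFilters(B, L, n_cells)


def write_movie(movie: Movie, path: str | Path) -> None:
    with h5py.File(path, "w") as h:
        d = h.create_dataset("frames", data=movie.frames, compression="gzip")
        d.attrs["pitch_um"] = movie.pitch_um
        d.attrs["dt_s"] = movie.dt_s
        if movie.seed is not None:
            d.attrs["seed"] = movie.seed


def read_movie(path: str | Path) -> Movie:
    with h5py.File(path, "r") as h:
        d = h["frames"]
        seed = int(d.attrs["seed"]) if "seed" in d.attrs else None
        return Movie(d[...], float(d.attrs["pitch_um"]), float(d.attrs["dt_s"]), seed)


def write_report(report: dict, path: str | Path) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(report, indent=2, default=default) + "\n")


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
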