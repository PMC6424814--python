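"""Spectral information bounds, information ratios, response correlations.

The reconstruction quality of the linear decoder is quantified by a spectral
lower bound on the mutual information between the stimulus trajectory S and
its reconstruction U.  Because the motion steps are Gaussian and the
reconstruction error e = s - u is approximately Gaussian, the information
density in each frequency band is bounded below by log2(P^s / P^e), where
P^s and P^e are the one-sided power spectra of non-overlapping 800-ms
stimulus and error segments.  Summing the densities over bands and over the
independent x and y axes gives a lower bound on the total rate in bits/s.

The information ratio I_pop / sum_k I_k compares the information of a joint
population reconstruction to the summed single-cell informations: values
above one indicate synergy, below one redundancy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .stimulus import FILTER_TAPS

DT = 1.0 / 30.0

#: Pairs whose summed single-cell information falls below this rate are
#: excluded from ratio analyses (their ratios are dominated by noise).
ELIGIBILITY_THRESHOLD_BITS_S = 0.1


@dataclass
class InfoSpectrum:
    """Per-frequency information density and the summed total rate."""

    freqs_hz: np.ndarray  # L/2 + 1 bands
    density: np.ndarray  # (n_axes, n_bands) bits/s/Hz (clipped at 0)
    Ps: np.ndarray  # (n_axes, n_bands) one-sided stimulus power
    Pe: np.ndarray  # (n_axes, n_bands) one-sided error power
    segment_taps: int
    dt: float
    n_segments: int
    unbounded: bool = False  # some band had zero error power

    @property
    def total_rate(self) -> float:
        """Total information in bits/s, summed over bands and axes."""
        return float(self.density.sum() / (self.segment_taps * self.dt))

    @property
    def per_axis_rate(self) -> np.ndarray:
        return self.density.sum(axis=1) / (self.segment_taps * self.dt)


def _one_sided_power(segments: np.ndarray) -> np.ndarray:
    """Mean one-sided power over segments: P_j = <|F_j|^2 + |F_-j|^2>."""
    F = np.fft.rfft(segments, axis=1)
    P = np.abs(F) ** 2
    L = segments.shape[1]
    # interior bands gain the mirrored negative frequency
    last = P.shape[1] - 1 if L % 2 == 0 else P.shape[1]
    P[:, 1:last] *= 2.0
    return P.mean(axis=0)


def info_lower_bound(
    stimulus: np.ndarray,
    reconstruction: np.ndarray,
    segment_taps: int = FILTER_TAPS,
    dt: float = DT,
) -> InfoSpectrum:
    """Spectral lower bound on I(S; U) from test-block segments.

    ``stimulus`` and ``reconstruction`` are aligned (T,) or (T, d) arrays.
    Each axis is processed independently: signals are split into
    non-overlapping segments of ``segment_taps`` frames (no tapering), the
    one-sided power spectra of stimulus and error segments are averaged
    over segments, and the per-band density log2(Ps/Pe) is summed.  Bands
    where finite sampling makes Pe exceed Ps contribute zero (clipping
    keeps the estimate a conservative lower bound).
    """
    s = np.asarray(stimulus, dtype=float)
    u = np.asarray(reconstruction, dtype=float)
    if s.ndim == 1:
        s = s[:, None]
    if u.ndim == 1:
        u = u[:, None]
    if s.shape != u.shape:
        raise ValueError("stimulus and reconstruction must be aligned")
    L = segment_taps
    n_seg = s.shape[0] // L
    if n_seg < 2:
        raise ValueError("test block must cover at least 2 segments")
    n_axes = s.shape[1]
    n_bands = L // 2 + 1
    density = np.zeros((n_axes, n_bands))
    Ps_all = np.zeros((n_axes, n_bands))
    Pe_all = np.zeros((n_axes, n_bands))
    unbounded = False
    for ax in range(n_axes):
        sa = s[: n_seg * L, ax] - s[:, ax].mean()
        ea = (s[:, ax] - u[:, ax])[: n_seg * L]
        ea = ea - (s[:, ax] - u[:, ax]).mean()
        Ps = _one_sided_power(sa.reshape(n_seg, L))
        Pe = _one_sided_power(ea.reshape(n_seg, L))
        with np.errstate(divide="ignore", invalid="ignore"):
            d = np.log2(np.where(Pe > 0, Ps / np.maximum(Pe, 1e-300), np.inf))
        if np.any(Pe == 0):
            unbounded = True
            d = np.where(Pe == 0, 0.0, d)
        density[ax] = np.clip(d, 0.0, None)
        Ps_all[ax], Pe_all[ax] = Ps, Pe
    freqs = np.arange(n_bands) / (L * dt)
    return InfoSpectrum(
        freqs, density, Ps_all, Pe_all, L, dt, n_seg, unbounded
    )


@dataclass
class InfoRatioResult:
    """Population vs summed single-cell information."""

    i_pop: float
    i_singles: list[float]
    eligible: bool = field(init=False)
    ratio: float | None = field(init=False)

    def __post_init__(self) -> None:
        total = float(np.sum(self.i_singles))
        self.eligible = total >= ELIGIBILITY_THRESHOLD_BITS_S
        self.ratio = self.i_pop / total if self.eligible else None

    @property
    def label(self) -> str:
        if not self.eligible:
            return "ineligible"
        return "synergy" if self.ratio > 1.0 else "redundancy"


def info_ratio(
    stimulus: np.ndarray,
    population_recon: np.ndarray,
    single_recons: Sequence[np.ndarray],
    segment_taps: int = FILTER_TAPS,
    dt: float = DT,
) -> InfoRatioResult:
    """I_pop / sum_k I_k on a common test block."""
    i_pop = info_lower_bound(stimulus, population_recon, segment_taps, dt).total_rate
    singles = [
        info_lower_bound(stimulus, u, segment_taps, dt).total_rate
        for u in single_recons
    ]
    return InfoRatioResult(i_pop, singles)


@dataclass
class CorrelationResult:
    r: float
    pairing: Literal["same_trial", "shuffled", "offset"]
    n: int


def response_correlation(
    counts_i: np.ndarray,
    counts_j: np.ndarray,
    pairing: Literal["same_trial", "shuffled", "offset"] = "same_trial",
) -> CorrelationResult:
    """Pearson correlation of two frame-binned count sequences."""
    ci = np.asarray(counts_i, dtype=float)
    cj = np.asarray(counts_j, dtype=float)
    if ci.shape != cj.shape:
        raise ValueError("count sequences must have equal length")
    if ci.std() == 0 or cj.std() == 0:
        raise ValueError("correlation undefined for a zero-variance sequence")
    return CorrelationResult(float(np.corrcoef(ci, cj)[0, 1]), pairing, ci.size)


def paired_stats(
    samples: np.ndarray,
    null_value: float | None = None,
    second_condition: np.ndarray | None = None,
):
    """Wilcoxon signed-rank test against a null value or between conditions.

    Returns the scipy result object (statistic, pvalue).
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 6:
        raise ValueError("need at least 6 samples for the signed-rank test")
    if second_condition is not None:
        y = np.asarray(second_condition, dtype=float)
        diffs = x - y
    elif null_value is not None:
        diffs = x - null_value
    else:
        raise ValueError("provide null_value or second_condition")
    if np.all(diffs == 0):
        import warnings
        from collections import namedtuple

        warnings.warn("all differences are zero; test degenerate", stacklevel=2)
        return namedtuple("WilcoxonResult", "statistic pvalue")(0.0, 1.0)
    return stats.wilcoxon(diffs)
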