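"""Canonical correlation analysis of stimulus-response segment pairs.

Links 2-s motion-trajectory segments to the paired 2-s spike-count segments
of a two-cell ensemble.  The cross-covariance between stimulus segments and
response segments is whitened on the stimulus side by the exact sigma^2 *
identity covariance of the white motion steps, and on the response side by
the symmetric inverse square root of the (shrinkage-regularized) response
covariance; the SVD of the whitened cross-covariance then yields ordered
pairs of stimulus components, response components and canonical
correlations.  The Pearson correlation between the two cells' halves of a
response component reveals whether the motion feature is carried by
correlated or anti-correlated firing of the pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DT = 1.0 / 30.0


@dataclass(frozen=True)
class CCAConfig:
    """Segment length and reporting defaults."""

    segment_taps: int = 60  # 2 s at 30 Hz
    n_components_reported: int = 5
    shrinkage: float = 1e-3  # Cf ridge as a fraction of tr(Cf)/dim


def build_cca_matrices(
    steps: np.ndarray,
    counts_pair: np.ndarray,
    config: CCAConfig = CCAConfig(),
) -> tuple[np.ndarray, np.ndarray]:
    """Sliding 2-s windows of stimulus and paired two-cell response.

    Returns (S_seg, F_seg), each with 2*L~ columns: x steps then y steps;
    cell-1 counts then cell-2 counts.  Rows overlap with stride one frame.
    """
    steps = np.asarray(steps, dtype=float)
    counts = np.atleast_2d(np.asarray(counts_pair, dtype=float))
    if counts.shape[0] != 2:
        raise ValueError("CCA is defined for exactly two cells")
    if counts.shape[1] != steps.shape[0]:
        raise ValueError("steps and counts are misaligned")
    Lt = config.segment_taps
    if steps.shape[0] < Lt + 2:
        raise ValueError("recording shorter than one segment")
    s_win = sliding_window_view(steps, Lt, axis=0)  # (n, 2, Lt)
    S = s_win.reshape(s_win.shape[0], -1)
    f_win = [sliding_window_view(counts[i], Lt) for i in range(2)]
    F = np.concatenate(f_win, axis=1)
    return np.ascontiguousarray(S), np.ascontiguousarray(F)


@dataclass
class CCAResults:
    """Ordered stimulus/response components and canonical correlations."""

    stim_components: np.ndarray  # (2*Lt, k) columns a~_k
    resp_components: np.ndarray  # (2*Lt, k) columns b~_k
    rhos: np.ndarray  # descending canonical correlations
    segment_taps: int
    dt: float = DT

    def component_response_correlation(self, k: int) -> float:
        """Pearson r between the two cells' halves of response component k."""
        b = self.resp_components[:, k]
        Lt = self.segment_taps
        h1, h2 = b[:Lt], b[Lt:]
        if h1.std() == 0 or h2.std() == 0:
            raise ValueError("zero-variance component half")
        return float(np.corrcoef(h1, h2)[0, 1])

    @property
    def resp_corrs(self) -> np.ndarray:
        return np.array(
            [self.component_response_correlation(k) for k in range(len(self.rhos))]
        )

    def summary(self, n: int = 5) -> str:
        n = min(n, len(self.rhos))
        lines = [
            "Stimulus-response CCA",
            "=" * 40,
            f"segment length: {self.segment_taps} frames"
            f" ({self.segment_taps * self.dt:.2f} s)",
            "  k    rho    resp_corr",
        ]
        for k in range(n):
            lines.append(
                f"  {k + 1}  {self.rhos[k]:.3f}   "
                f"{self.component_response_correlation(k):+.3f}"
            )
        return "\n".join(lines)


def _inv_sqrt_psd(M: np.ndarray) -> np.ndarray:
    w, V = np.linalg.eigh(M)
    w = np.clip(w, 1e-12, None)
    return (V / np.sqrt(w)) @ V.T


def run_cca(
    S_seg: np.ndarray,
    F_seg: np.ndarray,
    config: CCAConfig = CCAConfig(),
) -> CCAResults:
    """Whitened-SVD canonical correlation analysis.

    The stimulus covariance is taken as its exact form sigma^2 * I (the
    motion steps are white), with sigma^2 the mean empirical column
    variance; the response covariance receives shrinkage
    ``Cf + lambda * tr(Cf)/dim * I`` before inversion.  Component signs are
    fixed by making the largest-magnitude element of each stimulus
    component positive.
    """
    S = S_seg - S_seg.mean(axis=0)
    F = F_seg - F_seg.mean(axis=0)
    n = S.shape[0]
    Csf = S.T @ F / n
    sigma2 = float(S.var(axis=0).mean())
    if sigma2 <= 0:
        raise ValueError("degenerate stimulus segments")
    Cf = F.T @ F / n
    lam = config.shrinkage * np.trace(Cf) / Cf.shape[0]
    Cf_reg = Cf + lam * np.eye(Cf.shape[0])
    Cf_isqrt = _inv_sqrt_psd(Cf_reg)
    C = Csf / np.sqrt(sigma2) @ Cf_isqrt
    U, D, Vt = np.linalg.svd(C, full_matrices=False)
    A = U / np.sqrt(sigma2)  # stimulus components a~_k
    B = Cf_isqrt @ Vt.T  # response components b~_k
    # sign convention: largest |element| of each stimulus component positive
    for k in range(A.shape[1]):
        j = np.argmax(np.abs(A[:, k]))
        if A[j, k] < 0:
            A[:, k] *= -1
            B[:, k] *= -1
    rhos = np.clip(D, 0.0, 1.0)
    Lt = S.shape[1] // 2
    return CCAResults(A, B, rhos, Lt)


class MotionCCA:
    """Model object: CCA of a trajectory and a two-cell response.

    >>> res = MotionCCA(trajectory.steps, counts_pair).fit()   # doctest: +SKIP
    >>> res.rhos[0], res.component_response_correlation(0)     # doctest: +SKIP
    """

    def __init__(
        self,
        steps: np.ndarray,
        counts_pair: np.ndarray,
        config: CCAConfig = CCAConfig(),
    ):
        self.config = config
        self.S_seg, self.F_seg = build_cca_matrices(steps, counts_pair, config)

    def fit(self) -> CCAResults:
        return run_cca(self.S_seg, self.F_seg, self.config)
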