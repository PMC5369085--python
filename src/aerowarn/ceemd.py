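"""Empirical mode decomposition and its complementary-ensemble variant.

EMD adaptively splits a nonlinear, nonstationary signal into a small
set of intrinsic mode functions (IMFs) — oscillatory components whose
extrema and zero-crossing counts differ by at most one — plus a
monotone-ish residue, such that the components sum back exactly to the
input.  CEEMD stabilises EMD's mode mixing by decomposing the signal
with many paired +/- white-noise perturbations and averaging the
resulting IMFs; the paired noises cancel in the average, so the summed
output still reconstructs the original signal to machine precision.

The highest-frequency mode (IMF1) of an hourly pollutant series is
dominated by measurement noise; :func:`denoise` rebuilds the series
with IMF1 removed, which is the preprocessing step the forecasting
pipeline applies before model fitting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.interpolate import CubicSpline


@dataclass(frozen=True)
class CEEMDConfig:
    """Ensemble and sifting parameters for :func:`ceemd`.

    ``ensemble_size`` is the number of +/- noise *pairs* (each pair
    contributes two decompositions).  ``noise_std`` is the white-noise
    standard deviation as a fraction of the signal's standard
    deviation.  ``max_imfs`` fixes the number of modes extracted from
    every ensemble member so the member-wise average is well defined.
    """

    ensemble_size: int = 200
    noise_std: float = 0.4
    max_imfs: int = 8
    max_siftings: int = 50
    sd_threshold: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ensemble_size < 1:
            raise ValueError("ensemble_size must be >= 1")
        if self.noise_std < 0:
            raise ValueError("noise_std must be >= 0")
        if self.max_imfs < 1:
            raise ValueError("max_imfs must be >= 1")


@dataclass
class IMFSet:
    """Ordered intrinsic mode functions plus residue of one signal."""

    imfs: list[np.ndarray]
    residue: np.ndarray

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    def reconstruct(self) -> np.ndarray:
        """Sum of all IMFs and the residue (equals the decomposed signal)."""
        out = self.residue.copy()
        for imf in self.imfs:
            out += imf
        return out

    def as_matrix(self) -> np.ndarray:
        """Stack modes row-wise: imf1..imfK then the residue."""
        return np.vstack(self.imfs + [self.residue]) if self.imfs else self.residue[None, :]


def _local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of interior local maxima and minima (strict neighbours)."""
    d = np.diff(x)
    # treat flat steps by propagating the previous sign
    s = np.sign(d)
    for i in range(1, len(s)):
        if s[i] == 0:
            s[i] = s[i - 1]
    flips = np.diff(s)
    maxima = np.where(flips < 0)[0] + 1
    minima = np.where(flips > 0)[0] + 1
    return maxima, minima


def _envelope(x: np.ndarray, idx: np.ndarray, kind: str) -> np.ndarray:
    """Cubic-spline envelope through the extrema at ``idx``.

    Two extrema are mirrored beyond each boundary to tame end effects.
    """
    n = len(x)
    t = idx.astype(float)
    v = x[idx]
    # mirror up to two extrema across each end point
    k = min(2, len(idx))
    left_t = -t[:k][::-1]
    left_v = v[:k][::-1]
    right_t = 2 * (n - 1) - t[-k:][::-1]
    right_v = v[-k:][::-1]
    tt = np.concatenate([left_t, t, right_t])
    vv = np.concatenate([left_v, v, right_v])
    tt, keep = np.unique(tt, return_index=True)
    vv = vv[keep]
    if len(tt) < 2:
        return np.full(n, vv[0])
    if len(tt) < 4:
        return np.interp(np.arange(n), tt, vv)
    return CubicSpline(tt, vv)(np.arange(n))


def _sift(h: np.ndarray, max_siftings: int, sd_threshold: float) -> np.ndarray | None:
    """Extract one IMF from ``h``; ``None`` if ``h`` has too few extrema."""
    for _ in range(max_siftings):
        maxima, minima = _local_extrema(h)
        if len(maxima) + len(minima) < 2 or len(maxima) < 1 or len(minima) < 1:
            return None
        upper = _envelope(h, maxima, "max")
        lower = _envelope(h, minima, "min")
        mean = 0.5 * (upper + lower)
        h_new = h - mean
        denom = float(np.sum(h * h))
        sd = float(np.sum((h - h_new) ** 2)) / denom if denom > 0 else 0.0
        h = h_new
        if sd < sd_threshold:
            break
    return h


def emd(
    signal: Sequence[float],
    max_imfs: int = 8,
    max_siftings: int = 50,
    sd_threshold: float = 0.2,
) -> IMFSet:
    """Plain empirical mode decomposition.

    Stops when the running residue is monotone (fewer than two interior
    extrema) or ``max_imfs`` modes have been extracted.  The returned
    modes and residue sum back to ``signal`` exactly (floating point).
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1 or len(x) < 4:
        raise ValueError("signal must be 1-D with length >= 4")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal must be finite")

    imfs: list[np.ndarray] = []
    residue = x.copy()
    while len(imfs) < max_imfs:
        imf = _sift(residue, max_siftings, sd_threshold)
        if imf is None:
            break
        imfs.append(imf)
        residue = residue - imf
    return IMFSet(imfs, residue)


def ceemd(signal: Sequence[float], config: CEEMDConfig | None = None) -> IMFSet:
    """Complementary ensemble EMD with paired +/- white noise.

    Every ensemble member ``i`` decomposes both ``x + e*n_i`` and
    ``x - e*n_i`` with the *same* noise realisation ``n_i``; mode ``j``
    of the output is the average of mode ``j`` over all ``2N``
    decompositions.  Members whose decomposition yields fewer than
    ``max_imfs`` modes are zero-padded so the average is well defined.
    Deterministic given ``config.seed``.
    """
    cfg = config or CEEMDConfig()
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1 or len(x) < 4:
        raise ValueError("signal must be 1-D with length >= 4")

    if cfg.noise_std == 0 and cfg.ensemble_size == 1:
        return emd(x, cfg.max_imfs, cfg.max_siftings, cfg.sd_threshold)

    rng = np.random.default_rng(cfg.seed)
    eps = cfg.noise_std * float(np.std(x))
    k = cfg.max_imfs
    imf_sum = np.zeros((k, len(x)))
    res_sum = np.zeros(len(x))
    for _ in range(cfg.ensemble_size):
        noise = rng.normal(0.0, 1.0, len(x))
        for sgn in (1.0, -1.0):
            dec = emd(x + sgn * eps * noise, k, cfg.max_siftings, cfg.sd_threshold)
            for j, imf in enumerate(dec.imfs):
                imf_sum[j] += imf
            res_sum += dec.residue
    m = 2 * cfg.ensemble_size
    imfs = [imf_sum[j] / m for j in range(k)]
    residue = res_sum / m
    # drop trailing all-zero padded modes
    while imfs and np.allclose(imfs[-1], 0.0):
        imfs.pop()
    return IMFSet(imfs, residue)


def denoise(imfset: IMFSet) -> np.ndarray:
    """Rebuild the series with the first (highest-frequency) mode removed.

    Returns ``sum(IMF_j, j >= 2) + residue``; with no modes at all the
    residue is returned unchanged.
    """
    out = imfset.residue.copy()
    for imf in imfset.imfs[1:]:
        out += imf
    return out


def zero_crossings(x: np.ndarray) -> int:
    """Count sign changes, ignoring exact zeros."""
    s = np.sign(x)
    s = s[s != 0]
    return int(np.sum(s[1:] != s[:-1]))
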