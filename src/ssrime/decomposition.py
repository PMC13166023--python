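"""Empirical mode decomposition and CEEMDAN for single-channel EEG.

EMD decomposes a signal into intrinsic mode functions (IMFs) by iteratively
sifting: the mean of cubic-spline envelopes through local maxima and minima
is subtracted until the result oscillates around zero. CEEMDAN (complete
ensemble EMD with adaptive noise, Torres-style) averages the first mode over
many noise-perturbed realizations at each stage and updates the residual
recursively, which suppresses mode mixing while keeping the decomposition
exactly complete: the residual is defined by successive subtraction, so the
modes plus residual always sum back to the input.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._sift import count_extrema, count_zero_crossings, sift_kernel

logger = logging.getLogger(__name__)

__all__ = [
    "SignalEpoch",
    "IMFSet",
    "CeemdanParams",
    "TooFewExtremaError",
    "sift",
    "emd",
    "ceemdan",
    "reconstruct",
]


class TooFewExtremaError(ValueError):
    """Raised when a signal is monotone/trend-like: treat it as residual."""


@dataclass
class SignalEpoch:
    """One single-channel epoch: samples in µV at sampling rate fs (Hz)."""

    samples: np.ndarray
    fs: float
    channel_id: str = ""
    epoch_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.samples.ndim != 1 or self.samples.size < 4:
            raise ValueError("signal must be 1-D with length >= 4")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("signal contains non-finite samples")


@dataclass
class IMFSet:
    """Ordered IMFs plus residual for one signal.

    ``imfs`` is a (K, N) array, high to low frequency by extraction order;
    ``order_is_stabilized`` records whether a median-frequency reordering
    has been applied downstream.
    """

    imfs: np.ndarray
    residual: np.ndarray
    fs: float
    order_is_stabilized: bool = False

    def __post_init__(self) -> None:
        self.imfs = np.atleast_2d(np.asarray(self.imfs, dtype=np.float64))
        if self.imfs.size == 0:
            self.imfs = self.imfs.reshape(0, self.residual.shape[0] if hasattr(self.residual, "shape") else 0)
        self.residual = np.asarray(self.residual, dtype=np.float64)
        if self.imfs.shape[0] and self.imfs.shape[1] != self.residual.shape[0]:
            raise ValueError("IMF and residual lengths differ")

    @property
    def n_imfs(self) -> int:
        return self.imfs.shape[0]

    @property
    def source_length(self) -> int:
        return self.residual.shape[0]

    def to_matrix(self) -> np.ndarray:
        """(K+1, N) matrix, residual last — the documented export layout."""
        return np.vstack([self.imfs, self.residual[None, :]])

    @classmethod
    def from_matrix(cls, matrix: np.ndarray, fs: float, order_is_stabilized: bool = False) -> "IMFSet":
        matrix = np.atleast_2d(np.asarray(matrix, dtype=np.float64))
        return cls(imfs=matrix[:-1], residual=matrix[-1], fs=fs, order_is_stabilized=order_is_stabilized)


@dataclass
class CeemdanParams:
    """Ensemble-decomposition settings.

    noise_scale is the perturbation amplitude as a fraction of the current
    residual's standard deviation, so the decomposition is equivariant to
    global signal scaling.
    """

    n_realizations: int = 100
    noise_scale: float = 0.2
    max_imfs: int = 8
    sift_sd_threshold: float = 0.2
    max_sift_iters: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_realizations < 1:
            raise ValueError("n_realizations must be >= 1")
        if self.noise_scale <= 0:
            raise ValueError("noise_scale must be positive")
        if self.max_imfs < 1:
            raise ValueError("max_imfs must be >= 1")
        if self.sift_sd_threshold <= 0:
            raise ValueError("sift_sd_threshold must be positive")


def _as_array(signal) -> np.ndarray:
    if isinstance(signal, SignalEpoch):
        return signal.samples
    x = np.asarray(signal, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("signal must be 1-D")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite samples")
    return x


def sift(signal, sd_threshold: float = 0.2, max_iters: int = 100) -> np.ndarray:
    """Extract one candidate IMF by envelope-mean sifting.

    Stops when the Cauchy-type criterion
    ``SD = Σ(h_prev − h_new)² / Σ h_prev² < sd_threshold``
    holds, or after ``max_iters`` iterations (logged).

    Raises
    ------
    TooFewExtremaError
        If the input has fewer than two interior maxima or minima
        (monotone/trend input — treat as residual).
    """
    x = _as_array(signal)
    h, status = sift_kernel(x, float(sd_threshold), int(max_iters))
    if status == 2:
        raise TooFewExtremaError("too few extrema: monotone/trend input, treat as residual")
    if status == 1:
        logger.debug("sift reached max_iters=%d without meeting SD criterion", max_iters)
    return h


def is_imf(series: np.ndarray) -> bool:
    """IMF condition: extrema and zero-crossing counts differ by at most one."""
    n_max, n_min = count_extrema(np.asarray(series, dtype=np.float64))
    zc = count_zero_crossings(np.asarray(series, dtype=np.float64))
    return abs((n_max + n_min) - zc) <= 1


def effective_max_imfs(n_samples: int, max_imfs: int) -> int:
    """Cap on mode count: configured maximum, and ⌊log2 N⌋ − 1 dyadic bound."""
    return max(1, min(max_imfs, int(math.floor(math.log2(n_samples))) - 1))


def _decomposable(x: np.ndarray) -> bool:
    n_max, n_min = count_extrema(x)
    return n_max >= 2 and n_min >= 2


def emd(signal, params: CeemdanParams | None = None, fs: float = 1.0) -> IMFSet:
    """Plain EMD: repeatedly sift the residual until it is trend-like.

    The residual is whatever remains after the extracted modes, so the
    modes plus residual reconstruct the input to floating-point accuracy.
    """
    params = params or CeemdanParams()
    if isinstance(signal, SignalEpoch):
        fs = signal.fs
    x = _as_array(signal)
    k_max = effective_max_imfs(x.size, params.max_imfs)
    imfs: list[np.ndarray] = []
    r = x.copy()
    while len(imfs) < k_max and _decomposable(r):
        h, status = sift_kernel(r, params.sift_sd_threshold, params.max_sift_iters)
        if status == 2:
            break
        imfs.append(h)
        r = r - h
    if not imfs:
        logger.warning("degenerate input (no interior oscillation): K=0, residual = input")
        return IMFSet(imfs=np.empty((0, x.size)), residual=x.copy(), fs=fs)
    return IMFSet(imfs=np.vstack(imfs), residual=r, fs=fs)


def _first_mode(x: np.ndarray, params: CeemdanParams) -> np.ndarray | None:
    h, status = sift_kernel(x, params.sift_sd_threshold, params.max_sift_iters)
    if status == 2:
        return None
    return h


def ceemdan(signal, params: CeemdanParams | None = None, fs: float = 1.0) -> IMFSet:
    """Torres-style CEEMDAN.

    Stage 1 averages the first EMD mode of ``n_realizations`` copies of the
    signal perturbed with white noise scaled to ``noise_scale`` × std(x).
    Stage k perturbs the running residual with the k-th EMD mode of each
    stored noise realization (amplitude-matched to the residual) and
    averages the extracted first modes. The final residual is the input
    minus the sum of modes, so reconstruction is exact by construction.
    """
    params = params or CeemdanParams()
    if isinstance(signal, SignalEpoch):
        fs = signal.fs
    x = _as_array(signal)
    n = x.size
    k_max = effective_max_imfs(n, params.max_imfs)
    sd_x = float(np.std(x))
    if sd_x == 0.0 or not _decomposable(x):
        logger.warning("degenerate input for CEEMDAN: K=0, residual = input")
        return IMFSet(imfs=np.empty((0, n)), residual=x.copy(), fs=fs)

    rng = np.random.default_rng(params.seed)
    noise = rng.standard_normal((params.n_realizations, n))
    # EMD modes of each noise realization, reused across stages
    noise_modes: list[np.ndarray] = []
    for i in range(params.n_realizations):
        nm = emd(noise[i], params).imfs
        noise_modes.append(nm)

    imfs: list[np.ndarray] = []
    r = x.copy()
    for k in range(k_max):
        if not _decomposable(r):
            break
        beta = params.noise_scale * float(np.std(r))
        acc = np.zeros(n)
        n_ok = 0
        for i in range(params.n_realizations):
            if k == 0:
                perturbed = r + beta * noise[i]
            else:
                if k - 1 < noise_modes[i].shape[0]:
                    nm = noise_modes[i][k - 1]
                    nm_std = float(np.std(nm))
                    perturbed = r + (beta / nm_std) * nm if nm_std > 0 else r
                else:
                    perturbed = r
            mode = _first_mode(perturbed, params)
            if mode is not None:
                acc += mode
                n_ok += 1
        if n_ok == 0:
            break
        imfs.append(acc / n_ok)
        r = r - imfs[-1]
    if not imfs:
        return IMFSet(imfs=np.empty((0, n)), residual=x.copy(), fs=fs)
    return IMFSet(imfs=np.vstack(imfs), residual=r, fs=fs)


def reconstruct(imfset: IMFSet) -> np.ndarray:
    """Element-wise sum of modes plus residual."""
    if imfset.n_imfs and imfset.imfs.shape[1] != imfset.residual.shape[0]:
        raise ValueError("length mismatch among IMFSet components")
    if imfset.n_imfs == 0:
        return imfset.residual.copy()
    return imfset.imfs.sum(axis=0) + imfset.residual
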