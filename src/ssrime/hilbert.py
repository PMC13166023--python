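"""Analytic-signal analysis of IMFs: instantaneous amplitude, phase,
frequency, median frequency, Hilbert spectrum, and band energies.

The analytic signal z(t) = x(t) + j·H[x](t) gives A(t) = |z(t)| and
φ(t) = arg z(t); instantaneous frequency is f(t) = (1/2π)·dφ/dt, computed
by central differences on the unwrapped phase (one-sided at the ends).
Negative instantaneous frequencies — which appear when a mode is noisy or
multicomponent — are preserved: they inflate the dispersion penalty used
downstream and fall outside physiological bands in band energies.

Hilbert end effects are handled by trimming a fraction of samples at each
end (default 5%) from all statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert as _scipy_hilbert

__all__ = [
    "AnalyticIMF",
    "HilbertSpectrum",
    "analytic",
    "inst_frequency",
    "median_frequency",
    "hilbert_spectrum",
    "band_energy",
    "DEFAULT_EDGE_TRIM_FRAC",
]

DEFAULT_EDGE_TRIM_FRAC = 0.05


@dataclass
class AnalyticIMF:
    """Instantaneous amplitude/phase/frequency of one IMF.

    ``edge_trim`` samples at each end are excluded from all statistics
    (median frequency, dispersion, energies). ``freq_defined`` is False for
    an all-zero mode, whose instantaneous frequency is meaningless.
    """

    amplitude: np.ndarray
    phase: np.ndarray
    inst_freq: np.ndarray
    fs: float
    edge_trim: int
    freq_defined: bool = True

    @property
    def interior(self) -> slice:
        n = self.amplitude.shape[0]
        t = self.edge_trim
        if 2 * t >= n:
            t = max(0, (n - 1) // 2)
        return slice(t, n - t if t else n)

    def interior_freq(self) -> np.ndarray:
        return self.inst_freq[self.interior]

    def interior_amplitude(self) -> np.ndarray:
        return self.amplitude[self.interior]


def inst_frequency(phase: np.ndarray, fs: float) -> np.ndarray:
    """f(t) = (1/2π)·dφ/dt by central differences, one-sided at the ends.

    Negative values are preserved; they flag phase instability rather than
    physiological oscillation.
    """
    phase = np.asarray(phase, dtype=np.float64)
    return np.gradient(phase) * fs / (2.0 * np.pi)


def analytic(imf, fs: float, edge_trim_frac: float = DEFAULT_EDGE_TRIM_FRAC) -> AnalyticIMF:
    """Analytic representation of one IMF via the Hilbert transform."""
    x = np.asarray(imf, dtype=np.float64)
    if x.ndim != 1 or x.size < 8:
        raise ValueError("IMF must be 1-D with length >= 8")
    if not np.all(np.isfinite(x)):
        raise ValueError("IMF contains non-finite samples")
    trim = int(round(edge_trim_frac * x.size))
    if not np.any(x):
        zeros = np.zeros_like(x)
        return AnalyticIMF(zeros, zeros.copy(), zeros.copy(), fs, trim, freq_defined=False)
    z = _scipy_hilbert(x)
    amplitude = np.abs(z)
    phase = np.unwrap(np.angle(z))
    freq = inst_frequency(phase, fs)
    return AnalyticIMF(amplitude, phase, freq, fs, trim)


class UndefinedFrequencyError(ValueError):
    """Instantaneous frequency undefined (zero-energy IMF): cannot rank."""


def median_frequency(an: AnalyticIMF) -> float:
    """Median interior instantaneous frequency (Hz) — robust scale rank."""
    if not an.freq_defined:
        raise UndefinedFrequencyError("cannot rank zero-energy IMF")
    f = an.interior_freq()
    if f.size == 0:
        raise UndefinedFrequencyError("no interior samples")
    return float(np.median(f))


@dataclass
class HilbertSpectrum:
    """Time–frequency energy grid: each interior sample deposits A²(t) at
    (f(t), t). ``overflow`` collects energy whose frequency falls outside
    the grid so total energy is conserved exactly."""

    grid: np.ndarray
    freq_edges: np.ndarray
    time_edges: np.ndarray
    overflow: float
    aggregated: bool = True

    @property
    def total_energy(self) -> float:
        return float(self.grid.sum() + self.overflow)

    def to_matrix(self) -> np.ndarray:
        return self.grid.copy()


def _check_edges(edges: np.ndarray, name: str) -> np.ndarray:
    edges = np.asarray(edges, dtype=np.float64)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError(f"{name} must be strictly increasing with >= 2 entries")
    return edges


def hilbert_spectrum(
    analytic_imfs,
    freq_edges,
    time_edges,
) -> HilbertSpectrum:
    """Aggregate Hilbert spectrum over a list of analytic IMFs.

    Only interior samples contribute. Energy falling outside the frequency
    range is accumulated in ``overflow`` (conservation check:
    grid total + overflow == Σ A² over interior samples).
    """
    freq_edges = _check_edges(freq_edges, "freq_edges")
    time_edges = _check_edges(time_edges, "time_edges")
    grid = np.zeros((freq_edges.size - 1, time_edges.size - 1))
    overflow = 0.0
    for an in analytic_imfs:
        sl = an.interior
        idx = np.arange(an.amplitude.shape[0])[sl]
        t = idx / an.fs
        f = an.inst_freq[sl]
        e = an.amplitude[sl] ** 2
        in_t = (t >= time_edges[0]) & (t <= time_edges[-1])
        in_f = (f >= freq_edges[0]) & (f <= freq_edges[-1])
        keep = in_t & in_f
        h, _, _ = np.histogram2d(f[keep], t[keep], bins=(freq_edges, time_edges), weights=e[keep])
        grid += h
        overflow += float(e[~keep].sum())
    return HilbertSpectrum(grid, freq_edges, time_edges, overflow)


def band_energy(an: AnalyticIMF, band) -> float:
    """Σ A²(t) over interior samples whose instantaneous frequency lies in
    the half-open band [lo, hi)."""
    lo, hi = float(band[0]), float(band[1])
    if lo >= hi:
        raise ValueError("band must satisfy lo < hi")
    f = an.interior_freq()
    a2 = an.interior_amplitude() ** 2
    mask = (f >= lo) & (f < hi)
    return float(a2[mask].sum())


def total_interior_energy(an: AnalyticIMF) -> float:
    """Σ A²(t) over interior samples."""
    return float((an.interior_amplitude() ** 2).sum())
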