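"""SS-RIME features and comparison feature sets.

The SS-RIME descriptor scores each intrinsic mode function k of a signal as

    SS-RIME_k = S_k · W_k · Ē_k

where
  S_k = exp(−α·σ_k/|μ_k|)   penalizes modes with unstable instantaneous
                            frequency (σ, μ: interior std and mean of f_k(t)),
  W_k                       is the fraction of the mode's Hilbert spectral
                            energy (or time samples) inside the δ (1–4 Hz)
                            and θ (4–7.5 Hz) bands, and
  Ē_k = E_k / (Σ_i E_i + ε) is the mode's relative energy.

Modes are first reordered by descending median instantaneous frequency so
that the k-th feature refers to the same oscillatory scale across epochs
and subjects. The ablated RIME baseline keeps only Ē_k in extraction order;
RWE and PSD band power are conventional wavelet/Welch references.

Feature extractors are exposed both as functions on single epochs and as
scikit-learn transformers over (epochs × channels × samples) arrays, which
concatenate per-channel K-vectors in fixed channel order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pywt
from scipy.signal import welch
from sklearn.base import BaseEstimator, TransformerMixin

from .decomposition import CeemdanParams, IMFSet, ceemdan
from .hilbert import (
    DEFAULT_EDGE_TRIM_FRAC,
    AnalyticIMF,
    UndefinedFrequencyError,
    analytic,
    band_energy,
    median_frequency,
    total_interior_energy,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SSRIMEParams",
    "FeatureVector",
    "CANONICAL_BANDS",
    "stabilization_factor",
    "band_weight",
    "imf_energy",
    "relative_energies",
    "ssrime_vector",
    "rime_vector",
    "rwe_vector",
    "psd_bandpower_vector",
    "SSRIME",
    "RIME",
    "RWE",
    "PSDBandPower",
    "extract_feature_matrix",
    "ssrime_variant_matrices",
]

#: Canonical EEG band edges (Hz), half-open [lo, hi).
CANONICAL_BANDS = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 7.5),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, np.inf),
}


@dataclass
class SSRIMEParams:
    """Descriptor settings. ``alpha`` is the stabilization exponent (the
    penalty on the frequency-dispersion ratio σ/μ); bands are half-open
    [lo, hi) so the 4 Hz δ/θ boundary is counted once."""

    alpha: float = 1.0
    delta_band: tuple = (1.0, 4.0)
    theta_band: tuple = (4.0, 7.5)
    K: int = 8
    epsilon: float = 1e-12
    weight_mode: str = "spectral_energy"  # or "time_proportion"
    energy_mode: str = "raw_imf"  # or "analytic_amplitude"
    include_stabilization: bool = True
    include_weighting: bool = True
    include_normalization: bool = True
    dispersion_as_variance: bool = False
    edge_trim_frac: float = DEFAULT_EDGE_TRIM_FRAC

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.K < 1:
            raise ValueError("K must be >= 1")
        for band in (self.delta_band, self.theta_band):
            if band[0] >= band[1]:
                raise ValueError("band lo must be < hi")
        if self.delta_band[1] > self.theta_band[0] and self.theta_band[1] > self.delta_band[0]:
            if not (self.delta_band[1] <= self.theta_band[0] or self.theta_band[1] <= self.delta_band[0]):
                raise ValueError("delta and theta bands must not overlap")
        if self.weight_mode not in ("spectral_energy", "time_proportion"):
            raise ValueError("unknown weight_mode")
        if self.energy_mode not in ("raw_imf", "analytic_amplitude"):
            raise ValueError("unknown energy_mode")


@dataclass
class FeatureVector:
    """K-dimensional per-channel descriptor with method metadata."""

    values: np.ndarray
    method: str
    channel_id: str = ""
    epoch_id: str = ""
    per_imf_metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)


def stabilization_factor(an: AnalyticIMF, alpha: float, dispersion_as_variance: bool = False) -> float:
    """S = exp(−α·σ/|μ|) with σ, μ over interior instantaneous frequency.

    A degenerate mean frequency (|μ| < 1e−9 Hz) is maximally penalized:
    S = 0 (logged).
    """
    if not an.freq_defined:
        logger.debug("stabilization_factor: zero-energy IMF, S=0")
        return 0.0
    f = an.interior_freq()
    mu = float(np.mean(f))
    if abs(mu) < 1e-9:
        logger.debug("stabilization_factor: degenerate mean frequency, S=0")
        return 0.0
    disp = float(np.var(f)) if dispersion_as_variance else float(np.std(f))
    return float(np.exp(-alpha * disp / abs(mu)))


def band_weight(an: AnalyticIMF, params: SSRIMEParams) -> float:
    """Fraction of the mode lying in δ∪θ.

    spectral_energy: Hilbert spectral energy fraction (ratio of interior
    Σ A² with f in band to the total). time_proportion: fraction of interior
    samples with f in band. Zero total energy gives W = 0.
    """
    if not an.freq_defined:
        return 0.0
    if params.weight_mode == "time_proportion":
        f = an.interior_freq()
        if f.size == 0:
            return 0.0
        in_band = _in_union(f, params.delta_band, params.theta_band)
        return float(in_band.mean())
    total = total_interior_energy(an)
    if total == 0.0:
        return 0.0
    e = band_energy(an, params.delta_band) + band_energy(an, params.theta_band)
    return float(e / total)


def _in_union(f: np.ndarray, band_a, band_b) -> np.ndarray:
    return ((f >= band_a[0]) & (f < band_a[1])) | ((f >= band_b[0]) & (f < band_b[1]))


def _interior_slice(n: int, trim_frac: float) -> slice:
    t = int(round(trim_frac * n))
    if 2 * t >= n:
        t = max(0, (n - 1) // 2)
    return slice(t, n - t if t else n)


def imf_energy(imf_or_analytic, energy_mode: str = "raw_imf", fs: float = 1.0,
               edge_trim_frac: float = DEFAULT_EDGE_TRIM_FRAC) -> float:
    """Mode energy over interior samples.

    raw_imf: Σ x(t)²·Δt. analytic_amplitude: Σ A(t)²·Δt (the envelope form,
    ≈ twice the raw value for a narrowband mode since mean cos² = ½).
    """
    if energy_mode == "analytic_amplitude":
        an = imf_or_analytic if isinstance(imf_or_analytic, AnalyticIMF) else analytic(
            np.asarray(imf_or_analytic, dtype=np.float64), fs, edge_trim_frac)
        return float((an.interior_amplitude() ** 2).sum() / an.fs)
    if isinstance(imf_or_analytic, AnalyticIMF):
        raise TypeError("raw_imf mode requires the raw IMF series")
    x = np.asarray(imf_or_analytic, dtype=np.float64)
    sl = _interior_slice(x.size, edge_trim_frac)
    return float((x[sl] ** 2).sum() / fs)


def relative_energies(energies, epsilon: float = 1e-12) -> np.ndarray:
    """Ē_k = E_k / (Σ_i E_i + ε). All-zero input stays all-zero."""
    e = np.asarray(energies, dtype=np.float64)
    if np.any(e < 0):
        raise ValueError("energies must be non-negative")
    return e / (e.sum() + epsilon)


# ---------------------------------------------------------------------------
# per-IMF component cache and descriptor assembly

@dataclass
class _Components:
    """Per-mode quantities in extraction order, shared by all variants."""

    median_freq: np.ndarray  # NaN where undefined
    S: np.ndarray
    W: np.ndarray
    E: np.ndarray
    n_imfs: int


def _imf_components(imfset: IMFSet, params: SSRIMEParams) -> _Components:
    k = imfset.n_imfs
    fbar = np.full(k, np.nan)
    S = np.zeros(k)
    W = np.zeros(k)
    E = np.zeros(k)
    for i in range(k):
        an = analytic(imfset.imfs[i], imfset.fs, params.edge_trim_frac)
        try:
            fbar[i] = median_frequency(an)
        except UndefinedFrequencyError:
            pass  # rank by position (NaN sorts last)
        S[i] = stabilization_factor(an, params.alpha, params.dispersion_as_variance)
        W[i] = band_weight(an, params)
        if params.energy_mode == "analytic_amplitude":
            E[i] = imf_energy(an, "analytic_amplitude")
        else:
            E[i] = imf_energy(imfset.imfs[i], "raw_imf", imfset.fs, params.edge_trim_frac)
    return _Components(fbar, S, W, E, k)


def _stabilized_order(fbar: np.ndarray) -> np.ndarray:
    """Stable descending sort by median frequency; NaN (unrankable) last."""
    key = np.where(np.isnan(fbar), -np.inf, fbar)
    return np.argsort(-key, kind="stable")


def _assemble(comp: _Components, params: SSRIMEParams, *, reorder: bool,
              method: str) -> tuple[np.ndarray, dict]:
    order = _stabilized_order(comp.median_freq) if reorder else np.arange(comp.n_imfs)
    E = comp.E[order]
    ebar = relative_energies(E, params.epsilon)
    base = ebar if params.include_normalization else E
    values = base.copy()
    S = comp.S[order]
    W = comp.W[order]
    if params.include_stabilization:
        values = values * S
    if params.include_weighting:
        values = values * W
    meta = {
        "median_freq": comp.median_freq[order],
        "S": S,
        "W": W,
        "Ebar": ebar,
        "E": E,
        "order": order,
        "reordered": reorder,
    }
    k_out = params.K
    padded = comp.n_imfs < k_out
    if comp.n_imfs != k_out:
        values = _pad_truncate(values, k_out)
        for key in ("median_freq", "S", "W", "Ebar", "E"):
            meta[key] = _pad_truncate(meta[key], k_out, pad_value=np.nan if key == "median_freq" else 0.0)
    meta["padded"] = padded
    return values, meta


def _pad_truncate(v: np.ndarray, k: int, pad_value: float = 0.0) -> np.ndarray:
    if v.size >= k:
        return v[:k]
    out = np.full(k, pad_value)
    out[: v.size] = v
    return out


def ssrime_vector(imfset: IMFSet, params: SSRIMEParams | None = None,
                  channel_id: str = "", epoch_id: str = "") -> FeatureVector:
    """Full SS-RIME descriptor of one decomposed epoch.

    Pipeline: analytic signal per mode → stable reordering by descending
    median instantaneous frequency → S_k·W_k·Ē_k with components toggled by
    the include_* flags → pad/truncate to K.
    """
    params = params or SSRIMEParams()
    if imfset.n_imfs == 0:
        logger.warning("ssrime_vector: empty decomposition, all-zero vector")
        return FeatureVector(np.zeros(params.K), "ssrime", channel_id, epoch_id,
                             {"padded": True, "empty": True})
    comp = _imf_components(imfset, params)
    values, meta = _assemble(comp, params, reorder=True, method="ssrime")
    return FeatureVector(values, "ssrime", channel_id, epoch_id, meta)


def rime_vector(imfset: IMFSet, params: SSRIMEParams | None = None,
                channel_id: str = "", epoch_id: str = "") -> FeatureVector:
    """Ablated baseline: relative IMF energy Ē_k in extraction order,
    without reordering, stabilization, or band weighting."""
    params = params or SSRIMEParams()
    if imfset.n_imfs == 0:
        return FeatureVector(np.zeros(params.K), "rime", channel_id, epoch_id,
                             {"padded": True, "empty": True})
    rp = replace(params, include_stabilization=False, include_weighting=False,
                 include_normalization=True)
    comp = _imf_components(imfset, rp)
    values, meta = _assemble(comp, rp, reorder=False, method="rime")
    return FeatureVector(values, "rime", channel_id, epoch_id, meta)


def rwe_vector(signal, wavelet_name: str = "db4", n_levels: int = 5,
               channel_id: str = "", epoch_id: str = "") -> FeatureVector:
    """Relative wavelet energy: per-subband energies of a discrete wavelet
    decomposition, normalized to sum to one. Subbands are ordered high to
    low frequency (details d1..dn, then the approximation)."""
    x = np.asarray(getattr(signal, "samples", signal), dtype=np.float64)
    min_len = 2 ** n_levels
    if x.size < min_len:
        raise ValueError(f"signal too short for {n_levels}-level DWT: need >= {min_len} samples")
    coeffs = pywt.wavedec(x, wavelet_name, level=n_levels)
    # coeffs = [cA_n, cD_n, ..., cD_1]; report d1 (highest band) first
    energies = np.array([float((c ** 2).sum()) for c in coeffs[::-1]])  # d1..dn, a_n
    total = energies.sum()
    values = energies / total if total > 0 else energies
    return FeatureVector(values, "rwe", channel_id, epoch_id,
                         {"wavelet": wavelet_name, "n_levels": n_levels})


def psd_bandpower_vector(signal, fs: float | None = None, bands=None, relative: bool = True,
                         channel_id: str = "", epoch_id: str = "") -> FeatureVector:
    """Welch band power over the canonical δ/θ/α/β/γ bands."""
    x = np.asarray(getattr(signal, "samples", signal), dtype=np.float64)
    if fs is None:
        fs = getattr(signal, "fs", None)
        if fs is None:
            raise ValueError("fs required")
    if x.size < 64:
        raise ValueError("signal too short for Welch PSD: need >= 64 samples")
    bands = bands or CANONICAL_BANDS
    nperseg = int(min(x.size, 2 * fs))
    freqs, psd = welch(x, fs=fs, nperseg=nperseg)
    df = freqs[1] - freqs[0]
    powers = []
    for lo, hi in bands.values():
        mask = (freqs >= lo) & (freqs < hi)
        powers.append(float(psd[mask].sum() * df))
    values = np.asarray(powers)
    if relative:
        total = values.sum()
        values = values / total if total > 0 else values
    return FeatureVector(values, "psd", channel_id, epoch_id, {"bands": list(bands)})


# ---------------------------------------------------------------------------
# scikit-learn transformers over (epochs, channels, samples) arrays

def _validate_epochs(X) -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 3:
        raise ValueError("X must be (n_epochs, n_channels, n_samples)")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    return X


def _channel_seed(base_seed: int, epoch: int, channel: int) -> int:
    ss = np.random.SeedSequence(base_seed, spawn_key=(epoch, channel))
    return int(ss.generate_state(1)[0] % (2 ** 31))


class _EpochTransformer(TransformerMixin, BaseEstimator):
    """Base for feature extractors over epoched multichannel EEG.

    transform maps (n_epochs, n_channels, n_samples) to
    (n_epochs, n_features) by concatenating per-channel feature vectors in
    channel order.
    """

    def fit(self, X, y=None):
        X = _validate_epochs(X)
        self.n_channels_ = X.shape[1]
        self.n_features_out_ = self.n_channels_ * self._vector_length()
        return self

    def transform(self, X):
        X = _validate_epochs(X)
        n_epochs, n_channels, _ = X.shape
        out = np.empty((n_epochs, n_channels * self._vector_length()))
        for e in range(n_epochs):
            for c in range(n_channels):
                vec = self._channel_vector(X[e, c], e, c)
                out[e, c * self._vector_length():(c + 1) * self._vector_length()] = vec
        return out

    def feature_names(self, channel_names=None) -> list[str]:
        n_ch = getattr(self, "n_channels_", None)
        if channel_names is None:
            channel_names = [f"ch{c}" for c in range(n_ch)] if n_ch else []
        names = []
        for ch in channel_names:
            names.extend(f"{ch}_{s}" for s in self._component_names())
        return names


class _DecompositionTransformer(_EpochTransformer):
    """Shared CEEMDAN plumbing for SS-RIME and RIME transformers."""

    def _ceemdan_params(self, epoch: int, channel: int) -> CeemdanParams:
        return CeemdanParams(
            n_realizations=self.n_realizations,
            noise_scale=self.noise_scale,
            max_imfs=self.max_imfs if self.max_imfs is not None else self.K,
            sift_sd_threshold=self.sift_sd_threshold,
            max_sift_iters=self.max_sift_iters,
            seed=_channel_seed(self.seed, epoch, channel),
        )

    def _feature_params(self) -> SSRIMEParams:
        return SSRIMEParams(
            alpha=self.alpha, delta_band=self.delta_band, theta_band=self.theta_band,
            K=self.K, epsilon=self.epsilon, weight_mode=self.weight_mode,
            energy_mode=self.energy_mode,
            include_stabilization=self.include_stabilization,
            include_weighting=self.include_weighting,
            include_normalization=self.include_normalization,
            dispersion_as_variance=self.dispersion_as_variance,
            edge_trim_frac=self.edge_trim_frac,
        )

    def _vector_length(self) -> int:
        return self.K

    def _component_names(self):
        return [f"imf{k + 1}" for k in range(self.K)]


class SSRIME(_DecompositionTransformer):
    """Scale-stabilized relative intrinsic mode energy features.

    Parameters mirror :class:`SSRIMEParams` and :class:`CeemdanParams`;
    ``seed`` fixes the CEEMDAN noise so transform is deterministic.
    """

    def __init__(self, fs=250.0, K=8, alpha=1.0, delta_band=(1.0, 4.0),
                 theta_band=(4.0, 7.5), epsilon=1e-12,
                 weight_mode="spectral_energy", energy_mode="raw_imf",
                 include_stabilization=True, include_weighting=True,
                 include_normalization=True, dispersion_as_variance=False,
                 edge_trim_frac=DEFAULT_EDGE_TRIM_FRAC,
                 n_realizations=100, noise_scale=0.2, max_imfs=None,
                 sift_sd_threshold=0.2, max_sift_iters=100, seed=0):
        self.fs = fs
        self.K = K
        self.alpha = alpha
        self.delta_band = delta_band
        self.theta_band = theta_band
        self.epsilon = epsilon
        self.weight_mode = weight_mode
        self.energy_mode = energy_mode
        self.include_stabilization = include_stabilization
        self.include_weighting = include_weighting
        self.include_normalization = include_normalization
        self.dispersion_as_variance = dispersion_as_variance
        self.edge_trim_frac = edge_trim_frac
        self.n_realizations = n_realizations
        self.noise_scale = noise_scale
        self.max_imfs = max_imfs
        self.sift_sd_threshold = sift_sd_threshold
        self.max_sift_iters = max_sift_iters
        self.seed = seed

    def _channel_vector(self, x, epoch, channel):
        imfset = ceemdan(x, self._ceemdan_params(epoch, channel), fs=self.fs)
        return ssrime_vector(imfset, self._feature_params()).values


class RIME(_DecompositionTransformer):
    """Ablated baseline: relative IMF energies in extraction order."""

    def __init__(self, fs=250.0, K=8, epsilon=1e-12, energy_mode="raw_imf",
                 edge_trim_frac=DEFAULT_EDGE_TRIM_FRAC,
                 n_realizations=100, noise_scale=0.2, max_imfs=None,
                 sift_sd_threshold=0.2, max_sift_iters=100, seed=0):
        self.fs = fs
        self.K = K
        self.epsilon = epsilon
        self.energy_mode = energy_mode
        self.edge_trim_frac = edge_trim_frac
        self.n_realizations = n_realizations
        self.noise_scale = noise_scale
        self.max_imfs = max_imfs
        self.sift_sd_threshold = sift_sd_threshold
        self.max_sift_iters = max_sift_iters
        self.seed = seed

    # RIME does not use alpha/bands/weighting, keep required params default
    alpha = 1.0
    delta_band = (1.0, 4.0)
    theta_band = (4.0, 7.5)
    weight_mode = "spectral_energy"
    include_stabilization = False
    include_weighting = False
    include_normalization = True
    dispersion_as_variance = False

    def _channel_vector(self, x, epoch, channel):
        imfset = ceemdan(x, self._ceemdan_params(epoch, channel), fs=self.fs)
        return rime_vector(imfset, self._feature_params()).values


class RWE(_EpochTransformer):
    """Relative wavelet energy features."""

    def __init__(self, wavelet_name="db4", n_levels=5):
        self.wavelet_name = wavelet_name
        self.n_levels = n_levels

    def _vector_length(self) -> int:
        return self.n_levels + 1

    def _component_names(self):
        return [f"d{k + 1}" for k in range(self.n_levels)] + [f"a{self.n_levels}"]

    def _channel_vector(self, x, epoch, channel):
        return rwe_vector(x, self.wavelet_name, self.n_levels).values


class PSDBandPower(_EpochTransformer):
    """Welch band-power features over the canonical EEG bands."""

    def __init__(self, fs=250.0, relative=True):
        self.fs = fs
        self.relative = relative

    def _vector_length(self) -> int:
        return len(CANONICAL_BANDS)

    def _component_names(self):
        return list(CANONICAL_BANDS)

    def _channel_vector(self, x, epoch, channel):
        return psd_bandpower_vector(x, self.fs, relative=self.relative).values


#: Ablation variants of the SS-RIME descriptor (flag overrides).
SSRIME_VARIANTS = {
    "ssrime": {},
    "no_stabilization": {"include_stabilization": False},
    "no_weighting": {"include_weighting": False},
    "no_normalization": {"include_normalization": False},
}


def ssrime_variant_matrices(data, fs, params: SSRIMEParams | None = None,
                            cparams: CeemdanParams | None = None,
                            variants=None, include_rime: bool = True,
                            base_seed: int = 0) -> dict[str, np.ndarray]:
    """Feature matrices for several SS-RIME ablation variants from a single
    CEEMDAN decomposition per channel-epoch (the variants share modes, so
    decomposing once keeps the ablation paired and fast)."""
    X = _validate_epochs(data)
    params = params or SSRIMEParams()
    cparams = cparams or CeemdanParams()
    variants = dict(SSRIME_VARIANTS if variants is None else variants)
    n_epochs, n_channels, _ = X.shape
    k = params.K
    out = {name: np.empty((n_epochs, n_channels * k)) for name in variants}
    if include_rime:
        out["rime"] = np.empty((n_epochs, n_channels * k))
    for e in range(n_epochs):
        for c in range(n_channels):
            cp = replace(cparams, seed=_channel_seed(base_seed, e, c))
            imfset = ceemdan(X[e, c], cp, fs=fs)
            col = slice(c * k, (c + 1) * k)
            if imfset.n_imfs == 0:
                for name in out:
                    out[name][e, col] = 0.0
                continue
            comp = _imf_components(imfset, params)
            for name, overrides in variants.items():
                p = replace(params, **overrides)
                values, _ = _assemble(comp, p, reorder=True, method=name)
                out[name][e, col] = values
            if include_rime:
                rp = replace(params, include_stabilization=False,
                             include_weighting=False, include_normalization=True)
                values, _ = _assemble(comp, rp, reorder=False, method="rime")
                out["rime"][e, col] = values
    return out


def extract_feature_matrix(data, fs, method: str = "ssrime", **kwargs) -> np.ndarray:
    """One-call feature matrix for a named method."""
    transformers = {"ssrime": SSRIME, "rime": RIME, "rwe": RWE, "psd": PSDBandPower}
    if method not in transformers:
        raise ValueError(f"unknown method {method!r}; choose from {sorted(transformers)}")
    cls = transformers[method]
    if method in ("ssrime", "rime", "psd"):
        kwargs.setdefault("fs", fs)
    est = cls(**kwargs)
    return est.fit(data).transform(data)
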