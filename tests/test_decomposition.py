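"""Decomposition contracts: sifting behaviour, completeness, ordering,
determinism, and scale equivariance."""

import numpy as np
import pytest

from ssrime.decomposition import (
    CeemdanParams,
    IMFSet,
    SignalEpoch,
    TooFewExtremaError,
    ceemdan,
    emd,
    reconstruct,
    sift,
)
from ssrime.hilbert import analytic, median_frequency


def _interior_corr(a, b, trim=200):
    a, b = a[trim:-trim], b[trim:-trim]
    return np.corrcoef(a, b)[0, 1]


class TestSift:
    def test_pure_tone_passes_through(self):
        t = np.arange(0, 3, 1 / 250.0)
        x = np.sin(2 * np.pi * 10 * t)
        h = sift(x)
        assert _interior_corr(h, x, trim=25) > 0.99

    def test_monotone_ramp_is_residual(self):
        with pytest.raises(TooFewExtremaError):
            sift(np.linspace(0.0, 1.0, 500))

    def test_dc_offset_removed(self):
        t = np.arange(0, 3, 1 / 250.0)
        x = np.sin(2 * np.pi * 10 * t) + 5.0
        h = sift(x)
        assert abs(h.mean()) < 0.05  # amplitude 1

    def test_signal_epoch_input(self):
        t = np.arange(0, 2, 1 / 250.0)
        ep = SignalEpoch(np.sin(2 * np.pi * 8 * t), fs=250.0)
        h = sift(ep)
        assert h.shape == ep.samples.shape


class TestEMD:
    def test_constant_signal_k0(self):
        x = np.full(500, 3.14)
        s = emd(x)
        assert s.n_imfs == 0
        np.testing.assert_array_equal(s.residual, x)

    def test_two_tone_separation(self, two_tone_500hz):
        hi, lo, fs = two_tone_500hz
        s = emd(hi + lo, fs=fs)
        assert s.n_imfs >= 2
        assert _interior_corr(s.imfs[0], hi) > 0.95
        later = max(_interior_corr(s.imfs[k], lo) for k in range(1, s.n_imfs))
        assert later > 0.95

    def test_completeness(self, two_tone_500hz):
        hi, lo, _ = two_tone_500hz
        x = hi + lo
        err = np.abs(reconstruct(emd(x)) - x).max()
        assert err < 1e-8 * np.abs(x).max()


class TestCeemdan:
    def test_determinism(self, two_tone_500hz, fast_ceemdan):
        hi, lo, fs = two_tone_500hz
        x = hi + lo
        a = ceemdan(x, fast_ceemdan, fs=fs)
        b = ceemdan(x, fast_ceemdan, fs=fs)
        np.testing.assert_array_equal(a.imfs, b.imfs)
        np.testing.assert_array_equal(a.residual, b.residual)

    def test_completeness_exact(self, two_tone_500hz, fast_ceemdan):
        hi, lo, _ = two_tone_500hz
        x = hi + lo
        s = ceemdan(x, fast_ceemdan)
        assert np.abs(reconstruct(s) - x).max() < 1e-8 * np.abs(x).max()

    def test_scale_equivariance(self, two_tone_500hz, fast_ceemdan):
        hi, lo, _ = two_tone_500hz
        x = hi + lo
        for c in (0.1, 10.0):
            a = ceemdan(x, fast_ceemdan)
            b = ceemdan(c * x, fast_ceemdan)
            assert a.n_imfs == b.n_imfs
            denom = np.abs(c * a.imfs).max()
            assert np.abs(b.imfs - c * a.imfs).max() < 1e-6 * denom

    def test_degenerate_input(self, fast_ceemdan):
        s = ceemdan(np.zeros(600), fast_ceemdan)
        assert s.n_imfs == 0
        np.testing.assert_array_equal(s.residual, np.zeros(600))

    def test_mode_mixing_reduced_vs_emd(self):
        """Noise-assisted averaging should mix the two tones less than plain
        EMD, measured by max cross-correlation between the recovered modes."""
        fs = 250.0
        t = np.arange(0, 3, 1 / fs)
        params = CeemdanParams(n_realizations=20, seed=0)

        def mixing(imfset, f_hi, f_lo):
            ref_hi = np.sin(2 * np.pi * f_hi * t)
            ref_lo = np.sin(2 * np.pi * f_lo * t)
            k_hi = np.argmax([abs(_interior_corr(m, ref_hi, 75)) for m in imfset.imfs])
            k_lo = np.argmax([abs(_interior_corr(m, ref_lo, 75)) for m in imfset.imfs])
            if k_hi == k_lo:
                return 1.0
            return abs(_interior_corr(imfset.imfs[k_hi], imfset.imfs[k_lo], 75))

        rng = np.random.default_rng(42)
        deltas = []
        for _ in range(10):
            f_hi = rng.uniform(20, 30)
            f_lo = rng.uniform(3, 6)
            # intermittent high tone provokes mixing in plain EMD
            gate = (np.sin(2 * np.pi * 0.5 * t) > 0).astype(float)
            x = gate * np.sin(2 * np.pi * f_hi * t) + 2 * np.sin(2 * np.pi * f_lo * t)
            p = CeemdanParams(n_realizations=20, seed=int(rng.integers(2 ** 31)))
            deltas.append(mixing(emd(x, params), f_hi, f_lo)
                          - mixing(ceemdan(x, p), f_hi, f_lo))
        assert np.mean(deltas) > 0

    def test_frequency_ordering(self, fast_ceemdan):
        """Median instantaneous frequency should be non-increasing across
        modes for nearly all random two-tone signals. Tone splitting can tie
        adjacent modes at the same scale, so inversions up to 10% of the
        preceding median are tolerated and modes carrying < 2% of the energy
        (noise-dominated split-tone remnants) are not ranked."""
        rng = np.random.default_rng(3)
        fs = 250.0
        t = np.arange(0, 3, 1 / fs)
        ok = 0
        n_trials = 20
        for i in range(n_trials):
            f1, f2 = rng.uniform(15, 30), rng.uniform(2, 6)
            x = (np.sin(2 * np.pi * f1 * t + rng.uniform(0, 6))
                 + 2 * np.sin(2 * np.pi * f2 * t + rng.uniform(0, 6))
                 + 0.1 * rng.standard_normal(t.size))
            p = CeemdanParams(n_realizations=20, seed=int(rng.integers(2 ** 31)))
            s = ceemdan(x, p, fs=fs)
            energies = np.array([(m ** 2).sum() for m in s.imfs])
            keep = energies >= 0.02 * energies.sum()
            med = [median_frequency(analytic(m, fs)) for m in s.imfs[keep]]
            if all(med[k + 1] <= 1.1 * med[k] for k in range(len(med) - 1)):
                ok += 1
        assert ok / n_trials >= 0.95


class TestReconstructAndSerialization:
    def test_k0_reconstruct(self):
        x = np.linspace(0, 1, 300)
        s = IMFSet(imfs=np.empty((0, 300)), residual=x, fs=250.0)
        np.testing.assert_array_equal(reconstruct(s), x)

    def test_zeroed_imf1_removes_high_tone(self, two_tone_500hz):
        hi, lo, fs = two_tone_500hz
        x = hi + lo
        s = emd(x, fs=fs)  # plain EMD puts the clean 25 Hz tone in IMF1
        m = s.to_matrix()
        m[0] = 0.0
        y = IMFSet.from_matrix(m, fs=fs)
        rec = reconstruct(y)

        def power_at(sig, f0):
            spec = np.abs(np.fft.rfft(sig)) ** 2
            freqs = np.fft.rfftfreq(sig.size, 1 / fs)
            return spec[(freqs > f0 - 1) & (freqs < f0 + 1)].sum()

        assert power_at(rec, 25.0) < 0.05 * power_at(x, 25.0)

    def test_matrix_round_trip(self, two_tone_500hz, fast_ceemdan):
        hi, lo, fs = two_tone_500hz
        s = ceemdan(hi + lo, fast_ceemdan, fs=fs)
        r = IMFSet.from_matrix(s.to_matrix(), fs=fs)
        np.testing.assert_array_equal(r.imfs, s.imfs)
        np.testing.assert_array_equal(r.residual, s.residual)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            IMFSet(imfs=np.zeros((2, 100)), residual=np.zeros(90), fs=250.0)


def test_params_validation():
    with pytest.raises(ValueError):
        CeemdanParams(n_realizations=0)
    with pytest.raises(ValueError):
        CeemdanParams(noise_scale=0.0)
    with pytest.raises(ValueError):
        CeemdanParams(max_imfs=0)
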