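"""Feature-descriptor contracts: closed-form stabilization, band weights,
energies, normalization, assembly toggles, and amplitude invariance."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ssrime.decomposition import CeemdanParams, ceemdan
from ssrime.features import (
    PSDBandPower,
    RIME,
    RWE,
    SSRIME,
    SSRIMEParams,
    band_weight,
    imf_energy,
    psd_bandpower_vector,
    relative_energies,
    rime_vector,
    rwe_vector,
    ssrime_vector,
    stabilization_factor,
)
from ssrime.hilbert import AnalyticIMF, analytic

FS = 250.0


def _an_from_freqs(freqs):
    f = np.asarray(freqs, dtype=float)
    return AnalyticIMF(np.ones(f.size), np.zeros(f.size), f, FS, edge_trim=0)


class TestStabilizationFactor:
    def test_constant_frequency_gives_one(self):
        assert stabilization_factor(_an_from_freqs([10.0] * 20), alpha=1.0) == 1.0

    def test_closed_form_mu10_sigma2(self):
        # mean 10, population std 2, alpha 1 -> exp(-0.2)
        an = _an_from_freqs([8.0, 12.0, 8.0, 12.0])
        assert stabilization_factor(an, alpha=1.0) == pytest.approx(math.exp(-0.2), abs=1e-12)

    def test_alpha_zero_disables(self):
        an = _an_from_freqs([3.0, 9.0, 30.0])
        assert stabilization_factor(an, alpha=0.0) == 1.0

    def test_degenerate_mean_penalized(self):
        an = _an_from_freqs([1.0, -1.0])
        assert stabilization_factor(an, alpha=1.0) == 0.0

    def test_monotone_in_alpha_and_dispersion(self):
        alphas = [0.5, 1.0, 2.0, 4.0]
        s_alpha = [stabilization_factor(_an_from_freqs([8.0, 12.0] * 5), a) for a in alphas]
        assert all(a > b for a, b in zip(s_alpha, s_alpha[1:]))
        sigmas = [0.5, 1.0, 2.0, 4.0]
        s_sigma = [stabilization_factor(_an_from_freqs([10 - s, 10 + s] * 5), 1.0) for s in sigmas]
        assert all(a > b for a, b in zip(s_sigma, s_sigma[1:]))

    def test_variance_form_option(self):
        an = _an_from_freqs([8.0, 12.0] * 5)  # sigma=2, var=4, mu=10
        assert stabilization_factor(an, 1.0, dispersion_as_variance=True) == pytest.approx(
            math.exp(-0.4), abs=1e-12)


class TestBandWeight:
    @pytest.mark.parametrize("mode", ["spectral_energy", "time_proportion"])
    def test_theta_tone_high_beta_tone_low(self, mode):
        t = np.arange(0, 3, 1 / FS)
        p = SSRIMEParams(weight_mode=mode)
        assert band_weight(analytic(np.sin(2 * np.pi * 6 * t), FS), p) >= 0.95
        assert band_weight(analytic(np.sin(2 * np.pi * 20 * t), FS), p) <= 0.05

    def test_zero_series(self):
        assert band_weight(analytic(np.zeros(500), FS), SSRIMEParams()) == 0.0

    def test_union_additivity_spectral_mode(self):
        """W over δ∪θ equals the sum of the separate band fractions."""
        rng = np.random.default_rng(0)
        t = np.arange(0, 3, 1 / FS)
        x = (np.sin(2 * np.pi * 2.5 * t) + np.sin(2 * np.pi * 6 * t)
             + 0.3 * rng.standard_normal(t.size))
        an = analytic(x, FS)
        from ssrime.hilbert import band_energy, total_interior_energy

        total = total_interior_energy(an)
        w_union = band_weight(an, SSRIMEParams())
        w_parts = (band_energy(an, (1.0, 4.0)) + band_energy(an, (4.0, 7.5))) / total
        assert w_union == pytest.approx(w_parts, rel=1e-12)


class TestIMFEnergy:
    def test_zero_series(self):
        assert imf_energy(np.zeros(500), "raw_imf", FS) == 0.0

    def test_unit_tone_analytic_vs_raw(self):
        t = np.arange(0, 3, 1 / FS)
        x = np.sin(2 * np.pi * 10 * t)
        e_analytic = imf_energy(x, "analytic_amplitude", FS)
        e_raw = imf_energy(x, "raw_imf", FS)
        n_interior = t.size - 2 * int(round(0.05 * t.size))
        assert e_analytic == pytest.approx(n_interior / FS, rel=0.02)
        assert e_raw == pytest.approx(0.5 * e_analytic, rel=0.02)


class TestRelativeEnergies:
    @pytest.mark.parametrize("energies,expected", [
        ([2.0, 2.0], [0.5, 0.5]),
        ([0.0, 0.0, 0.0], [0.0, 0.0, 0.0]),
        ([1.0, 3.0], [0.25, 0.75]),
    ])
    def test_examples(self, energies, expected):
        np.testing.assert_allclose(relative_energies(energies), expected, atol=1e-9)

    @given(st.lists(st.floats(min_value=0.0, max_value=1e6), min_size=1, max_size=12))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_sum_bounded_by_one(self, energies):
        ebar = relative_energies(energies)
        assert np.all(ebar >= 0)
        assert ebar.sum() <= 1.0 + 1e-12

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            relative_energies([1.0, -0.5])


@pytest.fixture(scope="module")
def theta_beta_imfset():
    """Two-tone fixture: equal-energy 6 Hz and 20 Hz components."""
    t = np.arange(0, 3, 1 / FS)
    x = np.sin(2 * np.pi * 6 * t) + np.sin(2 * np.pi * 20 * t)
    return ceemdan(x, CeemdanParams(n_realizations=20, seed=5), fs=FS)


class TestSSRIMEVector:
    def test_toggles_off_equals_rime_after_reordering(self, theta_beta_imfset):
        p = SSRIMEParams(include_stabilization=False, include_weighting=False)
        ss = ssrime_vector(theta_beta_imfset, p)
        ri = rime_vector(theta_beta_imfset, p)
        order = ss.per_imf_metadata["order"]
        k = order.size
        np.testing.assert_allclose(ss.values[:k], ri.values[:k][order], atol=1e-15)

    def test_theta_imf_dominates_beta_imf(self, theta_beta_imfset):
        fv = ssrime_vector(theta_beta_imfset, SSRIMEParams())
        med = fv.per_imf_metadata["median_freq"]
        theta_k = np.nanargmin(np.abs(med - 6.0))
        beta_k = np.nanargmin(np.abs(med - 20.0))
        assert fv.values[theta_k] > 5 * fv.values[beta_k]

    def test_amplitude_invariance(self, theta_beta_imfset):
        t = np.arange(0, 3, 1 / FS)
        x = np.sin(2 * np.pi * 6 * t) + np.sin(2 * np.pi * 20 * t)
        base = ssrime_vector(theta_beta_imfset, SSRIMEParams()).values
        for c in (0.1, 10.0):
            s = ceemdan(c * x, CeemdanParams(n_realizations=20, seed=5), fs=FS)
            v = ssrime_vector(s, SSRIMEParams()).values
            assert np.abs(v - base).max() < 1e-6

    def test_ssrime_bounded_by_relative_energy(self, theta_beta_imfset):
        fv = ssrime_vector(theta_beta_imfset, SSRIMEParams())
        assert np.all(fv.values <= fv.per_imf_metadata["Ebar"] + 1e-15)

    def test_reordering_idempotent(self, theta_beta_imfset):
        from ssrime.features import _imf_components, _stabilized_order

        comp = _imf_components(theta_beta_imfset, SSRIMEParams())
        order1 = _stabilized_order(comp.median_freq)
        order2 = _stabilized_order(comp.median_freq[order1])
        np.testing.assert_array_equal(order2, np.arange(order2.size))

    def test_empty_imfset_zero_vector(self):
        from ssrime.decomposition import IMFSet

        s = IMFSet(imfs=np.empty((0, 600)), residual=np.zeros(600), fs=FS)
        fv = ssrime_vector(s, SSRIMEParams(K=8))
        assert fv.values.shape == (8,)
        assert np.all(fv.values == 0)

    def test_padding_to_k(self, theta_beta_imfset):
        fv = ssrime_vector(theta_beta_imfset, SSRIMEParams(K=12))
        assert fv.values.shape == (12,)


class TestRIMEVector:
    def test_sums_to_one(self, theta_beta_imfset):
        fv = rime_vector(theta_beta_imfset)
        assert fv.values.sum() == pytest.approx(1.0, abs=1e-9)

    def test_single_imf(self):
        from ssrime.decomposition import IMFSet

        t = np.arange(0, 3, 1 / FS)
        s = IMFSet(imfs=np.sin(2 * np.pi * 6 * t)[None, :], residual=np.zeros(t.size), fs=FS)
        fv = rime_vector(s, SSRIMEParams(K=1))
        np.testing.assert_allclose(fv.values, [1.0], atol=1e-9)


class TestRWEVector:
    def test_sums_to_one_and_zero_signal(self):
        rng = np.random.default_rng(1)
        fv = rwe_vector(rng.standard_normal(768))
        assert fv.values.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(rwe_vector(np.zeros(768)).values == 0)

    def test_too_short_raises(self):
        with pytest.raises(ValueError, match="32"):
            rwe_vector(np.zeros(16), n_levels=5)

    def test_white_noise_energy_tracks_bandwidth(self):
        """Dyadic subbands halve in width; white-noise energy should follow,
        within sampling tolerance over seeds."""
        rng = np.random.default_rng(7)
        vals = np.mean([rwe_vector(rng.standard_normal(4096), n_levels=4).values
                        for _ in range(20)], axis=0)
        # d1 covers half the spectrum, d2 a quarter, ...
        expected = np.array([0.5, 0.25, 0.125, 0.0625, 0.0625])
        np.testing.assert_allclose(vals, expected, rtol=0.3)


class TestPSDBandPower:
    def test_theta_tone_theta_dominant(self):
        t = np.arange(0, 3, 1 / FS)
        fv = psd_bandpower_vector(np.sin(2 * np.pi * 6 * t), FS)
        assert fv.values[1] >= 0.9  # theta is index 1

    def test_alpha_tone_alpha_dominant(self):
        t = np.arange(0, 3, 1 / FS)
        fv = psd_bandpower_vector(np.sin(2 * np.pi * 10 * t), FS)
        assert np.argmax(fv.values) == 2

    def test_zero_signal(self):
        assert np.all(psd_bandpower_vector(np.zeros(750), FS).values == 0)


class TestTransformers:
    def test_shapes_and_feature_names(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((3, 2, 750))
        for est, width in [(SSRIME(fs=FS, K=4, n_realizations=5), 8),
                           (RIME(fs=FS, K=4, n_realizations=5), 8),
                           (RWE(n_levels=4), 10),
                           (PSDBandPower(fs=FS), 10)]:
            mat = est.fit(X).transform(X)
            assert mat.shape == (3, width)
            assert len(est.feature_names()) == width

    def test_sklearn_clone_and_params(self):
        from sklearn.base import clone

        est = SSRIME(fs=FS, K=4, alpha=2.0)
        c = clone(est)
        assert c.get_params()["alpha"] == 2.0

    def test_pipeline_composition(self):
        from sklearn.pipeline import make_pipeline
        from sklearn.svm import SVC

        rng = np.random.default_rng(2)
        X = rng.standard_normal((10, 2, 750))
        y = np.array([0, 1] * 5)
        pipe = make_pipeline(RWE(n_levels=4), SVC())
        pipe.fit(X, y)
        assert pipe.predict(X).shape == (10,)

    def test_invalid_input_rejected(self):
        with pytest.raises(ValueError):
            SSRIME().fit(np.zeros((3, 750)))


def test_params_validation():
    with pytest.raises(ValueError):
        SSRIMEParams(alpha=-0.1)
    with pytest.raises(ValueError):
        SSRIMEParams(epsilon=0.0)
    with pytest.raises(ValueError):
        SSRIMEParams(delta_band=(4.0, 1.0))
    with pytest.raises(ValueError):
        SSRIMEParams(weight_mode="nope")
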