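"""Morlet decomposition, phase/amplitude extraction and band bookkeeping."""

import numpy as np
import pytest
import pywt
from hypothesis import given, settings
from hypothesis import strategies as st

from nirsnet import (
    ANALYSIS_BAND,
    PHYSIOLOGICAL_BANDS,
    BandSet,
    Decomposition,
    WaveletSpec,
    amplitude,
    band_average,
    cwt_morlet,
    phase,
)

FS = 13.33


def make_decomp(coeffs: np.ndarray, freqs=None) -> Decomposition:
    if freqs is None:
        freqs = np.linspace(0.1, 1.0, coeffs.shape[0])
    return Decomposition(coefficients=coeffs, frequencies=freqs, fs=FS)


class TestGridAndBands:
    def test_grid_log_spaced_increasing_below_nyquist(self):
        f = WaveletSpec().frequencies()
        assert (np.diff(f) > 0).all()
        assert f[0] == pytest.approx(0.005)
        assert f[-1] == pytest.approx(2.0)
        ratios = f[1:13] / f[:12]
        np.testing.assert_allclose(ratios, 2 ** (1 / 12), rtol=1e-9)

    def test_six_contiguous_physiological_intervals(self):
        bands = BandSet()
        assert len(bands.bands) == 6
        assert bands.contiguous()
        assert bands.bands["IV"] == (0.021, 0.052)  # neurogenic
        assert bands.analysis_band == (0.01, 0.1)

    def test_restrict_keeps_strict_interior(self):
        spec = WaveletSpec().restrict(ANALYSIS_BAND)
        f = spec.frequencies()
        assert (f > 0.01).all() and (f < 0.1).all()


class TestCwt:
    def test_zero_signal_zero_coefficients(self):
        d = cwt_morlet(np.zeros(8000), fs=FS)
        np.testing.assert_array_equal(d.coefficients, 0.0)

    def test_linearity(self, rng):
        x = rng.standard_normal(8000)
        d1 = cwt_morlet(x, fs=FS)
        d2 = cwt_morlet(2.5 * x, fs=FS)
        np.testing.assert_allclose(d2.coefficients, 2.5 * d1.coefficients, atol=1e-10)

    def test_sinusoid_peaks_at_its_frequency(self):
        """Argmax over the grid lands on the probe frequency (inner-product oracle)."""
        spec = WaveletSpec(fmin=0.05, fmax=2.0)
        freqs = spec.frequencies()
        f0 = freqs[18]
        n = 8000
        t = np.arange(n) / FS
        x = np.sin(2 * np.pi * f0 * t)
        d = cwt_morlet(x, spec=spec, fs=FS)
        mean_mod = np.abs(d.coefficients).mean(axis=1)
        assert freqs[np.argmax(mean_mod)] == pytest.approx(f0)
        # L1 normalization: a unit real sinusoid responds with modulus ~1/2.
        assert mean_mod.max() == pytest.approx(0.5, rel=0.02)

    def test_matches_direct_inner_product_oracle(self):
        """Coefficients equal the brute-force wavelet inner product
        (1/s) * sum_u x[u] psi*((u - t)/s) away from the edges."""
        spec = WaveletSpec()
        rng = np.random.default_rng(7)
        x = rng.standard_normal(1200)
        f0 = 0.5
        d = cwt_morlet(x, spec=spec, fs=FS, frequencies=np.array([f0]))
        s = spec.center * FS / f0
        u = np.arange(1200)
        for t0 in [400, 600, 800]:
            arg = (u - t0) / s
            psi = (
                (np.pi * spec.bandwidth) ** -0.5
                * np.exp(2j * np.pi * spec.center * arg)
                * np.exp(-(arg**2) / spec.bandwidth)
            )
            expected = (x * psi.conj()).sum() / s
            assert d.coefficients[0, t0] == pytest.approx(expected, rel=1e-6)

    def test_agrees_with_pywavelets_oracle(self):
        """Independent cross-check: phases match pywt's cmor2.0-0.5 away from
        the edges, and moduli agree up to one scale-dependent constant."""
        spec = WaveletSpec()
        rng = np.random.default_rng(3)
        x = rng.standard_normal(4000)
        freqs = np.array([0.2, 0.5, 1.0])
        d = cwt_morlet(x, spec=spec, fs=FS, frequencies=freqs)
        scales = spec.center * FS / freqs
        ref, ref_freqs = pywt.cwt(x, scales, "cmor2.0-0.5", sampling_period=1 / FS)
        np.testing.assert_allclose(ref_freqs, freqs, rtol=1e-6)
        sl = slice(1000, 3000)
        for k in range(freqs.size):
            mine = np.angle(d.coefficients[k, sl])
            theirs = np.angle(ref[k, sl])
            # strong phase locking up to pywt's sign/offset convention
            locking = max(
                np.abs(np.exp(1j * (mine - theirs)).mean()),
                np.abs(np.exp(1j * (mine + theirs)).mean()),
            )
            assert locking > 0.98
            ratio = np.abs(d.coefficients[k, sl]).mean() / np.abs(ref[k, sl]).mean()
            assert 0.05 < ratio < 20

    def test_nyquist_and_length_preconditions(self):
        with pytest.raises(ValueError, match="Nyquist"):
            cwt_morlet(np.zeros(1000), fs=1.0, frequencies=np.array([0.6]))
        with pytest.raises(ValueError, match="cycles"):
            cwt_morlet(np.zeros(100), fs=1.0, frequencies=np.array([0.01]))


class TestPhase:
    @pytest.mark.parametrize(
        "a,b,expected",
        [(1.0, 0.0, 0.0), (0.0, 1.0, np.pi / 2), (-1.0, 0.0, np.pi)],
    )
    def test_four_quadrant_angle(self, a, b, expected):
        d = make_decomp(np.array([[a + 1j * b]]), freqs=np.array([0.1]))
        assert phase(d)[0, 0] == pytest.approx(expected)

    def test_zero_magnitude_flagged(self):
        d = make_decomp(np.array([[0.0 + 0.0j, 1.0 + 0.0j]]), freqs=np.array([0.1]))
        ph = phase(d)
        assert np.isnan(ph[0, 0]) and ph[0, 1] == 0.0

    def test_range_and_scale_invariance(self, rng):
        coeffs = rng.standard_normal((4, 50)) + 1j * rng.standard_normal((4, 50))
        d = make_decomp(coeffs)
        ph = phase(d)
        assert (ph > -np.pi).all() and (ph <= np.pi).all()
        np.testing.assert_allclose(phase(make_decomp(3.0 * coeffs)), ph, atol=1e-12)


class TestAmplitude:
    def test_three_four_five(self):
        d = make_decomp(np.full((1, 10), 3.0 + 4.0j), freqs=np.array([0.1]))
        assert amplitude(d)[0] == pytest.approx(5.0)

    def test_zero_coefficients(self):
        d = make_decomp(np.zeros((2, 8), dtype=complex))
        np.testing.assert_array_equal(amplitude(d), 0.0)

    def test_matches_elementwise_loop_oracle(self, rng):
        coeffs = rng.standard_normal((3, 40)) + 1j * rng.standard_normal((3, 40))
        d = make_decomp(coeffs)
        expected = [
            sum(abs(coeffs[k, t]) for t in range(40)) / 40 for k in range(3)
        ]
        np.testing.assert_allclose(amplitude(d), expected, atol=1e-12)

    @settings(derandomize=True, deadline=None, max_examples=20)
    @given(seed=st.integers(0, 2**20), c=st.floats(-4, 4, allow_nan=False))
    def test_positive_homogeneity(self, seed, c):
        r = np.random.default_rng(seed)
        coeffs = r.standard_normal((2, 30)) + 1j * r.standard_normal((2, 30))
        d, dc = make_decomp(coeffs), make_decomp(c * coeffs)
        np.testing.assert_allclose(amplitude(dc), abs(c) * amplitude(d), atol=1e-10)

    def test_sinusoid_amplitude_proportionality(self):
        """Band amplitude scales 1:2:4 with input amplitudes 1, 2, 4."""
        spec = WaveletSpec(fmin=0.02, fmax=0.2)
        freqs = spec.frequencies()
        n = 8000
        t = np.arange(n) / FS
        vals = []
        for A in (1.0, 2.0, 4.0):
            d = cwt_morlet(A * np.sin(2 * np.pi * 0.05 * t), spec=spec, fs=FS)
            vals.append(band_average(amplitude(d), freqs, (0.03, 0.08)))
        assert vals[1] / vals[0] == pytest.approx(2.0, rel=0.01)
        assert vals[2] / vals[0] == pytest.approx(4.0, rel=0.01)


class TestBandAverage:
    def test_constant_returns_constant(self):
        f = np.linspace(0.01, 0.1, 11)
        assert band_average(np.full(11, 0.42), f, (0.0, 1.0)) == pytest.approx(0.42)

    def test_single_point_band(self):
        f = np.array([0.01, 0.05, 0.2])
        assert band_average(np.array([1.0, 7.0, 3.0]), f, (0.04, 0.06)) == 7.0

    def test_linear_values_match_loop_oracle(self):
        f = np.linspace(0.02, 0.08, 7)
        v = np.arange(7.0)
        lo, hi = 0.01, 0.1
        expected = np.mean([v[i] for i in range(7) if lo < f[i] < hi])
        assert band_average(v, f, (lo, hi)) == pytest.approx(expected)

    def test_empty_band_rejected(self):
        with pytest.raises(ValueError):
            band_average(np.ones(3), np.array([0.1, 0.2, 0.3]), (0.4, 0.5))


class TestConeOfInfluence:
    def test_mask_wider_at_lower_frequencies(self, rng):
        from nirsnet.wavelet import coi_mask

        d = cwt_morlet(rng.standard_normal(8000), fs=FS)
        mask = coi_mask(d)
        widths = mask.sum(axis=1)
        assert (np.diff(widths) <= 0).all()  # low freq first on the grid? no: grid ascends
        assert widths[0] > widths[-1]  # slowest scale has the widest cone

    def test_excluding_coi_changes_only_edge_weighting(self, rng):
        from nirsnet.wavelet import coi_mask

        x = rng.standard_normal(8000)
        d = cwt_morlet(x, fs=FS, frequencies=np.array([0.5]))
        full = amplitude(d)
        interior = amplitude(d, exclude_coi=True)
        mask = ~coi_mask(d)[0]
        expected = np.abs(d.coefficients[0])[mask].mean()
        assert interior[0] == pytest.approx(expected)
        assert interior[0] != full[0]


class TestExportModulus:
    def test_container_and_header_roundtrip(self, rng, tmp_path):
        import json

        from nirsnet.wavelet import export_modulus

        d = cwt_morlet(rng.standard_normal(8000), fs=FS)
        out = tmp_path / "decomp.npz"
        export_modulus(d, out)
        data = np.load(out)
        np.testing.assert_allclose(data["modulus"], np.abs(d.coefficients))
        header = json.loads((tmp_path / "decomp.json").read_text())
        assert header["fs_hz"] == FS
        np.testing.assert_allclose(header["frequencies_hz"], d.frequencies)
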