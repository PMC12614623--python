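"""Analytic-signal construction, envelope and baseline features, and
feature-matrix assembly, each checked against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal as sp_signal
from scipy.linalg import hadamard

from hybridbci import (
    Modality,
    ValidationError,
    analytic_signal,
    bandpower_features,
    build_feature_matrix,
    fwht_feature,
    htabs,
    segment,
    stat_features,
)
from hybridbci.features import EEG_BANDS, HilbertEnvelope, fwht


def _tone(freq, fs=250.0, dur=2.4, amp=1.0, phase=0.0):
    t = np.arange(int(dur * fs)) / fs
    return amp * np.cos(2 * np.pi * freq * t + phase)


def _dft_analytic_oracle(x):
    """Direct O(n^2) construction: DFT, -i*sign(omega) phase shift for the
    imaginary part, independent of any FFT library path."""
    n = len(x)
    k = np.arange(n)
    W = np.exp(-2j * np.pi * np.outer(k, k) / n)
    X = W @ x
    sign = np.zeros(n)
    sign[1:(n + 1) // 2] = 1.0
    sign[(n + 2) // 2:] = -1.0  # negative-frequency bins
    Xh = -1j * sign * X
    hilbert_part = (np.conj(W).T @ Xh) / n
    return x + 1j * hilbert_part.real


class TestAnalyticSignal:
    def test_quadrature_identity_for_cosine(self):
        # integer number of periods: imag part is the matching sine
        x = _tone(10.0)
        t = np.arange(len(x)) / 250.0
        a = analytic_signal(x)
        np.testing.assert_allclose(a.real, x, atol=1e-9)
        np.testing.assert_allclose(
            a.imag[50:-50], np.sin(2 * np.pi * 10.0 * t)[50:-50], atol=1e-6
        )

    def test_zero_signal_maps_to_zero(self):
        np.testing.assert_array_equal(analytic_signal(np.zeros(64)), 0.0)

    @pytest.mark.parametrize("n", [16, 64, 65, 128])
    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_direct_dft_oracle(self, n, seed):
        x = np.random.default_rng(seed).standard_normal(n)
        np.testing.assert_allclose(
            analytic_signal(x), _dft_analytic_oracle(x), atol=1e-8
        )

    def test_matches_scipy_hilbert(self, rng):
        x = rng.standard_normal(200)
        np.testing.assert_allclose(
            analytic_signal(x), sp_signal.hilbert(x), atol=1e-10
        )

    def test_too_short_or_nan_raises(self):
        with pytest.raises(ValidationError):
            analytic_signal(np.array([1.0]))
        with pytest.raises(ValidationError):
            analytic_signal(np.array([1.0, np.nan, 2.0]))


class TestHtabs:
    def test_tone_envelope_equals_amplitude(self):
        assert htabs(_tone(10.0, amp=2.0)) == pytest.approx(2.0, rel=0.01)

    def test_zero_window_gives_zero(self):
        assert htabs(np.zeros(128)) == 0.0

    def test_homogeneity(self, rng):
        x = rng.standard_normal(300)
        assert htabs(3.0 * x) == pytest.approx(3.0 * htabs(x), rel=1e-10)

    # magnitudes >= 1e-6 or exactly 0: squaring denormal-range values
    # underflows to 0 in the modulus, which is float arithmetic, not a
    # property of the feature
    @given(st.lists(
        st.one_of(st.just(0.0), st.floats(1e-6, 1e3), st.floats(-1e3, -1e-6)),
        min_size=2, max_size=64,
    ))
    @settings(max_examples=50, deadline=None)
    def test_non_negative_and_zero_iff_zero(self, values):
        x = np.asarray(values)
        v = htabs(x)
        assert v >= 0.0
        if np.any(x != 0.0):
            assert v > 0.0
        else:
            assert v == 0.0


class TestWalshHadamard:
    def test_constant_signal_feature(self):
        # orthonormal transform of a constant c: single coeff c*sqrt(n)
        c, m = 3.0, 4
        n = 2 ** m
        assert fwht_feature(np.full(n, c)) == pytest.approx(
            abs(c) * 2 ** (m / 2) / n, rel=1e-12
        )

    def test_zero_signal(self):
        assert fwht_feature(np.zeros(8)) == 0.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_hadamard_matrix_oracle(self, seed):
        x = np.random.default_rng(seed).standard_normal(8)
        H = hadamard(8)
        expected = np.mean(np.abs(H @ x / np.sqrt(8)))
        assert fwht_feature(x) == pytest.approx(expected, abs=1e-10)

    def test_non_power_of_two_is_zero_padded(self, rng):
        x = rng.standard_normal(24)
        padded = np.pad(x, (0, 8))
        H = hadamard(32)
        expected = np.mean(np.abs(H @ padded / np.sqrt(32)))
        assert fwht_feature(x) == pytest.approx(expected, abs=1e-10)

    def test_transform_is_orthonormal(self, rng):
        x = rng.standard_normal(64)
        np.testing.assert_allclose(np.sum(fwht(x) ** 2), np.sum(x ** 2), rtol=1e-10)


class TestBandPower:
    def test_alpha_tone_concentrates_in_alpha(self):
        x = _tone(10.0)
        bp = bandpower_features(x, 250.0, ((8.0, 13.0), (13.0, 30.0)))
        assert bp[0] >= 50.0 * bp[1]

    def test_zero_signal_gives_zero(self):
        bp = bandpower_features(np.zeros(600), 250.0, EEG_BANDS)
        np.testing.assert_array_equal(bp, 0.0)

    def test_white_noise_power_proportional_to_bandwidth(self):
        rng = np.random.default_rng(7)
        bands = ((8.0, 13.0), (13.0, 30.0))  # widths 5 and 17 Hz
        acc = np.zeros(2)
        for _ in range(100):
            acc += bandpower_features(rng.standard_normal(600), 250.0, bands)
        ratio = acc[1] / acc[0]
        assert ratio == pytest.approx(17.0 / 5.0, rel=0.25)

    def test_band_beyond_nyquist_raises(self):
        with pytest.raises(ValidationError):
            bandpower_features(np.zeros(600), 250.0, ((130.0, 140.0),))


class TestStatFeatures:
    def test_constant_window(self):
        f = stat_features(np.full(16, -2.5))
        mean, var, skew, kurt, mav, rms = f
        assert (mean, var, skew, kurt) == (-2.5, 0.0, 0.0, 0.0)
        assert mav == rms == 2.5

    def test_alternating_signal_hand_arithmetic(self):
        f = stat_features(np.array([1.0, -1.0, 1.0, -1.0]))
        mean, var, skew, kurt, mav, rms = f
        assert mean == 0.0 and var == 1.0 and mav == 1.0 and rms == 1.0

    def test_matches_two_pass_moment_oracle(self, rng):
        x = rng.standard_normal(100)
        mean = sum(x) / len(x)
        var = sum((v - mean) ** 2 for v in x) / len(x)
        skew = (sum((v - mean) ** 3 for v in x) / len(x)) / var ** 1.5
        kurt = (sum((v - mean) ** 4 for v in x) / len(x)) / var ** 2
        mav = sum(abs(v) for v in x) / len(x)
        rms = (sum(v ** 2 for v in x) / len(x)) ** 0.5
        np.testing.assert_allclose(
            stat_features(x), [mean, var, skew, kurt, mav, rms], atol=1e-10
        )

    def test_too_short_raises(self):
        with pytest.raises(ValidationError):
            stat_features(np.array([1.0, 2.0, 3.0]))


@pytest.fixture(scope="module")
def segments(preprocessed_dataset):
    return segment(preprocessed_dataset, 2.4)


class TestFeatureMatrix:
    @pytest.mark.parametrize(
        "modality_set,n_cols",
        [("eeg+oxy", 48), ("eeg+deoxy", 48), ("eeg", 30), ("deoxy", 18)],
    )
    def test_ht_column_arithmetic(self, segments, modality_set, n_cols):
        fm = build_feature_matrix(segments, modality_set, "ht")
        assert fm.X.shape == (1200, n_cols)
        assert len(set(fm.columns)) == n_cols
        np.testing.assert_array_equal(
            np.sort(np.unique(fm.labels)), [1, 2, 3, 4]
        )

    def test_per_band_mode_concatenates_four_envelopes(self, segments):
        fm = build_feature_matrix(segments, "eeg", "ht", ht_mode="per_band")
        assert fm.X.shape == (1200, 120)

    @pytest.mark.parametrize("family,cols", [("fwht", 48), ("sf", 288), ("bp", 138)])
    def test_baseline_family_shapes(self, segments, family, cols):
        # fwht: 1/ch; sf: 6/ch; bp: 4/EEG ch + 1/NIRS ch = 120 + 18
        fm = build_feature_matrix(segments[:40], "eeg+oxy", family)
        assert fm.X.shape == (40, cols)

    def test_row_permutation_is_row_exact(self, segments):
        sub = segments[:60]
        fm = build_feature_matrix(sub, "eeg+oxy", "ht")
        perm = np.random.default_rng(0).permutation(len(sub))
        fm_p = build_feature_matrix([sub[i] for i in perm], "eeg+oxy", "ht")
        np.testing.assert_array_equal(fm_p.X, fm.X[perm])
        assert fm_p.groups == tuple(fm.groups[i] for i in perm)

    def test_missing_modality_raises(self, default_dataset):
        segs = segment(default_dataset, 2.4)  # raw: no OXY yet
        with pytest.raises(ValidationError, match="oxy"):
            build_feature_matrix(segs[:10], "eeg+oxy", "ht")

    def test_envelope_extractor_rejects_2d_input(self):
        with pytest.raises(ValidationError):
            HilbertEnvelope().fit(np.zeros((10, 600)))
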