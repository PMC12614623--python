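"""Feature extraction: Hilbert-envelope features and the FWHT/BP/SF baselines.

The primary feature is the mean modulus of the analytic signal over a window
(``HTabs``): the analytic signal is built in the frequency domain by zeroing
negative-frequency bins and doubling positive ones — equivalently applying
the -i*sign(omega) phase shift of the Hilbert transform to form the
imaginary part — and the feature is (1/n) * sum sqrt(Re^2 + Im^2).  One
value per channel per window; hybrid modality sets concatenate channels
(30 EEG + 18 NIRS = 48 columns).

Baselines: mean absolute orthonormal Walsh-Hadamard coefficient (FWHT),
Welch band power over canonical EEG bands (BP), and six statistical moments
(SF).

Feature extractors are sklearn-style transformers over 3-D arrays
(n_segments, n_channels, n_times) -> 2-D feature matrices, so they compose
with sklearn pipelines the way mne.decoding transformers do.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal
from scipy import stats as sp_stats
from sklearn.base import BaseEstimator, TransformerMixin

from .datamodel import Modality, ValidationError
from .windowing import Segment

__all__ = [
    "analytic_signal",
    "htabs",
    "fwht",
    "fwht_feature",
    "bandpower_features",
    "stat_features",
    "HilbertEnvelope",
    "WalshHadamardMean",
    "BandPower",
    "StatisticalMoments",
    "FeatureMatrix",
    "build_feature_matrix",
    "EEG_BANDS",
    "NIRS_BANDS",
]

logger = logging.getLogger(__name__)

#: canonical EEG rhythm bands (Hz): delta, theta, alpha, beta
EEG_BANDS = ((1.0, 4.0), (4.0, 8.0), (8.0, 13.0), (13.0, 30.0))
#: hemodynamic activity band (Hz)
NIRS_BANDS = ((0.01, 0.2),)

STAT_NAMES = ("mean", "variance", "skewness", "kurtosis", "mav", "rms")


# ---------------------------------------------------------------------------
# analytic signal / Hilbert envelope

def analytic_signal(x: np.ndarray) -> np.ndarray:
    """Discrete analytic signal of ``x`` along the last axis.

    Frequency-domain construction: FFT, zero the negative-frequency bins,
    double the positive ones (DC and Nyquist unchanged), inverse FFT.  The
    real part equals ``x`` to numerical precision; the imaginary part is the
    Hilbert transform.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    if n < 2:
        raise ValidationError("analytic_signal requires length >= 2")
    if not np.all(np.isfinite(x)):
        raise ValidationError("analytic_signal input contains non-finite values")
    spectrum = np.fft.fft(x, axis=-1)
    h = np.zeros(n)
    h[0] = 1.0
    if n % 2 == 0:
        h[1:n // 2] = 2.0
        h[n // 2] = 1.0
    else:
        h[1:(n + 1) // 2] = 2.0
    return np.fft.ifft(spectrum * h, axis=-1)


def htabs(x: np.ndarray) -> np.ndarray | float:
    """Mean modulus of the analytic signal along the last axis.

    For a pure tone of amplitude A over whole periods this equals A; it is
    non-negative and zero only for the all-zero window.
    """
    out = np.mean(np.abs(analytic_signal(x)), axis=-1)
    return float(out) if np.ndim(out) == 0 else out


# ---------------------------------------------------------------------------
# Walsh-Hadamard

def _next_pow2(n: int) -> int:
    return 1 << (n - 1).bit_length()


def fwht(x: np.ndarray) -> np.ndarray:
    """Orthonormal fast Walsh-Hadamard transform along the last axis.

    Input length must be a power of two; the butterfly is O(n log n) and the
    result is normalized by 1/sqrt(n) (natural/Hadamard ordering).
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    if n & (n - 1) or n == 0:
        raise ValidationError("fwht requires a power-of-two length")
    y = x.copy()
    h = 1
    while h < n:
        y = y.reshape(*x.shape[:-1], n // (2 * h), 2, h)
        a = y[..., 0, :] + y[..., 1, :]
        b = y[..., 0, :] - y[..., 1, :]
        y = np.concatenate([a[..., None, :], b[..., None, :]], axis=-2)
        y = y.reshape(*x.shape[:-1], n)
        h *= 2
    return y / np.sqrt(n)


def fwht_feature(x: np.ndarray) -> np.ndarray | float:
    """Mean absolute orthonormal Walsh-Hadamard coefficient.

    ``x`` is zero-padded to the next power of two along the last axis.
    Mirrors the "mean magnitude" shape of the Hilbert feature.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValidationError("fwht_feature input contains non-finite values")
    n = x.shape[-1]
    m = _next_pow2(max(n, 1))
    if m != n:
        pad = [(0, 0)] * (x.ndim - 1) + [(0, m - n)]
        x = np.pad(x, pad)
    out = np.mean(np.abs(fwht(x)), axis=-1)
    return float(out) if np.ndim(out) == 0 else out


# ---------------------------------------------------------------------------
# band power

def bandpower_features(
    x: np.ndarray, fs: float, bands: tuple[tuple[float, float], ...]
) -> np.ndarray:
    """Welch band power of ``x`` (last axis = time), one value per band.

    Welch parameters: Hann taper, segment length min(n, 256), 50% overlap.
    A band contributes the rectangle-integrated PSD over the frequency bins
    whose cells overlap (low, high); a band entirely outside the resolvable
    grid raises.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    for low, high in bands:
        if not 0 <= low < high:
            raise ValidationError("band edges must satisfy 0 <= low < high")
        if high >= fs / 2 and low >= fs / 2:
            raise ValidationError(f"band ({low}, {high}) Hz beyond Nyquist {fs / 2}")
    nperseg = min(n, 256)
    freqs, psd = sp_signal.welch(
        x, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2, axis=-1
    )
    df = freqs[1] - freqs[0] if len(freqs) > 1 else fs / 2
    out = []
    for low, high in bands:
        mask = (freqs + df / 2 > low) & (freqs - df / 2 < high)
        if not mask.any():
            raise ValidationError(
                f"band ({low}, {high}) Hz is empty after discretization "
                f"(df={df:.4g} Hz)"
            )
        out.append(psd[..., mask].sum(axis=-1) * df)
    return np.stack(out, axis=-1)


# ---------------------------------------------------------------------------
# statistical features

def stat_features(x: np.ndarray) -> np.ndarray:
    """Six moments per window: mean, population variance, skewness,
    non-excess kurtosis, mean absolute value, root mean square.

    Zero-variance windows report skewness/kurtosis as 0 (logged)."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < 4:
        raise ValidationError("stat_features requires length >= 4")
    mean = x.mean(axis=-1)
    var = x.var(axis=-1)
    import warnings as _warnings

    with np.errstate(invalid="ignore", divide="ignore"), _warnings.catch_warnings():
        # constant windows trip scipy's catastrophic-cancellation warning;
        # they are handled explicitly below
        _warnings.simplefilter("ignore", RuntimeWarning)
        skew = sp_stats.skew(x, axis=-1, bias=True)
        kurt = sp_stats.kurtosis(x, axis=-1, fisher=False, bias=True)
    degenerate = ~np.isfinite(skew) | ~np.isfinite(kurt) | (var == 0)
    if np.any(degenerate):
        logger.info("zero-variance window(s): skewness/kurtosis reported as 0")
        skew = np.where(degenerate, 0.0, skew)
        kurt = np.where(degenerate, 0.0, kurt)
    mav = np.abs(x).mean(axis=-1)
    rms = np.sqrt((x ** 2).mean(axis=-1))
    return np.stack([mean, var, skew, kurt, mav, rms], axis=-1)


# ---------------------------------------------------------------------------
# sklearn-style extractors over (n_segments, n_channels, n_times)

class _SegmentFeatureExtractor(TransformerMixin, BaseEstimator):
    """Base: validates the 3-D input, exposes per-channel feature labels."""

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValidationError("expected (n_segments, n_channels, n_times)")
        self.n_channels_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValidationError("expected (n_segments, n_channels, n_times)")
        feats = self._extract(X)  # (n_seg, n_ch, n_feat)
        return feats.reshape(X.shape[0], -1)

    def feature_labels(self) -> tuple[str, ...]:
        raise NotImplementedError


class HilbertEnvelope(_SegmentFeatureExtractor):
    """HTabs per channel: one value ('broadband') or one per EEG rhythm band
    ('per_band', band-pass then envelope; requires ``sampling_rate_hz``)."""

    def __init__(self, ht_mode: str = "broadband",
                 bands: tuple = EEG_BANDS, sampling_rate_hz: float | None = None):
        self.ht_mode = ht_mode
        self.bands = bands
        self.sampling_rate_hz = sampling_rate_hz

    def _extract(self, X):
        if self.ht_mode == "broadband":
            return htabs(X)[..., None]
        if self.ht_mode != "per_band":
            raise ValidationError("ht_mode must be 'broadband' or 'per_band'")
        if self.sampling_rate_hz is None:
            raise ValidationError("per_band mode requires sampling_rate_hz")
        cols = []
        for low, high in self.bands:
            sos = sp_signal.butter(4, [low, high], btype="bandpass",
                                   fs=self.sampling_rate_hz, output="sos")
            xb = sp_signal.sosfiltfilt(sos, X, axis=-1)
            cols.append(htabs(xb))
        return np.stack(cols, axis=-1)

    def feature_labels(self):
        if self.ht_mode == "broadband":
            return ("htabs",)
        return tuple(f"htabs_{low:g}-{high:g}Hz" for low, high in self.bands)


class WalshHadamardMean(_SegmentFeatureExtractor):
    """Mean absolute orthonormal Walsh-Hadamard coefficient per channel."""

    def _extract(self, X):
        return fwht_feature(X)[..., None]

    def feature_labels(self):
        return ("fwht",)


class BandPower(_SegmentFeatureExtractor):
    """Welch band power per channel over the configured bands."""

    def __init__(self, bands: tuple = EEG_BANDS, sampling_rate_hz: float = 250.0):
        self.bands = bands
        self.sampling_rate_hz = sampling_rate_hz

    def _extract(self, X):
        return bandpower_features(X, self.sampling_rate_hz, self.bands)

    def feature_labels(self):
        return tuple(f"bp_{low:g}-{high:g}Hz" for low, high in self.bands)


class StatisticalMoments(_SegmentFeatureExtractor):
    """The six statistical moments per channel."""

    def _extract(self, X):
        return stat_features(X)

    def feature_labels(self):
        return STAT_NAMES


# ---------------------------------------------------------------------------
# feature matrix assembly

@dataclass
class FeatureMatrix:
    """segments x named features, with labels and trial groups per row."""

    X: np.ndarray
    columns: tuple[str, ...]
    labels: np.ndarray
    groups: tuple[str, ...]      # parent trial id per row
    subjects: tuple[str, ...]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.columns = tuple(self.columns)
        self.groups = tuple(self.groups)
        self.subjects = tuple(self.subjects)
        if self.X.ndim != 2:
            raise ValidationError("feature matrix must be 2-D")
        if not np.all(np.isfinite(self.X)):
            raise ValidationError("feature matrix has missing/non-finite values")
        if len(self.columns) != self.X.shape[1]:
            raise ValidationError("column name count mismatch")
        if len(set(self.columns)) != len(self.columns):
            raise ValidationError("column names not unique")
        if not (len(self.labels) == len(self.groups) == len(self.subjects)
                == self.X.shape[0]):
            raise ValidationError("row metadata length mismatch")

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]


MODALITY_SETS: dict[str, tuple[Modality, ...]] = {
    "eeg": (Modality.EEG,),
    "oxy": (Modality.OXY,),
    "deoxy": (Modality.DEOXY,),
    "eeg+oxy": (Modality.EEG, Modality.OXY),
    "eeg+deoxy": (Modality.EEG, Modality.DEOXY),
}


def _extractor_for(feature_family: str, modality: Modality, rate: float,
                   ht_mode: str) -> _SegmentFeatureExtractor:
    family = feature_family.lower()
    if family == "ht":
        mode = ht_mode if modality is Modality.EEG else "broadband"
        return HilbertEnvelope(ht_mode=mode, sampling_rate_hz=rate)
    if family == "fwht":
        return WalshHadamardMean()
    if family == "bp":
        bands = EEG_BANDS if modality is Modality.EEG else NIRS_BANDS
        return BandPower(bands=bands, sampling_rate_hz=rate)
    if family == "sf":
        return StatisticalMoments()
    raise ValidationError(f"unknown feature family {feature_family!r}")


def build_feature_matrix(
    segments: list[Segment],
    modality_set: str,
    feature_family: str,
    ht_mode: str = "broadband",
    channel_ids: dict[Modality, tuple[str, ...]] | None = None,
) -> FeatureMatrix:
    """Compute the family's features per channel per modality and concatenate.

    For hybrid sets the EEG and NIRS columns are concatenated row-aligned by
    segment; with the HT family this yields 30 (EEG), 18 (OXY/DEOXY) or 48
    (hybrid) columns.
    """
    if not segments:
        raise ValidationError("no segments")
    key = modality_set.lower()
    if key not in MODALITY_SETS:
        raise ValidationError(f"unknown modality set {modality_set!r}")
    blocks: list[np.ndarray] = []
    names: list[str] = []
    for mod in MODALITY_SETS[key]:
        if any(mod not in s.blocks for s in segments):
            raise ValidationError(
                f"modality {mod.value} missing from segments (preprocess first?)"
            )
        X3 = np.stack([s.blocks[mod] for s in segments])
        rate = segments[0].sampling_rates[mod]
        extractor = _extractor_for(feature_family, mod, rate, ht_mode)
        feats = extractor.fit(X3).transform(X3)
        blocks.append(feats)
        n_ch = X3.shape[1]
        chans = (
            channel_ids[mod]
            if channel_ids is not None
            else tuple(f"ch{c:02d}" for c in range(n_ch))
        )
        for c in range(n_ch):
            for lab in extractor.feature_labels():
                names.append(f"{mod.value}:{chans[c]}:{lab}")
    X = np.concatenate(blocks, axis=1)
    return FeatureMatrix(
        X=X,
        columns=tuple(names),
        labels=np.array([s.label for s in segments]),
        groups=tuple(s.parent_trial_id for s in segments),
        subjects=tuple(s.subject_id for s in segments),
    )
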