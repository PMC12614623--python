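"""Noise filtering and Beer-Lambert inversion.

Both modalities are cleaned with 2nd-order Butterworth band-stop filters:
48-53 Hz on EEG (power-line interference) and 0.1-5 Hz on the NIRS optical
densities, applied zero-phase (forward-backward) by default.  Hemoglobin
concentration changes are then recovered from the two optical-density
wavelengths by solving the 2x2 modified Beer-Lambert system per channel and
time point.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal
from sklearn.base import BaseEstimator, TransformerMixin

from .datamodel import (
    Dataset,
    Modality,
    ModalityRecording,
    Montage,
    Trial,
    ValidationError,
)

__all__ = [
    "FilterSpec",
    "NyquistError",
    "EEG_FILTER",
    "NIRS_FILTER",
    "design_bandstop",
    "apply_filter",
    "BandStopFilter",
    "mbl_invert",
    "preprocess_dataset",
]

logger = logging.getLogger(__name__)

#: fraction of Nyquist beyond which a stop edge is numerically degenerate
_EDGE_CLIP = 0.98


class NyquistError(ValidationError):
    """A filter edge is at or above the Nyquist frequency."""


@dataclass(frozen=True)
class FilterSpec:
    """Band-stop (or the band-pass alternative) Butterworth filter spec."""

    low_hz: float
    high_hz: float
    order: int = 2
    zero_phase: bool = True
    kind: str = "band_stop"

    def __post_init__(self) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise ValidationError("need 0 < low_hz < high_hz")
        if self.order < 1:
            raise ValidationError("order must be >= 1")
        if self.kind not in ("band_stop", "band_pass"):
            raise ValidationError("kind must be 'band_stop' or 'band_pass'")


EEG_FILTER = FilterSpec(low_hz=48.0, high_hz=53.0)
NIRS_FILTER = FilterSpec(low_hz=0.1, high_hz=5.0)


def design_bandstop(spec: FilterSpec, fs: float) -> np.ndarray:
    """Design the Butterworth filter for sampling rate ``fs``; returns SOS.

    Edges at or above Nyquist raise :class:`NyquistError`.  A high edge in
    the degenerate zone just below Nyquist (>= 0.98 x Nyquist, e.g. the 5 Hz
    edge at fs = 10.17) is clipped to 0.98 x Nyquist with a warning.
    """
    if fs <= 0:
        raise ValidationError("fs must be > 0")
    nyq = fs / 2.0
    if spec.low_hz >= _EDGE_CLIP * nyq:
        raise NyquistError(
            f"low edge {spec.low_hz} Hz is at/above Nyquist ({nyq} Hz) for fs={fs}"
        )
    if spec.high_hz >= nyq:
        raise NyquistError(
            f"high edge {spec.high_hz} Hz is at/above Nyquist ({nyq} Hz) for fs={fs}"
        )
    high = spec.high_hz
    if high >= _EDGE_CLIP * nyq:
        high = _EDGE_CLIP * nyq
        warnings.warn(
            f"stop edge {spec.high_hz} Hz clipped to {high:.4g} Hz "
            f"(0.98 x Nyquist at fs={fs})",
            stacklevel=2,
        )
        logger.debug("filter edge clipped: %.4g -> %.4g Hz", spec.high_hz, high)
    btype = "bandstop" if spec.kind == "band_stop" else "bandpass"
    return signal.butter(spec.order, [spec.low_hz, high], btype=btype, fs=fs,
                         output="sos")


def _filter_array(x: np.ndarray, spec: FilterSpec, fs: float) -> np.ndarray:
    sos = design_bandstop(spec, fs)
    if spec.zero_phase:
        # forward-backward pass; scipy reflect-pads the edges internally
        return signal.sosfiltfilt(sos, x, axis=-1)
    return signal.sosfilt(sos, x, axis=-1)


def apply_filter(rec: ModalityRecording, spec: FilterSpec) -> ModalityRecording:
    """Filter every channel of ``rec``; output shape equals input shape."""
    if not np.all(np.isfinite(rec.samples)):
        raise ValidationError("recording contains non-finite samples")
    filtered = _filter_array(rec.samples, spec, rec.sampling_rate_hz)
    return ModalityRecording(
        modality=rec.modality,
        samples=filtered,
        sampling_rate_hz=rec.sampling_rate_hz,
        channel_ids=rec.channel_ids,
    )


class BandStopFilter(TransformerMixin, BaseEstimator):
    """sklearn-style transformer applying the Butterworth band-stop.

    Operates on arrays whose last axis is time: (n_signals, n_times) or
    (n_epochs, n_channels, n_times).  ``fit`` validates the spec against the
    sampling rate; ``transform`` filters along the time axis.
    """

    def __init__(self, low_hz: float = 48.0, high_hz: float = 53.0,
                 order: int = 2, zero_phase: bool = True,
                 sampling_rate_hz: float = 250.0, kind: str = "band_stop"):
        self.low_hz = low_hz
        self.high_hz = high_hz
        self.order = order
        self.zero_phase = zero_phase
        self.sampling_rate_hz = sampling_rate_hz
        self.kind = kind

    def _spec(self) -> FilterSpec:
        return FilterSpec(low_hz=self.low_hz, high_hz=self.high_hz,
                          order=self.order, zero_phase=self.zero_phase,
                          kind=self.kind)

    def fit(self, X, y=None):
        self.sos_ = design_bandstop(self._spec(), self.sampling_rate_hz)
        return self

    def transform(self, X):
        if not hasattr(self, "sos_"):
            self.fit(X)
        X = np.asarray(X, dtype=float)
        if not np.all(np.isfinite(X)):
            raise ValidationError("input contains non-finite values")
        return _filter_array(X, self._spec(), self.sampling_rate_hz)


def mbl_invert(
    od_wl1: ModalityRecording,
    od_wl2: ModalityRecording,
    montage: Montage,
) -> tuple[ModalityRecording, ModalityRecording]:
    """Solve the modified Beer-Lambert system for hemoglobin changes.

    Per channel z and time point: [dHbO; dHbR] = (1 / (v * du)) * E^-1 *
    [OD(wl1); OD(wl2)] with E the 2x2 extinction matrix in 1/(mM*cm), v the
    emitter-detector separation and du the differential path-length factor.
    Returns recordings tagged OXY and DEOXY in mM.
    """
    if od_wl1.samples.shape != od_wl2.samples.shape:
        raise ValidationError("optical-density recordings have mismatched shapes")
    if abs(od_wl1.sampling_rate_hz - od_wl2.sampling_rate_hz) > 1e-9:
        raise ValidationError("optical-density recordings have mismatched rates")
    E = montage.extinction_matrix
    det = np.linalg.det(E)
    if abs(det) <= montage.det_epsilon:
        raise ValidationError("extinction matrix is singular; cannot invert")
    inv = np.linalg.inv(E) / montage.pathlength_cm
    oxy = inv[0, 0] * od_wl1.samples + inv[0, 1] * od_wl2.samples
    deoxy = inv[1, 0] * od_wl1.samples + inv[1, 1] * od_wl2.samples
    mk = lambda mod, x: ModalityRecording(
        modality=mod, samples=x, sampling_rate_hz=od_wl1.sampling_rate_hz,
        channel_ids=od_wl1.channel_ids,
    )
    return mk(Modality.OXY, oxy), mk(Modality.DEOXY, deoxy)


def preprocess_dataset(
    dataset: Dataset,
    eeg_filter: FilterSpec = EEG_FILTER,
    nirs_filter: FilterSpec = NIRS_FILTER,
) -> Dataset:
    """Full preprocessing pass over a dataset.

    EEG is band-stop filtered; optical densities are band-stop filtered and
    then inverted to OXY/DEOXY via the Beer-Lambert system (filtering of the
    OD signals precedes the inversion).  Trials that already carry OXY/DEOXY
    and no optical densities are passed through with EEG filtering only.
    """
    out_trials: list[Trial] = []
    for trial in dataset.trials:
        recs: dict[Modality, ModalityRecording] = {}
        if Modality.EEG in trial.recordings:
            recs[Modality.EEG] = apply_filter(trial.recordings[Modality.EEG], eeg_filter)
        if Modality.OD_WL1 in trial.recordings and Modality.OD_WL2 in trial.recordings:
            od1 = apply_filter(trial.recordings[Modality.OD_WL1], nirs_filter)
            od2 = apply_filter(trial.recordings[Modality.OD_WL2], nirs_filter)
            oxy, deoxy = mbl_invert(od1, od2, dataset.montage)
            recs[Modality.OXY] = oxy
            recs[Modality.DEOXY] = deoxy
        else:
            for mod in (Modality.OXY, Modality.DEOXY):
                if mod in trial.recordings:
                    recs[mod] = trial.recordings[mod]
        if not recs:
            raise ValidationError(f"trial {trial.trial_id} has no usable modality")
        out_trials.append(
            Trial(
                trial_id=trial.trial_id,
                session_id=trial.session_id,
                subject_id=trial.subject_id,
                label=trial.label,
                recordings=recs,
                duration_s=trial.duration_s,
            )
        )
    return Dataset(trials=out_trials, montage=dataset.montage,
                   provenance={**dataset.provenance, "preprocessed": True})
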