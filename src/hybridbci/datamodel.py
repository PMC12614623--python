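"""Core domain types for hybrid EEG+fNIRS recordings.

The analysis operates on labeled 24 s task trials, each carrying one EEG
recording (30 channels, 250 Hz) and one NIRS recording per optical wavelength
(18 emitter-detector channels, 10.17 Hz).  Labels code the four scrolling-text
directions: right (1), left (2), up (3), down (4).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ValidationError",
    "Modality",
    "CLASS_NAMES",
    "Montage",
    "default_montage",
    "ModalityRecording",
    "Trial",
    "Dataset",
    "RunConfig",
]


class ValidationError(ValueError):
    """An invariant of a domain object is violated."""


class Modality(str, enum.Enum):
    """Signal kinds attached to a trial.

    ``OD_WL1``/``OD_WL2`` are optical-density changes at the montage's two
    wavelengths (unitless); ``OXY``/``DEOXY`` are hemoglobin concentration
    changes in mM obtained from them via the modified Beer-Lambert law.
    EEG is in microvolts.
    """

    EEG = "eeg"
    OD_WL1 = "od_wl1"
    OD_WL2 = "od_wl2"
    OXY = "oxy"
    DEOXY = "deoxy"


CLASS_NAMES = {1: "right", 2: "left", 3: "up", 4: "down"}

#: 30 scalp electrode names (10/20 extended system); one acquisition
#: electrode serves as reference and is not part of the analyzed data.
EEG_CHANNELS_30 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "CP5", "CP1", "CP2", "CP6",
    "P7", "P3", "Pz", "P4", "P8",
    "PO9", "O1", "Oz", "O2", "PO10",
)

#: 18 emitter-detector channels formed from 8 emitters (S) and 8 detectors (D).
NIRS_CHANNELS_18 = (
    "S1-D1", "S1-D2", "S2-D1", "S2-D2", "S2-D3", "S3-D2", "S3-D4",
    "S4-D3", "S4-D4", "S5-D5", "S5-D6", "S6-D5", "S6-D6", "S6-D7",
    "S7-D6", "S7-D8", "S8-D7", "S8-D8",
)


@dataclass(frozen=True)
class Montage:
    """Channel geometry and Beer-Lambert constants.

    ``extinction`` holds the molar extinction coefficients in 1/(mM*cm):
    row i corresponds to wavelength ``wavelengths_nm[i]`` and columns are
    (oxyhemoglobin, deoxyhemoglobin).  ``dpf`` is the dimensionless
    differential path-length factor and ``separation_cm`` the
    emitter-detector distance, so the effective optical path is
    ``separation_cm * dpf``.
    """

    eeg_channels: tuple[str, ...] = EEG_CHANNELS_30
    nirs_channels: tuple[str, ...] = NIRS_CHANNELS_18
    wavelengths_nm: tuple[float, float] = (760.0, 850.0)
    extinction: tuple[tuple[float, float], tuple[float, float]] = (
        (0.1486, 0.3843),  # 760 nm: HbO, HbR
        (0.2526, 0.1798),  # 850 nm: HbO, HbR
    )
    dpf: float = 6.0
    separation_cm: float = 3.0
    det_epsilon: float = 1e-9

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if len(self.wavelengths_nm) != 2:
            raise ValidationError("Montage requires exactly 2 wavelengths")
        E = self.extinction_matrix
        if E.shape != (2, 2):
            raise ValidationError("extinction must be a 2x2 matrix")
        if abs(np.linalg.det(E)) <= self.det_epsilon:
            raise ValidationError(
                "extinction matrix is singular (|det| <= %g)" % self.det_epsilon
            )
        if not self.dpf > 0:
            raise ValidationError("dpf must be > 0")
        if not self.separation_cm > 0:
            raise ValidationError("separation_cm must be > 0")
        for name, chans in (("eeg", self.eeg_channels), ("nirs", self.nirs_channels)):
            if len(set(chans)) != len(chans):
                raise ValidationError(f"{name} channel identifiers not unique")

    @property
    def extinction_matrix(self) -> np.ndarray:
        return np.asarray(self.extinction, dtype=float)

    @property
    def pathlength_cm(self) -> float:
        """Effective optical path v * du in cm."""
        return self.separation_cm * self.dpf

    def to_dict(self) -> dict:
        return {
            "eeg_channels": list(self.eeg_channels),
            "nirs_channels": list(self.nirs_channels),
            "wavelengths_nm": list(self.wavelengths_nm),
            "extinction": [list(row) for row in self.extinction],
            "dpf": self.dpf,
            "separation_cm": self.separation_cm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Montage":
        return cls(
            eeg_channels=tuple(d["eeg_channels"]),
            nirs_channels=tuple(d["nirs_channels"]),
            wavelengths_nm=tuple(d["wavelengths_nm"]),
            extinction=tuple(tuple(row) for row in d["extinction"]),
            dpf=float(d["dpf"]),
            separation_cm=float(d["separation_cm"]),
        )


def default_montage() -> Montage:
    """The default 30-EEG / 18-NIRS montage at 760/850 nm."""
    return Montage()


@dataclass
class ModalityRecording:
    """One channels x time signal block of a single modality."""

    modality: Modality
    samples: np.ndarray
    sampling_rate_hz: float
    channel_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        self.modality = Modality(self.modality)
        self.samples = np.asarray(self.samples, dtype=float)
        self.channel_ids = tuple(self.channel_ids)
        self.validate()

    def validate(self) -> None:
        if self.samples.ndim != 2:
            raise ValidationError("samples must be a 2-D channels x time matrix")
        if self.samples.shape[0] != len(self.channel_ids):
            raise ValidationError(
                f"row count {self.samples.shape[0]} does not match "
                f"{len(self.channel_ids)} channel ids"
            )
        if not self.sampling_rate_hz > 0:
            raise ValidationError("sampling rate must be > 0")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("samples contain non-finite values")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]


@dataclass
class Trial:
    """A labeled 24 s task epoch with co-registered multimodal recordings."""

    trial_id: str
    session_id: str
    subject_id: str
    label: int
    recordings: dict[Modality, ModalityRecording]
    duration_s: float = 24.0

    def __post_init__(self) -> None:
        self.recordings = {Modality(k): v for k, v in self.recordings.items()}
        self.validate()

    def validate(self) -> None:
        if self.label not in CLASS_NAMES:
            raise ValidationError(
                f"trial {self.trial_id}: label {self.label} not in "
                f"{sorted(CLASS_NAMES)}"
            )
        if not self.recordings:
            raise ValidationError(f"trial {self.trial_id} has no recordings")
        for mod, rec in self.recordings.items():
            rec.validate()
            if rec.modality is not mod:
                raise ValidationError(
                    f"trial {self.trial_id}: recording tagged {rec.modality} "
                    f"stored under {mod}"
                )
            expected = math.floor(self.duration_s * rec.sampling_rate_hz + 1e-9)
            if abs(rec.n_samples - expected) > 1:
                raise ValidationError(
                    f"trial {self.trial_id}, {mod.value}: {rec.n_samples} samples "
                    f"does not span the nominal {self.duration_s} s duration "
                    f"(expected ~{expected})"
                )


@dataclass
class Dataset:
    """A collection of trials sharing one montage."""

    trials: list[Trial]
    montage: Montage
    provenance: dict = field(default_factory=lambda: {"source": "external"})

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.trials:
            raise ValidationError("dataset has no trials")
        self.montage.validate()
        rates: dict[Modality, float] = {}
        ids = set()
        for trial in self.trials:
            trial.validate()
            if trial.trial_id in ids:
                raise ValidationError(f"duplicate trial_id {trial.trial_id}")
            ids.add(trial.trial_id)
            for mod, rec in trial.recordings.items():
                if mod in rates and abs(rates[mod] - rec.sampling_rate_hz) > 1e-9:
                    raise ValidationError(
                        f"inconsistent sampling rate for {mod.value}"
                    )
                rates.setdefault(mod, rec.sampling_rate_hz)
                expected_chans = (
                    self.montage.eeg_channels
                    if mod is Modality.EEG
                    else self.montage.nirs_channels
                )
                if rec.channel_ids != expected_chans:
                    raise ValidationError(
                        f"trial {trial.trial_id}, {mod.value}: channel ids do not "
                        f"match the montage"
                    )

    @property
    def modalities(self) -> list[Modality]:
        return sorted({m for t in self.trials for m in t.recordings}, key=lambda m: m.value)

    @property
    def sampling_rates(self) -> dict[Modality, float]:
        rates: dict[Modality, float] = {}
        for t in self.trials:
            for mod, rec in t.recordings.items():
                rates.setdefault(mod, rec.sampling_rate_hz)
        return rates

    @property
    def subjects(self) -> list[str]:
        return sorted({t.subject_id for t in self.trials})

    def class_counts(self) -> dict[int, int]:
        counts = {c: 0 for c in CLASS_NAMES}
        for t in self.trials:
            counts[t.label] += 1
        return counts


WINDOW_CHOICES = (2.4, 4.8, 12.0, 24.0)
MODALITY_SET_CHOICES = ("eeg", "oxy", "deoxy", "eeg+oxy", "eeg+deoxy")
FEATURE_CHOICES = ("ht", "fwht", "bp", "sf")
CLASSIFIER_CHOICES = ("knn", "svm", "dt", "rf")
DISTANCE_CHOICES = ("euclidean", "cosine", "cityblock", "correlation")
SPLIT_CHOICES = ("window_random", "trial_random", "loso")


@dataclass
class RunConfig:
    """Configuration of one evaluation experiment.

    ``n_runs`` repetitions of a ``train_fraction`` split with exact per-class
    balance; run r derives its randomness from ``seed + r``.  ``k=None``
    selects k per run by random subsampling on the training set.
    """

    window_s: float = 2.4
    modality_set: str = "eeg+oxy"
    feature_family: str = "ht"
    classifier: str = "knn"
    distance: str = "euclidean"
    n_runs: int = 50
    train_fraction: float = 0.75
    split_scheme: str = "window_random"
    seed: int = 0
    ht_mode: str = "broadband"
    k: int | None = None
    #: optional overrides for the preprocessing filters, as FilterSpec kwargs
    eeg_filter: dict | None = None
    nirs_filter: dict | None = None

    def __post_init__(self) -> None:
        self.modality_set = self.modality_set.lower()
        self.feature_family = self.feature_family.lower()
        self.classifier = self.classifier.lower()
        self.distance = self.distance.lower()
        self.split_scheme = self.split_scheme.lower()
        self.validate()

    def validate(self) -> None:
        if not self.window_s > 0:
            raise ValidationError("window_s must be > 0")
        if self.modality_set not in MODALITY_SET_CHOICES:
            raise ValidationError(f"modality_set must be one of {MODALITY_SET_CHOICES}")
        if self.feature_family not in FEATURE_CHOICES:
            raise ValidationError(f"feature_family must be one of {FEATURE_CHOICES}")
        if self.classifier not in CLASSIFIER_CHOICES:
            raise ValidationError(f"classifier must be one of {CLASSIFIER_CHOICES}")
        if self.distance not in DISTANCE_CHOICES:
            raise ValidationError(f"distance must be one of {DISTANCE_CHOICES}")
        if not 0 < self.train_fraction < 1:
            raise ValidationError("train_fraction must be in (0, 1)")
        if self.split_scheme not in SPLIT_CHOICES:
            raise ValidationError(f"split_scheme must be one of {SPLIT_CHOICES}")
        if self.n_runs < 1:
            raise ValidationError("n_runs must be >= 1")
        if self.ht_mode not in ("broadband", "per_band"):
            raise ValidationError("ht_mode must be 'broadband' or 'per_band'")
        if self.k is not None and self.k < 1:
            raise ValidationError("k must be >= 1 when given")

    def to_dict(self) -> dict:
        return {
            "window_s": self.window_s,
            "modality_set": self.modality_set,
            "feature_family": self.feature_family,
            "classifier": self.classifier,
            "distance": self.distance,
            "n_runs": self.n_runs,
            "train_fraction": self.train_fraction,
            "split_scheme": self.split_scheme,
            "seed": self.seed,
            "ht_mode": self.ht_mode,
            "k": self.k,
            "eeg_filter": self.eeg_filter,
            "nirs_filter": self.nirs_filter,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)
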