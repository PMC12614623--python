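"""Synthetic four-class hybrid EEG+NIRS paradigm generator.

Emulates the scrolling-text acquisition protocol: 6 sessions x 20 trials of
24 s task epochs per subject, exactly balanced over the four directions
(right, left, up, down).  Each class drives a distinct spatial gain pattern:

* EEG — a band-limited oscillation (default 8-13 Hz, random frequency and
  phase per trial) scaled per channel by the class gain, on top of white and
  1/f-shaped background noise plus 50 Hz line interference;
* NIRS — a hemodynamic HbO time course (double-gamma impulse response
  convolved with the 24 s task boxcar, peak-normalized) scaled per channel by
  the class gain, with HbR tied to HbO by a negative ratio, rendered to
  optical density at both wavelengths via the forward Beer-Lambert relation,
  plus white OD noise.

Only the task epochs are generated; rest/cue phases are not part of the
analyzed data.  Identical seeds give bitwise-identical datasets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .datamodel import (
    Dataset,
    Modality,
    ModalityRecording,
    Montage,
    Trial,
    ValidationError,
    default_montage,
)

__all__ = ["GeneratorConfig", "simulate_subject", "hrf", "forward_mbl"]

N_CLASSES = 4

# double-gamma shape/scale (s): response peak near 6 s, undershoot near 16 s
_HRF_PEAK_SHAPE, _HRF_PEAK_SCALE = 6.0, 1.2
_HRF_UNDER_SHAPE, _HRF_UNDER_SCALE = 16.0, 1.07
_HRF_UNDER_RATIO = 1.0 / 6.0


@dataclass
class GeneratorConfig:
    """Study-condition parameters of the synthetic subject.

    Defaults mirror the acquisition protocol (6 x 20 trials, 24 s, 250 Hz EEG,
    10.17 Hz NIRS) with a modest class effect relative to the background
    noise; ``class_pattern`` maps each class to a per-channel gain vector per
    modality and defaults to four disjoint channel groups per modality.
    """

    n_sessions: int = 6
    trials_per_session: int = 20
    trial_duration_s: float = 24.0
    eeg_rate_hz: float = 250.0
    nirs_rate_hz: float = 10.17
    eeg_effect: float = 2.0          # uV oscillation amplitude
    eeg_band_hz: tuple[float, float] = (8.0, 13.0)
    hemo_effect_mM: float = 1e-3     # peak HbO change
    hbr_ratio: float = -0.3          # HbR = ratio * HbO
    noise_sd_eeg: float = 5.0        # uV, white
    pink_sd_eeg: float = 5.0         # uV, 1/f-shaped
    noise_sd_od: float = 2e-3        # OD units, white, per wavelength
    line_noise_amp: float = 5.0      # uV at 50 Hz
    class_pattern: dict[str, np.ndarray] | None = None
    seed: int = 0

    def validate(self, montage: Montage) -> None:
        for name in (
            "trial_duration_s", "eeg_rate_hz", "nirs_rate_hz", "eeg_effect",
            "hemo_effect_mM", "noise_sd_eeg", "pink_sd_eeg", "noise_sd_od",
            "line_noise_amp",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if self.trial_duration_s <= 0:
            raise ValidationError("trial_duration_s must be > 0")
        n_trials = self.n_sessions * self.trials_per_session
        if n_trials <= 0 or n_trials % N_CLASSES:
            raise ValidationError(
                f"n_sessions x trials_per_session = {n_trials} must be a "
                f"positive multiple of {N_CLASSES} for balanced classes"
            )
        patt = self.resolved_pattern(montage)
        for key, n_ch in (("eeg", len(montage.eeg_channels)),
                          ("nirs", len(montage.nirs_channels))):
            if patt[key].shape != (N_CLASSES, n_ch):
                raise ValidationError(
                    f"class_pattern['{key}'] must have shape ({N_CLASSES}, {n_ch})"
                )

    def resolved_pattern(self, montage: Montage) -> dict[str, np.ndarray]:
        if self.class_pattern is not None:
            return {k: np.asarray(v, dtype=float) for k, v in self.class_pattern.items()}
        return {
            "eeg": default_class_pattern(len(montage.eeg_channels)),
            "nirs": default_class_pattern(len(montage.nirs_channels)),
        }

    def to_dict(self) -> dict:
        d = {
            k: v for k, v in self.__dict__.items() if k != "class_pattern"
        }
        d["eeg_band_hz"] = list(self.eeg_band_hz)
        d["class_pattern"] = (
            None
            if self.class_pattern is None
            else {k: np.asarray(v).tolist() for k, v in self.class_pattern.items()}
        )
        return d


def default_class_pattern(n_channels: int) -> np.ndarray:
    """Four spatial gain vectors over ``n_channels``: each class gets gain 1
    on its own contiguous channel group and a 0.1 leak elsewhere, a stylized
    direction-dependent topography."""
    pattern = np.full((N_CLASSES, n_channels), 0.1)
    bounds = np.linspace(0, n_channels, N_CLASSES + 1).astype(int)
    for c in range(N_CLASSES):
        pattern[c, bounds[c]:bounds[c + 1]] = 1.0
    return pattern


def complementary_class_pattern(n_eeg: int, n_nirs: int) -> dict[str, np.ndarray]:
    """Gain vectors making classes 1-2 separable only in EEG and classes 3-4
    only in NIRS — the construction for showing hybrid complementarity:
    either single modality tops out near 75% while the fused features can
    resolve all four classes."""
    eeg = np.zeros((N_CLASSES, n_eeg))
    nirs = np.zeros((N_CLASSES, n_nirs))
    eeg[0, : n_eeg // 2] = 1.0
    eeg[1, n_eeg // 2:] = 1.0
    nirs[2, : n_nirs // 2] = 1.0
    nirs[3, n_nirs // 2:] = 1.0
    return {"eeg": eeg, "nirs": nirs}


def hrf(t: np.ndarray | Sequence[float]) -> np.ndarray:
    """Canonical double-gamma hemodynamic response on time grid ``t`` (s).

    Peak near 6 s, undershoot near 16 s, normalized so the global peak is 1.
    Raises on negative time points.
    """
    t = np.asarray(t, dtype=float)
    if t.size and t.min() < 0:
        raise ValidationError("hrf requires a non-negative time grid")

    def _raw(tt: np.ndarray) -> np.ndarray:
        return stats.gamma.pdf(tt, _HRF_PEAK_SHAPE, scale=_HRF_PEAK_SCALE) - (
            _HRF_UNDER_RATIO
            * stats.gamma.pdf(tt, _HRF_UNDER_SHAPE, scale=_HRF_UNDER_SCALE)
        )

    # global peak evaluated once on a dense grid; response is negligible >32 s
    peak = np.max(_raw(np.arange(0.0, 32.0, 0.01)))
    return _raw(t) / peak


def forward_mbl(
    oxy: np.ndarray, deoxy: np.ndarray, montage: Montage
) -> tuple[np.ndarray, np.ndarray]:
    """Render hemoglobin concentration changes (mM) to optical density.

    OD(wl_i) = (eps_HbO(wl_i) * dHbO + eps_HbR(wl_i) * dHbR) * v * du,
    elementwise over channels x time; the exact linear forward model whose
    inverse is :func:`hybridbci.preprocessing.mbl_invert`.
    """
    oxy = np.asarray(oxy, dtype=float)
    deoxy = np.asarray(deoxy, dtype=float)
    if oxy.shape != deoxy.shape:
        raise ValidationError("oxy and deoxy must have matching shapes")
    E = montage.extinction_matrix
    scale = montage.pathlength_cm
    od1 = (E[0, 0] * oxy + E[0, 1] * deoxy) * scale
    od2 = (E[1, 0] * oxy + E[1, 1] * deoxy) * scale
    return od1, od2


def _pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                sd: float, fs: float = 1.0, knee_hz: float = 1.0) -> np.ndarray:
    """1/f-amplitude-shaped Gaussian noise with a low-frequency knee.

    Amplitude falls as 1/sqrt(f) above ``knee_hz`` and is flat below it —
    unbounded 1/f power at f -> 0 is unphysical and EEG acquisition is
    high-passed, so the spectrum flattens at the lowest frequencies.
    """
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shaping = 1.0 / np.sqrt(np.maximum(freqs, knee_hz))
    shaping[0] = 0.0  # no DC offset
    pink = np.fft.irfft(spec * shaping, n=n_samples, axis=-1)
    # scale by the EXPECTED output std (Parseval), not the realized per-trial
    # std: realized normalization would couple windows of one trial and make
    # the noise non-stationary across windows
    weight = np.full_like(freqs, 2.0)
    weight[0] = 1.0
    if n_samples % 2 == 0:
        weight[-1] = 1.0
    expected_std = np.sqrt(np.sum(weight * shaping ** 2) / n_samples)
    return sd * pink / expected_std


def simulate_subject(
    cfg: GeneratorConfig | None = None,
    montage: Montage | None = None,
    subject_id: str = "S01",
) -> Dataset:
    """Simulate one subject's full recording set.

    Returns a :class:`Dataset` of ``n_sessions * trials_per_session`` trials
    with exactly balanced classes in seed-randomized order; trials carry EEG
    and the two optical-density modalities (hemoglobin is recovered later by
    preprocessing, as for real recordings).
    """
    cfg = cfg or GeneratorConfig()
    montage = montage or default_montage()
    cfg.validate(montage)
    rng = np.random.default_rng(cfg.seed)
    pattern = cfg.resolved_pattern(montage)

    n_trials = cfg.n_sessions * cfg.trials_per_session
    labels = np.repeat(np.arange(1, N_CLASSES + 1), n_trials // N_CLASSES)
    rng.shuffle(labels)

    n_eeg = math.floor(cfg.trial_duration_s * cfg.eeg_rate_hz + 1e-9)
    n_nirs = math.floor(cfg.trial_duration_s * cfg.nirs_rate_hz + 1e-9)
    if n_eeg < 2 or n_nirs < 2:
        raise ValidationError("trial duration too short for the sampling rates")
    t_eeg = np.arange(n_eeg) / cfg.eeg_rate_hz
    t_nirs = np.arange(n_nirs) / cfg.nirs_rate_hz

    # task-evoked hemodynamic template: hrf convolved with the 24 s boxcar
    h = hrf(t_nirs)
    response = np.convolve(h, np.ones(n_nirs))[:n_nirs]
    peak = np.max(np.abs(response))
    if peak > 0:
        response = response / peak

    trials: list[Trial] = []
    for idx in range(n_trials):
        session = idx // cfg.trials_per_session + 1
        label = int(labels[idx])
        g_eeg = pattern["eeg"][label - 1]
        g_nirs = pattern["nirs"][label - 1]

        freq = rng.uniform(*cfg.eeg_band_hz)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        osc = np.sin(2.0 * np.pi * freq * t_eeg + phase)
        eeg = cfg.eeg_effect * g_eeg[:, None] * osc[None, :]
        eeg += _pink_noise(rng, len(g_eeg), n_eeg, cfg.pink_sd_eeg,
                           fs=cfg.eeg_rate_hz)
        eeg += cfg.noise_sd_eeg * rng.standard_normal((len(g_eeg), n_eeg))
        line_phase = rng.uniform(0.0, 2.0 * np.pi)
        eeg += cfg.line_noise_amp * np.sin(2.0 * np.pi * 50.0 * t_eeg + line_phase)

        oxy = cfg.hemo_effect_mM * g_nirs[:, None] * response[None, :]
        deoxy = cfg.hbr_ratio * oxy
        od1, od2 = forward_mbl(oxy, deoxy, montage)
        od1 = od1 + cfg.noise_sd_od * rng.standard_normal(od1.shape)
        od2 = od2 + cfg.noise_sd_od * rng.standard_normal(od2.shape)

        trial_id = f"{subject_id}_s{session:02d}_t{idx % cfg.trials_per_session + 1:02d}"
        recordings = {
            Modality.EEG: ModalityRecording(
                Modality.EEG, eeg, cfg.eeg_rate_hz, montage.eeg_channels
            ),
            Modality.OD_WL1: ModalityRecording(
                Modality.OD_WL1, od1, cfg.nirs_rate_hz, montage.nirs_channels
            ),
            Modality.OD_WL2: ModalityRecording(
                Modality.OD_WL2, od2, cfg.nirs_rate_hz, montage.nirs_channels
            ),
        }
        trials.append(
            Trial(
                trial_id=trial_id,
                session_id=f"{subject_id}_s{session:02d}",
                subject_id=subject_id,
                label=label,
                recordings=recordings,
                duration_s=cfg.trial_duration_s,
            )
        )

    provenance = {"source": "hybridbci.simulate", "config": cfg.to_dict(),
                  "subject_id": subject_id}
    return Dataset(trials=trials, montage=montage, provenance=provenance)
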