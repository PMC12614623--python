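"""Time-window segmentation ("data augmentation through time segmentation").

Each 24 s trial is cut into k = floor(duration / window) contiguous
non-overlapping windows anchored at trial onset; window lengths of 2.4, 4.8,
12 and 24 s divide evenly into the task interval.  Per modality a window
holds n_w = floor(window_s * rate) samples, so window i covers samples
[i*n_w, (i+1)*n_w); trailing samples beyond the last full window are
discarded.  Windows of different modalities share the window index, i.e. the
same nominal time interval.  Every segment inherits its parent trial's label
and keeps the parent id for leakage-aware splitting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .datamodel import Dataset, Modality, Trial, ValidationError

__all__ = ["Segment", "segment"]


@dataclass
class Segment:
    """A windowed slice of a trial with inherited label."""

    segment_id: str
    parent_trial_id: str
    subject_id: str
    session_id: str
    window_index: int
    label: int
    window_s: float
    blocks: dict[Modality, np.ndarray]          # channels x window samples
    sampling_rates: dict[Modality, float]

    def n_samples(self, modality: Modality) -> int:
        return self.blocks[modality].shape[1]


def samples_per_window(window_s: float, rate_hz: float) -> int:
    """floor(window_s * rate), with a guard against float representation."""
    return math.floor(window_s * rate_hz + 1e-9)


def windows_per_trial(duration_s: float, window_s: float) -> int:
    return math.floor(duration_s / window_s + 1e-9)


def segment(dataset: Dataset, window_s: float) -> list[Segment]:
    """Segment every trial of ``dataset`` into ``window_s`` windows.

    Returns k * n_trials segments where k = floor(duration / window_s);
    raises if the window exceeds the trial duration.
    """
    if window_s <= 0:
        raise ValidationError("window_s must be > 0")
    segments: list[Segment] = []
    for trial in dataset.trials:
        if window_s > trial.duration_s + 1e-9:
            raise ValidationError(
                f"window {window_s} s exceeds trial duration {trial.duration_s} s"
            )
        k = windows_per_trial(trial.duration_s, window_s)
        counts = {
            mod: samples_per_window(window_s, rec.sampling_rate_hz)
            for mod, rec in trial.recordings.items()
        }
        for mod, n_w in counts.items():
            if n_w < 2:
                raise ValidationError(
                    f"window {window_s} s gives {n_w} sample(s) at "
                    f"{trial.recordings[mod].sampling_rate_hz} Hz ({mod.value})"
                )
        for i in range(k):
            blocks = {
                mod: rec.samples[:, i * counts[mod]:(i + 1) * counts[mod]].copy()
                for mod, rec in trial.recordings.items()
            }
            segments.append(
                Segment(
                    segment_id=f"{trial.trial_id}_w{i:02d}",
                    parent_trial_id=trial.trial_id,
                    subject_id=trial.subject_id,
                    session_id=trial.session_id,
                    window_index=i,
                    label=trial.label,
                    window_s=window_s,
                    blocks=blocks,
                    sampling_rates={
                        mod: rec.sampling_rate_hz
                        for mod, rec in trial.recordings.items()
                    },
                )
            )
    return segments
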