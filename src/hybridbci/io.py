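"""Plain-text dataset container.

Layout (all text, diffable, language-neutral)::

    <root>/
      metadata.json            subject/session/trial table, montage, rates
      trials/
        <trial_id>__<modality>.csv   rows = samples, columns = channel ids

Values are written with shortest round-trip float formatting, so a
write -> read cycle reproduces float64 samples exactly.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    Dataset,
    Modality,
    ModalityRecording,
    Montage,
    Trial,
    ValidationError,
)

__all__ = ["write_dataset", "read_dataset"]

logger = logging.getLogger(__name__)

_FORMAT_VERSION = 1


def _trial_filename(trial_id: str, modality: Modality) -> str:
    return f"{trial_id}__{modality.value}.csv"


def write_dataset(dataset: Dataset, path: str | Path) -> None:
    """Write ``dataset`` to directory ``path``.

    Validates the dataset before any file is created; ordering of trials and
    channels is the dataset's own, so the layout is deterministic.
    """
    dataset.validate()
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    trials_dir = root / "trials"
    trials_dir.mkdir(exist_ok=True)

    meta = {
        "format_version": _FORMAT_VERSION,
        "montage": dataset.montage.to_dict(),
        "provenance": dataset.provenance,
        "sampling_rates": {m.value: r for m, r in dataset.sampling_rates.items()},
        "trials": [
            {
                "trial_id": t.trial_id,
                "session_id": t.session_id,
                "subject_id": t.subject_id,
                "label": t.label,
                "duration_s": t.duration_s,
                "modalities": [m.value for m in sorted(t.recordings, key=lambda m: m.value)],
            }
            for t in dataset.trials
        ],
    }
    for trial in dataset.trials:
        for mod in sorted(trial.recordings, key=lambda m: m.value):
            rec = trial.recordings[mod]
            frame = pd.DataFrame(rec.samples.T, columns=list(rec.channel_ids))
            frame.to_csv(trials_dir / _trial_filename(trial.trial_id, mod),
                         index=False, float_format="%.17g")
    with open(root / "metadata.json", "w") as fh:
        json.dump(meta, fh, indent=1)
    logger.info("wrote dataset: %d trials to %s", len(dataset.trials), root)


def read_dataset(path: str | Path) -> Dataset:
    """Read a dataset container written by :func:`write_dataset`."""
    root = Path(path)
    meta_path = root / "metadata.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"no metadata.json under {root}")
    with open(meta_path) as fh:
        try:
            meta = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValidationError(f"malformed metadata.json: {exc}") from exc

    montage = Montage.from_dict(meta["montage"])
    rates = {Modality(m): float(r) for m, r in meta["sampling_rates"].items()}

    trials: list[Trial] = []
    for row in meta["trials"]:
        trial_id = row["trial_id"]
        recordings: dict[Modality, ModalityRecording] = {}
        for mod_name in row["modalities"]:
            mod = Modality(mod_name)
            fpath = root / "trials" / _trial_filename(trial_id, mod)
            if not fpath.exists():
                raise FileNotFoundError(
                    f"trial {trial_id}: missing {mod.value} file {fpath.name}"
                )
            frame = pd.read_csv(fpath, float_precision="round_trip")
            samples = frame.to_numpy(dtype=float).T
            if not np.all(np.isfinite(samples)):
                raise ValidationError(
                    f"trial {trial_id}, {mod.value}: non-numeric or non-finite cells"
                )
            expected = (
                montage.eeg_channels if mod is Modality.EEG else montage.nirs_channels
            )
            if tuple(frame.columns) != expected:
                raise ValidationError(
                    f"trial {trial_id}, {mod.value}: file has {len(frame.columns)} "
                    f"channels, montage declares {len(expected)} (or order differs)"
                )
            recordings[mod] = ModalityRecording(
                modality=mod,
                samples=samples,
                sampling_rate_hz=rates[mod],
                channel_ids=expected,
            )
        trials.append(
            Trial(
                trial_id=trial_id,
                session_id=row["session_id"],
                subject_id=row["subject_id"],
                label=int(row["label"]),
                recordings=recordings,
                duration_s=float(row["duration_s"]),
            )
        )
    return Dataset(trials=trials, montage=montage, provenance=meta.get("provenance", {}))
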