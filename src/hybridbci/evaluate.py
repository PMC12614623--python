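"""The repeated-split evaluation protocol.

Per run r (seeded by ``cfg.seed + r``): preprocess, segment, extract the
configured feature family, split segments 75/25 with exact per-class balance
on both sides (down-sampling to the minimum class count), z-score columns on
the training rows only, select k by inner subsampling (k-NN) or fit a
baseline, and score the held-out rows.  Accuracies are aggregated as
mean +/- SD over the runs, with a pooled confusion matrix and per-class
precision/recall/F1.

Split schemes: ``window_random`` splits segments at random (the protocol's
literal reading — windows of one trial can land on both sides, which leaks
trial-level structure); ``trial_random`` keeps all windows of a trial
together; ``loso`` holds out one subject per run.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import dataclass, field

import numpy as np
from sklearn.preprocessing import StandardScaler

from .datamodel import Dataset, Modality, RunConfig, ValidationError
from .features import FeatureMatrix, build_feature_matrix
from .knn import KNNClassifier, baseline_classify, select_k
from .metrics import ConfusionMatrix, classification_accuracy, confusion, precision_recall_f1
from .preprocessing import preprocess_dataset
from .windowing import segment

__all__ = ["EvaluationReport", "run_experiment", "balanced_split"]

logger = logging.getLogger(__name__)

N_CLASSES = 4


@dataclass
class EvaluationReport:
    """Aggregated result of the repeated-split protocol."""

    run_ca: list[float]
    mean_ca: float
    sd_ca: float
    pooled_confusion: list[list[int]]
    per_class: dict
    config: dict
    seeds: list[int]
    selected_ks: list[int | None]

    def __post_init__(self) -> None:
        if not self.run_ca:
            raise ValidationError("report has no runs")
        if abs(self.mean_ca - float(np.mean(self.run_ca))) > 1e-9:
            raise ValidationError("mean_ca inconsistent with per-run list")
        for v in self.run_ca + [self.mean_ca]:
            if not 0.0 <= v <= 100.0:
                raise ValidationError("accuracy outside [0, 100]")

    def to_dict(self) -> dict:
        return {
            "run_ca": self.run_ca,
            "mean_ca": self.mean_ca,
            "sd_ca": self.sd_ca,
            "pooled_confusion": self.pooled_confusion,
            "per_class": self.per_class,
            "config": self.config,
            "seeds": self.seeds,
            "selected_ks": self.selected_ks,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "EvaluationReport":
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "EvaluationReport":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _balance_and_split_rows(indices_by_class: dict[int, np.ndarray],
                            train_fraction: float,
                            rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Down-sample each class to the minimum count, then split each class
    train/test at ``train_fraction`` — exact balance on both sides."""
    m = min(len(v) for v in indices_by_class.values())
    if m < 2:
        raise ValidationError("fewer than 2 segments per class")
    n_tr = int(np.floor(train_fraction * m))
    n_tr = min(max(n_tr, 1), m - 1)
    tr, te = [], []
    for c in sorted(indices_by_class):
        idx = rng.permutation(indices_by_class[c])[:m]
        tr.append(idx[:n_tr])
        te.append(idx[n_tr:])
    return np.concatenate(tr), np.concatenate(te)


def balanced_split(
    fm: FeatureMatrix,
    scheme: str,
    train_fraction: float,
    rng: np.random.Generator,
    run_index: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Row indices (train, test) under the requested scheme, class-balanced."""
    y = fm.labels
    groups = np.asarray(fm.groups)
    subjects = np.asarray(fm.subjects)

    if scheme == "window_random":
        by_class = {c: np.flatnonzero(y == c) for c in np.unique(y)}
        return _balance_and_split_rows(by_class, train_fraction, rng)

    if scheme == "trial_random":
        # split whole trials, then map back to their segments
        trial_ids, first = np.unique(groups, return_index=True)
        trial_labels = y[first]
        by_class = {c: trial_ids[trial_labels == c] for c in np.unique(trial_labels)}
        m = min(len(v) for v in by_class.values())
        if m < 2:
            raise ValidationError("fewer than 2 trials per class")
        n_tr = min(max(int(np.floor(train_fraction * m)), 1), m - 1)
        tr_trials, te_trials = [], []
        for c in sorted(by_class):
            ids = rng.permutation(by_class[c])[:m]
            tr_trials.extend(ids[:n_tr])
            te_trials.extend(ids[n_tr:])
        tr = np.flatnonzero(np.isin(groups, tr_trials))
        te = np.flatnonzero(np.isin(groups, te_trials))
        return tr, te

    if scheme == "loso":
        subs = sorted(set(subjects))
        if len(subs) < 2:
            raise ValidationError("loso requires >= 2 subjects")
        held_out = subs[run_index % len(subs)]
        te_mask = subjects == held_out
        tr_all = np.flatnonzero(~te_mask)
        te_all = np.flatnonzero(te_mask)
        # balance classes independently within each side
        tr_by_class = {c: tr_all[y[tr_all] == c] for c in np.unique(y[tr_all])}
        te_by_class = {c: te_all[y[te_all] == c] for c in np.unique(y[te_all])}
        m_tr = min(len(v) for v in tr_by_class.values())
        m_te = min(len(v) for v in te_by_class.values())
        if m_tr < 1 or m_te < 1:
            raise ValidationError("a class is absent from one loso side")
        tr = np.concatenate(
            [rng.permutation(v)[:m_tr] for _, v in sorted(tr_by_class.items())]
        )
        te = np.concatenate(
            [rng.permutation(v)[:m_te] for _, v in sorted(te_by_class.items())]
        )
        return tr, te

    raise ValidationError(f"unknown split scheme {scheme!r}")


def run_experiment(dataset: Dataset, cfg: RunConfig) -> EvaluationReport:
    """Execute the full pipeline and the ``cfg.n_runs`` repeated splits."""
    t0 = time.perf_counter()
    needs_hemo = "oxy" in cfg.modality_set or "deoxy" in cfg.modality_set
    have_hemo = all(
        Modality.OXY in t.recordings and Modality.DEOXY in t.recordings
        for t in dataset.trials
    )
    if have_hemo and not any(
        Modality.OD_WL1 in t.recordings for t in dataset.trials
    ):
        ds = dataset
    else:
        from .preprocessing import EEG_FILTER, NIRS_FILTER, FilterSpec

        eeg_spec = (FilterSpec(**cfg.eeg_filter) if cfg.eeg_filter
                    else EEG_FILTER)
        nirs_spec = (FilterSpec(**cfg.nirs_filter) if cfg.nirs_filter
                     else NIRS_FILTER)
        ds = preprocess_dataset(dataset, eeg_filter=eeg_spec,
                                nirs_filter=nirs_spec)

    segs = segment(ds, cfg.window_s)
    channel_ids = {
        Modality.EEG: ds.montage.eeg_channels,
        Modality.OXY: ds.montage.nirs_channels,
        Modality.DEOXY: ds.montage.nirs_channels,
    }
    fm = build_feature_matrix(
        segs, cfg.modality_set, cfg.feature_family, ht_mode=cfg.ht_mode,
        channel_ids=channel_ids,
    )
    logger.info(
        "stage=features seed=%d rows=%d cols=%d elapsed=%.2fs",
        cfg.seed, fm.n_rows, len(fm.columns), time.perf_counter() - t0,
    )

    run_cas: list[float] = []
    seeds: list[int] = []
    selected: list[int | None] = []
    pooled = ConfusionMatrix(np.zeros((N_CLASSES, N_CLASSES), dtype=int))
    for r in range(cfg.n_runs):
        run_seed = cfg.seed + r
        rng = np.random.default_rng(run_seed)
        tr, te = balanced_split(fm, cfg.split_scheme, cfg.train_fraction, rng,
                                run_index=r)
        scaler = StandardScaler().fit(fm.X[tr])
        Xtr = scaler.transform(fm.X[tr])
        Xte = scaler.transform(fm.X[te])
        ytr, yte = fm.labels[tr], fm.labels[te]

        if cfg.classifier == "knn":
            k = cfg.k if cfg.k is not None else select_k(
                Xtr, ytr, metric=cfg.distance, seed=run_seed
            )
            pred = KNNClassifier(n_neighbors=k, metric=cfg.distance).fit(
                Xtr, ytr
            ).predict(Xte)
            selected.append(int(k))
        else:
            pred = baseline_classify(Xtr, ytr, Xte, cfg.classifier, seed=run_seed)
            selected.append(None)

        cm = confusion(yte, pred, n_classes=N_CLASSES)
        run_cas.append(classification_accuracy(cm))
        pooled = pooled + cm
        seeds.append(run_seed)

    report = EvaluationReport(
        run_ca=run_cas,
        mean_ca=float(np.mean(run_cas)),
        sd_ca=float(np.std(run_cas, ddof=1)) if len(run_cas) > 1 else 0.0,
        pooled_confusion=pooled.counts.tolist(),
        per_class=precision_recall_f1(pooled),
        config=cfg.to_dict(),
        seeds=seeds,
        selected_ks=selected,
    )
    logger.info(
        "stage=evaluate seed=%d runs=%d mean_ca=%.2f sd=%.2f elapsed=%.2fs",
        cfg.seed, cfg.n_runs, report.mean_ca, report.sd_ca,
        time.perf_counter() - t0,
    )
    return report
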