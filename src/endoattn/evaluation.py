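"""Confusion counts, the five classification metrics, and the
case-count learning curve.

Malignant (class 1) is the positive class: sensitivity is the probability
that a diseased sample is flagged, specificity that a disease-free sample
is cleared.  Metrics with a zero denominator are reported as ``None`` (with
a warning) rather than silently as 0; a strict-scoring mode maps them to 0.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass

import numpy as np

from .nn.autograd import Tensor
from .synthetic import DatasetManifest
from .training import TrainConfig, _ImageCache, train

__all__ = [
    "ConfusionCounts", "MetricSet", "confusion_counts", "compute_metrics",
    "evaluate", "learning_curve",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricSet:
    """The five metrics; an undefined (0/0) metric is ``None``."""

    accuracy: float | None
    precision: float | None
    sensitivity: float | None
    specificity: float | None
    f1: float | None

    def as_dict(self) -> dict:
        return {k: v for k, v in vars(self).items()}


def confusion_counts(predicted, actual, positive_class: int = 1
                     ) -> ConfusionCounts:
    """Tally TP/FP/TN/FN for binary labels."""
    p = np.asarray(predicted)
    a = np.asarray(actual)
    if p.shape != a.shape:
        raise ValueError("predicted and actual have different lengths")
    pos_p = p == positive_class
    pos_a = a == positive_class
    return ConfusionCounts(
        tp=int((pos_p & pos_a).sum()),
        fp=int((pos_p & ~pos_a).sum()),
        tn=int((~pos_p & ~pos_a).sum()),
        fn=int((~pos_p & pos_a).sum()),
    )


def _ratio(num: int, den: int, name: str, undefined):
    if den == 0:
        warnings.warn(f"{name} undefined: zero denominator")
        return undefined
    return num / den


def compute_metrics(cc: ConfusionCounts, undefined=None) -> MetricSet:
    """Accuracy, precision, sensitivity, specificity and F1 from counts.

    F1 is the harmonic mean of precision and sensitivity,
    ``2 P S / (P + S)``.  Pass ``undefined=0.0`` for strict scoring.
    """
    if cc.total == 0:
        raise ValueError("no evaluated samples")
    accuracy = (cc.tp + cc.tn) / cc.total
    precision = _ratio(cc.tp, cc.tp + cc.fp, "precision", undefined)
    sensitivity = _ratio(cc.tp, cc.tp + cc.fn, "sensitivity", undefined)
    specificity = _ratio(cc.tn, cc.fp + cc.tn, "specificity", undefined)
    if cc.tp + cc.fp == 0 or cc.tp + cc.fn == 0:
        f1 = undefined  # warning already issued for the parent metric
    elif precision + sensitivity == 0:
        warnings.warn("f1 undefined: precision + sensitivity is zero")
        f1 = undefined
    else:
        f1 = 2 * precision * sensitivity / (precision + sensitivity)
    return MetricSet(accuracy=accuracy, precision=precision,
                     sensitivity=sensitivity, specificity=specificity, f1=f1)


def evaluate(network, manifest: DatasetManifest, indices=None,
             positive_class: int = 1, patient_level: bool = False,
             batch_size: int = 8) -> tuple[MetricSet, list[dict]]:
    """Deterministic inference over manifest records.

    Runs the network in eval mode (fixed batch-norm statistics), decides by
    argmax, and returns the metric set plus a per-record predictions table.
    With ``patient_level=True`` the per-image decisions are aggregated into
    one majority-vote decision per patient before computing metrics.
    Unreadable images are recorded as errors and skipped with a warning.
    """
    if not manifest.records:
        raise ValueError("empty manifest")
    if indices is None:
        indices = np.arange(len(manifest.records))
    indices = np.asarray(indices)
    cache = _ImageCache(manifest, network.input_side)
    network.eval()
    rows: list[dict] = []
    preds, actuals, patients = [], [], []
    for start in range(0, len(indices), batch_size):
        chunk = indices[start:start + batch_size]
        loaded, ok = [], []
        for i in chunk:
            rec = manifest.records[i]
            try:
                loaded.append(cache[i])
                ok.append(i)
            except Exception as exc:  # unreadable image: skip, keep going
                warnings.warn(f"skipping {rec.image_path}: {exc}")
                rows.append({"image_path": rec.image_path,
                             "actual": rec.class_label, "predicted": None,
                             "error": str(exc)})
        if not ok:
            continue
        logits = network(Tensor(np.stack(loaded))).data
        for i, row_logits in zip(ok, logits):
            rec = manifest.records[i]
            pred = int(row_logits.argmax())
            rows.append({"image_path": rec.image_path,
                         "actual": rec.class_label, "predicted": pred,
                         "error": None})
            preds.append(pred)
            actuals.append(rec.class_label)
            patients.append(rec.patient_id)
    if not preds:
        raise ValueError("no readable records to evaluate")
    if patient_level:
        preds, actuals = _majority_by_patient(preds, actuals, patients)
    cc = confusion_counts(preds, actuals, positive_class)
    return compute_metrics(cc), rows


def _majority_by_patient(preds, actuals, patients):
    agg_p, agg_a = [], []
    for pid in sorted(set(patients)):
        mask = [i for i, p in enumerate(patients) if p == pid]
        votes = [preds[i] for i in mask]
        # ties break toward the positive (malignant) call
        agg_p.append(int(np.round(np.mean(votes) + 1e-9)))
        agg_a.append(int(np.round(np.mean([actuals[i] for i in mask]))))
    return agg_p, agg_a


def learning_curve(network_factory, manifest: DatasetManifest,
                   case_counts, cfg: TrainConfig,
                   eval_indices=None, csv_path=None) -> list[dict]:
    """Train from scratch at increasing patient counts, evaluating each run
    on one fixed held-out set.

    ``network_factory(seed)`` must return a fresh, initialised network.
    ``eval_indices`` defaults to the patient-level test partition of
    ``cfg.patient_level_split``; training patients are subsampled (seeded)
    from the remaining pool.  Returns one row of metrics per count and
    optionally writes them as CSV.
    """
    from .training import patient_split  # local import to avoid cycle noise

    case_counts = list(case_counts)
    rows: list[dict] = []
    if case_counts:
        split = patient_split(manifest, cfg.patient_level_split, cfg.seed)
        if eval_indices is None:
            eval_indices = split["test"] if len(split.get("test", ())) else \
                split.get("val", np.arange(len(manifest.records)))
        eval_indices = np.asarray(eval_indices)
        patients = manifest.patients()
        labels = manifest.labels()
        held_out = set(patients[eval_indices])
        pool = np.array(sorted(set(patients) - held_out))
        # a patient carries a single diagnosis; stratify the subsample so
        # both classes stay represented at every count
        patient_class = {p: int(labels[patients == p][0]) for p in pool}
        by_class = {c: pool[[patient_class[p] == c for p in pool]]
                    for c in sorted(set(patient_class.values()))}
        for k, count in enumerate(case_counts):
            if count > pool.size:
                raise ValueError(
                    f"requested {count} patients but only {pool.size} "
                    "are available outside the held-out set")
            rng = np.random.default_rng(cfg.seed + 1000 * (k + 1))
            chosen: set = set()
            if count >= len(by_class):
                quota = {c: max(1, round(count * len(g) / pool.size))
                         for c, g in by_class.items()}
                while sum(quota.values()) > count:
                    c = max(quota, key=lambda c: quota[c])
                    quota[c] -= 1
                while sum(quota.values()) < count:
                    c = min(quota, key=lambda c: quota[c] / len(by_class[c]))
                    quota[c] += 1
                for c, g in by_class.items():
                    q = min(quota[c], len(g))
                    chosen |= set(rng.choice(g, size=q, replace=False))
            if len(chosen) < count:  # fewer classes than count, or remainder
                rest = np.array(sorted(set(pool) - chosen))
                chosen |= set(rng.choice(rest, size=count - len(chosen),
                                         replace=False))
            train_idx = np.flatnonzero([p in chosen for p in patients])
            net = network_factory(cfg.seed + k)
            net, _ = train(net, manifest, cfg, train_indices=train_idx)
            metrics, _ = evaluate(net, manifest, indices=eval_indices)
            row = {"n_cases": count, "n_images": int(train_idx.size)}
            row.update(metrics.as_dict())
            rows.append(row)
    if csv_path is not None:
        fields = list(rows[0].keys()) if rows else \
            ["n_cases", "n_images", "accuracy", "precision", "sensitivity",
             "specificity", "f1"]
        with open(csv_path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=fields)
            writer.writeheader()
            writer.writerows(rows)
    return rows
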