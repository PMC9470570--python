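"""Imbalance-aware training: weighted cross-entropy, label shuffling, and
the seeded Adam training loop.

The clinical motivation is a skewed cohort (many more benign than malignant
cases); two complementary counters are provided.

* Weighted cross-entropy.  Per sample with logits x and true class c the
  loss is ``W_c * (-x_c + log sum_j exp(x_j))``; inverse-frequency weights
  (mean-normalised) up-weight the minority class.

* Label shuffling.  An oversampling read order: with N the largest class
  size, each class's shuffled record list is indexed by ``i mod n`` for
  i = 0..N-1, the per-class lists are concatenated and reshuffled.  Every
  class contributes exactly N entries per epoch and every record of a class
  appears floor(N/n) or ceil(N/n) times.

The optimizer settings mirror the study: Adam, learning rate 0.02,
first-moment decay ("momentum") 0.89, weight decay 5e-4, batch size 8.
Splitting is patient-level so images of one patient never span partitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import imageio.v3 as iio
import numpy as np
from scipy.special import logsumexp
from skimage import transform as sk_transform

from .nn import Adam
from .nn import functional as F
from .nn.autograd import Tensor
from .synthetic import DatasetManifest

__all__ = [
    "TrainConfig", "cross_entropy", "weighted_cross_entropy",
    "class_weights_from_counts", "label_shuffle", "patient_split",
    "load_input", "train", "refresh_batchnorm_stats",
]


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.02
    optimizer: str = "adam"
    beta1: float = 0.89
    beta2: float = 0.999
    weight_decay: float = 5e-4
    batch_size: int = 8
    epochs: int = 10
    seed: int = 0
    balance: str = "label_shuffling"
    patient_level_split: tuple[float, ...] = (0.7, 0.15, 0.15)
    class_weights: tuple[float, ...] | None = None  # None: inverse frequency

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")
        if not (0 < self.beta1 < 1 and 0 < self.beta2 < 1):
            raise ValueError("betas must lie in (0, 1)")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be non-negative")
        if self.batch_size < 1 or self.epochs < 0:
            raise ValueError("batch_size >= 1 and epochs >= 0 required")
        if self.balance not in ("label_shuffling", "none"):
            raise ValueError(f"unknown balance mode {self.balance!r}")
        if abs(sum(self.patient_level_split) - 1.0) > 1e-9 or \
                any(f < 0 for f in self.patient_level_split):
            raise ValueError("patient_level_split fractions must be "
                             "non-negative and sum to 1")


# ---------------------------------------------------------------------------
# losses


def cross_entropy(logits, label: int) -> float:
    """Softmax cross-entropy of one logit vector, stable for large |x|."""
    x = np.asarray(logits, dtype=np.float64)
    if x.ndim != 1 or not np.isfinite(x).all():
        raise ValueError("logits must be a finite 1-D vector")
    if not 0 <= label < x.size:
        raise ValueError("class index out of range")
    return float(logsumexp(x) - x[label])


def weighted_cross_entropy(logits, label: int, weights) -> float:
    """``W_class`` times the plain cross-entropy (non-negative convention)."""
    w = np.asarray(weights, dtype=np.float64)
    if (w <= 0).any():
        raise ValueError("class weights must be positive")
    return float(w[label] * cross_entropy(logits, label))


def class_weights_from_counts(counts) -> np.ndarray:
    """Inverse-frequency weights, mean-normalised: ``total / (K * n_c)``.

    The minority class receives the larger weight; balanced counts give
    all-ones.
    """
    n = np.asarray(counts, dtype=np.float64)
    if n.ndim != 1 or n.size < 2:
        raise ValueError("need counts for at least two classes")
    if (n < 1).any():
        raise ValueError("every class needs at least one sample")
    return n.sum() / (n.size * n)


# ---------------------------------------------------------------------------
# balancing and splitting


def label_shuffle(labels, seed: int) -> np.ndarray:
    """Oversampled, class-balanced read order over record indices."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("no records to shuffle")
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(labels, return_counts=True)
    n_max = int(counts.max())
    order: list[np.ndarray] = []
    for c in classes:
        idx = np.flatnonzero(labels == c)
        perm = rng.permutation(idx)
        order.append(perm[np.arange(n_max) % idx.size])
    return rng.permutation(np.concatenate(order))


def patient_split(manifest: DatasetManifest, fractions, seed: int
                  ) -> dict[str, np.ndarray]:
    """Partition record indices train/val/test with no patient straddling
    two partitions."""
    patients = manifest.patients()
    unique = np.unique(patients)
    rng = np.random.default_rng(seed)
    shuffled = rng.permutation(unique)
    bounds = np.floor(np.cumsum(fractions) * unique.size + 0.5).astype(int)
    names = ("train", "val", "test")[:len(tuple(fractions))]
    out = {}
    start = 0
    for name, stop in zip(names, bounds):
        chosen = set(shuffled[start:stop])
        out[name] = np.flatnonzero([p in chosen for p in patients])
        start = stop
    return out


# ---------------------------------------------------------------------------
# data loading


def load_input(path, side: int) -> np.ndarray:
    """Read an RGB image and produce a CHW float input at the given side."""
    img = np.asarray(iio.imread(path), dtype=np.float64)
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    img = img[..., :3] / 255.0
    if img.shape[0] != side or img.shape[1] != side:
        img = sk_transform.resize(img, (side, side), anti_aliasing=True,
                                  preserve_range=True)
    return np.moveaxis(img - 0.5, 2, 0)


class _ImageCache:
    def __init__(self, manifest: DatasetManifest, side: int):
        self.manifest = manifest
        self.side = side
        self._cache: dict[int, np.ndarray] = {}

    def __getitem__(self, i: int) -> np.ndarray:
        if i not in self._cache:
            path = self.manifest.resolve(self.manifest.records[i].image_path)
            self._cache[i] = load_input(path, self.side)
        return self._cache[i]

    def batch(self, indices) -> np.ndarray:
        return np.stack([self[i] for i in indices])


# ---------------------------------------------------------------------------
# training loop


def refresh_batchnorm_stats(network, batches) -> None:
    """Recompute batch-norm running statistics from a data pass.

    After only a few optimizer steps the exponentially averaged statistics
    still carry their initialisation, which makes eval-mode inference
    inconsistent with the trained batch statistics in a deep stack of
    normalised layers.  This sets every layer's running mean/variance to
    the arithmetic mean of the batch statistics over the supplied batches
    (momentum ``1/(i+1)`` for batch i is a cumulative average).
    """
    from .nn.layers import BatchNorm2d

    bns = [m for m in network.modules() if isinstance(m, BatchNorm2d)]
    saved = [bn.momentum for bn in bns]
    network.train()
    for i, batch in enumerate(batches):
        for bn in bns:
            bn.momentum = 1.0 / (i + 1)
        network(Tensor(batch))
    for bn, mom in zip(bns, saved):
        bn.momentum = mom


def _accuracy(network, cache: _ImageCache, indices, labels,
              batch_size: int) -> float:
    network.eval()
    correct = 0
    for start in range(0, len(indices), batch_size):
        chunk = indices[start:start + batch_size]
        logits = network(Tensor(cache.batch(chunk))).data
        correct += int((logits.argmax(axis=1) == labels[chunk]).sum())
    return correct / len(indices)


def train(network, manifest: DatasetManifest, cfg: TrainConfig,
          train_indices=None) -> tuple[object, list[dict]]:
    """Fit the network on the manifest's training partition.

    Returns the network and a per-epoch history of the mean batch loss and
    the training accuracy.  Fully reproducible given ``cfg.seed``: the
    label-shuffling read order is re-drawn each epoch from ``seed + epoch``.
    """
    if not manifest.records:
        raise ValueError("empty manifest")
    labels_all = manifest.labels()
    if train_indices is None:
        if cfg.patient_level_split[0] >= 1.0 - 1e-12:
            train_indices = np.arange(len(manifest.records))
        else:
            train_indices = patient_split(
                manifest, cfg.patient_level_split, cfg.seed)["train"]
    train_indices = np.asarray(train_indices)
    train_labels = labels_all[train_indices]
    classes, counts = np.unique(train_labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("training partition contains a single class")
    if cfg.class_weights is not None:
        weights = np.asarray(cfg.class_weights, dtype=np.float64)
    else:
        weights = class_weights_from_counts(counts)

    cache = _ImageCache(manifest, network.input_side)
    history: list[dict] = []
    if cfg.epochs == 0:
        return network, history

    optimizer = Adam(network.parameters(), lr=cfg.learning_rate,
                     betas=(cfg.beta1, cfg.beta2),
                     weight_decay=cfg.weight_decay)
    for epoch in range(cfg.epochs):
        if cfg.balance == "label_shuffling":
            order = label_shuffle(train_labels, cfg.seed + epoch)
        else:
            order = np.random.default_rng(cfg.seed + epoch).permutation(
                train_labels.size)
        read_order = train_indices[order]
        network.train()
        losses = []
        for start in range(0, len(read_order), cfg.batch_size):
            batch = read_order[start:start + cfg.batch_size]
            x = Tensor(cache.batch(batch))
            y = labels_all[batch]
            optimizer.zero_grad()
            loss = F.cross_entropy_logits(network(x), y, weights)
            loss.backward()
            optimizer.step()
            losses.append(loss.item())
        refresh_batchnorm_stats(
            network, (cache.batch(train_indices[s:s + cfg.batch_size])
                      for s in range(0, len(train_indices), cfg.batch_size)))
        acc = _accuracy(network, cache, train_indices, labels_all,
                        cfg.batch_size)
        history.append({"epoch": epoch, "loss": float(np.mean(losses)),
                        "train_accuracy": acc})
    return network, history
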