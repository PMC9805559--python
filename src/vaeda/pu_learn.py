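"""Positive-Unlabeled bagging on the latent features.

The simulated doublets are the positive set P; the input cells are unlabeled
(U) because real doublets hide among them.  Each of N repetitions splits U
into K folds; a fresh logistic classifier is trained to discriminate P from
each fold U_k and scored on the held-out cells U \\ U_k.  A cell's final
doublet score xi is its prediction averaged over every classifier that did
not train on it — N*(K-1) predictions per cell.

The classifier is logistic regression realized as a tiny network
(batch-norm -> dense -> sigmoid, zero-initialized output).  Its training
length is chosen once by probing a 250-epoch fit on the first fold and
locating the knee of the loss curve (Kneedle maximum-difference criterion).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._nn import Adamax, BatchNorm, Dense, sigmoid

log = logging.getLogger("vaeda")

__all__ = [
    "PUFeatures",
    "PUConfig",
    "PUResult",
    "LogisticClassifier",
    "make_classifier",
    "determine_epochs",
    "pu_bagging",
]


@dataclass
class PUFeatures:
    """Latent embedding with the preliminary score appended: Zbar = [Z, s]."""

    Zbar: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.Zbar = np.asarray(self.Zbar, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if self.Zbar.ndim != 2 or self.Zbar.shape[0] != self.labels.size:
            raise ValueError("Zbar rows must align with labels")
        last = self.Zbar[:, -1]
        if last.size and (last.min() < -1e-9 or last.max() > 1 + 1e-9):
            raise ValueError("last Zbar column (preliminary score) must lie in [0, 1]")


@dataclass
class PUConfig:
    n_reps: int = 5
    n_folds: int = 5
    epoch_probe: int = 250
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


@dataclass
class PUResult:
    scores_unlabeled: np.ndarray  # xi, one per unlabeled row
    scores_positive: np.ndarray  # mean prediction of all N*K classifiers on P
    counts: np.ndarray  # number of classifiers contributing to each xi
    epochs_used: int


class LogisticClassifier:
    """Logistic regression as batch-norm -> dense(1, zero init) -> sigmoid.

    Trains full-batch with Adamax and binary cross-entropy; with a zero
    initialization the untrained model outputs 0.5 everywhere.  Batch-norm
    momentum is 0.9 so running statistics track the data within the short
    knee-selected training runs.
    """

    def __init__(self, n_features: int, rng_seed: int = 0, learning_rate: float = 0.01) -> None:
        rng = np.random.default_rng(rng_seed)
        self.bn = BatchNorm(n_features, momentum=0.9)
        self.dense = Dense(n_features, 1, rng, zero_init=True)
        self.opt = Adamax([self.bn, self.dense], lr=learning_rate)

    def _logits(self, x: np.ndarray, training: bool) -> np.ndarray:
        return self.dense.forward(self.bn.forward(x, training), training)[:, 0]

    def fit(self, x: np.ndarray, y: np.ndarray, epochs: int) -> list[float]:
        """Full-batch training; one epoch = one gradient step. Returns the loss curve."""
        x = np.asarray(x, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        m = x.shape[0]
        curve: list[float] = []
        for _ in range(epochs):
            p = sigmoid(self._logits(x, training=True))
            loss = float(-np.mean(y * np.log(np.clip(p, 1e-12, None))
                                  + (1 - y) * np.log(np.clip(1 - p, 1e-12, None))))
            curve.append(loss)
            grad = ((p - y) / m)[:, None]
            self.bn.backward(self.dense.backward(grad))
            self.opt.step()
        return curve

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return sigmoid(self._logits(np.asarray(x, dtype=np.float64), training=False))


def make_classifier(n_features: int, rng_seed: int = 0, learning_rate: float = 0.01) -> LogisticClassifier:
    return LogisticClassifier(n_features, rng_seed=rng_seed, learning_rate=learning_rate)


def determine_epochs(loss_curve, epoch_probe: int = 250, smooth_window: int = 5) -> int:
    """Knee of a decreasing loss curve (Kneedle maximum-difference criterion).

    The curve is lightly smoothed, min-max normalized, flipped to a concave
    increasing shape, and the index maximizing the difference to the straight
    chord is returned (as an epoch count, 1-based).  Curves without genuine
    curvature — constant, linear, or increasing — fall back to ``epoch_probe``.
    """
    y = np.asarray(loss_curve, dtype=np.float64)
    if y.size < 3:
        return epoch_probe
    if smooth_window > 1:
        kernel = np.ones(min(smooth_window, y.size)) / min(smooth_window, y.size)
        y = np.convolve(y, kernel, mode="valid")
    rng_y = y.max() - y.min()
    if rng_y <= 0 or y[-1] >= y[0]:
        return epoch_probe
    x_n = np.linspace(0.0, 1.0, y.size)
    y_n = (y - y.min()) / rng_y
    diff = (1.0 - y_n) - x_n  # flipped curve minus the chord
    if diff.max() <= 0.05:  # indistinguishable from a straight line
        return epoch_probe
    return int(np.argmax(diff)) + 1


def pu_bagging(F: PUFeatures, cfg: PUConfig, classifier_factory=None) -> PUResult:
    """PU bagging: average held-out predictions over N repetitions of K folds.

    ``classifier_factory(n_features, rng_seed)`` must return an object with
    ``fit(x, y, epochs) -> loss curve`` and ``predict_proba(x)``; the default
    builds the logistic network above.  Fold splits of repetition r are
    seeded by ``rng_seed + r`` (r = 1..N); the probe fit uses ``rng_seed``.
    """
    if classifier_factory is None:
        classifier_factory = make_classifier
    y = np.asarray(F.labels)
    u_idx = np.flatnonzero(y == 0)
    p_idx = np.flatnonzero(y == 1)
    if p_idx.size == 0:
        raise ValueError("no positive (simulated doublet) rows")
    if cfg.n_folds > u_idx.size:
        raise ValueError(f"n_folds={cfg.n_folds} exceeds the {u_idx.size} unlabeled rows")
    n_features = F.Zbar.shape[1]
    x_pos = F.Zbar[p_idx]

    # probe fit on the first fold of a seeded split to pick the epoch count
    probe_rng = np.random.default_rng(cfg.rng_seed)
    probe_fold = np.array_split(probe_rng.permutation(u_idx), cfg.n_folds)[0]
    probe_clf = classifier_factory(n_features, cfg.rng_seed)
    x_probe = np.vstack([x_pos, F.Zbar[probe_fold]])
    y_probe = np.concatenate([np.ones(p_idx.size), np.zeros(probe_fold.size)])
    curve = probe_clf.fit(x_probe, y_probe, cfg.epoch_probe)
    epochs = determine_epochs(curve, cfg.epoch_probe)
    log.info("PU probe selected %d training epochs", epochs)

    f_sum = np.zeros(u_idx.size)
    counts = np.zeros(u_idx.size, dtype=np.int64)
    pos_sum = np.zeros(p_idx.size)
    pos_in_u = {j: i for i, j in enumerate(u_idx)}

    for rep in range(1, cfg.n_reps + 1):
        rng = np.random.default_rng(cfg.rng_seed + rep)
        folds = np.array_split(rng.permutation(u_idx), cfg.n_folds)
        for k, fold in enumerate(folds):
            clf = classifier_factory(n_features, cfg.rng_seed + 1000 * rep + k)
            x_train = np.vstack([x_pos, F.Zbar[fold]])
            y_train = np.concatenate([np.ones(p_idx.size), np.zeros(fold.size)])
            clf.fit(x_train, y_train, epochs)
            held_out = np.setdiff1d(u_idx, fold, assume_unique=True)
            preds = clf.predict_proba(F.Zbar[held_out])
            pos_of = np.fromiter((pos_in_u[j] for j in held_out), dtype=np.int64)
            f_sum[pos_of] += preds
            counts[pos_of] += 1
            pos_sum += clf.predict_proba(x_pos)

    if np.any(counts == 0):
        raise RuntimeError("some unlabeled rows were never held out; check fold bookkeeping")
    return PUResult(
        scores_unlabeled=f_sum / counts,
        scores_positive=pos_sum / (cfg.n_reps * cfg.n_folds),
        counts=counts,
        epochs_used=epochs,
    )
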