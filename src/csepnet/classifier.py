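"""The 38-class speech-intelligibility CNN.

Architecture (full profile, 299 × 299 × 3 input):

    Conv2D(32, 16×16) → LeakyReLU → Conv2D(8, 8×8) → LeakyReLU →
    MaxPool(2×2, stride 2) → Conv2D(8, 4×4) → LeakyReLU →
    MaxPool(2×2, stride 1) → Conv2D(3, 3×3) → LeakyReLU →
    MaxPool(2×2, stride 1) → BatchNorm → Dense(38) → Softmax

All convolutions are same-padded (they preserve the 299 × 299 spatial
size); the three pools use strides 2, 1, 1 — the only strides that
reproduce the reference 299 → 149 → 148 → 147 shape progression.  Batch
normalization sits after the last pool, immediately before the single
fully connected layer.  Output units cover all 38 observed score classes
regardless of which classes a particular run's data contains.

Training follows the reference recipe: Adam, learning rate 0.001, batch
size 64, 5 epochs, 20 % of the training images held out for validation,
shuffling before training.  A ``small`` profile (128 × 128 input, filter
counts divided by 4) makes single-CPU end-to-end runs tractable; it is a
test/validation profile, not the reference architecture.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from . import nn
from .labels import N_CLASSES, SCORE_GRID, class_to_score, score_to_class

#: Reference layer-by-layer output shapes (H, W, D) for the full profile.
REFERENCE_SHAPE_TABLE = (
    ("Input", (299, 299, 3)),
    ("Conv2D", (299, 299, 32)),
    ("LeakyReLU", (299, 299, 32)),
    ("Conv2D", (299, 299, 8)),
    ("LeakyReLU", (299, 299, 8)),
    ("Maxpooling2D", (149, 149, 8)),
    ("Conv2D", (149, 149, 8)),
    ("LeakyReLU", (149, 149, 8)),
    ("Maxpooling2D", (148, 148, 8)),
    ("Conv2D", (148, 148, 3)),
    ("LeakyReLU", (148, 148, 3)),
    ("Maxpooling2D", (147, 147, 3)),
    ("Batch normalization", (147, 147, 3)),
    ("Fully connected", (38,)),
    ("Softmax", (38,)),
)


class ShapeAuditError(ValueError):
    pass


@dataclass(frozen=True)
class ModelSpec:
    input_size: int = 299
    conv_filters: tuple = (32, 8, 8, 3)
    conv_kernels: tuple = ((16, 16), (8, 8), (4, 4), (3, 3))
    pool_strides: tuple = (2, 1, 1)
    n_classes: int = N_CLASSES
    leaky_slope: float = 0.01
    profile: str = "full"

    @classmethod
    def small(cls) -> "ModelSpec":
        """128 × 128 input with filter counts divided by 4 (floor, min 1)."""
        return cls(
            input_size=128,
            conv_filters=tuple(max(1, f // 4) for f in (32, 8, 8, 3)),
            profile="small",
        )

    def expected_shapes(self) -> tuple:
        """The layer table implied by same-padding convs and the pool strides."""
        n = self.input_size
        f1, f2, f3, f4 = self.conv_filters
        s1, s2, s3 = self.pool_strides
        p1 = (n - 2) // s1 + 1
        p2 = (p1 - 2) // s2 + 1
        p3 = (p2 - 2) // s3 + 1
        return (
            ("Input", (n, n, 3)),
            ("Conv2D", (n, n, f1)),
            ("LeakyReLU", (n, n, f1)),
            ("Conv2D", (n, n, f2)),
            ("LeakyReLU", (n, n, f2)),
            ("Maxpooling2D", (p1, p1, f2)),
            ("Conv2D", (p1, p1, f3)),
            ("LeakyReLU", (p1, p1, f3)),
            ("Maxpooling2D", (p2, p2, f3)),
            ("Conv2D", (p2, p2, f4)),
            ("LeakyReLU", (p2, p2, f4)),
            ("Maxpooling2D", (p3, p3, f4)),
            ("Batch normalization", (p3, p3, f4)),
            ("Fully connected", (self.n_classes,)),
            ("Softmax", (self.n_classes,)),
        )


def build_model(spec: ModelSpec = ModelSpec(), seed: int = 0,
                dtype=np.float32) -> nn.Sequential:
    """Instantiate the network and audit its shape table against the spec.

    Raises :class:`ShapeAuditError` printing both shape tables on mismatch.
    """
    rng = np.random.default_rng(seed)
    f1, f2, f3, f4 = spec.conv_filters
    k1, k2, k3, k4 = spec.conv_kernels
    s1, s2, s3 = spec.pool_strides
    expected = spec.expected_shapes()
    flat_dim = int(np.prod(expected[-3][1]))
    model = nn.Sequential([
        nn.Conv2D(3, f1, k1, rng, dtype),
        nn.LeakyReLU(spec.leaky_slope),
        nn.Conv2D(f1, f2, k2, rng, dtype),
        nn.LeakyReLU(spec.leaky_slope),
        nn.MaxPool2D(2, s1),
        nn.Conv2D(f2, f3, k3, rng, dtype),
        nn.LeakyReLU(spec.leaky_slope),
        nn.MaxPool2D(2, s2),
        nn.Conv2D(f3, f4, k4, rng, dtype),
        nn.LeakyReLU(spec.leaky_slope),
        nn.MaxPool2D(2, s3),
        nn.BatchNorm2D(f4, dtype=dtype),
        nn.Flatten(),
        nn.Dense(flat_dim, spec.n_classes, rng, dtype),
    ])
    trace = model.shape_trace((spec.input_size, spec.input_size, 3))
    built = [shape for _, shape in trace]
    built = built[:-2] + [built[-1], built[-1]]  # Flatten folded into FC row
    want = [shape for _, shape in expected]
    if built != want:
        raise ShapeAuditError(
            "layer shape audit failed\nexpected: "
            + "\n          ".join(map(str, expected))
            + "\nbuilt:    "
            + "\n          ".join(map(str, trace))
        )
    return model


def shape_audit(spec: ModelSpec = ModelSpec(), seed: int = 0) -> list:
    """Forward shape trace of the built model, one row per reference-table layer."""
    model = build_model(spec, seed)
    trace = model.shape_trace((spec.input_size, spec.input_size, 3))
    rows = trace[:-2] + [("Fully connected", trace[-1][1]), ("Softmax", trace[-1][1])]
    return rows


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.001
    batch_size: int = 64
    epochs: int = 5
    validation_fraction: float = 0.2
    shuffle: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.batch_size, self.epochs) <= 0:
            raise ValueError("learning_rate, batch_size and epochs must be positive")
        if not 0 < self.validation_fraction < 1:
            raise ValueError("validation_fraction must be in (0, 1)")


class CSEPImageClassifier(ClassifierMixin, BaseEstimator):
    """Scikit-learn style estimator over the numpy CNN.

    ``fit(X, y)`` takes rendered images X of shape (n, size, size, 3) with
    values in [0, 1] and behavioral scores y on the observed 2.5-step grid.
    Internally every score maps to its fixed 38-class index; classes absent
    from the data keep their output units.

    Fitted attributes: ``model_`` (the network), ``classes_`` (observed
    score levels), ``history_`` (per-epoch train/validation loss and
    accuracy).
    """

    def __init__(self, profile: str = "full", learning_rate: float = 0.001,
                 batch_size: int = 64, epochs: int = 5,
                 validation_fraction: float = 0.2, shuffle: bool = True,
                 leaky_slope: float = 0.01, random_state: int = 0):
        self.profile = profile
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.validation_fraction = validation_fraction
        self.shuffle = shuffle
        self.leaky_slope = leaky_slope
        self.random_state = random_state

    def _spec(self) -> ModelSpec:
        if self.profile == "full":
            return ModelSpec(leaky_slope=self.leaky_slope)
        if self.profile == "small":
            base = ModelSpec.small()
            return ModelSpec(**{**base.__dict__, "leaky_slope": self.leaky_slope})
        raise ValueError(f"unknown profile {self.profile!r}")

    def _check_X(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        size = self._spec().input_size
        if X.ndim != 4 or X.shape[1:] != (size, size, 3):
            raise ValueError(
                f"X must be (n, {size}, {size}, 3) for profile {self.profile!r}, "
                f"got {X.shape}"
            )
        return X

    def fit(self, X, y):
        X = self._check_X(X)
        y = np.asarray(y, dtype=np.float64).ravel()
        if len(y) != len(X):
            raise ValueError("X and y length mismatch")
        targets = np.array([score_to_class(s) for s in y])
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("training requires at least 2 classes")

        rng = np.random.default_rng(self.random_state)
        spec = self._spec()
        self.model_ = build_model(spec, seed=int(rng.integers(0, 2**31 - 1)))

        n_val = int(round(self.validation_fraction * len(X)))
        perm = rng.permutation(len(X))
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        opt = nn.Adam(self.model_.params(), lr=self.learning_rate)

        self.history_ = {"train_loss": [], "train_acc": [],
                         "val_loss": [], "val_acc": []}
        for _epoch in range(self.epochs):
            order = rng.permutation(tr_idx) if self.shuffle else tr_idx
            losses, correct, total = [], 0, 0
            for i in range(0, len(order), self.batch_size):
                idx = order[i : i + self.batch_size]
                logits = self.model_.forward(X[idx], train=True)
                loss, dlogits, probs = nn.softmax_cross_entropy(logits, targets[idx])
                self.model_.backward(dlogits)
                opt.step()
                losses.append(loss * len(idx))
                correct += int((probs.argmax(1) == targets[idx]).sum())
                total += len(idx)
            self.history_["train_loss"].append(float(np.sum(losses) / total))
            self.history_["train_acc"].append(correct / total)
            if n_val:
                vl, va = self._eval_loss_acc(X[val_idx], targets[val_idx])
            else:
                vl, va = float("nan"), float("nan")
            self.history_["val_loss"].append(vl)
            self.history_["val_acc"].append(va)
        return self

    def _eval_loss_acc(self, X, targets):
        probs = self.model_.predict_proba(X, self.batch_size)
        eps = 1e-12
        loss = float(-np.mean(np.log(probs[np.arange(len(targets)), targets] + eps)))
        acc = float((probs.argmax(1) == targets).mean())
        return loss, acc

    def predict_proba_grid(self, X) -> np.ndarray:
        """(n, 38) softmax probabilities over the full score grid."""
        X = self._check_X(X)
        return self.model_.predict_proba(X, self.batch_size)

    def predict_proba(self, X) -> np.ndarray:
        """Probabilities over ``classes_`` (renormalized full-grid columns)."""
        full = self.predict_proba_grid(X)
        cols = [score_to_class(s) for s in self.classes_]
        p = full[:, cols]
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, X) -> np.ndarray:
        full = self.predict_proba_grid(X)
        return np.array([class_to_score(i) for i in full.argmax(1)])

    def score(self, X, y) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y, dtype=np.float64)))


def train(train_images: np.ndarray, scores: np.ndarray,
          cfg: TrainConfig = TrainConfig(), profile: str = "full") -> CSEPImageClassifier:
    """Fit a classifier on rendered images with the reference training recipe."""
    clf = CSEPImageClassifier(
        profile=profile, learning_rate=cfg.learning_rate, batch_size=cfg.batch_size,
        epochs=cfg.epochs, validation_fraction=cfg.validation_fraction,
        shuffle=cfg.shuffle, random_state=cfg.seed,
    )
    return clf.fit(train_images, scores)


def evaluate_accuracy(clf: CSEPImageClassifier, X, y) -> dict:
    """Overall accuracy (%) plus the micro-averaged confusion-matrix form.

    ``confusion_accuracy_pct`` is (TN+TP)/(TN+TP+FN+FP) with the four counts
    summed over all 38 classes in one-vs-rest form.
    """
    y = np.asarray(y, dtype=np.float64).ravel()
    if len(y) == 0:
        raise ValueError("empty test set")
    pred = clf.predict(X)
    n = len(y)
    accuracy = float(np.mean(pred == y)) * 100.0
    errors = int(np.sum(pred != y))
    k = N_CLASSES
    # per class: an error adds one FP and one FN; everything else is TP/TN
    tp = n - errors
    fp = fn = errors
    tn = n * k - tp - fp - fn
    confusion_accuracy = (tn + tp) / (tn + tp + fn + fp) * 100.0
    return {
        "accuracy_pct": accuracy,
        "confusion_accuracy_pct": confusion_accuracy,
        "n_test": n,
        "n_errors": errors,
    }


def chance_level_pct(n_classes: int = N_CLASSES) -> float:
    """Probabilistic chance level for uniform guessing, in percent."""
    return 100.0 / n_classes


_CKPT_ATTRS = ("W", "b", "gamma", "beta", "running_mean", "running_var")


def save_model(path, clf: CSEPImageClassifier) -> None:
    """Write a fitted classifier (weights + config + history) to an .npz."""
    import json

    arrays = {}
    for i, layer in enumerate(clf.model_.layers):
        for attr in _CKPT_ATTRS:
            if hasattr(layer, attr):
                arrays[f"l{i}_{attr}"] = getattr(layer, attr)
    manifest = {
        "params": clf.get_params(),
        "classes": np.asarray(clf.classes_).tolist(),
        "history": clf.history_,
    }
    np.savez_compressed(path, manifest=np.frombuffer(
        json.dumps(manifest).encode(), dtype=np.uint8), **arrays)


def load_model(path) -> CSEPImageClassifier:
    """Restore a classifier saved by :func:`save_model`."""
    import json

    with np.load(path) as z:
        manifest = json.loads(bytes(z["manifest"]).decode())
        arrays = {k: z[k] for k in z.files if k != "manifest"}
    clf = CSEPImageClassifier(**manifest["params"])
    clf.model_ = build_model(clf._spec(), seed=0)
    for i, layer in enumerate(clf.model_.layers):
        for attr in _CKPT_ATTRS:
            key = f"l{i}_{attr}"
            if key in arrays:
                getattr(layer, attr)[...] = arrays[key]
    clf.classes_ = np.asarray(manifest["classes"], dtype=np.float64)
    clf.history_ = manifest["history"]
    return clf
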