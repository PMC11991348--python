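"""Per-region binary PPE classifiers.

Each region (face, palm, torso) gets one binary classifier answering
"is the protective item worn in this crop?".  The trainable part is a
small head: dropout (rate 0.2) -> dense layer of width 712 -> ReLU ->
dense scalar -> sigmoid, trained with Adam on binary cross-entropy for
ten epochs against a held-out validation split of 20%.

The head sits on top of a frozen feature extractor mapping a
224 x 224 x 3 crop to a fixed-length vector.  The default extractor is
:class:`RandomProjectionFeatureExtractor`, a deterministic seeded linear
projection of the block-downsampled crop: it preserves colour/intensity
structure (which is what distinguishes PPE patches in the synthetic
scenes) and keeps the whole stack dependency-light and exactly
reproducible.  Any callable producing a fixed-length vector per crop can
be plugged in instead — the head's hidden layer adapts to the feature
dimension it sees at fit time.

Estimators follow scikit-learn conventions (``fit`` / ``predict`` /
``predict_proba``, ``get_params``, fitted attributes with trailing
underscores) and compose with sklearn model selection.
"""

from __future__ import annotations

import json
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .stats import ConfusionMatrix2x2

CROP_SIZE = 224


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class RandomProjectionFeatureExtractor(BaseEstimator, TransformerMixin):
    """Deterministic seeded linear feature extractor for 224x224x3 crops.

    The crop is scaled to [0, 1], block-averaged down to
    ``downsample x downsample`` per channel, flattened, and multiplied by
    a fixed Gaussian projection matrix drawn once from ``seed``.  The
    map is linear with a dense projection matrix, so an all-zero image
    maps to the zero vector and any single-pixel change perturbs the
    output.

    Parameters
    ----------
    output_dim : feature vector length F (default 712).
    downsample : side of the intermediate block-averaged image; must
        divide 224.
    seed : seed of the fixed projection matrix (not a per-call RNG).
    """

    def __init__(self, output_dim: int = 712, downsample: int = 32, seed: int = 0):
        self.output_dim = output_dim
        self.downsample = downsample
        self.seed = seed

    def _projection(self) -> np.ndarray:
        if CROP_SIZE % self.downsample != 0:
            raise ValueError(f"downsample must divide {CROP_SIZE}")
        d_in = self.downsample * self.downsample * 3
        rng = np.random.default_rng(self.seed)
        return rng.normal(0.0, 1.0 / np.sqrt(d_in), size=(d_in, self.output_dim))

    def fit(self, X=None, y=None):  # stateless; kept for pipeline compatibility
        self.projection_ = self._projection()
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Map crops (n, 224, 224, 3) — or one crop — to features (n, F)."""
        imgs = np.asarray(X)
        single = imgs.ndim == 3
        if single:
            imgs = imgs[None]
        if imgs.ndim != 4 or imgs.shape[1:] != (CROP_SIZE, CROP_SIZE, 3):
            raise ValueError(
                f"expected crops of shape (n, {CROP_SIZE}, {CROP_SIZE}, 3), got {imgs.shape}"
            )
        if not hasattr(self, "projection_"):
            self.fit()
        block = CROP_SIZE // self.downsample
        x = imgs.astype(np.float64) / 255.0
        x = x.reshape(len(imgs), self.downsample, block, self.downsample, block, 3)
        x = x.mean(axis=(2, 4)).reshape(len(imgs), -1)
        feats = x @ self.projection_
        return feats[0] if single else feats


class RegionPPEClassifier(BaseEstimator, ClassifierMixin):
    """Binary classifier head for one region's PPE item.

    Architecture: dropout(rate) on the input features, dense
    (F -> hidden_dim), ReLU, dense (hidden_dim -> 1), sigmoid.  Trained
    with mini-batch Adam on binary cross-entropy; a seeded shuffle holds
    out ``validation_fraction`` of the data, and per-epoch train/val
    loss and accuracy are recorded in ``history_``.

    All randomness (validation split, weight init, dropout masks, batch
    order) derives from ``random_state``, so identical seed and data
    reproduce identical weights and history.
    """

    def __init__(
        self,
        hidden_dim: int = 712,
        dropout_rate: float = 0.2,
        epochs: int = 10,
        batch_size: int = 32,
        learning_rate: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        adam_eps: float = 1e-8,
        validation_fraction: float = 0.2,
        decision_threshold: float = 0.5,
        random_state: int = 0,
    ):
        self.hidden_dim = hidden_dim
        self.dropout_rate = dropout_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.beta1 = beta1
        self.beta2 = beta2
        self.adam_eps = adam_eps
        self.validation_fraction = validation_fraction
        self.decision_threshold = decision_threshold
        self.random_state = random_state

    # --- forward -----------------------------------------------------

    def _forward(self, X: np.ndarray) -> np.ndarray:
        h = np.maximum(X @ self.W1_ + self.b1_, 0.0)
        return _sigmoid(h @ self.W2_ + self.b2_)

    # --- training ----------------------------------------------------

    def fit(self, X: np.ndarray, y: Sequence[int]) -> "RegionPPEClassifier":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y).astype(int).ravel()
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be (n, F) with matching labels")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must lie in (0, 1)")
        classes = np.unique(y)
        if not np.array_equal(classes, [0, 1]):
            raise ValueError(
                "training data must contain both classes with labels in {0, 1}; "
                f"got classes {classes.tolist()}"
            )
        rng = np.random.default_rng(self.random_state)
        n, F = X.shape
        perm = rng.permutation(n)
        n_val = max(1, int(round(self.validation_fraction * n)))
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        Xtr, ytr = X[tr_idx], y[tr_idx]
        Xval, yval = X[val_idx], y[val_idx]
        if len(Xtr) == 0:
            raise ValueError("validation split leaves no training data")

        H = self.hidden_dim
        self.W1_ = rng.normal(0.0, np.sqrt(2.0 / F), size=(F, H))
        self.b1_ = np.zeros(H)
        self.W2_ = rng.normal(0.0, np.sqrt(2.0 / H), size=(H, 1)).ravel()
        self.b2_ = 0.0

        params = ["W1_", "b1_", "W2_", "b2_"]
        m = {p: np.zeros_like(np.asarray(getattr(self, p), dtype=float)) for p in params}
        v = {p: np.zeros_like(np.asarray(getattr(self, p), dtype=float)) for p in params}
        t = 0
        keep = 1.0 - self.dropout_rate
        history = []
        for epoch in range(1, self.epochs + 1):
            order = rng.permutation(len(Xtr))
            for start in range(0, len(Xtr), self.batch_size):
                idx = order[start : start + self.batch_size]
                xb, yb = Xtr[idx], ytr[idx]
                # inverted dropout on the head input
                if self.dropout_rate > 0:
                    mask = (rng.random(xb.shape) < keep) / keep
                    xb = xb * mask
                z1 = xb @ self.W1_ + self.b1_
                h = np.maximum(z1, 0.0)
                p = _sigmoid(h @ self.W2_ + self.b2_)
                # BCE gradient: dL/dz2 = p - y
                dz2 = (p - yb) / len(yb)
                grads = {
                    "W2_": h.T @ dz2,
                    "b2_": dz2.sum(),
                }
                dh = np.outer(dz2, self.W2_)
                dz1 = dh * (z1 > 0)
                grads["W1_"] = xb.T @ dz1
                grads["b1_"] = dz1.sum(axis=0)
                t += 1
                for pname in params:
                    g = grads[pname]
                    m[pname] = self.beta1 * m[pname] + (1 - self.beta1) * g
                    v[pname] = self.beta2 * v[pname] + (1 - self.beta2) * g * g
                    mhat = m[pname] / (1 - self.beta1**t)
                    vhat = v[pname] / (1 - self.beta2**t)
                    step = self.learning_rate * mhat / (np.sqrt(vhat) + self.adam_eps)
                    setattr(self, pname, getattr(self, pname) - step)
            history.append(
                {
                    "epoch": epoch,
                    "train_loss": self._bce(Xtr, ytr),
                    "train_acc": self._acc(Xtr, ytr),
                    "val_loss": self._bce(Xval, yval),
                    "val_acc": self._acc(Xval, yval),
                }
            )
        self.history_ = history
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = F
        return self

    def _bce(self, X: np.ndarray, y: np.ndarray) -> float:
        p = np.clip(self._forward(X), 1e-12, 1 - 1e-12)
        return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))

    def _acc(self, X: np.ndarray, y: np.ndarray) -> float:
        return float(np.mean((self._forward(X) >= self.decision_threshold) == y))

    # --- inference ---------------------------------------------------

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """P(item worn) per crop feature vector; dropout disabled."""
        check_is_fitted(self, "W1_")
        X = np.asarray(X, dtype=np.float64)
        single = X.ndim == 1
        p1 = self._forward(X[None] if single else X)
        p1 = p1[0] if single else p1
        return p1

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Boolean prediction: probability >= decision_threshold."""
        return self.predict_proba(X) >= self.decision_threshold

    def evaluate(self, X: np.ndarray, y: Sequence[int]) -> ConfusionMatrix2x2:
        """Prediction-vs-truth confusion matrix, truth on rows."""
        check_is_fitted(self, "W1_")
        y = np.asarray(y).astype(bool).ravel()
        if len(y) == 0:
            raise ValueError("cannot evaluate on an empty dataset")
        pred = self.predict(X)
        return ConfusionMatrix2x2(
            a=int(np.sum(y & pred)),
            b=int(np.sum(y & ~pred)),
            c=int(np.sum(~y & pred)),
            d=int(np.sum(~y & ~pred)),
        )

    # --- persistence -------------------------------------------------

    def to_json_dict(self) -> dict:
        check_is_fitted(self, "W1_")
        return {
            "format": "ppewatch-head-v1",
            "params": self.get_params(),
            "weights": {
                "W1": self.W1_.tolist(),
                "b1": self.b1_.tolist(),
                "W2": self.W2_.tolist(),
                "b2": float(self.b2_),
            },
        }

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh)

    @classmethod
    def from_json_dict(cls, d: dict) -> "RegionPPEClassifier":
        if d.get("format") != "ppewatch-head-v1":
            raise ValueError("not a ppewatch head weight bundle")
        clf = cls(**d["params"])
        w = d["weights"]
        clf.W1_ = np.asarray(w["W1"], dtype=float)
        clf.b1_ = np.asarray(w["b1"], dtype=float)
        clf.W2_ = np.asarray(w["W2"], dtype=float)
        clf.b2_ = float(w["b2"])
        clf.classes_ = np.array([0, 1])
        clf.n_features_in_ = clf.W1_.shape[0]
        clf.history_ = d.get("history", [])
        return clf

    @classmethod
    def load_json(cls, path) -> "RegionPPEClassifier":
        with open(path) as fh:
            return cls.from_json_dict(json.load(fh))


def training_log_frame(clf: RegionPPEClassifier):
    """Per-epoch training log as a DataFrame (epoch, losses, accuracies)."""
    import pandas as pd

    check_is_fitted(clf, "history_")
    return pd.DataFrame(clf.history_)
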