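"""Scikit-learn-style convolutional classifier for SNP images.

``ConvNetClassifier`` wraps the numpy network stack behind the estimator
protocol (``fit`` / ``predict`` / ``predict_proba``, ``get_params`` /
``set_params``) so it composes with sklearn model selection.  Training
follows the study protocol: Adam, cross-entropy loss, batch size 8, L2
regularisation; learning rate 1e-3 for 20 epochs (residual families) or
1e-2 for 30 epochs (plain CNN); a stratified 25% validation split guides
model selection — the weights from the epoch with the best validation loss
are kept.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .errors import ConfigurationError
from .nn.layers import softmax_cross_entropy
from .nn.models import ArchitectureSpec, build_model

#: per-family training defaults (learning rate, max epochs)
FAMILY_DEFAULTS = {
    "plain_cnn": {"learning_rate": 1e-2, "epochs": 30},
    "resnet18": {"learning_rate": 1e-3, "epochs": 20},
    "resnet34": {"learning_rate": 1e-3, "epochs": 20},
}


@dataclass
class TrainConfig:
    """Bag of training hyperparameters (CLI/pipeline configuration surface)."""

    family: str = "resnet18"
    learning_rate: float = None
    batch_size: int = 8
    epochs: int = None
    weight_decay: float = 1e-4
    width: float = 1.0
    validation_fraction: float = 0.25
    seed: int = 0

    def resolved(self) -> "TrainConfig":
        d = FAMILY_DEFAULTS[self.family]
        return TrainConfig(
            family=self.family,
            learning_rate=self.learning_rate if self.learning_rate is not None else d["learning_rate"],
            batch_size=self.batch_size,
            epochs=self.epochs if self.epochs is not None else d["epochs"],
            weight_decay=self.weight_decay,
            width=self.width,
            validation_fraction=self.validation_fraction,
            seed=self.seed,
        )


class ConvNetClassifier(BaseEstimator, ClassifierMixin):
    """CNN / ResNet classifier over square images.

    Parameters
    ----------
    family : {"plain_cnn", "resnet18", "resnet34"}
    width : float
        Channel-width multiplier (1.0 = production size).
    learning_rate, epochs : optional overrides of the family defaults.
    batch_size : minibatch size (default 8).
    weight_decay : L2 coefficient added to weight gradients.
    validation_fraction : stratified share of the fit data held out to pick
        the best epoch by validation loss (0 disables selection).
    center_inputs : subtract the training-set mean image before the network.
    random_state : seed for the validation split, initialisation, batch order.

    Attributes (after fit)
    ----------------------
    model_ : the underlying network, selected at ``best_epoch_``.
    classes_, n_features_in_, loss_trace_ : fitted metadata.
    """

    def __init__(
        self,
        family: str = "plain_cnn",
        width: float = 1.0,
        learning_rate: float = None,
        batch_size: int = 8,
        epochs: int = None,
        weight_decay: float = 1e-4,
        validation_fraction: float = 0.25,
        center_inputs: bool = True,
        augment_missing: float = 0.0,
        random_state: int = 0,
    ):
        self.family = family
        self.width = width
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.weight_decay = weight_decay
        self.validation_fraction = validation_fraction
        self.center_inputs = center_inputs
        self.augment_missing = augment_missing
        self.random_state = random_state

    # -- helpers ------------------------------------------------------------
    def _as_images(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 2:
            side = int(math.isqrt(X.shape[1]))
            if side * side != X.shape[1]:
                raise ConfigurationError("flat input length is not a perfect square")
            X = X.reshape(len(X), side, side)
        if X.ndim != 3 or X.shape[1] != X.shape[2]:
            raise ConfigurationError(f"expected square images, got shape {X.shape}")
        return X

    def _encode_labels(self, y) -> tuple[np.ndarray, np.ndarray]:
        y = np.asarray(y)
        if y.ndim == 2:  # one-hot
            classes = np.arange(y.shape[1])
            return classes, np.argmax(y, axis=1)
        classes = np.unique(y)
        lut = {c: i for i, c in enumerate(classes)}
        return classes, np.array([lut[v] for v in y])

    # -- estimator API ------------------------------------------------------
    def fit(self, X, y):
        X = self._as_images(X)
        self.classes_, yi = self._encode_labels(y)
        if len(self.classes_) < 2:
            raise ConfigurationError("need at least two classes")
        rng = np.random.default_rng(self.random_state)

        self.input_mean_ = X.mean(axis=0) if self.center_inputs else np.zeros_like(X[0])
        Xc = X - self.input_mean_

        resolved = TrainConfig(
            family=self.family,
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            epochs=self.epochs,
            weight_decay=self.weight_decay,
            width=self.width,
            validation_fraction=self.validation_fraction,
            seed=self.random_state,
        ).resolved()

        spec = ArchitectureSpec(
            family=self.family, side=X.shape[1], n_classes=len(self.classes_), width=self.width
        )
        model = build_model(spec, seed=int(rng.integers(0, 2**31 - 1)))

        # stratified validation split
        if self.validation_fraction > 0 and len(X) >= 8:
            val_idx = _stratified_take(yi, self.validation_fraction, rng)
        else:
            val_idx = np.zeros(len(X), dtype=bool)
        tr_idx = ~val_idx
        onehot = np.eye(len(self.classes_), dtype=np.float32)[yi]

        model, trace, best_epoch = _train_loop(
            model,
            Xc[tr_idx],
            onehot[tr_idx],
            Xc[val_idx],
            onehot[val_idx],
            resolved,
            rng,
            augment_missing=self.augment_missing,
            missing_value=-self.input_mean_,
        )
        self.model_ = model
        self.loss_trace_ = trace
        self.best_epoch_ = best_epoch
        self.n_features_in_ = X.shape[1] * X.shape[2]
        self.train_config_ = resolved
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        X = self._as_images(X) - self.input_mean_
        return self.model_.predict_proba(X)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def decision_function(self, X) -> np.ndarray:
        """Binary score: probability margin for the positive (last) class."""
        proba = self.predict_proba(X)
        if proba.shape[1] != 2:
            raise ConfigurationError("decision_function requires a binary classifier")
        return proba[:, 1] - proba[:, 0]

    def grad_cam(self, X, class_idx=None, batch_size: int = 32) -> np.ndarray:
        """Saliency heatmaps for ``X`` (input centering applied as in fit)."""
        check_is_fitted(self, "model_")
        from .interpret import grad_cam as _grad_cam

        X = self._as_images(X) - self.input_mean_
        return _grad_cam(self.model_, X, class_idx=class_idx, batch_size=batch_size)


def _stratified_take(yi: np.ndarray, fraction: float, rng) -> np.ndarray:
    """Boolean mask selecting ~fraction of each class (floor, at least 1)."""
    take = np.zeros(len(yi), dtype=bool)
    for c in np.unique(yi):
        members = np.flatnonzero(yi == c)
        n_take = max(1, int(np.floor(fraction * len(members))))
        take[rng.permutation(members)[:n_take]] = True
    return take


def _train_loop(model, Xtr, Ytr, Xval, Yval, cfg: TrainConfig, rng,
                augment_missing: float = 0.0, missing_value=None):
    """Adam minibatch training; returns (best model, loss trace, best epoch).

    ``augment_missing`` masks that fraction of pixels per training batch to
    the missing-call value — genotyping-dropout augmentation that discourages
    memorising individual pixels.
    """
    opt = model.make_optimizer(lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
    has_val = len(Xval) > 0
    best_state, best_val, best_epoch = model.state(), np.inf, 0
    rows = []
    n = len(Xtr)
    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb = Xtr[idx]
            if augment_missing > 0:
                mask = rng.random(xb.shape) < augment_missing
                xb = np.where(mask, missing_value[None, ...], xb)
            logits = model.forward(xb, train=True)
            loss, dlogits = softmax_cross_entropy(logits, Ytr[idx])
            if not np.isfinite(loss):
                raise ArithmeticError(
                    f"non-finite training loss at epoch {epoch}; try a lower learning rate"
                )
            model.backward(dlogits)
            opt.step()
            epoch_loss += loss
            n_batches += 1
        train_loss = epoch_loss / max(n_batches, 1)
        if has_val:
            vlogits = model.forward(Xval, train=False)
            val_loss, _ = softmax_cross_entropy(vlogits, Yval)
        else:
            val_loss = train_loss
        rows.append({"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss})
        if val_loss < best_val:
            best_val, best_epoch = val_loss, epoch
            best_state = model.state()
    if cfg.epochs > 0:
        model.load_state(best_state)
    return model, pd.DataFrame(rows), best_epoch
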