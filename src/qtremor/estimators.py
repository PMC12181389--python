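"""scikit-learn-style estimators wrapping the filter and the two networks.

`QuanvolutionTransformer` is a stateless transformer (the filter has no
trainable parameters); `ClassicalCNNClassifier` and `HybridTremorClassifier`
are classifiers with the usual fit/predict/predict_proba/score surface, so
they compose with sklearn pipelines and model selection.

Input convention: X is a stack of grayscale images, shape (N, H, W) (or
(N, H, W, C) for precomputed feature maps), values in [0, 1] or 8-bit.
Both classifiers resize 2-D images to 32 x 215 (bilinear) before the conv
trunk, mirroring the preprocessing of the reference architecture; pass
``resize=None`` to skip (e.g. for precomputed feature stacks).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted

from . import network
from .quantvolution import QuantvolutionConfig, normalize_image, quantvolve_image

__all__ = ["QuanvolutionTransformer", "ClassicalCNNClassifier", "HybridTremorClassifier",
           "resize_images"]


def resize_images(x: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    """Bilinear resize of an (N, H, W) stack to ``size`` = (height, width),
    renormalised to [0, 1]."""
    from PIL import Image

    x = np.asarray(x)
    h, w = size
    if x.shape[1:] == (h, w):
        return normalize_image(x.reshape(-1, h * w)).reshape(x.shape)
    out = np.empty((x.shape[0], h, w))
    for i in range(x.shape[0]):
        img = normalize_image(x[i]).astype(np.float32)
        out[i] = np.asarray(Image.fromarray(img, mode="F").resize((w, h), Image.BILINEAR))
    return np.clip(out, 0.0, 1.0)


class QuanvolutionTransformer(TransformerMixin, BaseEstimator):
    """Apply the fixed quanvolution filter image-wise.

    transform maps (N, H, W) images to (N, H', W', k**2) feature stacks of
    per-qubit P(1) marginals.
    """

    def __init__(self, k: int = 2, stride: int | None = None, theta_mode: str = "arccos",
                 theta_source: str = "first", mode: str = "exact", shots: int = 1024,
                 random_state: int = 0):
        self.k = k
        self.stride = stride
        self.theta_mode = theta_mode
        self.theta_source = theta_source
        self.mode = mode
        self.shots = shots
        self.random_state = random_state

    def _config(self) -> QuantvolutionConfig:
        return QuantvolutionConfig(k=self.k, stride=self.stride, theta_mode=self.theta_mode,
                                   theta_source=self.theta_source, mode=self.mode,
                                   shots=self.shots, seed=self.random_state)

    def fit(self, X, y=None):
        X = np.asarray(X)
        if X.ndim != 3:
            raise ValueError(f"expected (N, H, W) images, got shape {X.shape}")
        self._config()  # validates
        self.n_features_in_ = X.shape[1] * X.shape[2]
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X)
        cfg = self._config()
        return np.stack([quantvolve_image(img, cfg) for img in X])


class _BaseTremorNet(ClassifierMixin, BaseEstimator):
    """Shared fit/predict machinery for both network kinds."""

    _kind = "classical"

    def _spec(self, input_shape) -> network.ModelSpec:
        raise NotImplementedError

    def _features(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X)
        resize = getattr(self, "resize", (32, 215))
        if X.ndim == 3 and resize is not None:
            X = resize_images(X, resize)
        if X.ndim == 3:
            X = normalize_image(X.reshape(X.shape[0], -1)).reshape(X.shape)[..., None]
        elif X.ndim == 4:
            X = X.astype(float)
        else:
            raise ValueError(f"expected (N, H, W) or (N, H, W, C), got {X.shape}")
        return X

    def _train_config(self) -> network.TrainConfig:
        return network.TrainConfig(epochs=self.epochs, batch_size=self.batch_size,
                                   lr0=self.lr0, end_lr=self.end_lr, power=self.power,
                                   label_noise=self.label_noise, seed=self.random_state)

    def fit(self, X, y, validation_data=None, test_data=None):
        """Fit the network.  Without explicit ``validation_data`` a seeded
        stratified fraction of (X, y) is held out for the validation metrics;
        ``test_data`` defaults to the validation split."""
        y = np.asarray(y, dtype=int)
        feats = self._features(X)
        self.classes_ = np.arange(network.N_CLASSES)
        if validation_data is None:
            strat = y if np.bincount(y, minlength=4).min() >= 2 else None
            tr, va = train_test_split(np.arange(len(y)),
                                      test_size=max(0.1, 4 / len(y)),
                                      random_state=self.random_state, stratify=strat)
            x_tr, y_tr = feats[tr], y[tr]
            x_va, y_va = feats[va], y[va]
        else:
            x_tr, y_tr = feats, y
            x_va = self._features(validation_data[0])
            y_va = np.asarray(validation_data[1], dtype=int)
        if test_data is None:
            x_te, y_te = x_va, y_va
        else:
            x_te = self._features(test_data[0])
            y_te = np.asarray(test_data[1], dtype=int)
        spec = self._spec(x_tr.shape[1:])
        self.model_ = network.build_model(spec, seed=self.random_state)
        ds = network.ArrayDataset(x_tr, y_tr, x_va, y_va, x_te, y_te)
        self.result_ = network.train(self.model_, ds, self._train_config())
        self.n_features_in_ = int(np.prod(feats.shape[1:]))
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        return self.model_.predict_proba(self._features(X))

    def predict(self, X) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)


class ClassicalCNNClassifier(_BaseTremorNet):
    """The classical baseline: two 16-filter 3x3 conv blocks, one 2x2 pool,
    dense-32, 50% dropout, dense-4 softmax."""

    _kind = "classical"

    def __init__(self, epochs: int = 100, batch_size: int = 32, lr0: float = 1e-3,
                 end_lr: float = 1e-5, power: float = 1.0, label_noise: float = 0.05,
                 dropout_conv: float = 0.2, resize: tuple[int, int] | None = (32, 215),
                 random_state: int = 0):
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr0 = lr0
        self.end_lr = end_lr
        self.power = power
        self.label_noise = label_noise
        self.dropout_conv = dropout_conv
        self.resize = resize
        self.random_state = random_state

    def _spec(self, input_shape) -> network.ModelSpec:
        return network.ModelSpec(kind="classical", input_shape=tuple(input_shape),
                                 dropout_conv=self.dropout_conv)


class HybridTremorClassifier(_BaseTremorNet):
    """The hybrid network: optional quanvolution preprocessing, a conv +
    batch-norm trunk, fc1..fc4, and either the QuantClass head (default)
    or a dense-4 softmax head (the "no QuantClass" ablation variants).

    quantvolution: None (off), 2 or 4 (the filter window size).
    head_mode 'functional' is trainable; 'literal' is the printed circuit,
    whose gradients are identically zero.
    """

    _kind = "hybrid"

    def __init__(self, quantvolution: int | None = 2, head: str = "quantclass",
                 head_mode: str = "functional", n_angles: int = 2,
                 fc_widths: tuple[int, ...] = (256, 64, 16, 2),
                 epochs: int = 100, batch_size: int = 32, lr0: float = 1e-3,
                 end_lr: float = 1e-5, power: float = 1.0, label_noise: float = 0.05,
                 dropout_conv: float = 0.2, jitter_sigma: float = 0.0,
                 head_eval: str = "exact", shots: int = 1024,
                 resize: tuple[int, int] | None = (32, 215), random_state: int = 0):
        self.quantvolution = quantvolution
        self.head = head
        self.head_mode = head_mode
        self.n_angles = n_angles
        self.fc_widths = fc_widths
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr0 = lr0
        self.end_lr = end_lr
        self.power = power
        self.label_noise = label_noise
        self.dropout_conv = dropout_conv
        self.jitter_sigma = jitter_sigma
        self.head_eval = head_eval
        self.shots = shots
        self.resize = resize
        self.random_state = random_state

    def _features(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X)
        if X.ndim == 3 and self.quantvolution in (2, 4):
            if self.resize is not None:
                X = resize_images(X, self.resize)
            tf = QuanvolutionTransformer(k=self.quantvolution,
                                         random_state=self.random_state)
            return tf.fit(X).transform(X)
        return super()._features(X)

    def _spec(self, input_shape) -> network.ModelSpec:
        return network.ModelSpec(kind="hybrid", input_shape=tuple(input_shape),
                                 dropout_conv=self.dropout_conv,
                                 fc_widths=tuple(self.fc_widths), head=self.head,
                                 head_mode=self.head_mode, n_angles=self.n_angles,
                                 jitter_sigma=self.jitter_sigma,
                                 head_eval=self.head_eval, shots=self.shots)
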