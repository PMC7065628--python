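"""The classifier ladder: eight models under one sklearn-style contract.

Every estimator implements ``fit(X, y)``, ``predict_proba`` (activation
score in column 1), ``predict`` (threshold 0.5, ties classify positive)
and ``get_params``/``set_params``; neural models additionally expose
``logits`` and, where meaningful, ``feature_layer`` (penultimate
representation) and ``input_gradient`` (for saliency maps).

The ladder, in order of capacity:

1. ``frequency`` — constant score equal to the training positive fraction.
2-4. ``lasso_pixels`` / ``lasso_scalar`` / ``lasso_cp`` — L1-regularized
   logistic regression on the three featurizations, with inverse-class-
   frequency weights.
5. ``mlp`` — one-hidden-layer fully connected network on the 6724 pixel
   vector, weighted cross-entropy, patience-10 early stopping.
6. ``lenet`` — LeNet-style CNN (two conv + two pool layers) on 82 x 82
   one-channel images.
7. ``pretrained_offshelf`` — frozen backbone; new head (average pooling +
   1024-unit hidden layer) trained on final-layer feature maps.
8. ``pretrained_finetune`` — trailing ``n_finetune`` backbone modules plus
   the output layer are trained from their initialized weights; earlier
   modules stay frozen, with bottleneck activations cached at the boundary.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression

from .backbone import BackboneSpec, BottleneckCache, MiniBackbone
from .nn import (Conv2D, Dense, Flatten, GlobalAvgPool, MaxPool2D, ReLU,
                 Sequential, TrainingConfig)
from .nn.network import softmax

__all__ = [
    "MODEL_KINDS",
    "class_weights",
    "FrequencyClassifier",
    "LassoLogisticClassifier",
    "PixelMLPClassifier",
    "LeNetClassifier",
    "OffShelfHeadClassifier",
    "FineTuneClassifier",
    "make_model",
]

MODEL_KINDS = ("frequency", "lasso_pixels", "lasso_scalar", "lasso_cp",
               "mlp", "lenet", "pretrained_offshelf", "pretrained_finetune")


def class_weights(y: np.ndarray) -> np.ndarray:
    """Inverse-class-frequency weights w_c = N / (2 N_c), mean-normalized
    over the two classes."""
    y = np.asarray(y)
    n = len(y)
    counts = np.array([(y == 0).sum(), (y == 1).sum()], dtype=float)
    if (counts == 0).any():
        # single-class training set: unweighted
        return np.ones(2)
    return n / (2.0 * counts)


class _ScoreMixin:
    """Shared prediction surface: threshold 0.5, ties positive."""

    classes_ = np.array([0, 1])

    def score01(self, X) -> np.ndarray:
        return self.predict_proba(X)[:, 1]

    def predict(self, X) -> np.ndarray:
        return (self.score01(X) >= 0.5).astype(int)


class FrequencyClassifier(_ScoreMixin, ClassifierMixin, BaseEstimator):
    """Constant-score baseline: the positive fraction of the training set.

    Permutation-invariant in its inputs and independent of X entirely.
    """

    def fit(self, X, y):
        y = np.asarray(y)
        if len(y) == 0:
            raise ValueError("frequency classifier needs >= 1 training label")
        self.rate_ = float((y == 1).mean())
        return self

    def predict_proba(self, X) -> np.ndarray:
        n = len(X)
        p = np.full(n, self.rate_)
        return np.column_stack([1.0 - p, p])


class LassoLogisticClassifier(_ScoreMixin, ClassifierMixin, BaseEstimator):
    """L1-penalized weighted logistic regression on a feature matrix.

    ``lambda_`` is the regularization strength (sklearn C = 1 / lambda_).
    Exposes the nonzero-coefficient count and per-feature odds ratios,
    both raw (exp(beta)) and adjusted to one SD of each feature
    (exp(beta * sd)) for cross-feature comparison.
    """

    def __init__(self, lambda_: float = 1.0, class_weighting: bool = True,
                 seed: int = 0, max_iter: int = 300):
        self.lambda_ = lambda_
        self.class_weighting = class_weighting
        self.seed = seed
        self.max_iter = max_iter

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if not np.isfinite(X).all():
            raise ValueError("non-finite feature values")
        if self.lambda_ < 0:
            raise ValueError("lambda_ must be >= 0")
        # standardize internally: the penalty then acts uniformly across
        # features of very different magnitudes (pixel counts vs texture
        # statistics) and the solver converges orders of magnitude faster;
        # coefficients are mapped back to the original feature scale below
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        self.scale_ = np.where(sd > 0, sd, 1.0)
        Xs = (X - self.mean_) / self.scale_
        C = 1e12 if self.lambda_ == 0 else 1.0 / self.lambda_
        w = class_weights(y) if self.class_weighting else np.ones(2)
        import sklearn
        l1_kw = ({"l1_ratio": 1.0}
                 if tuple(map(int, sklearn.__version__.split(".")[:2])) >= (1, 8)
                 else {"penalty": "l1"})
        # saga: true L1 subgradient solver with an unpenalized intercept;
        # far faster than coordinate descent when the signal is weak
        self._lr = LogisticRegression(
            solver="saga", C=C,
            class_weight={0: w[0], 1: w[1]},
            max_iter=self.max_iter,
            random_state=self.seed, **l1_kw)
        import warnings as _warnings
        with _warnings.catch_warnings():
            from sklearn.exceptions import ConvergenceWarning
            _warnings.simplefilter("ignore", ConvergenceWarning)
            self._lr.fit(Xs, y)
        coef_std = self._lr.coef_[0]
        self.coef_ = coef_std / self.scale_
        self.intercept_ = float(self._lr.intercept_[0]
                                - (coef_std * self.mean_ / self.scale_).sum())
        self.n_nonzero_ = int(np.count_nonzero(self.coef_))
        self.odds_ratios_ = np.exp(self.coef_)
        # odds ratio per one-SD increment of each feature
        self.sd_adjusted_odds_ratios_ = np.exp(coef_std)
        return self

    def predict_proba(self, X) -> np.ndarray:
        Xs = (np.asarray(X, dtype=float) - self.mean_) / self.scale_
        return self._lr.predict_proba(Xs)

    def logits(self, X) -> np.ndarray:
        """Two-class logits (0, z) with z the linear decision value."""
        z = np.asarray(X, dtype=float) @ self.coef_ + self.intercept_
        return np.column_stack([np.zeros_like(z), z])

    def input_gradient(self, x: np.ndarray, target_class: int = 1,
                       guided: bool = False) -> np.ndarray:
        """Gradient of the class score (linear logit) w.r.t. the input:
        the weight vector itself, reshaped to the input."""
        x = np.asarray(x, dtype=float)
        g = self.coef_ if target_class == 1 else -self.coef_
        return g.reshape(x.shape).astype(float)


class _NeuralBase(_ScoreMixin, ClassifierMixin, BaseEstimator):
    """Common fit/predict plumbing for the NumPy neural models."""

    net_: Sequential

    def _training_config(self) -> TrainingConfig:
        return TrainingConfig(
            learning_rate=self.learning_rate, batch_size=self.batch_size,
            max_epochs=self.max_epochs, patience=self.patience,
            seed=self.seed)

    def _fit_net(self, X, y, early_stop, require_early_stop=True):
        if early_stop is None:
            if require_early_stop:
                raise ValueError(
                    "this model requires an early-stopping set: pass "
                    "early_stop=(X_early, y_early)")
            early_stop = (X, y)
        Xe, ye = early_stop
        w = (class_weights(y) if self.class_weighting else np.ones(2))
        self.history_ = self.net_.fit(
            X, np.asarray(y), np.asarray(Xe), np.asarray(ye), w,
            self._training_config())
        return self

    def logits(self, X) -> np.ndarray:
        return self.net_.predict_logits(self._prep(X))

    def predict_proba(self, X) -> np.ndarray:
        return softmax(self.logits(X))

    #: raw-input units per prepped unit (chain-rule factor for gradients
    #: reported on the caller's pixel scale)
    _input_scale = 1.0

    def input_gradient(self, x, target_class: int = 1,
                       guided: bool = False) -> np.ndarray:
        xb = self._prep(np.asarray(x)[None] if self._is_single(x) else x)
        g = self.net_.input_gradient(xb, target_class, guided=guided)
        g = g / self._input_scale
        return g[0] if self._is_single(x) else g

    def _is_single(self, x) -> bool:
        return np.asarray(x).ndim == self._single_ndim

    def _prep(self, X):  # pragma: no cover - overridden
        return np.asarray(X, dtype=float)


class PixelMLPClassifier(_NeuralBase):
    """One-hidden-layer fully connected network on 6724 pixel vectors."""

    _single_ndim = 1
    _input_scale = 255.0

    def __init__(self, hidden_units: int = 64, learning_rate: float = 1e-2,
                 batch_size: int = 32, max_epochs: int = 200,
                 patience: int = 10, class_weighting: bool = True,
                 seed: int = 0):
        self.hidden_units = hidden_units
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.class_weighting = class_weighting
        self.seed = seed

    def _prep(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape[-1] != 6724:
            raise ValueError("MLP expects 6724-long pixel vectors")
        return X / 255.0

    def fit(self, X, y, early_stop=None):
        rng = np.random.default_rng(self.seed)
        self.net_ = Sequential([
            Dense(6724, self.hidden_units, rng), ReLU(),
            Dense(self.hidden_units, 2, rng)])
        es = None if early_stop is None else (
            self._prep(early_stop[0]), early_stop[1])
        return self._fit_net(self._prep(X), y, es)


class LeNetClassifier(_NeuralBase):
    """LeNet-style CNN for 82 x 82 single-channel images.

    Two 5x5 convolutions (6 and 16 filters, the original layer widths)
    each followed by 2x2 pooling, then 120- and 84-unit dense layers."""

    _single_ndim = 2
    _input_scale = 255.0
    INPUT_SIDE = 82

    def __init__(self, learning_rate: float = 1e-2, batch_size: int = 32,
                 max_epochs: int = 100, patience: int = 10,
                 class_weighting: bool = True, seed: int = 0):
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.class_weighting = class_weighting
        self.seed = seed

    def _prep(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[None]
        if X.ndim == 3:
            X = X[:, None, :, :]
        if X.shape[1:] != (1, self.INPUT_SIDE, self.INPUT_SIDE):
            raise ValueError(
                f"LeNet expects {self.INPUT_SIDE}x{self.INPUT_SIDE} "
                f"one-channel images, got {X.shape[1:]}")
        return X / 255.0

    def fit(self, X, y, early_stop=None):
        rng = np.random.default_rng(self.seed)
        side = self.INPUT_SIDE
        s1 = (side - 4) // 2          # after conv5 + pool2
        s2 = (s1 - 4) // 2            # after conv5 + pool2
        self.net_ = Sequential([
            Conv2D(1, 6, 5, rng), ReLU(), MaxPool2D(2),
            Conv2D(6, 16, 5, rng), ReLU(), MaxPool2D(2),
            Flatten(), Dense(16 * s2 * s2, 120, rng), ReLU(),
            Dense(120, 84, rng), ReLU(), Dense(84, 2, rng)])
        es = None if early_stop is None else (
            self._prep(early_stop[0]), early_stop[1])
        return self._fit_net(self._prep(X), y, es)

    def feature_layer(self, X) -> np.ndarray:
        """Penultimate (84-unit) representation."""
        return self.net_.forward_upto(self._prep(X), len(self.net_.layers) - 1)


class OffShelfHeadClassifier(_NeuralBase):
    """Frozen backbone + new head (average pooling, 1024-unit hidden layer).

    ``fit`` consumes final-layer backbone feature maps produced with the
    fully frozen backbone (``boundary == n_modules``); passing activations
    from a partially unfrozen run is an error.  Backbone weights are never
    touched — only the head trains.
    """

    _single_ndim = 3

    def __init__(self, backbone: MiniBackbone | None = None,
                 hidden_units: int = 1024, learning_rate: float = 1e-2,
                 batch_size: int = 32, max_epochs: int = 200,
                 patience: int = 10, class_weighting: bool = True,
                 seed: int = 0):
        self.backbone = backbone
        self.hidden_units = hidden_units
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.class_weighting = class_weighting
        self.seed = seed

    def _prep(self, F):
        F = np.asarray(F, dtype=float)
        if F.ndim != 4:
            raise ValueError("expected final-layer feature maps (n,c,h,w)")
        return F

    def fit(self, F, y, early_stop=None, boundary: int | None = None):
        bb = self.backbone or MiniBackbone()
        self.backbone = bb
        if boundary is not None and boundary != bb.n_modules:
            raise ValueError(
                "off-the-shelf head requires features from the fully "
                f"frozen backbone (boundary {bb.n_modules}), got {boundary}")
        F = self._prep(F)
        if F.shape[1] != bb.feature_dim:
            raise ValueError(
                f"feature maps have {F.shape[1]} channels, backbone "
                f"produces {bb.feature_dim}")
        rng = np.random.default_rng(self.seed)
        self.net_ = Sequential([
            GlobalAvgPool(),
            Dense(bb.feature_dim, self.hidden_units, rng), ReLU(),
            Dense(self.hidden_units, 2, rng)])
        es = None if early_stop is None else (
            self._prep(early_stop[0]), early_stop[1])
        return self._fit_net(F, y, es)

    def head_parameter_count(self) -> int:
        return sum(p.size for p in self.net_.parameters())

    def feature_layer(self, F) -> np.ndarray:
        """Penultimate (hidden-layer) representation."""
        return self.net_.forward_upto(self._prep(F), len(self.net_.layers) - 1)


class FineTuneClassifier(_NeuralBase):
    """Partial fine-tuning: train the trailing ``n_finetune`` backbone
    modules plus the output layer; earlier modules stay frozen.

    The frozen prefix is evaluated once through a :class:`BottleneckCache`;
    training then runs only on the unfrozen suffix, which is initialized
    with the backbone's existing ("pretrained") weights.  No new layers are
    added beyond the binary output layer.
    """

    _single_ndim = 3

    def __init__(self, backbone: MiniBackbone | None = None,
                 n_finetune: int = 1, learning_rate: float = 1e-3,
                 batch_size: int = 32, max_epochs: int = 100,
                 patience: int = 10, class_weighting: bool = True,
                 seed: int = 0, cache: BottleneckCache | None = None):
        self.backbone = backbone
        self.n_finetune = n_finetune
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.class_weighting = class_weighting
        self.seed = seed
        self.cache = cache

    def _prep(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim != 4:
            raise ValueError("expected prepared images (n, 3, side, side)")
        return X

    def fit(self, X, y, early_stop=None, cache_key: str = "train"):
        import copy

        bb = self.backbone or MiniBackbone()
        self.backbone = bb
        if not 1 <= self.n_finetune <= bb.n_modules:
            raise ValueError(
                f"n_finetune must be in [1, {bb.n_modules}], "
                f"got {self.n_finetune}")
        self.boundary_ = bb.n_modules - self.n_finetune
        cache = self.cache or BottleneckCache()
        self.cache = cache
        X = self._prep(X)
        B = cache.extract(bb, X, self.boundary_, key=cache_key)

        # fine-tune a private copy initialized with the pretrained weights;
        # the shared backbone object stays pristine for other folds/models
        self.backbone_ = copy.deepcopy(bb)
        rng = np.random.default_rng(self.seed)
        suffix = self.backbone_.module_layers(self.boundary_)
        self.net_ = Sequential(
            list(suffix) + [GlobalAvgPool(),
                            Dense(bb.feature_dim, 2, rng)])
        if early_stop is None:
            es = None
        else:
            Be = cache.extract(bb, self._prep(early_stop[0]),
                               self.boundary_, key=cache_key + "_early")
            es = (Be, early_stop[1])
        return self._fit_net(B, y, es)

    def logits(self, X) -> np.ndarray:
        B = self.backbone_.forward_modules(self._prep(X), 0, self.boundary_)
        return self.net_.predict_logits(B)

    def feature_layer(self, X) -> np.ndarray:
        """Pooled representation right before the output layer."""
        B = self.backbone_.forward_modules(self._prep(X), 0, self.boundary_)
        return self.net_.forward_upto(B, len(self.net_.layers) - 1)

    def input_gradient(self, x, target_class: int = 1,
                       guided: bool = False) -> np.ndarray:
        """Gradient of the class logit through the full network (frozen
        prefix included) back to the input image."""
        single = np.asarray(x).ndim == 3
        xb = self._prep(np.asarray(x)[None] if single else x)
        full = Sequential(self.backbone_.module_layers(0, self.boundary_)
                          + self.net_.layers)
        g = full.input_gradient(xb, target_class, guided=guided)
        return g[0] if single else g


def make_model(model_kind: str, config: dict | None = None):
    """Factory mapping a model kind plus a config dict to an estimator."""
    config = dict(config or {})
    if model_kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {model_kind!r}")
    if model_kind == "frequency":
        return FrequencyClassifier()
    if model_kind in ("lasso_pixels", "lasso_scalar", "lasso_cp"):
        return LassoLogisticClassifier(**config)
    if model_kind == "mlp":
        return PixelMLPClassifier(**config)
    if model_kind == "lenet":
        return LeNetClassifier(**config)
    if model_kind == "pretrained_offshelf":
        return OffShelfHeadClassifier(**config)
    return FineTuneClassifier(**config)
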