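"""Post-hoc model interpretation.

Three tools: temperature scaling of logits for confidence calibration
(a single scalar T > 0 fitted by negative log-likelihood on a validation
set; T = 1 is the identity), 2-D embeddings (UMAP or t-SNE) of learned or
raw feature representations for visual inspection of class separation,
and saliency maps — the gradient of the output class score with respect
to the input image, computed by standard backpropagation or by guided
backpropagation (negative upstream gradients zeroed at every rectifier).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .nn.network import softmax

__all__ = [
    "CalibrationModel",
    "Embedding2D",
    "SaliencyMap",
    "fit_temperature",
    "calibrate",
    "embed_features",
    "saliency_backprop",
    "saliency_guided",
]

_T_BOUNDS = (0.05, 20.0)


@dataclass(frozen=True)
class CalibrationModel:
    """A fitted softmax temperature."""

    temperature: float

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


def _as_two_column_logits(logits: np.ndarray) -> np.ndarray:
    logits = np.asarray(logits, dtype=float)
    if logits.ndim == 1:  # logit differences: pair with a zero column
        logits = np.column_stack([np.zeros_like(logits), logits])
    return logits


def fit_temperature(logits: np.ndarray, labels: np.ndarray
                    ) -> CalibrationModel:
    """Fit T minimizing the NLL of softmax(logits / T) on held-out labels.

    Accepts (n, 2) logits or a length-n vector of logit differences.
    Requires both classes present; all-equal logits leave T unidentified.
    """
    z = _as_two_column_logits(logits)
    y = np.asarray(labels, dtype=int)
    if len(y) < 2 or y.min() == y.max():
        raise ValueError(
            "temperature fitting needs >= 2 samples with both classes")
    d = z[:, 1] - z[:, 0]
    if np.allclose(d, d[0]):
        raise ValueError("degenerate logits (all equal): T is undefined")

    def nll(t: float) -> float:
        p = softmax(z / t)
        eps = 1e-12
        return float(-np.log(p[np.arange(len(y)), y] + eps).mean())

    res = minimize_scalar(nll, bounds=_T_BOUNDS, method="bounded",
                          options={"xatol": 1e-6})
    return CalibrationModel(temperature=float(res.x))


def calibrate(logits: np.ndarray, model: CalibrationModel) -> np.ndarray:
    """Temperature-scaled class probabilities softmax(logits / T).

    In the binary case this is 1 / (1 + exp(-(z1 - z0) / T)) for the
    positive class; T = 1 reproduces the raw softmax and T -> infinity
    drives every probability to 0.5.  Scaling is strictly monotone in the
    logit, so rankings (and AUC) are unchanged."""
    z = _as_two_column_logits(logits)
    return softmax(z / model.temperature)


@dataclass
class Embedding2D:
    """2-D coordinates of n cells plus overlay metadata for plotting."""

    coordinates: np.ndarray     # (n, 2)
    method: str                 # "umap" | "tsne"
    params: dict
    seed: int
    overlay: pd.DataFrame | None = None  # label/predicted/misclassified

    def __post_init__(self) -> None:
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 2:
            raise ValueError("coordinates must be (n, 2)")
        if not np.isfinite(self.coordinates).all():
            raise ValueError("non-finite embedding coordinates")


def embed_features(features: np.ndarray, method: str = "umap",
                   params: dict | None = None, seed: int = 0,
                   labels: np.ndarray | None = None,
                   predicted: np.ndarray | None = None) -> Embedding2D:
    """Project an (n, d) feature matrix to 2-D with UMAP or t-SNE.

    Defaults follow common practice for these embeddings: UMAP with
    n_neighbors 15, min_dist 0.1, euclidean metric; t-SNE with perplexity
    30.  Deterministic given the seed.  Optional labels/predictions are
    attached as an overlay table flagging misclassified cells, which plots
    typically draw with thick outlines."""
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[1] == 0:
        raise ValueError("features must be a nonempty (n, d) matrix")
    if X.shape[0] < 10:
        raise ValueError("embedding defaults need n >= 10 cells")
    params = dict(params or {})
    if method == "umap":
        import umap

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reducer = umap.UMAP(
                n_components=2,
                n_neighbors=params.get("n_neighbors", 15),
                min_dist=params.get("min_dist", 0.1),
                metric=params.get("metric", "euclidean"),
                random_state=seed)
            coords = np.asarray(reducer.fit_transform(X), dtype=float)
    elif method == "tsne":
        from sklearn.manifold import TSNE

        coords = TSNE(
            n_components=2,
            perplexity=min(params.get("perplexity", 30),
                           (X.shape[0] - 1) / 3.0),
            metric=params.get("metric", "euclidean"),
            random_state=seed, init="pca").fit_transform(X)
        coords = np.asarray(coords, dtype=float)
    else:
        raise ValueError(f"unknown embedding method {method!r}")

    overlay = None
    if labels is not None:
        overlay = pd.DataFrame({"label": np.asarray(labels)})
        if predicted is not None:
            overlay["predicted"] = np.asarray(predicted)
            overlay["misclassified"] = (
                overlay["label"] != overlay["predicted"])
    return Embedding2D(coordinates=coords, method=method, params=params,
                       seed=seed, overlay=overlay)


@dataclass
class SaliencyMap:
    """Per-pixel gradient of the class score for one input image."""

    values: np.ndarray
    method: str                 # "backprop" | "guided_backprop"
    target_class: int


def _input_grad(model, image: np.ndarray, target_class: int,
                guided: bool) -> np.ndarray:
    if not hasattr(model, "input_gradient"):
        raise TypeError(
            f"{type(model).__name__} is not differentiable with respect "
            "to its input; saliency is undefined")
    return np.asarray(
        model.input_gradient(image, target_class, guided=guided))


def _to_image_shape(grad: np.ndarray, image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if grad.shape == image.shape:
        return grad
    if grad.ndim == 3:  # channel-first multi-channel input: sum channels
        g = grad.sum(axis=0)
        if g.shape == image.shape[-2:]:
            return g
    return grad.reshape(image.shape)


def saliency_backprop(model, image: np.ndarray,
                      target_class: int = 1) -> SaliencyMap:
    """Standard-backpropagation saliency: d(class score)/d(input)."""
    grad = _input_grad(model, image, target_class, guided=False)
    return SaliencyMap(values=_to_image_shape(grad, image),
                       method="backprop", target_class=target_class)


def saliency_guided(model, image: np.ndarray,
                    target_class: int = 1) -> SaliencyMap:
    """Guided-backpropagation saliency.

    Identical to the standard gradient except that at every rectifier the
    backward pass also zeroes negative upstream gradients, so only
    positive evidence flows back to the pixels."""
    grad = _input_grad(model, image, target_class, guided=True)
    return SaliencyMap(values=_to_image_shape(grad, image),
                       method="guided_backprop", target_class=target_class)
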