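"""Post-hoc explainability: Grad-CAM for the image branch and Integrated
Gradients for the clinical branch.

Grad-CAM weights each channel of a convolutional activation map A^k by the
global average of the gradient of the class score with respect to that
channel, and rectifies the weighted sum:

    w_k = (1/Z) sum_ij d(score_c)/dA^k_ij        (Z = pixels in the map)
    L^c = ReLU(sum_k w_k A^k)

Integrated Gradients attributes the class score to each clinical input
feature by a Riemann sum over the straight-line path from a baseline x' to
the input x (the baseline defaults to the zero vector in encoded space):

    IG_i ~= (x_i - x'_i) * (1/S) sum_{s=1..S} d f(x' + (s/S)(x - x')) / dx_i

Absolute attributions are normalized to [0, 1] for the relevance ranking.
The metadata input is held fixed during the Grad-CAM backward pass and the
image is held fixed during the IG path, so each method attributes exactly
one branch.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from matplotlib import colormaps
from PIL import Image
from skimage.transform import resize

from ._tensor import Tensor
from .nn import Module
from .train_eval import MetadataOnlyNet, MultimodalNet

__all__ = [
    "GradCamMap", "AttributionVector", "gradcam_map", "integrated_gradients",
    "rank_clinical_features", "aggregate_onehot", "render_overlay",
]


@dataclass
class GradCamMap:
    heatmap: np.ndarray                # L^c at the layer's resolution, >= 0
    overlay: np.ndarray                # upsampled to input size, in [0, 1]
    channel_weights: np.ndarray        # one weight per channel
    target_class: int
    target_layer: str
    all_zero: bool = False             # flagged when ReLU kills the whole map


@dataclass
class AttributionVector:
    attributions: np.ndarray           # signed IG_i per encoded column
    relevance: np.ndarray              # |IG| normalized so max == 1
    feature_names: list[str]
    baseline: np.ndarray
    steps: int
    all_zero: bool = False

    @property
    def abs_attributions(self) -> np.ndarray:
        return np.abs(self.attributions)


def gradcam_map(model: Module, image: np.ndarray,
                metadata: np.ndarray | None, target_class: int,
                target_layer: str = "stage4") -> GradCamMap:
    """Grad-CAM heatmap for one sample.

    ``image`` is (3, S, S) in [0, 1]; ``metadata`` the encoded clinical row
    (ignored by image-only models).  The default target layer is the deepest
    convolutional stage.
    """
    if isinstance(model, MetadataOnlyNet):
        raise ValueError("Grad-CAM requires an image branch")
    model.eval()
    model.zero_grad()
    capture: dict[str, Tensor] = {}
    # the input requires a gradient so the captured activation is always in
    # the backward graph, even for parameter-free toy models
    x_img = Tensor(image[None].astype(np.float32), requires_grad=True)
    x_meta = (Tensor(np.asarray(metadata, dtype=np.float32)[None])
              if metadata is not None else None)
    scores = model(x_img, x_meta, capture=capture)
    if target_layer not in capture:
        raise ValueError(
            f"unknown target layer {target_layer!r}; available spatial "
            f"layers: {sorted(capture)}")
    act = capture[target_layer]
    if act.ndim != 4:
        raise ValueError(f"target layer {target_layer!r} is not spatial")
    scores[0, target_class].backward()
    model.zero_grad()

    a = act.data[0]                                 # (K, h, w)
    g = act.grad[0]
    weights = g.mean(axis=(1, 2))                   # alpha_k: global average
    raw = np.einsum("k,kij->ij", weights, a)
    heat = np.maximum(raw, 0.0)                     # ReLU
    all_zero = not np.any(heat > 0)

    size = image.shape[1]
    up = resize(heat, (size, size), order=1, preserve_range=True,
                anti_aliasing=False)
    rng_ = up.max() - up.min()
    overlay = (up - up.min()) / rng_ if rng_ > 0 else np.zeros_like(up)
    return GradCamMap(heatmap=heat, overlay=overlay, channel_weights=weights,
                      target_class=target_class, target_layer=target_layer,
                      all_zero=all_zero)


def render_overlay(image: np.ndarray, cam: GradCamMap, path: str | Path,
                   alpha: float = 0.45, cmap: str = "jet") -> np.ndarray:
    """Alpha-blend the heatmap over the input image and write a PNG."""
    img = np.asarray(image)
    if img.shape[0] == 3 and img.ndim == 3:
        img = img.transpose(1, 2, 0)
    colors = colormaps[cmap](cam.overlay)[..., :3]
    blended = (1 - alpha) * img + alpha * colors
    out = np.clip(np.round(blended * 255), 0, 255).astype(np.uint8)
    Image.fromarray(out).save(path)
    return out


def _score_function(model, image: np.ndarray | None, target_class: int,
                    steps: int):
    """Build g(X_meta batch) -> (B,) class-score Tensor, image held fixed."""
    if isinstance(model, MultimodalNet):
        if image is None:
            raise ValueError("a fused model needs the image input")
        model.eval()
        fx = model.image_encoder.features(
            Tensor(image[None].astype(np.float32))).data

        def g(xm: Tensor) -> Tensor:
            fx_rep = Tensor(np.repeat(fx, xm.shape[0], axis=0))
            z = model.fusion(fx_rep, model.clinical_encoder(xm))
            logits = model.fc2(model.fc1(z).relu())
            return logits[:, target_class]
        return g
    if isinstance(model, MetadataOnlyNet):
        model.eval()

        def g(xm: Tensor) -> Tensor:
            return model(None, xm)[:, target_class]
        return g
    if callable(model):
        def g(xm: Tensor) -> Tensor:
            out = model(xm)
            return out[:, target_class] if out.ndim == 2 else out
        return g
    raise TypeError(f"cannot attribute model of type {type(model)!r}")


def integrated_gradients(model, clinical_x: np.ndarray,
                         image: np.ndarray | None = None,
                         target_class: int = 0,
                         baseline: np.ndarray | None = None,
                         steps: int = 50,
                         feature_names: list[str] | None = None
                         ) -> AttributionVector:
    """Integrated Gradients over the clinical input for one sample.

    ``model`` may be a fitted network (fused or metadata-only) or any
    callable mapping a (B, d) Tensor to scores.  The Riemann sum uses the
    right-endpoint rule with ``steps`` interpolation points on the path from
    ``baseline`` (zero vector by default) to ``clinical_x``.
    """
    if steps < 1:
        raise ValueError(f"steps must be >= 1, got {steps}")
    x = np.asarray(clinical_x, dtype=np.float32).ravel()
    x0 = (np.zeros_like(x) if baseline is None
          else np.asarray(baseline, dtype=np.float32).ravel())
    if x0.shape != x.shape:
        raise ValueError("baseline and input must have the same shape")

    alphas = (np.arange(1, steps + 1, dtype=np.float32) / steps)[:, None]
    path = x0[None, :] + alphas * (x - x0)[None, :]
    xm = Tensor(path, requires_grad=True)
    g = _score_function(model, image, target_class, steps)
    scores = g(xm)
    scores.sum().backward()
    mean_grad = xm.grad.mean(axis=0)
    ig = (x - x0) * mean_grad

    absa = np.abs(ig)
    top = absa.max()
    all_zero = top == 0
    relevance = absa / top if top > 0 else np.zeros_like(absa)
    names = (feature_names if feature_names is not None
             else [f"feature_{i}" for i in range(len(x))])
    return AttributionVector(attributions=ig, relevance=relevance,
                             feature_names=list(names), baseline=x0,
                             steps=steps, all_zero=all_zero)


def aggregate_onehot(attr: AttributionVector) -> AttributionVector:
    """Aggregate encoded one-hot columns back to their original categorical
    feature by summing member columns' absolute attributions."""
    groups: dict[str, float] = {}
    order: list[str] = []
    for name, a in zip(attr.feature_names, attr.attributions):
        base = name.split("=", 1)[0]
        if base not in groups:
            groups[base] = 0.0
            order.append(base)
        groups[base] += abs(float(a))
    agg = np.array([groups[b] for b in order])
    top = agg.max()
    return AttributionVector(
        attributions=agg, relevance=agg / top if top > 0 else agg,
        feature_names=order, baseline=attr.baseline, steps=attr.steps,
        all_zero=top == 0)


def rank_clinical_features(attr: AttributionVector,
                           names: list[str] | None = None) -> pd.DataFrame:
    """Relevance table sorted by descending importance (ties by name).

    The top feature has relative importance 1.00 whenever any attribution is
    nonzero.
    """
    names = list(names) if names is not None else attr.feature_names
    if len(names) != len(attr.relevance):
        raise ValueError(
            f"{len(names)} names for {len(attr.relevance)} attributions")
    df = pd.DataFrame({"feature": names, "relative_importance": attr.relevance})
    df = df.sort_values(["relative_importance", "feature"],
                        ascending=[False, True], kind="stable")
    return df.reset_index(drop=True)
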