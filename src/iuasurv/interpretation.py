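"""Grad-CAM heatmaps for the scalar conception-hazard output.

Gradient-weighted class activation mapping localizes the image regions that
drive the model's log-hazard.  Because the output is a conception hazard
while clinicians read the maps as subfertility risk, the default sign
negates the output before backpropagation so that hot (red) regions mark
risk factors for subfertility (adhesion tissue); the raw-hazard direction
is available via ``sign="hazard"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from PIL import Image

from .imaging_model import DeepSurvModel

__all__ = ["Heatmap", "grad_cam", "overlay"]


@dataclass
class Heatmap:
    """Normalized relevance map at input resolution."""

    values: np.ndarray  # in [0, 1], shape = input H x W
    source_layer: str
    sign: str  # "hazard" or "risk-of-subfertility"


def _bilinear_upsample(arr: np.ndarray, size: tuple) -> np.ndarray:
    img = Image.fromarray(arr.astype(np.float32), mode="F")
    return np.asarray(img.resize((size[1], size[0]), Image.BILINEAR), dtype=float)


def grad_cam(
    model: DeepSurvModel,
    image: np.ndarray,
    target_layer: int | None = None,
    sign: str = "risk-of-subfertility",
) -> Heatmap:
    """Compute a Grad-CAM heatmap for one preprocessed image.

    ``target_layer`` is an index into the model's convolutional layers
    (default: the last one).  Channel weights are the spatial means of the
    output gradient at that layer; the weighted activation sum is rectified,
    max-normalized to [0, 1] and bilinearly upsampled to the input size.
    A model with zero gradient everywhere yields an all-zero map (with a
    warning), never NaNs.
    """
    if sign not in ("hazard", "risk-of-subfertility"):
        raise ValueError("sign must be 'hazard' or 'risk-of-subfertility'")
    if not model.conv_layer_indices:
        raise ValueError("model has no convolutional layers for Grad-CAM")
    conv_pos = (
        model.conv_layer_indices[-1]
        if target_layer is None
        else model.conv_layer_indices[target_layer]
    )
    x = image[None] if image.ndim == 3 else image
    h_in, w_in = x.shape[1], x.shape[2]

    net = model.net
    net.zero_grad()
    net.forward(x, train=False, keep_activations=True)
    acts = net.activations[conv_pos]  # (1, h, w, c)
    dout = np.ones((1, 1)) if sign == "hazard" else -np.ones((1, 1))
    grad = net.backward(dout, stop_at=conv_pos)  # d(output)/d(acts)
    net.zero_grad()

    weights = grad[0].mean(axis=(0, 1))  # (c,)
    cam = np.maximum((acts[0] * weights).sum(axis=-1), 0.0)
    peak = cam.max()
    if peak <= 0:
        if np.all(grad == 0):
            warnings.warn("zero gradient everywhere; returning all-zero heatmap")
        cam = np.zeros_like(cam)
    else:
        cam = cam / peak
    values = np.clip(_bilinear_upsample(cam, (h_in, w_in)), 0.0, 1.0)
    return Heatmap(values=values, source_layer=f"conv[{conv_pos}]", sign=sign)


def overlay(heatmap: Heatmap, image: np.ndarray, alpha: float = 0.4) -> np.ndarray:
    """Alpha-blend a red-hot colormapped heatmap over an RGB image.

    ``image`` is uint8 RGB or float in [0, 1]; returns uint8 RGB.
    ``alpha=0`` returns the original image, ``alpha=1`` the pure colormap.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    img = np.asarray(image)
    if img.dtype == np.uint8:
        base = img.astype(float) / 255.0
    else:
        base = np.clip(img, 0.0, 1.0)
    if base.shape[:2] != heatmap.values.shape:
        raise ValueError(
            f"dimension mismatch: image {base.shape[:2]} vs heatmap "
            f"{heatmap.values.shape}"
        )
    from matplotlib import cm

    colored = cm.jet(heatmap.values)[..., :3]
    out = (1.0 - alpha) * base + alpha * colored
    return (np.clip(out, 0.0, 1.0) * 255).astype(np.uint8)
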