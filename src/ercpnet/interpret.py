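"""Gradient-weighted class activation mapping (Grad-CAM).

The gradient of a chosen class's pre-softmax score with respect to a named
stage output is spatially averaged into per-channel weights; the rectified,
weighted channel sum is upsampled to the input grid and min-max normalized.
Gradients are taken on the logit, so the map is invariant to adding a
constant to all class scores.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .autodiff import Tensor
from .network import Network

__all__ = ["grad_cam", "overlay_heatmap"]


def grad_cam(net: Network, image: np.ndarray, target_class: int,
             layer_name: str | None = None) -> np.ndarray:
    """Heatmap in [0, 1] on the input image grid for one image (3, H, W).

    layer_name defaults to the last attention stage (or the last stage output
    the variant provides).  A constant pre-normalization map yields all zeros.
    """
    if image.ndim != 3:
        raise ValueError("grad_cam expects a single (3, H, W) image")
    if not (0 <= target_class < net.num_classes):
        raise ValueError(f"target_class must lie in [0, {net.num_classes})")
    was_training = net.training
    net.eval()
    record: dict = {}
    logits = net.forward_logits(Tensor(image[None]), record=record)
    valid = [k for k in record if k not in ("input", "gap", "fc")]
    if layer_name is None:
        attn = [k for k in valid if k.startswith("attn_")]
        layer_name = attn[-1] if attn else valid[-1]
    if layer_name not in valid:
        raise ValueError(f"unknown layer {layer_name!r}; valid layers: {valid}")
    activation = record[layer_name]
    logits.backward(_one_hot_grad(logits.shape, target_class))
    if was_training:
        net.train()
    act = activation.data[0]                    # (C, h, w)
    grad = activation.grad[0]
    weights = grad.mean(axis=(1, 2))            # per-channel importance
    cam = np.maximum((weights[:, None, None] * act).sum(axis=0), 0.0)
    zoom = (image.shape[1] / cam.shape[0], image.shape[2] / cam.shape[1])
    cam = ndimage.zoom(cam, zoom, order=1)
    lo, hi = cam.min(), cam.max()
    if hi - lo < 1e-12:
        return np.zeros_like(cam)
    return (cam - lo) / (hi - lo)


def _one_hot_grad(shape: tuple, target_class: int) -> np.ndarray:
    g = np.zeros(shape)
    g[:, target_class] = 1.0
    return g


def overlay_heatmap(image: np.ndarray, heatmap: np.ndarray,
                    alpha: float = 0.5) -> np.ndarray:
    """Blend a red-channel rendering of the heatmap onto the image (3, H, W)."""
    colored = np.zeros_like(image)
    colored[0] = heatmap
    colored[2] = 1.0 - heatmap
    return np.clip((1 - alpha) * image + alpha * colored, 0, 1)
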