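"""Model introspection: guided backprop, Grad-CAM and occlusion maps.

Guided backpropagation yields a pixel-space gradient of one task logit
with rectifier backward passes masked so only positive gradients flow
through positively activated units.  Grad-CAM weighs the last
convolutional layer's feature maps by the spatial mean of the task
logit's gradient, rectifies the weighted sum and upsamples it to input
resolution.  Their pointwise product is the guided Grad-CAM saliency
map.  Occlusion maps slide a pure-white patch over the tile and record
the task confidence of every occluded variant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from .model import TASKS, TileClassifier, predict_batch

__all__ = [
    "SaliencyMap",
    "OcclusionMap",
    "guided_backprop",
    "grad_cam",
    "guided_grad_cam",
    "occlusion_map",
]


@dataclass
class SaliencyMap:
    values: np.ndarray  # (H, W) nonnegative relevance
    task: str

    def __post_init__(self):
        if np.asarray(self.values).min() < 0:
            raise ValueError("saliency must be nonnegative")


@dataclass
class OcclusionMap:
    values: np.ndarray  # (rows, cols) confidences in [0, 1]
    patch_px: int = 16
    stride_px: int = 1
    task: str = "cored"


def _task_index(task) -> int:
    if isinstance(task, str):
        return TASKS.index(task)
    task = int(task)
    if not 0 <= task < len(TASKS):
        raise ValueError(f"task index out of range: {task}")
    return task


def _forward_collect(model: TileClassifier, x: np.ndarray, collect: int | None = None):
    """Forward pass in eval mode, optionally keeping one layer's output."""
    kept = None
    for i, layer in enumerate(model.net.layers):
        x = layer.forward(x, train=False)
        if i == collect:
            kept = x.copy()
    return x, kept


def _seed_grad(logits: np.ndarray, k: int) -> np.ndarray:
    d = np.zeros_like(logits)
    d[:, k] = 1.0
    return d


def guided_backprop(model: TileClassifier, tile: np.ndarray, task) -> np.ndarray:
    """Signed gradient of the task logit w.r.t. input pixels, guided
    rectifier rule; returns (H, W, 3)."""
    k = _task_index(task)
    x = model.scale_input(tile)
    logits, _ = _forward_collect(model, x)
    dx = model.net.backward(_seed_grad(logits, k), guided=True)
    return dx[0]


def grad_cam(model: TileClassifier, tile: np.ndarray, task) -> np.ndarray:
    """Rectified, gradient-weighted sum of last-conv feature maps,
    bilinearly upsampled to the input size; nonnegative (H, W)."""
    k = _task_index(task)
    x = model.scale_input(tile)
    target = model.last_conv_index  # rectifier after the final convolution
    logits, acts = _forward_collect(model, x, collect=target)
    d_act = model.net.backward(_seed_grad(logits, k), upto=target + 1)
    weights = d_act[0].mean(axis=(0, 1))  # per-channel spatial average
    cam = acts[0] @ weights
    cam = np.maximum(cam, 0.0)
    side = model.config.input_px
    return resize(cam, (side, side), order=1, mode="edge", anti_aliasing=False)


def guided_grad_cam(model: TileClassifier, tile: np.ndarray, task,
                    per_channel: bool = False) -> SaliencyMap:
    """Pointwise product of guided backprop and Grad-CAM.

    The guided map is rectified and summed over RGB before the product
    (matching single-channel saliency renderings); ``per_channel``
    keeps the three channels, returning (H, W, 3).
    """
    k = _task_index(task)
    gbp = np.maximum(guided_backprop(model, tile, k), 0.0)
    cam = grad_cam(model, tile, k)
    if per_channel:
        values = gbp * cam[..., None]
    else:
        values = gbp.sum(axis=2) * cam
    return SaliencyMap(values, TASKS[k])


def occlusion_map(model: TileClassifier, tile: np.ndarray, task,
                  patch_px: int = 16, stride_px: int = 1,
                  batch: int = 64) -> OcclusionMap:
    """Task confidence after occluding each patch position with pure
    white (255) in raw input space; lattice (i, j) covers the patch with
    top-left (i * stride, j * stride).  Batched, but bit-identical to
    occluding and predicting one position at a time."""
    k = _task_index(task)
    tile = np.asarray(tile)
    h, w = tile.shape[:2]
    if patch_px > min(h, w):
        raise ValueError("patch larger than tile")
    rows = (h - patch_px) // stride_px + 1
    cols = (w - patch_px) // stride_px + 1
    positions = [(i * stride_px, j * stride_px) for i in range(rows) for j in range(cols)]
    values = np.empty(len(positions), dtype=np.float32)
    for start in range(0, len(positions), batch):
        chunk = positions[start:start + batch]
        stack = np.repeat(tile[None], len(chunk), axis=0)
        for b, (y, x) in enumerate(chunk):
            stack[b, y:y + patch_px, x:x + patch_px] = 255
        values[start:start + batch] = predict_batch(model, stack)[:, k]
    return OcclusionMap(values.reshape(rows, cols), patch_px, stride_px, TASKS[k])
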