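"""Sliding-window prediction confidence heatmaps and expert-agreement maps.

A trained tile classifier is slid across a slide region; every fully
contained 256 px window contributes one lattice cell of per-task
confidences.  Maps for display are bottom-capped (only confidences at or
above a floor are shown).  Agreement maps compare the thresholded
confidence lattice, upsampled to pixel resolution, against expert
bounding boxes, partitioning the region into TP / FP / TN / FN pixels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import map_coordinates

from .model import TileClassifier, predict_batch

__all__ = [
    "HeatmapGrid",
    "AgreementMap",
    "TN", "FP", "FN", "TP",
    "sliding_window_map",
    "cap_heatmap",
    "agreement_map",
    "save_heatmap",
    "load_heatmap",
    "render_heatmap",
]

TN, FP, FN, TP = 0, 1, 2, 3


@dataclass
class HeatmapGrid:
    values: np.ndarray  # (rows, cols, 3) float32 confidences
    window_px: int = 256
    stride_px: int = 16
    origin: tuple = (0, 0)
    slide_id: str = ""

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.ndim != 3 or v.shape[2] != 3:
            raise ValueError("values must be rows x cols x 3")
        if v.size and (v.min() < 0 or v.max() > 1):
            raise ValueError("confidences must lie in [0, 1]")

    @classmethod
    def expected_shape(cls, h: int, w: int, window_px: int, stride_px: int) -> tuple:
        return ((h - window_px) // stride_px + 1, (w - window_px) // stride_px + 1)


@dataclass
class AgreementMap:
    categories: np.ndarray  # (H, W) uint8 of TN/FP/FN/TP codes
    threshold: float = 0.90


def sliding_window_map(model: TileClassifier, region: np.ndarray,
                       stride_px: int = 16, batch: int = 64,
                       slide_id: str = "", origin: tuple = (0, 0)) -> HeatmapGrid:
    """Confidence lattice over all fully contained windows.

    Cell (i, j) equals ``predict`` on the window whose top-left corner is
    (i * stride, j * stride).  Evaluation is batched but bit-identical to
    the per-window loop (the network evaluates samples independently).
    """
    region = np.asarray(region)
    window = model.config.input_px
    h, w = region.shape[:2]
    if h < window or w < window:
        raise ValueError(f"region must be at least {window} px in both dimensions")
    rows, cols = HeatmapGrid.expected_shape(h, w, window, stride_px)
    positions = [(i * stride_px, j * stride_px) for i in range(rows) for j in range(cols)]
    values = np.empty((rows * cols, 3), dtype=np.float32)
    buf = np.empty((batch, window, window, 3), dtype=region.dtype)
    for start in range(0, len(positions), batch):
        chunk = positions[start:start + batch]
        for b, (y, x) in enumerate(chunk):
            buf[b] = region[y:y + window, x:x + window]
        values[start:start + batch] = predict_batch(model, buf[:len(chunk)])
    return HeatmapGrid(values.reshape(rows, cols, 3), window, stride_px,
                       origin, slide_id)


def cap_heatmap(grid: HeatmapGrid, floor: float = 0.8) -> np.ma.MaskedArray:
    """Mask out cells below the display floor; cells >= floor unchanged."""
    if not (0.0 <= floor <= 1.0):
        raise ValueError("floor must lie in [0, 1]")
    v = np.asarray(grid.values)
    return np.ma.masked_array(v, mask=v < floor)


def _upsample(grid: HeatmapGrid, task: int, shape: tuple, mode: str) -> np.ndarray:
    v = np.asarray(grid.values)[:, :, task].astype(np.float64)
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]].astype(np.float64)
    half = (grid.window_px - 1) / 2.0
    iy = (yy - grid.origin[0] - half) / grid.stride_px
    ix = (xx - grid.origin[1] - half) / grid.stride_px
    if mode == "nearest":
        iy = np.clip(np.rint(iy), 0, v.shape[0] - 1)
        ix = np.clip(np.rint(ix), 0, v.shape[1] - 1)
        return v[iy.astype(int), ix.astype(int)]
    if mode == "bilinear":
        return map_coordinates(v, [np.clip(iy, 0, v.shape[0] - 1),
                                   np.clip(ix, 0, v.shape[1] - 1)], order=1)
    raise ValueError("mode must be 'nearest' or 'bilinear'")


def agreement_map(grid: HeatmapGrid, truth_boxes, region_shape: tuple,
                  task: int = 0, threshold: float = 0.90,
                  mode: str = "nearest") -> AgreementMap:
    """Per-pixel TP/FP/TN/FN partition of a region.

    Each pixel takes the confidence of the nearest window center
    (bilinear interpolation optional), is called positive when that
    value is >= threshold, and is compared against membership in any
    ground-truth box (half-open pixel boxes).
    """
    h, w = region_shape[:2]
    in_box = np.zeros((h, w), dtype=bool)
    for (y0, x0, y1, x1) in truth_boxes:
        if y0 < 0 or x0 < 0 or y1 > h or x1 > w:
            raise ValueError(f"box {(y0, x0, y1, x1)} outside region {region_shape}")
        in_box[y0:y1, x0:x1] = True
    conf = _upsample(grid, task, (h, w), mode)
    pred = conf >= threshold
    cats = np.empty((h, w), dtype=np.uint8)
    cats[~pred & ~in_box] = TN
    cats[pred & ~in_box] = FP
    cats[~pred & in_box] = FN
    cats[pred & in_box] = TP
    return AgreementMap(cats, threshold)


# ---------------------------------------------------------------------------
# serialization / rendering (presentation only)

def save_heatmap(grid: HeatmapGrid, prefix: str | Path):
    prefix = Path(prefix)
    from .model import TASKS
    for k, task in enumerate(TASKS):
        np.save(f"{prefix}_{task}.npy", np.asarray(grid.values[:, :, k], dtype=np.float32))
    sidecar = {"window_px": grid.window_px, "stride_px": grid.stride_px,
               "origin": list(grid.origin), "slide_id": grid.slide_id,
               "tasks": list(TASKS)}
    Path(f"{prefix}.json").write_text(json.dumps(sidecar, indent=2))


def load_heatmap(prefix: str | Path) -> HeatmapGrid:
    prefix = Path(prefix)
    from .model import TASKS
    meta = json.loads(Path(f"{prefix}.json").read_text())
    values = np.stack([np.load(f"{prefix}_{task}.npy") for task in TASKS], axis=-1)
    return HeatmapGrid(values, meta["window_px"], meta["stride_px"],
                       tuple(meta["origin"]), meta["slide_id"])


def render_heatmap(grid: HeatmapGrid, path: str | Path, floor: float = 0.8):
    """Write a three-panel PNG (one per task), yellow high / purple low."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from .model import TASKS
    capped = cap_heatmap(grid, floor)
    fig, axes = plt.subplots(1, 3, figsize=(12, 4))
    for k, (ax, task) in enumerate(zip(axes, TASKS)):
        im = ax.imshow(capped[:, :, k], cmap="viridis", vmin=floor, vmax=1.0)
        ax.set_title(task)
        ax.axis("off")
        fig.colorbar(im, ax=ax, shrink=0.7)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
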