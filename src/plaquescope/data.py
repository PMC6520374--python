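"""File-backed annotation store, slide-stratified splitting, class
balancing and tile augmentation.

Annotations are multi-label: one 256 px tile (128 um at 0.5 mpp) can
hold more than one pathology, so a record carries an arbitrary subset of
{cored, diffuse, caa}.  A record flagged ``negative`` has no stained
object at all and must carry an empty label set.  ``not_sure`` and
``flagged`` mark annotator uncertainty or segmentation failures; those
records stay in the store but are excluded from training and evaluation.

Splitting is by slide: a tile inherits its slide's split, so training
and validation never share a slide (the leakage guard downstream models
rely on).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.transform import warp

LABELS = ("cored", "diffuse", "caa")
SPLITS = ("train", "validation", "test")

__all__ = [
    "LABELS",
    "SPLITS",
    "AnnotationRecord",
    "SplitAssignment",
    "AugmentConfig",
    "split_by_slide",
    "oversample_weights",
    "augment",
    "trainable",
    "label_matrix",
    "write_annotations",
    "read_annotations",
]


@dataclass(frozen=True)
class AnnotationRecord:
    tile_id: str
    slide_id: str
    labels: frozenset = frozenset()
    negative: bool = False
    not_sure: bool = False
    flagged: bool = False
    timestamp: str = "1970-01-01T00:00:00"

    def __post_init__(self):
        object.__setattr__(self, "labels", frozenset(self.labels))
        if not self.labels <= set(LABELS):
            raise ValueError(f"unknown labels: {set(self.labels) - set(LABELS)}")
        if self.negative and self.labels:
            raise ValueError("a negative tile cannot carry labels")


@dataclass(frozen=True)
class SplitAssignment:
    assignment: dict  # slide_id -> split name

    def __getitem__(self, slide_id: str) -> str:
        return self.assignment[slide_id]

    def for_record(self, record: AnnotationRecord) -> str:
        return self.assignment[record.slide_id]

    def slides(self, split: str) -> list[str]:
        return sorted(s for s, v in self.assignment.items() if v == split)


def split_by_slide(records: list[AnnotationRecord],
                   fractions: tuple[float, float, float] = (0.8, 0.2, 0.0),
                   seed: int = 0) -> SplitAssignment:
    """Shuffle slides by seed and partition them by the given fractions
    (train, validation, test); tiles inherit their slide's split."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    slides = sorted({r.slide_id for r in records})
    n_groups = sum(f > 0 for f in fractions)
    if len(slides) < n_groups:
        raise ValueError(f"{len(slides)} slides cannot fill {n_groups} split groups")
    rng = np.random.default_rng(seed)
    order = [slides[i] for i in rng.permutation(len(slides))]
    # largest-remainder apportionment, guaranteeing >= 1 slide per
    # nonzero fraction
    n = len(slides)
    counts = [int(np.floor(f * n)) for f in fractions]
    for i, f in enumerate(fractions):
        if f > 0 and counts[i] == 0:
            counts[i] = 1
    while sum(counts) > n:
        counts[int(np.argmax(counts))] -= 1
    rema = [f * n - c for f, c in zip(fractions, counts)]
    while sum(counts) < n:
        i = int(np.argmax([r if fractions[j] > 0 else -np.inf for j, r in enumerate(rema)]))
        counts[i] += 1
        rema[i] = -np.inf
    assignment = {}
    pos = 0
    for split, c in zip(SPLITS, counts):
        for s in order[pos:pos + c]:
            assignment[s] = split
        pos += c
    return SplitAssignment(assignment)


def trainable(records: list[AnnotationRecord]) -> list[AnnotationRecord]:
    """Drop not-sure and flagged records (kept in the store, never trained on)."""
    return [r for r in records if not (r.not_sure or r.flagged)]


def _group(record: AnnotationRecord) -> list[str]:
    return ["negative"] if record.negative else sorted(record.labels)


def oversample_weights(records: list[AnnotationRecord]) -> np.ndarray:
    """Per-record sampling weights balancing {cored, diffuse, caa, negative}.

    With-replacement draws under these weights hit each represented
    class equally often.  A multi-label record contributes the mean of
    its classes' inverse counts (exact balance is only achievable when
    label sets are disjoint).  Weights are positive and sum to 1.
    """
    if not records:
        raise ValueError("no records")
    counts: dict[str, int] = {}
    for r in records:
        for g in _group(r):
            counts[g] = counts.get(g, 0) + 1
    w = np.array([np.mean([1.0 / counts[g] for g in _group(r)]) for r in records])
    return w / w.sum()


def label_matrix(records: list[AnnotationRecord]) -> np.ndarray:
    """(n, 3) binary matrix over (cored, diffuse, caa)."""
    return np.array([[1.0 if lab in r.labels else 0.0 for lab in LABELS]
                     for r in records], dtype=np.float32)


@dataclass(frozen=True)
class AugmentConfig:
    p_flip: float = 0.5
    rotation_deg: float = 180.0
    zoom: tuple = (0.9, 1.1)
    shear_deg: float = 10.0
    brightness: float = 0.1
    contrast: float = 0.1
    saturation: float = 0.1
    hue: float = 0.02  # fraction of the hue circle


def _affine(center: float, flip_h: bool, flip_v: bool, angle: float,
            zoom: float, shear: float) -> np.ndarray:
    t_neg = np.array([[1, 0, -center], [0, 1, -center], [0, 0, 1.0]])
    t_pos = np.array([[1, 0, center], [0, 1, center], [0, 0, 1.0]])
    f = np.diag([-1.0 if flip_v else 1.0, -1.0 if flip_h else 1.0, 1.0])
    c, s = np.cos(angle), np.sin(angle)
    r = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
    z = np.diag([zoom, zoom, 1.0])
    sh = np.array([[1.0, np.tan(shear), 0], [0, 1.0, 0], [0, 0, 1.0]])
    return t_pos @ r @ z @ sh @ f @ t_neg


def augment(tile: np.ndarray, seed: int,
            config: AugmentConfig = AugmentConfig()) -> np.ndarray:
    """Seeded random flip / rotation / zoom / shear / color jitter.

    Geometric transforms act about the tile center with reflection
    padding (avoids dark corners that would mimic plaque cores).  Output
    has the input's shape, uint8 in [0, 255].
    """
    tile = np.asarray(tile)
    if tile.ndim != 3 or tile.shape[2] != 3:
        raise ValueError("tile must be H x W x 3")
    rng = np.random.default_rng(seed)
    flip_h = rng.random() < config.p_flip
    flip_v = rng.random() < config.p_flip
    angle = np.deg2rad(rng.uniform(-config.rotation_deg, config.rotation_deg))
    zoom = rng.uniform(*config.zoom)
    shear = np.deg2rad(rng.uniform(-config.shear_deg, config.shear_deg))
    img = tile.astype(np.float32) / 255.0
    m = _affine((tile.shape[0] - 1) / 2.0, flip_h, flip_v, angle, zoom, shear)
    img = warp(img, np.linalg.inv(m), order=1, mode="reflect")
    if config.brightness or config.contrast or config.saturation or config.hue:
        b = 1.0 + rng.uniform(-config.brightness, config.brightness)
        c = 1.0 + rng.uniform(-config.contrast, config.contrast)
        s = 1.0 + rng.uniform(-config.saturation, config.saturation)
        dh = rng.uniform(-config.hue, config.hue)
        # brightness then contrast about the brightened mean, fused into
        # one affine pass; saturation as a lerp from per-pixel luma and
        # hue as a small rotation about the gray axis, fused into one
        # 3x3 color matrix (linear stand-ins for HSV edits)
        mean = img.mean()
        img = np.clip(img * np.float32(b * c) + np.float32(b * mean * (1.0 - c)), 0, 1)
        luma_w = np.array([0.299, 0.587, 0.114])
        color = s * np.eye(3) + (1.0 - s) * np.outer(np.ones(3), luma_w)
        color = _hue_rotation(2 * np.pi * dh) @ color
        img = np.clip(img @ color.T.astype(np.float32), 0, 1)
    return np.clip(img * 255.0, 0, 255).round().astype(np.uint8)


def _hue_rotation(theta: float) -> np.ndarray:
    """Rodrigues rotation of RGB about the gray axis (1,1,1)/sqrt(3)."""
    axis = np.ones(3) / np.sqrt(3)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    r = np.eye(3) + np.sin(theta) * k + (1 - np.cos(theta)) * (k @ k)
    return r.astype(np.float32)


# ---------------------------------------------------------------------------
# CSV store

_COLUMNS = ["tile_id", "slide_id", "cored", "diffuse", "caa",
            "negative", "not_sure", "flagged", "timestamp"]


def write_annotations(records: list[AnnotationRecord], path: str | Path):
    rows = [{"tile_id": r.tile_id, "slide_id": r.slide_id,
             **{lab: int(lab in r.labels) for lab in LABELS},
             "negative": int(r.negative), "not_sure": int(r.not_sure),
             "flagged": int(r.flagged), "timestamp": r.timestamp} for r in records]
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, index=False)


def read_annotations(path: str | Path) -> list[AnnotationRecord]:
    df = pd.read_csv(path, dtype={"tile_id": str, "slide_id": str, "timestamp": str})
    out = []
    for _, r in df.iterrows():
        out.append(AnnotationRecord(
            tile_id=r["tile_id"], slide_id=r["slide_id"],
            labels=frozenset(lab for lab in LABELS if int(r[lab])),
            negative=bool(int(r["negative"])), not_sure=bool(int(r["not_sure"])),
            flagged=bool(int(r["flagged"])), timestamp=r["timestamp"]))
    return out


def write_split(split: SplitAssignment, path: str | Path):
    pd.DataFrame(sorted(split.assignment.items()),
                 columns=["slide_id", "split"]).to_csv(path, index=False)


def read_split(path: str | Path) -> SplitAssignment:
    df = pd.read_csv(path, dtype=str)
    return SplitAssignment(dict(zip(df["slide_id"], df["split"])))
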