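"""Synthetic whole-slide images with planted amyloid-beta pathology.

Generates reproducible stand-ins for IHC-stained (DAB, brown) brain
tissue slides at a declared microns-per-pixel resolution: a white slide
background, one contiguous pinkish tissue region, and brown-hue stained
objects of three morphologies —

* cored plaque: dark compact disk with a lighter surrounding halo,
* diffuse plaque: amorphous light-brown blob (union of jittered disks),
* CAA: brown annulus emulating amyloid in a vessel wall.

Object colors are drawn inside the default stain-mask HSV range
(hue 10-30 deg, saturation >= 0.4, value 0.2-0.7) and every object
carries at least ~1500 stained pixels, so the downstream segmentation
stage can recover them by construction.  Everything is deterministic
for a fixed spec + seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.color import hsv2rgb
from skimage.draw import polygon as draw_polygon

from .data import AnnotationRecord

__all__ = [
    "SlideSpec",
    "GroundTruthObject",
    "SlideImage",
    "InfeasibleDensityError",
    "make_slide",
    "make_tile_dataset",
    "write_slide",
    "read_slide",
    "write_ground_truth",
    "read_ground_truth",
]

BACKGROUND_RGB = (247, 247, 247)
TISSUE_RGB = (241, 216, 226)  # pink: high lightness, low chroma


class InfeasibleDensityError(ValueError):
    """Requested objects cannot be placed without overlap."""


@dataclass(frozen=True)
class SlideSpec:
    width_px: int
    height_px: int
    mpp: float = 0.5
    n_cored: int = 0
    n_diffuse: int = 0
    n_caa: int = 0
    tissue_fraction: float = 0.5
    seed: int = 0
    min_separation_px: int = 0  # extra center-to-center spacing between objects
    placement: str = "rejection"  # or "lattice" (jittered hex grid, dense packing)

    def __post_init__(self):
        if self.width_px < 256 or self.height_px < 256:
            raise ValueError("slide dimensions must be at least 256 px")
        if min(self.n_cored, self.n_diffuse, self.n_caa) < 0:
            raise ValueError("object counts must be non-negative")
        if not (0.0 <= self.tissue_fraction <= 1.0):
            raise ValueError("tissue_fraction must lie in [0, 1]")
        if self.mpp <= 0:
            raise ValueError("mpp must be positive")
        if self.placement not in ("rejection", "lattice"):
            raise ValueError("placement must be 'rejection' or 'lattice'")


@dataclass(frozen=True)
class GroundTruthObject:
    class_label: str  # cored | diffuse | caa
    bbox: tuple  # half-open (y0, x0, y1, x1)
    stained_area_px: int


@dataclass
class SlideImage:
    pixels: np.ndarray  # (H, W, 3) uint8
    mpp: float
    slide_id: str

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be H x W x 3")
        if self.mpp <= 0:
            raise ValueError("mpp must be positive")


def _tissue_mask(spec: SlideSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.height_px, spec.width_px
    if spec.tissue_fraction == 0:
        return np.zeros((h, w), dtype=bool)
    # smoothed superelliptic polygon around the slide center (tissue
    # sections fill the frame corners more than an ellipse would); axes
    # chosen so the enclosed area approximates tissue_fraction, which
    # saturates near ~0.85 for near-full coverage
    p = 4.0  # superellipse exponent
    area_const = 3.708  # 4 * Gamma(1.25)^2 / Gamma(1.5) for p = 4
    area = spec.tissue_fraction * w * h
    ratio = rng.uniform(0.9, 1.1)
    a = min(np.sqrt(area * ratio / area_const), 0.49 * h)  # semi-axis rows
    b = min(area / (area_const * a), 0.49 * w)  # semi-axis cols
    theta = np.linspace(0, 2 * np.pi, 241, endpoint=False)
    # low-frequency radial perturbation for an organic outline
    n_harm = 5
    amp = 0.05
    pert = np.zeros_like(theta)
    for k in range(1, n_harm + 1):
        pert += rng.normal(0, 1) * np.cos(k * theta) + rng.normal(0, 1) * np.sin(k * theta)
    pert = 1.0 + amp * pert / np.sqrt(n_harm)
    cy, cx = h / 2, w / 2
    r_se = (np.abs(np.sin(theta) / a) ** p + np.abs(np.cos(theta) / b) ** p) ** (-1.0 / p)
    rr = cy + r_se * np.sin(theta) * pert
    cc = cx + r_se * np.cos(theta) * pert
    rr = np.clip(rr, 0, h - 1)
    cc = np.clip(cc, 0, w - 1)
    mask = np.zeros((h, w), dtype=bool)
    pr, pc = draw_polygon(rr, cc, shape=(h, w))
    mask[pr, pc] = True
    return mask


def _clip_to_canvas(canvas, rows, cols, *values):
    """Drop pixels outside the canvas (objects may straddle tile edges)."""
    h, w = canvas.shape[:2]
    keep = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
    return (rows[keep], cols[keep]) + tuple(np.asarray(v)[keep] for v in values)


def _paint(canvas: np.ndarray, rows: np.ndarray, cols: np.ndarray,
           hue: float, sat: np.ndarray, val: np.ndarray):
    hsv = np.stack([np.full_like(val, hue), sat, np.clip(val, 0.2, 0.7)], axis=-1)
    canvas[rows, cols] = hsv2rgb(hsv[None])[0] * 255.0


def _draw_cored(canvas, cy, cx, rng):
    r_core = rng.uniform(20, 28)
    r_out = r_core * rng.uniform(1.5, 1.85)
    hue = rng.uniform(12, 22) / 360.0
    size = int(np.ceil(r_out)) + 1
    yy, xx = np.mgrid[-size:size + 1, -size:size + 1]
    dist = np.hypot(yy, xx)
    mask = dist <= r_out
    core = dist <= r_core
    rows, cols = np.nonzero(mask)
    rows, cols = rows - size, cols - size  # indices -> centered offsets
    sat = np.where(core[mask], rng.uniform(0.70, 0.85), rng.uniform(0.45, 0.60))
    val = np.where(core[mask], rng.uniform(0.28, 0.38), rng.uniform(0.55, 0.65))
    val = val * (1 + 0.04 * rng.standard_normal(val.shape))
    rows, cols, sat, val = _clip_to_canvas(canvas, rows + cy, cols + cx, sat, val)
    _paint(canvas, rows, cols, hue, sat, val)
    out = np.zeros_like(canvas[..., 0], dtype=bool)
    out[rows, cols] = True
    return out


def _draw_diffuse(canvas, cy, cx, rng):
    spread = rng.uniform(30, 42)
    hue = rng.uniform(14, 28) / 360.0
    size = int(np.ceil(spread + 14))
    yy, xx = np.mgrid[-size:size + 1, -size:size + 1]
    mask = np.zeros(yy.shape, dtype=bool)
    # keep adding jittered disks until the blob is safely above the
    # candidate-size floor of 1500 stained pixels
    n_disks = rng.integers(9, 15)
    while True:
        for _ in range(n_disks):
            ang = rng.uniform(0, 2 * np.pi)
            rad = rng.uniform(0, spread - 8)
            oy, ox = rad * np.sin(ang), rad * np.cos(ang)
            r = rng.uniform(8, 14)
            mask |= np.hypot(yy - oy, xx - ox) <= r
        if mask.sum() >= 1700:
            break
        n_disks = 3
    rows, cols = np.nonzero(mask)
    rows, cols = rows - size, cols - size
    sat = np.full(rows.shape, rng.uniform(0.42, 0.55))
    val = rng.uniform(0.55, 0.68) * (1 + 0.05 * rng.standard_normal(rows.shape))
    rows, cols, sat, val = _clip_to_canvas(canvas, rows + cy, cols + cx, sat, val)
    _paint(canvas, rows, cols, hue, sat, val)
    out = np.zeros_like(canvas[..., 0], dtype=bool)
    out[rows, cols] = True
    return out


def _draw_caa(canvas, cy, cx, rng):
    r_out = rng.uniform(30, 38)
    thick = rng.uniform(10, 12)
    hue = rng.uniform(12, 24) / 360.0
    size = int(np.ceil(r_out)) + 1
    yy, xx = np.mgrid[-size:size + 1, -size:size + 1]
    dist = np.hypot(yy, xx)
    mask = (dist <= r_out) & (dist >= r_out - thick)
    rows, cols = np.nonzero(mask)
    rows, cols = rows - size, cols - size
    sat = np.full(rows.shape, rng.uniform(0.55, 0.70))
    val = rng.uniform(0.40, 0.52) * (1 + 0.04 * rng.standard_normal(rows.shape))
    rows, cols, sat, val = _clip_to_canvas(canvas, rows + cy, cols + cx, sat, val)
    _paint(canvas, rows, cols, hue, sat, val)
    out = np.zeros_like(canvas[..., 0], dtype=bool)
    out[rows, cols] = True
    return out


_DRAWERS = {"cored": (_draw_cored, 56), "diffuse": (_draw_diffuse, 58), "caa": (_draw_caa, 40)}
_MAX_RETRIES = 1000
_LATTICE_JITTER = 16


def _hex_sites(spec: SlideSpec, tissue: np.ndarray, halfsize: int,
               rng: np.random.Generator) -> list[tuple[int, int]]:
    """Jittered hexagonal lattice sites whose object boxes lie inside
    tissue; pitch guarantees the requested minimum separation after
    per-site jitter."""
    h, w = spec.height_px, spec.width_px
    base = max(spec.min_separation_px, 2 * halfsize + 8)
    # extra pitch beyond the guaranteed minimum: typical neighbor spacing
    # then sits well above min_separation rather than at it
    pitch = base + 2 * _LATTICE_JITTER + 24
    theta = rng.uniform(0, np.pi / 3)
    v1 = pitch * np.array([np.sin(theta), np.cos(theta)])
    v2 = pitch * np.array([np.sin(theta + np.pi / 3), np.cos(theta + np.pi / 3)])
    origin = np.array([h / 2, w / 2]) + rng.uniform(-pitch / 2, pitch / 2, size=2)
    reach = int(np.ceil((h + w) / pitch)) + 2
    sites = []
    for i in range(-reach, reach + 1):
        for j in range(-reach, reach + 1):
            y, x = origin + i * v1 + j * v2
            cy, cx = int(round(y)), int(round(x))
            m = halfsize + _LATTICE_JITTER
            if not (m + 1 <= cy < h - m - 1 and m + 1 <= cx < w - m - 1):
                continue
            if tissue[cy - m:cy + m + 1, cx - m:cx + m + 1].all():
                sites.append((cy, cx))
    order = rng.permutation(len(sites))
    return [sites[k] for k in order]


def make_slide(spec: SlideSpec, slide_id: str | None = None
               ) -> tuple[SlideImage, list[GroundTruthObject]]:
    """Render a synthetic slide and its exact ground truth.

    Object placement uses rejection sampling: bounding regions must lie
    inside tissue, inside the slide, and must not overlap previously
    placed objects (plus ``min_separation_px`` center spacing).  After
    1000 failed draws for any single object an
    :class:`InfeasibleDensityError` is raised.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height_px, spec.width_px
    canvas = np.empty((h, w, 3), dtype=np.float64)
    canvas[:] = BACKGROUND_RGB
    tissue = _tissue_mask(spec, rng)
    canvas[tissue] = TISSUE_RGB

    wanted = (["cored"] * spec.n_cored + ["diffuse"] * spec.n_diffuse + ["caa"] * spec.n_caa)
    if wanted and not tissue.any():
        raise InfeasibleDensityError("no tissue region to place objects in")

    placed: list[tuple[int, int, int]] = []  # (cy, cx, halfsize)
    truth: list[GroundTruthObject] = []
    gap = 6
    sites: list[tuple[int, int]] = []
    if spec.placement == "lattice" and wanted:
        halfmax = max(_DRAWERS[lab][1] for lab in wanted)
        sites = _hex_sites(spec, tissue, halfmax, rng)
        if len(sites) < len(wanted):
            raise InfeasibleDensityError(
                f"lattice holds {len(sites)} sites for {len(wanted)} objects")
    for label in wanted:
        drawer, halfsize = _DRAWERS[label]
        if spec.placement == "lattice":
            sy_, sx_ = sites[len(placed)]
            cy = sy_ + int(rng.integers(-_LATTICE_JITTER, _LATTICE_JITTER + 1))
            cx = sx_ + int(rng.integers(-_LATTICE_JITTER, _LATTICE_JITTER + 1))
        else:
            for attempt in range(_MAX_RETRIES):
                cy = int(rng.integers(halfsize + 1, h - halfsize - 1))
                cx = int(rng.integers(halfsize + 1, w - halfsize - 1))
                box = tissue[cy - halfsize:cy + halfsize + 1,
                             cx - halfsize:cx + halfsize + 1]
                if not box.all():
                    continue
                ok = True
                for (py, px, ph) in placed:
                    if (abs(cy - py) < halfsize + ph + gap
                            and abs(cx - px) < halfsize + ph + gap):
                        ok = False
                        break
                    if spec.min_separation_px and \
                            np.hypot(cy - py, cx - px) < spec.min_separation_px:
                        ok = False
                        break
                if ok:
                    break
            else:
                raise InfeasibleDensityError(
                    f"could not place {label} object #{len(placed)} after "
                    f"{_MAX_RETRIES} draws")
        stain = drawer(canvas, cy, cx, rng)
        rows, cols = np.nonzero(stain)
        bbox = (int(rows.min()), int(cols.min()), int(rows.max()) + 1, int(cols.max()) + 1)
        truth.append(GroundTruthObject(label, bbox, int(stain.sum())))
        placed.append((cy, cx, halfsize))

    canvas += rng.normal(0, 4.0, size=canvas.shape)
    pixels = np.clip(canvas, 0, 255).round().astype(np.uint8)
    if slide_id is None:
        slide_id = f"synth-{spec.seed:05d}"
    return SlideImage(pixels, spec.mpp, slide_id), truth


def make_tile_dataset(n_per_class: tuple[int, int, int],
                      n_negative: int = 0,
                      seed: int = 0,
                      tile_px: int = 256,
                      n_slides: int = 8,
                      center_jitter_px: int = 72,
                      mpp: float = 0.5,
                      ) -> list[tuple[np.ndarray, AnnotationRecord]]:
    """Labeled 256 px tiles, each holding one planted object on tissue.

    Objects sit near the tile center with a small uniform jitter
    (candidate centering in the real pipeline lands on the stained
    component's centroid, which is off the visual center for irregular
    deposits).  Negative tiles mirror the content a sliding window
    meets on an unstained slide: plain tissue (60%), a tissue /
    background boundary (20%) or slide background (20%).  Tiles are
    assigned round-robin to ``n_slides`` pseudo-slides so
    slide-stratified splitting has something to stratify over.
    """
    if min(n_per_class) < 0 or n_negative < 0:
        raise ValueError("counts must be non-negative")
    rng = np.random.default_rng(seed)
    labels = (["cored"] * n_per_class[0] + ["diffuse"] * n_per_class[1]
              + ["caa"] * n_per_class[2] + [None] * n_negative)
    out = []
    for i, label in enumerate(labels):
        canvas = np.empty((tile_px, tile_px, 3), dtype=np.float64)
        canvas[:] = TISSUE_RGB
        if label is not None:
            drawer, halfsize = _DRAWERS[label]
            jmax = min(center_jitter_px, tile_px // 2 - halfsize - 2)
            ang = rng.uniform(0, 2 * np.pi)
            rad = rng.uniform(0, jmax)
            cy = tile_px // 2 + int(round(rad * np.sin(ang)))
            cx = tile_px // 2 + int(round(rad * np.cos(ang)))
            drawer(canvas, cy, cx, rng)
        else:
            kind = rng.random()
            if kind >= 0.8:  # slide background
                canvas[:] = BACKGROUND_RGB
            elif kind >= 0.6:  # tissue/background boundary through the tile
                phi = rng.uniform(0, 2 * np.pi)
                dist = rng.uniform(-tile_px / 4, tile_px / 4)
                yy, xx = np.mgrid[0:tile_px, 0:tile_px]
                half = (np.cos(phi) * (yy - tile_px / 2)
                        + np.sin(phi) * (xx - tile_px / 2)) > dist
                canvas[half] = BACKGROUND_RGB
            elif kind >= 0.4:  # neighboring-object sliver at the tile edge
                # neighboring-candidate rule: an object centered well away
                # from the tile center belongs to a different candidate
                # tile and is not annotated here, even if it overlaps the
                # frame; this makes object counts identifiable from
                # heatmap blobs
                frag_label = ("cored", "diffuse", "caa")[int(rng.integers(3))]
                drawer, _ = _DRAWERS[frag_label]
                phi = rng.uniform(0, 2 * np.pi)
                off = rng.uniform(112, 176)
                cy = tile_px // 2 + int(round(off * np.sin(phi)))
                cx = tile_px // 2 + int(round(off * np.cos(phi)))
                drawer(canvas, cy, cx, rng)
        canvas += rng.normal(0, 4.0, size=canvas.shape)
        tile = np.clip(canvas, 0, 255).round().astype(np.uint8)
        rec = AnnotationRecord(
            tile_id=f"tile-{seed}-{i:05d}",
            slide_id=f"synthslide-{seed}-{i % n_slides:02d}",
            labels=frozenset() if label is None else frozenset({label}),
            negative=label is None,
            timestamp=f"2026-01-01T00:{(i // 60) % 60:02d}:{i % 60:02d}",
        )
        out.append((tile, rec))
    return out


# ---------------------------------------------------------------------------
# file IO

def write_slide(slide: SlideImage, path: str | Path):
    iio.imwrite(Path(path), slide.pixels)


def read_slide(path: str | Path, mpp: float = 0.5, slide_id: str | None = None) -> SlideImage:
    pixels = np.asarray(iio.imread(Path(path)))
    if pixels.ndim == 3 and pixels.shape[2] == 4:
        pixels = pixels[..., :3]
    return SlideImage(pixels, mpp, slide_id or Path(path).stem)


def write_ground_truth(truth: list[GroundTruthObject], slide_id: str, path: str | Path):
    rows = [{"slide_id": slide_id, "class": t.class_label,
             "y0": t.bbox[0], "x0": t.bbox[1], "y1": t.bbox[2], "x1": t.bbox[3],
             "stained_area_px": t.stained_area_px} for t in truth]
    pd.DataFrame(rows, columns=["slide_id", "class", "y0", "x0", "y1", "x1",
                                "stained_area_px"]).to_csv(path, index=False)


def read_ground_truth(path: str | Path) -> dict[str, list[GroundTruthObject]]:
    df = pd.read_csv(path)
    out: dict[str, list[GroundTruthObject]] = {}
    for _, r in df.iterrows():
        out.setdefault(r["slide_id"], []).append(GroundTruthObject(
            r["class"], (int(r["y0"]), int(r["x0"]), int(r["y1"]), int(r["x1"])),
            int(r["stained_area_px"])))
    return out
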