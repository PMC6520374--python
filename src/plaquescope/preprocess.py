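"""Slide preprocessing: color normalization, stain segmentation,
candidate extraction and tissue-area measurement.

The front end of the pipeline.  Slides are color-normalized by channel
moment matching in a perceptual transfer colorspace (Reinhard-style
statistics transfer; the decorrelated log-LMS "l-alpha-beta" space by
default, CIELAB behind a config switch).  DAB-stained objects are then
segmented with a permissive brown HSV color mask, smoothed by
morphological opening/closing, and connected components above a minimum
stained area become candidate objects, each center-cropped to a fixed
256 px tile.  Tissue area is measured with a lightness/chroma mask in
LCH space and converted to mm^2 through the slide's microns-per-pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage import morphology
from skimage.color import rgb2hsv, rgb2lab, lab2rgb, lab2lch
from skimage.measure import label as cc_label, regionprops

from .synthetic import SlideImage

__all__ = [
    "PreprocessConfig",
    "ColorStats",
    "CandidateObject",
    "color_stats",
    "reinhard_normalize",
    "tile_slide",
    "stain_mask",
    "refine_mask",
    "extract_candidates",
    "crop_candidate",
    "tissue_area",
    "candidates_from_slide",
    "to_transfer_space",
    "from_transfer_space",
]


@dataclass(frozen=True)
class PreprocessConfig:
    tile_px: int = 1536
    candidate_px: int = 256
    min_stain_area_px: int = 1500  # 375 um^2 at 0.5 mpp
    hsv_low: tuple = (0.0, 0.25, 0.10)  # hue fraction of the circle
    hsv_high: tuple = (40.0 / 360.0, 1.0, 0.90)
    morph_radius_px: int = 2
    connectivity: int = 8
    mpp: float = 0.5
    colorspace: str = "lalphabeta"  # or "cielab"
    tissue_lightness_max: float = 90.0
    tissue_chroma_min: float = 6.0
    tissue_morph_radius_px: int = 5

    def __post_init__(self):
        if self.candidate_px > self.tile_px:
            raise ValueError("candidate_px must not exceed tile_px")
        if self.min_stain_area_px < 1:
            raise ValueError("min_stain_area_px must be >= 1")
        if self.morph_radius_px < 0:
            raise ValueError("morph_radius_px must be >= 0")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.colorspace not in ("lalphabeta", "cielab"):
            raise ValueError("colorspace must be 'lalphabeta' or 'cielab'")


@dataclass(frozen=True)
class ColorStats:
    mean: tuple  # per-channel mean in the transfer colorspace
    std: tuple  # per-channel standard deviation (population)
    colorspace: str = "lalphabeta"

    def __post_init__(self):
        if len(self.mean) != 3 or len(self.std) != 3:
            raise ValueError("mean and std must have three channels")
        if min(self.std) < 0:
            raise ValueError("standard deviations must be >= 0")


@dataclass(frozen=True)
class CandidateObject:
    slide_id: str
    centroid: tuple  # (row, col), float
    bbox: tuple  # half-open (y0, x0, y1, x1)
    stained_area_px: int


# --- Reinhard-style moment transfer --------------------------------------
# RGB -> LMS cone response, then log10, then the decorrelating
# l-alpha-beta rotation (Ruderman's opponent axes).

_RGB2LMS = np.array([[0.3811, 0.5783, 0.0402],
                     [0.1967, 0.7244, 0.0782],
                     [0.0241, 0.1288, 0.8444]])
_LMS2RGB = np.linalg.inv(_RGB2LMS)
_LAB_ROT = np.diag([1 / np.sqrt(3), 1 / np.sqrt(6), 1 / np.sqrt(2)]) @ np.array(
    [[1.0, 1.0, 1.0],
     [1.0, 1.0, -2.0],
     [1.0, -1.0, 0.0]])
_LAB_ROT_INV = np.linalg.inv(_LAB_ROT)
_LMS_FLOOR = 1e-6


def to_transfer_space(pixels: np.ndarray, colorspace: str = "lalphabeta") -> np.ndarray:
    """8-bit RGB (H, W, 3) -> float transfer-space channels."""
    rgb = np.asarray(pixels, dtype=np.float64) / 255.0
    if colorspace == "cielab":
        return rgb2lab(rgb)
    lms = rgb @ _RGB2LMS.T
    log_lms = np.log10(np.maximum(lms, _LMS_FLOOR))
    return log_lms @ _LAB_ROT.T


def from_transfer_space(lab: np.ndarray, colorspace: str = "lalphabeta") -> np.ndarray:
    """Transfer-space channels -> float RGB in [0, 255] (unclipped)."""
    if colorspace == "cielab":
        return lab2rgb(lab) * 255.0
    log_lms = np.asarray(lab) @ _LAB_ROT_INV.T
    lms = np.power(10.0, log_lms)
    return (lms @ _LMS2RGB.T) * 255.0


def color_stats(image: SlideImage, colorspace: str = "lalphabeta") -> ColorStats:
    """Per-channel mean and population std over all pixels."""
    if image.pixels.size == 0:
        raise ValueError("empty image")
    lab = to_transfer_space(image.pixels, colorspace)
    mean = lab.reshape(-1, 3).mean(axis=0)
    std = lab.reshape(-1, 3).std(axis=0)
    return ColorStats(tuple(mean), tuple(std), colorspace)


def normalize_transfer_array(lab: np.ndarray, source: ColorStats, reference: ColorStats,
                             sigma_floor: float = 1e-6) -> np.ndarray:
    """(x - mu_src) * sigma_ref / sigma_src + mu_ref per channel.

    Channels with source std below ``sigma_floor`` keep unit scale, so a
    constant image maps exactly onto the reference mean color.
    """
    mu_s = np.asarray(source.mean)
    mu_r = np.asarray(reference.mean)
    sd_s = np.asarray(source.std)
    sd_r = np.asarray(reference.std)
    scale = np.where(sd_s < sigma_floor, 1.0, sd_r / np.where(sd_s < sigma_floor, 1.0, sd_s))
    return (lab - mu_s) * scale + mu_r


def reinhard_normalize(image: SlideImage, reference: ColorStats) -> SlideImage:
    """Match the image's transfer-space channel moments to the reference."""
    space = reference.colorspace
    lab = to_transfer_space(image.pixels, space)
    src = color_stats(image, space)
    lab = normalize_transfer_array(lab, src, reference)
    rgb = from_transfer_space(lab, space)
    pixels = np.clip(rgb, 0, 255).round().astype(np.uint8)
    return SlideImage(pixels, image.mpp, image.slide_id)


# --- tiling and segmentation ---------------------------------------------

def tile_slide(image: SlideImage, tile_px: int = 1536) -> list[tuple[int, int, np.ndarray]]:
    """Non-overlapping full tiles as (origin_row, origin_col, pixels);
    partial border tiles are dropped."""
    if tile_px < 1:
        raise ValueError("tile_px must be >= 1")
    h, w = image.pixels.shape[:2]
    out = []
    for y0 in range(0, h - tile_px + 1, tile_px):
        for x0 in range(0, w - tile_px + 1, tile_px):
            out.append((y0, x0, image.pixels[y0:y0 + tile_px, x0:x0 + tile_px]))
    return out


def stain_mask(image: SlideImage, config: PreprocessConfig = PreprocessConfig()) -> np.ndarray:
    """Permissive brown color mask in HSV; hue compared circularly."""
    hsv = rgb2hsv(image.pixels)
    h, s, v = hsv[..., 0], hsv[..., 1], hsv[..., 2]
    h_lo, s_lo, v_lo = config.hsv_low
    h_hi, s_hi, v_hi = config.hsv_high
    if h_lo <= h_hi:
        hue_ok = (h >= h_lo) & (h <= h_hi)
    else:  # wrap-around band, e.g. reds spanning the hue origin
        hue_ok = (h >= h_lo) | (h <= h_hi)
    return hue_ok & (s >= s_lo) & (s <= s_hi) & (v >= v_lo) & (v <= v_hi)


def refine_mask(mask: np.ndarray, morph_radius_px: int = 2) -> np.ndarray:
    """Morphological opening then closing with a disk element."""
    if morph_radius_px == 0:
        return mask.copy()
    selem = morphology.disk(morph_radius_px)
    opened = morphology.closing(morphology.opening(mask, selem), selem)
    return opened.astype(bool)


def extract_candidates(mask: np.ndarray,
                       config: PreprocessConfig = PreprocessConfig(),
                       slide_id: str = "") -> list[CandidateObject]:
    """Connected components with area >= min_stain_area_px, sorted by
    centroid (row, col)."""
    conn = 2 if config.connectivity == 8 else 1
    labeled = cc_label(mask, connectivity=conn)
    cands = []
    for rp in regionprops(labeled):
        if rp.area < config.min_stain_area_px:
            continue
        y0, x0, y1, x1 = rp.bbox
        cands.append(CandidateObject(slide_id, tuple(rp.centroid),
                                     (y0, x0, y1, x1), int(rp.area)))
    cands.sort(key=lambda c: c.centroid)
    return cands


def crop_candidate(image: SlideImage, candidate: CandidateObject,
                   candidate_px: int = 256) -> np.ndarray:
    """Fixed-size tile centered on the candidate centroid; area outside
    the slide is filled white."""
    h, w = image.pixels.shape[:2]
    cy, cx = (int(round(c)) for c in candidate.centroid)
    if not (0 <= cy < h and 0 <= cx < w):
        raise ValueError("candidate centroid lies outside the image")
    half = candidate_px // 2
    y0, x0 = cy - half, cx - half
    tile = np.full((candidate_px, candidate_px, 3), 255, dtype=np.uint8)
    sy0, sx0 = max(y0, 0), max(x0, 0)
    sy1, sx1 = min(y0 + candidate_px, h), min(x0 + candidate_px, w)
    if sy1 > sy0 and sx1 > sx0:
        tile[sy0 - y0:sy1 - y0, sx0 - x0:sx1 - x0] = image.pixels[sy0:sy1, sx0:sx1]
    return tile


def tissue_area(image: SlideImage,
                config: PreprocessConfig = PreprocessConfig()) -> tuple[int, float]:
    """Tissue pixels and mm^2 via an LCH color mask.

    A pixel is tissue when its chroma exceeds ``tissue_chroma_min`` or
    its lightness falls below ``tissue_lightness_max`` (white slide
    background is bright and neutral; pink tissue and brown stain are
    not).  The mask is smoothed by opening/closing before counting.
    """
    if image.mpp <= 0:
        raise ValueError("mpp must be positive")
    lch = lab2lch(rgb2lab(np.asarray(image.pixels, dtype=np.float64) / 255.0))
    light, chroma = lch[..., 0], lch[..., 1]
    mask = (chroma >= config.tissue_chroma_min) | (light <= config.tissue_lightness_max)
    mask = refine_mask(mask, config.tissue_morph_radius_px)
    area_px = int(mask.sum())
    area_mm2 = area_px * (image.mpp / 1000.0) ** 2
    return area_px, area_mm2


def candidates_from_slide(slide: SlideImage,
                          config: PreprocessConfig = PreprocessConfig(),
                          reference: ColorStats | None = None,
                          ) -> tuple[list[CandidateObject], np.ndarray]:
    """Normalize (optional), segment, refine and extract in one call."""
    if reference is not None:
        slide = reinhard_normalize(slide, reference)
    mask = refine_mask(stain_mask(slide, config), config.morph_radius_px)
    return extract_candidates(mask, config, slide.slide_id), mask


def write_candidates(cands: list[CandidateObject], path: str | Path):
    rows = [{"slide_id": c.slide_id,
             "centroid_row": c.centroid[0], "centroid_col": c.centroid[1],
             "y0": c.bbox[0], "x0": c.bbox[1], "y1": c.bbox[2], "x1": c.bbox[3],
             "area_px": c.stained_area_px} for c in cands]
    pd.DataFrame(rows, columns=["slide_id", "centroid_row", "centroid_col",
                                "y0", "x0", "y1", "x1", "area_px"]).to_csv(path, index=False)
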