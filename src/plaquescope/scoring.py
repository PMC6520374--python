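"""Whole-slide amyloid-burden scoring from confidence heatmaps.

Heatmaps are thresholded per class, smoothed morphologically, and
connected components above a per-class minimum size (in heatmap-lattice
cells) are counted as discrete objects.  The per-class count divided by
the slide's tissue area (mm^2) is the slide's burden score, which is
compared against ordinal semi-quantitative categories (none / sparse /
moderate / frequent) via Spearman rank correlation and pairwise
two-sided Student's t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skimage.measure import label as cc_label, regionprops

from .heatmap import HeatmapGrid
from .model import TASKS
from .preprocess import refine_mask

__all__ = [
    "ScoringConfig",
    "WsiScore",
    "CeradRecord",
    "CERAD_CATEGORIES",
    "segment_heatmap",
    "wsi_score",
    "spearman",
    "pairwise_ttests",
    "density_category",
]

CERAD_CATEGORIES = ("none", "sparse", "moderate", "frequent")  # ordinal 0..3


@dataclass(frozen=True)
class ScoringConfig:
    confidence_threshold: dict = field(default_factory=lambda: {
        "cored": 0.1, "diffuse": 0.95, "caa": 0.9})
    min_size_px: dict = field(default_factory=lambda: {
        "cored": 100, "diffuse": 1, "caa": 200})  # heatmap-lattice cells
    morph_radius: int = 1

    def __post_init__(self):
        for v in self.confidence_threshold.values():
            if not (0.0 < v < 1.0):
                raise ValueError("confidence thresholds must lie in (0, 1)")
        for v in self.min_size_px.values():
            if v < 1:
                raise ValueError("size thresholds must be >= 1")


@dataclass(frozen=True)
class WsiScore:
    slide_id: str
    counts: dict  # class -> object count
    tissue_area_mm2: float
    scores: dict  # class -> count per mm^2

    def __post_init__(self):
        if self.tissue_area_mm2 <= 0:
            raise ValueError("tissue area must be positive")


@dataclass(frozen=True)
class CeradRecord:
    slide_id: str
    categories: dict  # class -> ordinal 0..3

    def __post_init__(self):
        for v in self.categories.values():
            if v not in (0, 1, 2, 3):
                raise ValueError("categories must be ordinal 0..3")


def segment_heatmap(grid: HeatmapGrid, task, config: ScoringConfig = ScoringConfig(),
                    use_morphology: bool = True) -> int:
    """Count discrete supra-threshold objects in one task's heatmap."""
    if isinstance(task, int):
        task = TASKS[task]
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}")
    k = TASKS.index(task)
    mask = np.asarray(grid.values)[:, :, k] >= config.confidence_threshold[task]
    if use_morphology and config.morph_radius > 0:
        mask = refine_mask(mask, config.morph_radius)
    labeled = cc_label(mask, connectivity=2)
    return sum(1 for rp in regionprops(labeled) if rp.area >= config.min_size_px[task])


def wsi_score(slide_id: str, counts: dict, tissue_area_mm2: float) -> WsiScore:
    """Objects per mm^2 of tissue for each class."""
    if tissue_area_mm2 <= 0:
        raise ValueError("tissue area must be positive")
    scores = {c: counts[c] / tissue_area_mm2 for c in counts}
    return WsiScore(slide_id, dict(counts), float(tissue_area_mm2), scores)


def spearman(scores, categories) -> float:
    """Spearman rho with average-rank tie handling."""
    x = np.asarray(scores, dtype=float)
    y = np.asarray(categories, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("scores and categories must be equal-length 1-D arrays")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in scores or categories")
    return float(stats.spearmanr(x, y).statistic)


def pairwise_ttests(groups: dict) -> pd.DataFrame:
    """Two-sided equal-variance t-test p-values for every category pair.

    ``groups`` maps category (ordinal or name) to a sample of scores.
    The matrix is symmetric with unit diagonal; groups with fewer than
    two members are skipped and their entries flagged as NaN.
    """
    keys = sorted(groups)
    if sum(len(np.atleast_1d(groups[k])) >= 2 for k in keys) < 2:
        raise ValueError("need at least two groups with at least two members each")
    n = len(keys)
    p = np.full((n, n), np.nan)
    np.fill_diagonal(p, 1.0)
    for i in range(n):
        for j in range(i + 1, n):
            a = np.atleast_1d(np.asarray(groups[keys[i]], dtype=float))
            b = np.atleast_1d(np.asarray(groups[keys[j]], dtype=float))
            if len(a) < 2 or len(b) < 2:
                continue
            res = stats.ttest_ind(a, b, equal_var=True)
            p[i, j] = p[j, i] = float(res.pvalue)
    return pd.DataFrame(p, index=keys, columns=keys)


def density_category(density_per_mm2: float,
                     thresholds: tuple = (12.0, 25.0)) -> int:
    """Map an object density (per mm2 of tissue) to a CERAD-like ordinal:
    none (0), sparse (up to the first threshold), moderate (up to the
    second), frequent (beyond)."""
    if density_per_mm2 <= 0:
        return 0
    if density_per_mm2 <= thresholds[0]:
        return 1
    if density_per_mm2 <= thresholds[1]:
        return 2
    return 3
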