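"""Classification metrics and the dataset-size ablation harness.

AUROC is computed as the Mann-Whitney rank statistic (probability that a
random positive outscores a random negative, ties counted one half),
which is exact under ties; AUPR is the step-wise (non-interpolated) sum
of precision over recall increments.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import model as model_mod
from .model import ClassifyThresholds, ModelConfig, TrainConfig, TASKS

__all__ = ["auroc", "aupr", "multilabel_accuracy", "ablation_curve"]


def _check(scores, truths):
    s = np.asarray(scores, dtype=float)
    t = np.asarray(truths)
    if s.shape != t.shape or s.ndim != 1 or len(s) == 0:
        raise ValueError("scores and truths must be equal-length 1-D arrays")
    if not np.isin(t, (0, 1)).all():
        raise ValueError("truths must be binary")
    return s, t.astype(bool)


def auroc(scores, truths) -> float:
    """Mann-Whitney AUROC: P(score+ > score-) + 0.5 P(score+ = score-)."""
    s, t = _check(scores, truths)
    n_pos, n_neg = int(t.sum()), int((~t).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("auroc needs at least one positive and one negative")
    ranks = rankdata(s)
    return float((ranks[t].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def aupr(scores, truths) -> float:
    """Area under the precision-recall step function over all thresholds."""
    s, t = _check(scores, truths)
    n_pos = int(t.sum())
    if n_pos == 0:
        raise ValueError("aupr needs at least one positive")
    order = np.argsort(-s, kind="stable")
    s, t = s[order], t[order]
    # group tied scores: one operating point per distinct threshold
    distinct = np.r_[np.nonzero(np.diff(s))[0], len(s) - 1]
    tp = np.cumsum(t)[distinct]
    n_at = distinct + 1.0
    precision = tp / n_at
    recall = tp / n_pos
    prev_recall = np.r_[0.0, recall[:-1]]
    return float(np.sum((recall - prev_recall) * precision))


def multilabel_accuracy(confidences, truths,
                        thresholds: ClassifyThresholds = ClassifyThresholds()) -> float:
    """Fraction of (tile, task) cells where thresholded prediction
    agrees with truth (strictly-above rule, as in classification)."""
    c = np.atleast_2d(np.asarray(confidences, dtype=float))
    t = np.atleast_2d(np.asarray(truths))
    if c.shape != t.shape:
        raise ValueError("confidences and truths must have equal shapes")
    preds = c > thresholds.as_array()
    return float((preds == t.astype(bool)).mean())


def subset_seed(seed: int, size: int, repeat: int) -> int:
    """Deterministic child seed for one ablation cell."""
    return int(np.random.SeedSequence((seed, size, repeat)).generate_state(1)[0] % (2 ** 31))


def _stratified_subset(slide_ids: np.ndarray, size: int, rng: np.random.Generator) -> np.ndarray:
    """Random subset of tile indices, proportional per slide."""
    slides, inv = np.unique(slide_ids, return_inverse=True)
    n = len(slide_ids)
    quotas = np.floor(np.bincount(inv) * size / n).astype(int)
    short = size - quotas.sum()
    if short > 0:
        extra = rng.choice(len(slides), size=short, replace=False,
                           p=np.bincount(inv) / n)
        for e in extra:
            quotas[e] += 1
    picked = []
    for si in range(len(slides)):
        idx = np.nonzero(inv == si)[0]
        k = min(quotas[si], len(idx))
        picked.append(rng.choice(idx, size=k, replace=False))
    return np.sort(np.concatenate(picked))


def ablation_curve(tiles: np.ndarray,
                   labels: np.ndarray,
                   slide_ids,
                   eval_tiles: np.ndarray,
                   eval_labels: np.ndarray,
                   subset_sizes,
                   n_repeats: int = 5,
                   seed: int = 0,
                   model_config: ModelConfig = ModelConfig(),
                   train_config: TrainConfig = TrainConfig(),
                   sample_weights_fn=None,
                   augment_fn=None) -> pd.DataFrame:
    """Train a fresh seeded model per (subset size, repeat) on a
    slide-stratified random subset and evaluate on a fixed held-out set.

    Returns a tidy table with one row per (size, repeat, task).  Subsets
    are re-drawn independently for every repeat.
    """
    tiles = np.asarray(tiles)
    labels = np.asarray(labels, dtype=np.float32)
    slide_ids = np.asarray(slide_ids)
    n = len(tiles)
    rows = []
    for size in subset_sizes:
        if size > n:
            raise ValueError(f"subset size {size} exceeds dataset size {n}")
        for rep in range(n_repeats):
            child = subset_seed(seed, int(size), rep)
            rng = np.random.default_rng(child)
            idx = (np.arange(n) if size == n
                   else _stratified_subset(slide_ids, int(size), rng))
            sub_tiles, sub_labels = tiles[idx], labels[idx]
            mdl = model_mod.build_model(
                ModelConfig(**{**model_config.__dict__, "seed": child}))
            weights = sample_weights_fn(idx) if sample_weights_fn else None
            tc = TrainConfig(**{**train_config.__dict__, "seed": child})
            model_mod.train(mdl, sub_tiles, sub_labels, tc,
                            sample_weights=weights, augment_fn=augment_fn)
            conf = model_mod.predict_batch(mdl, eval_tiles)
            for k, task in enumerate(TASKS):
                truth = np.asarray(eval_labels)[:, k]
                if truth.min() == truth.max():
                    a_roc = a_pr = np.nan  # single-class task on this eval set
                else:
                    a_roc = auroc(conf[:, k], truth)
                    a_pr = aupr(conf[:, k], truth)
                rows.append({"size": int(size), "repeat": rep, "task": task,
                             "auroc": a_roc, "aupr": a_pr})
    return pd.DataFrame(rows)
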