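"""End-to-end orchestration: synthesize (optional) -> preprocess ->
split -> train -> evaluate -> heatmap -> score.

Stages communicate exclusively through files inside the run's output
directory, so a run can resume after deleting any intermediate: a stage
is skipped when all of its artifacts already exist.  Every stochastic
stage consumes a seed derived deterministically from the run seed and
the stage name, and the run manifest records every artifact path, the
configuration echo and all derived seeds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import data as data_mod
from . import evaluate as eval_mod
from . import heatmap as heatmap_mod
from . import model as model_mod
from . import preprocess as pp_mod
from . import scoring as scoring_mod
from . import synthetic as synth_mod

log = logging.getLogger("plaquescope")

__all__ = ["PipelineConfig", "PipelineError", "validate_config", "write_config",
           "run_end_to_end", "stage_seed"]


@dataclass(frozen=True)
class SynthSection:
    n_slides: int = 6
    slide_px: int = 768
    tissue_fraction: float = 0.8
    max_cored: int = 6  # slide i gets a count ramp up to these maxima
    max_diffuse: int = 4
    max_caa: int = 2
    tiles_per_class: int = 150
    negative_tiles: int = 150
    mpp: float = 0.5


@dataclass(frozen=True)
class DatasetSection:
    fractions: tuple = (0.8, 0.2, 0.0)
    augment: data_mod.AugmentConfig = field(default_factory=data_mod.AugmentConfig)


@dataclass(frozen=True)
class HeatmapSection:
    stride_px: int = 16


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    outdir: str = "plaquescope_run"
    verbosity: str = "info"
    synth: SynthSection = field(default_factory=SynthSection)
    preprocess: pp_mod.PreprocessConfig = field(default_factory=pp_mod.PreprocessConfig)
    dataset: DatasetSection = field(default_factory=DatasetSection)
    model: model_mod.ModelConfig = field(default_factory=model_mod.ModelConfig)
    train: model_mod.TrainConfig = field(default_factory=model_mod.TrainConfig)
    heatmap: HeatmapSection = field(default_factory=HeatmapSection)
    scoring: scoring_mod.ScoringConfig = field(default_factory=scoring_mod.ScoringConfig)

    def __post_init__(self):
        if self.seed < 0:
            raise ValueError("seed must be a non-negative integer")


class PipelineError(RuntimeError):
    """Stage failure with a machine-readable code."""

    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}/{code}] {message}")
        self.stage = stage
        self.code = code


def _from_dict(cls, payload: dict, path: str = ""):
    if not isinstance(payload, dict):
        raise PipelineError("config", "schema", f"expected a mapping at '{path or '.'}'")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(payload) - set(fields)
    if unknown:
        raise PipelineError("config", "unknown-key",
                            f"unknown key(s) {sorted(unknown)} at '{path or '.'}'")
    kwargs = {}
    for name, value in payload.items():
        f = fields[name]
        sub = f"{path}.{name}" if path else name
        if dataclasses.is_dataclass(f.type) or (isinstance(f.type, type)
                                                and dataclasses.is_dataclass(f.type)):
            kwargs[name] = _from_dict(f.type, value, sub)
        elif isinstance(value, dict) and dataclasses.is_dataclass(_resolve(cls, name)):
            kwargs[name] = _from_dict(_resolve(cls, name), value, sub)
        elif isinstance(value, list):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise PipelineError("config", "invalid-value", f"at '{path or '.'}': {exc}")


def _resolve(cls, name):
    # dataclass field default types for nested sections
    defaults = {f.name: f.default_factory() if f.default_factory is not dataclasses.MISSING
                else f.default for f in dataclasses.fields(cls)}
    return type(defaults[name])


def validate_config(path: str | Path | None = None, payload: dict | None = None) -> PipelineConfig:
    """Load, default-fill and type-check a YAML config; unknown keys are
    rejected with their key path.  An empty file yields all defaults."""
    if payload is None:
        text = Path(path).read_text() if path is not None else ""
        payload = yaml.safe_load(text) or {}
    return _from_dict(PipelineConfig, payload)


def write_config(config: PipelineConfig, path: str | Path):
    Path(path).write_text(yaml.safe_dump(asdict(config), sort_keys=False))


def stage_seed(run_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    digest = hashlib.sha256(f"{run_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def _exists(paths) -> bool:
    return all(Path(p).exists() for p in paths)


def _ramp(maximum: int, i: int, n: int) -> int:
    return int(round(maximum * i / max(1, n - 1)))


def run_end_to_end(config: PipelineConfig, resume: bool = False) -> dict:
    """Execute the full pipeline; returns the manifest (also written to
    ``<outdir>/manifest.json``)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(getattr(logging, config.verbosity.upper(), logging.INFO))
    manifest = {"seed": config.seed, "config": asdict(config), "stages": {}}

    def stage(name, artifacts, fn):
        paths = [str(out / a) for a in artifacts]
        t0 = time.time()
        if resume and _exists(paths):
            log.info("stage %s: resumed (artifacts exist)", name)
            manifest["stages"][name] = {"artifacts": paths, "seed": stage_seed(config.seed, name),
                                        "skipped": True}
            return
        try:
            fn(stage_seed(config.seed, name))
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(name, type(exc).__name__, str(exc)) from exc
        missing = [p for p in paths if not Path(p).exists()]
        if missing:
            raise PipelineError(name, "missing-artifact", f"stage did not write {missing}")
        log.info("stage %s: done in %.1fs -> %d artifact(s)", name, time.time() - t0, len(paths))
        manifest["stages"][name] = {"artifacts": paths, "seed": stage_seed(config.seed, name),
                                    "skipped": False}

    s = config.synth
    slide_files = [f"slides/slide_{i:02d}.png" for i in range(s.n_slides)]

    def do_synth(seed):
        (out / "slides").mkdir(exist_ok=True)
        (out / "tiles").mkdir(exist_ok=True)
        truth_rows = []
        for i in range(s.n_slides):
            spec = synth_mod.SlideSpec(
                s.slide_px, s.slide_px, mpp=s.mpp,
                n_cored=_ramp(s.max_cored, i, s.n_slides),
                n_diffuse=_ramp(s.max_diffuse, i, s.n_slides),
                n_caa=_ramp(s.max_caa, i, s.n_slides),
                tissue_fraction=s.tissue_fraction, seed=seed + i)
            slide, truth = synth_mod.make_slide(spec, slide_id=f"slide_{i:02d}")
            synth_mod.write_slide(slide, out / "slides" / f"slide_{i:02d}.png")
            for t in truth:
                truth_rows.append({"slide_id": slide.slide_id, "class": t.class_label,
                                   "y0": t.bbox[0], "x0": t.bbox[1],
                                   "y1": t.bbox[2], "x1": t.bbox[3],
                                   "stained_area_px": t.stained_area_px})
        pd.DataFrame(truth_rows, columns=["slide_id", "class", "y0", "x0", "y1", "x1",
                                          "stained_area_px"]).to_csv(
            out / "slides" / "ground_truth.csv", index=False)
        pairs = synth_mod.make_tile_dataset(
            (s.tiles_per_class,) * 3, n_negative=s.negative_tiles, seed=seed)
        for tile, rec in pairs:
            synth_mod.write_slide(synth_mod.SlideImage(tile, s.mpp, rec.tile_id),
                                  out / "tiles" / f"{rec.tile_id}.png")
        data_mod.write_annotations([r for _, r in pairs], out / "annotations.csv")

    stage("synth", slide_files + ["slides/ground_truth.csv", "annotations.csv"], do_synth)

    def do_preprocess(seed):
        ref_slide = synth_mod.read_slide(out / "slides" / "slide_00.png", mpp=s.mpp)
        reference = pp_mod.color_stats(ref_slide, config.preprocess.colorspace)
        rows = []
        tissue_rows = []
        for i in range(s.n_slides):
            slide = synth_mod.read_slide(out / "slides" / f"slide_{i:02d}.png",
                                         mpp=s.mpp, slide_id=f"slide_{i:02d}")
            cands, _ = pp_mod.candidates_from_slide(slide, config.preprocess, reference)
            for c in cands:
                rows.append({"slide_id": c.slide_id,
                             "centroid_row": c.centroid[0], "centroid_col": c.centroid[1],
                             "y0": c.bbox[0], "x0": c.bbox[1], "y1": c.bbox[2],
                             "x1": c.bbox[3], "area_px": c.stained_area_px})
            area_px, area_mm2 = pp_mod.tissue_area(slide, config.preprocess)
            tissue_rows.append({"slide_id": slide.slide_id, "tissue_px": area_px,
                                "tissue_mm2": area_mm2})
        pd.DataFrame(rows, columns=["slide_id", "centroid_row", "centroid_col",
                                    "y0", "x0", "y1", "x1", "area_px"]).to_csv(
            out / "candidates.csv", index=False)
        pd.DataFrame(tissue_rows).to_csv(out / "tissue_area.csv", index=False)

    stage("preprocess", ["candidates.csv", "tissue_area.csv"], do_preprocess)

    def do_split(seed):
        records = data_mod.read_annotations(out / "annotations.csv")
        split = data_mod.split_by_slide(records, config.dataset.fractions, seed)
        data_mod.write_split(split, out / "split.csv")

    stage("split", ["split.csv"], do_split)

    def _load_tiles(records):
        tiles = np.stack([synth_mod.read_slide(out / "tiles" / f"{r.tile_id}.png").pixels
                          for r in records])
        return tiles, data_mod.label_matrix(records)

    def do_train(seed):
        records = data_mod.trainable(data_mod.read_annotations(out / "annotations.csv"))
        split = data_mod.read_split(out / "split.csv")
        train_recs = [r for r in records if split.for_record(r) == "train"]
        val_recs = [r for r in records if split.for_record(r) == "validation"]
        if not train_recs:
            raise PipelineError("train", "empty-dataset", "no training records after split")
        tiles, labels = _load_tiles(train_recs)
        vtiles, vlabels = (None, None)
        if val_recs:
            vtiles, vlabels = _load_tiles(val_recs)
        mdl = model_mod.build_model(
            model_mod.ModelConfig(**{**config.model.__dict__, "seed": seed}))
        tc = model_mod.TrainConfig(**{**config.train.__dict__, "seed": seed})
        weights = data_mod.oversample_weights(train_recs)
        aug = config.dataset.augment
        mdl, history = model_mod.train(
            mdl, tiles, labels, tc, sample_weights=weights,
            augment_fn=lambda t, sd: data_mod.augment(t, sd, aug),
            val_tiles=vtiles, val_labels=vlabels)
        model_mod.save_checkpoint(mdl, out / "model")
        history.to_csv(out / "history.csv", index=False)

    stage("train", ["model.npz", "model.json", "history.csv"], do_train)

    def do_evaluate(seed):
        records = data_mod.trainable(data_mod.read_annotations(out / "annotations.csv"))
        split = data_mod.read_split(out / "split.csv")
        val_recs = [r for r in records if split.for_record(r) == "validation"] or records
        tiles, labels = _load_tiles(val_recs)
        mdl = model_mod.load_checkpoint(out / "model")
        conf = model_mod.predict_batch(mdl, tiles)
        metrics = {"n_tiles": len(val_recs),
                   "accuracy": eval_mod.multilabel_accuracy(conf, labels)}
        for k, task in enumerate(model_mod.TASKS):
            truth = labels[:, k]
            if truth.min() == truth.max():
                metrics[task] = {"auroc": None, "aupr": None}
            else:
                metrics[task] = {"auroc": eval_mod.auroc(conf[:, k], truth),
                                 "aupr": eval_mod.aupr(conf[:, k], truth)}
        pd.DataFrame([{"tile_id": r.tile_id, **dict(zip(model_mod.TASKS, c))}
                      for r, c in zip(val_recs, conf)]).to_csv(
            out / "predictions.csv", index=False)
        (out / "metrics.json").write_text(json.dumps(metrics, indent=2))

    stage("evaluate", ["metrics.json", "predictions.csv"], do_evaluate)

    heatmap_artifacts = []
    for i in range(s.n_slides):
        heatmap_artifacts += [f"heatmaps/slide_{i:02d}_{t}.npy" for t in model_mod.TASKS]
        heatmap_artifacts.append(f"heatmaps/slide_{i:02d}.json")

    def do_heatmap(seed):
        (out / "heatmaps").mkdir(exist_ok=True)
        mdl = model_mod.load_checkpoint(out / "model")
        for i in range(s.n_slides):
            slide = synth_mod.read_slide(out / "slides" / f"slide_{i:02d}.png",
                                         mpp=s.mpp, slide_id=f"slide_{i:02d}")
            grid = heatmap_mod.sliding_window_map(
                mdl, slide.pixels, config.heatmap.stride_px, batch=1,
                slide_id=slide.slide_id)
            heatmap_mod.save_heatmap(grid, out / "heatmaps" / f"slide_{i:02d}")
        heatmap_mod.render_heatmap(grid, out / "heatmaps" / "last_slide.png")

    stage("heatmap", heatmap_artifacts + ["heatmaps/last_slide.png"], do_heatmap)

    def do_score(seed):
        tissue = pd.read_csv(out / "tissue_area.csv").set_index("slide_id")
        truth = pd.read_csv(out / "slides" / "ground_truth.csv")
        rows = []
        for i in range(s.n_slides):
            sid = f"slide_{i:02d}"
            grid = heatmap_mod.load_heatmap(out / "heatmaps" / sid)
            counts = {t: scoring_mod.segment_heatmap(grid, t, config.scoring)
                      for t in model_mod.TASKS}
            area = float(tissue.loc[sid, "tissue_mm2"])
            score = scoring_mod.wsi_score(sid, counts, area)
            planted = int(((truth["slide_id"] == sid) & (truth["class"] == "cored")).sum())
            rows.append({"slide_id": sid, **{f"{t}_count": counts[t] for t in model_mod.TASKS},
                         "tissue_mm2": area,
                         **{f"{t}_per_mm2": score.scores[t] for t in model_mod.TASKS},
                         "planted_cored": planted,
                         "planted_category": scoring_mod.density_category(planted / area)})
        df = pd.DataFrame(rows)
        df.to_csv(out / "scores.csv", index=False)
        stats = {}
        cats = df["planted_category"].to_numpy()
        if len(df) >= 3 and np.ptp(cats) > 0 and np.ptp(df["cored_per_mm2"].to_numpy()) > 0:
            stats["spearman_cored"] = scoring_mod.spearman(df["cored_per_mm2"], cats)
        groups = {int(c): df.loc[df["planted_category"] == c, "cored_per_mm2"].to_numpy()
                  for c in sorted(set(cats))}
        try:
            stats["ttest_p"] = scoring_mod.pairwise_ttests(groups).to_dict()
        except ValueError:
            stats["ttest_p"] = None
        (out / "stats.json").write_text(json.dumps(stats, indent=2))

    stage("score", ["scores.csv", "stats.json"], do_score)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    log.removeHandler(handler)
    handler.close()
    return manifest
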