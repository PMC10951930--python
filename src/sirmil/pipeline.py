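"""End-to-end experiment plumbing: cohort -> tiles -> bags -> folds -> model.

These helpers wire the pipeline stages together for scripted experiments on
synthetic cohorts and back the command-line interface.  Tile rasters are
cached per slide at the encoder input resolution, so RED-1 and RAND-n bag
sets can be built from the same tiling without re-reading slides.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import slideio
from .bagbuild import Bag, BagSetConfig, build_bags, resize_tile
from .evaluation import EvalReport, compute_metrics, predict_wsi
from .milmodel import MILModel
from .slideio import SlideRecord, TileRecord
from .synthdata import SynthConfig, generate_cohort
from .training import BagItem, FoldAssignment, TrainConfig, stratified_folds, train_model

__all__ = [
    "CohortData",
    "prepare_cohort",
    "load_cohort",
    "build_bag_items",
    "run_fold",
    "run_experiment",
    "normalize_tile",
]

LABEL_TO_INT = {"mild": 0, "severe": 1}


def normalize_tile(tile_rgb_uint8: np.ndarray) -> np.ndarray:
    """uint8 (H, W, 3) -> float64 (3, H, W) in [-0.5, 0.5]."""
    return np.transpose(tile_rgb_uint8.astype(np.float64) / 255.0 - 0.5, (2, 0, 1))


@dataclass
class CohortData:
    """Tiled cohort: slide records, their valid tiles, and tile rasters."""

    records: list[SlideRecord]
    valid_tiles: dict[str, list[TileRecord]]
    tile_arrays: dict[str, dict[tuple[int, int], np.ndarray]]  # uint8 (r, r, 3)
    tile_manifest: pd.DataFrame


def load_cohort(
    records: Sequence[SlideRecord],
    tile_side: int,
    overlap: float = 0.5,
    resize_px: int = 224,
    init_threshold: float = 0.5,
    min_tiles: int = 10,
) -> CohortData:
    """Tile every slide, keep the valid tiles and their resized rasters."""
    valid_tiles: dict[str, list[TileRecord]] = {}
    tile_arrays: dict[str, dict[tuple[int, int], np.ndarray]] = {}
    frames = []
    for rec in records:
        image = slideio.read_image(rec.image_ref)
        mask = slideio.read_mask(rec.mask_ref) if rec.mask_ref else None
        frame = slideio.tile_slide(
            rec, side_px=tile_side, overlap=overlap, image=image, mask=mask,
            init_threshold=init_threshold, min_tiles=min_tiles,
        )
        frames.append(frame)
        tiles = slideio.tile_records_from_frame(frame, valid_only=True)
        valid_tiles[rec.slide_id] = tiles
        tile_arrays[rec.slide_id] = {
            (t.x, t.y): resize_tile(
                slideio.extract_tile(image, t.x, t.y, tile_side), resize_px
            )
            for t in tiles
        }
    manifest = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    return CohortData(
        records=list(records),
        valid_tiles=valid_tiles,
        tile_arrays=tile_arrays,
        tile_manifest=manifest,
    )


def prepare_cohort(
    synth_cfg: SynthConfig,
    out_dir: str | Path,
    resize_px: int = 32,
    overlap: float = 0.5,
    min_tiles: int = 10,
) -> CohortData:
    """Generate a synthetic cohort and tile it at the generator's tile side."""
    out_dir = Path(out_dir)
    generate_cohort(synth_cfg, out_dir)
    records = slideio.read_cohort_manifest(out_dir / "manifest.csv")
    return load_cohort(
        records,
        tile_side=synth_cfg.tile_px,
        overlap=overlap,
        resize_px=resize_px,
        min_tiles=min_tiles,
    )


def build_bag_items(
    cohort: CohortData, bag_cfg: BagSetConfig
) -> tuple[dict[str, list[tuple[Bag, np.ndarray]]], list[BagItem]]:
    """Assemble bags (and their tile stacks) for every slide of a cohort."""
    by_slide: dict[str, list[tuple[Bag, np.ndarray]]] = {}
    items: list[BagItem] = []
    for i, rec in enumerate(sorted(cohort.records, key=lambda r: r.slide_id)):
        tiles = cohort.valid_tiles[rec.slide_id]
        bags = build_bags(tiles, bag_cfg, proxy_label=rec.label, slide_seed=i)
        arrays = []
        for bag in bags:
            stack = np.stack(
                [normalize_tile(cohort.tile_arrays[rec.slide_id][(t.x, t.y)]) for t in bag.tiles]
            )
            arrays.append(stack)
            items.append(
                BagItem(
                    bag_id=bag.bag_id,
                    slide_id=rec.slide_id,
                    label=LABEL_TO_INT[rec.label],
                    tiles=stack,
                )
            )
        by_slide[rec.slide_id] = list(zip(bags, arrays))
    return by_slide, items


def run_fold(
    cohort: CohortData,
    by_slide: dict[str, list[tuple[Bag, np.ndarray]]],
    items: Sequence[BagItem],
    fold: FoldAssignment,
    train_cfg: TrainConfig,
    model_kwargs: dict | None = None,
    augment: bool = False,
    threshold: float = 0.5,
) -> dict:
    """Train on one fold and score its test slides with one-wins-all."""
    part = fold.partition
    train_items = [it for it in items if part[it.slide_id] == "train"]
    val_items = [it for it in items if part[it.slide_id] == "val"]
    model = MILModel(**(model_kwargs or {}))
    model, log = train_model(train_items, val_items, model, train_cfg, augment=augment)

    labels = {r.slide_id: LABEL_TO_INT[r.label] for r in cohort.records}
    y_true, y_pred, scores, preds = [], [], [], []
    for sid in fold.test_ids:
        bags = [b for b, _ in by_slide[sid]]
        arrays = [a for _, a in by_slide[sid]]
        pred = predict_wsi(model, bags, arrays, threshold=threshold)
        y_true.append(labels[sid])
        y_pred.append(1 if pred.wsi_label_hat == "severe" else 0)
        scores.append(pred.wsi_score)
        preds.append({"slide_id": sid, "wsi_score": pred.wsi_score,
                      "label_hat": pred.wsi_label_hat, "label": labels[sid]})
    return {
        "model": model,
        "log": log,
        "y_true": y_true,
        "y_pred": y_pred,
        "scores": scores,
        "predictions": pd.DataFrame(preds),
    }


def run_experiment(
    synth_cfg: SynthConfig,
    bag_cfg: BagSetConfig,
    train_cfg: TrainConfig,
    out_dir: str | Path,
    model_kwargs: dict | None = None,
    resize_px: int = 32,
    n_folds: int = 5,
    folds_to_run: Sequence[int] = (1,),
    min_tiles: int = 10,
    augment: bool = False,
    cohort: CohortData | None = None,
) -> dict:
    """Full synthetic experiment; trains the requested folds and reports.

    Returns a dict with the tiled cohort (reusable across bag modes), the
    per-fold results, and the aggregated EvalReport over the trained folds.
    """
    if cohort is None:
        cohort = prepare_cohort(synth_cfg, out_dir, resize_px=resize_px, min_tiles=min_tiles)
    by_slide, items = build_bag_items(cohort, bag_cfg)
    folds = stratified_folds(cohort.records, n_folds=n_folds, seed=train_cfg.seed)
    fold_results = {}
    triples = []
    for fid in folds_to_run:
        fold = folds[fid - 1]
        res = run_fold(cohort, by_slide, items, fold, train_cfg,
                       model_kwargs=model_kwargs, augment=augment)
        fold_results[fid] = res
        triples.append((res["y_true"], res["y_pred"], res["scores"]))
    report = compute_metrics(triples)
    return {"cohort": cohort, "folds": folds, "fold_results": fold_results, "report": report}
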