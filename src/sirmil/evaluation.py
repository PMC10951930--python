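"""Slide-level inference, the metric panel, and attention export.

A slide with n bags gets n bag-level probabilities; the slide score is
their maximum ("one wins all": the most severe bag decides), thresholded at
0.5 for the binary call with severe as the positive class.

Metrics follow the usual two-tier reporting for small cohorts: Accuracy and
F1 per fold (mean +/- sample sd across folds, to show reproducibility) and
Recall, Specificity, Precision, F2 and MCC on the confusion matrix summed
over the folds; AUC is computed on the pooled test scores.  Metrics with a
zero denominator are reported as NaN, never silently as 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image
from sklearn.metrics import roc_auc_score

from .bagbuild import Bag
from .milmodel import MILModel
from .slideio import SlideRecord

__all__ = [
    "SlidePrediction",
    "EvalReport",
    "predict_wsi",
    "confusion_matrix",
    "compute_metrics",
    "export_attention",
]

DEFAULT_THRESHOLD = 0.5


@dataclass(frozen=True)
class SlidePrediction:
    """One slide's bag probabilities and one-wins-all decision."""

    slide_id: str
    bag_probabilities: np.ndarray
    threshold: float = DEFAULT_THRESHOLD

    @property
    def wsi_score(self) -> float:
        return float(np.max(self.bag_probabilities))

    @property
    def wsi_label_hat(self) -> str:
        return "severe" if self.wsi_score >= self.threshold else "mild"


def predict_wsi(
    model: MILModel,
    bags: Sequence[Bag],
    bag_arrays: Sequence[np.ndarray],
    threshold: float = DEFAULT_THRESHOLD,
) -> SlidePrediction:
    """One inference pass per bag, then one-wins-all over the bag scores."""
    if len(bags) == 0:
        raise ValueError("need at least one bag")
    if len(bags) != len(bag_arrays):
        raise ValueError("bags and bag_arrays must align")
    slide_ids = {b.slide_id for b in bags}
    if len(slide_ids) != 1:
        raise ValueError(f"bags span multiple slides: {sorted(slide_ids)}")
    probs = np.array([model.predict_bag(arr).probability for arr in bag_arrays])
    return SlidePrediction(
        slide_id=bags[0].slide_id, bag_probabilities=probs, threshold=threshold
    )


# ---------------------------------------------------------------------------
# metric panel
# ---------------------------------------------------------------------------

def confusion_matrix(y_true: Sequence[int], y_pred: Sequence[int]) -> dict[str, int]:
    """TP/FP/TN/FN with severe (1) as the positive class."""
    yt = np.asarray(y_true, dtype=int)
    yp = np.asarray(y_pred, dtype=int)
    return {
        "TP": int(np.sum((yt == 1) & (yp == 1))),
        "FP": int(np.sum((yt == 0) & (yp == 1))),
        "TN": int(np.sum((yt == 0) & (yp == 0))),
        "FN": int(np.sum((yt == 1) & (yp == 0))),
    }


def _safe_div(num: float, den: float) -> float:
    return num / den if den != 0 else float("nan")


def matrix_metrics(m: dict[str, int]) -> dict[str, float]:
    """Standard panel from one confusion matrix; NaN marks undefined values."""
    tp, fp, tn, fn = m["TP"], m["FP"], m["TN"], m["FN"]
    n = tp + fp + tn + fn
    precision = _safe_div(tp, tp + fp)
    recall = _safe_div(tp, tp + fn)
    specificity = _safe_div(tn, tn + fp)

    def f_beta(beta: float) -> float:
        if not (np.isfinite(precision) and np.isfinite(recall)):
            return float("nan")
        return _safe_div((1 + beta**2) * precision * recall, beta**2 * precision + recall)

    mcc_den = np.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    return {
        "accuracy": _safe_div(tp + tn, n),
        "precision": precision,
        "recall": recall,
        "specificity": specificity,
        "f1": f_beta(1.0),
        "f2": f_beta(2.0),
        "mcc": _safe_div(tp * tn - fp * fn, mcc_den),
    }


@dataclass
class EvalReport:
    """Per-fold and aggregated evaluation results."""

    per_fold: list[dict]
    aggregated: dict

    def to_json(self, path: str | Path | None = None) -> str:
        def sanitize(obj):
            if isinstance(obj, float) and not np.isfinite(obj):
                return None
            if isinstance(obj, dict):
                return {k: sanitize(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [sanitize(v) for v in obj]
            return obj

        payload = json.dumps(
            sanitize({"per_fold": self.per_fold, "aggregated": self.aggregated}),
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


def compute_metrics(
    per_fold: Sequence[tuple[Sequence[int], Sequence[int], Sequence[float]]],
    pooled_auc: bool = True,
) -> EvalReport:
    """Metric panel from per-fold (truth, prediction, score) triples.

    Accuracy and F1 are reported per fold with mean and sample (n-1) sd;
    the remaining panel is computed on the entrywise sum of the per-fold
    confusion matrices.  AUC uses the rank statistic on the pooled scores
    (or, with ``pooled_auc=False``, the mean of per-fold AUCs).
    """
    folds = []
    agg = {"TP": 0, "FP": 0, "TN": 0, "FN": 0}
    pooled_truth: list[int] = []
    pooled_scores: list[float] = []
    fold_aucs = []
    for f, (yt, yp, ys) in enumerate(per_fold, start=1):
        m = confusion_matrix(yt, yp)
        panel = matrix_metrics(m)
        folds.append({"fold": f, "confusion": m,
                      "accuracy": panel["accuracy"], "f1": panel["f1"]})
        for key in agg:
            agg[key] += m[key]
        pooled_truth.extend(int(v) for v in yt)
        pooled_scores.extend(float(v) for v in ys)
        fold_aucs.append(
            roc_auc_score(yt, ys) if len(set(map(int, yt))) == 2 else float("nan")
        )

    accs = np.array([f["accuracy"] for f in folds], dtype=float)
    f1s = np.array([f["f1"] for f in folds], dtype=float)
    agg_panel = matrix_metrics(agg)
    if len(set(pooled_truth)) == 2:
        auc = (
            float(roc_auc_score(pooled_truth, pooled_scores))
            if pooled_auc
            else float(np.nanmean(fold_aucs))
        )
    else:
        auc = float("nan")
    aggregated = {
        "confusion": agg,
        "accuracy_mean": float(np.nanmean(accs)),
        "accuracy_sd": float(np.nanstd(accs, ddof=1)) if len(accs) > 1 else float("nan"),
        "f1_mean": float(np.nanmean(f1s)) if np.isfinite(f1s).any() else float("nan"),
        "f1_sd": float(np.nanstd(f1s, ddof=1)) if len(f1s) > 1 else float("nan"),
        "recall": agg_panel["recall"],
        "specificity": agg_panel["specificity"],
        "precision": agg_panel["precision"],
        "f2": agg_panel["f2"],
        "mcc": agg_panel["mcc"],
        "accuracy_aggregated": agg_panel["accuracy"],
        "f1_aggregated": agg_panel["f1"],
        "auc": auc,
    }
    return EvalReport(per_fold=folds, aggregated=aggregated)


# ---------------------------------------------------------------------------
# attention export
# ---------------------------------------------------------------------------

def export_attention(
    model: MILModel,
    slide: SlideRecord,
    bags: Sequence[Bag],
    bag_arrays: Sequence[np.ndarray],
    out_dir: str | Path | None = None,
    top_n: int = 10,
    tile_images: Sequence[Sequence[np.ndarray]] | None = None,
) -> pd.DataFrame:
    """Rank every tile in a slide's bags by its attention weight.

    Returns a frame (slide_id, bag_id, x, y, attention, bag_probability)
    sorted by descending attention.  With ``out_dir`` set, writes the CSV
    and — when the raw tile rasters are supplied — PNGs of the ``top_n``
    highest-attention tiles, the review artefact clinicians inspect.
    """
    if model.aggregation != "gated_attention":
        raise ValueError(
            "attention export requires a gated-attention model; "
            "max-pooling models have no attention weights"
        )
    rows = []
    for bag, arr in zip(bags, bag_arrays):
        if bag.slide_id != slide.slide_id:
            raise ValueError("bag does not belong to the given slide")
        out = model.predict_bag(arr)
        for t, tile in enumerate(bag.tiles):
            rows.append(
                {
                    "slide_id": slide.slide_id,
                    "bag_id": bag.bag_id,
                    "tile_index": t,
                    "x": tile.x,
                    "y": tile.y,
                    "attention": float(out.attention[t]),
                    "bag_probability": out.probability,
                }
            )
    df = (
        pd.DataFrame(rows)
        .sort_values("attention", ascending=False, kind="stable")
        .reset_index(drop=True)
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        df.to_csv(out_dir / f"{slide.slide_id}_attention.csv", index=False)
        if tile_images is not None:
            lookup = {
                (bag.bag_id, t): img
                for bag, imgs in zip(bags, tile_images)
                for t, img in enumerate(imgs)
            }
            for rank, row in df.head(top_n).iterrows():
                img = lookup.get((row.bag_id, int(row.tile_index)))
                if img is not None:
                    Image.fromarray(np.asarray(img).astype(np.uint8)).save(
                        out_dir / f"{slide.slide_id}_top{rank:02d}_{row.bag_id}_t{int(row.tile_index)}.png"
                    )
    return df
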