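"""One-wins-all inference, the metric panel, and attention export."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from sirmil.bagbuild import BagSetConfig
from sirmil.evaluation import (
    SlidePrediction,
    compute_metrics,
    confusion_matrix,
    export_attention,
    matrix_metrics,
    predict_wsi,
)
from sirmil.milmodel import MILModel
from sirmil.pipeline import build_bag_items, load_cohort, normalize_tile, run_fold
from sirmil.synthdata import SynthConfig, generate_cohort
from sirmil.training import TrainConfig, stratified_folds
from sirmil import slideio


class TestSlidePrediction:
    def test_one_wins_all(self):
        pred = SlidePrediction("s", np.array([0.1, 0.2, 0.9]))
        assert pred.wsi_score == 0.9
        assert pred.wsi_label_hat == "severe"

    def test_all_below_threshold_is_mild(self):
        pred = SlidePrediction("s", np.array([0.1, 0.45, 0.3]))
        assert pred.wsi_label_hat == "mild"

    def test_single_bag_decision_equals_bag_decision(self):
        assert SlidePrediction("s", np.array([0.6])).wsi_label_hat == "severe"
        assert SlidePrediction("s", np.array([0.4])).wsi_label_hat == "mild"


class TestPredictWsi:
    def test_score_is_max_of_bag_probabilities(self, small_cohort):
        model = MILModel(backbone="tiny_cnn", attention_dim=8, seed=0)
        by_slide, _ = build_bag_items(small_cohort, BagSetConfig(k=5, mode="randn", seed=0))
        sid = small_cohort.records[0].slide_id
        bags = [b for b, _ in by_slide[sid]]
        arrays = [a for _, a in by_slide[sid]]
        pred = predict_wsi(model, bags, arrays)
        per_bag = [model.predict_bag(a).probability for a in arrays]
        assert pred.wsi_score == pytest.approx(max(per_bag), abs=1e-12)
        assert len(pred.bag_probabilities) == len(bags)

    def test_monotone_under_added_bags(self, small_cohort):
        """Adding a bag never flips a severe call back to mild."""
        model = MILModel(backbone="tiny_cnn", attention_dim=8, seed=0)
        by_slide, _ = build_bag_items(small_cohort, BagSetConfig(k=5, mode="randn", seed=0))
        sid = small_cohort.records[0].slide_id
        bags = [b for b, _ in by_slide[sid]]
        arrays = [a for _, a in by_slide[sid]]
        for n in range(1, len(bags)):
            a = predict_wsi(model, bags[:n], arrays[:n])
            b = predict_wsi(model, bags[: n + 1], arrays[: n + 1])
            assert b.wsi_score >= a.wsi_score

    def test_mixed_slides_rejected(self, small_cohort):
        model = MILModel(backbone="tiny_cnn", seed=0)
        by_slide, _ = build_bag_items(small_cohort, BagSetConfig(k=5, mode="randn", seed=0))
        (s1, s2) = (small_cohort.records[0].slide_id, small_cohort.records[1].slide_id)
        bags = [by_slide[s1][0][0], by_slide[s2][0][0]]
        arrays = [by_slide[s1][0][1], by_slide[s2][0][1]]
        with pytest.raises(ValueError, match="multiple slides"):
            predict_wsi(model, bags, arrays)


class TestMetricPanel:
    def test_perfect_classifier(self):
        yt = [1] * 76 + [0] * 76
        ys = [0.9] * 76 + [0.1] * 76
        report = compute_metrics([(yt, yt, ys)])
        agg = report.aggregated
        for key in ("recall", "specificity", "precision", "f2", "mcc", "auc",
                    "accuracy_mean", "f1_mean"):
            assert agg[key] == pytest.approx(1.0)
        assert agg["confusion"] == {"TP": 76, "FP": 0, "TN": 76, "FN": 0}

    def test_recall_matches_known_split(self):
        """49 of 76 severe slides detected gives a recall of 64.47%."""
        m = {"TP": 49, "FN": 27, "FP": 0, "TN": 0}
        assert matrix_metrics(m)["recall"] * 100 == pytest.approx(64.47, abs=0.005)

    def test_hand_evaluated_matrix(self):
        panel = matrix_metrics({"TP": 3, "FP": 1, "TN": 4, "FN": 2})
        assert panel["precision"] == pytest.approx(0.75)
        assert panel["recall"] == pytest.approx(0.6)
        assert panel["f1"] == pytest.approx(2 / 3, rel=1e-6)
        assert panel["f2"] == pytest.approx(0.625)
        assert panel["mcc"] == pytest.approx(10 / np.sqrt(600), rel=1e-9)

    def test_undefined_metrics_are_nan_not_zero(self):
        panel = matrix_metrics({"TP": 0, "FP": 0, "TN": 5, "FN": 0})
        assert np.isnan(panel["precision"])
        assert np.isnan(panel["recall"])
        assert panel["specificity"] == 1.0

    def test_aggregated_matrix_is_sum_of_folds(self):
        rng = np.random.default_rng(0)
        per_fold = []
        for _ in range(5):
            yt = rng.integers(0, 2, size=12).tolist()
            yp = rng.integers(0, 2, size=12).tolist()
            ys = rng.uniform(size=12).tolist()
            if len(set(yt)) < 2:
                yt[0], yt[1] = 0, 1
            per_fold.append((yt, yp, ys))
        report = compute_metrics(per_fold)
        total = {"TP": 0, "FP": 0, "TN": 0, "FN": 0}
        for yt, yp, _ in per_fold:
            m = confusion_matrix(yt, yp)
            for key in total:
                total[key] += m[key]
        assert report.aggregated["confusion"] == total
        accs = [f["accuracy"] for f in report.per_fold]
        assert report.aggregated["accuracy_sd"] == pytest.approx(np.std(accs, ddof=1))

    def test_auc_extremes(self):
        yt = [1, 1, 0, 0]
        perfect = compute_metrics([(yt, yt, [0.8, 0.7, 0.2, 0.1])])
        constant = compute_metrics([(yt, yt, [0.5, 0.5, 0.5, 0.5])])
        assert perfect.aggregated["auc"] == 1.0
        assert constant.aggregated["auc"] == 0.5

    def test_json_export_handles_nan(self, tmp_path):
        report = compute_metrics([(([1, 1]), ([0, 0]), ([0.1, 0.2]))])
        text = report.to_json(tmp_path / "r.json")
        assert "NaN" not in text


class TestExportAttention:
    def test_uniform_attention_for_identical_tiles(self, small_cohort, rng):
        model = MILModel(backbone="tiny_cnn", attention_dim=8, seed=1)
        rec = small_cohort.records[0]
        tiles = small_cohort.valid_tiles[rec.slide_id][:1] * 6
        from sirmil.bagbuild import Bag

        bag = Bag("b0", rec.slide_id, tuple(tiles), rec.label)
        arr = np.repeat(
            normalize_tile(small_cohort.tile_arrays[rec.slide_id][(tiles[0].x, tiles[0].y)])[None],
            6, axis=0,
        )
        df = export_attention(model, rec, [bag], [arr])
        np.testing.assert_allclose(df["attention"], 1 / 6, atol=1e-9)

    def test_sorted_descending_and_csv_written(self, small_cohort, tmp_path):
        model = MILModel(backbone="tiny_cnn", attention_dim=8, seed=1)
        rec = small_cohort.records[0]
        by_slide, _ = build_bag_items(small_cohort, BagSetConfig(k=5, mode="randn", seed=1))
        bags = [b for b, _ in by_slide[rec.slide_id]]
        arrays = [a for _, a in by_slide[rec.slide_id]]
        df = export_attention(model, rec, bags, arrays, out_dir=tmp_path)
        assert (df["attention"].values[:-1] >= df["attention"].values[1:]).all()
        assert (tmp_path / f"{rec.slide_id}_attention.csv").exists()

    def test_max_pool_model_rejected(self, small_cohort):
        model = MILModel(backbone="tiny_cnn", aggregation="max_pool", seed=0)
        rec = small_cohort.records[0]
        with pytest.raises(ValueError, match="attention"):
            export_attention(model, rec, [], [])

    def test_trained_model_attends_to_bridging_lesion(self, tmp_path):
        """After training, a severe slide's single bridge tile ranks in the
        top-10 attention export in at least 8 of 10 seeded runs."""
        synth = SynthConfig(n_slides=8, class_balance=0.5, tile_px=64, seed=21,
                            lesion_density=0.1)
        cohort_dir = tmp_path / "cohort"
        generate_cohort(synth, cohort_dir)
        records = slideio.read_cohort_manifest(cohort_dir / "manifest.csv")
        cohort = load_cohort(records, tile_side=64, resize_px=32)
        hits = 0
        for seed in range(10):
            by_slide, items = build_bag_items(cohort, BagSetConfig(k=5, mode="randn", seed=seed))
            model = MILModel(backbone="tiny_cnn", attention_dim=32, seed=seed)
            from sirmil.training import train_model

            cfg = TrainConfig(encoder_lr=1e-3, head_lr=1e-3, max_epochs=6, patience=6,
                              batch_size_bags=6, seed=seed)
            model, _ = train_model(items, [], model, cfg, augment=True)
            # severe slide with its ground-truth bridge map
            import json as _json

            severe = next(r for r in records if r.label == "severe")
            truth = _json.loads((cohort_dir / f"{severe.slide_id}_truth.json").read_text())
            bridges = [l for l in truth["lesions"] if l["kind"] == "bridge"]
            bags = [b for b, _ in by_slide[severe.slide_id]]
            arrays = [a for _, a in by_slide[severe.slide_id]]
            df = export_attention(model, severe, bags, arrays)

            def tile_hits_bridge(x, y, side=64):
                for lesion in bridges:
                    for px, py, r in lesion["disks"]:
                        if x - r <= px <= x + side + r and y - r <= py <= y + side + r:
                            return True
                return False

            top = df.head(10)
            hits += any(tile_hits_bridge(r.x, r.y) for r in top.itertuples())
        assert hits >= 8
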