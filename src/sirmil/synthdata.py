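"""Synthetic Sirius-Red-like slide generator.

Produces seeded RGB slides that mimic the appearance regularities the
pipeline relies on: green or yellow counterstained tissue cores on a grey
or pale-blue background, compact red "portal tract" blobs in both classes
(natural collagen — a confounder for naive red quantification), and
elongated red "bridging" lesions only on severe slides.  Optional artifacts
reproduce common failure modes of retrospective clinical material: a large
red vein streak, crumbling (fragmented) tissue, and faded stain.

Every slide is generated from a seed and is pixel-identical across runs.
Ground truth (tissue mask, lesion inventory, label) is stored alongside so
tests can validate maskers, red scoring, and attention exports against it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .slideio import COLOR_CATEGORIES, LABELS

__all__ = ["SynthConfig", "SynthTruth", "generate_slide", "generate_cohort", "allocate_labels"]

# Cohort appearance: tissue/background colours per category.  Only the
# ordinal relations (red vs non-red, saturated tissue vs pale background)
# matter to the pipeline, so flat colours plus Gaussian noise suffice.
CATEGORY_COLORS: dict[str, dict[str, tuple[int, int, int]]] = {
    "green_grey": {"tissue": (90, 140, 90), "background": (200, 200, 200)},
    "green_blue": {"tissue": (90, 140, 90), "background": (190, 200, 225)},
    "yellow_grey": {"tissue": (180, 170, 90), "background": (200, 200, 200)},
}
RED = (180, 40, 40)

# Category frequencies of the modelled cohort: 75 green/grey, 56 green/blue,
# 21 yellow/grey out of 152 slides.
DEFAULT_CATEGORY_WEIGHTS = (75 / 152, 56 / 152, 21 / 152)


@dataclass
class SynthConfig:
    """Cohort-level generation parameters.

    ``slide_px`` defaults to eight tile sides (tiles of ``tile_px`` on a 50%
    overlap grid then give a 15 x 15 = 225-position candidate grid, the same
    geometry as full-scale slides tiled at 1651 px).
    """

    n_slides: int = 152
    class_balance: float = 0.5          # fraction of severe slides
    category_weights: tuple[float, float, float] = DEFAULT_CATEGORY_WEIGHTS
    tile_px: int = 64                   # tile side the cohort is meant to be tiled at
    slide_px: int | None = None         # default: 8 * tile_px
    n_portal_blobs: tuple[int, int] = (3, 8)    # uniform range, both classes
    lesion_density: float = 2.0         # expected bridging lesions per severe slide
    bridge_width_px: tuple[int, int] = (3, 10)
    min_bridge_span: float = 0.20       # bridge endpoint distance, fraction of slide side
    max_bridge_span: float | None = None  # cap for sparse-signal regimes
    artifact_rate: float = 0.0          # P(slide carries a red vein streak)
    crumble_rate: float = 0.0           # P(fragmented tissue)
    fade_rate: float = 0.0              # P(faded red stain)
    noise_sigma: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.class_balance, self.artifact_rate, self.crumble_rate, self.fade_rate):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        if abs(sum(self.category_weights) - 1.0) > 1e-9:
            raise ValueError("category_weights must sum to 1")
        if self.slide_px is None:
            self.slide_px = 8 * self.tile_px
        if self.slide_px < self.tile_px:
            raise ValueError("slide_px must be at least the tile side")


@dataclass
class SynthTruth:
    """Ground truth for one generated slide."""

    slide_id: str
    label: str
    color_category: str
    tissue_mask: np.ndarray            # bool (H, W)
    lesions: list[dict] = field(default_factory=list)  # kind, points/center, size

    @property
    def n_bridges(self) -> int:
        return sum(1 for l in self.lesions if l["kind"] == "bridge")

    def lesion_mask(self, kinds: Sequence[str] = ("portal_blob", "bridge", "vein_artifact")) -> np.ndarray:
        """Rasterised union of the stored lesions of the given kinds.

        Mirrors the renderer: blobs and bridges are clipped to the tissue
        mask, vein artifacts are not.
        """
        h, w = self.tissue_mask.shape
        mask = np.zeros((h, w), dtype=bool)
        for lesion in self.lesions:
            if lesion["kind"] not in kinds:
                continue
            drawn = np.zeros((h, w), dtype=bool)
            for px, py, r in lesion["disks"]:
                _stamp_disk(drawn, px, py, r, True)
            if lesion["kind"] != "vein_artifact":
                drawn &= self.tissue_mask
            mask |= drawn
        return mask


def _stamp_disk(canvas: np.ndarray, cx: float, cy: float, r: float, value) -> None:
    h, w = canvas.shape[:2]
    x0, x1 = max(0, int(cx - r) - 1), min(w, int(cx + r) + 2)
    y0, y1 = max(0, int(cy - r) - 1), min(h, int(cy + r) + 2)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    inside = (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2
    canvas[y0:y1, x0:x1][inside] = value


def _ellipse_mask(h: int, w: int, cx: float, cy: float, ax: float, ay: float, theta: float) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    ct, st = np.cos(theta), np.sin(theta)
    u = (xx - cx) * ct + (yy - cy) * st
    v = -(xx - cx) * st + (yy - cy) * ct
    return (u / ax) ** 2 + (v / ay) ** 2 <= 1.0


def _bezier_points(p0, p1, p2, n: int = 200) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n)[:, None]
    return (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t**2 * p2


def generate_slide(
    label: str,
    color_category: str,
    cfg: SynthConfig,
    seed: int,
    slide_id: str = "synthetic",
) -> tuple[np.ndarray, SynthTruth]:
    """Render one synthetic slide and its ground truth.

    Severe slides always carry at least one bridging lesion (an elongated
    red Bezier band between two tissue-core centres); mild slides carry
    none.  Portal blobs and the optional vein artifact occur in both
    classes.  Identical ``(label, category, cfg, seed)`` give pixel-identical
    output.
    """
    if label not in LABELS:
        raise ValueError(f"unknown label {label!r}")
    if color_category not in COLOR_CATEGORIES:
        raise ValueError(f"unknown color category {color_category!r}")
    rng = np.random.default_rng(seed)
    s = int(cfg.slide_px)
    colors = CATEGORY_COLORS[color_category]

    # --- tissue cores: 2-3 elongated strips (needle-biopsy cores) ----------
    n_cores = int(rng.integers(2, 4))
    tissue = np.zeros((s, s), dtype=bool)
    core_masks: list[np.ndarray] = []
    for _ in range(n_cores):
        cx, cy = rng.uniform(0.2 * s, 0.8 * s, size=2)
        ax = rng.uniform(0.25 * s, 0.42 * s)
        ay = rng.uniform(0.05 * s, 0.10 * s)
        theta = rng.uniform(0, np.pi)
        core = _ellipse_mask(s, s, cx, cy, ax, ay, theta)
        core_masks.append(core)
        tissue |= core

    lesions: list[dict] = []

    def _point_in(mask: np.ndarray) -> tuple[float, float]:
        for _ in range(1000):
            x, y = rng.uniform(0, s, size=2)
            if mask[int(y), int(x)]:
                return x, y
        ys, xs = np.nonzero(mask)
        i = int(rng.integers(len(xs)))
        return float(xs[i]), float(ys[i])

    def _in_tissue_point() -> tuple[float, float]:
        return _point_in(tissue)

    # --- portal blobs (both classes) ---------------------------------------
    n_blobs = int(rng.integers(cfg.n_portal_blobs[0], cfg.n_portal_blobs[1] + 1))
    for _ in range(n_blobs):
        x, y = _in_tissue_point()
        r = rng.uniform(0.008 * s, 0.02 * s)
        lesions.append({"kind": "portal_blob", "disks": [(x, y, r)]})

    # --- bridging lesions (severe only) ------------------------------------
    if label == "severe":
        n_bridges = max(1, int(rng.poisson(cfg.lesion_density)))
        for _ in range(n_bridges):
            # bridging connects structures within one tissue core, so both
            # endpoints are drawn from the same core and the band stays in tissue
            core = core_masks[int(rng.integers(len(core_masks)))]
            x0, y0 = _point_in(core)
            x1, y1 = _point_in(core)
            # re-draw endpoints until the bridge spans the configured range
            lo = cfg.min_bridge_span * s
            hi = cfg.max_bridge_span * s if cfg.max_bridge_span is not None else np.inf
            for _ in range(200):
                if lo <= np.hypot(x1 - x0, y1 - y0) <= hi:
                    break
                x1, y1 = _point_in(core)
            mid = np.array([(x0 + x1) / 2, (y0 + y1) / 2]) + rng.uniform(-0.05 * s, 0.05 * s, 2)
            pts = _bezier_points(np.array([x0, y0]), mid, np.array([x1, y1]))
            width = rng.uniform(*cfg.bridge_width_px)
            disks = [(float(px), float(py), width / 2) for px, py in pts[::4]]
            lesions.append({"kind": "bridge", "disks": disks})

    # --- vein artifact (both classes) --------------------------------------
    if rng.uniform() < cfg.artifact_rate:
        x0, y0 = _in_tissue_point()
        angle = rng.uniform(0, np.pi)
        length = rng.uniform(0.3 * s, 0.6 * s)
        x1, y1 = x0 + length * np.cos(angle), y0 + length * np.sin(angle)
        pts = _bezier_points(np.array([x0, y0]), np.array([(x0 + x1) / 2, (y0 + y1) / 2]), np.array([x1, y1]))
        width = rng.uniform(0.02 * s, 0.04 * s)
        disks = [(float(px), float(py), width / 2) for px, py in pts[::4]]
        lesions.append({"kind": "vein_artifact", "disks": disks})

    # --- crumbling: punch holes out of the tissue mask ----------------------
    if rng.uniform() < cfg.crumble_rate:
        for _ in range(int(rng.integers(30, 60))):
            x, y = _in_tissue_point()
            _stamp_disk(tissue, x, y, rng.uniform(0.01 * s, 0.04 * s), False)

    # --- render --------------------------------------------------------------
    img = np.empty((s, s, 3), dtype=np.float64)
    img[:] = colors["background"]
    img[tissue] = colors["tissue"]

    red = np.array(RED, dtype=np.float64)
    if rng.uniform() < cfg.fade_rate:
        # faded stain: red drifts toward the tissue colour
        red = 0.45 * red + 0.55 * np.asarray(colors["tissue"], dtype=np.float64)

    lesion_canvas = np.zeros((s, s), dtype=bool)
    for lesion in lesions:
        drawn = np.zeros((s, s), dtype=bool)
        for px, py, r in lesion["disks"]:
            _stamp_disk(drawn, px, py, r, True)
        # lesions live inside tissue; clip all but artifacts to the mask
        if lesion["kind"] != "vein_artifact":
            drawn &= tissue
        lesion_canvas |= drawn
    img[lesion_canvas] = red

    img += rng.normal(0.0, cfg.noise_sigma, size=img.shape)
    img = np.clip(img, 0, 255).astype(np.uint8)

    truth = SynthTruth(
        slide_id=slide_id,
        label=label,
        color_category=color_category,
        tissue_mask=tissue,
        lesions=lesions,
    )
    return img, truth


def allocate_labels(n_slides: int, class_balance: float) -> list[str]:
    """Deterministic label allocation: exactly round(n * balance) severe slides."""
    if n_slides < 2:
        raise ValueError("need at least 2 slides")
    n_severe = round(n_slides * class_balance)
    return ["severe"] * n_severe + ["mild"] * (n_slides - n_severe)


def generate_cohort(cfg: SynthConfig, out_dir: str | Path) -> pd.DataFrame:
    """Write a full synthetic cohort: slides, masks, truth JSON, manifest CSV.

    Labels follow ``class_balance`` exactly (deterministic allocation);
    color categories are sampled from ``category_weights``.  Returns the
    manifest frame; the CSV is written as ``manifest.csv`` in ``out_dir``
    with image paths relative to it, ready for the tiling stage.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    labels = allocate_labels(cfg.n_slides, cfg.class_balance)
    rng = np.random.default_rng(cfg.seed)
    # interleave classes so folds of any prefix stay roughly balanced
    order = rng.permutation(cfg.n_slides)
    rows = []
    for i in order:
        label = labels[i]
        slide_id = f"slide_{i:04d}"
        category = COLOR_CATEGORIES[int(rng.choice(3, p=cfg.category_weights))]
        img, truth = generate_slide(label, category, cfg, seed=int(cfg.seed + 1000 + i), slide_id=slide_id)
        Image.fromarray(img).save(out_dir / f"{slide_id}.png")
        Image.fromarray((truth.tissue_mask * 255).astype(np.uint8)).save(out_dir / f"{slide_id}_mask.png")
        with open(out_dir / f"{slide_id}_truth.json", "w") as fh:
            json.dump(
                {
                    "slide_id": slide_id,
                    "label": label,
                    "color_category": category,
                    "lesions": [
                        {"kind": l["kind"], "disks": [[float(a), float(b), float(c)] for a, b, c in l["disks"]]}
                        for l in truth.lesions
                    ],
                },
                fh,
            )
        rows.append(
            {
                "slide_id": slide_id,
                "image_path": f"{slide_id}.png",
                "mask_path": f"{slide_id}_mask.png",
                "label": label,
                "color_category": category,
            }
        )
    manifest = pd.DataFrame(sorted(rows, key=lambda r: r["slide_id"]))
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
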