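"""MIL bag assembly: the RED-1 and RAND-n dataloaders, resizing, augmentation.

Two bag-construction strategies are provided.  RED-1 builds a single bag per
slide from the k tiles with the highest red-pixel fraction (prior knowledge:
fibrosis stains red).  RAND-n shuffles the valid tiles and partitions them
into floor(N/k) disjoint bags of k, so every part of the tissue can be seen
at training and inference time; each bag inherits the slide label as a proxy
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .slideio import TileRecord

__all__ = [
    "Bag",
    "BagSetConfig",
    "build_bag_red1",
    "build_bags_randn",
    "build_bags",
    "resize_tile",
    "augment_tile",
    "write_bag_manifest",
    "read_bag_manifest",
]


@dataclass(frozen=True)
class Bag:
    """Fixed-size ordered collection of tiles from one slide."""

    bag_id: str
    slide_id: str
    tiles: tuple[TileRecord, ...]
    proxy_label: str

    def __post_init__(self) -> None:
        if len(self.tiles) == 0:
            raise ValueError("a bag must contain at least one tile")
        if any(t.slide_id != self.slide_id for t in self.tiles):
            raise ValueError("all tiles in a bag must come from the bag's slide")


@dataclass
class BagSetConfig:
    """Bag-construction settings: size k, dataloader mode, determinism."""

    k: int = 10
    mode: str = "randn"  # {"red1", "randn"}
    seed: int = 0
    augment: bool = False
    resize_px: int = 224

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("bag size k must be >= 1")
        if self.resize_px < 1:
            raise ValueError("resize_px must be >= 1")
        if self.mode not in ("red1", "randn"):
            raise ValueError(f"mode must be 'red1' or 'randn', got {self.mode!r}")


def _red1_sort_key(tile: TileRecord):
    # highest red first; ties broken by ascending (y, x) for determinism
    return (-tile.red_fraction, tile.y, tile.x)


def build_bag_red1(valid_tiles: Sequence[TileRecord], k: int, proxy_label: str = "") -> Bag:
    """One bag per slide: the min(k, N) tiles of highest red-pixel fraction."""
    if len(valid_tiles) == 0:
        raise ValueError("no valid tiles to build a bag from")
    chosen = sorted(valid_tiles, key=_red1_sort_key)[: min(k, len(valid_tiles))]
    slide_id = valid_tiles[0].slide_id
    return Bag(
        bag_id=f"{slide_id}_red1_0",
        slide_id=slide_id,
        tiles=tuple(chosen),
        proxy_label=proxy_label,
    )


def build_bags_randn(
    valid_tiles: Sequence[TileRecord], k: int, seed: int, proxy_label: str = ""
) -> list[Bag]:
    """floor(N/k) disjoint bags of k tiles, sampled without replacement.

    A seeded uniform shuffle of the valid tiles is cut into consecutive
    blocks of k; the N mod k leftover tiles are unused.  The same seed
    always yields the same partition.
    """
    n = len(valid_tiles)
    if n < k:
        raise ValueError(
            f"only {n} valid tiles for bag size k={k}; "
            "fall back to a single bag containing all tiles"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    slide_id = valid_tiles[0].slide_id
    bags = []
    for b in range(n // k):
        idx = perm[b * k : (b + 1) * k]
        bags.append(
            Bag(
                bag_id=f"{slide_id}_randn_{b}",
                slide_id=slide_id,
                tiles=tuple(valid_tiles[i] for i in idx),
                proxy_label=proxy_label,
            )
        )
    return bags


def build_bags(
    valid_tiles: Sequence[TileRecord], cfg: BagSetConfig, proxy_label: str, slide_seed: int = 0
) -> list[Bag]:
    """Dispatch on the dataloader mode; RAND-n falls back to one bag of all
    tiles when a slide has fewer than k valid tiles."""
    if cfg.mode == "red1":
        return [build_bag_red1(valid_tiles, cfg.k, proxy_label)]
    try:
        return build_bags_randn(valid_tiles, cfg.k, seed=cfg.seed + slide_seed, proxy_label=proxy_label)
    except ValueError:
        slide_id = valid_tiles[0].slide_id
        return [
            Bag(
                bag_id=f"{slide_id}_randn_0",
                slide_id=slide_id,
                tiles=tuple(valid_tiles),
                proxy_label=proxy_label,
            )
        ]


def resize_tile(tile_rgb: np.ndarray, out_px: int = 224) -> np.ndarray:
    """Bicubic resize of a square tile to ``out_px`` x ``out_px``."""
    arr = np.asarray(tile_rgb)
    if arr.shape[0] != arr.shape[1]:
        raise ValueError(f"expected a square tile, got {arr.shape[:2]}")
    if arr.shape[0] == out_px:
        return arr.copy()
    im = Image.fromarray(arr)
    return np.asarray(im.resize((out_px, out_px), Image.BICUBIC))


def augment_tile(tile_rgb: np.ndarray, seed: int) -> np.ndarray:
    """Seeded training-time augmentation: flips and a right-angle rotation.

    Horizontal and vertical flips are applied independently with probability
    0.5 each, followed by a rotation drawn uniformly from {0, 90, 180, 270}
    degrees.  All operations permute pixels, so intensity statistics are
    untouched.
    """
    rng = np.random.default_rng(seed)
    arr = np.asarray(tile_rgb)
    if rng.uniform() < 0.5:
        arr = arr[:, ::-1]
    if rng.uniform() < 0.5:
        arr = arr[::-1, :]
    arr = np.rot90(arr, k=int(rng.integers(0, 4)))
    return np.ascontiguousarray(arr)


def write_bag_manifest(bags: Sequence[Bag], cfg: BagSetConfig, path: str | Path) -> pd.DataFrame:
    """Serialise bags to CSV: one row per tile slot, keyed by bag_id."""
    rows = []
    for bag in bags:
        for pos, t in enumerate(bag.tiles):
            rows.append(
                {
                    "bag_id": bag.bag_id,
                    "slide_id": bag.slide_id,
                    "position": pos,
                    "x": t.x,
                    "y": t.y,
                    "side_px": t.side_px,
                    "tissue_fraction": t.tissue_fraction,
                    "red_fraction": t.red_fraction,
                    "proxy_label": bag.proxy_label,
                    "mode": cfg.mode,
                    "seed": cfg.seed,
                }
            )
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df


def read_bag_manifest(path: str | Path) -> list[Bag]:
    df = pd.read_csv(path)
    bags = []
    for bag_id, grp in df.groupby("bag_id", sort=True):
        grp = grp.sort_values("position")
        tiles = tuple(
            TileRecord(
                slide_id=str(r.slide_id),
                x=int(r.x),
                y=int(r.y),
                side_px=int(r.side_px),
                tissue_fraction=float(r.tissue_fraction),
                red_fraction=float(r.red_fraction),
            )
            for r in grp.itertuples(index=False)
        )
        bags.append(
            Bag(
                bag_id=str(bag_id),
                slide_id=str(grp["slide_id"].iloc[0]),
                tiles=tiles,
                proxy_label=str(grp["proxy_label"].iloc[0]),
            )
        )
    return bags
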