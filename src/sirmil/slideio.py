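"""Slide and mask I/O, tile-grid computation, and tissue/red tile scoring.

Sirius-Red whole-slide images show counterstained tissue (green or yellow)
on a grey or blue scanner background, with collagen — including fibrotic
bridges — in shades of red.  This module turns a slide into a manifest of
grid tiles scored for tissue content and red-pixel content, and applies the
adaptive tissue-content threshold that guarantees a minimum number of tiles
per slide.

Coordinates are 0-based pixel positions at the working magnification;
``(x, y)`` is the tile's top-left corner and the tile covers the half-open
square ``[x, x + side) x [y, y + side)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage
from skimage import color as skcolor

__all__ = [
    "LABELS",
    "COLOR_CATEGORIES",
    "SlideRecord",
    "TileRecord",
    "read_image",
    "read_mask",
    "generate_tissue_mask",
    "compute_tile_grid",
    "tissue_fraction",
    "red_pixel_fraction",
    "select_valid_tiles",
    "tile_slide",
    "read_cohort_manifest",
    "write_tile_manifest",
    "read_tile_manifest",
]

LABELS = ("mild", "severe")
COLOR_CATEGORIES = ("green_grey", "green_blue", "yellow_grey")

# Tile geometry: 2.5 mm square patches at 5x magnification are 1651 px wide,
# extracted on a grid with 50% overlap.
DEFAULT_TILE_SIDE_PX = 1651
DEFAULT_OVERLAP = 0.5

# Pillow refuses very large images by default; slides are legitimately huge.
Image.MAX_IMAGE_PIXELS = None


@dataclass(frozen=True)
class SlideRecord:
    """One slide of the cohort: image reference, label and appearance category."""

    slide_id: str
    image_ref: Path
    width_px: int
    height_px: int
    label: str
    color_category: str
    mask_ref: Path | None = None

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("slide dimensions must be positive")
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        if self.color_category not in COLOR_CATEGORIES:
            raise ValueError(
                f"color_category must be one of {COLOR_CATEGORIES}, "
                f"got {self.color_category!r}"
            )


@dataclass(frozen=True)
class TileRecord:
    """One grid tile with its tissue and red-content scores."""

    slide_id: str
    x: int
    y: int
    side_px: int
    tissue_fraction: float
    red_fraction: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.tissue_fraction <= 1.0):
            raise ValueError("tissue_fraction must lie in [0, 1]")
        if not (0.0 <= self.red_fraction <= 1.0):
            raise ValueError("red_fraction must lie in [0, 1]")
        if self.x < 0 or self.y < 0:
            raise ValueError("tile coordinates must be non-negative")


def _ensure_rgb(image: np.ndarray) -> np.ndarray:
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an RGB raster (H, W, 3), got shape {image.shape}")
    return image


def read_image(path: str | Path, target_magnification: float | None = None,
               base_magnification: float = 40.0) -> np.ndarray:
    """Read a slide image as an RGB uint8 array.

    Plain PNG/TIFF images are returned as stored (taken to be already at the
    working magnification).  For pyramid TIFFs, when ``target_magnification``
    is given, the pyramid level whose magnification (``base_magnification``
    divided by its downsample factor relative to level 0) is closest to the
    target is returned.
    """
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        with tifffile.TiffFile(path) as tf:
            series = tf.series[0]
            levels = getattr(series, "levels", [series])
            if target_magnification is None or len(levels) == 1:
                arr = levels[0].asarray()
            else:
                w0 = levels[0].shape[1] if levels[0].ndim >= 2 else 1
                best, best_gap = 0, float("inf")
                for i, lev in enumerate(levels):
                    mag = base_magnification * lev.shape[1] / w0
                    gap = abs(mag - target_magnification)
                    if gap < best_gap:
                        best, best_gap = i, gap
                arr = levels[best].asarray()
    else:
        arr = np.asarray(Image.open(path).convert("RGB"))
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    return _ensure_rgb(np.ascontiguousarray(arr[..., :3]))


def read_mask(path: str | Path) -> np.ndarray:
    """Read a binary tissue mask (PNG/TIFF); nonzero pixels count as tissue."""
    arr = np.asarray(Image.open(Path(path)))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > 0


def generate_tissue_mask(
    slide_image: np.ndarray,
    saturation_threshold: float = 0.25,
    median_size: int = 5,
    fill_holes: bool = True,
) -> np.ndarray:
    """Fallback tissue masker: saturation thresholding with smoothing.

    Counterstained tissue is strongly saturated (green/yellow) while the
    grey or pale-blue scanner background is not, so a median-smoothed
    saturation threshold separates the two.  Only used when no external
    mask accompanies the slide.
    """
    img = _ensure_rgb(np.asarray(slide_image))
    hsv = skcolor.rgb2hsv(img)
    sat = hsv[..., 1]
    if median_size > 1:
        sat = ndimage.median_filter(sat, size=median_size)
    mask = sat > saturation_threshold
    if fill_holes:
        mask = ndimage.binary_fill_holes(mask)
    return mask


def compute_tile_grid(
    width_px: int, height_px: int, side_px: int, overlap: float
) -> list[tuple[int, int]]:
    """Top-left positions of all fully contained tiles, row-major.

    The stride is ``floor(side_px * (1 - overlap))`` so the realised overlap
    is never below the nominal one; tiles that would hang over the slide
    border are dropped (no padding).  A slide smaller than one tile yields
    an empty list.
    """
    if side_px <= 0:
        raise ValueError("side_px must be positive")
    if not (0.0 <= overlap < 1.0):
        raise ValueError("overlap must lie in [0, 1)")
    # exact floor of side * (1 - overlap); plain float multiplication can
    # land an epsilon below an integer and floor one stride too short
    stride = int(Fraction(side_px) * (1 - Fraction(overlap)))
    if stride <= 0:
        raise ValueError("overlap too close to 1: stride rounds to zero")
    xs = range(0, width_px - side_px + 1, stride)
    ys = range(0, height_px - side_px + 1, stride)
    return [(x, y) for y in ys for x in xs]


def tissue_fraction(tile_mask: np.ndarray) -> float:
    """Fraction of mask pixels flagged as tissue."""
    mask = np.asarray(tile_mask)
    if mask.size == 0:
        raise ValueError("empty mask raster")
    return float(np.count_nonzero(mask) / mask.size)


def red_pixel_fraction(
    tile_rgb: np.ndarray,
    hue_low_deg: float = 25.0,
    hue_high_deg: float = 335.0,
    min_saturation: float = 0.30,
    min_value: float = 0.20,
) -> float:
    """Fraction of pixels that look red — the collagen/fibrosis proxy.

    A pixel is "red" when its hue falls in the wrap-around window
    ``[0, hue_low_deg] U [hue_high_deg, 360]`` degrees and both saturation
    and value clear their floors, which keeps faint or dark pixels out.
    """
    img = _ensure_rgb(np.asarray(tile_rgb))
    if img.size == 0:
        raise ValueError("empty raster")
    hsv = skcolor.rgb2hsv(img)
    hue_deg = hsv[..., 0] * 360.0
    red = (
        ((hue_deg <= hue_low_deg) | (hue_deg >= hue_high_deg))
        & (hsv[..., 1] >= min_saturation)
        & (hsv[..., 2] >= min_value)
    )
    return float(red.mean())


def select_valid_tiles(
    tiles: Sequence[TileRecord],
    init_threshold: float = 0.5,
    min_tiles: int = 10,
    step: float = 0.05,
    floor: float = 0.05,
) -> list[TileRecord]:
    """Adaptive tissue-content filter guaranteeing a minimum tile count.

    Tiles with ``tissue_fraction >= t`` are retained, starting at
    ``t = init_threshold``; when fewer than ``min_tiles`` survive (e.g. on
    crumbling tissue), ``t`` is lowered by ``step`` and the filter re-applied,
    down to ``floor``.  If even the floor retains too few, the
    ``min(min_tiles, len(tiles))`` tiles of highest tissue fraction are
    returned, so a slide always contributes tiles.
    """
    if len(tiles) == 0:
        raise ValueError("no tiles to select from")
    t = init_threshold
    # tolerance guards against 0.5 - k*0.05 drifting below the floor in floats
    while t >= floor - 1e-9:
        retained = [tile for tile in tiles if tile.tissue_fraction >= t - 1e-12]
        if len(retained) >= min_tiles:
            return retained
        t -= step
    order = sorted(
        range(len(tiles)),
        key=lambda i: (-tiles[i].tissue_fraction, tiles[i].y, tiles[i].x),
    )
    keep = sorted(order[: min(min_tiles, len(tiles))])
    return [tiles[i] for i in keep]


def extract_tile(image: np.ndarray, x: int, y: int, side_px: int) -> np.ndarray:
    """Crop the half-open square ``[x, x+side) x [y, y+side)`` from a raster."""
    return image[y : y + side_px, x : x + side_px]


def tile_slide(
    record: SlideRecord,
    side_px: int = DEFAULT_TILE_SIDE_PX,
    overlap: float = DEFAULT_OVERLAP,
    image: np.ndarray | None = None,
    mask: np.ndarray | None = None,
    init_threshold: float = 0.5,
    min_tiles: int = 10,
    mask_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Score every grid tile of one slide and flag the valid ones.

    Returns a tile manifest frame with columns ``slide_id, x, y, side_px,
    tissue_fraction, red_fraction, valid``.  An external mask, when present
    on the record (or passed in), always takes precedence over the built-in
    saturation masker.
    """
    if image is None:
        image = read_image(record.image_ref)
    if mask is None:
        if record.mask_ref is not None:
            mask = read_mask(record.mask_ref)
        else:
            mask = generate_tissue_mask(image, **(mask_kwargs or {}))
    if mask.shape[:2] != image.shape[:2]:
        raise ValueError("mask dimensions do not match the slide image")

    positions = compute_tile_grid(image.shape[1], image.shape[0], side_px, overlap)
    tiles: list[TileRecord] = []
    for x, y in positions:
        tmask = extract_tile(mask, x, y, side_px)
        trgb = extract_tile(image, x, y, side_px)
        tiles.append(
            TileRecord(
                slide_id=record.slide_id,
                x=x,
                y=y,
                side_px=side_px,
                tissue_fraction=tissue_fraction(tmask),
                red_fraction=red_pixel_fraction(trgb),
            )
        )
    valid = (
        set(
            (t.x, t.y)
            for t in select_valid_tiles(
                tiles, init_threshold=init_threshold, min_tiles=min_tiles
            )
        )
        if tiles
        else set()
    )
    return pd.DataFrame(
        {
            "slide_id": [t.slide_id for t in tiles],
            "x": [t.x for t in tiles],
            "y": [t.y for t in tiles],
            "side_px": [t.side_px for t in tiles],
            "tissue_fraction": [t.tissue_fraction for t in tiles],
            "red_fraction": [t.red_fraction for t in tiles],
            "valid": [int((t.x, t.y) in valid) for t in tiles],
        }
    )


def read_cohort_manifest(path: str | Path) -> list[SlideRecord]:
    """Load a cohort manifest CSV into SlideRecords.

    Required columns: slide_id, image_path, label, color_category; an
    optional mask_path column supplies external tissue masks.  Image
    dimensions are read from the image headers.
    """
    df = pd.read_csv(path)
    base = Path(path).parent
    records = []
    for row in df.itertuples(index=False):
        image_ref = Path(str(row.image_path))
        if not image_ref.is_absolute():
            image_ref = base / image_ref
        mask_ref = None
        if "mask_path" in df.columns and isinstance(row.mask_path, str) and row.mask_path:
            mask_ref = Path(row.mask_path)
            if not mask_ref.is_absolute():
                mask_ref = base / mask_ref
        with Image.open(image_ref) as im:
            width, height = im.size
        records.append(
            SlideRecord(
                slide_id=str(row.slide_id),
                image_ref=image_ref,
                width_px=width,
                height_px=height,
                label=str(row.label),
                color_category=str(row.color_category),
                mask_ref=mask_ref,
            )
        )
    return records


def write_tile_manifest(frames: Iterable[pd.DataFrame], path: str | Path) -> pd.DataFrame:
    """Concatenate per-slide tile frames and write the tile manifest CSV."""
    manifest = pd.concat(list(frames), ignore_index=True)
    manifest.to_csv(path, index=False)
    return manifest


def read_tile_manifest(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def tile_records_from_frame(df: pd.DataFrame, valid_only: bool = True) -> list[TileRecord]:
    """Materialise TileRecords from a tile-manifest frame."""
    if valid_only and "valid" in df.columns:
        df = df[df["valid"] == 1]
    return [
        TileRecord(
            slide_id=str(r.slide_id),
            x=int(r.x),
            y=int(r.y),
            side_px=int(r.side_px),
            tissue_fraction=float(r.tissue_fraction),
            red_fraction=float(r.red_fraction),
        )
        for r in df.itertuples(index=False)
    ]
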