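"""Slide reading and tiling.

Digitized slides come either as pyramidal files (SVS / pyramidal TIFF, read
through :mod:`tifffile`) or as plain RGB images (PNG/JPG, read through
Pillow).  A slide is reduced to one working pyramid level held in memory as
an RGB array, then cut into a lattice of non-overlapping square tiles.
Partial tiles at the right/bottom edges are dropped so every tile has
identical pixel dimensions, which downstream feature extractors require.

Coordinates are 0-based with the origin at the slide's top-left; a tile
covers the half-open pixel interval ``[x0, x0 + size_px) x [y0, y0 + size_px)``
and tiles are ordered row-major by ``(row, col)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "SlideHandle",
    "Tile",
    "TileGrid",
    "FormatError",
    "open_slide",
    "slide_from_array",
    "tile_slide",
    "filter_background",
    "DEFAULT_MIN_SATURATION",
    "DEFAULT_MIN_INTENSITY_SD",
]

PLAIN_EXTENSIONS = {".png", ".jpg", ".jpeg"}
PYRAMIDAL_EXTENSIONS = {".tif", ".tiff", ".svs", ".ndpi"}

#: target resolution used to auto-select a pyramid level (um/px); mirrors a
#: standard x20 scan.
TARGET_MPP = 0.5

# Conservative background thresholds: a tile is discarded only when it is both
# nearly colorless and nearly flat, so tissue edges survive.
DEFAULT_MIN_SATURATION = 0.05
DEFAULT_MIN_INTENSITY_SD = 4 / 255


class FormatError(ValueError):
    """Raised for files whose extension/format is not a supported slide type."""


@dataclass
class SlideHandle:
    """One slide opened at a fixed working pyramid level."""

    slide_id: str
    width_px: int
    height_px: int
    mpp: float | None
    source_path: str
    level: int
    image: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("slide dimensions must be positive")
        if self.mpp is not None and self.mpp <= 0:
            raise ValueError("mpp must be positive when present")
        if self.image.shape[:2] != (self.height_px, self.width_px):
            raise ValueError("image array does not match declared dimensions")


@dataclass
class Tile:
    tile_id: str
    row: int
    col: int
    x0: int
    y0: int
    size_px: int
    pixels: np.ndarray = field(repr=False)
    is_tissue: bool = True


@dataclass
class TileGrid:
    slide: SlideHandle
    tile_size_px: int
    tiles: list[Tile]
    n_rows: int
    n_cols: int

    def tissue_tiles(self) -> list[Tile]:
        return [t for t in self.tiles if t.is_tissue]

    def to_frame(self):
        """Tile table as a pandas DataFrame (tile_id, row, col, x0, y0, size_px, is_tissue)."""
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "tile_id": t.tile_id,
                    "row": t.row,
                    "col": t.col,
                    "x0": t.x0,
                    "y0": t.y0,
                    "size_px": t.size_px,
                    "is_tissue": t.is_tissue,
                }
                for t in self.tiles
            ]
        )


def _as_rgb(arr: np.ndarray) -> np.ndarray:
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:
        arr = arr[..., :3]
    if arr.dtype != np.uint8:
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    return np.ascontiguousarray(arr)


def _tiff_mpp(page) -> float | None:
    """Best-effort microns-per-pixel from TIFF metadata."""
    desc = page.description or ""
    # Aperio SVS carries "MPP = 0.5" in the ImageDescription.
    for token in desc.replace("|", "\n").splitlines():
        if "MPP" in token and "=" in token:
            try:
                return float(token.split("=")[1].strip())
            except ValueError:
                pass
    tags = page.tags
    if "XResolution" in tags and "ResolutionUnit" in tags:
        num, den = tags["XResolution"].value
        unit = getattr(tags["ResolutionUnit"].value, "value", tags["ResolutionUnit"].value)
        if den and num:
            px_per_unit = num / den
            if unit == 2:  # inch
                return 25400.0 / px_per_unit
            if unit == 3:  # centimeter
                return 10000.0 / px_per_unit
    return None


def open_slide(path: str | Path, level: int | None = None) -> SlideHandle:
    """Open a slide file and load one pyramid level.

    Parameters
    ----------
    path
        SVS / pyramidal TIFF / NDPI (via tifffile) or PNG/JPG (single level).
    level
        Pyramid level to load.  ``None`` selects the level whose resolution
        is closest to 0.5 um/px when metadata carries mpp, else level 0.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"slide file not found: {path}")
    ext = path.suffix.lower()
    if ext in PLAIN_EXTENSIONS:
        from PIL import Image

        if level not in (None, 0):
            raise ValueError(f"plain image {path} has a single level 0, got level={level}")
        try:
            with Image.open(path) as im:
                arr = _as_rgb(np.asarray(im.convert("RGB")))
        except Exception as exc:  # pragma: no cover - corrupt-file path
            raise IOError(f"could not read image {path}: {exc}") from exc
        h, w = arr.shape[:2]
        return SlideHandle(path.stem, w, h, None, str(path), 0, arr)
    if ext not in PYRAMIDAL_EXTENSIONS:
        supported = sorted(PLAIN_EXTENSIONS | PYRAMIDAL_EXTENSIONS)
        raise FormatError(f"unsupported slide format {ext!r}; supported: {supported}")

    import tifffile

    try:
        with tifffile.TiffFile(path) as tf:
            series = tf.series[0]
            levels = list(series.levels) if hasattr(series, "levels") else [series]
            mpp0 = _tiff_mpp(tf.pages[0])
            if level is None:
                level = _auto_level(levels, mpp0)
            if not (0 <= level < len(levels)):
                raise ValueError(
                    f"level {level} out of range for {path} ({len(levels)} levels)"
                )
            arr = _as_rgb(levels[level].asarray())
            scale = levels[0].shape[1] / arr.shape[1] if arr.shape[1] else 1.0
            mpp = mpp0 * scale if mpp0 is not None else None
    except ValueError:
        raise
    except Exception as exc:
        raise IOError(f"could not read slide {path}: {exc}") from exc
    h, w = arr.shape[:2]
    return SlideHandle(path.stem, w, h, mpp, str(path), level, arr)


def _auto_level(levels, mpp0: float | None) -> int:
    if mpp0 is None:
        return 0
    best, best_err = 0, float("inf")
    base_w = levels[0].shape[1]
    for i, lv in enumerate(levels):
        mpp_i = mpp0 * base_w / lv.shape[1]
        err = abs(mpp_i - TARGET_MPP)
        if err < best_err:
            best, best_err = i, err
    return best


def slide_from_array(
    image: np.ndarray, slide_id: str, mpp: float | None = None
) -> SlideHandle:
    """Wrap an in-memory RGB array (e.g. a synthetic slide) as a SlideHandle."""
    arr = _as_rgb(np.asarray(image))
    h, w = arr.shape[:2]
    return SlideHandle(slide_id, w, h, mpp, "<memory>", 0, arr)


def tile_slide(slide: SlideHandle, tile_size_px: int) -> TileGrid:
    """Cut the slide into the row-major lattice of non-overlapping tiles.

    ``n_cols = floor(width / s)``, ``n_rows = floor(height / s)``; partial
    edge tiles are dropped.  Every tile starts flagged as tissue.
    """
    if tile_size_px < 32:
        raise ValueError(f"tile_size_px must be >= 32, got {tile_size_px}")
    n_cols = slide.width_px // tile_size_px
    n_rows = slide.height_px // tile_size_px
    if n_cols == 0 or n_rows == 0:
        raise ValueError(
            f"slide smaller than tile: {slide.width_px}x{slide.height_px} "
            f"vs tile {tile_size_px}"
        )
    tiles = []
    for row in range(n_rows):
        for col in range(n_cols):
            x0, y0 = col * tile_size_px, row * tile_size_px
            tiles.append(
                Tile(
                    tile_id=f"{slide.slide_id}_r{row:04d}_c{col:04d}",
                    row=row,
                    col=col,
                    x0=x0,
                    y0=y0,
                    size_px=tile_size_px,
                    pixels=slide.image[y0 : y0 + tile_size_px, x0 : x0 + tile_size_px],
                )
            )
    return TileGrid(slide=slide, tile_size_px=tile_size_px, tiles=tiles,
                    n_rows=n_rows, n_cols=n_cols)


def tile_saturation_and_sd(pixels: np.ndarray) -> tuple[float, float]:
    """Mean HSV saturation and grayscale SD of one tile, both on a 0-1 scale."""
    rgb = pixels.astype(np.float64) / 255.0
    mx = rgb.max(axis=-1)
    mn = rgb.min(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        sat = np.where(mx > 0, (mx - mn) / mx, 0.0)
    gray = rgb @ np.array([0.2125, 0.7154, 0.0721])
    return float(sat.mean()), float(gray.std())


def filter_background(
    grid: TileGrid,
    min_saturation: float = DEFAULT_MIN_SATURATION,
    min_intensity_sd: float = DEFAULT_MIN_INTENSITY_SD,
) -> TileGrid:
    """Flag blank tiles: ``is_tissue=False`` when mean saturation AND gray SD
    both fall below their thresholds.  Geometry is unchanged; thresholds of 0
    disable the filter."""
    if min_saturation < 0 or min_intensity_sd < 0:
        raise ValueError("thresholds must be >= 0")
    n_dropped = 0
    for tile in grid.tiles:
        if not tile.is_tissue:
            continue
        sat, sd = tile_saturation_and_sd(tile.pixels)
        if sat < min_saturation and sd < min_intensity_sd:
            tile.is_tissue = False
            n_dropped += 1
    if n_dropped and n_dropped == len(grid.tiles):
        warnings.warn("all tiles flagged as background", stacklevel=2)
    return grid
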