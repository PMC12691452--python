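"""Tile-grid computation, tile extraction, brightness filtering and downscaling.

A whole-slide image (WSI) of W x H pixels is divided into R_W x R_H tiles.
In the default non-overlapping mode the grid holds ``floor(W / R_W)`` tiles
horizontally and ``floor(H / R_H)`` vertically; partial edge tiles are
discarded, so a 16,000 x 16,000 slide yields at most 31 x 31 = 961 tiles of
512 x 512. Dark or empty tiles are removed with a brightness threshold
(mean intensity below 25/255 is dropped), and retained tiles are reduced
with Lanczos resampling (512 -> 256 gives an exact 4x pixel reduction).

Coordinates are 0-based with half-open windows ``[x, x + R_W)``; tiles are
enumerated row-major by (y, x).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from PIL import Image

# WSIs trip Pillow's decompression-bomb guard; tiling is the mitigation.
Image.MAX_IMAGE_PIXELS = None

#: Default dark-tile threshold: tiles with mean intensity < 25/255 are dropped.
DEFAULT_BRIGHTNESS_MIN = 25.0

#: ITU-R BT.601 luma weights, optional alternative to the unweighted mean.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass(frozen=True)
class TileGrid:
    """Geometry of a tiling of a ``W x H`` image into ``R_W x R_H`` tiles."""

    image_width: int
    image_height: int
    tile_width: int
    tile_height: int
    stride_x: int
    stride_y: int
    nh: int
    nv: int
    origins: tuple[tuple[int, int], ...] = field(repr=False)

    @property
    def n_tiles(self) -> int:
        return len(self.origins)


@dataclass
class Tile:
    """One tile window of a source image.

    ``mean_intensity`` is the unweighted channel mean of ``pixels`` (the
    grayscale reading used by the brightness filter). ``kept`` is unset
    until :func:`brightness_filter` runs.
    """

    image_id: str
    x: int
    y: int
    pixels: np.ndarray  # (tile_h, tile_w, 3) uint8
    mean_intensity: float
    kept: bool | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


def mean_intensity(pixels: np.ndarray, luma: bool = False) -> float:
    """Mean intensity of an RGB array, by default the unweighted channel mean."""
    arr = np.asarray(pixels, dtype=np.float64)
    if luma and arr.ndim == 3 and arr.shape[2] == 3:
        return float((arr * np.asarray(LUMA_WEIGHTS)).sum(axis=2).mean())
    return float(arr.mean())


def _axis_origins(length: int, tile: int, step: int) -> list[int]:
    """Origins along one axis; the last origin is clamped so the tile fits."""
    if length < tile:
        return []
    last = length - tile
    xs = list(range(0, last + 1, step))
    if xs[-1] != last:
        xs.append(last)
    return xs


def compute_tile_grid(
    width: int,
    height: int,
    tile_width: int = 512,
    tile_height: int = 512,
    stride: int | str = "non-overlapping",
) -> TileGrid:
    """Compute the tile grid for a ``width x height`` image.

    Parameters
    ----------
    stride
        ``"non-overlapping"`` (default) places tiles edge to edge:
        ``Nh = floor(W / R_W)``, ``Nv = floor(H / R_H)``. An integer stride
        enumerates origins every ``stride`` pixels per axis, clamping the
        final origin so the tile fits inside the image. An image smaller
        than the tile yields an empty grid, not an error.
    """
    for name, v in (("width", width), ("height", height),
                    ("tile_width", tile_width), ("tile_height", tile_height)):
        if int(v) <= 0:
            raise ValueError(f"{name} must be positive, got {v}")

    if stride == "non-overlapping":
        nh = width // tile_width
        nv = height // tile_height
        xs = [i * tile_width for i in range(nh)]
        ys = [j * tile_height for j in range(nv)]
        sx, sy = tile_width, tile_height
    else:
        sx = sy = int(stride)
        if sx <= 0:
            raise ValueError(f"stride must be positive, got {stride}")
        xs = _axis_origins(width, tile_width, sx)
        ys = _axis_origins(height, tile_height, sy)
        nh, nv = len(xs), len(ys)

    origins = tuple((x, y) for y in ys for x in xs)
    return TileGrid(width, height, tile_width, tile_height, sx, sy, nh, nv, origins)


def overlap_grid(
    width: int,
    height: int,
    tile_width: int = 512,
    tile_height: int = 512,
    overlap: int = 50,
) -> TileGrid:
    """Overlapping-tile dialect: adjacent tiles share ``overlap`` pixels.

    The step is ``tile_size - overlap`` (e.g. 512 - 50 = 462), preserving
    tissue continuity across tile borders without exploding the tile count.
    """
    if not 0 <= overlap < min(tile_width, tile_height):
        raise ValueError(f"overlap must be in [0, tile size), got {overlap}")
    if overlap == 0:
        return compute_tile_grid(width, height, tile_width, tile_height)
    return compute_tile_grid(width, height, tile_width, tile_height,
                             stride=tile_width - overlap)


def extract_tiles(image: np.ndarray, grid: TileGrid, image_id: str = "") -> list[Tile]:
    """Cut one :class:`Tile` per grid origin, row-major by (y, x)."""
    image = np.asarray(image)
    h, w = image.shape[0], image.shape[1]
    if (w, h) != (grid.image_width, grid.image_height):
        raise ValueError(
            f"image is {w}x{h} but grid expects "
            f"{grid.image_width}x{grid.image_height}"
        )
    tiles = []
    for x, y in grid.origins:
        window = np.ascontiguousarray(
            image[y: y + grid.tile_height, x: x + grid.tile_width]
        )
        tiles.append(Tile(image_id, x, y, window, mean_intensity(window)))
    return tiles


def brightness_filter(
    tiles: list[Tile], threshold: float = DEFAULT_BRIGHTNESS_MIN,
    max_mean: float | None = None,
) -> list[Tile]:
    """Drop dark tiles: mean intensity strictly below ``threshold`` is removed.

    A tile whose mean equals the threshold is kept (the rule is "< 25/255").
    Input order is preserved and every input tile's ``kept`` flag is set.
    ``max_mean``, off by default, additionally drops near-white tiles.
    """
    if not 0 <= threshold <= 255:
        raise ValueError(f"threshold must be in [0, 255], got {threshold}")
    kept = []
    for t in tiles:
        t.kept = t.mean_intensity >= threshold and (
            max_mean is None or t.mean_intensity <= max_mean
        )
        if t.kept:
            kept.append(t)
    return kept


def downscale_tile(tile: Tile, target: int = 256) -> Tile:
    """Lanczos-downscale a tile to ``target x target`` pixels.

    Implements the resolution-reduction step D: a 512x512 tile becomes
    256x256, a 4x reduction in pixel count and bytes at equal bit depth.
    Identity when the tile already has the target size.
    """
    if target <= 0:
        raise ValueError(f"target must be positive, got {target}")
    th, tw = tile.shape
    if target > min(th, tw):
        raise ValueError(f"target {target} exceeds tile size {tw}x{th}")
    if (th, tw) == (target, target):
        return replace(tile, pixels=tile.pixels.copy())
    out = np.asarray(
        Image.fromarray(tile.pixels).resize((target, target), Image.LANCZOS)
    )
    return replace(tile, pixels=out, mean_intensity=mean_intensity(out))


def reduction_factor(source: int, target: int) -> float:
    """Pixel (and byte, at fixed depth) reduction factor of ``source -> target``."""
    return (source * source) / float(target * target)


def tile_accounting(
    class_wsi_counts: dict[str, int], bag_size: int = 50
) -> tuple[pd.DataFrame, int]:
    """Per-class tile bookkeeping: tile count = WSI count x bag size.

    Returns the (class, wsi_count, tile_count) table and the grand total,
    e.g. 41 mucinous-carcinoma WSIs at bag size 50 contribute 2050 tiles.
    """
    if bag_size < 0 or any(v < 0 for v in class_wsi_counts.values()):
        raise ValueError("counts must be non-negative")
    rows = [
        {"class": c, "wsi_count": int(n), "tile_count": int(n) * bag_size}
        for c, n in class_wsi_counts.items()
    ]
    table = pd.DataFrame(rows, columns=["class", "wsi_count", "tile_count"])
    total = int(table["tile_count"].sum()) if rows else 0
    return table, total


def write_tile_manifest(tiles: list[Tile], paths: list[str | None] | None = None) -> pd.DataFrame:
    """Tile manifest rows: image_id, x, y, mean_intensity, kept, path."""
    paths = paths if paths is not None else [None] * len(tiles)
    return pd.DataFrame(
        [
            {
                "image_id": t.image_id, "x": t.x, "y": t.y,
                "mean_intensity": t.mean_intensity, "kept": bool(t.kept),
                "path": p,
            }
            for t, p in zip(tiles, paths)
        ],
        columns=["image_id", "x", "y", "mean_intensity", "kept", "path"],
    )
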