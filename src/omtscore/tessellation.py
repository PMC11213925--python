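"""Tessellation of a slide into overlapping tiles and epithelium filtering.

Slides are tiled with 512 x 512 px tiles at 50 % overlap (stride 256) at the
0.50 mpp working resolution; only tiles whose footprint is at least half
epithelium (basal + epithelial + keratin layers) are retained for feature
extraction.  Tile footprints are half-open squares ``[x0, x0+size) x
[y0, y0+size)``; the last row/column of the grid is snapped inward so tiles
never extend past the slide border.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io import EPITHELIUM_CODES, LayerMask, NucleusRecord

TILE_SIZE = 512
TILE_STRIDE = 256
MIN_EPITHELIUM_FRACTION = 0.5


@dataclass(frozen=True)
class Tile:
    slide_id: str
    origin: tuple[int, int]
    size: int = TILE_SIZE
    epithelium_fraction: float | None = None


def _axis_origins(extent: int, tile_size: int, stride: int) -> list[int]:
    if extent < tile_size:
        raise ValueError(f"slide extent {extent} smaller than tile size {tile_size}")
    last = extent - tile_size
    origins = list(range(0, last + 1, stride))
    if origins[-1] != last:
        origins.append(last)  # snap final tile to the border
    return origins


def tessellate(
    slide_width: int,
    slide_height: int,
    tile_size: int = TILE_SIZE,
    stride: int = TILE_STRIDE,
    slide_id: str = "",
) -> list[Tile]:
    """Grid of tile origins covering the slide, border row/column snapped in."""
    xs = _axis_origins(slide_width, tile_size, stride)
    ys = _axis_origins(slide_height, tile_size, stride)
    return [Tile(slide_id=slide_id, origin=(x, y), size=tile_size) for y in ys for x in xs]


def epithelium_fraction(tile: Tile, mask: LayerMask, nuclei_mpp: float = 0.50) -> float:
    """Fraction of the tile footprint covered by intra-epithelial layers.

    The footprint (in nuclei-frame pixels) is rescaled to the mask resolution
    with nearest-cell indexing when the two resolutions differ.
    """
    scale = nuclei_mpp / mask.resolution_mpp
    x0, y0 = tile.origin
    c0 = int(round(x0 * scale))
    r0 = int(round(y0 * scale))
    c1 = int(round((x0 + tile.size) * scale))
    r1 = int(round((y0 + tile.size) * scale))
    h, w = mask.shape
    if c0 < 0 or r0 < 0 or c1 > w or r1 > h:
        raise ValueError(
            f"tile at {tile.origin} (size {tile.size}) outside mask bounds {w}x{h}"
        )
    window = mask.labels[r0:r1, c0:c1]
    return float(np.isin(window, EPITHELIUM_CODES).mean())


def filter_tiles(
    tiles: Iterable[Tile],
    mask: LayerMask,
    min_fraction: float = MIN_EPITHELIUM_FRACTION,
    nuclei_mpp: float = 0.50,
) -> list[Tile]:
    """Keep tiles with epithelium fraction >= ``min_fraction`` (inclusive)."""
    kept = []
    for t in tiles:
        frac = epithelium_fraction(t, mask, nuclei_mpp=nuclei_mpp)
        if frac >= min_fraction:
            kept.append(Tile(t.slide_id, t.origin, t.size, epithelium_fraction=frac))
    return kept


def assign_nuclei_to_tile(
    tile: Tile, nuclei: Sequence[NucleusRecord]
) -> list[NucleusRecord]:
    """Nuclei whose centroid falls inside the tile's half-open footprint."""
    x0, y0 = tile.origin
    x1, y1 = x0 + tile.size, y0 + tile.size
    return [
        n for n in nuclei if x0 <= n.centroid[0] < x1 and y0 <= n.centroid[1] < y1
    ]
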