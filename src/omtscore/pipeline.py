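"""End-to-end helpers: slide -> retained tiles -> per-tile feature table.

Feature tables are CSV, one row per retained tile, columns
``slide_id, x0, y0`` followed by the 168 canonical feature names.  Per-slide
shape descriptors are computed once and re-used across overlapping tiles.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io
from .features import (
    N_FEATURES,
    feature_class_index,
    feature_names,
    morphological_stats,
    neighbor_counts,
    shape_descriptor_matrix,
    tile_spatial_features,
)
from .io import LayerMask, NucleusRecord
from .tessellation import (
    MIN_EPITHELIUM_FRACTION,
    TILE_SIZE,
    TILE_STRIDE,
    Tile,
    filter_tiles,
    tessellate,
)


def slide_tiles(
    mask: LayerMask,
    slide_id: str = "",
    tile_size: int = TILE_SIZE,
    stride: int = TILE_STRIDE,
    min_fraction: float = MIN_EPITHELIUM_FRACTION,
    nuclei_mpp: float = 0.50,
) -> list[Tile]:
    """Tessellate the mask's slide frame and keep epithelium-rich tiles."""
    scale = mask.resolution_mpp / nuclei_mpp
    height, width = mask.shape
    tiles = tessellate(
        int(width * scale), int(height * scale), tile_size, stride, slide_id
    )
    return filter_tiles(tiles, mask, min_fraction, nuclei_mpp=nuclei_mpp)


def extract_slide_features(
    mask: LayerMask,
    nuclei: Sequence[NucleusRecord],
    slide_id: str = "",
    tile_size: int = TILE_SIZE,
    stride: int = TILE_STRIDE,
    min_fraction: float = MIN_EPITHELIUM_FRACTION,
    nuclei_mpp: float = 0.50,
) -> pd.DataFrame:
    """Per-tile 168-feature table for one slide."""
    tiles = slide_tiles(mask, slide_id, tile_size, stride, min_fraction, nuclei_mpp)
    desc = shape_descriptor_matrix(nuclei, nuclei_mpp)
    cents = np.array([n.centroid for n in nuclei], dtype=float).reshape(-1, 2)
    cls = np.array([feature_class_index(n.model_class) for n in nuclei], dtype=int)

    rows = []
    for tile in tiles:
        x0, y0 = tile.origin
        in_tile = (
            (cents[:, 0] >= x0)
            & (cents[:, 0] < x0 + tile.size)
            & (cents[:, 1] >= y0)
            & (cents[:, 1] < y0 + tile.size)
        )
        morph = morphological_stats(desc[in_tile], cls[in_tile])
        counts = neighbor_counts(cents[in_tile], cls[in_tile])
        spat = tile_spatial_features(counts, cls[in_tile])
        rows.append(
            {"slide_id": slide_id, "x0": x0, "y0": y0}
            | dict(zip(feature_names(), np.concatenate([morph, spat])))
        )
    if not rows:
        return pd.DataFrame(columns=["slide_id", "x0", "y0", *feature_names()])
    return pd.DataFrame(rows)


def features_from_directory(
    data_dir: str | Path, cohort: io.CohortTable, **kwargs
) -> dict[str, pd.DataFrame]:
    """Feature tables for every cohort slide stored in ``data_dir``."""
    data_dir = Path(data_dir)
    out = {}
    for slide_id in cohort.slide_ids:
        mask = io.read_layer_mask(data_dir / f"{slide_id}_mask.png")
        nuclei = io.read_nuclei(data_dir / f"{slide_id}_nuclei.json")
        out[slide_id] = extract_slide_features(mask, nuclei, slide_id, **kwargs)
    return out


def feature_matrix(table: pd.DataFrame) -> np.ndarray:
    """(n_tiles, 168) float matrix from a per-tile feature table."""
    return table[feature_names()].to_numpy(dtype=float)


def write_features(directory: str | Path, tables: dict[str, pd.DataFrame]) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for slide_id, table in tables.items():
        table.to_csv(directory / f"{slide_id}_features.csv", index=False)


def read_features(
    directory: str | Path, cohort: io.CohortTable
) -> dict[str, pd.DataFrame]:
    directory = Path(directory)
    out = {}
    for slide_id in cohort.slide_ids:
        table = pd.read_csv(directory / f"{slide_id}_features.csv")
        if table.shape[1] != 3 + N_FEATURES:
            raise ValueError(f"{slide_id}: malformed feature table")
        out[slide_id] = table
    return out
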