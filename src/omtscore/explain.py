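"""Post-hoc explainability analyses.

Three analyses probe what drives the slide scores: (1) cellular composition
and tissue-ratio comparisons between the top-5 predicted patches of true
positives and true negatives (Welch t-tests with Benjamini-Hochberg FDR,
Cohen's d with pooled SD); (2) Random-Forest mean-decrease-in-impurity
ranking of the 168 tile features on those top patches; (3) partial-dependence
curves sweeping one feature at a time from its observed minimum to maximum in
100 increments.  Prediction heatmaps average tile probabilities per pixel.

Composition classes: a nucleus is "other" if the segmentation model called
it other; remaining (epithelial-family) nuclei are subdivided by the tissue
layer under their centroid — basal layer -> basal, keratin layer -> keratin,
otherwise epithelial.  "Keratin nucleus" and "basal nucleus" are therefore
layer-derived classes, not segmentation-model outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from statsmodels.stats.multitest import multipletests

from .io import (
    LAYER_BASAL,
    LAYER_KERATIN,
    LAYER_OTHER_TISSUE,
    LayerMask,
    NucleusClass,
    NucleusRecord,
)
from .model import OMTModel, SlidePrediction
from .tessellation import Tile, assign_nuclei_to_tile

COMPOSITION_CLASSES = ["other", "basal", "epithelial", "keratin"]
EPITHELIUM_REGION_CODES = (2, 3, 4)


def top_k_patches(prediction: SlidePrediction, k: int = 5) -> np.ndarray:
    """Indices of the k tiles with highest probability (ties -> lowest index)."""
    probs = np.asarray(prediction.tile_probs)
    if k <= 0:
        return np.array([], dtype=int)
    order = np.lexsort((np.arange(len(probs)), -probs))
    return order[: min(k, len(probs))]


@dataclass(frozen=True)
class PatchComposition:
    """Nuclear counts per composition class in three regions + tissue ratios."""

    entire: dict[str, int]
    epithelium: dict[str, int]
    connective: dict[str, int]
    tissue_ratios: dict[str, float]


def _layer_at(mask: LayerMask, x: float, y: float, nuclei_mpp: float) -> int:
    scale = nuclei_mpp / mask.resolution_mpp
    r = min(int(y * scale), mask.shape[0] - 1)
    c = min(int(x * scale), mask.shape[1] - 1)
    return int(mask.labels[r, c])


def patch_composition(
    tile: Tile,
    nuclei: Sequence[NucleusRecord],
    mask: LayerMask,
    nuclei_mpp: float = 0.50,
) -> PatchComposition:
    """Composition of one patch: counts in the entire patch, the epithelium
    region and the connective-tissue region, plus per-layer pixel ratios."""
    scale = nuclei_mpp / mask.resolution_mpp
    x0, y0 = tile.origin
    r0, c0 = int(round(y0 * scale)), int(round(x0 * scale))
    r1, c1 = int(round((y0 + tile.size) * scale)), int(round((x0 + tile.size) * scale))
    h, w = mask.shape
    if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
        raise ValueError("tile outside mask bounds")
    window = mask.labels[r0:r1, c0:c1]

    entire = {c: 0 for c in COMPOSITION_CLASSES}
    epith = {c: 0 for c in COMPOSITION_CLASSES}
    conn = {c: 0 for c in COMPOSITION_CLASSES}
    for n in assign_nuclei_to_tile(tile, nuclei):
        layer = _layer_at(mask, n.centroid[0], n.centroid[1], nuclei_mpp)
        if n.model_class is NucleusClass.OTHER:
            comp = "other"
        elif layer == LAYER_BASAL:
            comp = "basal"
        elif layer == LAYER_KERATIN:
            comp = "keratin"
        else:
            comp = "epithelial"
        entire[comp] += 1
        if layer in EPITHELIUM_REGION_CODES:
            epith[comp] += 1
        elif layer == LAYER_OTHER_TISSUE:
            conn[comp] += 1

    total = window.size
    ratios = {
        name: float((window == code).sum() / total)
        for name, code in [
            ("other_tissue", 1),
            ("basal", 2),
            ("epithelium", 3),
            ("keratin", 4),
        ]
    }
    return PatchComposition(entire=entire, epithelium=epith, connective=conn,
                            tissue_ratios=ratios)


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Cohen's d with pooled standard deviation (a minus b)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    pooled = np.sqrt(
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    )
    if pooled == 0:
        return 0.0
    return float((a.mean() - b.mean()) / pooled)


def group_compare(
    tp_values: pd.DataFrame, tn_values: pd.DataFrame
) -> pd.DataFrame:
    """Per-feature TP-vs-TN comparison: means, Cohen's d, Welch p, BH-FDR q.

    Both inputs are patch-by-feature tables with identical columns; the BH
    adjustment is applied across the whole tested family.
    """
    if len(tp_values) < 2 or len(tn_values) < 2:
        raise ValueError("each group needs >=2 patches")
    rows = []
    for col in tp_values.columns:
        a = tp_values[col].to_numpy(dtype=float)
        b = tn_values[col].to_numpy(dtype=float)
        if a.std() == 0 and b.std() == 0:
            p = 1.0  # both groups constant: no evidence either way
        else:
            p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        rows.append(
            {
                "feature": col,
                "mean_tp": float(a.mean()),
                "mean_tn": float(b.mean()),
                "d": cohens_d(a, b),
                "p": p,
            }
        )
    out = pd.DataFrame(rows).set_index("feature")
    out["p_adj"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out


def rf_importance(
    patch_features: pd.DataFrame,
    patch_labels: Sequence[int],
    top_n: int = 10,
    seed: int = 0,
    n_trees: int = 500,
) -> pd.DataFrame:
    """Random-Forest MDI feature ranking on top-patch feature vectors.

    Patches carry their slide's outcome label.  Importances are normalised to
    sum 1 (sklearn's convention); the top ``top_n`` features are returned
    with their TP-vs-TN comparison statistics.
    """
    labels = np.asarray(patch_labels, dtype=int)
    if len(set(labels.tolist())) < 2:
        raise ValueError("need both outcome classes among patches")
    rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    rf.fit(patch_features.to_numpy(dtype=float), labels)
    imp = pd.Series(rf.feature_importances_, index=patch_features.columns)
    top = imp.sort_values(ascending=False).head(top_n)
    comp = group_compare(
        patch_features[labels == 1], patch_features[labels == 0]
    ).loc[top.index]
    out = comp.copy()
    out.insert(0, "mdi", top)
    return out


def partial_dependence(
    model: OMTModel,
    feature_index: int,
    tile_features: np.ndarray,
    n_grid: int = 100,
) -> pd.DataFrame:
    """Partial-dependence curve of one feature on the tile probability.

    The feature is swept over ``n_grid`` equally spaced values from its
    observed min to max; at each value it is overwritten in every evaluation
    tile and the mean positive-class probability recorded.
    """
    tile_features = np.atleast_2d(np.asarray(tile_features, dtype=float))
    if not 0 <= feature_index < tile_features.shape[1]:
        raise ValueError(f"invalid feature index {feature_index}")
    lo = tile_features[:, feature_index].min()
    hi = tile_features[:, feature_index].max()
    grid = np.array([lo]) if lo == hi else np.linspace(lo, hi, n_grid)
    mean_prob = []
    work = tile_features.copy()
    for v in grid:
        work[:, feature_index] = v
        mean_prob.append(float(model.predict_proba(work).mean()))
    return pd.DataFrame({"value": grid, "mean_probability": mean_prob})


def heatmap(
    tiles: Sequence[Tile],
    tile_probs: Sequence[float],
    slide_width: int,
    slide_height: int,
) -> np.ndarray:
    """Per-pixel mean probability over all covering tiles (NaN = uncovered)."""
    total = np.zeros((slide_height, slide_width))
    cover = np.zeros((slide_height, slide_width), dtype=int)
    for tile, p in zip(tiles, tile_probs):
        x0, y0 = tile.origin
        total[y0 : y0 + tile.size, x0 : x0 + tile.size] += p
        cover[y0 : y0 + tile.size, x0 : x0 + tile.size] += 1
    with np.errstate(invalid="ignore"):
        out = np.where(cover > 0, total / np.maximum(cover, 1), np.nan)
    return out
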