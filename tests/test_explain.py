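import numpy as np
import pandas as pd
import pytest

from omtscore import io
from omtscore.explain import (
    cohens_d,
    group_compare,
    heatmap,
    partial_dependence,
    patch_composition,
    rf_importance,
    top_k_patches,
)
from omtscore.model import ModelConfig, OMTModel, SlidePrediction, _MLP
from omtscore.tessellation import Tile
from oracles import brute_bh, brute_top_k


class TestTopK:
    def test_fewer_tiles_than_k(self):
        pred = SlidePrediction("s", np.array([0.2, 0.9, 0.4]))
        assert top_k_patches(pred, k=5).tolist() == [1, 2, 0]

    def test_k_zero_empty(self):
        pred = SlidePrediction("s", np.array([0.2, 0.9]))
        assert top_k_patches(pred, k=0).size == 0

    def test_matches_sort_oracle_with_ties(self, rng):
        for _ in range(100):
            probs = rng.choice([0.1, 0.4, 0.7, 0.9], size=20)
            pred = SlidePrediction("s", probs)
            assert top_k_patches(pred, 5).tolist() == brute_top_k(probs, 5)


def _banded_mask(size=64):
    labels = np.zeros((size, size), dtype=np.uint8)
    labels[:8] = io.LAYER_KERATIN
    labels[8:32] = io.LAYER_EPITHELIUM
    labels[32:40] = io.LAYER_BASAL
    labels[40:] = io.LAYER_OTHER_TISSUE
    return io.LayerMask(labels=labels, resolution_mpp=0.5)


def _nucleus(i, x, y, cls):
    return io.NucleusRecord(
        i, (x, y), ((x - 1, y - 1), (x + 1, y - 1), (x, y + 1)), cls
    )


class TestPatchComposition:
    def test_layer_derived_classes_and_regions(self):
        mask = _banded_mask()
        tile = Tile("s", (0, 0), 64)
        nuclei = [
            _nucleus(0, 10, 4, io.NucleusClass.EPITHELIAL),    # keratin band
            _nucleus(1, 10, 20, io.NucleusClass.EPITHELIAL),   # epithelium
            _nucleus(2, 10, 35, io.NucleusClass.BASAL_EPITHELIAL),  # basal band
            _nucleus(3, 10, 50, io.NucleusClass.OTHER),        # connective
            _nucleus(4, 20, 20, io.NucleusClass.OTHER),        # intra-epithelial
        ]
        comp = patch_composition(tile, nuclei, mask)
        assert comp.entire == {"other": 2, "basal": 1, "epithelial": 1, "keratin": 1}
        assert comp.epithelium == {"other": 1, "basal": 1, "epithelial": 1, "keratin": 1}
        assert comp.connective == {"other": 1, "basal": 0, "epithelial": 0, "keratin": 0}

    def test_region_counts_additive(self, rng):
        mask = _banded_mask()
        tile = Tile("s", (0, 0), 64)
        nuclei = [
            _nucleus(
                i, x, y,
                io.NucleusClass(rng.choice(["epithelial", "other", "basal_epithelial"])),
            )
            for i, (x, y) in enumerate(rng.uniform(2, 62, size=(50, 2)))
        ]
        comp = patch_composition(tile, nuclei, mask)
        for cls in comp.entire:
            assert comp.epithelium[cls] + comp.connective[cls] <= comp.entire[cls]
        assert sum(comp.entire.values()) == 50

    def test_tissue_ratios_match_band_geometry(self):
        comp = patch_composition(Tile("s", (0, 0), 64), [], _banded_mask())
        assert comp.tissue_ratios["keratin"] == pytest.approx(8 / 64)
        assert comp.tissue_ratios["epithelium"] == pytest.approx(24 / 64)
        assert comp.tissue_ratios["basal"] == pytest.approx(8 / 64)
        assert comp.tissue_ratios["other_tissue"] == pytest.approx(24 / 64)
        assert sum(comp.tissue_ratios.values()) <= 1.0


class TestGroupCompare:
    def test_identical_groups_null(self, rng):
        a = pd.DataFrame({"f": rng.normal(size=20)})
        out = group_compare(a, a.copy())
        assert out.loc["f", "d"] == 0.0
        assert out.loc["f", "p"] == pytest.approx(1.0)

    def test_bh_adjustment_step_up(self):
        out = group_compare(
            pd.DataFrame(np.random.default_rng(0).normal(size=(10, 4)), columns=list("abcd")),
            pd.DataFrame(np.random.default_rng(1).normal(size=(10, 4)), columns=list("abcd")),
        )
        np.testing.assert_allclose(
            out["p_adj"].to_numpy(), brute_bh(out["p"].tolist()), rtol=1e-12
        )
        assert (out["p_adj"] >= out["p"] - 1e-15).all()

    def test_bh_textbook_vector(self):
        # p = (.01, .02, .03, .04) -> adjusted all 0.04 by step-up
        np.testing.assert_allclose(brute_bh([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)
        from statsmodels.stats.multitest import multipletests

        np.testing.assert_allclose(
            multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1], [0.04] * 4
        )

    def test_planted_one_sd_shift(self, rng):
        a = pd.DataFrame({"f": rng.normal(1.0, 1.0, 100)})
        b = pd.DataFrame({"f": rng.normal(0.0, 1.0, 100)})
        out = group_compare(a, b)
        assert out.loc["f", "d"] == pytest.approx(1.0, abs=0.3)
        assert out.loc["f", "p_adj"] < 0.001

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            group_compare(pd.DataFrame({"f": [1.0]}), pd.DataFrame({"f": [1.0, 2.0]}))

    def test_cohens_d_pooled_sd_closed_form(self):
        d = cohens_d(np.array([2.0, 4.0]), np.array([0.0, 2.0]))
        # means 3 and 1, pooled sd sqrt(2) -> d = sqrt(2)
        assert d == pytest.approx(np.sqrt(2))


class TestRFImportance:
    def test_planted_informative_feature_ranked_first(self, rng):
        n = 120
        labels = rng.integers(0, 2, n)
        x = rng.normal(size=(n, 12))
        x[:, 7] += 3.0 * labels
        df = pd.DataFrame(x, columns=[f"f{i}" for i in range(12)])
        out = rf_importance(df, labels, top_n=5, seed=0, n_trees=200)
        assert out.index[0] == "f7"
        assert out["mdi"].iloc[0] > 0.5

    def test_importances_sum_to_one_and_reproducible(self, rng):
        labels = rng.integers(0, 2, 60)
        labels[:2] = [0, 1]
        df = pd.DataFrame(rng.normal(size=(60, 6)), columns=list("abcdef"))
        out1 = rf_importance(df, labels, top_n=6, seed=3, n_trees=50)
        out2 = rf_importance(df, labels, top_n=6, seed=3, n_trees=50)
        assert out1["mdi"].sum() == pytest.approx(1.0)
        pd.testing.assert_frame_equal(out1, out2)

    def test_single_class_rejected(self, rng):
        df = pd.DataFrame(rng.normal(size=(10, 3)))
        with pytest.raises(ValueError):
            rf_importance(df, np.ones(10, dtype=int))


def _logistic_model(n_features=4, j=1, weight=2.0):
    """An MLP whose output is a monotone logistic function of feature j."""
    cfg = ModelConfig(input_dim=n_features, hidden_dim=2, dropout=0.0)
    weights = {
        "W1": np.zeros((n_features, 2)),
        "b1": np.zeros(2),
        "W2": np.zeros((2, 2)),
        "b2": np.zeros(2),
    }
    weights["W1"][j, 0] = 1.0  # h0 = leaky(x_j); identity for x_j scaled below
    weights["W2"][0, 1] = weight
    return OMTModel(cfg, weights, np.zeros(n_features), np.ones(n_features))


class TestPartialDependence:
    def test_flat_for_ignored_feature(self, rng):
        model = _logistic_model(j=1)
        x = rng.normal(size=(30, 4))
        curve = partial_dependence(model, 3, x)  # feature 3 has zero weights
        assert curve.mean_probability.nunique() == 1

    def test_monotone_increasing_for_positive_weight(self, rng):
        model = _logistic_model(j=1, weight=2.0)
        x = rng.normal(size=(30, 4))
        curve = partial_dependence(model, 1, x)
        assert len(curve) == 100
        assert (np.diff(curve.mean_probability) >= -1e-12).all()
        assert curve.mean_probability.iloc[-1] > curve.mean_probability.iloc[0]

    def test_matches_per_tile_averaging_oracle(self, rng):
        model = _logistic_model(j=0)
        x = rng.normal(size=(15, 4))
        curve = partial_dependence(model, 0, x, n_grid=10)
        for v, got in zip(curve.value, curve.mean_probability):
            work = x.copy()
            work[:, 0] = v
            assert got == pytest.approx(model.predict_proba(work).mean(), rel=1e-12)

    def test_constant_feature_single_point(self, rng):
        model = _logistic_model()
        x = rng.normal(size=(5, 4))
        x[:, 2] = 1.5
        assert len(partial_dependence(model, 2, x)) == 1

    def test_invalid_index_errors(self, rng):
        with pytest.raises(ValueError):
            partial_dependence(_logistic_model(), 9, rng.normal(size=(5, 4)))


class TestHeatmap:
    def test_single_tile_uniform(self):
        hm = heatmap([Tile("s", (2, 2), 4)], [0.7], 10, 10)
        assert np.nanmax(hm) == np.nanmin(hm[2:6, 2:6]) == pytest.approx(0.7)
        assert np.isnan(hm[0, 0])

    def test_overlap_is_mean(self):
        tiles = [Tile("s", (0, 0), 4), Tile("s", (2, 0), 4)]
        hm = heatmap(tiles, [0.2, 0.8], 6, 4)
        assert hm[0, 0] == pytest.approx(0.2)
        assert hm[0, 3] == pytest.approx(0.5)
        assert hm[0, 5] == pytest.approx(0.8)

    def test_range_within_unit_interval(self, rng):
        tiles = [Tile("s", (int(x), int(y)), 8) for x, y in rng.integers(0, 24, (10, 2))]
        hm = heatmap(tiles, rng.random(10), 32, 32)
        vals = hm[~np.isnan(hm)]
        assert (vals >= 0).all() and (vals <= 1).all()
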