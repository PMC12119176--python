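"""Percentile-band reclassification, weighted stacking, zonal ranking."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from kelpniche import (
    BandRecipe,
    ConfigurationError,
    EnvLayer,
    GridGeoref,
    recipe_from_summary,
    reclassify_band,
    stack_score,
    zonal_stats,
)
from kelpniche.ecoregions import Ecoregion
from kelpniche.suitability import SuitabilityMap


ROW = {"variable_code": "bo_sst_x", "min": 5.0, "p25": 10.0, "p75": 20.0, "max": 30.0}


class TestRecipe:
    def test_iqr_mode(self):
        r = recipe_from_summary(ROW, mode="iqr", weight=1.0)
        assert (r.lo, r.hi) == (10.0, 20.0)
        assert (r.exclusion_min, r.exclusion_max) == (5.0, 30.0)

    def test_range_mode(self):
        r = recipe_from_summary(ROW, mode="range")
        assert (r.lo, r.hi) == (5.0, 30.0)
        assert r.exclusion_min is None and r.exclusion_max is None

    def test_degenerate_band(self):
        row = dict(ROW, p25=12.0, p75=12.0)
        r = recipe_from_summary(row, mode="iqr")
        assert r.lo == r.hi == 12.0

    def test_unknown_mode_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            recipe_from_summary(ROW, mode="kernel")

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ConfigurationError):
            BandRecipe("v", lo=5.0, hi=3.0)
        with pytest.raises(ConfigurationError):
            BandRecipe("v", lo=5.0, hi=9.0, exclusion_min=6.0)


def layer_of(values, code="bo_sst_x", georef=None, nodata=-9999.0):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    g = georef or GridGeoref(0.0, float(values.shape[0]), 1.0, 1.0, *values.shape)
    return EnvLayer(code, "", g, values, nodata=nodata)


class TestReclassify:
    def test_inclusive_bounds(self):
        layer = layer_of([[9.99, 10.0, 15.0, 20.0, 20.01]])
        out = reclassify_band(layer, BandRecipe("bo_sst_x", 10.0, 20.0))
        np.testing.assert_array_equal(out.values, [[0, 1, 1, 1, 0]])

    def test_all_nodata_stays_nodata(self):
        layer = layer_of(np.full((3, 3), -9999.0))
        out = reclassify_band(layer, BandRecipe("bo_sst_x", 0.0, 1.0))
        assert out.mask.all()

    def test_exclusion_bounds_force_zero(self):
        layer = layer_of([[4.0, 7.0, 15.0, 25.0, 31.0]])
        recipe = recipe_from_summary(ROW, mode="iqr")
        out = reclassify_band(layer, recipe)
        # 4 and 31 are beyond the observed extremes, 7 and 25 merely off-band
        np.testing.assert_array_equal(out.values, [[0, 0, 1, 0, 0]])

    def test_graded_three_levels(self):
        layer = layer_of([[4.0, 7.0, 15.0, 25.0, 31.0]])
        recipe = recipe_from_summary(ROW, mode="graded", weight=2.0)
        out = reclassify_band(layer, recipe)
        np.testing.assert_array_equal(out.values, [[0.0, 0.5, 1.0, 0.5, 0.0]])

    def test_code_mismatch_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            reclassify_band(layer_of([[1.0]], code="bo_salinity"),
                            BandRecipe("bo_sst_x", 0.0, 1.0))

    def test_per_cell_oracle_40x40(self, rng):
        vals = rng.uniform(0, 30, (40, 40))
        vals[rng.random((40, 40)) < 0.1] = -9999.0
        layer = layer_of(vals)
        lo, hi = sorted(rng.uniform(0, 30, 2))
        out = reclassify_band(layer, BandRecipe("bo_sst_x", lo, hi))
        for r in range(40):
            for c in range(40):
                v = vals[r, c]
                want = -9999.0 if v == -9999.0 else float(lo <= v <= hi)
                assert out.values[r, c] == want


class TestStack:
    def _binary(self, rng, shape=(40, 40), georef=None):
        g = georef or GridGeoref(0.0, float(shape[0]), 1.0, 1.0, *shape)
        vals = (rng.random(shape) < 0.5).astype(float)
        return EnvLayer("v", "", g, vals, nodata=-9999.0)

    def test_three_aligned_all_ones(self, rng):
        g = GridGeoref(0, 5, 1.0, 1.0, 5, 5)
        ones = [EnvLayer("v", "", g, np.ones((5, 5))) for _ in range(3)]
        smap = stack_score(ones, [1.0, 1.0, 1.0])
        assert (smap.scores == 3.0).all() and smap.max_score == 3.0

    def test_zero_weight_layer_is_neutral(self, rng):
        layers = [self._binary(rng) for _ in range(3)]
        with_zero = stack_score(layers, [2.0, 0.0, 1.0])
        without = stack_score([layers[0], layers[2]], [2.0, 1.0])
        np.testing.assert_array_equal(with_zero.scores, without.scores)
        assert with_zero.max_score == 3.0 and without.max_score == 3.0

    def test_per_cell_oracle_4_random_layers(self, rng):
        layers = [self._binary(rng) for _ in range(4)]
        weights = [float(w) for w in rng.integers(1, 4, 4)]
        smap = stack_score(layers, weights)
        want = sum(w * l.values for w, l in zip(weights, layers))
        np.testing.assert_array_equal(smap.scores, want)
        assert np.nanmax(smap.scores) <= sum(weights)
        assert np.nanmin(smap.scores) >= 0

    def test_integer_scores_with_unit_weights(self, rng):
        layers = [self._binary(rng) for _ in range(5)]
        smap = stack_score(layers, [1.0] * 5)
        valid = smap.scores[~np.isnan(smap.scores)]
        np.testing.assert_array_equal(valid, np.round(valid))

    def test_order_invariance(self, rng):
        layers = [self._binary(rng) for _ in range(4)]
        weights = [1.0, 2.0, 3.0, 4.0]
        base = stack_score(layers, weights)
        perm = [2, 0, 3, 1]
        permuted = stack_score([layers[i] for i in perm], [weights[i] for i in perm])
        np.testing.assert_array_equal(base.scores, permuted.scores)

    def test_nodata_conjunctive(self, rng):
        g = GridGeoref(0, 2, 1.0, 1.0, 2, 2)
        a = EnvLayer("v", "", g, [[1.0, -9999.0], [1.0, 1.0]], nodata=-9999.0)
        b = EnvLayer("v", "", g, [[1.0, 1.0], [-9999.0, 1.0]], nodata=-9999.0)
        smap = stack_score([a, b], [1.0, 1.0])
        assert np.isnan(smap.scores[0, 1]) and np.isnan(smap.scores[1, 0])
        assert smap.scores[0, 0] == 2.0 and smap.scores[1, 1] == 2.0

    def test_lenient_policy_rescales(self):
        g = GridGeoref(0, 1, 1.0, 1.0, 1, 2)
        a = EnvLayer("v", "", g, [[1.0, 1.0]], nodata=-9999.0)
        b = EnvLayer("v", "", g, [[1.0, -9999.0]], nodata=-9999.0)
        smap = stack_score([a, b], [1.0, 1.0], nodata_policy="lenient")
        assert smap.scores[0, 0] == 2.0
        assert smap.scores[0, 1] == 2.0  # 1 valid of weight 1, rescaled by 2/1

    def test_resampling_to_finest_grid(self, rng):
        fine = GridGeoref(0.0, 4.0, 0.5, 0.5, 8, 8)
        coarse = GridGeoref(0.0, 4.0, 1.0, 1.0, 4, 4)
        cl = EnvLayer("v", "", coarse, (rng.random((4, 4)) < 0.5).astype(float))
        fl = EnvLayer("v", "", fine, np.ones((8, 8)))
        smap = stack_score([cl, fl], [1.0, 1.0])
        assert smap.georef == fine
        # each coarse cell covers a 2x2 block of fine cells
        np.testing.assert_array_equal(
            smap.scores, np.kron(cl.values, np.ones((2, 2))) + 1.0)

    def test_empty_stack_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            stack_score([], [])


class TestZonal:
    def test_uniform_score_single_zone(self):
        g = GridGeoref(0.0, 4.0, 1.0, 1.0, 4, 4)
        smap = SuitabilityMap(g, np.full((4, 4), 2.0), max_score=3.0)
        out = zonal_stats(smap, [Ecoregion(1, "all", box(0, 0, 4, 4))])
        row = out.iloc[0]
        assert row["n_cells"] == 16 and row["mean_score"] == 2.0
        assert row["fraction_at_max"] == 0.0  # nothing reaches max_score 3

    def test_zone_outside_grid(self):
        g = GridGeoref(0.0, 4.0, 1.0, 1.0, 4, 4)
        smap = SuitabilityMap(g, np.ones((4, 4)), max_score=1.0)
        out = zonal_stats(smap, [Ecoregion(1, "far", box(100, 100, 101, 101))])
        assert out.iloc[0]["n_cells"] == 0
        assert np.isnan(out.iloc[0]["mean_score"])

    def test_cell_center_membership_oracle(self, rng):
        g = GridGeoref(0.0, 10.0, 1.0, 1.0, 10, 10)
        scores = rng.integers(0, 4, (10, 10)).astype(float)
        scores[rng.random((10, 10)) < 0.1] = np.nan
        smap = SuitabilityMap(g, scores, max_score=3.0)
        zones = [Ecoregion(1, "W", box(0, 0, 5.5, 10)), Ecoregion(2, "E", box(5.5, 0, 10, 10))]
        out = zonal_stats(smap, zones).set_index("zone_id")
        # oracle: scan all cell centers against the rectangle bounds
        for zid, (w, e) in [(1, (0, 5.5)), (2, (5.5, 10))]:
            vals = []
            for r in range(10):
                for c in range(10):
                    lat, lon = g.cell_center(r, c)
                    if w <= lon <= e and not np.isnan(scores[r, c]):
                        # the center at lon 5.5 sits on the shared edge and
                        # goes to the smaller zone id
                        if zid == 1 or lon > w:
                            vals.append(scores[r, c])
            assert out.loc[zid, "n_cells"] == len(vals)
            assert out.loc[zid, "mean_score"] == pytest.approx(np.mean(vals))
            assert out.loc[zid, "max_score_observed"] == max(vals)
            assert out.loc[zid, "fraction_at_max"] == pytest.approx(
                np.mean(np.asarray(vals) == 3.0))

    def test_sorted_by_mean_then_id(self):
        g = GridGeoref(0.0, 1.0, 1.0, 1.0, 1, 4)
        smap = SuitabilityMap(g, np.array([[0.0, 2.0, 1.0, 1.0]]), max_score=2.0)
        zones = [Ecoregion(i + 1, str(i), box(i, 0, i + 1, 1)) for i in range(4)]
        out = zonal_stats(smap, zones)
        assert out["zone_id"].tolist() == [2, 3, 4, 1]


def test_monotonicity_widening_band_never_decreases_scores(rng):
    vals = rng.uniform(0, 30, (20, 20))
    layer = layer_of(vals)
    narrow = reclassify_band(layer, BandRecipe("bo_sst_x", 10.0, 20.0))
    wide = reclassify_band(layer, BandRecipe("bo_sst_x", 8.0, 22.0))
    assert (wide.values >= narrow.values).all()


def test_end_to_end_box_niche(rng):
    """A species with a box niche in two variables: only cells inside both
    bands reach the full score."""
    g = GridGeoref(0.0, 20.0, 1.0, 1.0, 20, 20)
    sst = EnvLayer("sst", "", g, rng.uniform(0, 30, (20, 20)))
    sal = EnvLayer("sal", "", g, rng.uniform(30, 38, (20, 20)))
    b1 = reclassify_band(sst, BandRecipe("sst", 10.0, 20.0))
    b2 = reclassify_band(sal, BandRecipe("sal", 33.0, 35.0))
    smap = stack_score([b1, b2], [2.0, 1.0])
    inside = ((sst.values >= 10) & (sst.values <= 20)
              & (sal.values >= 33) & (sal.values <= 35))
    assert (smap.scores[inside] == 3.0).all()
    assert (smap.scores[~inside] < 3.0).all()
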