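"""Social profiler: HDI classification, zonal profiles, continental
disaggregation, overlap statistics, sensitivity sweeps."""

import numpy as np
import pandas as pd
import pytest

import thirty30 as t30
from thirty30.grid import CATEGORICAL_NODATA, CellMask, Grid, RasterLayer
from thirty30.social import hdi_category_codes


def make_layers(grid, *, pop=None, hdi=None, wild=None, farm=None,
                livestock=None, tropics=None, continents=None, land=None,
                pop1=None):
    """Hand-assembled SocialLayers with simple defaults."""
    shape = grid.shape
    ca = grid.cell_area_km2
    pop = np.full(shape, 100.0) if pop is None else np.asarray(pop, float)
    pop1 = pop * 1.1 if pop1 is None else np.asarray(pop1, float)
    hdi = np.full(shape, 0.6) if hdi is None else np.asarray(hdi, float)
    wild = np.zeros(shape) if wild is None else np.asarray(wild, float)
    if farm is None:
        farm = (np.full(shape, 0.5 * ca), np.full(shape, 0.3 * ca),
                np.full(shape, 0.2 * ca))
    livestock = (np.zeros(shape, int) if livestock is None
                 else np.asarray(livestock, int))
    tropics = (CellMask.full(grid) if tropics is None else tropics)
    continents = (np.zeros(shape, int) if continents is None
                  else np.asarray(continents, int))
    land = CellMask.full(grid) if land is None else land
    return t30.SocialLayers(
        population_t0=RasterLayer(grid, pop, kind="count"),
        population_t1=RasterLayer(grid, pop1, kind="count"),
        hdi=RasterLayer(grid, hdi),
        wildharvest_pop=RasterLayer(grid, wild, kind="count"),
        farm_nonfarmed=RasterLayer(grid, farm[0], kind="count"),
        farm_small=RasterLayer(grid, farm[1], kind="count"),
        farm_large=RasterLayer(grid, farm[2], kind="count"),
        livestock_system=RasterLayer(grid, livestock, kind="categorical"),
        tropics=tropics,
        continents=RasterLayer(grid, continents, kind="categorical"),
        land=land,
    )


class TestHdiCategories:
    @pytest.mark.parametrize("value,code", [
        (0.54, 0), (0.549, 0),          # Low
        (0.55, 1), (0.699, 1),          # Medium (half-open at 0.70)
        (0.70, 2), (0.799, 2),          # High
        (0.80, 3), (1.0, 3),            # Very High
        (0.0, 0),
    ])
    def test_threshold_boundaries(self, value, code):
        assert hdi_category_codes(np.array([value]))[0] == code

    def test_nodata_maps_to_minus_one(self):
        assert hdi_category_codes(np.array([np.nan]))[0] == -1


class TestProfile:
    def test_uniform_population_single_category(self, grid3):
        layers = make_layers(grid3, hdi=np.full(grid3.shape, 0.6))
        mask = CellMask.empty(grid3)
        mask.included[:2, :2] = True
        p = t30.profile(mask, layers)
        assert p.resident_pop == pytest.approx(400.0)
        assert p.hdi_category_pcts["medium"] == pytest.approx(100.0)
        assert sum(p.hdi_category_pops.values()) == pytest.approx(p.resident_pop)

    def test_hand_built_world_matches_enumeration(self):
        grid = t30.Grid(3, 3, 5.0)
        pop = np.array([[10, 20, 30], [0, 5, 5], [100, 0, 0]], float)
        hdi = np.array([[0.4, 0.6, 0.75], [0.9, 0.5, 0.65], [0.3, 0.8, 0.85]])
        wild = pop * 0.5
        tropics = CellMask(grid, np.array([[0, 0, 0], [1, 1, 1], [1, 1, 1]], bool))
        ls = np.array([[2, 0, 0], [0, 2, 0], [0, 0, 0]])
        layers = make_layers(grid, pop=pop, hdi=hdi, wild=wild,
                             livestock=ls, tropics=tropics)
        mask = CellMask(grid, np.array([[1, 1, 0], [0, 1, 0], [1, 0, 0]], bool))
        p = t30.profile(mask, layers, buffer_km=5.0)
        # enumeration: mask cells (0,0),(0,1),(1,1),(2,0)
        assert p.resident_pop == 10 + 20 + 5 + 100
        # HDI classes: 0.4 low, 0.6 medium, 0.5 low, 0.3 low
        assert p.hdi_category_pops == {
            "low": 10 + 5 + 100, "medium": 20, "high": 0.0, "very_high": 0.0}
        expect_mean = (10 * 0.4 + 20 * 0.6 + 5 * 0.5 + 100 * 0.3) / 135
        assert p.mean_hdi == pytest.approx(expect_mean)
        # tropics cells in mask: (1,1) and (2,0): wild 2.5+50 over pop 105
        assert p.tropical_resident_pop == 105
        assert p.wildharvest_share_pct == pytest.approx(100 * 52.5 / 105)
        # livestock_only (code 2) mask cells: (0,0) and (1,1) of 4
        assert p.rangeland_share_pct == pytest.approx(100 * 2 / 4)
        # buffer at 5 km: orthogonal neighbours of mask cells, outside mask:
        # (0,2) pop 30, (1,0) pop 0, (1,2) pop 5, (2,1) pop 0
        assert p.buffer_pop == 30 + 0 + 5 + 0

    def test_growth_from_two_epochs(self, grid3):
        layers = make_layers(grid3, pop=np.full(grid3.shape, 50.0),
                             pop1=np.full(grid3.shape, 60.0))
        p = t30.profile(CellMask.full(grid3), layers)
        assert p.growth_pct == pytest.approx(20.0)

    def test_zero_tropical_population_flagged(self, grid3):
        layers = make_layers(grid3, tropics=CellMask.empty(grid3))
        p = t30.profile(CellMask.full(grid3), layers)
        assert p.wildharvest_share_pct is None

    def test_zero_resident_population_growth_flagged(self, grid3):
        layers = make_layers(grid3, pop=np.zeros(grid3.shape))
        p = t30.profile(CellMask.full(grid3), layers)
        assert p.growth_pct is None

    def test_farm_shares_sum_to_100_when_components_tile(self, grid3):
        layers = make_layers(grid3)
        p = t30.profile(CellMask.full(grid3), layers)
        assert sum(p.farm_shares_pct.values()) == pytest.approx(100.0, abs=0.1)

    def test_resident_and_buffer_cells_disjoint(self, world, baseline_net):
        ring = t30.buffer_mask(baseline_net.mask, 10.0)
        assert not (ring.included & baseline_net.mask.included).any()

    def test_scaling_equivariance(self, world, baseline_net):
        import dataclasses
        p1 = t30.profile(baseline_net.mask, world.layers)
        scaled = dataclasses.replace(
            world.layers,
            population_t0=RasterLayer(world.grid, world.layers.population_t0.values * 3,
                                      kind="count"),
            population_t1=RasterLayer(world.grid, world.layers.population_t1.values * 3,
                                      kind="count"),
            wildharvest_pop=RasterLayer(world.grid, world.layers.wildharvest_pop.values * 3,
                                        kind="count"),
        )
        p3 = t30.profile(baseline_net.mask, scaled)
        assert p3.resident_pop == pytest.approx(3 * p1.resident_pop)
        assert p3.buffer_pop == pytest.approx(3 * p1.buffer_pop)
        assert p3.mean_hdi == pytest.approx(p1.mean_hdi)
        assert p3.wildharvest_share_pct == pytest.approx(p1.wildharvest_share_pct)
        for k in p1.hdi_category_pcts:
            assert p3.hdi_category_pcts[k] == pytest.approx(p1.hdi_category_pcts[k])

    def test_hdi_category_pops_partition_resident_pop(self, world, baseline_net):
        p = t30.profile(baseline_net.mask, world.layers)
        hdi_ok = ~np.isnan(world.layers.hdi.values)
        pop_defined = world.layers.population_t0.values[
            baseline_net.mask.included & hdi_ok].sum()
        assert sum(p.hdi_category_pops.values()) == pytest.approx(pop_defined)
        assert sum(p.hdi_category_pcts.values()) == pytest.approx(100.0, abs=0.1)


class TestProfileByContinent:
    def test_single_continent_equals_global(self, grid3):
        layers = make_layers(grid3)
        mask = CellMask.full(grid3)
        df = t30.profile_by_continent(mask, layers)
        assert len(df) == 1
        p = t30.profile(mask, layers)
        assert df.resident_pop.iloc[0] == pytest.approx(p.resident_pop)

    def test_two_continent_fixture_matches_hand_computation(self):
        grid = t30.Grid(2, 4, 5.0)
        cont = np.array([[0, 0, 1, 1], [0, 0, 1, 1]])
        pop = np.array([[10, 20, 30, 40], [1, 2, 3, 4]], float)
        hdi = np.array([[0.4, 0.4, 0.8, 0.8], [0.6, 0.6, 0.7, 0.7]])
        layers = make_layers(grid, pop=pop, hdi=hdi, continents=cont)
        mask = CellMask(grid, np.array([[1, 0, 1, 0], [0, 1, 0, 1]], bool))
        df = t30.profile_by_continent(mask, layers).set_index("continent_code")
        assert df.loc[0].resident_pop == 10 + 2
        assert df.loc[1].resident_pop == 30 + 4
        assert df.loc[0].mean_hdi == pytest.approx((10 * 0.4 + 2 * 0.6) / 12)
        # continental mean over ALL continent cells, not only mask
        assert df.loc[0].continental_mean_hdi == pytest.approx(
            (10 * 0.4 + 20 * 0.4 + 1 * 0.6 + 2 * 0.6) / 33)
        assert df.resident_pop.sum() == pytest.approx(
            t30.profile(mask, layers).resident_pop)

    def test_continent_with_empty_mask_row_flagged(self):
        grid = t30.Grid(2, 4, 5.0)
        cont = np.array([[0, 0, 1, 1], [0, 0, 1, 1]])
        pop = np.zeros(grid.shape)
        layers = make_layers(grid, pop=pop, continents=cont)
        mask = CellMask.empty(grid)
        mask.included[0, 0] = True
        df = t30.profile_by_continent(mask, layers).set_index("continent_code")
        assert df.loc[1].n_cells == 0
        assert df.loc[1].resident_pop == 0
        assert df.loc[1].mean_hdi is None or np.isnan(df.loc[1].mean_hdi)

    def test_unassigned_row_for_missing_continent_codes(self, grid3):
        cont = np.zeros(grid3.shape, int)
        cont[0, 0] = CATEGORICAL_NODATA
        layers = make_layers(grid3, continents=cont)
        df = t30.profile_by_continent(CellMask.full(grid3), layers)
        assert "unassigned" in set(df.continent)
        assert df.resident_pop.sum() == pytest.approx(900.0)


class TestOverlapAnalysis:
    def _mask(self, grid, idx):
        m = CellMask.empty(grid)
        m.included.ravel()[list(idx)] = True
        return m

    def test_identical_masks(self, grid4):
        land = CellMask.full(grid4)
        base = CellMask.empty(grid4)
        m = self._mask(grid4, [0, 1, 2])
        rep = t30.overlap_analysis({"a": m, "b": m, "c": m}, land, base)
        assert all(v == 0.0 for v in rep.unique_fraction.values())
        assert rep.triple_shared_fraction == 1.0

    def test_pairwise_disjoint_masks(self, grid4):
        land = CellMask.full(grid4)
        base = CellMask.empty(grid4)
        rep = t30.overlap_analysis(
            {"a": self._mask(grid4, [0]), "b": self._mask(grid4, [5]),
             "c": self._mask(grid4, [10])}, land, base)
        assert all(v == 1.0 for v in rep.unique_fraction.values())
        assert rep.triple_shared_fraction == 0.0
        assert all(v == 0.0 for v in rep.pairwise_directional.values())

    def test_hand_drawn_masks_by_set_enumeration(self, grid4):
        land = CellMask.full(grid4)
        base = self._mask(grid4, [15])
        a = self._mask(grid4, [0, 1, 2, 3])
        b = self._mask(grid4, [2, 3, 4])
        c = self._mask(grid4, [3, 4, 5])
        rep = t30.overlap_analysis({"a": a, "b": b, "c": c}, land, base)
        assert rep.unique_fraction["a"] == pytest.approx(2 / 4)  # {0,1}
        assert rep.pairwise_directional[("a", "b")] == pytest.approx(2 / 4)
        assert rep.pairwise_directional[("b", "a")] == pytest.approx(2 / 3)
        assert rep.pairwise_jaccard[("a", "b")] == pytest.approx(2 / 5)
        assert rep.triple_shared_fraction == pytest.approx(1 / 6)  # {3} of {0..5}
        # none: 16 land - (6 new + 1 baseline) = 9
        assert rep.none_fraction == pytest.approx(9 / 16)
        # unique + shared partition: a's new cells
        shared_a = int((a.included & (b.included | c.included)).sum())
        assert rep.unique_fraction["a"] + shared_a / 4 == pytest.approx(1.0)

    def test_baseline_intersection_rejected(self, grid4):
        land = CellMask.full(grid4)
        base = self._mask(grid4, [0])
        with pytest.raises(ValueError, match="baseline"):
            t30.overlap_analysis({"a": self._mask(grid4, [0, 1])}, land, base)


class TestSensitivitySweep:
    def test_noop_sweep_equals_single_profile(self, grid3):
        layers = make_layers(grid3)
        mask = CellMask.full(grid3)
        df = t30.sensitivity_sweep(mask, layers, alternates={}, buffer_list=[10.0])
        assert len(df) == 1
        p = t30.profile(mask, layers, buffer_km=10.0)
        assert df.resident_pop.iloc[0] == pytest.approx(p.resident_pop)

    def test_buffer_population_monotone_in_distance(self, world, baseline_net):
        df = t30.sensitivity_sweep(baseline_net.mask, world.layers,
                                   buffer_list=[5.0, 10.0, 15.0])
        pops = df.sort_values("buffer_km").buffer_pop.tolist()
        assert pops == sorted(pops)

    def test_population_scaling_oracle(self, grid3):
        layers = make_layers(grid3)
        mask = CellMask.empty(grid3)
        mask.included[0] = True
        doubled = {"pop2x": {
            "population_t0": RasterLayer(grid3, layers.population_t0.values * 2,
                                         kind="count"),
            "population_t1": RasterLayer(grid3, layers.population_t1.values * 2,
                                         kind="count"),
            "wildharvest_pop": RasterLayer(grid3, layers.wildharvest_pop.values * 2,
                                           kind="count"),
        }}
        df = t30.sensitivity_sweep(mask, layers, alternates=doubled,
                                   buffer_list=[10.0]).set_index("dataset")
        assert df.loc["pop2x"].resident_pop == pytest.approx(
            2 * df.loc["primary"].resident_pop)
        assert df.loc["pop2x"].mean_hdi == pytest.approx(df.loc["primary"].mean_hdi)
        for c in ("pct_hdi_low", "pct_hdi_medium", "pct_area_small_farms"):
            assert df.loc["pop2x"][c] == pytest.approx(df.loc["primary"][c])

    def test_grid_mismatch_combination_skipped(self, grid3, grid4, caplog):
        layers = make_layers(grid3)
        bad = {"wrong_grid": {
            "population_t0": RasterLayer(grid4, np.ones(grid4.shape), kind="count")}}
        import logging
        with caplog.at_level(logging.WARNING, logger="thirty30.social"):
            df = t30.sensitivity_sweep(CellMask.full(grid3), layers,
                                       alternates=bad, buffer_list=[10.0])
        assert set(df.dataset) == {"primary"}
        assert any("skipped" in r.message for r in caplog.records)


def test_planted_contrast_ordering_recovered():
    """A mask planted on IPLC-style low-HDI/high-wild-harvest cells profiles
    poorer and more harvest-dependent than masks in intact or dense areas."""
    ok = 0
    n = 12
    for seed in range(n):
        w = t30.generate(t30.WorldConfig(seed=100 + seed))
        w = t30.plant_contrast(w, iplc_hdi_offset=-0.2,
                               iplc_wildharvest_multiplier=2.0)
        hmi = np.nan_to_num(w.hmi.values, nan=1.0)
        pop = w.layers.population_t0.values
        li = w.land.included
        k = max(1, int(0.1 * w.land.n_cells))

        def top_mask(score):
            flat = np.where(li.ravel(), score.ravel(), -np.inf)
            m = CellMask.empty(w.grid)
            m.included.ravel()[np.argsort(-flat, kind="stable")[:k]] = True
            return m

        from thirty30.grid import rasterize_coverage, threshold_mask
        iplc_fp = threshold_mask(rasterize_coverage(
            [(str(i), g) for i, (g, f) in enumerate(w.iplc_lands)
             if f != "other_special_rights"], w.grid), 0.5) & w.land
        dense = top_mask(pop.astype(float))  # dense-area (biodiversity-style)
        p_itt = t30.profile(iplc_fp, w.layers, name="itt_style")
        p_dense = t30.profile(dense, w.layers, name="dense")
        if (p_itt.mean_hdi < p_dense.mean_hdi
                and (p_itt.wildharvest_share_pct or 0.0)
                >= (p_dense.wildharvest_share_pct or 0.0)):
            ok += 1
    assert ok >= 0.9 * n
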