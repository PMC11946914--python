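import numpy as np
import pandas as pd
import pytest

from heatmargin.impute import (MCMCSettings, estimate_lambda,
                               fit_phylo_mixed_model, initialize_missing,
                               run_bace, standardized_predict)
from heatmargin.phylo import read_newick
from heatmargin.simulate import (SimConfig, simulate_traits,
                                 simulate_trait_table, simulate_tree)

FAST = MCMCSettings(iterations=800, burn_in=300, thin=2)


def _table(species, ctmax, se=0.4, t_acc=22.0, **kw):
    n = len(species)
    base = {
        "species": species,
        "ctmax": ctmax,
        "ctmax_se": [se] * n if np.isscalar(se) else se,
        "t_acc": [t_acc] * n if np.isscalar(t_acc) else t_acc,
        "acc_duration": 10.0, "ramp_rate": 1.0,
        "endpoint": "onset_of_spasms", "medium": "water",
        "life_stage": "adult", "ecotype": "ground-dwelling", "body_mass": 5.0,
    }
    base.update(kw)
    return pd.DataFrame(base)


class TestInitializeMissing:
    def test_mean_fill(self):
        df = pd.DataFrame({"species": list("abc"),
                           "x": [1.0, np.nan, 3.0]})
        out = initialize_missing(df, seed=0)
        assert out.x.tolist() == [1.0, 2.0, 3.0]

    def test_single_level_categorical(self):
        df = pd.DataFrame({"species": list("abc"),
                           "medium": ["water", "water", None]})
        out = initialize_missing(df, seed=0)
        assert (out.medium == "water").all()

    def test_observed_untouched(self):
        df = pd.DataFrame({"species": list("abcd"),
                           "x": [1.0, np.nan, 3.0, 4.0],
                           "cat": ["u", "v", None, "u"]})
        out = initialize_missing(df, seed=3)
        assert out.x[[0, 2, 3]].tolist() == [1.0, 3.0, 4.0]
        assert out.cat[[0, 1, 3]].tolist() == ["u", "v", "u"]

    def test_fully_missing_column_error(self):
        df = pd.DataFrame({"species": ["a"], "x": [np.nan]})
        with pytest.raises(ValueError, match="x"):
            initialize_missing(df, seed=0)

    def test_categorical_frequencies_preserved(self):
        rng = np.random.default_rng(0)
        levels = rng.choice(["p", "q"], p=[0.7, 0.3], size=400).astype(object)
        mask = rng.random(400) < 0.3
        col = levels.copy()
        col[mask] = None
        fracs = []
        for seed in range(200):
            df = pd.DataFrame({"species": "s", "cat": col})
            out = initialize_missing(df, seed=seed)
            fracs.append((out.cat[mask] == "p").mean())
        observed_p = (levels[~mask] == "p").mean()
        # binomial error of the mean over 200 seeds is tiny
        assert abs(np.mean(fracs) - observed_p) < 0.02


class TestFitPhyloMixedModel:
    def test_needs_two_species(self):
        tree = read_newick("(a:1,b:1);")
        df = _table(["a", "a"], [35.0, 36.0])
        with pytest.raises(ValueError):
            fit_phylo_mixed_model(df, tree, FAST)

    def test_positive_se_required(self):
        tree = read_newick("(a:1,b:1);")
        df = _table(["a", "b"], [35.0, 36.0], se=[0.4, -1.0])
        with pytest.raises(ValueError, match="positive"):
            fit_phylo_mixed_model(df, tree, FAST)

    def test_duplicated_records_leave_fixed_effects(self):
        tree = simulate_tree(20, seed=1)
        cfg = SimConfig(n_species=20, prop_missing=0.0, seed=1)
        truth = simulate_traits(tree, cfg)
        table = simulate_trait_table(truth, cfg)
        comp = initialize_missing(table, seed=0)
        doubled = pd.concat([comp, comp], ignore_index=True)
        f1 = fit_phylo_mixed_model(comp, tree, FAST, seed=0)
        f2 = fit_phylo_mixed_model(doubled, tree, FAST, seed=0)
        b1 = f1.fixed_effects_summary().set_index("term")["mean"]
        b2 = f2.fixed_effects_summary().set_index("term")["mean"]
        mc = 3 * np.hypot(f1.fixed_effects_summary().set_index("term")["sd"],
                          f2.fixed_effects_summary().set_index("term")["sd"])
        assert (np.abs(b1 - b2) < np.maximum(mc, 0.15)).all()

    def test_lambda_near_zero_without_signal(self):
        tree = simulate_tree(200, seed=2)
        cfg = SimConfig(n_species=200, prop_missing=0.0, lambda_true=0.0,
                        residual_sd=0.0, seed=2)
        truth = simulate_traits(tree, cfg)
        table = simulate_trait_table(truth, cfg)
        comp = initialize_missing(table, seed=0)
        fit = fit_phylo_mixed_model(
            comp, tree, MCMCSettings(iterations=2500, burn_in=800, thin=2),
            seed=0)
        assert float(np.median(fit.draws["lambda"])) < 0.2

    def test_lambda_draws_in_unit_interval(self, small_truth_table):
        tree, _, table = small_truth_table
        comp = initialize_missing(table, seed=0)
        fit = fit_phylo_mixed_model(comp, tree, FAST, seed=0)
        lam = fit.draws["lambda"]
        assert ((lam >= 0) & (lam <= 1)).all()

    def test_estimate_lambda_limits(self, small_truth_table):
        tree, _, table = small_truth_table
        comp = initialize_missing(table, seed=0)
        fit = fit_phylo_mixed_model(comp, tree, FAST, seed=0)
        fit.draws["var_us"] = np.zeros_like(fit.draws["var_us"])
        fit.draws["lambda"] = fit.draws["var_up"] / (
            fit.draws["var_up"] + fit.draws["var_us"])
        lam, _ = estimate_lambda(fit)
        assert lam == pytest.approx(1.0)
        fit.draws["var_us"] = fit.draws["var_up"].copy()
        fit.draws["lambda"] = fit.draws["var_up"] / (
            fit.draws["var_up"] + fit.draws["var_us"])
        lam, _ = estimate_lambda(fit)
        assert lam == pytest.approx(0.5)


class TestStandardizedPredict:
    def test_imputed_se_exceeds_measured(self):
        tree = simulate_tree(30, seed=3)
        cfg = SimConfig(n_species=30, prop_missing=0.5, seed=3)
        truth = simulate_traits(tree, cfg)
        table = simulate_trait_table(truth, cfg)
        result = run_bace(table, tree, n_cycles=2, mcmc=FAST, seed=3)
        med = result.imputed[result.imputed.level == "median"]
        se_imp = med.loc[med.provenance == "fully-imputed", "ctmax_se"]
        se_exp = med.loc[med.provenance == "experimental-informed", "ctmax_se"]
        assert se_imp.mean() >= se_exp.mean()

    def test_sister_shrinkage(self):
        # unmeasured tip b is sister to hot-measured a; prediction for b
        # should sit closer to a than to the cool distant clade
        tree = read_newick(
            "(((a:1,b:1):1,(c:1,d:1):1):1,((e:1,f:1):1,(g:1,h:1):1):1);")
        species = ["a"] * 4 + ["c", "d", "e", "f", "g", "h"]
        ctmax = [40.0] * 4 + [32.0] * 6
        df = _table(species, ctmax, se=0.2)
        df = pd.concat([df, _table(["b"], [np.nan], se=[np.nan],
                                   t_acc=[np.nan])], ignore_index=True)
        result = run_bace(df, tree, n_cycles=2, mcmc=FAST, seed=0)
        med = result.imputed[result.imputed.level == "median"]
        pred_b = float(med.loc[med.species == "b", "ctmax_hat"].iloc[0])
        assert pred_b > 33.5  # pulled up toward its hot sister

    def test_consistency_at_own_mean_t_acc(self):
        tree = simulate_tree(25, seed=4)
        cfg = SimConfig(n_species=25, prop_missing=0.0, residual_sd=0.1,
                        seed=4, max_records=8)
        truth = simulate_traits(tree, cfg)
        table = simulate_trait_table(truth, cfg)
        comp = initialize_missing(table, seed=0)
        fit = fit_phylo_mixed_model(comp, tree, FAST, seed=0)
        sp = comp.species.value_counts().idxmax()
        rows = comp[comp.species == sp]
        mu, sd = standardized_predict(fit, sp, float(rows.t_acc.mean()))
        # compare against the species' records adjusted to reference
        # conditions using the true generating effects
        adj = rows.ctmax - truth.effects["ecotype"][
            truth.ecotype[truth.species.index(sp)]]
        assert abs(mu - adj.mean()) < 3.0

    def test_unknown_species_error(self, small_truth_table):
        tree, _, table = small_truth_table
        comp = initialize_missing(table, seed=0)
        fit = fit_phylo_mixed_model(comp, tree, FAST, seed=0)
        with pytest.raises(KeyError):
            standardized_predict(fit, "not_a_species", 22.0)

    def test_out_of_range_warns(self, small_truth_table):
        tree, _, table = small_truth_table
        comp = initialize_missing(table, seed=0)
        fit = fit_phylo_mixed_model(comp, tree, FAST, seed=0)
        with pytest.warns(UserWarning, match="outside training range"):
            standardized_predict(fit, fit.model_species[0], 99.0)


class TestRunBace:
    def test_no_missing_single_fit(self):
        tree = simulate_tree(15, seed=5)
        cfg = SimConfig(n_species=15, prop_missing=0.0, seed=5)
        truth = simulate_traits(tree, cfg)
        table = simulate_trait_table(truth, cfg).dropna()
        result = run_bace(table, tree, n_cycles=5, mcmc=FAST, seed=1)
        assert len(result.drift) == 1  # cycles collapse when nothing to do
        assert set(result.imputed.level) == {"p5", "median", "p95"}
        assert (result.imputed.groupby("species").size() == 3).all()

    def test_observed_never_overwritten(self, small_truth_table):
        tree, _, table = small_truth_table
        result = run_bace(table, tree, n_cycles=2, mcmc=FAST, seed=2)
        obs = table.ctmax.notna()
        pd.testing.assert_series_equal(result.completed.loc[obs, "ctmax"],
                                       table.loc[obs, "ctmax"])

    def test_converged_after_first_cycle(self):
        # imputations move far less between cycles 1 and 5 than between
        # the naive initialization and cycle 1
        tree = simulate_tree(40, seed=6)
        cfg = SimConfig(n_species=40, prop_missing=0.5, seed=6)
        truth = simulate_traits(tree, cfg)
        table = simulate_trait_table(truth, cfg)
        result = run_bace(table, tree, n_cycles=5, mcmc=FAST, seed=6)
        c0, c1, c5 = (result.cycle_values[i] for i in (0, 1, 5))
        assert np.mean(np.abs(c5 - c1)) < np.mean(np.abs(c1 - c0))

    def test_n_cycles_validation(self, small_truth_table):
        tree, _, table = small_truth_table
        with pytest.raises(ValueError):
            run_bace(table, tree, n_cycles=0, mcmc=FAST)

    def test_species_not_in_tree(self, small_truth_table):
        tree, _, table = small_truth_table
        bad = pd.concat([table, _table(["species_x"], [35.0])],
                        ignore_index=True)
        with pytest.raises(KeyError, match="species_x"):
            run_bace(bad, tree, n_cycles=1, mcmc=FAST)

    def test_refs_steer_reference_temperatures(self, small_truth_table):
        tree, _, table = small_truth_table
        species = sorted(table.species.unique())
        refs = pd.DataFrame({"species": species, "t_p5": 18.0,
                             "t_median": 23.0, "t_p95": 28.0})
        result = run_bace(table, tree, n_cycles=1, mcmc=FAST, seed=0,
                          t_acc_refs=refs)
        med = result.imputed[result.imputed.level == "median"]
        assert (med.t_acc_ref == 23.0).all()
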