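"""Species-holdout cross-validation and parameter-recovery harness."""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .impute import (MCMCSettings, REFERENCE_COVARIATES, run_bace,
                     standardized_predict)
from .phylo import Phylogeny
from .simulate import (SimConfig, simulate_traits, simulate_trait_table,
                       simulate_tree)

__all__ = ["CrossvalReport", "crossval_holdout", "recovery_suite"]


@dataclass
class CrossvalReport:
    n_species_held: int
    n_estimates: int
    pearson_r: float
    mean_obs: float
    sd_obs: float
    mean_imp: float
    sd_imp: float
    pairs: pd.DataFrame | None = None   # species, observed, imputed

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("pairs")
        return d


def _comparable_mask(table: pd.DataFrame) -> pd.Series:
    """Held-out records usable for scoring: observed response, observed
    acclimatization temperature, adult animals (predictions are adult-only).
    Other assay covariates are standardized away with the fitted fixed
    effects before comparison."""
    return (table["ctmax"].notna()
            & (table["life_stage"] == REFERENCE_COVARIATES["life_stage"])
            & table["t_acc"].notna())


def crossval_holdout(table: pd.DataFrame, tree: Phylogeny,
                     frac: float = 0.05, seed: int = 0,
                     n_cycles: int = 5,
                     mcmc: MCMCSettings | None = None,
                     min_held: int = 1) -> CrossvalReport:
    """Mask all CT_max data for a fraction of measured species (and the
    same fraction of data-deficient species, preserving the missingness
    ratio), rerun the imputation, and score predictions against the
    held-out records measured under reference conditions.
    """
    if not (0.0 < frac < 1.0):
        raise ValueError("frac must be in (0, 1)")
    rng = np.random.default_rng(seed)
    comparable = _comparable_mask(table)
    measured_species = np.array(sorted(set(table.loc[comparable, "species"])))
    deficient_species = np.array(sorted(
        set(table["species"]) - set(table.loc[table["ctmax"].notna(), "species"])))
    n_hold = max(min_held, int(round(frac * len(measured_species))))
    if n_hold >= len(measured_species):
        raise ValueError("holdout fraction leaves no species to train on")
    held = rng.choice(measured_species, size=n_hold, replace=False)
    if len(deficient_species):
        n_hold_def = min(len(deficient_species),
                         max(1, int(round(frac * len(deficient_species)))))
        rng.choice(deficient_species, size=n_hold_def, replace=False)  # parity draw

    masked = table.copy()
    held_set = set(held)
    hold_rows = masked["species"].isin(held_set)
    masked.loc[hold_rows, ["ctmax", "ctmax_se"]] = np.nan
    assert masked.loc[hold_rows, "ctmax"].isna().all()  # no leakage

    result = run_bace(masked, tree, n_cycles=n_cycles, mcmc=mcmc, seed=seed)
    fit = result.fit

    score_idx = table.index[comparable & table["species"].isin(held_set)]
    # standardize observed records to reference assay conditions with the
    # fitted fixed effects, then compare against standardized predictions
    completed_rows = result.completed.loc[score_idx]
    beta = fit.draws["beta"].mean(axis=0)
    X_rec = fit.design.matrix(completed_rows)[:, fit.active_idx]
    obs, imp = [], []
    for (idx, row), x_rec in zip(completed_rows.iterrows(), X_rec):
        t_acc = float(table.loc[idx, "t_acc"])
        meta = fit.species_meta.loc[row["species"]]
        x_ref = fit.design.reference_row(t_acc, str(meta["ecotype"]),
                                         float(meta["log_mass"]))[fit.active_idx]
        adjustment = float((x_rec - x_ref) @ beta)
        mu, _ = standardized_predict(fit, row["species"], t_acc)
        obs.append(float(table.loc[idx, "ctmax"]) - adjustment)
        imp.append(mu)
    if len(obs) < 3:
        raise ValueError("too few comparable held-out records to score")
    obs_a, imp_a = np.asarray(obs), np.asarray(imp)
    r = float(pearsonr(obs_a, imp_a).statistic)
    pairs = pd.DataFrame({"species": completed_rows["species"].to_numpy(),
                          "observed": obs_a, "imputed": imp_a})
    return CrossvalReport(
        n_species_held=int(len(held)), n_estimates=int(len(obs)),
        pearson_r=r,
        mean_obs=float(obs_a.mean()), sd_obs=float(obs_a.std(ddof=1)),
        mean_imp=float(imp_a.mean()), sd_imp=float(imp_a.std(ddof=1)),
        pairs=pairs,
    )


def recovery_suite(config: SimConfig, n_replicates: int = 5,
                   seed: int = 0, mcmc: MCMCSettings | None = None,
                   exact_variance: bool = True) -> dict:
    """Simulate-and-refit replicates: lambda estimate + CI coverage of the
    generating value, and acclimatization-slope recovery (bias, RMSE).

    ``exact_variance`` pins the realized phylogenetic variance share to the
    generating value in each replicate (conditional simulation), so CI
    coverage reflects posterior calibration rather than replicate-level
    fluctuation of the realized split.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    mcmc = mcmc or MCMCSettings(iterations=2000, burn_in=600, thin=2)
    reps = []
    for r in range(n_replicates):
        rep_seed = seed + 1000 * r
        tree = simulate_tree(config.n_species, seed=rep_seed)
        rng = np.random.default_rng(rep_seed)
        truth = simulate_traits(tree, config, rng=rng,
                                exact_variance=exact_variance)
        table = simulate_trait_table(truth, config, rng=rng)
        result = run_bace(table, tree, n_cycles=1 if config.prop_missing == 0
                          else 5, mcmc=mcmc, seed=rep_seed)
        lam_mean, lam_ci = result.fit.lambda_summary()
        it = result.fit.design.columns.index("t_acc_c")
        arr_hat = float(result.fit.draws["beta"][:, it].mean())
        reps.append({
            "seed": rep_seed,
            "lambda_mean": lam_mean,
            "lambda_ci95": list(lam_ci),
            "lambda_covered": bool(lam_ci[0] <= config.lambda_true <= lam_ci[1]),
            "arr_hat": arr_hat,
            "arr_error": arr_hat - config.arr_mean,
        })
    lam_means = np.array([x["lambda_mean"] for x in reps])
    arr_errors = np.array([x["arr_error"] for x in reps])
    return {
        "n_replicates": n_replicates,
        "lambda_true": config.lambda_true,
        "lambda_mean_of_means": float(lam_means.mean()),
        "lambda_ci_coverage": float(np.mean([x["lambda_covered"] for x in reps])),
        "arr_mean_true": config.arr_mean,
        "arr_bias": float(arr_errors.mean()),
        "arr_rmse": float(np.sqrt(np.mean(arr_errors ** 2))),
        "replicates": reps,
    }
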