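"""Iterative chained-equation imputation on a Bayesian phylogenetic mixed model.

The response model for heat-tolerance records is

    ctmax_i = x_i' beta + u_p[s(i)] + u_s[s(i)]
              + (beta_t + v_p[s(i)] + v_s[s(i)]) * (t_acc_i - t_center)
              + eps_i

with u_p, v_p ~ MVN(0, var * C) on the relatedness correlation matrix C,
u_s, v_s iid normal species effects, and eps_i ~ N(0, sigma_e^2 / w_i)
where w_i = 1 / ctmax_se_i^2 (inverse sampling-variance weights).  The
phylogenetic signal is reported as lambda = var_phylo / (var_phylo +
var_species) per posterior draw.

Fitting is by Gibbs sampling: all conditionals are conjugate (normal for
location blocks, inverse-gamma for variances).  Chained cycles impute the
incomplete predictors with fast empirical-Bayes phylogenetic regressions,
then refit the response model; species never measured are predicted with
the phylogenetic conditional (kriging) mean given the sampled effects of
measured species, which propagates both effect and variance uncertainty.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular

from .phylo import Phylogeny

__all__ = [
    "MCMCSettings", "PhyloMixedModelFit", "BaceResult",
    "initialize_missing", "fit_phylo_mixed_model", "standardized_predict",
    "run_bace", "estimate_lambda",
    "CONTINUOUS_PREDICTORS", "CATEGORICAL_PREDICTORS", "REFERENCE_COVARIATES",
]

# reference assay conditions used for every standardized prediction
REFERENCE_COVARIATES = {
    "acc_duration": 10.0,   # days
    "ramp_rate": 1.0,       # degC / min
    "endpoint": "onset_of_spasms",
    "medium": "water",
    "life_stage": "adult",
}

CONTINUOUS_PREDICTORS = ["t_acc", "acc_duration", "ramp_rate", "body_mass"]
CATEGORICAL_PREDICTORS = ["endpoint", "medium", "life_stage", "ecotype"]

_JITTER = 1e-8


@dataclass
class MCMCSettings:
    iterations: int = 4000
    burn_in: int = 1000
    thin: int = 3
    prior_shape: float = 1e-3
    prior_scale: float = 1e-3

    def __post_init__(self) -> None:
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be smaller than iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_draws(self) -> int:
        return (self.iterations - self.burn_in + self.thin - 1) // self.thin


# ---------------------------------------------------------------------
# initialization

def initialize_missing(table: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Cycle-0 fill: column mean for continuous, random observed draw for
    categorical.  Observed values are never touched."""
    rng = np.random.default_rng(seed)
    out = table.copy()
    for col in out.columns:
        if col == "species":
            continue
        missing = out[col].isna()
        if not missing.any():
            continue
        observed = out.loc[~missing, col]
        if len(observed) == 0:
            raise ValueError(f"column {col!r} has no observed values to fill from")
        if pd.api.types.is_numeric_dtype(out[col]):
            out.loc[missing, col] = float(observed.mean())
        else:
            out.loc[missing, col] = rng.choice(observed.to_numpy(),
                                               size=int(missing.sum()))
    return out


# ---------------------------------------------------------------------
# design matrix

class _Design:
    """Fixed-effect design with categorical reference levels pinned to the
    standardized assay conditions."""

    def __init__(self, table: pd.DataFrame):
        self.t_center = float(table["t_acc"].mean())
        self.mass_center = float(np.log(table["body_mass"]).median())
        self.levels: dict[str, list[str]] = {}
        for col in CATEGORICAL_PREDICTORS:
            obs = sorted(set(table[col].dropna().astype(str)))
            ref = REFERENCE_COVARIATES.get(col)
            if ref in obs:
                obs.remove(ref)
                obs = [ref] + obs
            self.levels[col] = obs  # first level is the reference
        self.columns = ["intercept", "t_acc_c", "dur_c", "ramp_c", "log_mass_c"]
        for col in CATEGORICAL_PREDICTORS:
            self.columns += [f"{col}={lv}" for lv in self.levels[col][1:]]

    def matrix(self, table: pd.DataFrame) -> np.ndarray:
        n = len(table)
        cols = [np.ones(n),
                table["t_acc"].to_numpy(float) - self.t_center,
                table["acc_duration"].to_numpy(float) - REFERENCE_COVARIATES["acc_duration"],
                table["ramp_rate"].to_numpy(float) - REFERENCE_COVARIATES["ramp_rate"],
                np.log(table["body_mass"].to_numpy(float)) - self.mass_center]
        for col in CATEGORICAL_PREDICTORS:
            vals = table[col].astype(str).to_numpy()
            for lv in self.levels[col][1:]:
                cols.append((vals == lv).astype(float))
        return np.column_stack(cols)

    def reference_row(self, t_acc: float, ecotype: str, log_mass: float) -> np.ndarray:
        """Design row at standardized assay conditions for one species."""
        x = np.zeros(len(self.columns))
        x[0] = 1.0
        x[1] = t_acc - self.t_center
        x[2] = 0.0
        x[3] = 0.0
        x[4] = log_mass - self.mass_center
        name = f"ecotype={ecotype}"
        if name in self.columns:
            x[self.columns.index(name)] = 1.0
        return x


# ---------------------------------------------------------------------
# Gibbs sampler

def _sample_mvn_block(Cinv: np.ndarray, var_p: float, D: np.ndarray,
                      m: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw from N(P^-1 m, P^-1) with P = Cinv/var_p + diag(D)."""
    P = Cinv / var_p
    P[np.diag_indices_from(P)] += D + _JITTER
    L = cholesky(P, lower=True)
    mean = cho_solve((L, True), m)
    z = rng.standard_normal(len(m))
    return mean + solve_triangular(L, z, lower=True, trans="T")


def _inv_gamma(shape: float, scale: float, rng: np.random.Generator) -> float:
    return scale / rng.gamma(shape)


def _split_update(var_a: float, var_b: float, Qa: float, Qb: float, S: int,
                  rng: np.random.Generator, n_steps: int = 5,
                  step: float = 0.6) -> tuple[float, float]:
    """Metropolis update of a two-component variance split.

    Samples (total, proportion) with a flat prior on the proportion and a
    1/total prior on the total, against the exact Gaussian quadratic-form
    likelihood exp(-Q/(2 var)) / var^(S/2) for each component.  A flat
    proportion prior avoids the U-shaped implied prior (overconfident
    boundary-hugging posteriors) of independent scale-free inverse-gamma
    updates.
    """
    def logpost(lt: float, lg: float) -> float:
        tot = np.exp(lt)
        rho = 1.0 / (1.0 + np.exp(-lg))
        va, vb = tot * rho, tot * (1.0 - rho)
        ll = (-S / 2.0 * (np.log(va) + np.log(vb))
              - Qa / (2.0 * va) - Qb / (2.0 * vb))
        # priors: total ~ 1/total (flat in log), rho ~ U(0,1); Jacobians:
        # d(total)/d(log total) cancels the 1/total prior; logit transform
        # contributes rho(1-rho)
        return ll + np.log(rho) + np.log(1.0 - rho)

    lt = np.log(var_a + var_b)
    lg = np.log(var_a / var_b) if var_b > 0 else 10.0
    lp = logpost(lt, lg)
    for _ in range(n_steps):
        lt_new = lt + step * rng.standard_normal()
        lg_new = lg + step * rng.standard_normal()
        lp_new = logpost(lt_new, lg_new)
        if np.log(rng.random()) < lp_new - lp:
            lt, lg, lp = lt_new, lg_new, lp_new
    tot = np.exp(lt)
    rho = 1.0 / (1.0 + np.exp(-lg))
    return tot * rho, tot * (1.0 - rho)


def _run_gibbs(y, X, tc, sp, w, Cinv, settings: MCMCSettings,
               rng: np.random.Generator, slopes: bool = True) -> dict:
    """Gibbs sampler for the weighted phylogenetic mixed model.

    sp: integer species index per record into the S model species.
    Cinv: inverse relatedness correlation among the S model species.
    Returns thinned posterior draws of all blocks.
    """
    n, p = X.shape
    S = Cinv.shape[0]
    a0, b0 = settings.prior_shape, settings.prior_scale
    beta_prior_prec = 1e-4  # weak N(0, 100^2) guard on fixed effects

    # start from weighted least squares
    XtW = X.T * w
    A = XtW @ X + beta_prior_prec * np.eye(p)
    beta = np.linalg.solve(A, XtW @ y)
    resid0 = y - X @ beta
    sigma_e2 = max(float(np.average(resid0 ** 2 * w)), 1e-6)
    u_p = np.zeros(S)
    u_s = np.zeros(S)
    v_p = np.zeros(S)
    v_s = np.zeros(S)
    var_up, var_us = 1.0, 1.0
    var_vp, var_vs = 1e-3, 1e-3

    count = np.bincount(sp, minlength=S).astype(float)

    draws = {k: [] for k in ("beta", "u_p", "u_s", "v_p", "v_s",
                             "var_up", "var_us", "var_vp", "var_vs",
                             "sigma_e2", "lambda")}
    for it in range(settings.iterations):
        tau = w / sigma_e2  # per-record precision

        # fixed effects (flat prior)
        slope_eff = (v_p + v_s)[sp] * tc if slopes else 0.0
        r = y - (u_p + u_s)[sp] - slope_eff
        XtT = X.T * tau
        A = XtT @ X + beta_prior_prec * np.eye(p)
        cA = cho_factor(A)
        mean = cho_solve(cA, XtT @ r)
        Lups = cholesky(A, lower=True)
        beta = mean + solve_triangular(Lups, rng.standard_normal(p),
                                       lower=True, trans="T")
        fixed = X @ beta

        # intercept blocks
        r = y - fixed - slope_eff - u_s[sp]
        D = np.bincount(sp, weights=tau, minlength=S)
        m = np.bincount(sp, weights=tau * r, minlength=S)
        u_p = _sample_mvn_block(Cinv, var_up, D, m, rng)

        r = y - fixed - slope_eff - u_p[sp]
        m = np.bincount(sp, weights=tau * r, minlength=S)
        post_var = 1.0 / (1.0 / var_us + D)
        u_s = post_var * m + np.sqrt(post_var) * rng.standard_normal(S)

        if slopes:
            intercept_eff = (u_p + u_s)[sp]
            r = y - fixed - intercept_eff - v_s[sp] * tc
            Dt = np.bincount(sp, weights=tau * tc * tc, minlength=S)
            m = np.bincount(sp, weights=tau * tc * r, minlength=S)
            v_p = _sample_mvn_block(Cinv, var_vp, Dt, m, rng)

            r = y - fixed - intercept_eff - v_p[sp] * tc
            m = np.bincount(sp, weights=tau * tc * r, minlength=S)
            post_var = 1.0 / (1.0 / var_vs + Dt)
            v_s = post_var * m + np.sqrt(post_var) * rng.standard_normal(S)
            slope_eff = (v_p + v_s)[sp] * tc

        # variance components: Metropolis on the phylo/species intercept
        # split (flat prior on the proportion), inverse-gamma for the rest
        var_up, var_us = _split_update(var_up, var_us,
                                       float(u_p @ Cinv @ u_p),
                                       float(u_s @ u_s), S, rng)
        if slopes:
            var_vp = _inv_gamma(a0 + S / 2.0, b0 + float(v_p @ Cinv @ v_p) / 2.0, rng)
            var_vs = _inv_gamma(a0 + S / 2.0, b0 + float(v_s @ v_s) / 2.0, rng)

        eps = y - fixed - (u_p + u_s)[sp] - slope_eff
        sigma_e2 = _inv_gamma(a0 + n / 2.0, b0 + float(np.sum(w * eps ** 2)) / 2.0, rng)

        if it >= settings.burn_in and (it - settings.burn_in) % settings.thin == 0:
            draws["beta"].append(beta.copy())
            draws["u_p"].append(u_p.copy())
            draws["u_s"].append(u_s.copy())
            draws["v_p"].append(v_p.copy())
            draws["v_s"].append(v_s.copy())
            draws["var_up"].append(var_up)
            draws["var_us"].append(var_us)
            draws["var_vp"].append(var_vp)
            draws["var_vs"].append(var_vs)
            draws["sigma_e2"].append(sigma_e2)
            draws["lambda"].append(var_up / (var_up + var_us))

    return {k: np.asarray(v) for k, v in draws.items()}


# ---------------------------------------------------------------------
# fitted-model container

@dataclass
class PhyloMixedModelFit:
    """Posterior draws plus the machinery to predict any tree species."""

    design: _Design
    draws: dict
    active_idx: np.ndarray          # design columns identified in training
    model_species: list[str]        # species with observed response
    all_species: list[str]          # every species predictions cover
    krig_weights: np.ndarray        # (n_new, S): C_um @ C_mm^-1
    krig_cond_var: np.ndarray       # (n_new,): diag of conditional correlation
    species_meta: pd.DataFrame      # per-species ecotype and log body mass
    t_train_range: tuple[float, float]
    seed: int = 0
    _new_effect_cache: dict = field(default_factory=dict, repr=False)

    @property
    def n_draws(self) -> int:
        return len(self.draws["lambda"])

    def lambda_summary(self) -> tuple[float, tuple[float, float]]:
        lam = self.draws["lambda"]
        lo, hi = np.percentile(lam, [2.5, 97.5])
        return float(lam.mean()), (float(lo), float(hi))

    def fixed_effects_summary(self) -> pd.DataFrame:
        beta = self.draws["beta"]
        return pd.DataFrame({
            "term": [self.design.columns[j] for j in self.active_idx],
            "mean": beta.mean(axis=0),
            "sd": beta.std(axis=0),
        })

    def variance_summary(self) -> dict:
        d = self.draws
        out = {k: float(np.mean(d[k])) for k in
               ("var_up", "var_us", "var_vp", "var_vs", "sigma_e2")}
        lam_mean, lam_ci = self.lambda_summary()
        out["lambda_mean"] = lam_mean
        out["lambda_ci95"] = list(lam_ci)
        return out

    # -- per-species random effects over draws -------------------------

    def _species_effects(self, species: str) -> tuple[np.ndarray, np.ndarray]:
        """(intercept deviation, slope deviation) per posterior draw."""
        if species in self._new_effect_cache:
            return self._new_effect_cache[species]
        nd = self.n_draws
        if species in self.model_species:
            j = self.model_species.index(species)
            ueff = self.draws["u_p"][:, j] + self.draws["u_s"][:, j]
            veff = self.draws["v_p"][:, j] + self.draws["v_s"][:, j]
        else:
            new_idx = self.all_species.index(species)
            model_set = set(self.model_species)
            new_order = [s for s in self.all_species if s not in model_set]
            row = new_order.index(species)
            kw = self.krig_weights[row]
            cvar = max(float(self.krig_cond_var[row]), 0.0)
            rng = np.random.default_rng([self.seed, 7919, new_idx])
            z = rng.standard_normal((4, nd))
            u_mean = self.draws["u_p"] @ kw
            v_mean = self.draws["v_p"] @ kw
            ueff = (u_mean + np.sqrt(self.draws["var_up"] * cvar) * z[0]
                    + np.sqrt(self.draws["var_us"]) * z[1])
            veff = (v_mean + np.sqrt(self.draws["var_vp"] * cvar) * z[2]
                    + np.sqrt(self.draws["var_vs"]) * z[3])
        self._new_effect_cache[species] = (ueff, veff)
        return ueff, veff

    def predict(self, species: str, t_acc: float) -> tuple[float, float]:
        return standardized_predict(self, species, t_acc)

    def arr_slope(self, species: str) -> tuple[float, float]:
        """Posterior mean and sd of the species' acclimatization slope."""
        _, veff = self._species_effects(species)
        it = list(self.active_idx).index(self.design.columns.index("t_acc_c"))
        total = self.draws["beta"][:, it] + veff
        return float(total.mean()), float(total.std())


def standardized_predict(fit: PhyloMixedModelFit, species: str,
                         t_acc: float) -> tuple[float, float]:
    """Prediction at standardized assay conditions for one species.

    Returns posterior mean and sd over draws; the sd carries fixed-effect,
    random-effect and variance-split uncertainty.  Predictions outside the
    training acclimatization range (±5 degC guard band) emit a warning.
    """
    if species not in fit.all_species:
        raise KeyError(f"species {species!r} not covered by the fitted tree")
    lo, hi = fit.t_train_range
    if not (lo - 5.0 <= t_acc <= hi + 5.0):
        warnings.warn(f"t_acc={t_acc:.1f} outside training range "
                      f"[{lo:.1f}, {hi:.1f}] +- 5 for {species}")
    meta = fit.species_meta.loc[species]
    x = fit.design.reference_row(t_acc, str(meta["ecotype"]),
                                 float(meta["log_mass"]))[fit.active_idx]
    ueff, veff = fit._species_effects(species)
    pred = fit.draws["beta"] @ x + ueff + veff * (t_acc - fit.design.t_center)
    return float(pred.mean()), float(max(pred.std(), 1e-9))


# ---------------------------------------------------------------------
# model fitting

def fit_phylo_mixed_model(table: pd.DataFrame, tree: Phylogeny,
                          settings: MCMCSettings | None = None,
                          seed: int = 0, slopes: bool = True,
                          design: _Design | None = None) -> PhyloMixedModelFit:
    """Fit the weighted phylogenetic mixed model on completed records.

    Records with an observed ``ctmax`` (and positive ``ctmax_se``) train the
    model; every species of the table enters the prediction machinery, with
    unmeasured species handled by the phylogenetic conditional.
    """
    settings = settings or MCMCSettings()
    obs = table[table["ctmax"].notna()].copy()
    if obs["species"].nunique() < 2:
        raise ValueError("need observed CT_max for at least 2 species")
    if obs["ctmax_se"].isna().any() or (obs["ctmax_se"] <= 0).any():
        raise ValueError("every observed ctmax needs a positive ctmax_se")
    for col in CONTINUOUS_PREDICTORS + CATEGORICAL_PREDICTORS:
        if table[col].isna().any():
            raise ValueError(f"predictor {col!r} still has missing values; "
                             "run initialize_missing / the chained cycles first")

    all_species = sorted(table["species"].unique())
    missing_tips = set(all_species) - set(tree.tips)
    if missing_tips:
        raise KeyError(f"species absent from tree: {sorted(missing_tips)[:5]}")
    sub = tree.prune(all_species)
    corr = sub.covariance(lam=1.0, normalize=True)
    order = {s: i for i, s in enumerate(corr.labels)}

    model_species = sorted(obs["species"].unique())
    midx = np.array([order[s] for s in model_species])
    C_mm = corr.matrix[np.ix_(midx, midx)]
    C_mm_reg = C_mm + _JITTER * np.eye(len(midx))
    cf = cho_factor(C_mm_reg)
    Cinv = cho_solve(cf, np.eye(len(midx)))

    new_species = [s for s in all_species if s not in set(model_species)]
    if new_species:
        nidx = np.array([order[s] for s in new_species])
        C_nm = corr.matrix[np.ix_(nidx, midx)]
        krig = cho_solve(cf, C_nm.T).T               # C_nm @ C_mm^-1
        cond = np.diag(corr.matrix)[nidx] - np.sum(krig * C_nm, axis=1)
        cond = np.clip(cond, 0.0, None)
    else:
        krig = np.zeros((0, len(midx)))
        cond = np.zeros(0)

    design = design or _Design(table)
    X_full = design.matrix(obs)
    # drop design columns without variation in the training records (e.g. an
    # ecotype absent from measured species): unidentified, treated as baseline
    active = [0] + [j for j in range(1, X_full.shape[1])
                    if np.ptp(X_full[:, j]) > 0]
    if len(active) < X_full.shape[1]:
        dropped = [design.columns[j] for j in range(X_full.shape[1])
                   if j not in active]
        warnings.warn(f"dropping unidentified fixed effects: {dropped}")
    active_idx = np.asarray(active)
    X = X_full[:, active_idx]
    y = obs["ctmax"].to_numpy(float)
    w = 1.0 / obs["ctmax_se"].to_numpy(float) ** 2
    tc = obs["t_acc"].to_numpy(float) - design.t_center
    sp_lookup = {s: i for i, s in enumerate(model_species)}
    sp = obs["species"].map(sp_lookup).to_numpy()

    rng = np.random.default_rng(seed)
    draws = _run_gibbs(y, X, tc, sp, w, Cinv, settings, rng, slopes=slopes)

    meta = (table.assign(log_mass=np.log(table["body_mass"].astype(float)))
            .groupby("species")
            .agg(ecotype=("ecotype", lambda s: s.mode().iat[0]),
                 log_mass=("log_mass", "mean")))
    return PhyloMixedModelFit(
        design=design, draws=draws, active_idx=active_idx,
        model_species=model_species, all_species=all_species,
        krig_weights=krig, krig_cond_var=cond, species_meta=meta,
        t_train_range=(float(obs["t_acc"].min()), float(obs["t_acc"].max())),
        seed=seed,
    )


def estimate_lambda(fit: PhyloMixedModelFit) -> tuple[float, tuple[float, float]]:
    """Posterior mean and central 95% interval of the phylogenetic
    variance proportion."""
    return fit.lambda_summary()


# ---------------------------------------------------------------------
# chained predictor sub-models (empirical-Bayes phylogenetic regression)

_H_GRID = (0.05, 0.25, 0.5, 0.75, 0.95)


def _phylo_gls(z: np.ndarray, X: np.ndarray, C_oo: np.ndarray):
    """Profile the phylogenetic variance share h on a grid; return the
    best-h GLS machinery (beta, V^-1 residual, h, sigma2)."""
    n = len(z)
    best = None
    for h in _H_GRID:
        V = h * C_oo + (1.0 - h) * np.eye(n)
        cf = cho_factor(V + _JITTER * np.eye(n))
        Vi_X = cho_solve(cf, X)
        Vi_z = cho_solve(cf, z)
        A = X.T @ Vi_X + _JITTER * np.eye(X.shape[1])
        beta = np.linalg.solve(A, X.T @ Vi_z)
        r = z - X @ beta
        Vi_r = cho_solve(cf, r)
        sigma2 = max(float(r @ Vi_r) / n, 1e-10)
        logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        ll = -0.5 * (n * np.log(sigma2) + logdet + n)
        if best is None or ll > best[0]:
            best = (ll, h, beta, Vi_r, sigma2)
    return best[1], best[2], best[3], best[4]


def _chained_impute_predictor(col: str, table: pd.DataFrame,
                              orig_missing: pd.Series, corr_matrix: np.ndarray,
                              order: dict, design_cols: list[str]) -> pd.DataFrame:
    """Species-level phylogenetic regression of one incomplete predictor on
    the others; originally-missing cells are replaced by conditional means
    (argmax class for categoricals)."""
    work = table.copy()
    is_cat = col in CATEGORICAL_PREDICTORS
    # species-level response: mean (continuous) or mode (categorical) of
    # originally-observed cells
    obs_rows = work.loc[~orig_missing]
    if obs_rows.empty:
        return table
    if is_cat:
        resp = obs_rows.groupby("species")[col].agg(lambda s: s.mode().iat[0])
    else:
        resp = obs_rows.groupby("species")[col].mean()

    # species-level design from the other predictors (current filled values)
    feats = work.groupby("species").agg(
        ctmax=("ctmax", "mean"),
        t_acc=("t_acc", "mean"),
        acc_duration=("acc_duration", "mean"),
        ramp_rate=("ramp_rate", "mean"),
        log_mass=("body_mass", lambda s: float(np.log(s.astype(float)).mean())),
    )
    Xdf = feats.drop(columns=[c for c in feats.columns if c == col],
                     errors="ignore")
    X_all = np.column_stack([np.ones(len(Xdf))] +
                            [Xdf[c].to_numpy(float) - Xdf[c].mean()
                             for c in Xdf.columns])

    sp_all = list(feats.index)
    obs_sp = [s for s in sp_all if s in resp.index]
    mis_sp = [s for s in sp_all if s not in resp.index]
    oidx = np.array([order[s] for s in obs_sp])
    pos = {s: i for i, s in enumerate(sp_all)}
    X_obs = X_all[[pos[s] for s in obs_sp]]
    C_oo = corr_matrix[np.ix_(oidx, oidx)]

    def conditional_mean(z_obs: np.ndarray) -> pd.Series:
        h, beta, Vi_r, _ = _phylo_gls(z_obs, X_obs, C_oo)
        pred = pd.Series(index=sp_all, dtype=float)
        pred.loc[obs_sp] = z_obs  # keep species-level observed value
        if mis_sp:
            m_idx = np.array([order[s] for s in mis_sp])
            C_mo = corr_matrix[np.ix_(m_idx, oidx)]
            X_mis = X_all[[pos[s] for s in mis_sp]]
            pred.loc[mis_sp] = X_mis @ beta + h * (C_mo @ Vi_r)
        return pred

    if is_cat:
        levels = sorted(set(resp))
        if len(levels) == 1:
            fill = pd.Series(levels[0], index=sp_all)
        else:
            scores = {}
            for lv in levels:
                z = (resp.loc[obs_sp] == lv).to_numpy(float)
                scores[lv] = conditional_mean(z)
            score_df = pd.DataFrame(scores)
            fill = score_df.idxmax(axis=1)
        values = work["species"].map(fill)
    else:
        z = resp.loc[obs_sp].to_numpy(float)
        pred = conditional_mean(z)
        lo, hi = float(np.min(z)), float(np.max(z))
        pred = pred.clip(lo, hi)  # keep imputations inside the observed range
        values = work["species"].map(pred)
    work.loc[orig_missing, col] = values.loc[orig_missing]
    return work


# ---------------------------------------------------------------------
# BACE driver

@dataclass
class BaceResult:
    imputed: pd.DataFrame          # species x level standardized predictions
    fit: PhyloMixedModelFit
    drift: list[float]             # mean |change| of imputed CT_max per cycle
    completed: pd.DataFrame        # final completed training table
    cycle_values: list[np.ndarray] = field(default_factory=list)
    # imputed-CT_max vectors per cycle (cycle 0 = naive initialization)


def run_bace(table: pd.DataFrame, tree: Phylogeny, n_cycles: int = 5,
             mcmc: MCMCSettings | None = None, seed: int = 0,
             t_acc_refs: pd.DataFrame | None = None) -> BaceResult:
    """Chained-equation imputation with a phylogenetic mixed model core.

    Cycle 0 fills gaps naively; each subsequent cycle re-imputes every
    incomplete predictor with a phylogenetic regression on the others, then
    refits the response model and refreshes imputed CT_max values.  After
    the last cycle, standardized predictions are emitted for every species
    at its three reference acclimatization temperatures.

    ``t_acc_refs``: optional frame with columns species, t_p5, t_median,
    t_p95 (range-wide operative-temperature percentiles).  Without it the
    pooled percentiles of observed acclimatization temperatures are used
    for every species.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    mcmc = mcmc or MCMCSettings()
    missing_tips = set(table["species"]) - set(tree.tips)
    if missing_tips:
        raise KeyError(f"species absent from tree: {sorted(missing_tips)[:5]}")

    orig_missing = {c: table[c].isna() for c in table.columns if c != "species"}
    ctmax_missing = orig_missing["ctmax"]
    any_missing = any(m.any() for m in orig_missing.values())

    completed = initialize_missing(table, seed=seed)
    # SE for records with imputed response: start at the observed-SE scale
    se_floor = float(table["ctmax_se"].dropna().median()) if ctmax_missing.any() else 0.0

    sub = tree.prune(sorted(table["species"].unique()))
    corr = sub.covariance(lam=1.0, normalize=True)
    order = {s: i for i, s in enumerate(corr.labels)}

    design = _Design(completed)
    drift: list[float] = []
    fit = None
    prev_imputed = completed.loc[ctmax_missing, "ctmax"].to_numpy(float).copy()
    cycle_values = [prev_imputed.copy()]

    effective_cycles = n_cycles if any_missing else 1
    for cycle in range(1, effective_cycles + 1):
        if any_missing:
            for col in CONTINUOUS_PREDICTORS + CATEGORICAL_PREDICTORS:
                if orig_missing[col].any():
                    completed = _chained_impute_predictor(
                        col, completed, orig_missing[col], corr.matrix,
                        order, design.columns)
        train = completed.copy()
        # only genuinely observed responses train the model
        train.loc[ctmax_missing, "ctmax"] = np.nan
        train.loc[ctmax_missing, "ctmax_se"] = np.nan
        # common random numbers across cycles: per-cycle changes in the
        # imputations then reflect data-driven drift, not sampler noise
        fit = fit_phylo_mixed_model(train, tree, settings=mcmc,
                                    seed=seed + 1, design=design)
        if ctmax_missing.any():
            new_vals = np.empty(int(ctmax_missing.sum()))
            new_ses = np.empty_like(new_vals)
            rows = completed.loc[ctmax_missing]
            for k, (_, row) in enumerate(rows.iterrows()):
                mu, sd = standardized_predict(fit, row["species"],
                                              float(row["t_acc"]))
                new_vals[k] = mu
                new_ses[k] = max(sd, se_floor * 0.1)
            completed.loc[ctmax_missing, "ctmax"] = new_vals
            completed.loc[ctmax_missing, "ctmax_se"] = new_ses
            drift.append(float(np.mean(np.abs(new_vals - prev_imputed))))
            prev_imputed = new_vals.copy()
            cycle_values.append(new_vals.copy())
        else:
            drift.append(0.0)
            cycle_values.append(prev_imputed.copy())

    # reference acclimatization temperatures
    if t_acc_refs is not None:
        refs = t_acc_refs.set_index("species")
    else:
        pooled = table["t_acc"].dropna().to_numpy(float)
        p5, med, p95 = np.percentile(pooled, [5, 50, 95])
        refs = pd.DataFrame(
            {"t_p5": p5, "t_median": med, "t_p95": p95},
            index=sorted(table["species"].unique()))

    measured = set(table.loc[~ctmax_missing, "species"])
    rows = []
    for sp in fit.all_species:
        if sp not in refs.index:
            continue
        for level, col in (("p5", "t_p5"), ("median", "t_median"),
                           ("p95", "t_p95")):
            t_ref = float(refs.loc[sp, col])
            mu, sd = standardized_predict(fit, sp, t_ref)
            rows.append({
                "species": sp, "level": level, "t_acc_ref": t_ref,
                "ctmax_hat": mu, "ctmax_se": sd,
                "provenance": ("experimental-informed" if sp in measured
                               else "fully-imputed"),
            })
    imputed = pd.DataFrame(rows)
    return BaceResult(imputed=imputed, fit=fit, drift=drift,
                      completed=completed, cycle_values=cycle_values)
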