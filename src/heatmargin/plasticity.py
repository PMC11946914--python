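"""Per-species weighted meta-regression of CT_max on acclimatization
temperature, and daily plasticity-adjusted CT_max projection."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PlasticityModel", "fit_species_plasticity", "predict_ctmax",
           "project_daily_ctmax", "fit_all_species"]


@dataclass
class PlasticityModel:
    """Inverse-variance-weighted line CT_max = intercept + slope * t_acc."""

    species: str
    intercept: float
    slope_arr: float
    coef_covariance: np.ndarray   # 2x2, (intercept, slope) ordering
    residual_tau2: float = 0.0
    t_range: tuple[float, float] = (-np.inf, np.inf)

    def __post_init__(self) -> None:
        self.coef_covariance = np.asarray(self.coef_covariance, dtype=float)
        if self.coef_covariance.shape != (2, 2):
            raise ValueError("coef_covariance must be 2x2")


def fit_species_plasticity(points: pd.DataFrame,
                           include_tau2: bool = False) -> PlasticityModel:
    """Weighted meta-regression on the species' standardized estimates.

    ``points`` needs columns species, t_acc_ref, ctmax_hat, ctmax_se; the
    coefficient covariance is (X' W X)^-1 with W = 1/se^2, the fixed-effect
    meta-analytic convention.
    """
    t = points["t_acc_ref"].to_numpy(float)
    y = points["ctmax_hat"].to_numpy(float)
    se = points["ctmax_se"].to_numpy(float)
    if len(points) < 2:
        raise ValueError("need at least 2 points to fit a slope")
    if np.any(~np.isfinite(se)) or np.any(se <= 0):
        raise ValueError("all standard errors must be positive and finite")
    if np.ptp(t) == 0:
        raise ValueError("identical acclimatization temperatures: "
                         "slope unidentifiable")
    w = 1.0 / se ** 2
    X = np.column_stack([np.ones_like(t), t])
    A = (X.T * w) @ X
    cov = np.linalg.inv(A)
    beta = cov @ (X.T @ (w * y))
    tau2 = 0.0
    if include_tau2 and len(points) > 2:
        resid = y - X @ beta
        q = float(np.sum(w * resid ** 2))
        dof = len(points) - 2
        # DerSimonian-Laird style moment estimate
        denom = float(np.sum(w) - np.sum(w ** 2) / np.sum(w))
        tau2 = max(0.0, (q - dof) / denom) if denom > 0 else 0.0
    species = str(points["species"].iloc[0]) if "species" in points else ""
    return PlasticityModel(species=species, intercept=float(beta[0]),
                           slope_arr=float(beta[1]), coef_covariance=cov,
                           residual_tau2=tau2,
                           t_range=(float(t.min()), float(t.max())))


def predict_ctmax(model: PlasticityModel, t_acc,
                  include_tau2: bool = False):
    """Point prediction with SE from the coefficient covariance.

    Accepts scalar or array ``t_acc``; returns (ctmax, se, extrapolated)
    with matching shape.
    """
    t = np.asarray(t_acc, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    pred = model.intercept + model.slope_arr * t
    c = model.coef_covariance
    var = c[0, 0] + 2.0 * c[0, 1] * t + c[1, 1] * t ** 2
    if include_tau2:
        var = var + model.residual_tau2
    se = np.sqrt(np.clip(var, 0.0, None))
    extrap = (t < model.t_range[0]) | (t > model.t_range[1])
    if scalar:
        return float(pred[0]), float(se[0]), bool(extrap[0])
    return pred, se, extrap


def project_daily_ctmax(model: PlasticityModel, exposure: pd.DataFrame,
                        acclim_stat: str = "week_mean",
                        include_tau2: bool = False) -> pd.DataFrame:
    """Daily plasticity-adjusted CT_max along one cell's exposure series.

    Each retained day's acclimatization temperature is its trailing-week
    statistic (``week_mean`` by default; ``week_max`` for the conservative
    variant), already computed by the exposure stage.
    """
    if acclim_stat not in ("week_mean", "week_max"):
        raise ValueError("acclim_stat must be week_mean or week_max")
    if exposure[acclim_stat].isna().any():
        raise ValueError("exposure rows without trailing-week history")
    t = exposure[acclim_stat].to_numpy(float)
    pred, se, _ = predict_ctmax(model, t, include_tau2=include_tau2)
    out = exposure.copy()
    out["ctmax_day"] = pred
    out["ctmax_day_se"] = se
    out["species"] = model.species
    return out


def fit_all_species(imputed: pd.DataFrame,
                    include_tau2: bool = False) -> dict[str, PlasticityModel]:
    """Fit one meta-regression per species from the imputed table."""
    models = {}
    for sp, grp in imputed.groupby("species", sort=True):
        models[sp] = fit_species_plasticity(grp, include_tau2=include_tau2)
    return models
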