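"""Per-occurrence vulnerability metrics: thermal safety margin, expected
overheating-day count with binomial SE, and binary overheating risk.

Daily exceedance probabilities are normal upper-tail probabilities of the
simulated CT_max distribution, with its SE capped (default 1 degC) so
imputation uncertainty cannot inflate overheating counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = ["SigmaPolicy", "VulnerabilityRecord", "daily_tsm",
           "weighted_mean_se", "exceedance_probability", "overheating_days",
           "binary_risk", "tsm_summary", "assess_occurrences",
           "DEFAULT_N_DAYS"]

DEFAULT_N_DAYS = 910  # 91 warmest days x 10 non-burn-in years


@dataclass
class SigmaPolicy:
    """How the CT_max SE enters the exceedance probability."""

    cap: float = 1.0
    mode: str = "fixed_cap"   # fixed_cap | biological_range | none
    biological_cap: float = 2.0   # cross-species CT_max sd, printed band 1.84-2.17

    def __post_init__(self) -> None:
        if self.cap <= 0:
            raise ValueError("cap must be positive")
        if self.mode not in ("fixed_cap", "biological_range", "none"):
            raise ValueError(f"unknown sigma mode {self.mode!r}")

    def sigma(self, se):
        se = np.asarray(se, dtype=float)
        if self.mode == "fixed_cap":
            return np.minimum(se, self.cap)
        if self.mode == "biological_range":
            return np.minimum(se, self.biological_cap)
        return se


def daily_tsm(ctmax_day, daily_max):
    """CT_max minus daily maximum temperature; negative means overheating."""
    return np.asarray(ctmax_day, dtype=float) - np.asarray(daily_max, dtype=float)


def weighted_mean_se(values, ses) -> tuple[float, float]:
    """Inverse-variance weighted mean and its standard error."""
    values = np.asarray(values, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if values.size == 0:
        raise ValueError("empty input")
    if values.shape != ses.shape:
        raise ValueError("values and ses must have equal length")
    if np.any(ses <= 0):
        raise ValueError("standard errors must be positive")
    w = 1.0 / ses ** 2
    mean = float(np.sum(w * values) / np.sum(w))
    se = float(np.sqrt(1.0 / np.sum(w)))
    return mean, se


def exceedance_probability(daily_max, ctmax_day, ctmax_se,
                           policy: SigmaPolicy | None = None):
    """P(operative temperature exceeds the CT_max distribution) per day:
    Phi((daily_max - ctmax_day) / sigma) with the policy-capped sigma."""
    policy = policy or SigmaPolicy()
    se = np.asarray(ctmax_se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("ctmax_se must be positive")
    sigma = policy.sigma(se)
    z = (np.asarray(daily_max, dtype=float)
         - np.asarray(ctmax_day, dtype=float)) / sigma
    return norm.cdf(z)


def overheating_days(p_series, n_days: int = DEFAULT_N_DAYS) -> tuple[float, float]:
    """Expected overheating-day count and binomial SE from daily
    exceedance probabilities: n = mean(p) * n_days, se = sqrt(n_days p (1-p))."""
    p = np.asarray(p_series, dtype=float)
    if p.size == 0:
        raise ValueError("empty probability series")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    p_bar = float(p.mean())
    n = p_bar * n_days
    se = float(np.sqrt(n_days * p_bar * (1.0 - p_bar)))
    return float(n), se


def binary_risk(daily_max, ctmax_day, variant: str = "default",
                n: float | None = None, se: float | None = None) -> int:
    """1 if the species overheats on at least one day.

    ``default``: point-estimate rule, any day with daily_max > ctmax_day.
    ``ci``: 1 only if the 95% interval n +- 1.96 se excludes zero from below.
    """
    if variant == "default":
        exceed = np.asarray(daily_max, dtype=float) > np.asarray(ctmax_day, dtype=float)
        return int(bool(exceed.any()))
    if variant == "ci":
        if n is None or se is None:
            raise ValueError("ci variant needs n and se from overheating_days")
        return int(n - 1.96 * se > 0)
    raise ValueError(f"unknown risk variant {variant!r}")


@dataclass
class VulnerabilityRecord:
    species: str
    cell_id: str
    microhabitat: str
    scenario: str
    tsm_mean: float
    tsm_se: float
    p_bar: float
    n_overheat_days: float
    n_overheat_se: float
    risk_binary: int
    n_days_total: int


def tsm_summary(days: pd.DataFrame, policy: SigmaPolicy | None = None,
                variant: str = "default",
                n_days_total: int | None = None) -> VulnerabilityRecord:
    """All three metrics for one occurrence's aligned daily series.

    ``days`` carries one row per retained day with daily_max, ctmax_day,
    ctmax_day_se (plus species/cell_id/microhabitat/scenario passthrough).
    Variants: ``default``; ``p95-tsm`` (TSM against the 95th-percentile
    temperature of the period); ``max-tsm`` (against the period maximum);
    ``trimmed`` (days outside the 5th-95th temperature percentiles
    excluded); ``ci-risk`` (binary risk from the day-count interval).
    """
    policy = policy or SigmaPolicy()
    if days.empty:
        raise ValueError("no aligned days for this occurrence")
    required = {"daily_max", "ctmax_day", "ctmax_day_se"}
    if not required <= set(days.columns):
        raise ValueError(f"need columns {sorted(required)}")

    work = days
    if variant == "trimmed":
        lo, hi = np.percentile(days["daily_max"].to_numpy(float), [5, 95])
        work = days[(days["daily_max"] >= lo) & (days["daily_max"] <= hi)]

    temps = work["daily_max"].to_numpy(float)
    ct = work["ctmax_day"].to_numpy(float)
    ses = work["ctmax_day_se"].to_numpy(float)

    if variant == "p95-tsm":
        ref_temp = float(np.percentile(temps, 95))
        ct_mean, ct_se = weighted_mean_se(ct, ses)
        tsm_mean, tsm_se = ct_mean - ref_temp, ct_se
    elif variant == "max-tsm":
        ref_temp = float(temps.max())
        ct_mean, ct_se = weighted_mean_se(ct, ses)
        tsm_mean, tsm_se = ct_mean - ref_temp, ct_se
    else:
        tsm_mean, tsm_se = weighted_mean_se(daily_tsm(ct, temps), ses)

    n_total = n_days_total if n_days_total is not None else len(work)
    p = exceedance_probability(temps, ct, ses, policy)
    n, n_se = overheating_days(p, n_days=n_total)
    risk = binary_risk(temps, ct, variant="ci" if variant == "ci-risk" else "default",
                       n=n, se=n_se)

    def _meta(col, default=""):
        return str(work[col].iloc[0]) if col in work.columns else default

    return VulnerabilityRecord(
        species=_meta("species"), cell_id=_meta("cell_id"),
        microhabitat=_meta("microhabitat"), scenario=_meta("scenario"),
        tsm_mean=float(tsm_mean), tsm_se=float(tsm_se),
        p_bar=float(p.mean()), n_overheat_days=float(n),
        n_overheat_se=float(n_se), risk_binary=int(risk),
        n_days_total=int(n_total),
    )


def assess_occurrences(daily: pd.DataFrame, policy: SigmaPolicy | None = None,
                       variant: str = "default") -> pd.DataFrame:
    """Apply :func:`tsm_summary` per (species, cell); returns the long
    vulnerability table."""
    records = []
    for (sp, cell), grp in daily.groupby(["species", "cell_id"], sort=True):
        rec = tsm_summary(grp, policy=policy, variant=variant)
        records.append(rec.__dict__)
    return pd.DataFrame(records)
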