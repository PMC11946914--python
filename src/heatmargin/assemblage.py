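"""Grid-cell assemblage aggregation and headline ratio statistics."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .vulnerability import DEFAULT_N_DAYS, weighted_mean_se

__all__ = ["aggregate_cell", "aggregate_all", "percent", "fold_change",
           "reduction_percent", "percent_of_days", "headline_stats"]


def aggregate_cell(records: pd.DataFrame, weighted: bool = True) -> dict:
    """Assemblage summary for one cell: weighted TSM across species plus
    overheating counts from the binary risks."""
    if records.empty:
        raise ValueError("no records for this cell")
    for col in ("scenario", "microhabitat", "cell_id"):
        if records[col].nunique() > 1:
            raise ValueError(f"mixed {col} values in one aggregation call")
    if weighted:
        tsm_mean, tsm_se = weighted_mean_se(records["tsm_mean"],
                                            records["tsm_se"])
    else:
        tsm = records["tsm_mean"].to_numpy(float)
        tsm_mean = float(tsm.mean())
        tsm_se = float(tsm.std(ddof=1) / np.sqrt(len(tsm))) if len(tsm) > 1 else float("nan")
    n_species = int(records["species"].nunique())
    n_over = int(records["risk_binary"].sum())
    return {
        "cell_id": records["cell_id"].iloc[0],
        "microhabitat": records["microhabitat"].iloc[0],
        "scenario": records["scenario"].iloc[0],
        "n_species": n_species,
        "tsm_mean": tsm_mean,
        "tsm_se": tsm_se,
        "n_overheating_species": n_over,
        "prop_overheating": n_over / n_species,
    }


def aggregate_all(records: pd.DataFrame, weighted: bool = True) -> pd.DataFrame:
    """Per-cell assemblage summaries for a homogeneous scenario/habitat
    vulnerability table."""
    rows = [aggregate_cell(grp, weighted=weighted)
            for _, grp in records.groupby("cell_id", sort=True)]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------
# headline ratios (numerators/denominators always reported alongside)

def percent(numerator: float, denominator: float,
            decimals: int = 1) -> float | None:
    """100 * numerator / denominator rounded for display; None if undefined."""
    if denominator == 0:
        return None
    return round(100.0 * numerator / denominator, decimals) if decimals > 0 \
        else round(100.0 * numerator / denominator)


def fold_change(after: float, before: float) -> float | None:
    if before == 0:
        return None
    return after / before


def reduction_percent(n_ground: float, n_refuge: float,
                      decimals: int = 1) -> float | None:
    """Percentage reduction when retreating from ground to refuge."""
    if n_ground == 0:
        return None
    return round(100.0 * (1.0 - n_refuge / n_ground), decimals)


def percent_of_days(n_days: float, total: int = DEFAULT_N_DAYS,
                    decimals: int = 1) -> float | None:
    return percent(n_days, total, decimals=decimals)


def headline_stats(vulnerability: dict[str, pd.DataFrame],
                   n_species_total: int,
                   n_days_total: int = DEFAULT_N_DAYS) -> dict:
    """Cross-scenario report from per-scenario vulnerability tables.

    ``vulnerability`` maps scenario name -> occurrence-level table for one
    microhabitat.  Percentages follow display conventions (overall species
    shares to one decimal); raw numerators and denominators are retained.
    """
    report: dict = {"n_species_total": n_species_total,
                    "n_days_total": n_days_total, "scenarios": {}}
    counts = {}
    for scen, df in vulnerability.items():
        over = df[df["risk_binary"] == 1]
        n_over_species = int(over["species"].nunique())
        counts[scen] = n_over_species
        max_days = float(df["n_overheat_days"].max()) if len(df) else 0.0
        report["scenarios"][scen] = {
            "n_overheating_species": n_over_species,
            "n_overheating_occurrences": int(len(over)),
            "percent_species_overheating": percent(n_over_species,
                                                   n_species_total),
            "max_overheating_days": max_days,
            "percent_days_at_max": percent_of_days(max_days, n_days_total),
        }
    ordered = [s for s in ("current", "plus2", "plus4") if s in counts]
    if len(ordered) >= 2:
        first, last = ordered[0], ordered[-1]
        report["fold_change"] = {
            "from": first, "to": last,
            "value": fold_change(counts[last], counts[first]),
        }
    return report
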