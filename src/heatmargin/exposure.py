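"""Warmest-quarter exposure series with trailing-week statistics.

Daily temperature tables are reduced to the 91 warmest days of each
non-burn-in year per cell, carrying the trailing 7-day mean and maximum
computed on the full (pre-restriction) series so early-quarter days keep
their history.  Range-wide percentiles of the retained daily maxima feed
the imputation's reference acclimatization temperatures.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["select_warmest_quarter", "trailing_week_stats", "build_exposure",
           "range_percentiles", "QUARTER_DAYS"]

QUARTER_DAYS = 91


def select_warmest_quarter(values: np.ndarray, mode: str = "contiguous") -> np.ndarray:
    """Indices (sorted) of the 91 warmest days within one cell-year.

    ``mode="contiguous"``: the consecutive 91-day window with the highest
    mean daily maximum, ties broken to the earliest start.
    ``mode="top"``: the 91 individually hottest days.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < QUARTER_DAYS:
        raise ValueError(f"year has {n} days; need at least {QUARTER_DAYS}")
    if mode == "top":
        idx = np.argsort(values, kind="stable")[::-1][:QUARTER_DAYS]
        return np.sort(idx)
    if mode != "contiguous":
        raise ValueError(f"unknown mode {mode!r}")
    csum = np.concatenate([[0.0], np.cumsum(values)])
    window_sums = csum[QUARTER_DAYS:] - csum[:-QUARTER_DAYS]
    start = int(np.argmax(window_sums))  # argmax returns the first maximum
    return np.arange(start, start + QUARTER_DAYS)


def trailing_week_stats(series: np.ndarray, day: int,
                        window: int = 7) -> tuple[float, float]:
    """Mean and max of daily maxima over days day-window .. day-1."""
    if day < window:
        raise ValueError(f"day {day} has fewer than {window} prior days")
    chunk = np.asarray(series, dtype=float)[day - window:day]
    return float(chunk.mean()), float(chunk.max())


def build_exposure(temps: pd.DataFrame, burn_in_year: int | None = None,
                   window: int = 7, mode: str = "contiguous") -> pd.DataFrame:
    """Restrict daily series to warmest quarters with trailing-week stats.

    ``temps`` is a long table with columns cell_id, lat, lon, date, year,
    daily_max (plus microhabitat/scenario passthrough columns).  The first
    year is treated as burn-in unless ``burn_in_year`` overrides it; its
    days supply trailing history but are not retained.
    """
    required = {"cell_id", "date", "year", "daily_max"}
    missing = required - set(temps.columns)
    if missing:
        raise ValueError(f"temps table missing columns: {sorted(missing)}")
    if burn_in_year is None:
        burn_in_year = int(temps["year"].min())

    frames = []
    dropped_history = 0
    for cell, grp in temps.groupby("cell_id", sort=False):
        grp = grp.sort_values("date").reset_index(drop=True)
        vals = grp["daily_max"].to_numpy(float)
        roll = pd.Series(vals).rolling(window)
        week_mean = roll.mean().shift(1).to_numpy()
        week_max = roll.max().shift(1).to_numpy()
        grp = grp.assign(week_mean=week_mean, week_max=week_max)
        for year, ygrp in grp.groupby("year", sort=True):
            if year == burn_in_year:
                continue
            pos = ygrp.index.to_numpy()
            keep = pos[select_warmest_quarter(
                ygrp["daily_max"].to_numpy(float), mode=mode)]
            sel = grp.loc[keep]
            bad = sel["week_mean"].isna()
            dropped_history += int(bad.sum())
            frames.append(sel[~bad])
    if dropped_history:
        import warnings
        warnings.warn(f"{dropped_history} retained days dropped for "
                      "insufficient trailing history")
    out = pd.concat(frames, ignore_index=True)
    return out


def range_percentiles(occurrences: pd.DataFrame,
                      exposure: pd.DataFrame) -> pd.DataFrame:
    """Species-level 5th/50th/95th percentiles of retained daily maxima
    pooled over occupied cells (linear interpolation between order stats).

    ``exposure`` should be the terrestrial current-scenario series.
    """
    cells = exposure.groupby("cell_id")["daily_max"].apply(
        lambda s: s.to_numpy(float))
    rows = []
    missing: list[str] = []
    for sp, grp in occurrences.groupby("species", sort=True):
        pools = [cells[c] for c in grp["cell_id"].unique() if c in cells.index]
        if not pools:
            missing.append(sp)
            continue
        pool = np.concatenate(pools)
        p5, med, p95 = np.percentile(pool, [5, 50, 95])
        rows.append({"species": sp, "t_p5": p5, "t_median": med, "t_p95": p95})
    if missing:
        raise ValueError("no exposure data for occupied cells of species: "
                         f"{missing[:5]}{'...' if len(missing) > 5 else ''}")
    return pd.DataFrame(rows)
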