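"""Group-level richness trends, tree-based intervals, slopes, and grid maps.

Yearly group trends are built from the forest's individual trees: for every
tree, predictions are averaged over the plots of a group at each year,
giving a (trees × years) matrix of tree means. The confidence interval of
the yearly mean is mean ± 1.96·SD/√T over the T tree means; the prediction
interval is the empirical 0.05-0.95 quantile band of the tree means.
Period trends are OLS slopes of the yearly means on year. Plot-level change
values are mapped by averaging within 50 km × 50 km grid cells, reported
only for cells holding at least five plots.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .temporal_interpolation import DEFAULT_YEARS, resolve_area_policy

DEFAULT_PERIODS: tuple[tuple[int, int], ...] = ((1960, 1980), (1980, 2000), (2000, 2020))

#: Default biogeographic merge: high-latitude units pooled into one.
DEFAULT_REGION_MERGE: dict[str, str] = {
    "arctic": "arctic_boreal",
    "boreal": "arctic_boreal",
    "scandinavian_alpine": "arctic_boreal",
}


def tree_mean_trend(
    model,
    plots: pd.DataFrame,
    years: tuple[int, int] = DEFAULT_YEARS,
    area_policy: str | Mapping[str, float] = "data-medians",
) -> tuple[np.ndarray, np.ndarray]:
    """Per-tree, per-year mean richness over a group of plots.

    Returns ``(matrix, year_grid)`` with matrix shape (n_trees, n_years);
    entry (t, y) is the mean over the group's plots of tree t's prediction
    at year y, with plot area standardized by the area policy. The mean over
    the tree axis equals the aggregate-prediction group mean.
    """
    if plots.empty:
        raise ValueError("empty plot group")
    y0, y1 = int(years[0]), int(years[1])
    year_grid = np.arange(y0, y1 + 1)
    _, areas = resolve_area_policy(area_policy, plots)
    kept = plots.reset_index(drop=True)
    if areas is not None:
        kept["area_m2"] = kept["habitat"].map(areas).astype(float)
    n = len(kept)
    rep = kept.loc[kept.index.repeat(len(year_grid))].copy()
    rep["year"] = np.tile(year_grid, n)
    per_tree = model.predict_per_tree(rep)  # (T, n*Y)
    matrix = per_tree.reshape(per_tree.shape[0], n, len(year_grid)).mean(axis=1)
    return matrix, year_grid


def intervals(
    tree_matrix: np.ndarray,
    level_z: float = 1.96,
    pi_quantiles: tuple[float, float] = (0.05, 0.95),
) -> pd.DataFrame:
    """Per-year mean of tree means with confidence and prediction intervals.

    CI = mean ± level_z · SD/√T over the T tree means (n in the CI formula
    is the number of trees); PI = empirical quantiles of the tree means.
    Requires T >= 2 for the SD.
    """
    m = np.asarray(tree_matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError("tree_matrix must be 2-D (trees × years)")
    T = m.shape[0]
    if T < 2:
        raise ValueError("confidence interval undefined with a single tree")
    mean = m.mean(axis=0)
    half = level_z * m.std(axis=0, ddof=1) / np.sqrt(T)
    lo, hi = np.quantile(m, pi_quantiles, axis=0)
    return pd.DataFrame(
        {
            "mean": mean,
            "ci_low": mean - half,
            "ci_high": mean + half,
            "pi_low": lo,
            "pi_high": hi,
        }
    )


def period_trend_slopes(
    yearly_means: pd.Series,
    periods: Sequence[tuple[int, int]] = DEFAULT_PERIODS,
    baseline_year: int | None = None,
) -> pd.DataFrame:
    """OLS slope (species/year) of the yearly means within each period.

    ``yearly_means`` is indexed by year. Each period is inclusive at both
    ends (21 yearly values for a 1960-1980 period). When ``baseline_year``
    is given, slopes are additionally reported relative to that year's mean
    (a reporting transform; the fit itself is always in species/year).
    """
    rows = []
    for a, b in periods:
        win = yearly_means.loc[a:b]
        if len(win) < 2:
            raise ValueError(f"period {(a, b)} not covered by the yearly means")
        res = stats.linregress(win.index.to_numpy(dtype=float), win.to_numpy(dtype=float))
        rows.append((a, b, res.slope, res.stderr))
    out = pd.DataFrame(rows, columns=["year_start", "year_end", "slope", "slope_se"])
    if baseline_year is not None:
        base = float(yearly_means.loc[baseline_year])
        out["slope_rel_baseline"] = out["slope"] / base
    return out


def trend_summary(
    model,
    plots: pd.DataFrame,
    group_cols: Sequence[str] = ("habitat",),
    years: tuple[int, int] = DEFAULT_YEARS,
    area_policy: str | Mapping[str, float] = "data-medians",
    periods: Sequence[tuple[int, int]] = DEFAULT_PERIODS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tidy per-group yearly trend table plus period-slope table."""
    yearly_rows, slope_rows = [], []
    for key, grp in plots.groupby(list(group_cols), observed=True):
        key = key if isinstance(key, tuple) else (key,)
        matrix, year_grid = tree_mean_trend(model, grp, years, area_policy)
        iv = intervals(matrix)
        iv.insert(0, "year", year_grid)
        for col, val in zip(group_cols, key):
            iv.insert(0, col, val)
        iv["n_plots"] = len(grp)
        yearly_rows.append(iv)
        means = pd.Series(matrix.mean(axis=0), index=year_grid)
        sl = period_trend_slopes(means, periods, baseline_year=int(year_grid[0]))
        for col, val in zip(group_cols, key):
            sl.insert(0, col, val)
        slope_rows.append(sl)
    return (
        pd.concat(yearly_rows, ignore_index=True),
        pd.concat(slope_rows, ignore_index=True),
    )


def grid_aggregate(
    change_records: pd.DataFrame,
    value_col: str = "percent_change",
    cell_size_m: float = 50_000.0,
    min_plots: int = 5,
) -> pd.DataFrame:
    """Average plot-level change values within square grid cells.

    Cell index = floor(coordinate / cell size) per axis (half-open cells;
    a plot on the upper boundary belongs to the next cell). Cells with
    fewer than ``min_plots`` plots are omitted from the output but still
    counted in ``attrs['n_omitted_plots']``, so plot counts are conserved.
    SD uses the n−1 denominator.
    """
    df = change_records
    ex = np.floor(df["easting_m"].to_numpy(dtype=float) / cell_size_m).astype(int)
    ny = np.floor(df["northing_m"].to_numpy(dtype=float) / cell_size_m).astype(int)
    g = df.assign(easting_bin=ex, northing_bin=ny).groupby(
        ["easting_bin", "northing_bin"], observed=True
    )[value_col]
    cells = g.agg(n_plots="size", mean_change="mean", sd_change=lambda v: v.std(ddof=1))
    cells = cells.reset_index()
    cells["cell_easting_m"] = cells["easting_bin"] * cell_size_m
    cells["cell_northing_m"] = cells["northing_bin"] * cell_size_m
    retained = cells[cells["n_plots"] >= min_plots].reset_index(drop=True)
    retained.attrs["n_omitted_cells"] = int((cells["n_plots"] < min_plots).sum())
    retained.attrs["n_omitted_plots"] = int(
        cells.loc[cells["n_plots"] < min_plots, "n_plots"].sum()
    )
    return retained


def region_group(
    plots: pd.DataFrame,
    merge_map: Mapping[str, str] | None = None,
    label_col: str = "region_label",
) -> pd.DataFrame:
    """Attach a merged-region column for grouped trend reporting.

    Labels absent from the merge map pass through unchanged; missing labels
    become ``"unassigned"``. The default map pools the arctic, boreal and
    Scandinavian-alpine units into one high-latitude group.
    """
    merge_map = DEFAULT_REGION_MERGE if merge_map is None else dict(merge_map)
    out = plots.copy()
    lab = out[label_col] if label_col in out.columns else pd.Series(None, index=out.index)
    merged = lab.map(lambda x: merge_map.get(x, x) if pd.notna(x) else "unassigned")
    out["region"] = merged
    return out
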