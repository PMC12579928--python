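"""Canonical plot-record table, data filters, and static-selection.

The unit of analysis is one vegetation-plot observation (a row of the
canonical table, see :data:`divtrend.synthetic_world.PLOT_COLUMNS`).
Standard filters retain plots with complete records, coordinate uncertainty
below 1 km, one of the four habitat classes, plot area inside the
habitat-dependent window (1-100 m² outside forest, 100-1000 m² in forest)
and sampling year 1945-2023.
"""

from __future__ import annotations

import warnings
from collections import OrderedDict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from sklearn.model_selection import train_test_split

from .synthetic_world import HABITATS, PLOT_COLUMNS

#: Fields a record must carry to be analysable at all.
REQUIRED_FIELDS: tuple[str, ...] = (
    "easting_m",
    "northing_m",
    "elevation_m",
    "area_m2",
    "year",
    "habitat",
    "richness",
)

#: Fixed order in which rules are applied and reported.
RULE_ORDER: tuple[str, ...] = ("incomplete", "uncertainty", "habitat", "area", "year")


@dataclass
class FilterRules:
    """Retention rules; defaults are the standard archive filters."""

    max_coord_uncertainty_m: float = 1000.0  # strict: keep < 1 km
    habitats: tuple[str, ...] = HABITATS
    forest_area_range: tuple[float, float] = (100.0, 1000.0)
    nonforest_area_range: tuple[float, float] = (1.0, 100.0)
    year_range: tuple[int, int] = (1945, 2023)
    #: Extra boolean predicates, name -> callable(DataFrame) -> mask of keepers.
    extra_predicates: dict = field(default_factory=dict)


def apply_filters(
    records: pd.DataFrame, rules: FilterRules | None = None
) -> tuple[pd.DataFrame, "OrderedDict[str, int]"]:
    """Filter a plot table; return (retained, rejection log).

    Each record is charged to the *first* failing rule in :data:`RULE_ORDER`
    (then any extra predicates), so the log counts sum to the number of
    rejected records. Filtering is idempotent.
    """
    rules = rules or FilterRules()
    df = records
    n = len(df)

    incomplete = pd.Series(False, index=df.index)
    for col in REQUIRED_FIELDS:
        if col not in df.columns:
            incomplete |= True
        else:
            incomplete |= df[col].isna()

    uncertainty = pd.Series(False, index=df.index)
    if "coord_uncertainty_m" in df.columns:
        uncertainty = df["coord_uncertainty_m"] >= rules.max_coord_uncertainty_m

    if "habitat" in df.columns:
        habitat_bad = ~df["habitat"].isin(rules.habitats)
        is_forest = df["habitat"] == "forest"
        lo = np.where(is_forest, rules.forest_area_range[0], rules.nonforest_area_range[0])
        hi = np.where(is_forest, rules.forest_area_range[1], rules.nonforest_area_range[1])
        area = df["area_m2"] if "area_m2" in df.columns else pd.Series(np.nan, index=df.index)
        area_bad = (area < lo) | (area > hi)
        year_bad = (df["year"] < rules.year_range[0]) | (df["year"] > rules.year_range[1])
    else:  # degenerate input; everything is incomplete anyway
        habitat_bad = area_bad = year_bad = pd.Series(False, index=df.index)

    fail = {
        "incomplete": incomplete.fillna(True),
        "uncertainty": uncertainty.fillna(True),
        "habitat": habitat_bad.fillna(True),
        "area": area_bad.fillna(True),
        "year": year_bad.fillna(True),
    }
    for name, pred in rules.extra_predicates.items():
        fail[name] = ~pred(df)

    log: "OrderedDict[str, int]" = OrderedDict()
    rejected = pd.Series(False, index=df.index)
    for name in list(RULE_ORDER) + list(rules.extra_predicates):
        newly = fail[name] & ~rejected
        log[name] = int(newly.sum())
        rejected |= fail[name]

    retained = df.loc[~rejected].copy()
    assert len(retained) + sum(log.values()) == n
    return retained, log


def select_static(records: pd.DataFrame, seed: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Degrade time series to one observation each ("static" selection).

    Rows sharing a ``resurvey_id`` form a series; one observation per series
    is chosen uniformly at random. Rows without a ``resurvey_id`` are
    singleton series and are always selected. Returns
    ``(selected, remainder)``; reproducible under ``seed``.
    """
    rng = np.random.default_rng(seed)
    rid = records["resurvey_id"] if "resurvey_id" in records.columns else None
    if rid is None or rid.isna().all():
        return records.copy(), records.iloc[0:0].copy()
    is_series = rid.notna()
    take = np.zeros(len(records), dtype=bool)
    take[~is_series.to_numpy()] = True
    pos = pd.Series(np.arange(len(records)))
    # iterate series in a deterministic (sorted) order so that the draw
    # sequence does not depend on input row order
    for _, idx in sorted(pos[is_series.to_numpy()].groupby(rid[is_series].to_numpy()).groups.items()):
        chosen = rng.integers(0, len(idx))
        take[pos[idx].to_numpy()[chosen]] = True
    selected = records.iloc[take].copy()
    remainder = records.iloc[~take].copy()
    return selected, remainder


def stratified_split(
    records: pd.DataFrame,
    train_fraction: float = 0.8,
    n_bins: int = 10,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Train/test split stratified by quantile bins of richness.

    Falls back to an unstratified split (with a warning) when there are too
    few records to populate the bins.
    """
    if records.empty:
        raise ValueError("cannot split an empty table")
    strata = None
    try:
        binned = pd.qcut(records["richness"].rank(method="first"), q=n_bins, labels=False)
        if binned.value_counts().min() >= 2:
            strata = binned
    except ValueError:
        pass
    if strata is None:
        warnings.warn("too few records for stratified split; splitting unstratified")
    train, test = train_test_split(
        records,
        train_size=train_fraction,
        stratify=strata,
        random_state=int(seed) % (2**32),
        shuffle=True,
    )
    return train.copy(), test.copy()


# ---------------------------------------------------------------------------
# CSV I/O for the canonical dialect


def read_plots(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read a plot table CSV (optionally gzip-compressed).

    ``column_map`` renames foreign column names to the canonical ones; it
    may also be a path to a YAML file holding such a mapping.
    """
    if isinstance(column_map, (str,)) or hasattr(column_map, "read"):
        with open(column_map) as fh:
            column_map = yaml.safe_load(fh)
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    if "resurvey_id" in df.columns:
        df["resurvey_id"] = df["resurvey_id"].astype("string")
    if "obs_index" in df.columns:
        df["obs_index"] = df["obs_index"].astype("Int64")
    return df.reindex(columns=[c for c in PLOT_COLUMNS if c in df.columns] +
                      [c for c in df.columns if c not in PLOT_COLUMNS])


def write_plots(records: pd.DataFrame, path) -> None:
    """Write a plot table in the canonical column order."""
    cols = [c for c in PLOT_COLUMNS if c in records.columns]
    cols += [c for c in records.columns if c not in cols]
    records.loc[:, cols].to_csv(path, index=False)
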