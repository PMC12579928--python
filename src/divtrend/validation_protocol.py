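"""Validation of interpolated change predictions against resurvey series.

Static models are trained on three dataset configurations — (A) resurvey
data only, degraded to one observation per series, (B) one-time plots only,
(C) both — and scored on three criteria: richness of the held-out test
split, richness of the independent (non-selected) resurvey observations,
and the log response ratio of richness between the first and last
observation of each resurvey series. A positive correlation on the third
criterion means interpolations from temporally unreplicated data capture
observed richness change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import plot_data, richness_model
from .richness_model import EvalMetrics, Hyperparams

MODES = ("A", "B", "C")


@dataclass
class ValidationConfig:
    mode: str = "C"
    n_repeats: int = 1
    train_fraction: float = 0.8
    seed: int = 0
    hyperparams: Hyperparams = field(default_factory=Hyperparams)

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


def build_datasets(
    static_plots: pd.DataFrame,
    series: pd.DataFrame,
    mode: str,
    seed: int = 0,
    train_fraction: float = 0.8,
) -> dict[str, pd.DataFrame]:
    """Assemble train/test/independent tables for one dataset mode.

    Modes: ``"A"`` uses the degraded (one observation per series) resurvey
    data only; ``"B"`` the one-time plots only; ``"C"`` both. The
    independent set holds every series observation not selected into the
    static pool (for mode B: all series observations). Train and test are a
    stratified split of the mode's static pool.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    selected, remainder = plot_data.select_static(series, seed=seed)
    if mode == "A":
        pool, independent = selected, remainder
    elif mode == "B":
        if static_plots is None or static_plots.empty:
            raise ValueError("mode B requires one-time (static) plots")
        pool, independent = static_plots, series
    else:
        pool = pd.concat([static_plots, selected], ignore_index=True)
        independent = remainder
    train, test = plot_data.stratified_split(
        pool, train_fraction=train_fraction, seed=seed
    )
    return {"train": train, "test": test, "independent": independent.copy()}


def _series_endpoints(series: pd.DataFrame) -> pd.DataFrame:
    """First and last observation per series (by year, ties by obs_index)."""
    df = series.sort_values(["resurvey_id", "year", "obs_index"], kind="mergesort")
    g = df.groupby("resurvey_id", observed=True)
    first = g.head(1).set_index("resurvey_id")
    last = g.tail(1).set_index("resurvey_id")
    return first.join(last, lsuffix="_first", rsuffix="_last")


def score_change_prediction(
    model, series: pd.DataFrame
) -> tuple[pd.DataFrame, EvalMetrics]:
    """Observed vs predicted lnRR of richness for each resurvey series.

    Observed lnRR comes from the recorded richness at the first and last
    observation of the series; predicted lnRR from model predictions at
    those two years with the series' own covariates (location, elevation,
    habitat, and observed plot area). Series with non-positive recorded
    richness or a single distinct year are skipped (counted in
    ``attrs['n_skipped']``). Returns the per-series pair table and summary
    metrics over series.
    """
    ep = _series_endpoints(series)
    ok = (
        (ep["richness_first"] > 0)
        & (ep["richness_last"] > 0)
        & (ep["year_first"] != ep["year_last"])
    )
    skipped = int((~ok).sum())
    if skipped:
        warnings.warn(f"skipped {skipped} series with degenerate endpoints")
    ep = ep.loc[ok]
    covars = ["easting_m", "northing_m", "elevation_m", "area_m2", "habitat"]
    base = ep[[f"{c}_first" for c in covars]].copy()
    base.columns = covars
    pred = {}
    for end in ("first", "last"):
        frame = base.copy()
        frame["year"] = ep[f"year_{end}"].to_numpy()
        pred[end] = np.asarray(model.predict(frame), dtype=float)
    pairs = pd.DataFrame(
        {
            "resurvey_id": ep.index.to_numpy(),
            "year_first": ep["year_first"].to_numpy(),
            "year_last": ep["year_last"].to_numpy(),
            "observed_lnrr": np.log(
                ep["richness_last"].to_numpy(dtype=float)
                / ep["richness_first"].to_numpy(dtype=float)
            ),
            "predicted_lnrr": np.log(pred["last"] / pred["first"]),
        }
    )
    pairs.attrs["n_skipped"] = skipped
    summary = richness_model.metrics(
        pairs["observed_lnrr"].to_numpy(), pairs["predicted_lnrr"].to_numpy()
    )
    return pairs, summary


def permutation_pvalue(
    pairs: pd.DataFrame, n_permutations: int = 1000, seed: int = 0
) -> float:
    """One-sided permutation p-value for the observed-vs-predicted lnRR
    correlation being positive (series labels shuffled)."""
    obs = pairs["observed_lnrr"].to_numpy()
    prd = pairs["predicted_lnrr"].to_numpy()
    r_obs = np.corrcoef(obs, prd)[0, 1]
    rng = np.random.default_rng(seed)
    hits = sum(
        np.corrcoef(obs, rng.permutation(prd))[0, 1] >= r_obs
        for _ in range(n_permutations)
    )
    return (1 + hits) / (1 + n_permutations)


def run_validation(
    static_plots: pd.DataFrame,
    series: pd.DataFrame,
    config: ValidationConfig,
    repeat_seed: int | None = None,
) -> pd.DataFrame:
    """One validation pass: build datasets, fit, score the three criteria.

    Returns a tidy one-row-per-criterion table (rmse, r2, pearson_r).
    """
    seed = config.seed if repeat_seed is None else repeat_seed
    ds = build_datasets(
        static_plots, series, config.mode, seed=seed, train_fraction=config.train_fraction
    )
    hp = Hyperparams(
        n_trees=config.hyperparams.n_trees,
        min_node_size=config.hyperparams.min_node_size,
        mtry=config.hyperparams.mtry,
        seed=seed,
    )
    model = richness_model.fit(ds["train"], hp)
    rows = []
    m1 = richness_model.evaluate(model, ds["test"])
    rows.append(("test_richness", m1))
    if not ds["independent"].empty:
        m2 = richness_model.evaluate(model, ds["independent"])
        rows.append(("independent_resurvey_richness", m2))
    _, m3 = score_change_prediction(model, series)
    rows.append(("lnrr_change", m3))
    return pd.DataFrame(
        [(name, m.rmse, m.r2, m.pearson_r) for name, m in rows],
        columns=["criterion", "rmse", "r2", "pearson_r"],
    )


def repeat_validation(
    static_plots: pd.DataFrame,
    series: pd.DataFrame,
    config: ValidationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Repeat the validation with fresh random selections per repeat.

    Repeat seeds derive deterministically from the master seed. Returns the
    per-repeat table and an across-repeat mean/SD summary per criterion.
    """
    reports = []
    for rep in range(config.n_repeats):
        rep_seed = (config.seed + 7919 * rep) % (2**31)
        rpt = run_validation(static_plots, series, config, repeat_seed=rep_seed)
        rpt.insert(0, "repeat", rep)
        reports.append(rpt)
    full = pd.concat(reports, ignore_index=True)
    summary = (
        full.groupby("criterion", observed=True)[["rmse", "r2", "pearson_r"]]
        .agg(["mean", "std"])
    )
    summary.columns = ["_".join(c) for c in summary.columns]
    return full, summary.reset_index()
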