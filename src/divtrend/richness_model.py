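"""Ensemble regression of plot richness on space, time, area and habitat.

The model is a Random Forest regression of species richness S on the six
predictors

    S ~ easting + northing + elevation + plot area + year + habitat

backed by :class:`sklearn.ensemble.RandomForestRegressor`. The wrapper
exposes the full per-tree prediction matrix (needed for the tree-based
confidence and prediction intervals of the trend summaries), guards the
training schema against train/predict mismatches, and provides the standard
diagnostics: hold-out and repeated cross-validation metrics, grid tuning,
partial dependence, pairwise Friedman–Popescu H² interaction statistics,
binned residual correlograms, and block cross-validation.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import joblib
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from scipy.stats import pearsonr
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold

from .synthetic_world import HABITATS

#: The six model predictors, in canonical order.
PREDICTORS: tuple[str, ...] = (
    "easting_m",
    "northing_m",
    "elevation_m",
    "area_m2",
    "year",
    "habitat",
)

NUMERIC_PREDICTORS: tuple[str, ...] = tuple(p for p in PREDICTORS if p != "habitat")


@dataclass(frozen=True)
class Hyperparams:
    """Random-forest hyperparameters.

    ``min_node_size`` is the minimum number of records in a node for further
    splitting; ``mtry`` counts predictors (of the original six) sampled per
    split and is mapped proportionally onto the one-hot-encoded columns.
    """

    n_trees: int = 1000
    min_node_size: int = 5
    mtry: int = 3
    seed: int = 0

    def __post_init__(self):
        if not 1 <= self.mtry <= len(PREDICTORS):
            raise ValueError(f"mtry must be in [1, {len(PREDICTORS)}], got {self.mtry}")
        if self.min_node_size < 1:
            raise ValueError("min_node_size must be >= 1")


@dataclass
class EvalMetrics:
    rmse: float
    r2: float
    pearson_r: float


class SchemaError(ValueError):
    """Prediction-time records do not match the training schema."""


def _encode(records: pd.DataFrame, habitat_levels: tuple[str, ...]) -> pd.DataFrame:
    missing = [c for c in PREDICTORS if c not in records.columns]
    if missing:
        raise SchemaError(f"records lack predictor columns {missing}")
    unseen = set(records["habitat"].unique()) - set(habitat_levels)
    if unseen:
        raise SchemaError(
            f"habitat level(s) {sorted(unseen)} unseen at training time; refusing to extrapolate"
        )
    X = records.loc[:, list(NUMERIC_PREDICTORS)].astype(float).copy()
    for h in habitat_levels:
        X[f"habitat_{h}"] = (records["habitat"] == h).astype(float)
    return X


@dataclass
class FittedEnsemble:
    """A trained forest plus its training-schema fingerprint."""

    model: RandomForestRegressor
    habitat_levels: tuple[str, ...]
    feature_names: tuple[str, ...]
    hyperparams: Hyperparams
    train_richness_range: tuple[float, float]

    @property
    def n_trees(self) -> int:
        return len(self.model.estimators_)

    def _matrix(self, records: pd.DataFrame) -> np.ndarray:
        X = _encode(records, self.habitat_levels)
        if tuple(X.columns) != self.feature_names:
            raise SchemaError(
                f"feature mismatch: expected {self.feature_names}, got {tuple(X.columns)}"
            )
        return X.to_numpy()

    def predict(self, records: pd.DataFrame) -> np.ndarray:
        """Aggregate (forest-mean) prediction for each record."""
        return self.model.predict(self._matrix(records))

    def predict_per_tree(self, records: pd.DataFrame) -> np.ndarray:
        """Per-tree prediction matrix, shape (n_trees, n_records)."""
        X = self._matrix(records)
        return np.stack([tree.predict(X) for tree in self.model.estimators_])

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "FittedEnsemble":
        obj = joblib.load(path)
        if not isinstance(obj, FittedEnsemble):
            raise TypeError(f"{path} does not hold a FittedEnsemble")
        return obj


class FunctionModel:
    """Adapter giving an arbitrary function f(records) -> richness the
    prediction interface, e.g. to run diagnostics on a known oracle."""

    def __init__(self, fn):
        self._fn = fn

    def predict(self, records: pd.DataFrame) -> np.ndarray:
        return np.asarray(self._fn(records), dtype=float)


def _max_features(mtry: int, n_encoded: int) -> int:
    # map mtry over the six original predictors proportionally onto the
    # encoded columns
    return int(np.clip(round(mtry / len(PREDICTORS) * n_encoded), 1, n_encoded))


def fit(train_records: pd.DataFrame, hyperparams: Hyperparams | None = None) -> FittedEnsemble:
    """Train the forest on the six predictors.

    Training rows are put in a canonical order first (by ``plot_id`` where
    available, else by all predictor values) so that the fit is invariant to
    the row order of the input under a fixed seed.
    """
    hp = hyperparams or Hyperparams()
    if "plot_id" in train_records.columns and train_records["plot_id"].is_unique:
        train_records = train_records.sort_values("plot_id", kind="mergesort")
    else:
        train_records = train_records.sort_values(list(PREDICTORS) + ["richness"],
                                                  kind="mergesort")
    levels = tuple(h for h in HABITATS if h in set(train_records["habitat"]))
    if not levels:  # foreign habitat vocabulary: take levels as found
        levels = tuple(sorted(set(train_records["habitat"])))
    X = _encode(train_records, levels)
    y = train_records["richness"].to_numpy(dtype=float)
    rf = RandomForestRegressor(
        n_estimators=hp.n_trees,
        min_samples_split=max(2, hp.min_node_size),
        max_features=_max_features(hp.mtry, X.shape[1]),
        random_state=int(hp.seed) % (2**32),
        n_jobs=1,
    )
    rf.fit(X.to_numpy(), y)
    return FittedEnsemble(
        model=rf,
        habitat_levels=levels,
        feature_names=tuple(X.columns),
        hyperparams=hp,
        train_richness_range=(float(y.min()), float(y.max())),
    )


# ---------------------------------------------------------------------------
# Evaluation


def metrics(observed: np.ndarray, predicted: np.ndarray) -> EvalMetrics:
    """RMSE, Pearson r, and R² (the squared Pearson correlation)."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    rmse = float(np.sqrt(np.mean((observed - predicted) ** 2)))
    if np.std(predicted) == 0 or np.std(observed) == 0:
        warnings.warn("constant predictions or observations; correlation undefined")
        return EvalMetrics(rmse=rmse, r2=float("nan"), pearson_r=float("nan"))
    r = float(pearsonr(observed, predicted).statistic)
    return EvalMetrics(rmse=rmse, r2=r * r, pearson_r=r)


def evaluate(model, records: pd.DataFrame) -> EvalMetrics:
    return metrics(records["richness"].to_numpy(dtype=float), model.predict(records))


def repeated_cv(
    records: pd.DataFrame,
    hyperparams: Hyperparams | None = None,
    k: int = 10,
    repeats: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """k-fold cross-validation repeated ``repeats`` times.

    Returns one row per (repeat, fold) with rmse / r2 / pearson_r.
    """
    hp = hyperparams or Hyperparams()
    if k > len(records):
        raise ValueError(f"k={k} exceeds the {len(records)} available records")
    rows = []
    for rep in range(repeats):
        kf = KFold(n_splits=k, shuffle=True, random_state=(seed + 1000 * rep) % (2**32))
        for fold, (tr, te) in enumerate(kf.split(records)):
            m = fit(records.iloc[tr], hp)
            em = evaluate(m, records.iloc[te])
            rows.append((rep, fold, em.rmse, em.r2, em.pearson_r))
    return pd.DataFrame(rows, columns=["repeat", "fold", "rmse", "r2", "pearson_r"])


DEFAULT_GRID: tuple[tuple[int, int], ...] = tuple(
    (ns, mt) for ns in (2, 5, 10, 15, 20) for mt in (2, 3, 4, 5, 6)
)


def tune(
    train_records: pd.DataFrame,
    grid: tuple[tuple[int, int], ...] | None = None,
    k: int = 10,
    n_trees: int = 1000,
    seed: int = 0,
) -> tuple[Hyperparams, pd.DataFrame]:
    """Single k-fold CV over a (node size, mtry) grid; lowest mean RMSE wins.

    Ties are broken by smallest node size, then smallest mtry. Returns the
    winning :class:`Hyperparams` and the full tuning table.
    """
    grid = tuple(grid) if grid is not None else DEFAULT_GRID
    if k > len(train_records):
        raise ValueError(f"k={k} exceeds the {len(train_records)} available records")
    kf = KFold(n_splits=k, shuffle=True, random_state=seed % (2**32))
    splits = list(kf.split(train_records))
    rows = []
    for node_size, mtry in grid:
        hp = Hyperparams(n_trees=n_trees, min_node_size=node_size, mtry=mtry, seed=seed)
        ems = [
            evaluate(fit(train_records.iloc[tr], hp), train_records.iloc[te])
            for tr, te in splits
        ]
        rows.append(
            (node_size, mtry,
             float(np.mean([e.rmse for e in ems])),
             float(np.nanmean([e.r2 for e in ems])))
        )
    table = pd.DataFrame(rows, columns=["min_node_size", "mtry", "mean_rmse", "mean_r2"])
    best = table.sort_values(
        ["mean_rmse", "min_node_size", "mtry"], kind="mergesort"
    ).iloc[0]
    best_hp = Hyperparams(
        n_trees=n_trees,
        min_node_size=int(best["min_node_size"]),
        mtry=int(best["mtry"]),
        seed=seed,
    )
    return best_hp, table


# ---------------------------------------------------------------------------
# Partial dependence and H² interaction statistics


def partial_dependence(model, feature: str, grid_points, background: pd.DataFrame) -> pd.DataFrame:
    """PD(f, v) = mean prediction over the background with feature f set to v."""
    if feature not in PREDICTORS:
        raise ValueError(f"{feature!r} is not one of the model predictors {PREDICTORS}")
    if background.empty:
        raise ValueError("background records must be non-empty")
    values, pds = [], []
    for v in grid_points:
        shifted = background.copy()
        shifted[feature] = v
        values.append(v)
        pds.append(float(np.mean(model.predict(shifted))))
    return pd.DataFrame({feature: values, "partial_dependence": pds})


def _pd_at_background(model, background: pd.DataFrame, features: tuple[str, ...]) -> np.ndarray:
    """Centered partial-dependence of ``features`` evaluated at the
    background's own feature values (one value per background row)."""
    n = len(background)
    blocks = []
    for i in range(n):
        shifted = background.copy()
        for f in features:
            shifted[f] = background.iloc[i][f]
        blocks.append(shifted)
    preds = model.predict(pd.concat(blocks, ignore_index=True)).reshape(n, n)
    pd_vals = preds.mean(axis=1)
    return pd_vals - pd_vals.mean()


def h2_pairwise(
    model, features=PREDICTORS, background: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Pairwise Friedman–Popescu H² statistics.

    For each pair (j, k): H² = Σ[PD_jk − PD_j − PD_k]² / Σ[PD_jk]², with all
    partial-dependence terms mean-centered over the background sample and
    evaluated at the background's own feature values. Values are clipped to
    [0, 1]; a constant joint PD yields 0 with a warning. Symmetric matrix.
    """
    features = tuple(features)
    if len(features) < 2:
        raise ValueError("need at least two features")
    if background is None or background.empty:
        raise ValueError("background records must be non-empty")
    singles = {f: _pd_at_background(model, background, (f,)) for f in features}
    H = pd.DataFrame(0.0, index=list(features), columns=list(features))
    for j, k in itertools.combinations(features, 2):
        joint = _pd_at_background(model, background, (j, k))
        denom = float(np.sum(joint**2))
        if denom == 0.0:
            warnings.warn(f"constant joint partial dependence for ({j}, {k}); H2 set to 0")
            h2 = 0.0
        else:
            h2 = float(np.clip(np.sum((joint - singles[j] - singles[k]) ** 2) / denom, 0, 1))
        H.loc[j, k] = H.loc[k, j] = h2
    return H


# ---------------------------------------------------------------------------
# Spatial diagnostics


def residual_correlogram(
    model,
    records: pd.DataFrame,
    distance_bins,
    n_permutations: int = 199,
    seed: int = 0,
) -> pd.DataFrame:
    """Binned Moran-type spatial autocorrelation of model residuals.

    For each distance bin, the statistic is the mean over record pairs
    (i, j) in the bin of z_i·z_j / s², where z are centered residuals and
    s² their variance. A permutation envelope (residuals shuffled over
    locations) gives the 2.5%/97.5% null bounds per bin. Empty bins are
    reported with NaN, not imputed.
    """
    if len(records) < 2:
        raise ValueError("need at least two records")
    resid = records["richness"].to_numpy(dtype=float) - model.predict(records)
    coords = records[["easting_m", "northing_m"]].to_numpy(dtype=float)
    d = pdist(coords)
    edges = np.asarray(distance_bins, dtype=float)
    which = np.digitize(d, edges) - 1  # pair -> bin index, -1/out-of-range ignored
    n_bins = len(edges) - 1
    iu = np.triu_indices(len(records), k=1)

    def bin_stats(z: np.ndarray) -> np.ndarray:
        zc = z - z.mean()
        s2 = float(np.mean(zc**2))
        prod = zc[iu[0]] * zc[iu[1]]
        out = np.full(n_bins, np.nan)
        for b in range(n_bins):
            mask = which == b
            if mask.any():
                out[b] = float(prod[mask].mean()) / s2 if s2 > 0 else np.nan
        return out

    observed = bin_stats(resid)
    counts = np.array([(which == b).sum() for b in range(n_bins)])
    rng = np.random.default_rng(seed)
    null = np.stack(
        [bin_stats(rng.permutation(resid)) for _ in range(n_permutations)]
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins
        lo = np.nanpercentile(null, 2.5, axis=0)
        hi = np.nanpercentile(null, 97.5, axis=0)
    return pd.DataFrame(
        {
            "bin_left_m": edges[:-1],
            "bin_right_m": edges[1:],
            "n_pairs": counts,
            "correlation": observed,
            "null_low": lo,
            "null_high": hi,
        }
    )


def block_cv(
    records: pd.DataFrame,
    hyperparams: Hyperparams | None = None,
    scheme: str = "spatial",
    block_size_m: float | None = None,
    block_size_years: float | None = None,
    max_folds: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Block cross-validation with contiguous spatial/temporal folds.

    Each contiguous block is a fold (leave-one-block-out); when there are
    more blocks than ``max_folds``, blocks are merged round-robin into that
    many folds. This is a stress test of generalisation to unseen regions or
    periods, not the primary evaluation of an interpolation model.
    """
    if scheme not in ("spatial", "temporal", "spatiotemporal"):
        raise ValueError(f"unknown scheme {scheme!r}")
    keys = []
    if scheme in ("spatial", "spatiotemporal"):
        if not block_size_m:
            raise ValueError("block_size_m required for spatial blocking")
        keys.append(np.floor(records["easting_m"].to_numpy() / block_size_m).astype(int))
        keys.append(np.floor(records["northing_m"].to_numpy() / block_size_m).astype(int))
    if scheme in ("temporal", "spatiotemporal"):
        if not block_size_years:
            raise ValueError("block_size_years required for temporal blocking")
        keys.append(np.floor(records["year"].to_numpy() / block_size_years).astype(int))
    block_id = pd.Series(list(zip(*keys)), index=records.index)
    blocks = sorted(block_id.unique())
    if len(blocks) < 2:
        raise ValueError("block size leaves a single fold; choose a smaller block")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(blocks))
    n_folds = min(max_folds or len(blocks), len(blocks))
    fold_of_block = {blocks[b]: int(i % n_folds) for i, b in enumerate(order)}
    folds = block_id.map(fold_of_block)
    hp = hyperparams or Hyperparams()
    rows = []
    for f in range(n_folds):
        te = folds == f
        m = fit(records.loc[~te], hp)
        em = evaluate(m, records.loc[te])
        rows.append((f, int(te.sum()), em.rmse, em.r2, em.pearson_r))
    return pd.DataFrame(rows, columns=["fold", "n_test", "rmse", "r2", "pearson_r"])
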