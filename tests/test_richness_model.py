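"""The richness ensemble: fitting contract, metrics, tuning, diagnostics."""

import numpy as np
import pandas as pd
import pytest

import divtrend as dt
from divtrend import richness_model as rm
from divtrend import synthetic_world as sw
from divtrend.richness_model import FunctionModel, Hyperparams, SchemaError


class TestMetrics:
    def test_perfect_predictions(self):
        m = rm.metrics([1, 2, 3], [1, 2, 3])
        assert m.rmse == 0 and m.r2 == pytest.approx(1.0)

    def test_correlation_is_shift_invariant(self):
        m = rm.metrics([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert m.rmse == pytest.approx(1.0) and m.r2 == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # obs (1,2,3) vs pred (1,3,2): RMSE = sqrt(2/3), r = 1/2
        m = rm.metrics([1, 2, 3], [1, 3, 2])
        assert m.rmse == pytest.approx(np.sqrt(2 / 3), abs=1e-12)
        assert m.pearson_r == pytest.approx(0.5, abs=1e-12)
        assert m.r2 == pytest.approx(0.25, abs=1e-12)

    def test_constant_predictions_give_nan_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            m = rm.metrics([1, 2, 3], [2, 2, 2])
        assert np.isnan(m.r2)


class TestFit:
    def test_aggregate_equals_mean_of_trees(self, small_model, small_split):
        _, _, test = small_split
        per_tree = small_model.predict_per_tree(test)
        np.testing.assert_allclose(per_tree.mean(axis=0),
                                   small_model.predict(test), rtol=1e-9)

    def test_row_order_invariance(self, small_split):
        _, train, test = small_split
        hp = Hyperparams(n_trees=20, seed=9)
        a = rm.fit(train, hp).predict(test)
        shuffled = train.sample(frac=1.0, random_state=4)
        b = rm.fit(shuffled, hp).predict(test)
        np.testing.assert_array_equal(a, b)

    def test_predictions_bounded_by_training_richness(self, small_model, small_split):
        _, train, test = small_split
        p = small_model.predict(test)
        assert p.min() >= train["richness"].min()
        assert p.max() <= train["richness"].max()

    def test_unseen_habitat_raises(self, small_model, small_split):
        _, _, test = small_split
        alien = test.head(3).copy()
        alien["habitat"] = "heathland"
        with pytest.raises(SchemaError, match="heathland"):
            small_model.predict(alien)

    def test_missing_predictor_raises(self, small_model, small_split):
        _, _, test = small_split
        with pytest.raises(SchemaError, match="area_m2"):
            small_model.predict(test.drop(columns=["area_m2"]))

    def test_persistence_round_trip(self, tmp_path, small_model, small_split):
        _, _, test = small_split
        p = tmp_path / "model.joblib"
        small_model.save(p)
        loaded = rm.FittedEnsemble.load(p)
        np.testing.assert_array_equal(loaded.predict(test), small_model.predict(test))
        assert loaded.feature_names == small_model.feature_names


class TestTune:
    def test_grid_size_and_best_row(self, small_split):
        _, train, _ = small_split
        sub = train.head(200)
        grid = tuple((ns, mt) for ns in (2, 10) for mt in (2, 4))
        best, table = rm.tune(sub, grid=grid, k=4, n_trees=15, seed=1)
        assert len(table) == len(grid)
        row = table[(table.min_node_size == best.min_node_size)
                    & (table.mtry == best.mtry)]
        assert row["mean_rmse"].iloc[0] == table["mean_rmse"].min()

    def test_default_grid_has_25_combinations(self):
        assert len(rm.DEFAULT_GRID) == 25

    def test_tie_break_prefers_small_node_size_then_mtry(self, small_split):
        # constant response ties every combination at RMSE 0
        _, train, _ = small_split
        sub = train.head(60).copy()
        sub["richness"] = 7
        with pytest.warns(UserWarning):
            best, _ = rm.tune(sub, grid=((10, 3), (2, 5), (2, 3)), k=3, n_trees=5)
        assert (best.min_node_size, best.mtry) == (2, 3)

    def test_k_larger_than_n_raises(self, small_split):
        _, train, _ = small_split
        with pytest.raises(ValueError):
            rm.tune(train.head(5), k=10, n_trees=5)


class TestRepeatedCV:
    def test_shape_and_finiteness(self, small_split):
        _, train, _ = small_split
        out = rm.repeated_cv(train.head(300), Hyperparams(n_trees=15, seed=1),
                             k=3, repeats=2, seed=2)
        assert len(out) == 6
        assert np.isfinite(out["rmse"]).all()


def _area_only_world(n=1500, seed=0):
    """A world in which only plot area matters (flat space, time, habitat)."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "plot_id": [f"p{i}" for i in range(n)],
        "easting_m": rng.uniform(0, 1e6, n),
        "northing_m": rng.uniform(0, 1e6, n),
        "elevation_m": rng.uniform(0, 1000, n),
        "area_m2": np.exp(rng.uniform(np.log(1), np.log(100), n)),
        "year": rng.integers(1945, 2024, n),
        "habitat": rng.choice(sw.HABITATS, n),
    })
    mu = 10.0 * (df["area_m2"] / 10.0) ** 0.3
    df["richness"] = np.maximum(1, rng.poisson(mu))
    return df


class TestPartialDependence:
    def test_pd_over_area_nondecreasing_for_sar_model(self):
        df = _area_only_world()
        model = rm.fit(df, Hyperparams(n_trees=40, seed=1))
        grid = np.linspace(2, 90, 12)
        curve = rm.partial_dependence(model, "area_m2", grid, df.sample(150, random_state=0))
        diffs = np.diff(curve["partial_dependence"])
        assert diffs.min() > -0.05 * curve["partial_dependence"].mean()

    def test_pd_flat_for_ignored_feature(self):
        # the ignored predictor's PD range is a small fraction of the
        # signal-carrying predictor's PD range
        df = _area_only_world()
        model = rm.fit(df, Hyperparams(n_trees=40, seed=1))
        bg = df.sample(150, random_state=0)
        flat = rm.partial_dependence(model, "northing_m", np.linspace(0, 1e6, 8), bg)
        signal = rm.partial_dependence(model, "area_m2", np.linspace(2, 90, 8), bg)
        spread = lambda c: c["partial_dependence"].max() - c["partial_dependence"].min()
        assert spread(flat) < 0.2 * spread(signal)

    def test_single_point_single_background_is_plain_prediction(self, small_model, small_split):
        _, _, test = small_split
        one = test.head(1)
        curve = rm.partial_dependence(small_model, "year", [1990], one)
        expected = small_model.predict(one.assign(year=1990))[0]
        assert curve["partial_dependence"].iloc[0] == pytest.approx(expected, rel=1e-12)

    def test_area_ranks_top_by_permutation_importance(self):
        df = _area_only_world()
        model = rm.fit(df.head(1200), Hyperparams(n_trees=40, seed=1))
        held = df.tail(300)
        rng = np.random.default_rng(0)
        base = rm.evaluate(model, held).rmse
        bumps = {}
        for col in rm.NUMERIC_PREDICTORS:
            perm = held.copy()
            perm[col] = rng.permutation(perm[col].to_numpy())
            bumps[col] = rm.evaluate(model, perm).rmse - base
        assert max(bumps, key=bumps.get) == "area_m2"


class TestH2:
    @staticmethod
    def _background(n=30, seed=2):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "easting_m": rng.uniform(0, 1e6, n),
            "northing_m": rng.uniform(0, 1e6, n),
            "elevation_m": rng.uniform(0, 1000, n),
            "area_m2": rng.uniform(1, 100, n),
            "year": rng.integers(1960, 2021, n),
            "habitat": rng.choice(sw.HABITATS, n),
        })

    def test_additive_oracle_has_zero_h2(self):
        f = FunctionModel(lambda d: 0.001 * d["area_m2"].to_numpy()
                          + 0.1 * d["year"].to_numpy()
                          + 1e-6 * d["northing_m"].to_numpy())
        H = rm.h2_pairwise(f, ("area_m2", "year", "northing_m"), self._background())
        assert float(H.to_numpy().max()) < 1e-10

    def test_planted_interaction_dominates(self):
        f = FunctionModel(lambda d: 0.05 * d["area_m2"].to_numpy()
                          + 0.1 * d["year"].to_numpy()
                          + 1e-5 * d["northing_m"].to_numpy()
                          + 0.002 * d["area_m2"].to_numpy()
                          * (d["year"].to_numpy() - 1990))
        feats = ("area_m2", "year", "northing_m")
        H = rm.h2_pairwise(f, feats, self._background())
        assert H.loc["area_m2", "year"] > H.loc["area_m2", "northing_m"]
        assert H.loc["area_m2", "year"] > H.loc["year", "northing_m"]

    def test_symmetry_and_range(self, small_model, small_split):
        _, _, test = small_split
        H = rm.h2_pairwise(small_model, ("area_m2", "year", "habitat"),
                           test.head(20))
        assert np.allclose(H.to_numpy(), H.to_numpy().T)
        assert (H.to_numpy() >= 0).all() and (H.to_numpy() <= 1).all()

    def test_constant_function_reports_zero_with_warning(self):
        f = FunctionModel(lambda d: np.full(len(d), 3.0))
        with pytest.warns(UserWarning, match="constant"):
            H = rm.h2_pairwise(f, ("area_m2", "year"), self._background(10))
        assert float(H.to_numpy().max()) == 0.0


class TestCorrelogram:
    def test_colocated_identical_residuals_give_unit_bin(self):
        rng = np.random.default_rng(1)
        n = 40
        coords = rng.uniform(0, 1e5, size=(n, 2))
        resid = rng.normal(0, 3, n)
        df = pd.DataFrame({
            "easting_m": np.repeat(coords[:, 0], 2),
            "northing_m": np.repeat(coords[:, 1], 2),
            "richness": np.repeat(resid, 2),
        })
        zero_model = FunctionModel(lambda d: np.zeros(len(d)))
        out = rm.residual_correlogram(zero_model, df, [0.0, 1.0, 1e5], seed=0)
        assert out["correlation"].iloc[0] == pytest.approx(1.0, rel=1e-6)

    def test_scale_covariance(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({
            "easting_m": rng.uniform(0, 1e4, 60),
            "northing_m": rng.uniform(0, 1e4, 60),
            "richness": rng.normal(10, 2, 60),
        })
        zero_model = FunctionModel(lambda d: np.zeros(len(d)))
        bins = [0, 2e3, 5e3, 2e4]
        a = rm.residual_correlogram(zero_model, df, bins, n_permutations=9, seed=3)
        doubled = df.assign(easting_m=2 * df["easting_m"],
                            northing_m=2 * df["northing_m"])
        b = rm.residual_correlogram(zero_model, doubled, [2 * e for e in bins],
                                    n_permutations=9, seed=3)
        np.testing.assert_allclose(a["correlation"], b["correlation"], rtol=1e-9)

    def test_independent_noise_inside_null_envelope(self, small_model, small_split):
        _, _, test = small_split
        sub = test.head(250)
        out = rm.residual_correlogram(small_model, sub,
                                      np.linspace(0, 1.2e6, 7), seed=4)
        inside = ((out["correlation"] >= out["null_low"])
                  & (out["correlation"] <= out["null_high"]))
        assert inside[out["n_pairs"] > 50].all()


class TestBlockCV:
    def test_folds_partition_records(self, small_split):
        _, train, _ = small_split
        sub = train.head(400)
        out = rm.block_cv(sub, Hyperparams(n_trees=10, seed=0), scheme="spatial",
                          block_size_m=2.5e5, max_folds=4)
        assert out["n_test"].sum() == len(sub)

    def test_spatial_blocking_hurts_under_spatial_structure(self):
        # a smooth random bump surface gives each block spatial structure the
        # other blocks cannot supply, so blocked folds must do worse than
        # random folds
        rng = np.random.default_rng(6)
        n = 800
        df = pd.DataFrame({
            "easting_m": rng.uniform(0, 1e6, n),
            "northing_m": rng.uniform(0, 1e6, n),
            "elevation_m": rng.uniform(0, 500, n),
            "area_m2": rng.uniform(1, 100, n),
            "year": rng.integers(1960, 2021, n),
            "habitat": rng.choice(sw.HABITATS, n),
        })
        centers = rng.uniform(0, 1e6, size=(12, 2))
        w = rng.choice([-8.0, 8.0], 12)
        xy = df[["easting_m", "northing_m"]].to_numpy()
        d2 = ((xy[:, None, :] - centers[None]) ** 2).sum(-1)
        mu = np.maximum(1, 25 + (np.exp(-d2 / (2 * 1.5e5**2)) * w).sum(1))
        df["richness"] = np.maximum(1, rng.poisson(mu))
        hp = Hyperparams(n_trees=25, seed=1)
        blocked = rm.block_cv(df, hp, scheme="spatial", block_size_m=5e5, seed=1)
        random_cv = rm.repeated_cv(df, hp, k=4, repeats=1, seed=1)
        assert blocked["rmse"].mean() > random_cv["rmse"].mean()

    def test_temporal_blocking_harmless_on_time_flat_world(self):
        slopes = {h: (0.0, 0.0, 0.0) for h in sw.HABITATS}
        cfg = dt.WorldConfig(seed=7, n_static=800, n_series=2, trend_slopes=slopes,
                             trend_northing_modulation=0.0)
        df = sw.generate_static(cfg)
        hp = Hyperparams(n_trees=25, seed=1)
        blocked = rm.block_cv(df, hp, scheme="temporal", block_size_years=20,
                              seed=1)
        random_cv = rm.repeated_cv(df, hp, k=4, repeats=1, seed=1)
        assert blocked["rmse"].mean() < 1.25 * random_cv["rmse"].mean()

    def test_single_block_raises(self, small_split):
        _, train, _ = small_split
        with pytest.raises(ValueError, match="single fold"):
            rm.block_cv(train.head(50), scheme="spatial", block_size_m=1e7)
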