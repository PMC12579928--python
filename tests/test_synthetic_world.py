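"""The synthetic world: ground-truth surface, generators, and oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import divtrend as dt
from divtrend import synthetic_world as sw
from divtrend import temporal_interpolation as ti


def _flat_cfg(**kw):
    slopes = {h: (0.0, 0.0, 0.0) for h in sw.HABITATS}
    return dt.WorldConfig(trend_slopes=slopes, trend_northing_modulation=0.0, **kw)


class TestConfig:
    def test_invalid_mixture_rejected(self):
        with pytest.raises(sw.ConfigurationError):
            dt.WorldConfig(habitat_mix={"forest": 0.5, "grassland": 0.5,
                                        "scrub": 0.2, "wetland": -0.2})

    def test_area_ranges_must_respect_habitat_windows(self):
        with pytest.raises(sw.ConfigurationError):
            dt.WorldConfig(area_ranges={"forest": (100, 1000), "grassland": (1, 150),
                                        "scrub": (1, 100), "wetland": (1, 100)})

    def test_series_length_minimum(self):
        with pytest.raises(sw.ConfigurationError):
            dt.WorldConfig(series_length_range=(1, 5))

    def test_yaml_round_trip(self, tmp_path):
        cfg = dt.WorldConfig(seed=4, n_static=10)
        cfg.to_yaml(tmp_path / "w.yaml")
        assert dt.WorldConfig.from_yaml(tmp_path / "w.yaml") == cfg

    def test_bundled_default_config_loads(self):
        cfg = sw.default_config()
        assert cfg == dt.WorldConfig(seed=11, n_static=2500, n_series=150)


class TestGroundTruth:
    def test_species_area_power_law(self):
        cfg = dt.WorldConfig(sar_z={h: 0.25 for h in sw.HABITATS})
        kw = dict(easting=[5e5], northing=[5e5], elevation=[300.0], year=[1990],
                  habitat=["grassland"])
        s1 = sw.expected_richness(cfg, area=[20.0], **kw)
        s2 = sw.expected_richness(cfg, area=[40.0], **kw)
        assert s2 / s1 == pytest.approx(2**0.25, rel=1e-12)

    @given(st.floats(1.0, 100.0), st.floats(1.0, 9.0))
    def test_area_monotonicity(self, area, factor):
        cfg = dt.WorldConfig()
        kw = dict(easting=[2e5], northing=[8e5], elevation=[500.0], year=[1970],
                  habitat=["wetland"])
        s1 = sw.expected_richness(cfg, area=[area], **kw)
        s2 = sw.expected_richness(cfg, area=[area * factor], **kw)
        assert s2 >= s1

    def test_trend_linear_identity_and_continuity(self):
        # +1 species/decade in 2000-2020 at the reference area
        slopes = {h: (0.0, 0.0, 1.0) for h in sw.HABITATS}
        cfg = dt.WorldConfig(trend_slopes=slopes, trend_northing_modulation=0.0)
        kw = dict(easting=[5e5], northing=[5e5], elevation=[300.0],
                  area=[cfg.reference_area_m2], habitat=["forest"])
        s2000 = sw.expected_richness(cfg, year=[2000], **kw)
        s2020 = sw.expected_richness(cfg, year=[2020], **kw)
        assert s2020 - s2000 == pytest.approx(2.0, abs=1e-9)
        # continuity across the 1980 and 2000 boundaries
        for boundary in (1980, 2000):
            below = sw.expected_richness(dt.WorldConfig(), year=[boundary - 1e-6], **kw)
            at = sw.expected_richness(dt.WorldConfig(), year=[boundary], **kw)
            assert at == pytest.approx(below, abs=1e-4)

    def test_floor_at_one_species(self):
        cfg = dt.WorldConfig(baseline_richness={h: 1.0 for h in sw.HABITATS})
        s = sw.expected_richness(cfg, easting=[0], northing=[1e6], elevation=[3000.0],
                                 area=[1.0], year=[1980], habitat=["wetland"])
        assert s == 1.0


class TestGenerateStatic:
    def test_fixed_seed_determinism_byte_identical(self):
        cfg = dt.WorldConfig(seed=1, n_static=1000, n_series=10)
        a = sw.generate_static(cfg).to_csv(index=False)
        b = sw.generate_static(cfg).to_csv(index=False)
        assert a == b
        assert len(sw.generate_static(cfg)) == 1000

    def test_unique_plot_ids(self, small_static):
        assert small_static["plot_id"].is_unique

    def test_mean_richness_tracks_mu_per_habitat(self, small_cfg, small_static):
        """Monte-Carlo moment check against the mu oracle (3 SE)."""
        mu = sw.expected_richness_frame(small_cfg, small_static)
        for h in sw.HABITATS:
            sel = small_static["habitat"] == h
            n = int(sel.sum())
            se = np.sqrt(mu[sel.to_numpy()].mean() / n)  # Poisson noise
            assert abs(small_static.loc[sel, "richness"].mean()
                       - mu[sel.to_numpy()].mean()) < 3 * se + 0.05

    def test_negative_binomial_is_overdispersed(self):
        cfg = _flat_cfg(seed=3, n_static=4000, noise="negative_binomial",
                        nb_dispersion=2.0)
        nb = sw.generate_static(cfg)
        mu = sw.expected_richness_frame(cfg, nb)
        # compare within a narrow mu stratum so mixture variance cannot mask it
        band = (mu > 15) & (mu < 25)
        r = nb.loc[band, "richness"]
        assert r.var() > 1.5 * r.mean()


class TestGenerateSeries:
    def test_series_construction(self, small_cfg, small_series):
        g = small_series.groupby("resurvey_id")
        assert g.ngroups == small_cfg.n_series
        lengths = g.size()
        lo, hi = small_cfg.series_length_range
        assert lengths.between(lo, hi).all()
        assert (g["year"].nunique() == lengths).all()  # distinct years
        for col in ("easting_m", "northing_m", "area_m2", "habitat"):
            assert (g[col].nunique() == 1).all()  # fixed site

    def test_median_span_configurable(self):
        cfg = dt.WorldConfig(seed=2, n_static=10, n_series=600,
                             median_series_span_years=15.0)
        series = sw.generate_series(cfg)
        spans = series.groupby("resurvey_id")["year"].agg(lambda y: y.max() - y.min())
        assert 10 <= spans.median() <= 20

    def test_expected_change_matches_configured_trend(self):
        slopes = {h: (0.0, 0.0, 1.0) for h in sw.HABITATS}
        cfg = dt.WorldConfig(trend_slopes=slopes, trend_northing_modulation=0.0)
        t2000 = sw.trend_term(cfg, [2000, 2020], ["forest", "forest"])
        assert t2000[1] - t2000[0] == pytest.approx(2.0)


class TestTrueChange:
    def test_flat_world_has_zero_change(self, small_static):
        cfg = _flat_cfg()
        ch = sw.true_change(cfg, small_static.head(50), 1960, 2020)
        assert np.allclose(ch["percent_change"], 0.0, atol=1e-9)
        assert np.allclose(ch["slope"], 0.0, atol=1e-12)

    def test_percent_change_formula(self):
        assert ti.percent_change(10.0, 12.0) == pytest.approx(20.0, abs=1e-12)

    def test_oracle_equivalence_with_interpolation_formulas(self, small_cfg, small_static):
        """true_change must equal the change statistics computed by the
        interpolation module applied directly to the mu surface."""
        plots = small_static.head(20)
        ch = sw.true_change(small_cfg, plots, 1960, 2020)
        recs = plots.copy()
        mu_series = []
        for yr in range(1960, 2021):
            recs["year"] = yr
            mu_series.append(sw.expected_richness_frame(small_cfg, recs))
        mu_series = np.column_stack(mu_series)
        years = np.arange(1960, 2021)
        for i in range(len(plots)):
            s0, s1 = mu_series[i, 0], mu_series[i, -1]
            assert ch["percent_change"].iloc[i] == pytest.approx(
                float(ti.percent_change(s0, s1)), abs=1e-9)
            assert ch["lnrr"].iloc[i] == pytest.approx(
                float(ti.log_response_ratio(s0, s1)), abs=1e-12)
            assert ch["raw_diff"].iloc[i] == pytest.approx(s1 - s0, abs=1e-9)
            assert ch["slope"].iloc[i] == pytest.approx(
                ti.plot_slope(years, mu_series[i]), abs=1e-9)

    def test_year_outside_range_rejected(self, small_cfg, small_static):
        with pytest.raises(ValueError):
            sw.true_change(small_cfg, small_static.head(2), 1900, 2020)
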