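"""Synthetic vegetation-plot world with a fully known richness surface.

This module generates plot data with the statistical structure the
interpolation analysis assumes: a large set of one-time ("static") plots
plus a smaller set of resurvey time series, both drawn from a deterministic
expected-richness surface

    mu(x, y, elev, A, t, h) = max(1, [c_h + spatial terms + trend_h(t)] * (A / A_ref)^z_h)

where ``c_h`` is a habitat baseline at the reference area, the spatial terms
are linear gradients in northing and elevation, ``trend_h(t)`` is a
piecewise-linear temporal term (continuous in ``t``, one slope per habitat
per reporting period) optionally modulated along the north–south axis, and
``(A / A_ref)^z_h`` encodes a power-law species–area relationship.

Because mu is known in closed form, every downstream stage (model fit,
interpolation, change statistics, trend aggregation, validation protocol)
can be tested by parameter recovery against a noise-free oracle.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

HABITATS: tuple[str, ...] = ("forest", "grassland", "scrub", "wetland")

#: Reporting periods of the piecewise temporal trend (inclusive year bounds).
TREND_PERIODS: tuple[tuple[int, int], ...] = ((1960, 1980), (1980, 2000), (2000, 2020))

#: Canonical column order of the plot-table CSV dialect.
PLOT_COLUMNS: tuple[str, ...] = (
    "plot_id",
    "resurvey_id",
    "obs_index",
    "easting_m",
    "northing_m",
    "elevation_m",
    "area_m2",
    "year",
    "habitat",
    "richness",
    "coord_uncertainty_m",
    "region_label",
)

#: Biogeographic-style region labels laid out on the synthetic plane.
REGION_LABELS: tuple[str, ...] = (
    "mediterranean",
    "alpine",
    "atlantic",
    "continental",
    "arctic",
    "boreal",
    "scandinavian_alpine",
)


class ConfigurationError(ValueError):
    """Raised when a WorldConfig violates its invariants."""


def _default_habitat_mix() -> dict[str, float]:
    # Proportions roughly matching the habitat composition of the filtered
    # European archive data (forest 0.25, grassland 0.48, scrub 0.09, wetland 0.18).
    return {"forest": 0.25, "grassland": 0.48, "scrub": 0.09, "wetland": 0.18}


def _default_area_ranges() -> dict[str, tuple[float, float]]:
    return {
        "forest": (100.0, 1000.0),
        "grassland": (1.0, 100.0),
        "scrub": (1.0, 100.0),
        "wetland": (1.0, 100.0),
    }


def _default_sar_z() -> dict[str, float]:
    return {"forest": 0.25, "grassland": 0.22, "scrub": 0.25, "wetland": 0.20}


def _default_baseline() -> dict[str, float]:
    # Species at the reference area; wetlands poorest, grasslands richest.
    return {"forest": 16.0, "grassland": 30.0, "scrub": 20.0, "wetland": 12.0}


def _default_trend_slopes() -> dict[str, tuple[float, float, float]]:
    # Species per decade at the reference area, one slope per TREND_PERIODS
    # entry: decline 1960-1980, flat 1980-2000, gain 2000-2020.
    return {
        "forest": (-1.5, 0.0, 1.0),
        "grassland": (-1.0, 0.0, 0.8),
        "scrub": (-1.2, 0.0, 0.8),
        "wetland": (-0.8, 0.0, 1.5),
    }


@dataclass
class WorldConfig:
    """Parameters of the synthetic world.

    Units: coordinates and elevation in meters, areas in m², richness in
    species, trend slopes in species per decade at the reference area.
    """

    seed: int = 0
    n_static: int = 20_000
    n_series: int = 1_000
    series_length_range: tuple[int, int] = (2, 8)
    #: Target median of the within-series first-to-last year span.
    median_series_span_years: float = 15.0
    year_range: tuple[int, int] = (1945, 2023)
    #: (easting_min, easting_max, northing_min, northing_max) in m.
    extent: tuple[float, float, float, float] = (0.0, 1_000_000.0, 0.0, 1_000_000.0)

    # Elevation surface: smooth function of (x, y) plus noise, so elevation
    # and space are collinear as in real terrain.
    elevation_base_m: float = 200.0
    elevation_relief_m: float = 900.0
    elevation_noise_sd_m: float = 60.0

    habitat_mix: dict[str, float] = field(default_factory=_default_habitat_mix)
    area_ranges: dict[str, tuple[float, float]] = field(default_factory=_default_area_ranges)
    sar_z: dict[str, float] = field(default_factory=_default_sar_z)
    baseline_richness: dict[str, float] = field(default_factory=_default_baseline)

    #: Species per km of northing (negative: richness declines northwards).
    northing_gradient_per_km: float = -0.005
    #: Species per km of elevation.
    elevation_gradient_per_km: float = -2.0

    trend_slopes: dict[str, tuple[float, float, float]] = field(
        default_factory=_default_trend_slopes
    )
    #: Multiplicative north-south modulation of the trend term: the temporal
    #: term is scaled by 1 + m * u where u in [-1, 1] from south to north.
    trend_northing_modulation: float = 0.5

    reference_area_m2: float = 100.0

    noise: str = "poisson"  # or "negative_binomial"
    nb_dispersion: float = 5.0  # NB size parameter; variance = mu + mu^2/k

    #: Coordinate uncertainty drawn uniformly from this range (m).
    coord_uncertainty_range: tuple[float, float] = (1.0, 500.0)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        e0, e1, n0, n1 = self.extent
        if not (e1 > e0 and n1 > n0):
            raise ConfigurationError(f"degenerate spatial extent {self.extent}")
        mix = self.habitat_mix
        if set(mix) != set(HABITATS):
            raise ConfigurationError(f"habitat mixture must cover {HABITATS}, got {set(mix)}")
        if any(p < 0 for p in mix.values()) or abs(sum(mix.values()) - 1.0) > 1e-9:
            raise ConfigurationError("habitat mixture proportions must be >= 0 and sum to 1")
        for h, (lo, hi) in self.area_ranges.items():
            if not 0 < lo < hi:
                raise ConfigurationError(f"invalid area range for {h}: {(lo, hi)}")
            bound = (100.0, 1000.0) if h == "forest" else (1.0, 100.0)
            if lo < bound[0] or hi > bound[1]:
                raise ConfigurationError(
                    f"{h} area range {(lo, hi)} outside the permitted {bound} m² window"
                )
        for h, z in self.sar_z.items():
            if not 0.0 < z < 1.0:
                raise ConfigurationError(f"SAR exponent for {h} must be in (0, 1), got {z}")
        if self.series_length_range[0] < 2:
            raise ConfigurationError("series_length_range minimum must be >= 2")
        if self.year_range[0] >= self.year_range[1]:
            raise ConfigurationError(f"invalid year range {self.year_range}")
        if self.noise not in ("poisson", "negative_binomial"):
            raise ConfigurationError(f"unknown noise family {self.noise!r}")

    # -- serialization -----------------------------------------------------

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "WorldConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        for key in ("series_length_range", "year_range", "extent", "coord_uncertainty_range"):
            if key in data:
                data[key] = tuple(data[key])
        for key in ("area_ranges", "trend_slopes"):
            if key in data:
                data[key] = {h: tuple(v) for h, v in data[key].items()}
        return cls(**data)


def default_config() -> "WorldConfig":
    """The bundled default world (the fixture world used in the test suite)."""
    from importlib import resources

    ref = resources.files("divtrend") / "configs" / "default_world.yaml"
    with resources.as_file(ref) as path:
        return WorldConfig.from_yaml(path)


# ---------------------------------------------------------------------------
# Ground-truth surface


def elevation_surface(config: WorldConfig, easting, northing) -> np.ndarray:
    """Deterministic (noise-free) elevation model: smooth ridges over (x, y)."""
    e0, e1, n0, n1 = config.extent
    u = (np.asarray(easting, dtype=float) - e0) / (e1 - e0)
    v = (np.asarray(northing, dtype=float) - n0) / (n1 - n0)
    relief = 0.5 * (np.sin(2.3 * np.pi * u + 0.7) + np.cos(1.7 * np.pi * v - 0.3))
    return config.elevation_base_m + config.elevation_relief_m * 0.5 * (relief + 1.0)


def _trend_breakyears() -> np.ndarray:
    return np.array([TREND_PERIODS[0][0]] + [p[1] for p in TREND_PERIODS], dtype=float)


def trend_term(config: WorldConfig, year, habitat) -> np.ndarray:
    """Piecewise-linear temporal term, in species at the reference area.

    Anchored at 0 in the first break year (1960); continuous at period
    boundaries; extended with the first/last period slope outside the
    period window so the full configured year range is covered.
    """
    year = np.asarray(year, dtype=float)
    habitat = np.asarray(habitat)
    out = np.empty(year.shape, dtype=float)
    breaks = _trend_breakyears()
    for h in HABITATS:
        mask = habitat == h
        if not mask.any():
            continue
        slopes = np.asarray(config.trend_slopes[h], dtype=float) / 10.0  # per year
        # cumulative value at each break year, anchored at breaks[0]
        knots = np.concatenate([[0.0], np.cumsum(slopes * np.diff(breaks))])
        yr = year[mask]
        idx = np.clip(np.searchsorted(breaks, yr, side="right") - 1, 0, len(slopes) - 1)
        out[mask] = knots[idx] + slopes[idx] * (yr - breaks[idx])
    return out


def _northing_unit(config: WorldConfig, northing) -> np.ndarray:
    """Map northing to [-1, 1] across the extent (south -> north)."""
    _, _, n0, n1 = config.extent
    return 2.0 * (np.asarray(northing, dtype=float) - n0) / (n1 - n0) - 1.0


def expected_richness(
    config: WorldConfig, easting, northing, elevation, area, year, habitat
) -> np.ndarray:
    """The ground-truth expected richness mu, floored at 1 species."""
    habitat = np.asarray(habitat)
    c = pd.Series(habitat).map(config.baseline_richness).to_numpy(dtype=float)
    z = pd.Series(habitat).map(config.sar_z).to_numpy(dtype=float)
    spatial = (
        config.northing_gradient_per_km * np.asarray(northing, dtype=float) / 1000.0
        + config.elevation_gradient_per_km * np.asarray(elevation, dtype=float) / 1000.0
    )
    modulation = 1.0 + config.trend_northing_modulation * _northing_unit(config, northing)
    temporal = trend_term(config, year, habitat) * modulation
    area_factor = (np.asarray(area, dtype=float) / config.reference_area_m2) ** z
    return np.maximum(1.0, (c + spatial + temporal) * area_factor)


def expected_richness_frame(config: WorldConfig, records: pd.DataFrame) -> np.ndarray:
    """``expected_richness`` evaluated on rows of a canonical plot table."""
    return expected_richness(
        config,
        records["easting_m"].to_numpy(),
        records["northing_m"].to_numpy(),
        records["elevation_m"].to_numpy(),
        records["area_m2"].to_numpy(),
        records["year"].to_numpy(),
        records["habitat"].to_numpy(),
    )


# ---------------------------------------------------------------------------
# Sampling helpers


def assign_region(config: WorldConfig, easting, northing) -> np.ndarray:
    """Categorical region labels tiled over the plane.

    Three latitudinal bands; the northern band splits into arctic / boreal /
    Scandinavian-alpine thirds so the merge rule used in trend aggregation
    has something to merge.
    """
    e0, e1, n0, n1 = config.extent
    u = np.clip((np.asarray(easting, dtype=float) - e0) / (e1 - e0), 0, 1 - 1e-12)
    v = np.clip((np.asarray(northing, dtype=float) - n0) / (n1 - n0), 0, 1 - 1e-12)
    out = np.empty(u.shape, dtype=object)
    south, mid, north = v < 1 / 3, (v >= 1 / 3) & (v < 2 / 3), v >= 2 / 3
    out[south & (u < 0.5)] = "mediterranean"
    out[south & (u >= 0.5)] = "alpine"
    out[mid & (u < 0.5)] = "atlantic"
    out[mid & (u >= 0.5)] = "continental"
    out[north & (u < 1 / 3)] = "arctic"
    out[north & (u >= 1 / 3) & (u < 2 / 3)] = "boreal"
    out[north & (u >= 2 / 3)] = "scandinavian_alpine"
    return out


def _draw_richness(config: WorldConfig, mu: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if config.noise == "poisson":
        draws = rng.poisson(mu)
    else:
        k = config.nb_dispersion
        draws = rng.negative_binomial(k, k / (k + mu))
    # plots contain at least one vascular plant
    return np.maximum(1, draws).astype(int)


def _sample_sites(config: WorldConfig, n: int, rng: np.random.Generator) -> pd.DataFrame:
    e0, e1, n0, n1 = config.extent
    habitat = rng.choice(
        HABITATS, size=n, p=[config.habitat_mix[h] for h in HABITATS]
    ).astype(object)
    easting = rng.uniform(e0, e1, size=n)
    northing = rng.uniform(n0, n1, size=n)
    elevation = np.maximum(
        0.0,
        elevation_surface(config, easting, northing)
        + rng.normal(0.0, config.elevation_noise_sd_m, size=n),
    )
    lo = pd.Series(habitat).map({h: r[0] for h, r in config.area_ranges.items()}).to_numpy(float)
    hi = pd.Series(habitat).map({h: r[1] for h, r in config.area_ranges.items()}).to_numpy(float)
    # log-uniform plot areas within the habitat's permitted window
    area = np.exp(rng.uniform(np.log(lo), np.log(hi)))
    unc = rng.uniform(*config.coord_uncertainty_range, size=n)
    return pd.DataFrame(
        {
            "easting_m": easting,
            "northing_m": northing,
            "elevation_m": elevation,
            "area_m2": area,
            "habitat": habitat,
            "coord_uncertainty_m": unc,
            "region_label": assign_region(config, easting, northing),
        }
    )


def _finalize(df: pd.DataFrame) -> pd.DataFrame:
    out = df.reindex(columns=PLOT_COLUMNS).reset_index(drop=True)
    out["year"] = out["year"].astype(int)
    out["richness"] = out["richness"].astype(int)
    return out


# ---------------------------------------------------------------------------
# Public generators


def generate_static(config: WorldConfig, include_contaminants: int = 0) -> pd.DataFrame:
    """Generate one-time plots; optionally append filter-violating records.

    Each plot is sampled exactly once (unique ``plot_id``); observed richness
    is drawn from the configured noise family around the ground-truth mu.
    ``include_contaminants`` appends that many records that deliberately
    violate the standard data filters (for filter tests only).
    """
    rng = np.random.default_rng(config.seed)
    sites = _sample_sites(config, config.n_static, rng)
    y0, y1 = config.year_range
    sites["year"] = rng.integers(y0, y1 + 1, size=config.n_static)
    mu = expected_richness(
        config,
        sites["easting_m"],
        sites["northing_m"],
        sites["elevation_m"],
        sites["area_m2"],
        sites["year"],
        sites["habitat"],
    )
    sites["richness"] = _draw_richness(config, mu, rng)
    sites["plot_id"] = [f"S{i:07d}" for i in range(config.n_static)]
    sites["resurvey_id"] = pd.array([None] * config.n_static, dtype="string")
    sites["obs_index"] = pd.array([pd.NA] * config.n_static, dtype="Int64")
    out = _finalize(sites)
    if include_contaminants:
        out = pd.concat(
            [out, _contaminants(config, include_contaminants, rng)], ignore_index=True
        )
    return out


def _contaminants(config: WorldConfig, n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Records violating the data filters, one violation kind per record."""
    kinds = ["incomplete", "uncertainty", "habitat", "area", "year"]
    sites = _sample_sites(config, n, rng)
    y0, y1 = config.year_range
    sites["year"] = rng.integers(y0, y1 + 1, size=n)
    sites["richness"] = 1 + rng.poisson(10.0, size=n)
    sites["plot_id"] = [f"C{i:05d}" for i in range(n)]
    sites["resurvey_id"] = pd.array([None] * n, dtype="string")
    sites["obs_index"] = pd.array([pd.NA] * n, dtype="Int64")
    for i in range(n):
        kind = kinds[i % len(kinds)]
        if kind == "incomplete":
            sites.loc[i, "area_m2"] = np.nan
        elif kind == "uncertainty":
            sites.loc[i, "coord_uncertainty_m"] = 1000.0 + float(rng.uniform(0, 5000))
        elif kind == "habitat":
            sites.loc[i, "habitat"] = "saltmarsh"
        elif kind == "area":
            h = sites.loc[i, "habitat"]
            sites.loc[i, "area_m2"] = 150.0 if h != "forest" else 50.0
        elif kind == "year":
            sites.loc[i, "year"] = int(rng.choice([1940, 2030]))
    return _finalize(sites)


def generate_series(config: WorldConfig) -> pd.DataFrame:
    """Generate resurvey time series: fixed site, >= 2 observations.

    Each series has one location / area / habitat and 2+ observations at
    distinct years. The first-to-last span is drawn from an exponential
    distribution whose median is ``median_series_span_years``; interior
    observation years are uniform within the span.
    """
    rng = np.random.default_rng(config.seed + 1)
    n = config.n_series
    sites = _sample_sites(config, n, rng)
    kmin, kmax = config.series_length_range
    lengths = rng.integers(kmin, kmax + 1, size=n)
    y0, y1 = config.year_range
    scale = config.median_series_span_years / np.log(2.0)
    rows = []
    for i in range(n):
        k = int(lengths[i])
        span = int(np.clip(round(rng.exponential(scale)), k - 1, y1 - y0))
        first = int(rng.integers(y0, y1 - span + 1))
        interior = rng.choice(np.arange(1, span), size=k - 2, replace=False) if k > 2 else []
        years = np.sort(np.concatenate([[0, span], interior])).astype(int) + first
        site = sites.iloc[i]
        for j, yr in enumerate(years, start=1):
            rows.append((i, j, int(yr)))
    obs = pd.DataFrame(rows, columns=["_site", "obs_index", "year"])
    out = sites.iloc[obs["_site"]].reset_index(drop=True)
    out["obs_index"] = obs["obs_index"].astype("Int64")
    out["year"] = obs["year"]
    out["resurvey_id"] = pd.array(
        [f"R{i:05d}" for i in obs["_site"]], dtype="string"
    )
    out["plot_id"] = out["resurvey_id"].astype(object)
    mu = expected_richness(
        config,
        out["easting_m"],
        out["northing_m"],
        out["elevation_m"],
        out["area_m2"],
        out["year"],
        out["habitat"],
    )
    out["richness"] = _draw_richness(config, mu, rng)
    return _finalize(out)


def true_change(
    config: WorldConfig,
    records: pd.DataFrame,
    year_start: int,
    year_end: int,
    area: float | Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Noise-free change statistics from the ground-truth surface.

    Evaluates mu at ``year_start`` and ``year_end`` for each record (holding
    site covariates fixed; ``area`` overrides the observed plot area, either
    as a scalar or a per-habitat mapping) and returns the standard change
    records. Serves as the oracle in parameter-recovery tests.
    """
    from . import temporal_interpolation as ti

    lo, hi = min(year_start, year_end), max(year_start, year_end)
    if lo < config.year_range[0] or hi > config.year_range[1]:
        raise ValueError(
            f"years ({year_start}, {year_end}) outside configured range {config.year_range}"
        )
    recs = records.copy()
    if area is not None:
        if isinstance(area, Mapping):
            recs["area_m2"] = recs["habitat"].map(dict(area)).astype(float)
        else:
            recs["area_m2"] = float(area)
    years = np.arange(lo, hi + 1)
    mu_by_year = np.empty((len(recs), len(years)))
    for j, yr in enumerate(years):
        recs["year"] = yr
        mu_by_year[:, j] = expected_richness_frame(config, recs)
    s0 = mu_by_year[:, 0 if year_start == lo else -1]
    s1 = mu_by_year[:, -1 if year_end == hi else 0]
    # OLS slope of mu on year over the inclusive window, matching plot_slope
    yc = years - years.mean()
    slope = (mu_by_year @ yc) / (yc @ yc)
    return pd.DataFrame(
        {
            "plot_id": records["plot_id"].to_numpy(),
            "year_start": year_start,
            "year_end": year_end,
            "s_start": s0,
            "s_end": s1,
            "percent_change": ti.percent_change(s0, s1),
            "lnrr": ti.log_response_ratio(s0, s1),
            "raw_diff": s1 - s0,
            "slope": slope,
        }
    )
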