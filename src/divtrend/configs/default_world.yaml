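# Default synthetic-world configuration (the fixture world used in tests).
seed: 11
n_static: 2500
n_series: 150
series_length_range: [2, 8]
median_series_span_years: 15.0
year_range: [1945, 2023]
extent: [0.0, 1000000.0, 0.0, 1000000.0]
elevation_base_m: 200.0
elevation_relief_m: 900.0
elevation_noise_sd_m: 60.0
habitat_mix:
  forest: 0.25
  grassland: 0.48
  scrub: 0.09
  wetland: 0.18
area_ranges:
  forest: [100.0, 1000.0]
  grassland: [1.0, 100.0]
  scrub: [1.0, 100.0]
  wetland: [1.0, 100.0]
sar_z:
  forest: 0.25
  grassland: 0.22
  scrub: 0.25
  wetland: 0.20
baseline_richness:
  forest: 16.0
  grassland: 30.0
  scrub: 20.0
  wetland: 12.0
northing_gradient_per_km: -0.005
elevation_gradient_per_km: -2.0
trend_slopes:
  forest: [-1.5, 0.0, 1.0]
  grassland: [-1.0, 0.0, 0.8]
  scrub: [-1.2, 0.0, 0.8]
  wetland: [-0.8, 0.0, 1.5]
trend_northing_modulation: 0.5
reference_area_m2: 100.0
noise: poisson
nb_dispersion: 5.0
coord_uncertainty_range: [1.0, 500.0]
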