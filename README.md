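# ambientpop

Dasymetric mapping of **ambient population** — the time-averaged number of
people physically present in a place — onto a fine geographic grid, using
location-based-service (LBS) positioning counts as the disaggregation signal.

Administrative statistics (e.g. county-level permanent-resident counts) are
accurate but spatially coarse; LBS count rasters are spatially fine but are
not population. This package links the two: it averages daily count rasters
over a holiday-filtered calendar, fits a log-linear **geographically weighted
regression** (GWR) between zone populations and zone-aggregated counts, and
then redistributes each zone's statistic over its grid cells proportionally
to the locally predicted weights, conserving every zone total exactly. It is
aimed at spatial demographers and at health / disaster-risk modellers who
need a gridded population denominator between census years.

## Model

With `County_i` the permanent population of zone *i* and `Tencent_i` the
zone-aggregated mean LBS count, the fitted relation is

```
ln County_i = a_i · ln Tencent_i + b_i + ε_i,        ε_i ~ N(0, σ²)
```

where `(a_i, b_i)` are local coefficients estimated at each zone anchor by
weighted least squares with distance-decayed weights (bisquare or Gaussian
kernel; fixed or adaptive bandwidth selected by AICc or leave-one-out CV).
Each cell *j* of zone *i* with mean count `T_j` receives the weight
`w_ij = exp(b_i) · T_j^{a_i}`, and the zone population is allocated
pycnophylactically:

```
pop_ij = County_i · w_ij / Σ_j w_ij
```

A global OLS fit is kept as the baseline, and an accuracy-assessment module
scores any allocation against finer validation units (MSE on a configurable
population scale, squared Pearson correlation, through-origin slope).

Because real LBS feeds are proprietary, the package ships a first-class
synthetic-scenario generator (clustered truth surface, smooth coefficient
fields, contiguous county/town partitions, noisy daily stacks with inflated
holiday dates) so the entire pipeline is testable end to end offline.

## Worked example

```python
import ambientpop as ap

scen = ap.generate_scenario(ap.ScenarioConfig(seed=1))   # 100x100 grid, 400 counties
res  = ap.run_scenario_pipeline(scen, compare_uniform=True)

print(f"Pearson r (raw/log): {res.pearson_raw:.3f} / {res.pearson_log:.3f}")
print(f"OLS  R2 = {res.ols.r2:.3f}   RSS = {res.ols.rss:.2f}")
print(f"GWR  R2 = {res.gwr.r2:.3f}   RSS = {res.gwr.rss:.2f}")
print(f"max county conservation error: {res.diagnostics.max_relative_error():.2e}")
print(f"town-level MSE  weighted / uniform: "
      f"{res.town_report.mse:.2e} / {res.uniform_town_report.mse:.2e}")
```

prints

```
Pearson r (raw/log): 0.853 / 0.967
OLS  R2 = 0.934   RSS = 49.82
GWR  R2 = 0.999   RSS = 0.42
max county conservation error: 5.81e-16
town-level MSE  weighted / uniform: 3.02e-05 / 4.60e-04
```

The log transform strengthens the population–count correlation, the local
(GWR) fit captures the spatially varying exponent that the global OLS fit
cannot, county totals are conserved to machine precision, and the weighted
allocation beats a uniform-areal spread by an order of magnitude at the
(held-out) town level.

The same chain is available from the shell:

```bash
ambientpop simulate --seed 1 --out-dir data/
ambientpop average  --stack-dir data/ --months 3 --out mean.tif
ambientpop zonal    --raster mean.tif --zones data/counties.geojson \
                    --stats data/county_stats.csv --out-table table.csv \
                    --out-zone-raster zones.tif
ambientpop fit      --table table.csv --out-fit fit.csv
ambientpop allocate --raster mean.tif --zone-raster zones.tif \
                    --fit fit.csv --stats data/county_stats.csv --out pop.tif
ambientpop validate --surface pop.tif --unit-zones data/towns.geojson \
                    --unit-stats data/town_stats.csv --out-report report.csv
```

or all at once with `ambientpop run-all --seed 1 --out-dir out/`.

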