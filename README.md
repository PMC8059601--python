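# pyrodiv

Quantify **pyrodiversity** — the variation in spatio-temporal fire patterns
across a landscape — and model its socioecological drivers.

The package is aimed at landscape and fire ecologists working with
MTBS-style fire records: large-fire perimeter polygons with burn years and
ignition dates, plus per-fire burn-severity surfaces on the composite burn
index (CBI) scale, 0 (unchanged) to 3 (complete above-ground mortality). It
also ships a synthetic fire-mosaic generator so every step can be exercised,
tested and calibrated without external data.

## The metric

Four fire-regime traits are mapped per pixel over the record window
(frequency as fire return interval, CBI severity, ignition season as the
cosine of date, and the log-hectare size of the severity-class patch the
pixel burned in), each averaged over the pixel's fires with **recency
weighting by fire order**: the *k*-th most recent event gets weight
∝ (1 − d)^(k−1). The default decay d = 0.5 halves each older event's
weight; d = 0 weights all events equally and d = 1 keeps only the most
recent fire (the "visible mosaic").

Pyrodiversity of a landscape unit is then the **functional dispersion**
(FDis, Laliberté & Legendre) of its fire histories: each grid cell is an
individual, each unique discretized trait combination *x_j* a "species"
with abundance *a_j* (its pixel count), and

&nbsp;&nbsp;&nbsp;&nbsp;FDis = Σ_j a_j z_j / Σ_j a_j,

where *z_j* is the Gower-distance-based ordination distance of history *j*
from the abundance-weighted community centroid *c*. FDis is unitless, zero
for a uniform landscape, independent of the number of histories, and
tolerant of missing traits (never-burned pixels carry no season or patch).

Drivers are modeled with a linked two-stage hierarchical model: a hurdle
(Bernoulli × Gamma) model of the proportion of flammable area burned, feeding
a Beta regression of pyrodiversity with logit-linear mean

&nbsp;&nbsp;&nbsp;&nbsp;pyrodiversity_ij ~ Beta(P̄_ij θ, (1 − P̄_ij) θ),
logit(P̄_ij) = α₀ + α_j + β·X_i,

with climate (AET, CWD and their interaction), topography (elevation,
roughness, interaction), human influence (population density, proportion
wilderness), burn activity and its quadratic as predictors, and varying
intercepts α_j ~ N(0, σ) for the coarse watersheds the sample units nest
in. The quadratic vertex −β₁/(2β₂) gives the burned proportion at which
pyrodiversity peaks, convertible to a fire rotation (record years / peak
proportion).

## Worked example

```python
import pyrodiv as p

# a two-regime landscape: frequent low-severity small-patch fires in the
# west half, two rare high-severity large fires in the east half
records, units = p.two_regime_fixture(seed=0)
stack = p.build_trait_stack(records, decay=0.5)
for u in units:
    res = p.pyrodiversity_of_unit(stack, u)
    print(f"{u.unit_id:>6}: FDis = {res.fdis:.4f}  "
          f"({res.n_histories} histories, {res.n_pixels} px)")
```

```
  west: FDis = 0.0168  (9 histories, 5000 px)
  east: FDis = 0.0037  (4 histories, 5000 px)
 union: FDis = 0.1310  (13 histories, 10000 px)
```

Each half is internally near-uniform, so its dispersion is small; mixing
the two regimes adds large between-regime trait distances and the union's
FDis far exceeds either half — exactly the property that makes FDis a
useful pyrodiversity measure.

Fitting the driver model to data simulated from its own defaults recovers
the generative coefficients and the burn-activity optimum:

```python
sim = p.simulate_driver_table(p.ModelSpec(), n_units=500, n_groups=5, seed=1)
fit = p.fit_pyro_model(sim.table, n_draws=2000, seed=1)
dq = p.derived_quantities(fit, sim.scaling, record_years=34)
```

```
b_prop_burn: 2.55 (90% CI 2.41, 2.68)
b_prop_burn_sq: -0.81 (90% CI -0.87, -0.74)
peak at 146% burned (CI 140-151%), rotation 23 yr
```

(The generative truths are 2.5 and −0.78; the peak location depends on the
mean and spread of the simulated burned proportions, since the vertex is
back-transformed from standardized units.)

## Command line

```bash
pyrodiv simulate --params params.yaml --out sim/
pyrodiv ingest   --perimeters sim/perimeters.geojson --severity-dir sim/severity \
                 --start 1985 --end 2018 --out records/
pyrodiv traits   --records records/ --decay 0.5 --out traits/
pyrodiv fdis     --traits traits/ --units units.geojson --out pyrodiv.csv
pyrodiv covary   --traits traits/ --units units.geojson --records records/ \
                 --min-fires 1:15 --out covary.csv
pyrodiv drivers  --table drivers.csv --propagate --draws 2000 --seed 7 --out fit/
```

`simulate` writes the same layout `ingest` reads, so the whole chain round
trips.

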