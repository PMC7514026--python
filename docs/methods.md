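# Methods note

This note records the mathematical conventions, default parameters and
design decisions behind `poicrime`. Everything here is implemented and
tested in the package; nothing depends on external data.

## 1. Model

Let `p_1 … p_m` be POI locations, each belonging to a class `c(i)`, and
let `K_h(r)` be a radially symmetric kernel with bandwidth `h`,
normalised so that its planar integral is one:

```
∫_0^∞ 2π r K_h(r) dr = 1.
```

The crime intensity is modelled as

```
C(x) = w_0 + Σ_i w_{c(i)} K_h(‖x − p_i‖),
```

i.e. every POI contributes one kernel bump and all POIs of a class
share a weight. Grouping by class gives the linear model `C ≈ w_0 +
B w`, where column `j` of the basis `B` is the summed (unweighted)
kernel density of class `j` evaluated on a regular grid.

### Kernels

Six kernel profiles are provided, each with its closed-form planar
normalisation constant (`u = r/h`):

| kind | profile ∝ | constant |
|---|---|---|
| gaussian | exp(−u²/2) | 1/(2πh²) |
| tophat | 1{u ≤ 1} | 1/(πh²) |
| epanechnikov | (1 − u²)₊ | 2/(πh²) |
| exponential | exp(−u) | 1/(2πh²) |
| linear | (1 − u)₊ | 3/(πh²) |
| cosine | cos(πu/2)·1{u ≤ 1} | 1/((4 − 8/π)h²) |

Normalisation is verified by quadrature in the test suite to 1e-6.

### Grid and units

A study area is a square of side `S` (default 3000 m) centred on the
city centre, discretised into `n × n` cells (default `n = 150`, so
20 m cells and 22 500 samples, row-major with the row index increasing
northward; each sample sits at its cell centre). The default bandwidth
is `h = S/40 = 75 m`.

Density rasters use an **intensity scale**: values are points per km²,
so a raster of `N` points integrates (sum × cell area in km²) to `N`
up to boundary loss. This makes the cross-validation compensation
below meaningful. When building bases and responses, input points are
windowed to the area padded by one bandwidth, so POIs just outside the
square still contribute their bumps inside it.

### KDE evaluation

`estimate_density` evaluates the kernel sum **exactly** (dense
point-to-grid distances, processed in memory-bounded chunks). No
finite cutoff is applied to infinite-support kernels: at study sizes
(≈22 500 grid cells × a few thousand points) exact evaluation is fast,
and exactness lets the estimator be validated against a brute-force
double-loop oracle at 1e-10 relative tolerance.

## 2. Sparse fitting

The selection step solves

```
min_w  (1/2n) ‖ỹ − B̃w‖² + α ‖w‖₁
```

on standardised columns (centred, unit standard deviation; constant
columns get scale 1 and coefficient 0) and centred response, via
coordinate descent (scikit-learn's `Lasso`, tolerance 1e-8); `α = 0`
falls back to least squares. Coefficients are reported both on the
standardised and the original scale. `alpha_max = max|B̃ᵀỹ|/n` is the
smallest penalty with an empty support.

`select_alpha_for_support(k=10)` binary-searches `α` in
`(0, alpha_max)` for a support of exactly `k` classes. Because the
LASSO path can jump over a given support size, if the search exhausts
its iterations the smallest visited support larger than `k` is
truncated to the `k` largest |standardised coefficients| and the
result is flagged `fallback=True`. The final model is an **OLS refit**
on the selected classes only, removing shrinkage bias; the baseline
model is the same OLS on the alcohol-outlet column alone.

## 3. Cross-validation designs

**Point-split CV (per city).** Each point set — every POI class and
the crime set — is independently partitioned into `K` near-equal random
parts (default `K = 2`, 100 repeats). Fold densities are rescaled by
the inverse sampling fraction (`×K/(K−1)` for train, `×K` for test) so
both estimate the full-data intensity. For each repeat, selection and
refit run on the training densities and R² is computed between the
predicted and the held-out crime raster. Fold assignment is
deterministic given the seed and is keyed per point-set label (a CRC32
of the label selects an independent substream), so results do not
depend on the order classes are listed.

**Leave-one-city-out.** Bases from all-but-one city are stacked
(classes aligned by name; classes absent from a city contribute zero
columns), one model is fitted, and it is scored on the held-out city.

**Sweeps.** `alpha_sweep`, `kernel_sweep` and `bandwidth_sweep` re-run
the point-split CV over a grid of the respective parameter;
`kernel_sweep` returns kernels sorted by mean R².

### Improvement arithmetic

Per-city improvement is `trunc(100 · (model − baseline)/baseline)` —
**truncation toward zero, not rounding**. This choice reproduces all
ten rows of the packaged UK reference table exactly (rounding fails on
two cities), and gives mean improvements of 43.5 % over ten cities and
48.2 % excluding the one near-zero-improvement outlier city
(Liverpool). The reference table ships as package data
(`poicrime/data/uk_city_cv_reference.csv`).

## 4. Synthetic-city generator

`SyntheticCitySpec` describes a city: POI classes (count + layout per
class) and true per-class weights. Layouts:

- **uniform** over the padded area;
- **clustered**: points around `n_clusters` uniformly drawn centres
  with Gaussian scatter `cluster_sd`;
- **collinear**: points placed a small uniform-disc offset
  (`offset_radius`) from anchor points of another class, with anchors
  assigned by balanced cycled permutations so every anchor is used
  equally (sampling anchors with replacement adds multiplicity noise
  that destroys the intended near-collinearity).

Crimes are drawn from the exact generative model: a POI is chosen with
probability proportional to its class weight, then a displacement is
drawn from the kernel's radial law `f(r) ∝ r K_h(r)` — Rayleigh(`h`)
for gaussian, Gamma(2, `h`) for exponential (mean `2h`), `h√U` for
tophat, rejection sampling for the compact kernels — with resampling
of draws that land outside the padded area. All randomness flows
through `numpy.random.SeedSequence([seed, stage, substream])`, so
layouts and crimes are independently reproducible.

`anonymise_crimes` emulates public crime-data anonymisation by
snapping each crime to the nearest of a fixed set of snap points (ties
broken by lowest index) and reports the displacement distribution
(mean/median/90th-percentile and a 5 m-binned histogram).

**Benchmark city** (`benchmark_city_spec`): three causal classes with
weights 1.0 / 0.6 / 0.5 ("Pubs, Bars and Inns", "Fast Food and
Takeaway Outlets", "Bus Stops") plus twelve zero-weight clutter
classes, all clustered (4 clusters, 200 m scatter, 60 points per
class), 3000 crimes, exponential kernel at `h = 75 m` on a 60 × 60
grid. The clustered layout mirrors real city-centre POI geography —
under a uniform layout the classes are too weakly distinguished for
selection to be informative. The 60 × 60 grid and 3-repeat CV are
deliberate test-scale reductions of the 150 × 150 / 100-repeat study
configuration, chosen purely for runtime; they change no conventions.

### Realism and limitations

The generator draws crimes from the *same family of models that is
later fitted*, so it validates correctness of the pipeline (recovery
of known weights, kernel identification, baseline comparisons), not
the scientific adequacy of the model for real cities. It has no
temporal structure, no spatial covariates beyond POIs, and
homogeneous per-class weights.

## 5. Numerical and reproducibility choices

- All long-running estimators are chunked, not approximated.
- Seeds derived anywhere in the package stay below 2³¹.
- The CLI writes a `manifest.json` with SHA-256 hashes of every input
  and output file; reruns with the same config and seed are
  byte-identical.
- The British National Grid projection (Airy 1830 transverse Mercator
  plus a 7-parameter Helmert shift to WGS84) is implemented in-package
  and validated against the national mapping agency's published worked
  example to sub-millimetre accuracy, avoiding a heavyweight
  projection dependency.
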