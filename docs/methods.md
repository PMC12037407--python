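# Methods

## Scope and model

The package computes premature mortality attributable to ambient PM2.5
over a gridded population, apportioned by emission source, for multi-decade
emission scenarios. It deliberately starts *downstream* of the
chemistry-transport model: its inputs are annual-mean concentration fields
(a reference run plus per-source perturbed runs), gridded head counts by
5-year age group, and cause- and age-specific baseline mortality rates.
Atmospheric chemistry, meteorology and emission inventories are out of
scope; the grid is an abstract regular raster (uniform cell area, per-cell
region labels) because the burden arithmetic only ever pairs a cell's
concentration with the same cell's population — no geodesy is used.

### Source apportionment

For source *P* perturbed by emission fraction *f* (default 0.30):
`C_P = (C_NPC − C_PC)/f`. The estimate is exact when the concentration
response to the perturbation is linear; real chemistry is only near-linear,
so cells can come out negative (perturbed run above reference). Negatives
are **retained, not clipped** — clipping would bias national sums — and a
warning is logged when more than 5% of cells are negative, since widespread
negatives indicate nonlinear chemistry or a mismatched run pair. A
`floor_at_zero` flag exposes the clipped alternative; the default is no
floor. The perturbation fraction is a parameter rather than a constant so
near-linearity can itself be probed by varying it.

### Exposure-response

*Linear pathway* (all-cause, acute + chronic):
`RR(c) = 1 + (RR₁₀−1)(c−c₀)⁺/10`. Defaults: chronic RR₁₀ = 1.08 (the
WHO-recommended long-term all-cause meta-analytic value), counterfactual
c₀ = 0 (the linear pathway is conventionally reported without a threshold;
c₀ is configurable for sensitivity). The acute coefficient is **not an
epidemiological constant of this package**: it is a required configuration
value whose default (RR₁₀ = 1.0096) is a structural placeholder calibrated
so acute deaths are ≈11% of the linear total in a high-exposure baseline
year, matching the acute/chronic split of the scenario tables the
reporting stage consumes. Any real analysis should set it from the
short-term literature for its own region.

*Nonlinear pathway* (GEMM): `RR = exp(θ·ln(z/α+1)/(1+exp(−(z−μ)/ν)))`,
`z = (c − 2.4 µg m⁻³)⁺`, natural log, evaluated per cause for adults (25+)
— the hazard functions are adult-cohort fits, and the age restriction is
configurable per endpoint. The bundled `data/gemm_params.csv` transcribes
the published adult per-cause parameter sets; it is *data, not code*, and
every test asserts against declared fixture values (θ=0.1430, α=1.6,
μ=15.5, ν=36.8 for the combined NCD+LRI shape) so correctness never
depends on the transcription.

*Attributable fraction*: `AF = (RR−1)/RR` by default; the proportional
form `AF = RR−1` ("delta") is a config switch. Published burden
assessments use both without always saying which; the switch makes the
ambiguity explicit and testable. Delta is the default for *per-source*
burdens because it makes them exactly additive (the sum over sources
equals the burden of the summed fields), which is the property the source
accounting relies on.

### Burden accounting

`deaths = Σ_cells Σ_ages pop(cell,age) · rate(endpoint,age) · AF(RR(c(cell)))`,
aggregated by region label and nationally; regional rows must sum to the
national row (1e-9 relative). Baseline rates are held fixed across
projection years — the convention of using a single reference year of
vital statistics for all scenario years. Two totalization modes exist for
the nonlinear pathway: `sum_causes` (LC+COPD+IHD+stroke+LRI) and `ncd_lri`
(the joint NCD+LRI hazard). Published tables do not always state which
mode produced their totals — both are first-class and the package does not
guess.

### Reporting

Percent changes vs the 2010 baseline, equal-weight annual averages over
{2020, 2030, 2040, 2049}, the relative nonlinear-vs-linear gap of those
averages, cause shares, absolute decreases, and the per-source
decomposition of a 2010→2049 reduction. Internal values keep full
precision; rounding — **half away from zero**, integer percents and
2-decimal millions — is applied only at the reporting boundary. That
convention reproduces every checkable published cell (2.3875 → 2.39,
−13.4 → −13). Statistics formed from *already-rounded* table cells can
land one point away from prose formed from unrounded values (e.g. the
acute-death reduction 0.18/0.37 → 51% vs a printed 52%); those cells are
documented where tested and excluded from exactness claims. Region-share
statistics are computed but never asserted against published values: the
real regional mask is not public, and the synthetic mask is declared, not
inferred.

## Synthetic data: what it emulates and what it does not

The generator emits, per scenario (CLE-like and MFR-like) and year
(2010–2049 in five steps): NPC fields for all four species, four per-source
perturbed total-PM2.5 fields, gridded age-sliced population, and baseline
mortality — plus a `GroundTruth` record of the true decomposition.

Emulated structure, with defaults as the study conditions:

- **Spatial structure**: smoothed correlated noise plus a deterministic
  high-pollution block labelled "central-eastern" (25% of cells, 4×
  anthropogenic enhancement) where 75% of the population lives. No
  geostatistical fitting: only the exposure–population covariance matters
  to the burden math.
- **Levels and trends**: 2010 national mean 19.7 µg m⁻³ (4.0 background +
  15.7 anthropogenic); total-mean declines of 34% (CLE) and 78% (MFR) by
  2049, achieved by linearly scaling the anthropogenic part (background is
  natural and constant). The implied absolute drops (≈6.7 and
  ≈15.3 µg m⁻³) follow.
- **Sources**: shares of anthropogenic mass bi 40%, in 34%, re 16%, tr 10%.
  All four source fields share one anthropogenic spatial pattern scaled by
  these shares. This is a deliberate simplification: it makes
  exposure-weighted source contributions equal the configured shares by
  construction, giving the end-to-end pipeline a sharp oracle. Real
  sources have distinct spatial footprints; the pipeline handles that
  (nothing assumes a shared pattern), but the synthetic suite does not
  exercise it. Optional per-source decline weights let one source dominate
  the scenario decline (normalized so the share-weighted mean still hits
  the total decline target).
- **Perturbed runs**: `PC = NPC − f·(1 − ε·f)·C_s`. With ε = 0 the
  apportionment recovers ground truth to machine precision; ε > 0 yields a
  relative under-recovery of exactly ε·f, a controllable stand-in for
  chemistry nonlinearity.
- **Population**: national totals peak in 2020 (1.45 × 10⁹) and fall ~11%
  below 2010 by 2049; the 65+ share rises from exactly 8% (2010) to
  exactly 23% (2049) via two-anchor linear interpolation of the bundled
  pyramid (shares are inputs, so these are exact, not approximate).
- **Baseline mortality**: all-cause rate 8×10⁻⁴·e^(0.25·i) over age-group
  index i (crude rate ≈0.0068 yr⁻¹ under the 2010 pyramid), causes as
  fixed adult-only fractions of all-cause. The ramp is deliberately gentle:
  steep enough to be strictly age-increasing, gentle enough that scenario
  emission declines outweigh population ageing in the linear pathway — the
  regime in which source-attributable burdens *decline* under both
  scenarios and the 2010→2049 reduction decomposition is well-posed, which
  is the trend structure the suite is built to emulate. (With a much
  steeper ramp, ageing would dominate and the linear burden would rise
  under moderate control — a real possibility for strongly ageing
  populations, but not the emulated regime.)

What passing tests on this suite show: the pipeline's algebra (Eq.-style
apportionment, risk functions, burden sums, reporting arithmetic) is
correct, exactly, under known ground truth. What they do not show:
performance on real chemistry-transport output (nonlinear chemistry,
distinct source footprints, projection/regridding artefacts), real census
or GBD data quirks, or the validity of the transcribed hazard parameters.

## Numerical choices

- Grid I/O is NetCDF3-classic via xarray's scipy backend (self-describing,
  dependency-light); round-trips are bit-exact and property-tested.
  Tables are UTF-8 CSV.
- Rounding: half away from zero at the reporting boundary only.
- Degenerate inputs raise typed errors: zero baselines/denominators,
  years outside anchor ranges (no extrapolation), misaligned grids
  (first differing dimension named), missing baseline rows (endpoint and
  age named), reduction fraction ≤ 0, RR < 1, non-net-positive reduction
  decompositions.
- The linear-slope recovery check inverts the national death count with
  Brent root-finding on RR₁₀ ∈ (1, 2], xtol 1e-9.
- Problem sizes: unit tests run on 12×12 grids, the apportionment oracle
  on 50×50, the end-to-end desk run on the 40×40 default — small enough
  for interactive iteration, large enough that spatial structure is
  non-trivial.

## Known limitations

- No uncertainty propagation (hazard-parameter standard errors, baseline
  rate uncertainty); point estimates only.
- Morbidity, valuation, years-of-life-lost, and other pollutants are out
  of scope.
- GEMM-on-source-fields is available behind a flag but is non-standard:
  hazard nonlinearity makes per-source GEMM burdens non-additive, so the
  default source accounting is linear-pathway only.
- The synthetic population uses one shared structure across scenarios
  (isolating the concentration signal in scenario contrasts), and the
  regional mask is a declared block, not an inferred geography.
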