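# Methods

This note documents the models, the numerical choices and the synthetic study
design behind `sealtrend`, in the order the pipelines run.

## Colony demography

### Counts and provenance

A colony series is a list of `(year, count, kind)` records. `kind` records
whether the number is a direct February pup count or was derived from a
January adult-female count; the packaged census fixture stores the derived pup
numbers with that flag, so fits treat both kinds identically while preserving
provenance. Zero counts (Cedros 1965) are kept in the data but excluded from
log-linear fits with a logged warning, since ln 0 is undefined; nothing is
imputed.

### Attendance (haul-out) model

Breeding females arrive asynchronously and stay ashore for a fixed bout, so a
single-day female count undercounts the season total. We model arrival dates
as N(μ, σ²) and residence as a fixed D days, giving the expected fraction
ashore on day t as Φ((t−μ)/σ) − Φ((t−μ−D)/σ) — bounded in [0, 1], unimodal,
zero at both season extremes, and collapsing to an indicator as σ → 0. The
parameters are configuration (defaults μ = day 20, σ = 6 d, D = 31 d, with
day 0 = 1 December): they describe a San Benito-like season and must be
replaced when a colony-specific attendance curve is available. The birth rate
B = 0.7419 (sd 0.0345) converts season-total females to pups. Counts taken
when the attendance curve is ≈ 0 raise an explicit out-of-window error rather
than dividing by zero.

### Trend fits

λ = e^r with r the OLS slope of ln(count) on calendar year. λ is exp(slope)
*exactly* (same float), R² is the standard coefficient of determination
clamped to 0 for a constant response, and the slope standard error uses the
n−2 residual degrees of freedom (0 when n = 2). Both coefficient-of-variation
conventions (slope/SE and SE/slope) are computed because the field uses
either; `cv` aliases the configured one. Published CV values for this dataset
are not reproducible under either convention, so CV is reported but never
asserted.

### Breakpoints

For series with at least 10 positive counts, every observed year that leaves
≥ 2 points per side is a candidate break; two independent log-linear segments
are fitted and the candidate minimising their summed RSS wins, ties resolved
toward the earlier year. Because each segment gets its own OLS line, the
segmented RSS can never exceed the single-line RSS (nesting). Whether the
break year itself joins the left or right segment is an explicit option
(default left). Two caveats are deliberate:

- A break label inside a census gap is partition-equivalent to any other label
  in the same gap: for San Benito the optimal split separates 1965–1991 from
  2001–2016, and any nominal year in 1992–2000 describes the same model. We
  report the last observed year of the left segment.
- A discrete RSS-minimising search responds to the largest residual feature in
  the series. On the Guadalupe record this is the 1965→1969 count jump, so
  the search picks 1969 rather than the early-1990s regime change a
  continuity-constrained segmented regression would report. Users interested
  in a specific hypothesis should fit the configured windows directly (as the
  packaged reproduction config does).

### Population scaling

Total population = pups × M, where M is looked up (nearest λ) in a
user-supplied (λ, M, CI) table whose provenance the configuration records; the
default table carries the single published triple M(0.99) = 4.31 (3.59–5.02)
for this species. Rounding is half-away-from-zero. The 95% CI endpoints are,
by default, the *rounded* point estimate rescaled by M_CI/M rather than
pups × M_CI directly; the two differ by at most one individual and the former
matches the published reporting of the 2009 estimate. The option
`ci_from_rounded_point=False` gives the direct product.

## Gridded SST pipeline

### Lanczos low-pass filter

Weights are the ideal-sinc response times the Lanczos sigma taper, normalised
to unit sum (gain exactly 1 at frequency 0). The cutoff period is 14.4 months
(1.2 yr), chosen to remove the semi-annual and annual cycles while keeping
interannual variability. Window length matters: by direct Fourier transform of
the weights, a 37-weight filter at this cutoff still passes 21% of the annual
harmonic, while 61 weights (the package default) passes 8.5%. We accept the
larger end-loss (30 months per end) because suppressing the annual cycle is
the filter's purpose; the length is configurable, and a 3-weight filter is
allowed but warns that it is nearly all-pass. Filtering a field trims the
half-window at each end of the time axis.

### EOF / varimax decomposition

Anomalies (per-gridpoint line removed) are flattened over ocean gridpoints,
weighted by √cos(latitude) (configurable off), and decomposed by SVD:
Z = U S Vᵀ. Unrotated patterns are the right singular vectors (orthonormal,
variance-ordered); expansion coefficients are U S. The leading k loadings
L = V_k S_k are varimax-rotated with the classical iterative SVD algorithm
(tolerance 1e-12); rotated coefficients are U_k R, so the rotated modes
reconstruct the k-mode subspace exactly and their summed explained variance
equals the unrotated subspace's (checked to 1e-8 relative in tests, and
cross-checked against R's `stats::varimax` on a fixed matrix). k defaults
to 10 and must not exceed the matrix rank. EOF signs are arbitrary; we pin
each pattern positive at a user-named reference gridpoint, or at its gridpoint
of maximum absolute loading by default, so tests and reruns are reproducible.
Rotated modes are re-ordered by explained variance.

### ENSO removal and trend maps

The decomposition is computed from the filtered *and detrended* field, but the
mode is subtracted from the filtered, *not* detrended field, so the secular
trend survives while the oscillatory mode is removed. Trends are then mapped
over consecutive non-overlapping 30-year windows anchored at the first
complete calendar year of the (trimmed) record: per gridpoint, Sen's slope
(median of pairwise slopes, via `scipy.stats.theilslopes`) converted to
°C decade⁻¹, and a Mann-Kendall class (none / p<0.05 / p<0.01). A gridpoint
needs ≥ 80% of the window's months (configurable); land stays masked. A window
not fully covered by the record is an error, not a silent truncation.

### Mann-Kendall details

S = Σ_{i<j} sign(x_j − x_i); Var(S) uses the standard tie correction; Z uses
the ±1 continuity correction; p is two-sided normal. Missing values are
dropped, reducing n — the test's standard treatment of gappy records. An
exact-permutation null is available for n ≤ 9 tie-free series; the default is
the normal approximation, whose type-I error at α = 0.05 calibrates to
0.04–0.06 at n = 50 in the test suite. A degenerate all-tied series returns
S = 0, Z = 0, p = 1 rather than erroring.

## Station pipeline

Daily → monthly → seasonal means with explicit coverage rules (defaults: a
month needs ≥ 20 days, a season all 3 months, the annual mean ≥ 10 months;
all configurable and logged in the config hash). Seasons are meteorological
(DJF/MAM/JJA/SON) with December attached to the *following* year's winter, so
winter-1961 = Dec 1960 + Jan/Feb 1961. The anomaly baseline defaults to
1961–1990 (the conventional WMO normal; configurable). Seasonal trends reuse
the same Mann-Kendall/Sen implementation as the gridded pipeline — one code
path, asserted identical in tests — and Sen's slope (°C yr⁻¹) is reported only
when p < 0.05, otherwise withheld and flagged. A heat wave is a single day
with tmax ≥ 25.1 °C (inclusive threshold; the upper critical air temperature
for dry weaned harbour seal pups) inside December–April; the frequency
denominator counts only in-window days with non-missing tmax. Period
comparison is a Pearson 2×2 χ² on events/non-events, continuity correction
off by default (option available).

## Synthetic study design

The generators define the conditions every recovery test runs under; they are
deterministic given (parameters, seed).

- **Counts**: value(y) = start · Πλ with multiplicative lognormal noise,
  rounded to integers ≥ 1 — positivity-preserving and log-linear by
  construction. Reference scenario: λ = 1.03 then 0.97, break 1997,
  1965–2016, noise sd 0.02–0.05, emulating the census table's shape.
  Breakpoint recovery is validated at 20 years, +5%/−4% growth, break at year
  12, noise sd 0.02, 200 seeds (≥ 95% within ±1 yr).
- **SST fields**: mean + annual cycle + linear trend + Σ pattern·sin(2πt/T) +
  white noise, with an optional land mask; a 42–48-month oscillation stands in
  for ENSO as a fixed spatial pattern times a smooth oscillation. This
  emulates the layout and the signal/noise structure of a reconstruction
  product, not ENSO dynamics, teleconnection asymmetries or spatially
  correlated noise — so passing tests demonstrate the machinery recovers
  planted structure, not that real-data trends are certified.
- **Station records**: sinusoidal annual cycle (coldest late January) + trend
  + Gaussian noise; tmax/tmin as ±4 °C offsets with re-ordering so
  tmin ≤ tmean ≤ tmax always holds; gaps by i.i.d. seeded draws (real gaps
  cluster; coverage rules are exercised either way). The optional
  winter-exceedance mode plants an exact per-day probability that tmax reaches
  the heat threshold, giving a binomial oracle for heat-wave frequency.

Problem sizes in the suite (e.g. 7×9 to 20×20 grids, 30–66-year records,
200–500 seed replicates, 10⁴ Mann-Kendall null replicates) were chosen as the
smallest designs whose binomial/Monte-Carlo error still separates pass from
fail at the documented tolerances.

## Known limitations

- The attendance-curve parameters and the M(λ) table are external inputs; the
  defaults document plausible values, they are not re-derived from raw data.
- No mortality correction between birth and the February count: pup production
  is slightly underestimated in principle; annual, colony-level variation in
  early mortality makes a correction less defensible than the omission.
- The breakpoint search is discontinuous two-segment OLS, not a
  continuity-constrained segmented regression (see caveat above).
- Published correlations with external climate indices (MEI, PDO) and the
  station record's published trend values require the external datasets and
  are out of scope; the machinery that would compute them is tested on
  synthetic truth instead.
- netCDF output is NETCDF3-classic (xarray scipy backend).
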