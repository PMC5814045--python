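# sealtrend

Population-trend and regional climate-trend analysis for the northern elephant
seal (*Mirounga angustirostris*) colonies of Baja California, Mexico — and for
anyone with similar census-plus-climate data.

The Baja California breeding colonies (Guadalupe Island, San Benito Islands,
Cedros Island) are censused sparsely: some years have direct February pup
counts, others only January counts of adult females. `sealtrend` turns these
heterogeneous counts into pup-production estimates, growth-rate trends and a
total population size, and pairs that with the climate diagnostics needed to
ask whether the region the seals breed in is warming: filtered and
ENSO-corrected sea-surface-temperature trend maps and station
air-temperature/heat-wave statistics.

## What it computes

**Demography.** For a colony census series $N_t$ the intrinsic rate of increase
$r$ is the slope of the OLS regression $\ln N_t = a + r\,t$, reported as the
annual rate of increase $\lambda = e^{r}$ ($\lambda > 1$ growth, $\lambda < 1$
decline). January female counts are first converted to pup production with a
normal-arrival / fixed-residence attendance curve,

$$p(t) = \Phi\!\left(\tfrac{t-\mu}{\sigma}\right) - \Phi\!\left(\tfrac{t-\mu-D}{\sigma}\right),$$

(total females = count / $p(t)$; pups = females × birth rate $B = 0.7419 \pm
0.0345$). Series with $n \ge 10$ are scanned exhaustively for the two-segment
log-linear breakpoint minimising total RSS. Total pup production is scaled to
population size with a $\lambda$-dependent multiplier $M$ (user-supplied
lookup table with 95% CI).

**Climate.** Monthly SST fields are low-pass filtered (Lanczos, 1.2-yr
cutoff), detrended, and decomposed into empirical orthogonal functions with
varimax rotation of the leading modes; the ENSO mode is reconstructed and
subtracted from the filtered (not detrended) field; Sen's-slope trends
(°C decade⁻¹) with Mann-Kendall significance (95%/99%) are mapped over
consecutive 30-year windows. Daily station records are aggregated to
meteorological seasons with explicit gap rules, tested for monotone trends
(MK, Sen's slope in °C yr⁻¹ reported when p < 0.05), referenced to a 1961–1990
anomaly baseline, and scanned for single-day heat waves (tmax ≥ 25.1 °C,
December–April), with a χ² comparison of heat-wave frequency between periods.

All external datasets are replaced by seeded synthetic generators with planted
ground truth; the 1965–2016 census table ships as a packaged fixture.

## Worked example

```python
from sealtrend import RunConfig, run_demography_workflow

report = run_demography_workflow(RunConfig())
print(report.total_pups)                 # 5174
print({c: s[0] for c, s in report.shares.items()})
# {'guadalupe': 59, 'san_benito': 33, 'cedros': 8}
print(report.population.point, report.population.ci)
# 22300 (18575, 25974)
print(round(report.pooled_fit.lambda_, 2))   # 0.99
```

Read: in 2009 (the latest year all three colonies were censused) 5,174 pups
were born — 59% on Guadalupe, 33% on San Benito, 8% on Cedros. The pooled
1970–2009 growth rate is λ = 0.99 (roughly stationary), and at that λ the
multiplier M = 4.31 (95% CI 3.59–5.02) gives a total 2009 population of
22,300 individuals (CI 18,575–25,974). Per-colony fits in `report.fits` show
both major colonies declining at λ ≈ 0.97 since the 1990s.

The same things are available from the shell:

```sh
sealtrend trend --colony san_benito --from 1998 --to 2016
sealtrend breakpoint --colony san_benito
sealtrend popsize --year 2009
sealtrend simulate sst --seed 1 --out field.nc
sealtrend sst-trend --input field.nc --rotate-k 3 --out trends.nc
sealtrend heatwaves --input station.csv --threshold 25.1
```

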