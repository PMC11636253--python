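# Methods

`aqequity` couples four models — emission downscaling, reduced-complexity
atmospheric dispersion and chemistry, population-weighted exposure
statistics, and a concentration–response mortality model — and exercises
them end-to-end on synthetic inputs that emulate the structure of the
U.S. county system, its demography, its power-plant fleet, and its
on-road vehicle activity. This note documents the models, their
assumptions, the defaults, and what the synthetic setting does and does
not demonstrate.

## Synthetic study conditions

The default configuration is a planar 3000 km square tiled by 54
counties in 9 contiguous regions, with a 2020 national population of
30 million growing linearly by 20% to 2050. This is a deliberately
scaled-down domain (roughly a tenth of the U.S. population on a
U.S.-sized domain) chosen so a full six-scenario run completes in
seconds; all structural properties tested (conservation, zero-sum
disparity, linearity, orderings) are scale-free.

**Geography.** Counties are grid cells; regions are contiguous blocks of
cells. Physics enters only through inter-centroid distances, so a flat
km-coordinate domain is used rather than lon/lat — it removes projection
ambiguity with no loss. Each county's population-weighted centroid is
its geometric centroid jittered by up to a quarter cell; both emission
release and receptor evaluation happen at the population-weighted
centroid.

**Demography.** 2020 county totals follow a log-normal size distribution
(σ = 1.2), so a few counties are dense, as in reality. National group
shares follow linear trajectories between the 2020 and 2050 anchors:
White non-Hispanic 60%→48%, Hispanic 18%→25%, Black non-Hispanic
13%→14%, Other 9%→13% (the residual of the first three; the four
shares sum to exactly 1 at both anchors). Per-county group mixes are
drawn once as log-normal propensity multipliers and balanced each period
by iterative proportional fitting, so county totals keep a fixed share
of the growing nation while national group shares match the anchors to
machine precision (the final IPF step scales columns). Age structure is
a fixed four-band pyramid per group (0–29, 30–64, 65–79, 80+), with
White non-Hispanic oldest and Hispanic youngest — the feature that lets
per-capita mortality diverge from exposure rankings. Sex is not
modelled: nothing downstream consumes it.

**EGU fleet.** Dispatch clusters are assigned round-robin to regions;
each cluster's units sit in counties of one region, with 2020 generation
drawn log-normally (median ≈ 3.3 TWh/yr, the scale of a mid-size fossil
plant, so power-sector emissions have a realistic magnitude relative to
traffic). Every region also carries at least one planned unit and one
retired site (zero generation) that seed the grow-in-place siting tiers.
All existing fossil units release from the medium (250–500 m) effective
height bin, the bin that historically carries roughly two-thirds of EGU
emissions; traffic releases at ground level.

**Vehicle stock.** A cohort model: a cohort of vintage period *v*
survives through period *v* + 5·*L* inclusive (*L* the lifetime in
five-year periods, default 3, i.e. a 15-year service life). Sales each
period split between ICE and ZEV by the policy's ZEV sales-share
schedule; pre-ban cohorts persist until retirement, which is why a 2035
sales ban does not zero ICE emissions until 2035 + 5·*L*. The model
conserves vehicles exactly: stock(t+1) = stock(t) − retirements + sales.

**Policy scenarios.** Six stylized scenarios stand in for an
energy-system optimisation model. EGU emissions scale 2020 fossil
emissions by, per period: a gentle exponential decline (2%/yr) under
current policy; min(that, 1 − clean fraction) under a clean electricity
standard rising 80% (2030) → 100% (2050); exp(−k·tax) with elasticity
k = 0.035 per $/t and a floor of 8% of 2020 emissions under a carbon tax
rising $50 (2025) → $80 (2050) — the floor produces the late-period
plateau a tax of that level induces; and a linear 2020→2050 cap under
net-zero (applied to both sectors). ICE-ban scenarios add an
electricity-demand increment proportional to the electrified fleet share
(default 35% of 2020 fossil output at full electrification), realised as
new gas capacity sited by grow-in-place — the mechanism by which a
vehicle ban *raises* power-sector emissions absent a clean-grid policy.
On-road emissions are regional ICE VMT times per-mile factors, shrinking
with fleet turnover. These responses are explicitly not calibrated to
any optimisation model; they encode the qualitative structure (timing,
coupling, floors) that drives the comparative results.

## Downscaling

Regional emissions reach counties by two exactly mass-conserving paths.

*EGU*: each region×fuel total splits over that region's clusters in
proportion to cluster 2020 generation, then over each cluster's units by
the unit's share of 2020 cluster generation. Shares are computed once
from the 2020 fleet and frozen — growth or decline of a cluster scales
all its units proportionally. A cluster with zero 2020 generation gets
uniform shares (the choice preserves conservation; the case arises only
in stress tests). New capacity is sited planned → retired → existing
same-fuel, each tier filled proportionally to candidate capacity, the
last tier absorbing any remainder; tier order is an argument.

*On-road*: county VMT = regional VMT × S(i,j)/ΣS over the region, where
S is the county VMT surrogate for the period's surrogate year (2020–24
→ 2023, 2025–29 → 2026, 2030–34 → 2032; 2035+ applies vehicle-type
national scaling factors to the 2032 surrogate — a uniform factor
cancels in the shares). Emissions are VMT × per-mile factors at ground
level. Non-exhaust particles (brake/tire wear) are excluded: only fuel
combustion is modelled, so primary PM from traffic is conservative.

## Atmospheric model

An annual-average, sector-averaged Gaussian plume with 16 wind sectors
(default uniform rose), one transport speed (4 m/s), a rural
neutral-stability vertical-dispersion closure σ_z(x) = a·x/(1+b·x)^c
(a = 0.06, b = 0.0015 m⁻¹, c = 0.5), and a well-mixed boundary-layer cap
(1000 m): the concentration is the smaller of the reflected-plume
solution and the uniformly mixed box value, standard practice for
annual-average reduced-complexity models. Release heights are bin
midpoint-like values: 0 m ground, 125 m low, 375 m medium, 750 m tall.
The self-receptor (and any shorter) distance is floored at
0.5·√(area/π), half the county's equivalent radius, to avoid the x → 0
singularity. A single multiplicative calibration scalar (default 1)
stands where a monitor calibration would sit; no attempt is made to
replicate any proprietary climatology or calibration, so this module is
an AP3-class model, not a replica — all checks are against its own
closed forms, not external output.

Secondary inorganic PM forms at the receptor from the dispersed
precursor: 15% of SO2 mass arrives oxidisable to sulfate and 25% of NOx
to nitric acid (annual-average conversion fractions, configurable).
Partitioning against a county ammonia budget (default 0.5 µmol/m³) is a
simplified equilibrium: sulfate is neutralised first, forming ammonium
sulfate (mass 132/96 × sulfate) when ammonia covers 2 mol/mol, sulfuric
acid (98/96) otherwise; ammonium nitrate (80/62 × nitrate) forms only
from leftover ammonia. This makes secondary PM nonlinear in emissions,
which is why marginal concentrations use the add-one-ton algorithm: add
1 ton at a source, recompute the speciated field, subtract the baseline
field (the current-policy 2020 inventory, the NEI-style reference),
reset. Scenario fields are then emissions × marginal concentrations,
additive by source sector.

Two numerical notes. First, a marginal ton of SO2 can be *negative* at
an ammonia-limited receptor (each mole of added sulfate consumes two
moles of ammonia, displacing up to 160 g of ammonium nitrate against
132 g of ammonium sulfate gained); matrices are clipped at zero to stay
interpretable as nonnegative transfer coefficients. With the default
ammonia budget receptors sit in the ammonia-rich regime and the clip is
inactive. Second, the marginal linearisation is exact for primary PM2.5
and accurate for SO2/NOx only while scenario emissions perturb the
chemistry weakly; the test suite checks 5% agreement against brute-force
two-field recomputation in that regime, and nothing stronger is claimed.

## Exposure and disparity

Each person experiences their county's concentration. Group exposure is
the population-weighted mean over counties; disparity is group exposure
minus total-population exposure, computed nationally (one trace per
group, consistent with reporting one national disparity series). The
population-weighted sum of disparities is identically zero — an
algebraic identity the suite verifies to 1e-9 on every run. Disparities
use period-specific populations by default (switchable to fixed 2020
weights). Distributional summaries use population-weighted quantiles;
because the estimator convention for weighted percentiles is genuinely
open, both a midpoint-interpolation rule (default; reproduces the sample
median on equal weights) and a pure inverted-CDF step rule are
implemented and selectable.

## Health impact model

ΔMort = y₀ · Pop · (1 − e^(−β·ΔPM)) per county, group and adult age
band (30+), with β = ln(RR)/10 for RR stated per 10 µg/m³. The form is
isolated in one function so the alternative convention
(y₀·Pop·(e^(βΔPM) − 1)) is a one-line swap. Three variants bracket how
risk varies by race: (A) constant RR with all-person age-specific rates
(the race-specific table collapsed by adult population weights), (B)
constant RR with race- and age-specific rates, (C) race-specific RR with
race- and age-specific rates. Defaults are configuration placeholders
with realistic magnitudes, not empirical estimates: constant RR 1.06
per 10 µg/m³; variant C multiplies ln(RR) per group (Black non-Hispanic
3.0, White non-Hispanic 0.9, Hispanic and Other 1.2), so in the linear
regime the high-risk group's per-capita deaths triple relative to the
constant-RR case. Baseline mortality rates rise with age and are lowest
for Hispanic adults (the "Hispanic paradox" ordering).

Cumulative 2020–2050 deaths weight each period's annual deaths by the
years it represents — 5 for 2020 through 2045 and 1 for 2050, a 31-year
inclusive horizon (switchable to 5 × 7). Avoided deaths are baseline
(current-policy) minus policy deaths, reported as the min–max range over
the three variants; whether a min–max range is the right uncertainty
construct is an assumption, labelled as such. Per-capita rates divide by
the group's all-ages population (switchable to adults only).

## What the synthetic setting shows — and does not

Passing tests demonstrate the *structure* of the coupled analysis:
exact conservation through both downscaling paths, the zero-sum
disparity identity, correctness of the plume and response closed forms
against independent evaluation, marginal-matrix/brute-force agreement,
cohort accounting, reproducibility, and the qualitative policy
orderings (every policy avoids deaths vs current policy; exposure falls
over time for every group; the combined ban+CES dominates either single
instrument by 2050; a carbon tax starting 2025 beats later-starting
instruments on cumulative deaths; an ICE ban alone avoids the fewest).
They do **not** validate magnitudes against real U.S. data: the
geography, fleet, meteorology, chemistry, mortality rates and policy
responses are all synthetic or placeholder, so absolute deaths,
concentrations and disparities carry no empirical weight. Real-data
features not emulated include spatial correlation of demography with
point-source siting beyond random propensity draws, within-county
heterogeneity, seasonal meteorology and terrain, interannual emission
variability, and morbidity endpoints or monetised damages.

## Numerical choices

IPF runs to a 1e-13 row tolerance with a final column scaling (group
anchors exact by construction). All randomness flows from a single root
seed through spawned 31-bit substreams, one per generator, so modules
are testable in isolation while runs are byte-reproducible. Degenerate
inputs fail loudly: empty county sets, zero group populations, all-zero
quantile weights, regions with demand but no siting candidates, and
surrogate-less regions with nonzero VMT all raise with the offending
entity named. Ties in the weighted quantile resolve by stable sort
order; equal-value counties are interchangeable in both conventions.
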