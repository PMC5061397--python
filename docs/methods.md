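# Methods

This note documents the statistical machinery behind `dielclass`: the
models, the defaults and why they were chosen, what the synthetic-survey
generator does and does not emulate, and the numerical choices that matter
for reproducibility.

## Detection events and effort

The unit record is a *capture event*: one camera trigger for one species,
timestamped by its first frame (a trigger's photo burst counts once).
Consecutive triggers closer than a refractory window are not independent
observations of activity; `filter_independent_events` enforces the window
in software with a rolling rule — an event is kept iff it falls at least
the window length (default 5 min, the usual hardware delay) after the last
*kept* event of the same camera × species stream. The rolling form mirrors
the hardware behaviour and makes the filter idempotent. Effort is a ledger
of closed date intervals per camera; an event on a boundary date counts as
within effort, and one camera-day of effort is one trap-day.

## Solar computation and the diel partition

Sunrise and sunset come from the NOAA solar-position algorithm: solar
declination and the equation of time from the Julian-century series (mean
longitude and anomaly, equation of center, apparent longitude with
nutation, true obliquity), with rise/set at the official zenith 90.833°
(geometric horizon + 34′ standard refraction + 16′ solar semi-diameter).
The ephemeris is first evaluated at local solar noon and then re-evaluated
at the provisional event times (two iterations); near the equinoxes the
declination moves ~0.4°/day, and skipping this refinement shifts rise/set
by up to ~2 min and introduces a spurious ~8 min asymmetry between the two
equinoxes. The simpler fractional-year trigonometric expansion was tried
and rejected for exactly that reason. Times are local civil time at a fixed
UTC offset; daylight saving is not modelled. Latitudes within 66° of the
poles only — beyond that the sun may not cross the official zenith and the
partition below is undefined. A per-date CSV override (`date, sunrise,
sunset`) lets published almanac tables be injected bit-exactly.

The diel partition per civil date: *twilight* = sunrise ± 1 h and
sunset ± 1 h (closed intervals, 4 h total), *day* = the open interval
(sunrise + 1 h, sunset − 1 h), *night* = the open remainder, which spans
midnight and is resolved against the neighbouring dates' solar times.
Period durations are exact interval measures clipped to the civil date, so
twilight + day + night = 24 h identically. Seasons are calendar quarters
(winter Jan–Mar, spring Apr–Jun, summer Jul–Sep, autumn Oct–Dec).

## Photographic frequencies

The sampling unit for the categorical analysis is the calendar day pooled
over cameras. For date *d*, species *s*, period *p*:

    f(d, s, p) = count(s, p, d) / hours(p, d) / cameras_active(d) × 100

detections per hour of period per 100 trap-days. Normalizing by each
date's *actual* period durations matters: day length at the study latitude
ranges over ~6 h through the year, and a fixed-hours normalization would
manufacture seasonal artefacts. Zero rows are kept for every active date —
absence is data. Conservation holds exactly:
Σₚ f·hours·cameras / 100 recovers the day's event count.

Because twilight is always 4 h while day and night vary up to ~15 h, the
per-day frequency variance differs across periods (shorter denominator →
noisier frequency). The one-way ANOVA below assumes homoscedasticity; with
equal group sizes (every day contributes one value per period) the F test
is robust to this, and simulation with a planted-uniform species shows a
type-I rate near nominal (~6% at α = 0.05).

## Categorization: ANOVA + Steel–Dwass

Per species and scope (a season, or annual), the three period-frequency
samples are compared by classical one-way ANOVA. Degenerate all-constant
input returns p = 1 (no evidence of structure). If the ANOVA is not
significant at α = 0.05 the species is **cathemeral (Ca)**. Otherwise the
Steel–Dwass all-pairs comparison ranks the periods: for each pair, the
rank sum of the two groups alone (mid-ranks for ties), standardized by its
null mean and tie-corrected variance

    Var(W) = n₁n₂/12 · [(N+1) − Σ(t³−t) / (N(N−1))],

and referred to the studentized-range distribution with k = 3 groups and
infinite degrees of freedom via t\* = √2·|z| — the standard large-sample
form. Labels: top period beats both others pairwise → **D** / **N** /
**Cr**; top two mutually unseparated but both above the third → composite,
written in canonical order (Cr before D before N: `Cr/N`, `D/N`, `Cr/D`);
ANOVA significant but no such pattern → **undetermined** (explicit rather
than silently mislabelled). Labels are scale-invariant in the frequencies.
No multiple-testing correction is applied across species × season cells;
each cell is reported as its own test.

Small-sample caveat: against exhaustive permutation enumeration on three
groups of four, the infinite-df studentized-range p agrees in the decision
tail (|Δp| ≈ 0.02 at p ≈ 0.05–0.07) and exactly at the null, but
understates mid-range p values (e.g. 0.19 vs an exact 0.26) — the
asymptotic reference is a tail approximation and should not be read as an
exact p at n = 4. Classification decisions, which only compare p to α,
are unaffected in the regimes tested.

## Circular kernel density

Event times map to the 24 h circle (24 h = 2π). The estimate is a von
Mises mixture with one kernel per event,
ĝ(θ) = n⁻¹ Σᵢ exp(κ cos(θ−tᵢ)) / (2π I₀(κ)), evaluated on a 256-point
grid (trapezoidal integral = 1 ± 10⁻⁶; the exponentially scaled Bessel
form keeps any κ finite). The default concentration is Taylor's circular
plug-in rule: fit a single von Mises by mean resultant length (Fisher's
approximation for κ̂), then

    κ_kde = [ 3 n κ̂² I₂(2κ̂) / (4 √π I₁(κ̂)²) ]^{2/5},

deterministic, floored at κ = 0.5 when the resultant length is ≈ 0
(uniform data carry no bandwidth signal). Densities are computed on clock
time, not solar-anchored time, matching how activity curves are
conventionally drawn (with night/twilight shading varying by season);
sun-anchored *profiles* exist on the simulation side. Multimodality is
captured by the mixture-of-kernels form itself; no mode-count selection is
attempted.

## Poisson random-intercept co-detection models

Counts of a focal species per camera site × observation unit are modelled
as y ~ Poisson(μ), log μ = β₀ + βᵀx + uᵢ, uᵢ ~ N(0, σ²), where x holds
same-site-unit counts of explanatory species and uᵢ absorbs between-camera
heterogeneity (placement, trail quality, effort). No offset term is used;
effort differences between sites load on the intercepts. The default unit
is the site-day: a single season total per site would leave the random
intercept unidentifiable (one observation per level), while daily counts
give the intercept replication; the season-total mode is retained for
comparability with coarser analyses.

The marginal likelihood integrates u out per site. The fitter maximizes
the Laplace approximation: an inner damped-Newton solve (tolerance 1e-10
on the mode gradient; the per-site objective is strictly concave) locates
each conditional mode û, and the site integral becomes
h(û) + ½ log(2π / −h″(û)). The outer optimization is quasi-Newton
(L-BFGS-B) over (β, log σ²), initialized from the fixed-effects Poisson
GLM and σ² = 0.1, with log σ² bounded in [log 10⁻⁸, log 10³] so
zero-variance fits terminate cleanly at the boundary; convergence is
declared by the optimizer or a β-block gradient norm below 1e-6–1e-4
(finite-difference gradients of an objective containing an inner solve
make tighter thresholds noise-limited). Standard errors come from the
inverse finite-difference Hessian of the marginal log-likelihood at the
optimum (the β block alone when σ̂² sits on the boundary), giving Wald Z
and two-sided p. An adaptive Gauss–Hermite mode (nodes recentred at û and
rescaled by the mode curvature, 21 nodes by default) provides a
high-accuracy oracle; on test fixtures Laplace agrees to within 0.05%
relative, and σ² = 0 reproduces the plain Poisson log-likelihood exactly.

Separation: a covariate that never co-occurs with positive responses has
no finite MLE; such fits surface as large |β̂| with standard errors in the
tens, and the fitter attaches an explicit warning instead of masking them
— a pattern that real sparse-species tables produce routinely.

## Synthetic surveys

The generator exists so every stage can be validated against known truth.
Each species has a planted diel density (a von Mises mixture on the 24 h
circle; component locations are clock hours or offsets from the date's
sunrise/sunset), a base rate in expected events per camera-day, four
seasonal multipliers, and optional dependence terms adding γ to the
log-rate per same-site-day event of another species (simulated in
dependency order). Events are drawn per camera × day from the
inhomogeneous Poisson process λ(t) = rate · multiplier · pdf(t) by
Lewis–Shedler thinning with the exact mixture-maximum bound — exact in
continuous time and grid-free, unlike discretized Bernoulli schemes — and
then passed through the refractory filter so simulated counts carry the
same censoring as field data. Identical seeds give byte-identical event
CSVs.

`planted_category` computes the analytic expected label: the planted
hourly intensity integrated over each diel period per survey date, with
Ca declared when the max/min per-hour intensity ratio across periods is
below 1.2 (a generator-side convention: below that ratio no period
"meaningfully dominates").

Defaults mimic a boreal-forest survey: site 42.75° N, 141.45° E, UTC+9,
30 cameras, 5-min refractory window. Validation runs use scaled designs
(8 cameras × one 90-day season, rates ~2 events/camera-day, κ = 4–8)
chosen to keep per-species information comparable to a common mid-abundance
species while allowing hundreds of replicates; recovery of strongly planted
categories exceeds 95% there, and planted-uniform species classify as Ca
at ≈ 93–95%.

What the generator does **not** emulate: imperfect or size-dependent
detectability, animal movement and home-range autocorrelation (events are
conditionally independent given the intensity), camera failures beyond
effort gaps, weather covariates, and double counting of individuals.
Passing recovery tests therefore demonstrates the statistical pipeline is
correct and well calibrated under the stated model — not that field data
meet that model.

## Numerical and degenerate-input conventions

- Twilight intervals are closed; day/night take the open remainder (a
  timestamp exactly at sunrise is twilight).
- ANOVA on all-equal data → (F, p) = (0, 1); groups under 2 observations
  are an error; classification with under 4 days of data → undetermined.
- Steel–Dwass with an all-tied pair → z = 0, p = 1.
- KDE requires ≥ 2 events; the plug-in rule ≥ 10.
- GLMM requires ≥ 5 sites and a full-rank design; σ² < 0 is an error.
- Dates with zero active cameras are excluded from the frequency table
  with a warning; events outside effort are dropped with a warning.
- All simulation randomness flows from a single `numpy` Generator seeded
  by the design; iteration order over cameras and species is fixed, so
  outputs are reproducible byte-for-byte.
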