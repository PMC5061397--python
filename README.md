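# dielclass

Diel activity classification for camera-trap surveys.

Camera traps record *when* animals pass, and the time-of-day structure of
those detections — diurnal, nocturnal, crepuscular (twilight-active), or
cathemeral (active around the clock) — is a basic descriptor of a species'
temporal niche. `dielclass` implements a complete, testable pipeline for
deriving that structure from multi-camera survey data, aimed at wildlife
ecologists working with detection-event tables (camera id, species,
timestamp) and trap-effort ledgers:

1. **Solar-anchored diel periods.** Sunrise and sunset per date are computed
   with the NOAA solar-position algorithm (official zenith 90.833°); the
   24 h cycle splits into *twilight* (sunrise ± 1 h and sunset ± 1 h, 4 h
   total), *day* (sunrise + 1 h → sunset − 1 h) and *night* (the remainder).
2. **Effort-normalized photographic frequencies.** For day *d*, species *s*,
   period *p*:
   `f(d,s,p) = count(s,p,d) / hours(p,d) / cameras_active(d) × 100`,
   i.e. detections per hour of period per 100 trap-days.
3. **Formal categorization.** One-way ANOVA compares the daily frequencies
   across the three periods; no difference at α = 0.05 means **Ca**
   (cathemeral). Otherwise the Steel–Dwass all-pairs rank test (pairwise
   rank sums referred to the studentized-range distribution, k = 3, df = ∞)
   ranks the periods: a single dominant period gives **D**, **N** or **Cr**;
   two mutually indistinguishable top periods give a composite (**D/N**,
   **Cr/N**, …).
4. **Activity curves.** Circular kernel density estimates on the 24 h clock
   with a von Mises kernel, `ĝ(θ) = n⁻¹ Σᵢ vM(θ; tᵢ, κ)`, with a
   deterministic plug-in rule for κ.
5. **Co-detection models.** Poisson GLMMs
   `log μᵢⱼ = β₀ + βᵀxᵢⱼ + uᵢ, uᵢ ~ N(0, σ²)` with a camera-site random
   intercept, fitted by maximizing the Laplace-approximated marginal
   likelihood (adaptive Gauss–Hermite quadrature is built in as a
   cross-check), for probing predator–prey and competitor association.
6. **Synthetic surveys.** An inhomogeneous-Poisson (thinning) simulator with
   planted von Mises diel profiles — optionally anchored to sunrise/sunset —
   seasonal rate modulation, camera refractory windows, and species
   co-detection dependence, so the whole pipeline validates end to end
   against known truth.

## Worked example

Simulate a one-season, five-camera survey with a day-active and a
night-active species, then classify them:

```sh
$ cat profiles.yaml
species:
  - name: dayrunner
    base_rate: 2.0
    components:
      - {weight: 1.0, location: 13.0, kappa: 4}
  - name: nightrunner
    base_rate: 2.0
    components:
      - {weight: 1.0, location: 1.0, kappa: 4}

$ dielclass simulate --profiles profiles.yaml --seed 7 --cameras 5 \
    --start 2013-04-01 --end 2013-05-30 \
    --out events.csv --effort-out effort.csv
wrote 1135 events to events.csv

$ dielclass classify --events events.csv --effort effort.csv --scope spring
    species  scope category          F      anova_p  n_days  twilight_mean ...
  dayrunner spring        D 426.269999 2.121821e-68      60       0.666667
nightrunner spring        N 221.567691 6.465139e-49      60       5.166667
```

`category` is the ANOVA + Steel–Dwass label: the day-peaked profile comes
back **D** (its day-time mean frequency beats twilight and night pairwise at
α = 0.05) and the night-peaked one **N**; `F`/`anova_p` are the one-way
ANOVA results over the 60 daily frequency triples. A third species with a
flat profile would return **Ca**. `dielclass kde --events events.csv
--species dayrunner --plot curve.png` draws the corresponding activity
curve with night/twilight shading, and `dielclass interact --events
events.csv --effort effort.csv --focal dayrunner --covariates nightrunner`
fits the co-detection GLMM (estimate/SE/Z/p per explanatory species plus
the site-intercept variance).

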