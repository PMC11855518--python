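# Methods

This note documents the models, the synthetic data they are exercised on,
the numerical choices, and the limits of what the tests demonstrate.

## Units and geometry

All coordinates are planar metres in a local projection; distances are
Euclidean; times are seconds; speeds are m/s (10 km/h ≈ 2.778 m/s
pedestrian, 40 km/h ≈ 11.11 m/s ambulance free-flow).  No road network is
modelled: travel is straight-line at constant speed, optionally modulated
by a diurnal congestion multiplier.  This keeps every stage desk-scale and
dependency-free; absolute travel times are therefore optimistic relative
to a routed network, which matters for map-reading but not for the
relative comparisons the pipeline makes.

## Synthetic city and call stream

The generator defines the study conditions; its defaults are calibrated
once and not revisited.

* **Geography.** A 12 × 10 km bounding box with a four-component Gaussian
  mixture of population centres (dominant central cluster, weight 0.55).
  Events and the 624 candidate AED host establishments are both drawn from
  this mixture, so demand and candidates co-locate as they do in a real
  urban core.  Four ambulance bases sit near the cluster centres; the base
  count is a free parameter because base placement is configuration, not
  inference.
* **Call timing.** Call intensity over the day is log-linear in two
  harmonics, λ(h) = r·exp(Σₖ aₖ cos(2πkh/24 − φₖ)), with defaults
  (a₁ = 0.35, peak 11:00; a₂ = 0.45, peaks 05:00/17:00) chosen so the
  intensity peaks near 06:00 and 16:00 and bottoms out around midnight.
  Two harmonics are the minimum that can produce two peaks per day.
* **Response time.**  response = dispatch + travel, with
  dispatch ~ lognormal(median 446 s, log-sd 0.45) — the log-sd follows
  from the dispatch IQR (314–610 s) of the reference cohort — and
  travel = (distance to nearest base / free-flow speed) × m(h) × noise,
  where m(h) = 2.05·exp(0.22·cos(2π(h−11)/24)) peaks at 11:00 (congestion
  is deliberately a separate phenomenon from call frequency) and the noise
  is lognormal with log-sd 0.40.  The congestion base and noise were fixed
  by Monte Carlo so that, averaged over 20 seeds at 476 calls, the
  filtered cohort's median response is ≈ 690 s (target band 650–750 s) and
  the fraction exceeding 10 min is ≈ 0.62–0.66.  Per-seed fractions carry
  binomial noise of ~0.03 sd at n ≈ 260, so calibration targets are
  asserted on seed averages.
* **Clinical marginals.** Bystander CPR 51.92 / 43.90 / 4.18%
  (yes/no/unknown), shockable rhythm 31.01%, death 77%, male 58.54%,
  age ~ N(68, 14²) clipped to [1, 100].  Records are flagged incomplete
  completely at random with probability 1 − 287/476 ≈ 0.397; no
  missingness mechanism is modelled because none is identifiable from a
  descriptive table.
* **Reference cohort fixture.** A deterministic 287-record cohort whose
  categorical counts match the reference table exactly and whose
  continuous values are constructed so linear-interpolation quartiles hit
  the printed median/IQR values exactly (order statistics at positions
  72/73, 144 and 215/216 are pinned).  Shockable flags are aligned with
  response bins to reproduce the 2/37/50 cross-table.  One percent is
  irreproducible under a single rounding convention: 2/89 = 2.2472% rounds
  to 2.25, not 2.24; the package reports 2.25.

## Inclusion filter and descriptives

Retained: complete ∧ non-traumatic ∧ age ≥ 18 ∧ response ≤ 1200 s ("within
20 min" read inclusively).  Response bins are left-closed — [0, 300),
[300, 600), [600, 1200] s — because the three printed bin percents sum to
100, so the bins partition the cohort; the edge assignment itself is a
convention and is documented rather than inferred.  Quartiles use linear
interpolation between order statistics (the common statistical-software
default; the fixture depends on it).

## Isochrones

Raster classification of the demand grid rather than vector polygons: the
exceedance surface and the siting model are already cell-based, so
polygonisation would add geometry without adding anything testable.  The
ideal-condition field is distance/free-flow-speed only; a `realistic` flag
adds the median dispatch delay and day-average congestion multiplier.

## Spatial survival model

* **Censoring.** Response times above 300 s are right-censored at 300 s,
  per the 5-min early-defibrillation reference.  This discards information
  above the threshold by design (fidelity first); with a cohort where only
  ~2% of arrivals beat 300 s, the event times are few, so the spatial
  field and diurnal effect carry wide posteriors on realistic data.  The
  parameter-recovery studies therefore use a baseline rate giving ~50%
  censoring, where the model is identifiable at n = 400.
* **Baseline hazard.** Cubic B-spline on the log hazard with 5 equally
  spaced interior knots on (0, 300], clamped ends — a modest default,
  configurable.  Because the clamped basis sums to one, setting all
  ordinates to log λ yields an exactly constant baseline, which is how the
  exponential closed-form likelihood check achieves machine precision; the
  cumulative hazard uses 24-point Gauss–Legendre quadrature per event
  (exact for constants).
* **Spatial frailty.** Zero-mean Gaussian field on grid-cell centroids
  with covariance σ²·exp(−d/η); σ² is fixed at 1 (only the η prior is
  specified by the source analysis; sampling σ² is available but off by
  default to avoid weak identifiability with η under heavy censoring).
  The η prior is log-Gaussian with sd 0.5 centred at log √1000 — the
  geometric middle of the stated 1–1000 m range; the source description
  does not pin a unique log-mean, and this choice is flagged as an
  interpretation, not asserted as intent.
* **MCMC.** Metropolis-within-Gibbs: joint Gaussian random walks for β and
  ω, elliptical slice sampling for Y (tuning-free, always accepts), and a
  log-scale random walk for η whose ratio carries the GP prior of the
  current Y under the proposed range; a non-positive-definite proposal is
  rejected, not fatal.  Random-walk scales adapt toward 23% acceptance
  during burn-in only, preserving detailed balance afterwards.  Retention
  keeps every `thin`-th post-burn-in iteration: (nits − burn) // thin
  draws, i.e. 81 at the 50,000/10,000/490 headline settings and 300 at the
  2,000/500/5 desk-scale preset.
* **PEP.** Posterior mean of the survivor function at 300 s with
  day-average covariates (harmonics average to zero) and the cell's
  frailty: the probability that, at that location, the ambulance does not
  arrive within 5 min — not the probability that a posterior summary
  crosses a value.
* **Relative risk.** Per draw, risk(h) = exp(−H₀(300)·exp(x(h)ᵀβ)) is
  normalised by its geometric day-mean; the posterior median and central
  95% band are reported on a 0.25 h grid.  A standalone harmonic logistic
  regression on the exceedance indicator is provided as a frequentist
  cross-check of the curve's shape.

### Recovery studies (the simulation design)

Data are simulated from the model itself (constant baseline
λ = ln 2/300 s⁻¹, ~50% censoring), n = 400 events per replicate,
20 replicates.  β-recovery uses β = (0.5, 0, 0, 0) on a 6 × 6 grid with a
±0.4 two-district frailty; district ordering is read off the PEP surface.
Peak recovery injects a pure first-harmonic risk peak at 11:00 with
amplitude 0.6 (exceedance ratio ≈ 2.4 between peak and trough, of the
order seen in diurnal delay-risk curves).  At n = 400 the argmax of a
single replicate's posterior-median curve wobbles ±2 h because of the
nuisance second harmonic — a frequentist fit on the same data shows the
identical spread, so this is a property of the data size, not the sampler.
The peak is therefore assessed on seed-aggregated estimates (the mean
curve over 20 replicates and the circular median of per-replicate peaks),
which concentrate near 11:00.

## AED siting (MCLP)

* Cells are 500 m × 500 m squares (a literal 500 m² cell, ~22 m side, is
  inconsistent with a 500 m grid and with walking-radius coverage); cell
  membership is half-open, [x₀, x₀+s) × [y₀, y₀+s), so an event on a
  shared edge belongs to the upper/right cell.
* Coverage radius = pedestrian speed × cut-off = 2.778 m/s × 150 s
  ≈ 416.7 m from the demand centroid.
* The exact solver is the standard MCLP integer program via HiGHS
  (`scipy.optimize.milp`); on instances with ≤ 60 candidates the optimum
  is refined to the lexicographically smallest site-id selection by fixing
  sites one at a time (each fix is one MILP feasibility-of-optimum check);
  larger instances return the solver's deterministic optimum with
  redundant picks pruned.  Greedy breaks ties by lowest site id and stops
  when no site adds coverage.
* The objective weights cells by event count, but the headline coverage is
  the unweighted fraction of centroids covered; both are reported, since a
  weighted optimiser and a centroid-counting summary can legitimately
  coexist.
* AED "travel time" is the round trip (2 × one-way at walking speed):
  the bystander goes to the device and returns, which is also why the
  416.7 m radius corresponds to 300 s.  One-way is available by flag.
* The engineered 167-centroid geometry (27 paired cells served by midpoint
  candidates, 73 singles, 40 unreachable cells, 524 decoy candidates)
  makes 100 devices cover exactly 127 centroids (76%) under both solvers —
  a combinatorial reproduction of the headline coverage figure, labelled
  synthetic; it stands in for the real candidate roster, which is not
  derivable from a printed table.

## Wilcoxon signed-rank

Zero differences dropped; midranks for ties; exact null by convolution
over rank contributions (conditional on the tie pattern, midranks doubled
to keep integer support) for n ≤ 25; otherwise normal approximation with
tie-corrected variance and continuity correction.  Two-sided p by
doubling the smaller tail (capped at 1).  z is negative when the first
vector (AED times) tends below the second — the direction of interest.

## Pipeline

Stages communicate only via on-disk artifacts (CSV, GeoJSON, JSON); the
manifest records configuration, per-stage timings and SHA-256 hashes of
every artifact.  Artifact hashes are identical across runs with the same
config and seed.  GeoJSON is written as plain JSON with shapely
geometries; no CRS handling is needed because coordinates are already
planar metres.

## Problem sizes

Defaults are desk-scale by design: 476 calls, a 24 × 20 cell grid, 624
candidates, the 2,000/500/5 MCMC preset for anything iterative, and
n = 400 × 20 replicates for the recovery studies.  The 50,000/10,000/490
chain settings are available as `McmcConfig.full_scale()` for full-scale
runs.

## Known limitations

* Euclidean travel everywhere; no road or pedestrian network.
* Missingness is completely at random; real registries are not.
* σ² fixed at 1 and a single spatial range: no anisotropy, no
  space-time interaction in the frailty.
* With ~98% censoring at 300 s (the realistic regime), the exceedance
  surface is near-saturated and the diurnal curve's credible band covers
  1 across the day — the model faithfully reports that the data barely
  constrain it there.  Passing recovery tests at 50% censoring shows the
  machinery is correct, not that a 287-event registry pins these
  parameters tightly.
* The synthetic city reproduces marginal and coarse spatial structure; it
  does not emulate street-level clustering, address geocoding error, or
  the true candidate roster.
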