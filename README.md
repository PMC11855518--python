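# ohca-coverage

Ambulance response-time delay zones and optimal public AED placement for
out-of-hospital cardiac arrest (OHCA), as a tested, reusable Python
pipeline exercised end-to-end on a synthetic city.

## Who this is for

Emergency-services researchers and health geographers who want to analyse
where ambulances fail to reach cardiac arrests within the 5-minute
early-defibrillation window, and where to place automated external
defibrillators (AEDs) so bystanders can fetch one faster than the ambulance
arrives.  Real call registries are access-restricted, so the package ships
a calibrated synthetic-city generator: every stage runs, and is tested,
without any external data.

## What it computes

1. **Cohort descriptives** — inclusion filter (complete, non-traumatic,
   age ≥ 18, response ≤ 20 min) and a descriptive table: frequencies,
   median (IQR), and response-time bins 0–5 / 5–10 / >10 min.
2. **Isochrones** — straight-line travel-time field from ambulance bases,
   classified into ≤5 / ≤10 / ≤15 / >15 min service-area bands on a 500 m
   grid.
3. **Bayesian spatial survival** — response times right-censored at 300 s,
   proportional hazards
   `h(t | x, s) = h₀(t)·exp(xᵀβ + Y(s))`
   with a cubic B-spline log-baseline h₀, harmonic (sin/cos of call hour)
   covariates x, and a Gaussian spatial frailty Y with exponential-decay
   covariance (range η).  Priors: β ~ N(0, 100²), ω ~ N(0, 10²),
   log η ~ N(log √1000, 0.5²).  Metropolis-within-Gibbs MCMC (elliptical
   slice updates for Y) yields
   * the **posterior exceedance probability** per cell,
     PEP = E[S(300 s | Y(cell))] — the probability the ambulance does not
     arrive within 5 min at that location; and
   * the **diurnal relative risk** rr(h) of exceeding 300 s, normalised to
     geometric day-mean 1, with 95% credible bands.
4. **AED siting (MCLP)** — demand aggregated to 500 m cell centroids; a
   candidate covers a centroid within a 2.5-min walk at 10 km/h (416.7 m).
   The maximal covering location problem
   `max Σᵢ wᵢyᵢ  s.t.  yᵢ ≤ Σ_{j covers i} xⱼ,  Σⱼ xⱼ ≤ p`
   is solved exactly (HiGHS integer programming) and by the greedy
   heuristic with its (1 − 1/e) guarantee, plus coverage-vs-p curves.
5. **Paired comparison** — bystander AED round-trip times versus ambulance
   response times via the Wilcoxon signed-rank test (exact null
   enumeration for n ≤ 25, tie-corrected normal approximation beyond).

## Worked example

```sh
python examples/05_aed_vs_ambulance.py
```

```
AED round trip: mean 253 s, median 256 s
ambulance:      mean 701 s, median 691 s
Wilcoxon signed-rank: z = -13.259, p = 4.01e-40 (normal-approx)
```

On the default synthetic city (476 calls, 624 candidate establishments,
100 AEDs placed greedily), a bystander's round trip to the nearest AED
averages ~4 minutes — roughly a third of the ambulance's ~11½-minute
response — and the strongly negative z says this holds pairwise across
essentially every simulated arrest.  `examples/` holds one script per
capability (cohort table, isochrones, delay zones, siting curve,
comparison), each printing what it computes and what the numbers mean.

The whole pipeline, with a run manifest, is also available as a CLI:

```sh
ohca-coverage run --config run.cfg     # run.cfg: seed=1, preset=test, ...
```

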