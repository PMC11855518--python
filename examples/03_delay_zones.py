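"""Bayesian spatial survival analysis: where does the ambulance exceed 5 min?

Fits the proportional-hazards model with a B-spline baseline, harmonic
time-of-day covariates and a Gaussian spatial frailty to a synthetic call
stream (times right-censored at 300 s), then prints the distribution of the
per-cell posterior exceedance probability (PEP) and the diurnal
relative-risk curve's extremes.  Uses the desk-scale MCMC preset.
"""

import numpy as np

from ohca_coverage import (
    McmcConfig,
    aggregate_demand,
    build_dataset,
    compute_pep,
    filter_events,
    generate_city,
    relative_risk_curve,
    run_mcmc,
    simulate_events,
)

city = generate_city(seed=1)
cohort = filter_events(simulate_events(city, 476, seed=1))
grid = aggregate_demand(cohort, 500.0, bbox=city.bbox)

data = build_dataset(cohort, grid, prefiltered=True)
print(f"events: {data.n} ({data.censored.mean():.0%} censored at 300 s)")

samples = run_mcmc(data, McmcConfig.test_scale(seed=1))
print(f"retained {samples.n_samples} posterior draws; "
      f"acceptance rates: { {k: round(v, 2) for k, v in samples.acceptance.items()} }")

pep = compute_pep(samples, grid)
print(f"PEP: min {pep.min():.2f}, median {np.median(pep):.2f}, max {pep.max():.2f}")
print(f"cells with PEP >= 0.8 (delay zones): {(pep >= 0.8).sum()} of {len(pep)}")

rr = relative_risk_curve(samples)
print(f"relative risk of exceeding 300 s: min {rr.median.min():.2f} "
      f"at {rr.hours[rr.median.argmin()]:.2f} h, "
      f"max {rr.median.max():.2f} at {rr.peak_hour:.2f} h")

# A PEP of 0.8-1 in a cell means that in more than 80% of occurrences there
# the ambulance does not arrive within 5 min.  With ~90% of response times
# censored at 300 s, most of the city is a delay zone and the diurnal signal
# carries wide credible bands.
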