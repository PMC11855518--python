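"""Simulation-based checks of the survival model: parameter recovery,
diurnal-peak recovery, and slow/fast-district ordering of the exceedance
surface.  Shared between the test suite and the acceptance script.
"""

from __future__ import annotations

import math

import numpy as np

from .mclp import DemandGrid, GridCell
from .spatial_survival import (
    McmcConfig,
    compute_pep,
    harmonic_covariates,
    relative_risk_curve,
    run_mcmc,
    simulate_dataset,
)


def uniform_grid(nx: int, ny: int, cell_size_m: float = 500.0) -> DemandGrid:
    """An nx-by-ny grid of empty cells anchored at the origin."""
    cells = []
    for j in range(ny):
        for i in range(nx):
            cells.append(
                GridCell(
                    cell_id=f"{i}_{j}",
                    ix=i,
                    iy=j,
                    centroid=((i + 0.5) * cell_size_m, (j + 0.5) * cell_size_m),
                    event_count=0,
                    mean_response_s=float("nan"),
                )
            )
    return DemandGrid(cell_size_m=cell_size_m, origin=(0.0, 0.0), cells=tuple(cells))


def two_district_frailty(grid: DemandGrid, magnitude: float = 0.4) -> np.ndarray:
    """Frailty field: left half slow (negative Y), right half fast."""
    xs = sorted({c.ix for c in grid.cells})
    mid = xs[len(xs) // 2]
    return np.array(
        [-magnitude if c.ix < mid else magnitude for c in grid.cells]
    )


#: Baseline arrival rate giving ~50% censoring at the 300 s threshold.
HALF_CENSOR_RATE = math.log(2.0) / 300.0


def beta_recovery_replicate(
    seed: int,
    n: int = 400,
    beta_true: tuple = (0.5, 0.0, 0.0, 0.0),
    frailty_magnitude: float = 0.4,
    cfg: McmcConfig | None = None,
) -> dict:
    """Fit the full spatial model to data simulated from known parameters.

    Returns the posterior mean and 90% credible interval of beta_1, and the
    mean exceedance probability of the slow and fast districts.
    """
    grid = uniform_grid(6, 6)
    Y_true = two_district_frailty(grid, frailty_magnitude)
    data = simulate_dataset(
        grid, n, np.asarray(beta_true), HALF_CENSOR_RATE, Y_true, seed=seed
    )
    if cfg is None:
        cfg = McmcConfig(nits=1500, burn=400, thin=4, seed=seed + 10_000)
    samples = run_mcmc(data, cfg)
    b1 = samples.beta[:, 0]
    pep = compute_pep(samples, grid)
    slow = Y_true < 0
    return {
        "beta1_true": float(beta_true[0]),
        "beta1_mean": float(b1.mean()),
        "beta1_ci90": (float(np.percentile(b1, 5)), float(np.percentile(b1, 95))),
        "pep_slow_mean": float(pep[slow].mean()),
        "pep_fast_mean": float(pep[~slow].mean()),
    }


def diurnal_peak_beta(peak_hour: float, amplitude: float = 0.6,
                      K: int = 2) -> np.ndarray:
    """Harmonic coefficients whose exceedance risk peaks at ``peak_hour``.

    The hazard multiplier exp(x' beta) = exp(-A cos(2 pi (h - peak)/24)) is
    minimal at the peak hour, so the probability of exceeding the threshold
    is maximal there.
    """
    phi = 2.0 * np.pi * peak_hour / 24.0
    beta = np.zeros(2 * K)
    beta[0] = -amplitude * np.sin(phi)
    beta[1] = -amplitude * np.cos(phi)
    return beta


def peak_recovery_replicate(
    seed: int,
    peak_hour: float = 11.0,
    n: int = 400,
    cfg: McmcConfig | None = None,
) -> float:
    """Recovered posterior-median relative-risk peak hour (circular grid)."""
    grid = uniform_grid(2, 2)
    beta_true = diurnal_peak_beta(peak_hour)
    data = simulate_dataset(
        grid, n, beta_true, HALF_CENSOR_RATE, np.zeros(len(grid.cells)), seed=seed
    )
    if cfg is None:
        cfg = McmcConfig(nits=1500, burn=400, thin=4, seed=seed + 20_000)
    samples = run_mcmc(data, cfg, include_spatial=False)
    return relative_risk_curve(samples).peak_hour


def circular_hour_difference(h1: float, h2: float) -> float:
    """Absolute difference between hours of day on the 24-h circle."""
    d = abs(h1 - h2) % 24.0
    return min(d, 24.0 - d)
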