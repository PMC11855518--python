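"""Survival dataset construction, likelihood reductions, MCMC mechanics,
exceedance surface and diurnal relative risk."""

import math

import numpy as np
import pytest

from ohca_coverage.spatial_survival import (
    McmcConfig,
    PosteriorSamples,
    SpatialSurvivalModel,
    SurvivalDataset,
    build_dataset,
    compute_pep,
    harmonic_covariates,
    log_likelihood,
    logistic_exceedance_rr,
    relative_risk_curve,
    run_mcmc,
    simulate_dataset,
    spline_knots,
)
from ohca_coverage.mclp import aggregate_demand
from ohca_coverage.validation import (
    HALF_CENSOR_RATE,
    circular_hour_difference,
    diurnal_peak_beta,
    uniform_grid,
)
from tests.helpers import make_event


def _const_model(lam, grid, beta=None, Y=None, K=2):
    m = len(grid.cells)
    return SpatialSurvivalModel(
        knots=spline_knots(),
        omega=np.full(9, math.log(lam)),
        beta=np.zeros(2 * K) if beta is None else np.asarray(beta, float),
        Y=np.zeros(m) if Y is None else np.asarray(Y, float),
        eta=100.0,
    )


def _dataset(times, observed, grid, cell_idx=None, hours=None, K=2):
    times = np.asarray(times, dtype=float)
    n = len(times)
    hours = np.zeros(n) if hours is None else np.asarray(hours, float)
    return SurvivalDataset(
        time_s=times,
        observed=np.asarray(observed, bool),
        X=harmonic_covariates(hours, K),
        cell_idx=np.zeros(n, dtype=int) if cell_idx is None else np.asarray(cell_idx),
        grid=grid,
        K=K,
    )


class TestBuildDataset:
    def test_censoring_rule(self):
        grid = uniform_grid(4, 4)
        evs = [
            make_event(event_id="A", location=(100.0, 100.0), response_time_s=698.0),
            make_event(event_id="B", location=(600.0, 100.0),
                       response_time_s=290.0, dispatch_time_s=100.0),
        ]
        data = build_dataset(evs, grid)
        assert data.time_s[0] == 300.0 and data.censored[0]
        assert data.time_s[1] == 290.0 and data.observed[1]

    def test_midnight_covariates(self):
        X = harmonic_covariates(0.0, K=2)
        np.testing.assert_allclose(X, [[0.0, 1.0, 0.0, 1.0]], atol=1e-12)

    def test_invalid_K(self):
        grid = uniform_grid(2, 2)
        with pytest.raises(ValueError):
            build_dataset([make_event(location=(100.0, 100.0))], grid, K=0)

    def test_event_outside_grid(self):
        grid = uniform_grid(2, 2)
        with pytest.raises(ValueError, match="outside"):
            build_dataset([make_event(location=(5000.0, 5000.0))], grid)

    def test_applies_inclusion_filter(self):
        grid = uniform_grid(4, 4)
        evs = [make_event(event_id="ok", location=(100.0, 100.0)),
               make_event(event_id="minor", location=(100.0, 100.0), age=10.0)]
        data = build_dataset(evs, grid)
        assert data.n == 1


class TestLikelihood:
    @pytest.mark.parametrize("lam,t", [(0.01, 100.0), (0.005, 250.0)])
    def test_exponential_closed_form_uncensored(self, lam, t):
        grid = uniform_grid(2, 2)
        data = _dataset([t], [True], grid)
        ll = log_likelihood(_const_model(lam, grid), data)
        assert ll == pytest.approx(math.log(lam) - lam * t, abs=1e-12)

    def test_all_censored_closed_form(self):
        grid = uniform_grid(2, 2)
        lam, n = 0.01, 5
        data = _dataset([300.0] * n, [False] * n, grid)
        ll = log_likelihood(_const_model(lam, grid), data)
        assert ll == pytest.approx(-lam * 300.0 * n, abs=1e-10)

    def test_unused_frailty_does_not_change_likelihood(self):
        grid = uniform_grid(2, 2)
        data = _dataset([100.0], [True], grid, cell_idx=[0])
        base = log_likelihood(_const_model(0.01, grid), data)
        Y = np.array([0.0, 0.0, 0.0, 5.0])  # cell 3 has no events
        shifted = log_likelihood(_const_model(0.01, grid, Y=Y), data)
        assert shifted == base

    def test_nonfinite_hazard_raises_with_index(self):
        grid = uniform_grid(2, 2)
        data = _dataset([100.0], [True], grid)
        model = _const_model(0.01, grid, Y=[np.inf, 0, 0, 0])
        with pytest.raises(FloatingPointError, match="event index 0"):
            log_likelihood(model, data)

    def test_dimension_mismatch(self):
        grid = uniform_grid(2, 2)
        data = _dataset([100.0], [True], grid, K=2)
        with pytest.raises(ValueError):
            log_likelihood(_const_model(0.01, grid, K=3), data)


class TestMcmcConfig:
    def test_full_scale_retains_81(self):
        assert McmcConfig.full_scale().n_retained == 81

    def test_test_scale_retains_300(self):
        assert McmcConfig.test_scale().n_retained == 300

    @pytest.mark.parametrize("kw", [
        {"nits": 100, "burn": 100}, {"nits": 10, "burn": 20}, {"thin": 0}])
    def test_invalid_configs(self, kw):
        base = dict(nits=1000, burn=100, thin=5)
        base.update(kw)
        with pytest.raises(ValueError):
            McmcConfig(**base)


@pytest.fixture(scope="module")
def small_fit():
    grid = uniform_grid(3, 3)
    data = simulate_dataset(grid, 200, np.array([0.3, 0.0, 0.0, 0.0]),
                            HALF_CENSOR_RATE, np.zeros(9), seed=11)
    cfg = McmcConfig(nits=800, burn=200, thin=3, seed=11)
    return grid, data, cfg, run_mcmc(data, cfg)


class TestRunMcmc:
    def test_retention_count(self, small_fit):
        _, _, cfg, samples = small_fit
        assert samples.n_samples == cfg.n_retained == 200

    def test_deterministic_under_seed(self, small_fit):
        grid, data, cfg, samples = small_fit
        again = run_mcmc(data, cfg)
        np.testing.assert_array_equal(samples.beta, again.beta)
        np.testing.assert_array_equal(samples.Y, again.Y)
        np.testing.assert_array_equal(samples.eta, again.eta)

    def test_requires_enough_events(self):
        grid = uniform_grid(2, 2)
        data = simulate_dataset(grid, 10, np.zeros(4), HALF_CENSOR_RATE,
                                np.zeros(4), seed=1)
        with pytest.raises(ValueError):
            run_mcmc(data, McmcConfig.test_scale())

    def test_eta_within_prior_support(self, small_fit):
        _, _, _, samples = small_fit
        assert (samples.eta > 0).all()


class TestPep:
    def _samples(self, grid, H0, Y_rows):
        Y = np.asarray(Y_rows, dtype=float)
        S = Y.shape[0]
        return PosteriorSamples(
            beta=np.zeros((S, 4)), omega=np.zeros((S, 9)), Y=Y,
            eta=np.full(S, 100.0), H0_threshold=np.full(S, H0),
            knots=spline_knots(), grid=grid, K=2, threshold_s=300.0,
        )

    def test_all_survivor_one(self):
        grid = uniform_grid(2, 2)
        samples = self._samples(grid, H0=0.0, Y_rows=np.zeros((3, 4)))
        np.testing.assert_allclose(compute_pep(samples, grid), 1.0)

    def test_constant_half_life_hazard_gives_half(self):
        grid = uniform_grid(2, 2)
        samples = self._samples(grid, H0=math.log(2.0), Y_rows=np.zeros((5, 4)))
        np.testing.assert_allclose(compute_pep(samples, grid), 0.5)

    def test_monotone_in_frailty_shift(self, small_fit):
        grid, _, _, samples = small_fit
        pep = compute_pep(samples, grid)
        shifted = PosteriorSamples(
            beta=samples.beta, omega=samples.omega, Y=samples.Y + 0.5,
            eta=samples.eta, H0_threshold=samples.H0_threshold,
            knots=samples.knots, grid=grid, K=2, threshold_s=300.0)
        # larger frailty -> higher arrival hazard -> lower exceedance
        assert (compute_pep(shifted, grid) <= pep + 1e-12).all()

    def test_grid_mismatch_rejected(self, small_fit):
        grid, _, _, samples = small_fit
        with pytest.raises(ValueError):
            compute_pep(samples, uniform_grid(4, 4))

    def test_relabelling_invariance(self):
        grid = uniform_grid(2, 2)
        rng = np.random.default_rng(0)
        Y = rng.normal(size=(6, 4))
        samples = self._samples(grid, H0=0.5, Y_rows=Y)
        pep = compute_pep(samples, grid)
        perm = np.array([2, 0, 3, 1])
        grid_p = uniform_grid(2, 2)
        grid_p = type(grid_p)(
            cell_size_m=grid_p.cell_size_m, origin=grid_p.origin,
            cells=tuple(grid_p.cells[i] for i in perm))
        samples_p = self._samples(grid_p, H0=0.5, Y_rows=Y[:, perm])
        np.testing.assert_allclose(compute_pep(samples_p, grid_p), pep[perm])


class TestRelativeRisk:
    def test_zero_beta_flat_curve(self):
        grid = uniform_grid(2, 2)
        S = 7
        samples = PosteriorSamples(
            beta=np.zeros((S, 4)), omega=np.zeros((S, 9)),
            Y=np.zeros((S, 4)), eta=np.full(S, 100.0),
            H0_threshold=np.full(S, 0.7), knots=spline_knots(),
            grid=grid, K=2, threshold_s=300.0)
        rr = relative_risk_curve(samples)
        np.testing.assert_allclose(rr.median, 1.0, atol=1e-12)
        np.testing.assert_allclose(rr.hi95 - rr.lo95, 0.0, atol=1e-12)

    def test_geometric_day_mean_is_one(self, small_fit):
        _, _, _, samples = small_fit
        rr = relative_risk_curve(samples)
        log_gm = np.mean(np.log(rr.median))
        assert math.exp(log_gm) == pytest.approx(1.0, abs=0.02)

    def test_logistic_cross_check_agrees_with_bayesian_curve(self):
        grid = uniform_grid(2, 2)
        data = simulate_dataset(grid, 800, diurnal_peak_beta(11.0),
                                HALF_CENSOR_RATE, np.zeros(4), seed=1)
        hours, rr_log = logistic_exceedance_rr(data)
        samples = run_mcmc(data, McmcConfig(nits=1200, burn=300, thin=3, seed=1),
                           include_spatial=False)
        rr_bayes = relative_risk_curve(samples).median
        assert np.corrcoef(rr_log, rr_bayes)[0, 1] > 0.9
        peak_log = hours[int(np.argmax(rr_log))]
        assert circular_hour_difference(peak_log, 11.0) <= 3.0


def test_dataset_from_events_roundtrip(city, events):
    """End-to-end: cohort events -> grid -> dataset has consistent censoring."""
    from ohca_coverage.descriptives import filter_events

    cohort = filter_events(events)
    grid = aggregate_demand(cohort, 500.0, bbox=city.bbox)
    data = build_dataset(cohort, grid, prefiltered=True)
    resp = np.array([e.response_time_s for e in cohort])
    np.testing.assert_array_equal(data.censored, resp > 300.0)
    assert data.time_s.max() <= 300.0
    assert (data.time_s > 0).all()
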