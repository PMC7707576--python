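"""Posterior sampling, HPDI, WAIC, weights and Bayesian R-squared."""

import numpy as np
import pandas as pd
import pytest

from lexirate import (
    DataError,
    ModelSpec,
    PosteriorSummary,
    PREDICTORS,
    SamplerConfig,
    SimTruth,
    bayes_r2,
    compare_models,
    default_model_specs,
    fit_poisson_glm,
    hpdi,
    model_weights,
    simulate_study,
    waic,
)


def minimal_summary(log_lik, X=None, draws=None, y=None):
    """Bare PosteriorSummary for direct WAIC / R2 arithmetic checks."""
    S = log_lik.shape[0]
    d = 1 if draws is None else draws.shape[1]
    chain = (np.zeros((1, S, d)) if draws is None else draws.reshape(1, S, d))
    n = log_lik.shape[1]
    return PosteriorSummary(
        spec=ModelSpec("gains"),
        param_names=[f"p{i}" for i in range(d)],
        chain_draws=chain,
        log_lik=log_lik,
        X=np.ones((n, 1)) if X is None else X,
        y=np.zeros(n) if y is None else y,
        offset=np.zeros(n),
    )


# -- HPDI --------------------------------------------------------------------

def test_hpdi_point_mass():
    assert hpdi(np.full(20, 2.0), 0.9) == (2.0, 2.0)


def test_hpdi_uniform_grid_tie_breaks_low():
    lo, hi = hpdi(np.arange(1, 101, dtype=float), 0.9)
    assert (lo, hi) == (1.0, 90.0)


def test_hpdi_narrower_than_equal_tailed_on_skewed_sample():
    rng = np.random.default_rng(3)
    draws = rng.lognormal(0.0, 1.0, 5000)
    lo, hi = hpdi(draws, 0.9)
    q_lo, q_hi = np.quantile(draws, [0.05, 0.95])
    assert hi - lo < q_hi - q_lo
    assert lo < np.median(draws) < hi


def test_hpdi_input_validation():
    with pytest.raises(DataError):
        hpdi(np.arange(100.0), 1.5)
    with pytest.raises(DataError):
        hpdi(np.arange(5.0), 0.9)


# -- WAIC and weights --------------------------------------------------------

def test_waic_zero_variance_draws():
    ll = np.tile([-1.2, -0.7, -2.0], (5, 1))  # identical across draws
    res = waic(minimal_summary(ll))
    assert res["p_waic"] == pytest.approx(0.0)
    assert res["waic"] == pytest.approx(-2 * ll[0].sum())


def test_waic_additive_over_duplicated_observations():
    rng = np.random.default_rng(0)
    ll = -rng.random((40, 6))
    single, doubled = waic(minimal_summary(ll)), waic(minimal_summary(np.hstack([ll, ll])))
    assert doubled["lppd"] == pytest.approx(2 * single["lppd"])
    assert doubled["p_waic"] == pytest.approx(2 * single["p_waic"])


def test_waic_small_fixed_case_matches_plain_formula():
    ll = np.array([
        [-1.0, -2.0, -0.5],
        [-1.5, -1.8, -0.7],
        [-0.8, -2.2, -0.6],
        [-1.2, -1.9, -0.4],
    ])
    lppd = np.log(np.mean(np.exp(ll), axis=0)).sum()  # naive, no log-sum-exp
    p = np.var(ll, axis=0, ddof=1).sum()
    res = waic(minimal_summary(ll))
    assert res["waic"] == pytest.approx(-2 * (lppd - p))


def test_waic_agrees_with_arviz():
    import warnings
    import arviz as az

    rng = np.random.default_rng(5)
    ll = -rng.gamma(2.0, 1.0, (3, 200, 8))
    ps = minimal_summary(ll.reshape(600, 8))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        idata = az.from_dict(
            posterior={"alpha": np.zeros((3, 200))}, log_likelihood={"y": ll}
        )
        ref = az.waic(idata, scale="deviance")
    # arviz uses the ddof=0 variance in p_waic; we use the S-1 convention,
    # so agreement is to O(1/S), not exact
    assert waic(ps)["waic"] == pytest.approx(float(ref.elpd_waic), rel=5e-3)


def test_waic_needs_two_draws():
    with pytest.raises(DataError):
        waic(minimal_summary(np.zeros((1, 3))))


def test_model_weights_basics():
    assert model_weights([123.4]) == pytest.approx([1.0])
    assert model_weights([10.0, 10.0]) == pytest.approx([0.5, 0.5])
    w = model_weights([100.0, 104.0, 130.0])
    assert w.sum() == pytest.approx(1.0)
    assert np.argmax(w) == 0
    # invariant to adding a constant to every WAIC
    assert model_weights([0.0, 4.0, 30.0]) == pytest.approx(w)


def test_large_waic_gap_gives_weight_one():
    w = model_weights([50.0, 75.0, 90.0])
    assert w[0] == pytest.approx(1.0, abs=5e-6)


# -- Bayesian R2 -------------------------------------------------------------

def test_bayes_r2_null_model_is_zero():
    draws = np.full((30, 1), 1.7)
    ps = minimal_summary(np.zeros((30, 4)), X=np.ones((4, 1)), draws=draws)
    assert bayes_r2(ps) == pytest.approx(np.zeros(30))


def test_bayes_r2_two_point_arithmetic():
    X = np.array([[1.0, 0.0], [1.0, 1.0]])
    draws = np.array([[0.0, np.log(100.0)]])  # mu = (1, 100)
    ps = minimal_summary(np.zeros((1, 2)), X=X, draws=draws)
    assert bayes_r2(ps)[0] == pytest.approx(2450.25 / (2450.25 + 50.5))


def test_bayes_r2_bounded(fast_sampler):
    study = simulate_study(SimTruth(n_pairs=10, n_concepts=60, seed=2))
    ps = fit_poisson_glm(study.design, ModelSpec("gains", PREDICTORS), fast_sampler)
    r2 = bayes_r2(ps)
    assert ((r2 >= 0) & (r2 < 1)).all()


# -- fitting -----------------------------------------------------------------

@pytest.fixture(scope="module")
def default_fit():
    """One full-config fit: intercept-only on a constant response."""
    design = pd.DataFrame({"gains": [5] * 30})
    cfg = SamplerConfig(seed=42)
    return fit_poisson_glm(design, ModelSpec("gains"), cfg)


def test_intercept_posterior_matches_quadrature(default_fit):
    """Independent grid posterior for alpha under a constant response."""
    y = np.full(30, 5.0)
    grid = np.linspace(0.5, 2.5, 40001)
    log_post = y.sum() * grid - len(y) * np.exp(grid) - 0.5 * (grid / 10.0) ** 2
    dens = np.exp(log_post - log_post.max())
    cdf = np.cumsum(dens) / dens.sum()
    grid_median = grid[np.searchsorted(cdf, 0.5)]
    fitted_median = float(np.median(default_fit.draws[:, 0]))
    assert fitted_median == pytest.approx(grid_median, abs=0.02)
    assert fitted_median == pytest.approx(np.log(5.0), abs=0.1)


def test_default_config_pools_24000_draws(default_fit):
    assert default_fit.chain_draws.shape == (3, 8000, 1)
    assert default_fit.draws.shape[0] == 24_000


def test_healthy_fit_diagnostics(default_fit):
    assert default_fit.converged
    assert (default_fit.rhat < 1.01).all()
    assert (default_fit.ess >= 400).all()
    lo, hi = hpdi(default_fit.draws[:, 0], 0.9)
    assert lo <= np.median(default_fit.draws[:, 0]) <= hi


def test_seed_reproducible(fast_sampler):
    design = pd.DataFrame({"gains": [3, 7, 4, 6, 5, 5, 2, 8]})
    a = fit_poisson_glm(design, ModelSpec("gains"), fast_sampler)
    b = fit_poisson_glm(design, ModelSpec("gains"), fast_sampler)
    assert np.array_equal(a.chain_draws, b.chain_draws)


def test_prior_recovered_with_zero_observations():
    design = pd.DataFrame({"gains": pd.Series([], dtype=int),
                           "Isolation": pd.Series([], dtype=float)})
    ps = fit_poisson_glm(design, ModelSpec("gains", ("Isolation",)), SamplerConfig(seed=9))
    beta = ps.draws[:, 1]
    assert np.mean(beta) == pytest.approx(0.0, abs=0.15)
    assert np.std(beta) == pytest.approx(2.0, abs=0.15)
    alpha = ps.draws[:, 0]
    assert np.std(alpha) == pytest.approx(10.0, abs=0.8)


def test_emcee_backend_agrees_with_metropolis():
    study = simulate_study(SimTruth(n_pairs=12, n_concepts=80, seed=6))
    spec = ModelSpec("gains", ("logPopulation", "Isolation"))
    met = fit_poisson_glm(study.design, spec, SamplerConfig(seed=1))
    ens = fit_poisson_glm(study.design, spec, SamplerConfig(seed=1, backend="emcee"))
    assert np.allclose(
        np.median(met.draws, axis=0), np.median(ens.draws, axis=0), atol=0.05
    )


def test_fit_input_validation(fast_sampler):
    base = pd.DataFrame({"gains": [1, 2, 3, 4], "Isolation": [0.1, -0.2, 0.3, 0.4]})
    neg = base.assign(gains=[-1, 2, 3, 4])
    with pytest.raises(DataError, match="non-negative"):
        fit_poisson_glm(neg, ModelSpec("gains"), fast_sampler)
    frac = base.assign(gains=[1.5, 2, 3, 4])
    with pytest.raises(DataError, match="integer"):
        fit_poisson_glm(frac, ModelSpec("gains"), fast_sampler)
    const = base.assign(Isolation=1.0)
    with pytest.raises(DataError, match="Isolation"):
        fit_poisson_glm(const, ModelSpec("gains", ("Isolation",)), fast_sampler)
    with pytest.raises(DataError, match="backend"):
        fit_poisson_glm(base, ModelSpec("gains"),
                        SamplerConfig(seed=0, backend="nuts"))
    with pytest.raises(DataError, match="warmup"):
        SamplerConfig(iterations=100, warmup=100)


def test_offset_shifts_intercept(fast_sampler):
    design = pd.DataFrame({"gains": [10] * 20, "exposure": np.log(2.0)})
    plain = fit_poisson_glm(design, ModelSpec("gains"), fast_sampler)
    offset = fit_poisson_glm(design, ModelSpec("gains", offset="exposure"), fast_sampler)
    shift = np.median(plain.draws[:, 0]) - np.median(offset.draws[:, 0])
    assert shift == pytest.approx(np.log(2.0), abs=0.1)


# -- model comparison --------------------------------------------------------

def test_default_model_set_is_ten_models():
    specs = default_model_specs("turnover")
    assert len(specs) == 10
    names = [s.name for s in specs]
    assert "null" in names and "full" in names
    assert sum(n.startswith("only_") for n in names) == 5


def test_compare_models_weights_sum_to_one(fast_sampler):
    study = simulate_study(SimTruth(n_pairs=10, n_concepts=60, seed=8))
    specs = [
        ModelSpec("gains", (), name="null"),
        ModelSpec("gains", ("Isolation",), name="iso"),
        ModelSpec("gains", PREDICTORS, name="full"),
    ]
    comp = compare_models(study.design, specs, fast_sampler)
    assert comp.table["weight"].sum() == pytest.approx(1.0, abs=1e-9)
    assert comp.table["delta_waic"].min() == pytest.approx(0.0)
    assert set(comp.fits) == {"null", "iso", "full"}


def test_compare_models_requires_shared_response(fast_sampler):
    study = simulate_study(SimTruth(n_pairs=6, n_concepts=40, seed=8))
    specs = [ModelSpec("gains"), ModelSpec("losses")]
    with pytest.raises(DataError, match="response"):
        compare_models(study.design, specs, fast_sampler)
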