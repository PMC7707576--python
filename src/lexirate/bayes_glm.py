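"""Bayesian Poisson log-linear models with WAIC comparison.

The model for a response count y_i (word gains, losses or turnover per
sister pair) with standardised predictors x_i is

    y_i ~ Poisson(mu_i),   log(mu_i) = alpha + beta . x_i
    alpha ~ Normal(0, 10),  beta_k ~ Normal(0, 2)

i.e. weakly regularising priors on the log-rate scale.  Posteriors are
drawn with an adaptive random-walk Metropolis sampler (default backend)
whose proposal covariance comes from a Laplace approximation at the
posterior mode, run as several independent chains; an `emcee` ensemble
backend is available behind the same contract for cross-checking.

Summaries follow common practice for this kind of analysis: posterior
medians, highest-posterior-density intervals (the narrowest interval
holding the stated mass), split-Rhat and effective sample sizes, WAIC
with Akaike-style model weights, and a Bayesian R-squared in which the
Poisson residual variance is the model-implied mean.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .errors import ConvergenceError, DataError
from .predictors import PREDICTORS

logger = logging.getLogger(__name__)

RESPONSES = ("gains", "losses", "turnover")


# --------------------------------------------------------------------------
# specifications
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """One Poisson regression to fit."""

    response: str
    predictors: tuple[str, ...] = ()
    prior_alpha: tuple[float, float] = (0.0, 10.0)  # (mean, sd)
    prior_beta: tuple[float, float] = (0.0, 2.0)
    offset: str | None = None  # log-exposure column, off by default
    name: str = ""

    def __post_init__(self) -> None:
        if self.response not in RESPONSES:
            raise DataError(f"unknown response {self.response!r}")
        if not self.name:
            object.__setattr__(self, "name", "+".join(self.predictors) or "null")


@dataclass(frozen=True)
class SamplerConfig:
    """MCMC settings; defaults give 3 x (10000 - 2000) = 24000 draws."""

    chains: int = 3
    iterations: int = 10_000
    warmup: int = 2_000
    seed: int = 0
    rhat_threshold: float = 1.01
    min_ess: float = 400.0
    backend: str = "rw_metropolis"
    target_accept: float = 0.30

    def __post_init__(self) -> None:
        if self.warmup >= self.iterations:
            raise DataError("warmup must be smaller than iterations")


def default_model_specs(
    response: str,
    combos: Sequence[Sequence[str]] | None = None,
) -> list[ModelSpec]:
    """The 10-model comparison set for one response.

    Null, full, the five single-predictor models, and three additive
    combinations.  The default combinations are demography+geography,
    the three conflict scales together, and demography+conflict.
    """
    conflict = ("ConflictWithinCommunities", "ConflictWithinCultures", "ConflictBetweenCultures")
    if combos is None:
        combos = [
            ("logPopulation", "Isolation"),
            conflict,
            ("logPopulation",) + conflict,
        ]
    specs = [ModelSpec(response, (), name="null"), ModelSpec(response, PREDICTORS, name="full")]
    specs += [ModelSpec(response, (p,), name=f"only_{p}") for p in PREDICTORS]
    specs += [ModelSpec(response, tuple(c)) for c in combos]
    return specs


# --------------------------------------------------------------------------
# posterior container
# --------------------------------------------------------------------------

@dataclass
class PosteriorSummary:
    """Pooled posterior draws plus diagnostics for one fitted model."""

    spec: ModelSpec
    param_names: list[str]
    chain_draws: np.ndarray  # (chains, draws_per_chain, n_params)
    log_lik: np.ndarray      # (pooled draws, n_observations)
    X: np.ndarray            # (n_observations, n_params) incl. intercept column
    y: np.ndarray
    offset: np.ndarray
    rhat: pd.Series = field(default_factory=pd.Series)
    ess: pd.Series = field(default_factory=pd.Series)
    warnings: list[str] = field(default_factory=list)
    converged: bool = True

    @property
    def draws(self) -> np.ndarray:
        """Pooled post-warmup draws, (chains x draws_per_chain, n_params)."""
        c, s, d = self.chain_draws.shape
        return self.chain_draws.reshape(c * s, d)

    def summary(self, mass: float = 0.90) -> pd.DataFrame:
        pooled = self.draws
        rows = []
        for i, name in enumerate(self.param_names):
            lo, hi = hpdi(pooled[:, i], mass)
            rows.append(
                {
                    "parameter": name,
                    "median": float(np.median(pooled[:, i])),
                    "sd": float(np.std(pooled[:, i], ddof=1)),
                    f"hpdi_{mass:.0%}_lower": lo,
                    f"hpdi_{mass:.0%}_upper": hi,
                    "rhat": float(self.rhat.get(name, np.nan)),
                    "ess": float(self.ess.get(name, np.nan)),
                }
            )
        return pd.DataFrame(rows).set_index("parameter")


# --------------------------------------------------------------------------
# log posterior and Laplace mode
# --------------------------------------------------------------------------

def _make_log_post(
    X: np.ndarray, y: np.ndarray, offset: np.ndarray, prior_sd: np.ndarray
) -> Callable[[np.ndarray], np.ndarray]:
    """Vectorised unnormalised log posterior; theta may be (d,) or (m, d)."""

    def log_post(theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        eta = theta @ X.T + offset  # (m, n)
        with np.errstate(over="ignore"):
            lam = np.exp(eta)
        loglik = np.sum(y * eta - lam, axis=1)
        logprior = -0.5 * np.sum((theta / prior_sd) ** 2, axis=1)
        out = loglik + logprior
        return np.where(np.isfinite(out), out, -np.inf)

    return log_post


def _laplace_mode(
    X: np.ndarray, y: np.ndarray, offset: np.ndarray, prior_sd: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mode and covariance by damped Newton iteration."""
    n, d = X.shape
    prec = np.diag(1.0 / prior_sd**2)
    theta = np.zeros(d)
    if n:
        theta[0] = np.log(y.mean() + 0.5) - offset.mean()
    lp = _make_log_post(X, y, offset, prior_sd)
    current = lp(theta)[0]
    for _ in range(100):
        eta = X @ theta + offset
        mu = np.exp(np.clip(eta, -30, 30))
        grad = X.T @ (y - mu) - theta / prior_sd**2
        H = X.T @ (X * mu[:, None]) + prec
        step = np.linalg.solve(H, grad)
        t = 1.0
        while t > 1e-6:
            cand = theta + t * step
            val = lp(cand)[0]
            if val >= current:
                theta, current = cand, val
                break
            t /= 2.0
        if np.max(np.abs(t * step)) < 1e-10:
            break
    eta = X @ theta + offset
    mu = np.exp(np.clip(eta, -30, 30))
    H = X.T @ (X * mu[:, None]) + prec
    cov = np.linalg.inv(H)
    return theta, cov


# --------------------------------------------------------------------------
# samplers
# --------------------------------------------------------------------------

def _sample_rw_metropolis(
    log_post: Callable[[np.ndarray], np.ndarray],
    mode: np.ndarray,
    cov: np.ndarray,
    cfg: SamplerConfig,
) -> np.ndarray:
    """Adaptive random-walk Metropolis, all chains advanced in lock-step.

    The proposal is Gaussian with the Laplace covariance; a per-chain
    scalar step size is tuned toward the target acceptance rate during
    warmup only, so the post-warmup kernel is fixed and valid.
    """
    rng = np.random.default_rng(cfg.seed)
    d = mode.size
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(d))
    theta = mode + 0.1 * rng.standard_normal((cfg.chains, d)) @ chol.T
    logp = log_post(theta)
    log_scale = np.full(cfg.chains, np.log(2.38 / np.sqrt(d)))
    kept = np.empty((cfg.chains, cfg.iterations - cfg.warmup, d))
    for it in range(cfg.iterations):
        z = rng.standard_normal((cfg.chains, d))
        prop = theta + np.exp(log_scale)[:, None] * (z @ chol.T)
        logp_prop = log_post(prop)
        accept = np.log(rng.random(cfg.chains)) < logp_prop - logp
        theta = np.where(accept[:, None], prop, theta)
        logp = np.where(accept, logp_prop, logp)
        if it < cfg.warmup:
            # Robbins-Monro step-size tuning toward the target rate
            gamma = 2.0 / (1.0 + it / 50.0) * 0.05
            log_scale += gamma * (accept.astype(float) - cfg.target_accept)
        else:
            kept[:, it - cfg.warmup, :] = theta
    return kept


def _sample_emcee(
    log_post: Callable[[np.ndarray], np.ndarray],
    mode: np.ndarray,
    cov: np.ndarray,
    cfg: SamplerConfig,
) -> np.ndarray:
    """Affine-invariant ensemble backend (cross-check; same contract).

    Walkers play the role of chains; the pooled draw count matches the
    configured chains x (iterations - warmup) total.
    """
    import emcee

    d = mode.size
    nwalkers = max(2 * d + 2, 8)
    target = cfg.chains * (cfg.iterations - cfg.warmup)
    steps = int(np.ceil(target / nwalkers))
    burn = max(200, int(np.ceil(cfg.warmup / nwalkers)))
    rng = np.random.default_rng(cfg.seed)
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(d))
    p0 = mode + 0.3 * rng.standard_normal((nwalkers, d)) @ chol.T
    sampler = emcee.EnsembleSampler(nwalkers, d, lambda t: float(log_post(t)[0]))
    sampler.random_state = np.random.RandomState(cfg.seed).get_state()
    state = sampler.run_mcmc(p0, burn, progress=False)
    sampler.reset()
    sampler.run_mcmc(state, steps, progress=False)
    return np.swapaxes(sampler.get_chain(), 0, 1)  # (walkers, steps, d)


_BACKENDS: Mapping[str, Callable] = {
    "rw_metropolis": _sample_rw_metropolis,
    "emcee": _sample_emcee,
}


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------

def fit_poisson_glm(
    design: pd.DataFrame, spec: ModelSpec, cfg: SamplerConfig
) -> PosteriorSummary:
    """Draw from the posterior of one Poisson log-linear model.

    Convergence problems (Rhat above threshold, ESS below the floor) are
    recorded on the returned summary, never silently dropped.
    """
    y = np.asarray(design[spec.response], dtype=float)
    if y.size and ((y < 0).any() or not np.allclose(y, np.round(y))):
        raise DataError(f"response {spec.response!r} must be non-negative integers")
    y = y.astype(float)
    n = y.size
    cols = list(spec.predictors)
    Xp = design[cols].to_numpy(dtype=float) if cols else np.empty((n, 0))
    if not np.isfinite(Xp).all():
        raise DataError("non-finite values in design matrix")
    for j, c in enumerate(cols):
        if n > 1 and np.std(Xp[:, j]) == 0:
            raise DataError(f"predictor column {c!r} has zero variance")
    offset = (
        np.asarray(design[spec.offset], dtype=float) if spec.offset else np.zeros(n)
    )
    X = np.column_stack([np.ones(n), Xp]) if n else np.zeros((0, 1 + len(cols)))
    param_names = ["alpha"] + [f"beta_{c}" for c in cols]
    prior_sd = np.array([spec.prior_alpha[1]] + [spec.prior_beta[1]] * len(cols))

    log_post = _make_log_post(X, y, offset, prior_sd)
    mode, cov = _laplace_mode(X, y, offset, prior_sd)
    try:
        sampler = _BACKENDS[cfg.backend]
    except KeyError:
        raise DataError(f"unknown sampler backend {cfg.backend!r}") from None
    chain_draws = sampler(log_post, mode, cov, cfg)

    pooled = chain_draws.reshape(-1, chain_draws.shape[-1])
    log_lik = _pointwise_log_lik(pooled, X, y, offset)
    rhat, ess = _diagnostics(chain_draws, param_names)

    msgs: list[str] = []
    bad_rhat = rhat[rhat > cfg.rhat_threshold]
    if not bad_rhat.empty:
        msgs.append(f"Rhat above {cfg.rhat_threshold} for {list(bad_rhat.index)}")
    bad_ess = ess[ess < cfg.min_ess]
    if not bad_ess.empty:
        msgs.append(f"effective sample size below {cfg.min_ess:g} for {list(bad_ess.index)}")
    for m in msgs:
        logger.warning("model %s: %s", spec.name, m)
    return PosteriorSummary(
        spec=spec,
        param_names=param_names,
        chain_draws=chain_draws,
        log_lik=log_lik,
        X=X,
        y=y,
        offset=offset,
        rhat=rhat,
        ess=ess,
        warnings=msgs,
        converged=not msgs,
    )


def _pointwise_log_lik(
    pooled: np.ndarray, X: np.ndarray, y: np.ndarray, offset: np.ndarray
) -> np.ndarray:
    eta = pooled @ X.T + offset  # (S, n)
    return y * eta - np.exp(eta) - gammaln(y + 1.0)


def _diagnostics(
    chain_draws: np.ndarray, param_names: list[str]
) -> tuple[pd.Series, pd.Series]:
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        posterior = {
            name: chain_draws[:, :, i] for i, name in enumerate(param_names)
        }
        idata = az.from_dict(posterior=posterior)
        rhat_ds = az.rhat(idata)
        ess_ds = az.ess(idata)
    rhat = pd.Series({n: float(rhat_ds[n].values) for n in param_names})
    ess = pd.Series({n: float(ess_ds[n].values) for n in param_names})
    return rhat, ess


def check_convergence(ps: PosteriorSummary) -> None:
    """Raise :class:`ConvergenceError` if the fit failed its gate."""
    if not ps.converged:
        raise ConvergenceError(
            f"model {ps.spec.name}: " + "; ".join(ps.warnings)
        )


# --------------------------------------------------------------------------
# posterior summaries and model comparison
# --------------------------------------------------------------------------

def hpdi(draws: np.ndarray, mass: float = 0.90) -> tuple[float, float]:
    """Narrowest contiguous interval of sorted draws holding ``mass``.

    Among all windows of ceil(mass * n) consecutive order statistics the
    narrowest is returned; ties break toward the lowest window start.
    """
    if not 0 < mass < 1:
        raise DataError("mass must be in (0, 1)")
    s = np.sort(np.asarray(draws, dtype=float))
    n = s.size
    if n < 10:
        raise DataError("hpdi needs at least 10 draws")
    m = int(np.ceil(mass * n))
    if m >= n:
        return float(s[0]), float(s[-1])
    widths = s[m - 1 :] - s[: n - m + 1]
    i = int(np.argmin(widths))  # argmin returns the first minimum
    return float(s[i]), float(s[i + m - 1])


def waic(ps: PosteriorSummary) -> dict[str, float]:
    """WAIC on the deviance scale with its standard error.

    waic = -2 (lppd - p_waic); lppd_i = log mean_s exp(ll_si) computed
    with log-sum-exp; p_waic_i = var_s(ll_si).  The standard error comes
    from the spread of the pointwise deviance contributions.
    """
    ll = ps.log_lik
    S, n = ll.shape
    if S < 2:
        raise DataError("WAIC needs at least 2 draws")
    lppd_i = logsumexp(ll, axis=0) - np.log(S)
    p_i = np.var(ll, axis=0, ddof=1)
    waic_i = -2.0 * (lppd_i - p_i)
    se = float(np.sqrt(n * np.var(waic_i, ddof=1))) if n > 1 else 0.0
    return {
        "waic": float(np.sum(waic_i)),
        "se": se,
        "lppd": float(np.sum(lppd_i)),
        "p_waic": float(np.sum(p_i)),
    }


def model_weights(waics: Sequence[float]) -> np.ndarray:
    """Akaike-style weights: exp(-delta/2), normalised."""
    w = np.asarray(waics, dtype=float)
    if w.size == 0:
        raise DataError("no models to weight")
    rel = np.exp(-0.5 * (w - w.min()))
    return rel / rel.sum()


def bayes_r2(ps: PosteriorSummary) -> np.ndarray:
    """Posterior distribution of R-squared for a Poisson model.

    Per draw, explained variance is the variance of the fitted means
    over observations; residual variance is the mean of the fitted means
    (the Poisson variance).  Always in [0, 1).
    """
    eta = ps.draws @ ps.X.T + ps.offset  # (S, n)
    mu = np.exp(eta)
    var_fit = np.var(mu, axis=1, ddof=0)
    resid = np.mean(mu, axis=1)
    return var_fit / (var_fit + resid)


@dataclass
class ModelComparison:
    """WAIC table plus the fitted posteriors for one response."""

    response: str
    table: pd.DataFrame
    fits: dict[str, PosteriorSummary]


def compare_models(
    design: pd.DataFrame,
    specs: Sequence[ModelSpec],
    cfg: SamplerConfig,
    *,
    hpdi_mass: float = 0.90,
) -> ModelComparison:
    """Fit a model set on a shared design and rank by WAIC weight."""
    responses = {s.response for s in specs}
    if len(responses) != 1:
        raise DataError("all specs in a comparison must share the response")
    fits: dict[str, PosteriorSummary] = {}
    rows = []
    for k, spec in enumerate(specs):
        ps = fit_poisson_glm(design, spec, replace(cfg, seed=cfg.seed + 1000 * k))
        fits[spec.name] = ps
        w = waic(ps)
        r2 = bayes_r2(ps)
        r2_lo, r2_hi = hpdi(r2, hpdi_mass)
        rows.append(
            {
                "model": spec.name,
                "waic": w["waic"],
                "waic_se": w["se"],
                "p_waic": w["p_waic"],
                "bayes_r2": float(np.median(r2)),
                "bayes_r2_lower": r2_lo,
                "bayes_r2_upper": r2_hi,
                "converged": ps.converged,
            }
        )
    table = pd.DataFrame(rows).set_index("model")
    table["delta_waic"] = table["waic"] - table["waic"].min()
    table["weight"] = model_weights(table["waic"].to_numpy())
    table = table.sort_values("waic")
    return ModelComparison(response=responses.pop(), table=table, fits=fits)
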