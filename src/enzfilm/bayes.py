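"""Bayesian uncertainty quantification of the eight model parameters.

The prior is independent log-uniform over the feasible box; the likelihood is
the joint Gaussian over both observed series (so ``log L = const - loss/2``
with the calibration loss).  Sampling uses differential-evolution MCMC with
occasional snooker updates (DE-MC(z)-style proposals from differences of
states of parallel chains) on the log10-parameter scale, with chains
initialised by jittering the least-squares estimate.  The default budget --
40 chains, 500 iterations, thinning 5 -- retains 4000 draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import emcee
import numpy as np

from .calibrate import (FeasibleBox, PARAM_NAMES, theta_to_config)
from .config import ModelConfig
from .data import DegradationDataset, model_curves
from .model import SimulationError

__all__ = ["PriorSpec", "SamplerConfig", "PosteriorSamples",
           "CredibleSummary", "log_likelihood", "log_prior",
           "sample_posterior", "sample_logprob", "credible_intervals",
           "predictive_bands"]

_LN10 = np.log(10.0)


@dataclass(frozen=True)
class PriorSpec:
    """Independent log-uniform prior over the feasible box (proper since all
    lower bounds are positive)."""

    box: FeasibleBox = field(default_factory=FeasibleBox)

    def log_density(self, theta: np.ndarray) -> float:
        """Log prior density in natural parameter space."""
        theta = np.asarray(theta, dtype=float)
        if not self.box.contains(theta) or np.any(theta <= 0):
            return -np.inf
        width = self.box.log_hi - self.box.log_lo
        return float(-np.sum(np.log(theta * _LN10 * width)))


def log_prior(theta, prior: PriorSpec) -> float:
    return prior.log_density(theta)


def log_likelihood(theta, data: DegradationDataset,
                   config: ModelConfig) -> float:
    """Joint Gaussian log likelihood over both series; -inf if the forward
    simulation fails (the proposal is then rejected)."""
    try:
        cfg = theta_to_config(theta, config)
        wl_hat, xc_hat = model_curves(cfg, data.wl_times, data.xc_times)
    except (SimulationError, ValueError):
        return -np.inf
    sigmas = np.concatenate([data.wl_sd, data.xc_sd])
    resid = np.concatenate([wl_hat - data.wl_values, xc_hat - data.xc_values])
    norm = -0.5 * np.sum(np.log(2.0 * np.pi * sigmas ** 2))
    return float(norm - 0.5 * np.sum((resid / sigmas) ** 2))


@dataclass(frozen=True)
class SamplerConfig:
    """DE-MC sampler budget; retained draws = n_chains * n_iterations /
    thinning (burn-in is off by default, matching that arithmetic)."""

    n_chains: int = 40
    n_iterations: int = 500
    thinning: int = 5
    burn_in: int = 0
    sigma_init: float = 0.05  # log10-space jitter around the starting point
    snooker_prob: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chains < 4:
            raise ValueError("need at least 4 chains for DE proposals")
        if self.n_iterations % self.thinning:
            raise ValueError("n_iterations must be divisible by thinning")
        if not 0.0 <= self.snooker_prob <= 1.0:
            raise ValueError("snooker_prob must be in [0, 1]")

    @property
    def n_retained(self) -> int:
        return self.n_chains * (self.n_iterations - self.burn_in) // self.thinning


@dataclass
class PosteriorSamples:
    """Retained draws in natural parameter space with chain/iteration labels."""

    draws: np.ndarray          # (n_retained, d)
    chain: np.ndarray          # (n_retained,)
    iteration: np.ndarray      # (n_retained,) post-thinning iteration index
    log_posterior: np.ndarray  # (n_retained,)
    acceptance_fraction: np.ndarray
    param_names: tuple = PARAM_NAMES

    @property
    def n_retained(self) -> int:
        return self.draws.shape[0]


@dataclass
class CredibleSummary:
    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float
    param_names: tuple

    def as_dict(self) -> dict:
        return {name: {"mean": float(m), "lower": float(lo), "upper": float(hi)}
                for name, m, lo, hi in
                zip(self.param_names, self.mean, self.lower, self.upper)}


def sample_logprob(log_prob, x0: np.ndarray, config: SamplerConfig,
                   param_names=PARAM_NAMES) -> PosteriorSamples:
    """Run the DE + snooker ensemble sampler on an arbitrary log density.

    ``x0`` is (n_chains, d) -- the initial population, which must not be
    degenerate.  This lower-level entry point is also what the posterior
    sampler uses; draws are returned on the sampling scale.
    """
    x0 = np.asarray(x0, dtype=float)
    if x0.ndim != 2 or x0.shape[0] != config.n_chains:
        raise ValueError("x0 must have shape (n_chains, d)")
    if np.allclose(x0.std(axis=0), 0.0):
        raise ValueError("degenerate initial population (all chains identical)")
    d = x0.shape[1]
    if config.n_chains < 2 * d:
        raise ValueError(f"DE ensemble proposals need at least 2*d = {2 * d} "
                         f"chains for a {d}-parameter target")
    moves = [(emcee.moves.DEMove(), 1.0 - config.snooker_prob)]
    if config.snooker_prob > 0:
        moves.append((emcee.moves.DESnookerMove(), config.snooker_prob))
    sampler = emcee.EnsembleSampler(config.n_chains, d, log_prob, moves=moves)
    sampler.random_state = np.random.RandomState(config.seed).get_state()
    sampler.run_mcmc(x0, config.n_iterations, progress=False,
                     skip_initial_state_check=True)
    chain = sampler.get_chain(discard=config.burn_in, thin=config.thinning)
    logp = sampler.get_log_prob(discard=config.burn_in, thin=config.thinning)
    n_kept, n_chains, _ = chain.shape
    draws = chain.reshape(n_kept * n_chains, d)
    chain_ix = np.tile(np.arange(n_chains), n_kept)
    iter_ix = np.repeat(np.arange(n_kept), n_chains)
    return PosteriorSamples(
        draws=draws, chain=chain_ix, iteration=iter_ix,
        log_posterior=logp.reshape(-1),
        acceptance_fraction=sampler.acceptance_fraction,
        param_names=tuple(param_names),
    )


def sample_posterior(data: DegradationDataset, prior: PriorSpec,
                     config: SamplerConfig, model_config: ModelConfig,
                     theta_init: np.ndarray) -> PosteriorSamples:
    """Sample the posterior of theta given the dataset.

    Chains start from ``theta_init`` (typically the least-squares estimate)
    perturbed by seeded log10-space Gaussian jitter and clipped into the box.
    Sampling is on u = log10(theta), where the log-uniform prior is flat.
    """
    box = prior.box
    theta_init = box.clip(theta_init)
    rng = np.random.default_rng(config.seed)
    u_init = np.log10(theta_init)
    u0 = u_init + config.sigma_init * rng.standard_normal((config.n_chains, 8))
    u0 = np.clip(u0, box.log_lo, box.log_hi)
    width = box.log_hi - box.log_lo

    def log_post_u(u):
        if np.any(u < box.log_lo) or np.any(u > box.log_hi):
            return -np.inf
        # flat prior density in u-space: -sum(log width)
        ll = log_likelihood(10.0 ** u, data, model_config)
        return ll - float(np.sum(np.log(width)))

    raw = sample_logprob(log_post_u, u0, config)
    return PosteriorSamples(
        draws=10.0 ** raw.draws, chain=raw.chain, iteration=raw.iteration,
        log_posterior=raw.log_posterior,
        acceptance_fraction=raw.acceptance_fraction,
        param_names=PARAM_NAMES,
    )


def credible_intervals(samples: PosteriorSamples,
                       level: float = 0.95) -> CredibleSummary:
    """Posterior means and central credible intervals per parameter."""
    if samples.n_retained < 100:
        raise ValueError("need at least 100 retained draws")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    alpha = 0.5 * (1.0 - level)
    lo, hi = np.quantile(samples.draws, [alpha, 1.0 - alpha], axis=0)
    return CredibleSummary(mean=samples.draws.mean(axis=0), lower=lo,
                           upper=hi, level=level,
                           param_names=samples.param_names)


def predictive_bands(samples: PosteriorSamples, model_config: ModelConfig,
                     times, level: float = 0.95,
                     max_draws: int | None = None,
                     seed: int = 0) -> dict:
    """Posterior-predictive pointwise credible bands for both observables.

    Each retained draw (optionally a seeded subsample of ``max_draws``) is
    propagated through the forward model; bands are central pointwise
    intervals of the trajectory ensemble, and the central curve is the
    trajectory at the posterior-mean parameter vector.  Draws whose
    simulation fails are excluded and counted.
    """
    times = np.asarray(times, dtype=float)
    draws = samples.draws
    if max_draws is not None and max_draws < draws.shape[0]:
        rng = np.random.default_rng(seed)
        draws = draws[rng.choice(draws.shape[0], max_draws, replace=False)]

    wl_ens, xc_ens = [], []
    n_failed = 0
    for theta in draws:
        try:
            cfg = theta_to_config(theta, model_config)
            wl, xc = model_curves(cfg, times, times)
        except (SimulationError, ValueError):
            n_failed += 1
            continue
        wl_ens.append(wl)
        xc_ens.append(xc)
    if not wl_ens:
        raise SimulationError("every posterior draw failed to simulate")
    wl_ens = np.vstack(wl_ens)
    xc_ens = np.vstack(xc_ens)
    alpha = 0.5 * (1.0 - level)
    theta_mean = samples.draws.mean(axis=0)
    wl_mean, xc_mean = model_curves(theta_to_config(theta_mean, model_config),
                                    times, times)
    return {
        "times": times,
        "wl_lower": np.quantile(wl_ens, alpha, axis=0),
        "wl_upper": np.quantile(wl_ens, 1 - alpha, axis=0),
        "xc_lower": np.quantile(xc_ens, alpha, axis=0),
        "xc_upper": np.quantile(xc_ens, 1 - alpha, axis=0),
        "wl_mean_curve": wl_mean,
        "xc_mean_curve": xc_mean,
        "n_used": wl_ens.shape[0],
        "n_failed": n_failed,
        "level": level,
    }
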