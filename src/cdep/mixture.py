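"""Bayesian three-component Beta mixture for one-sided p-value distributions.

Rank-based permutation p-values from competitive statistics are not uniform
for unaffected genes: differentially expressed genes capture the extreme
ranks, so the bulk of the p-value distribution is hump-shaped.  The mixture
therefore models the p-values of one dataset and one direction as

    y_g ~ theta_1 Beta(1, b_1) + theta_2 Beta(a_2, b_2) + theta_3 Beta(a_3, 1)

where component 1 (mass near 0) captures genes significant in the tested
direction, component 2 the non-differential bulk, and component 3 (mass near
1) genes extreme in the opposite direction.  The fixed shape parameters
a_1 = b_3 = 1 pin the two skewed components to opposite ends of (0, 1) and
prevent label switching.

Priors: theta ~ Dirichlet(1, 18, 1); a_2 ~ Gamma(4, 2); b_2 ~ Gamma(1, 1);
a_3, b_1 ~ Gamma(400, 20), with Gamma(alpha, beta) parameterised so the mean
is alpha/beta.  Inference is Gibbs sampling with data augmentation over the
component labels and random-walk Metropolis (log scale) for the free Beta
shapes.  The estimated number of genes *not* regulated in the tested
direction is G * (theta_2 + theta_3), the quantity the likelihood stage of
the meta-analysis needs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import betaln, gammaln

__all__ = [
    "PriorSpec",
    "SamplerConfig",
    "MixtureFit",
    "fit_beta_mixture",
    "estimate_not_de_counts",
]

_CLAMP = 1e-6


@dataclass(frozen=True)
class PriorSpec:
    """Hyperparameters; Gamma(alpha, beta) has mean alpha/beta."""

    dirichlet: tuple = (1.0, 18.0, 1.0)
    a2: tuple = (4.0, 2.0)
    b2: tuple = (1.0, 1.0)
    a3: tuple = (400.0, 20.0)
    b1: tuple = (400.0, 20.0)


@dataclass(frozen=True)
class SamplerConfig:
    chains: int = 2
    iterations: int = 4000
    burn_in: int = 2000
    proposal_scale: float = 0.2
    rhat_threshold: float = 1.1
    point_estimate: str = "mean"  # or "median"


@dataclass
class MixtureFit:
    """Posterior summary of the mixture for one dataset and direction."""

    dataset_id: str
    direction: str
    theta: np.ndarray  # posterior point estimate, simplex
    beta_params: np.ndarray  # (3, 2) array of (a_k, b_k)
    m_not_de: int  # estimated genes NOT regulated in `direction`
    n_genes: int
    converged: bool
    rhat: float
    n_draws: int
    n_clamped: int = 0
    theta_draws: np.ndarray | None = field(default=None, repr=False)


def _gamma_logpdf(x: float, alpha: float, beta: float) -> float:
    return alpha * np.log(beta) + (alpha - 1.0) * np.log(x) - beta * x - gammaln(alpha)


def _split_rhat(chains: np.ndarray) -> float:
    """Split-R̂ of Gelman et al. on a (n_chains, n_draws) array."""
    n_chains, n_draws = chains.shape
    half = n_draws // 2
    if half < 2:
        return np.inf
    split = chains[:, : 2 * half].reshape(n_chains * 2, half)
    within = split.var(axis=1, ddof=1).mean()
    between = half * split.mean(axis=1).var(ddof=1)
    if within == 0:
        return 1.0
    var_hat = (half - 1) / half * within + between / half
    return float(np.sqrt(var_hat / within))


def _run_chain(
    logy: np.ndarray,
    log1my: np.ndarray,
    priors: PriorSpec,
    cfg: SamplerConfig,
    rng: np.random.Generator,
):
    G = logy.size
    # init at prior means, jittered per chain
    b1 = priors.b1[0] / priors.b1[1] * np.exp(0.1 * rng.standard_normal())
    a2 = priors.a2[0] / priors.a2[1] * np.exp(0.1 * rng.standard_normal())
    b2 = priors.b2[0] / priors.b2[1] * np.exp(0.1 * rng.standard_normal())
    a3 = priors.a3[0] / priors.a3[1] * np.exp(0.1 * rng.standard_normal())
    dprior = np.asarray(priors.dirichlet)
    theta = rng.dirichlet(dprior)

    n_keep = cfg.iterations - cfg.burn_in
    theta_draws = np.empty((n_keep, 3))
    shape_draws = np.empty((n_keep, 4))  # b1, a2, b2, a3
    step = cfg.proposal_scale

    def loglik_comp1(b1_):
        # Beta(1, b1): logpdf = log(b1) + (b1-1) log(1-y)
        return n1 * np.log(b1_) + (b1_ - 1.0) * s1m1

    def loglik_comp2(a2_, b2_):
        return (a2_ - 1.0) * sy2 + (b2_ - 1.0) * s1m2 - n2 * betaln(a2_, b2_)

    def loglik_comp3(a3_):
        # Beta(a3, 1): logpdf = log(a3) + (a3-1) log(y)
        return n3 * np.log(a3_) + (a3_ - 1.0) * sy3

    def mh_step(current, logpost):
        # random walk on log scale; Jacobian log(x) folded into the target
        prop = current * np.exp(step * rng.standard_normal())
        delta = logpost(prop) + np.log(prop) - logpost(current) - np.log(current)
        if np.log(rng.random()) < delta:
            return prop
        return current

    for it in range(cfg.iterations):
        # component log densities per gene
        l1 = np.log(b1) + (b1 - 1.0) * log1my
        l2 = (a2 - 1.0) * logy + (b2 - 1.0) * log1my - betaln(a2, b2)
        l3 = np.log(a3) + (a3 - 1.0) * logy
        L = np.stack([l1 + np.log(theta[0]), l2 + np.log(theta[1]), l3 + np.log(theta[2])], axis=1)
        L -= L.max(axis=1, keepdims=True)
        W = np.exp(L)
        W /= W.sum(axis=1, keepdims=True)
        u = rng.random(G)
        T = (u > W[:, 0]).astype(np.int64) + (u > W[:, 0] + W[:, 1])

        n1 = np.count_nonzero(T == 0)
        n3 = np.count_nonzero(T == 2)
        n2 = G - n1 - n3
        s1m1 = log1my[T == 0].sum()
        sy2 = logy[T == 1].sum()
        s1m2 = log1my[T == 1].sum()
        sy3 = logy[T == 2].sum()

        theta = rng.dirichlet(dprior + np.array([n1, n2, n3]))
        b1 = mh_step(b1, lambda x: loglik_comp1(x) + _gamma_logpdf(x, *priors.b1))
        a2 = mh_step(a2, lambda x: loglik_comp2(x, b2) + _gamma_logpdf(x, *priors.a2))
        b2 = mh_step(b2, lambda x: loglik_comp2(a2, x) + _gamma_logpdf(x, *priors.b2))
        a3 = mh_step(a3, lambda x: loglik_comp3(x) + _gamma_logpdf(x, *priors.a3))

        if it >= cfg.burn_in:
            k = it - cfg.burn_in
            theta_draws[k] = theta
            shape_draws[k] = (b1, a2, b2, a3)

    return theta_draws, shape_draws


def fit_beta_mixture(
    pvalues: np.ndarray,
    priors: PriorSpec | None = None,
    sampler: SamplerConfig | None = None,
    seed: int | np.random.SeedSequence | None = None,
    dataset_id: str = "",
    direction: str = "up",
) -> MixtureFit:
    """Fit the three-component Beta mixture to one-sided p-values.

    p-values are clamped into [1e-6, 1 - 1e-6] (the Beta log density is
    unbounded at the endpoints).  An empty input returns the prior (useful
    as a sampler diagnostic).  All-identical p-values are rejected.
    """
    priors = priors or PriorSpec()
    cfg = sampler or SamplerConfig()
    y = np.asarray(pvalues, dtype=float)
    if y.ndim != 1:
        raise ValueError("pvalues must be 1-D")
    if y.size > 0 and np.ptp(y) == 0.0:
        raise ValueError("all p-values are identical; mixture fit is degenerate")
    n_clamped = int(np.count_nonzero((y < _CLAMP) | (y > 1 - _CLAMP)))
    y = np.clip(y, _CLAMP, 1.0 - _CLAMP)
    logy = np.log(y)
    log1my = np.log1p(-y)

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    chain_seeds = ss.spawn(cfg.chains)
    theta_chains = []
    shape_chains = []
    for cs in chain_seeds:
        th, sh = _run_chain(logy, log1my, priors, cfg, np.random.default_rng(cs))
        theta_chains.append(th)
        shape_chains.append(sh)
    theta_all = np.stack(theta_chains)  # (chains, draws, 3)
    shape_all = np.stack(shape_chains)  # (chains, draws, 4)

    rhat = max(_split_rhat(theta_all[:, :, k]) for k in range(3))
    converged = bool(rhat < cfg.rhat_threshold)
    if not converged:
        warnings.warn(
            f"beta mixture for {dataset_id or 'dataset'}/{direction}: "
            f"split-Rhat {rhat:.3f} exceeds {cfg.rhat_threshold}",
            RuntimeWarning,
            stacklevel=2,
        )

    reduce_ = np.mean if cfg.point_estimate == "mean" else np.median
    theta_hat = reduce_(theta_all.reshape(-1, 3), axis=0)
    theta_hat = theta_hat / theta_hat.sum()
    b1, a2, b2, a3 = reduce_(shape_all.reshape(-1, 4), axis=0)
    beta_params = np.array([[1.0, b1], [a2, b2], [a3, 1.0]])

    G = y.size
    m_not = int(np.clip(round(G * (theta_hat[1] + theta_hat[2])), 1, max(G, 1)))
    return MixtureFit(
        dataset_id=dataset_id,
        direction=direction,
        theta=theta_hat,
        beta_params=beta_params,
        m_not_de=m_not,
        n_genes=G,
        converged=converged,
        rhat=rhat,
        n_draws=theta_all.shape[0] * theta_all.shape[1],
        n_clamped=n_clamped,
        theta_draws=theta_all,
    )


def estimate_not_de_counts(fit: MixtureFit, n_genes: int, direction: str) -> int:
    """Estimated number of genes not regulated in ``direction``.

    With the fit performed on p-values testing that same direction, the
    non-regulated mass is theta_2 + theta_3 (bulk plus opposite-extreme
    component).  Floored at 1 so downstream false-positive rates stay
    finite.
    """
    if direction != fit.direction:
        raise ValueError(
            f"fit is for direction {fit.direction!r}, requested {direction!r}"
        )
    count = round(n_genes * float(fit.theta[1] + fit.theta[2]))
    return int(np.clip(count, 1, n_genes))
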