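"""Seeded MCMC machinery for the hierarchical models.

Both model classes here share one scheme — Gibbs-within-Metropolis:

* subject-level parameter blocks are updated by per-coordinate random-walk
  Metropolis, proposed and accepted *simultaneously for all subjects*
  (subjects are conditionally independent given the group-level
  parameters), with proposal scales adapted during warmup toward a 0.44
  acceptance rate;
* group-level locations and scales are conjugate (Normal and
  inverse-gamma) and are drawn exactly.

Chains are fully determined by a :class:`numpy.random.SeedSequence`, so a
fixed seed reproduces every draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kernels import batch_loglik

TARGET_ACCEPT = 0.44


@dataclass(frozen=True)
class SamplerConfig:
    """MCMC run settings. ``n_draws`` are kept per chain after ``n_warmup``."""

    n_chains: int = 4
    n_warmup: int = 1000
    n_draws: int = 1000
    init_jitter: float = 0.1


#: reduced settings for desk-scale recovery runs
FAST_SAMPLER = SamplerConfig(n_chains=2, n_warmup=400, n_draws=400)


@dataclass(frozen=True)
class GroupPrior:
    """Independent Normal / inverse-gamma hyperpriors per coordinate.

    theta_sk ~ Normal(mu_k, sigma_k^2); mu_k ~ Normal(m0_k, s0_k^2);
    sigma_k^2 ~ InvGamma(a0, b0).
    """

    m0: np.ndarray
    s0: np.ndarray
    a0: float = 2.5
    b0: float = 1.0


def _adapt(scale, accepted, it):
    g = min(0.5, 3.0 / np.sqrt(1.0 + it))
    return scale * np.exp(g * (accepted - TARGET_ACCEPT))


def _sample_invgamma(rng, a, b):
    return b / rng.gamma(a)


def sample_hierarchical_learning(
    fam_id: int,
    theta_to_natural,
    choices: np.ndarray,
    outcomes: np.ndarray,
    env_high: np.ndarray,
    ptr: np.ndarray,
    prior: GroupPrior,
    cfg: SamplerConfig,
    seed,
    sigma_n: float,
    max_init_retries: int = 5,
) -> dict:
    """Hierarchical fit of one learning-model family.

    ``theta_to_natural`` maps an (n_subjects, K) transformed-parameter array
    to the (n_subjects, 4) natural-scale layout of
    :func:`epinc._kernels.batch_loglik` (p_low, p_high, beta, bias).

    Returns stacked draws with shape (chains, draws, ...) for keys
    ``theta``, ``mu``, ``sigma`` plus acceptance diagnostics.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    n_subj = ptr.shape[0] - 1
    K = prior.m0.shape[0]

    theta_ch, mu_ch, sigma_ch, acc_ch = [], [], [], []
    for chain_ss in ss.spawn(cfg.n_chains):
        rng = np.random.default_rng(chain_ss)
        cur_ll = np.empty(n_subj)
        for attempt in range(max_init_retries):
            theta = prior.m0[None, :] + cfg.init_jitter * rng.standard_normal((n_subj, K))
            batch_loglik(fam_id, theta_to_natural(theta), sigma_n,
                         choices, outcomes, env_high, ptr, cur_ll)
            if np.all(np.isfinite(cur_ll)):
                break
        else:
            raise RuntimeError("could not find a finite-likelihood initialization")
        mu = prior.m0.copy()
        sigma2 = prior.s0.copy() ** 2

        scale = np.full((n_subj, K), 0.3)
        prop_ll = np.empty(n_subj)
        thetas = np.empty((cfg.n_draws, n_subj, K))
        mus = np.empty((cfg.n_draws, K))
        sigmas = np.empty((cfg.n_draws, K))
        n_acc = 0.0
        n_tot = 0.0
        for it in range(cfg.n_warmup + cfg.n_draws):
            warm = it < cfg.n_warmup
            for k in range(K):
                prop = theta.copy()
                prop[:, k] = theta[:, k] + scale[:, k] * rng.standard_normal(n_subj)
                batch_loglik(fam_id, theta_to_natural(prop), sigma_n,
                             choices, outcomes, env_high, ptr, prop_ll)
                lp_diff = (
                    (prop_ll - cur_ll)
                    - 0.5 * ((prop[:, k] - mu[k]) ** 2 - (theta[:, k] - mu[k]) ** 2) / sigma2[k]
                )
                accept = np.log(rng.random(n_subj)) < lp_diff
                theta[accept, k] = prop[accept, k]
                cur_ll[accept] = prop_ll[accept]
                if warm:
                    scale[:, k] = _adapt(scale[:, k], accept.astype(float), it)
                else:
                    n_acc += accept.sum()
                    n_tot += n_subj
            # conjugate group-level updates
            for k in range(K):
                prec = n_subj / sigma2[k] + 1.0 / prior.s0[k] ** 2
                mean = (theta[:, k].sum() / sigma2[k] + prior.m0[k] / prior.s0[k] ** 2) / prec
                mu[k] = mean + rng.standard_normal() / np.sqrt(prec)
                resid = theta[:, k] - mu[k]
                sigma2[k] = _sample_invgamma(
                    rng, prior.a0 + 0.5 * n_subj, prior.b0 + 0.5 * resid @ resid
                )
            if not warm:
                j = it - cfg.n_warmup
                thetas[j] = theta
                mus[j] = mu
                sigmas[j] = np.sqrt(sigma2)
        theta_ch.append(thetas)
        mu_ch.append(mus)
        sigma_ch.append(sigmas)
        acc_ch.append(n_acc / max(n_tot, 1.0))

    return {
        "theta": np.stack(theta_ch),
        "mu": np.stack(mu_ch),
        "sigma": np.stack(sigma_ch),
        "accept_rate": np.array(acc_ch),
    }


def _pointwise_loglik(link, y, eta, sigma_e):
    s = 2.0 * y - 1.0
    if link == "logistic":
        z = -s * eta
        return -(np.logaddexp(0.0, z))
    resid = y - eta
    return -0.5 * np.log(2.0 * np.pi * sigma_e**2) - 0.5 * resid**2 / sigma_e**2


def _segment_sums(x, ptr):
    return np.add.reduceat(x, ptr[:-1]) if ptr[-1] > 0 else np.zeros(ptr.shape[0] - 1)


def sample_mixed_glm(
    y: np.ndarray,
    X: np.ndarray,
    subj_idx: np.ndarray,
    ptr: np.ndarray,
    random_mask: np.ndarray,
    link: str,
    cfg: SamplerConfig,
    seed,
    beta_prior_sd: float = 5.0,
    scale_a0: float = 2.0,
    scale_b0: float = 0.5,
) -> dict:
    """Bayesian mixed-effects GLM (logistic or identity link).

    Rows must be sorted by subject; ``ptr`` gives each subject's span.
    Columns flagged in ``random_mask`` get subject-level coefficients
    theta_sk ~ Normal(beta_k, sigma_k^2); the rest get shared coefficients
    gamma with Normal(0, beta_prior_sd^2) priors.

    Returns stacked draws for ``beta`` (centers of random coordinates),
    ``gamma`` (fixed-only coordinates), ``sigma`` (random-effect SDs),
    ``theta`` (subject coefficients) and, for the identity link,
    ``sigma_e``.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    n, p = X.shape
    n_subj = ptr.shape[0] - 1
    r_cols = np.flatnonzero(random_mask)
    f_cols = np.flatnonzero(~random_mask)
    Kr, Kf = len(r_cols), len(f_cols)

    out = {k: [] for k in ("beta", "gamma", "sigma", "theta", "sigma_e")}
    acc_ch = []
    for chain_ss in ss.spawn(cfg.n_chains):
        rng = np.random.default_rng(chain_ss)
        theta = cfg.init_jitter * rng.standard_normal((n_subj, Kr))
        gamma = cfg.init_jitter * rng.standard_normal(Kf)
        beta = np.zeros(Kr)
        sigma2 = np.ones(Kr)
        sigma_e = max(np.std(y), 0.1) if link == "identity" else 1.0

        eta = X[:, f_cols] @ gamma if Kf else np.zeros(n)
        for j, c in enumerate(r_cols):
            eta = eta + X[:, c] * theta[subj_idx, j]

        scale_t = np.full((n_subj, Kr), 0.5)
        scale_g = np.full(Kf, 0.1)
        betas = np.empty((cfg.n_draws, Kr))
        gammas = np.empty((cfg.n_draws, Kf))
        sigmas = np.empty((cfg.n_draws, Kr))
        thetas = np.empty((cfg.n_draws, n_subj, Kr))
        sigma_es = np.empty(cfg.n_draws)
        n_acc = 0.0
        n_tot = 0.0

        cur_pt = _pointwise_loglik(link, y, eta, sigma_e)
        cur_ll_s = _segment_sums(cur_pt, ptr)
        for it in range(cfg.n_warmup + cfg.n_draws):
            warm = it < cfg.n_warmup
            # subject-level coordinates, all subjects at once
            for j, c in enumerate(r_cols):
                step = scale_t[:, j] * rng.standard_normal(n_subj)
                d_eta = X[:, c] * step[subj_idx]
                new_pt = _pointwise_loglik(link, y, eta + d_eta, sigma_e)
                new_ll_s = _segment_sums(new_pt, ptr)
                th_new = theta[:, j] + step
                lp_diff = (
                    new_ll_s - cur_ll_s
                    - 0.5 * ((th_new - beta[j]) ** 2 - (theta[:, j] - beta[j]) ** 2) / sigma2[j]
                )
                accept = np.log(rng.random(n_subj)) < lp_diff
                if accept.any():
                    row_acc = accept[subj_idx]
                    eta = np.where(row_acc, eta + d_eta, eta)
                    cur_pt = np.where(row_acc, new_pt, cur_pt)
                    cur_ll_s[accept] = new_ll_s[accept]
                    theta[accept, j] = th_new[accept]
                if warm:
                    scale_t[:, j] = _adapt(scale_t[:, j], accept.astype(float), it)
                else:
                    n_acc += accept.sum()
                    n_tot += n_subj
            # shared coordinates
            for j, c in enumerate(f_cols):
                step = scale_g[j] * rng.standard_normal()
                d_eta = X[:, c] * step
                new_pt = _pointwise_loglik(link, y, eta + d_eta, sigma_e)
                g_new = gamma[j] + step
                lp_diff = (
                    new_pt.sum() - cur_pt.sum()
                    - 0.5 * (g_new**2 - gamma[j] ** 2) / beta_prior_sd**2
                )
                if np.log(rng.random()) < lp_diff:
                    gamma[j] = g_new
                    eta = eta + d_eta
                    cur_pt = new_pt
                    cur_ll_s = _segment_sums(cur_pt, ptr)
                    acc_f = 1.0
                else:
                    acc_f = 0.0
                if warm:
                    scale_g[j] = float(_adapt(np.array([scale_g[j]]), np.array([acc_f]), it)[0])
            # conjugate: centers and scales of the random coordinates
            for j in range(Kr):
                prec = n_subj / sigma2[j] + 1.0 / beta_prior_sd**2
                mean = theta[:, j].sum() / sigma2[j] / prec
                beta[j] = mean + rng.standard_normal() / np.sqrt(prec)
                resid = theta[:, j] - beta[j]
                sigma2[j] = _sample_invgamma(
                    rng, scale_a0 + 0.5 * n_subj, scale_b0 + 0.5 * resid @ resid
                )
            # residual scale (identity link)
            if link == "identity":
                resid = y - eta
                sigma_e = np.sqrt(_sample_invgamma(
                    rng, 1.0 + 0.5 * n, 1.0 + 0.5 * resid @ resid
                ))
                cur_pt = _pointwise_loglik(link, y, eta, sigma_e)
                cur_ll_s = _segment_sums(cur_pt, ptr)
            if not warm:
                i = it - cfg.n_warmup
                betas[i] = beta
                gammas[i] = gamma
                sigmas[i] = np.sqrt(sigma2)
                thetas[i] = theta
                sigma_es[i] = sigma_e
        out["beta"].append(betas)
        out["gamma"].append(gammas)
        out["sigma"].append(sigmas)
        out["theta"].append(thetas)
        out["sigma_e"].append(sigma_es)
        acc_ch.append(n_acc / max(n_tot, 1.0))

    return {k: np.stack(v) for k, v in out.items()} | {"accept_rate": np.array(acc_ch)}
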