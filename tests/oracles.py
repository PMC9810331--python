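"""Independent reference implementations used only by the tests.

These deliberately share no code with the package: the grid filter does
exact Bayesian changepoint inference by numerical integration, the HMM
oracle enumerates context paths exhaustively, and d' is recomputed from
normal quantiles directly.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.stats import norm


def grid_changepoint_filter(outcomes, hazard, sigma_n, n_grid=401, tau0=0.5):
    """Exact Bayesian filter for the Gaussian changepoint model on a grid.

    Generative model: latent mean mu on [0, 1]; with probability ``hazard``
    per trial mu resets to Uniform(0, 1); observations x ~ N(mu, sigma_n^2).
    The prior matches the reduced filter's start: mu ~ N(0.5, sigma_est0^2)
    with sigma_est0^2 = sigma_n^2 * tau0 / (1 - tau0), truncated to [0, 1].

    Returns (mean_series, tau_series): the posterior mean of mu and the
    relative uncertainty var(mu) / (var(mu) + sigma_n^2), both *before*
    each observation is incorporated (choice-time alignment).
    """
    grid = np.linspace(0.0, 1.0, n_grid)
    w = np.gradient(grid)  # trapezoid weights
    sd0 = sigma_n * np.sqrt(tau0 / (1.0 - tau0))
    p = norm.pdf(grid, 0.5, sd0)
    p /= np.sum(p * w)
    uniform = np.ones_like(grid)

    means, taus = [], []
    for x in outcomes:
        m = np.sum(grid * p * w)
        v = np.sum((grid - m) ** 2 * p * w)
        means.append(m)
        taus.append(v / (v + sigma_n**2))
        # predict (hazard mixing), then update
        p = (1.0 - hazard) * p + hazard * uniform
        p = p * norm.pdf(x, grid, sigma_n)
        p /= np.sum(p * w)
    return np.array(means), np.array(taus)


def enumerate_context_paths(outcomes, choices, hazard, sigma_n,
                            means=(0.63, 0.37)):
    """Posterior over the two lucky-deck contexts by exhaustive path sums.

    Context 0: deck A lucky. Transitions switch with probability
    ``hazard``; uniform initial distribution; Gaussian emissions of the
    chosen deck's outcome. Returns the final posterior (p0, p1).
    """
    T = len(outcomes)
    post = np.zeros(2)
    for path in itertools.product((0, 1), repeat=T):
        w = 0.5
        for t in range(1, T):
            w *= hazard if path[t] != path[t - 1] else 1.0 - hazard
        for t, ctx in enumerate(path):
            chose_a = choices[t] == "A"
            lucky_chosen = (ctx == 0) == chose_a
            mu = means[0] if lucky_chosen else means[1]
            w *= norm.pdf(outcomes[t], mu, sigma_n)
        post[path[-1]] += w
    post /= post.sum()
    return np.array([post[0], post[1]])


def dprime_reference(n_hit, n_old, n_fa, n_new):
    """Log-linear-corrected d' straight from normal quantiles."""
    return norm.ppf((n_hit + 0.5) / (n_old + 1)) - norm.ppf((n_fa + 0.5) / (n_new + 1))


def rw1q_reference(choices, outcomes, alpha, q0=0.5):
    """Independent recursion for the single-estimate learner."""
    q = q0
    qs = []
    for c, x in zip(choices, outcomes):
        qs.append(q)
        e = x if c == "A" else 1.0 - x
        q = q + alpha * (e - q)
    return np.array(qs)


def simulate_changepoint_sequence(rng, n_trials, hazard, sigma_n):
    """A sequence from the changepoint generative model (clipped to [0,1])."""
    mu = rng.uniform()
    xs, mus = [], []
    for _ in range(n_trials):
        if rng.random() < hazard:
            mu = rng.uniform()
        xs.append(np.clip(mu + sigma_n * rng.standard_normal(), 0.0, 1.0))
        mus.append(mu)
    return np.array(xs), np.array(mus)
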