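"""Numba-jitted choice log-likelihoods for the learning-model families.

These duplicate the recursions in :mod:`epinc.filters` in flat-array form so
that the hierarchical sampler can evaluate thousands of candidate parameter
vectors per second. Consistency between the two implementations is enforced
by the test suite.

Conventions: choices coded 0 = deck A, 1 = deck B; outcomes in [0, 1]
dollars; ``env_high`` 1 in the high-volatility block; state resets whenever
``env_high`` changes (block boundary) and at t = 0.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

FAM_RW1A, FAM_RW2A, FAM_RB1H, FAM_RB2H, FAM_CI, FAM_RW1Q = 0, 1, 2, 3, 4, 5

V_LUCKY, V_UNLUCKY = 0.63, 0.37


@njit(cache=True, inline="always")
def _softplus(x):
    if x > 0.0:
        return x + math.log1p(math.exp(-x))
    return math.log1p(math.exp(x))


@njit(cache=True)
def subject_loglik(fam, p_low, p_high, beta, bias, sigma_n,
                   choices, outcomes, env_high):
    """Choice log-likelihood of one subject's sequence under one family."""
    n = choices.shape[0]
    ll = 0.0
    bA = 0.5
    bB = 0.5
    tau = 0.5
    q = 0.5
    pA = 0.5  # CI: posterior p(context: deck A lucky)
    s2 = sigma_n * sigma_n
    inv_sqrt2pi = 1.0 / math.sqrt(2.0 * math.pi)
    for t in range(n):
        if t == 0 or env_high[t] != env_high[t - 1]:
            bA = 0.5
            bB = 0.5
            tau = 0.5
            q = 0.5
            pA = 0.5
        p = p_high if (env_high[t] == 1 and (fam == FAM_RW2A or fam == FAM_RB2H)) else p_low

        if fam == FAM_RW1Q:
            vA = q
            vB = 1.0 - q
        elif fam == FAM_CI:
            vA = pA * V_LUCKY + (1.0 - pA) * V_UNLUCKY
            vB = (1.0 - pA) * V_LUCKY + pA * V_UNLUCKY
        else:
            vA = bA
            vB = bB

        eta = bias + beta * (vA - vB)
        if choices[t] == 0:
            ll += -_softplus(-eta)
        else:
            ll += -_softplus(eta)

        x = outcomes[t]
        if fam == FAM_RW1A or fam == FAM_RW2A:
            if choices[t] == 0:
                bA += p * (x - bA)
            else:
                bB += p * (x - bB)
        elif fam == FAM_RB1H or fam == FAM_RB2H:
            b = bA if choices[t] == 0 else bB
            total_var = s2 / (1.0 - tau)
            dens = math.exp(-0.5 * (x - b) * (x - b) / total_var) * inv_sqrt2pi / math.sqrt(total_var)
            omega = p / (p + (1.0 - p) * dens)
            alpha_t = omega + (1.0 - omega) * tau
            delta = x - b
            b = b + alpha_t * delta
            nu = (omega * s2 + (1.0 - omega) * tau * s2
                  + omega * (1.0 - omega) * (delta * (1.0 - tau)) ** 2)
            tau = nu / (nu + s2)
            if choices[t] == 0:
                bA = b
            else:
                bB = b
        elif fam == FAM_CI:
            pred = (1.0 - p) * pA + p * (1.0 - pA)
            if choices[t] == 0:
                muA = V_LUCKY   # context A-lucky, chose A
                muB = V_UNLUCKY  # context B-lucky, chose A
            else:
                muA = V_UNLUCKY
                muB = V_LUCKY
            likA = math.exp(-0.5 * (x - muA) * (x - muA) / s2)
            likB = math.exp(-0.5 * (x - muB) * (x - muB) / s2)
            num = pred * likA
            den = num + (1.0 - pred) * likB
            if den > 1e-300:
                pA = num / den
            else:
                pA = pred
        else:  # FAM_RW1Q
            evidence = x if choices[t] == 0 else 1.0 - x
            q += p * (evidence - q)
    return ll


@njit(cache=True)
def batch_loglik(fam, params, sigma_n, choices, outcomes, env_high, ptr, out):
    """Per-subject log-likelihoods for stacked sequences.

    ``params``: (n_subjects, 4) columns p_low, p_high, beta, bias on the
    natural scale; ``ptr``: CSR-style offsets of each subject's span in the
    stacked arrays; results written into ``out``.
    """
    n_subj = ptr.shape[0] - 1
    for s in range(n_subj):
        lo, hi = ptr[s], ptr[s + 1]
        out[s] = subject_loglik(
            fam, params[s, 0], params[s, 1], params[s, 2], params[s, 3],
            sigma_n, choices[lo:hi], outcomes[lo:hi], env_high[lo:hi],
        )
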