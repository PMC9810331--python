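"""Online learning filters for the reversal bandit.

Each filter maps one subject's choice/outcome sequence to trial-wise latent
series: per-deck value estimates, and for the reduced Bayesian (RB) family
the uncertainty quantities that drive an adaptive learning rate —

* relative uncertainty (RU, ``tau``): the fraction of total predictive
  variance attributable to imprecision in the value estimate itself,
* changepoint probability (CPP, ``omega``): the posterior probability that
  the latest outcome reflects a reversal rather than outcome noise,
* the effective learning rate ``alpha_t = omega + (1 - omega) * tau``.

Families
--------
RW1A / RW2A
    Rescorla-Wagner delta rule with a fixed learning rate (one shared, or
    one per volatility environment). Only the chosen deck is updated.
RB1H / RB2H
    Reduced Bayesian changepoint learner: a delta rule whose learning rate
    is modulated trial-by-trial by CPP and RU, parameterized by a hazard
    rate H (one shared, or one per environment) giving the assumed per-trial
    reversal probability.
CI
    Contextual inference: a two-state hidden Markov filter over which deck
    is currently lucky, with switch probability H; deck values are
    posterior-weighted design means rather than learned averages.
RW1Q
    Delta rule on a single "deck A is lucky" estimate, updated with signed
    evidence from whichever deck was chosen.

All internal values are in [0, 1] dollars; cents appear only at I/O. The
belief state resets at every environment-block boundary (new casino, fresh
luckiness assignment), and environment-indexed parameters switch there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

FAMILIES = ("RW1A", "RW2A", "RB1H", "RB2H", "CI", "RW1Q")
FAMILY_IDS = {f: i for i, f in enumerate(FAMILIES)}

#: SD of outcomes around a deck's expected value under the design's outcome
#: pools (same for the lucky and unlucky pool by symmetry), dollar units.
DESIGN_SIGMA_N = 0.2883

#: design expected values, dollar units
V_LUCKY, V_UNLUCKY = 0.63, 0.37


def design_outcome_sd(pool_counts=(2, 4, 7, 8, 11, 8)) -> float:
    """Outcome SD implied by a lucky-pool composition (dollars)."""
    vals = np.repeat(np.arange(0.0, 1.2, 0.2), pool_counts)
    return float(vals.std())


@dataclass
class BeliefState:
    """Latent state of an RB/RW-style learner at one trial."""

    B: dict[str, float] = field(default_factory=lambda: {"A": 0.5, "B": 0.5})
    tau: float = 0.5
    omega: float = 0.0
    alpha_t: float = 0.0
    delta: float = 0.0
    H: float = 0.1
    sigma_n: float = DESIGN_SIGMA_N

    @property
    def ape(self) -> float:
        return abs(self.delta)


def rw_step(B: dict[str, float], chosen: str, outcome: float, alpha: float) -> tuple[dict, float]:
    """Delta-rule update of the chosen deck; returns (new values, delta)."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"learning rate {alpha} outside [0, 1]")
    if not 0.0 <= outcome <= 1.0:
        raise ValueError(f"outcome {outcome} outside the normalized [0, 1] range")
    delta = outcome - B[chosen]
    new = dict(B)
    new[chosen] = B[chosen] + alpha * delta
    return new, delta


def compute_cpp(b: float, tau: float, outcome: float, H: float, sigma_n: float) -> float:
    """Changepoint probability: hazard-weighted density ratio.

    Omega = H * U / (H * U + (1 - H) * N(outcome | b, sigma_n^2 + sigma_est^2))
    with U the uniform density over the unit outcome range and
    sigma_est^2 = sigma_n^2 * tau / (1 - tau), so the predictive variance
    under "no change" is sigma_n^2 / (1 - tau).
    """
    if sigma_n <= 0:
        raise ValueError("sigma_n must be positive")
    if not 0.0 < H < 1.0:
        if H == 0.0:
            return 0.0
        if H == 1.0:
            return 1.0
        raise ValueError("hazard rate must lie in [0, 1]")
    total_var = sigma_n * sigma_n / (1.0 - tau)
    dens = math.exp(-0.5 * (outcome - b) ** 2 / total_var) / math.sqrt(2 * math.pi * total_var)
    u = 1.0  # uniform density on [0, 1]
    return H * u / (H * u + (1.0 - H) * dens)


def compute_learning_rate(omega: float, tau: float) -> float:
    """Effective learning rate alpha_t = omega + (1 - omega) * tau."""
    return omega + (1.0 - omega) * tau


def rb_step(state: BeliefState, chosen: str, outcome: float) -> BeliefState:
    """One reduced Bayesian update on the chosen deck.

    Composes the changepoint probability, the adaptive learning rate, the
    delta-rule value update, and the relative-uncertainty recursion that
    mixes change and no-change posterior variances:

    nu = omega*s2 + (1-omega)*tau*s2 + omega*(1-omega)*(delta*(1-tau))^2
    tau' = nu / (nu + s2),  s2 = sigma_n^2.
    """
    if not 0.0 <= outcome <= 1.0:
        raise ValueError(f"outcome {outcome} outside the normalized [0, 1] range")
    b = state.B[chosen]
    omega = compute_cpp(b, state.tau, outcome, state.H, state.sigma_n)
    alpha_t = compute_learning_rate(omega, state.tau)
    delta = outcome - b
    newB = dict(state.B)
    newB[chosen] = b + alpha_t * delta
    s2 = state.sigma_n * state.sigma_n
    nu = (
        omega * s2
        + (1.0 - omega) * state.tau * s2
        + omega * (1.0 - omega) * (delta * (1.0 - state.tau)) ** 2
    )
    tau_new = nu / (nu + s2)
    return BeliefState(
        B=newB, tau=tau_new, omega=omega, alpha_t=alpha_t, delta=delta,
        H=state.H, sigma_n=state.sigma_n,
    )


def ci_step(
    posterior: np.ndarray,
    chosen: str,
    outcome: float,
    H: float,
    sigma_n: float = DESIGN_SIGMA_N,
    means: tuple[float, float] = (V_LUCKY, V_UNLUCKY),
    floor: float = 1e-12,
) -> np.ndarray:
    """Forward step of the two-context HMM.

    ``posterior`` is (p(A lucky), p(B lucky)). Transition with switch
    probability H, then multiply by the Gaussian outcome likelihood of the
    chosen deck under each context and renormalize. A numerical floor
    guards against zero total likelihood.
    """
    p = np.asarray(posterior, dtype=float)
    pred = np.array([(1 - H) * p[0] + H * p[1], H * p[0] + (1 - H) * p[1]])
    mu_chosen = np.array(means) if chosen == "A" else np.array(means[::-1])
    lik = np.exp(-0.5 * ((outcome - mu_chosen) / sigma_n) ** 2) / (
        sigma_n * math.sqrt(2 * math.pi)
    )
    post = pred * lik
    tot = post.sum()
    if tot <= floor:
        post = pred  # degenerate likelihood: fall back on the prediction
        tot = post.sum()
    return post / tot


def rw1q_step(q: float, chosen: str, outcome: float, alpha: float) -> float:
    """Single-estimate delta rule: q tracks 'deck A is lucky' in value units.

    Evidence is the outcome itself when deck A was chosen and its complement
    when deck B was chosen; deck values derive as (q, 1 - q).
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"learning rate {alpha} outside [0, 1]")
    evidence = outcome if chosen == "A" else 1.0 - outcome
    return q + alpha * (evidence - q)


def choice_likelihood(beta_temp: float, b_a: float, b_b: float, bias: float = 0.0) -> float:
    """Probability of choosing deck A: logistic of beta * (B_A - B_B) + bias."""
    if beta_temp <= 0:
        raise ValueError("inverse temperature must be positive")
    x = bias + beta_temp * (b_a - b_b)
    return 1.0 / (1.0 + math.exp(-x))


@dataclass(frozen=True)
class ModelSpec:
    """A learning-model family plus its parameters for one subject.

    ``params`` holds the family's learning parameter(s): ``alpha`` or
    ``(alpha_low, alpha_high)`` for RW families, ``h`` or
    ``(h_low, h_high)`` for RB families / CI.
    """

    family: str
    params: tuple[float, ...]
    beta_temp: float = 5.0
    bias: float = 0.0
    sigma_n: float = DESIGN_SIGMA_N

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        need = 2 if self.family in ("RW2A", "RB2H") else 1
        if len(self.params) != need:
            raise ValueError(f"{self.family} takes {need} learning parameter(s)")
        if self.beta_temp <= 0:
            raise ValueError("beta_temp must be positive")

    def param_for_env(self, env_code: float) -> float:
        if len(self.params) == 2:
            return self.params[1] if env_code > 0 else self.params[0]
        return self.params[0]


class LearningFilterEstimator(BaseEstimator, TransformerMixin):
    """sklearn-style wrapper: deterministic transform of one subject's trials.

    Parameters are the subject's learning parameters; ``transform`` takes a
    trial table (columns ``env_code``, ``choice_deck``, ``outcome_cents``,
    plus ``trial_index``) and returns the trial-wise latent series.
    """

    def __init__(self, family: str = "RB2H", params: tuple[float, ...] = (0.1, 0.1),
                 beta_temp: float = 5.0, bias: float = 0.0,
                 sigma_n: float = DESIGN_SIGMA_N):
        self.family = family
        self.params = params
        self.beta_temp = beta_temp
        self.bias = bias
        self.sigma_n = sigma_n

    def fit(self, X=None, y=None):
        self.spec_ = ModelSpec(self.family, tuple(self.params), self.beta_temp,
                               self.bias, self.sigma_n)
        return self

    def transform(self, trials: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "spec_"):
            self.fit()
        return run_filter(self.spec_, trials)


def run_filter(spec: ModelSpec, trials: pd.DataFrame) -> pd.DataFrame:
    """Run a learning filter over one subject's trial table.

    The series are aligned to choice time: ``deckval_A/B`` and ``ru`` are
    the learner's state *before* trial t's outcome (what could have driven
    the choice), while ``cpp``, ``ape``, ``lr`` and ``ru_post`` derive from
    trial t's outcome. State resets and environment-indexed parameters
    switch at block boundaries (detected by a change in ``env_code`` or a
    restart of ``trial_index``).
    """
    env = trials["env_code"].to_numpy(dtype=float)
    choices = trials["choice_deck"].to_numpy()
    outcomes = trials["outcome_cents"].to_numpy(dtype=float) / 100.0
    tidx = trials["trial_index"].to_numpy()
    n = len(trials)

    out = {k: np.full(n, np.nan) for k in
           ("deckval_A", "deckval_B", "ru", "cpp", "ape", "lr", "ru_post", "p_choose_A")}

    state: BeliefState | None = None
    ci_post: np.ndarray | None = None
    q = 0.5
    for t in range(n):
        if t == 0 or env[t] != env[t - 1]:
            state = BeliefState(H=spec.param_for_env(env[t]), sigma_n=spec.sigma_n)
            ci_post = np.array([0.5, 0.5])
            q = 0.5
        chosen = choices[t]
        x = outcomes[t]
        fam = spec.family
        if fam in ("RW1A", "RW2A"):
            bA, bB = state.B["A"], state.B["B"]
            out["deckval_A"][t], out["deckval_B"][t] = bA, bB
            alpha = spec.param_for_env(env[t])
            newB, delta = rw_step(state.B, chosen, x, alpha)
            state.B = newB
            out["ape"][t] = abs(delta)
            out["lr"][t] = alpha
        elif fam in ("RB1H", "RB2H"):
            state.H = spec.param_for_env(env[t])
            bA, bB = state.B["A"], state.B["B"]
            out["deckval_A"][t], out["deckval_B"][t] = bA, bB
            out["ru"][t] = state.tau
            state = rb_step(state, chosen, x)
            out["cpp"][t] = state.omega
            out["ape"][t] = state.ape
            out["lr"][t] = state.alpha_t
            out["ru_post"][t] = state.tau
        elif fam == "CI":
            bA = ci_post[0] * V_LUCKY + ci_post[1] * V_UNLUCKY
            bB = ci_post[1] * V_LUCKY + ci_post[0] * V_UNLUCKY
            out["deckval_A"][t], out["deckval_B"][t] = bA, bB
            ape = abs(x - (bA if chosen == "A" else bB))
            ci_post = ci_step(ci_post, chosen, x, spec.param_for_env(env[t]), spec.sigma_n)
            out["ape"][t] = ape
        elif fam == "RW1Q":
            bA, bB = q, 1.0 - q
            out["deckval_A"][t], out["deckval_B"][t] = bA, bB
            evidence = x if chosen == "A" else 1.0 - x
            out["ape"][t] = abs(evidence - q)
            alpha = spec.param_for_env(env[t])
            q = rw1q_step(q, chosen, x, alpha)
            out["lr"][t] = alpha
        else:  # pragma: no cover
            raise ValueError(f"unknown family {fam!r}")
        out["p_choose_A"][t] = choice_likelihood(
            spec.beta_temp, out["deckval_A"][t], out["deckval_B"][t], spec.bias
        )

    res = pd.DataFrame(out, index=trials.index)
    res.insert(0, "trial_index", tidx)
    if "subject_id" in trials.columns:
        res.insert(0, "subject_id", trials["subject_id"].to_numpy())
    if "task" in trials.columns:
        res.insert(1, "task", trials["task"].to_numpy())
    return res
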