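"""Synthetic subjects with known ground truth.

An agent couples three components:

* an online learning filter (reduced Bayesian by default) tracking deck
  values and relative uncertainty (RU) exactly as the analysis models do;
* a combined-choice policy mirroring the combined choice model: the choice
  logit sums a deck bias, the learned deck-value difference, an old-object
  bias, episodic object value, and its interactions with environment and
  with RU — so the uncertainty-arbitration weight exists in the generative
  ground truth and can be recovered;
* an imperfect episodic memory: an old object is recognized with
  probability ``p_recognize``, and its remembered value is perturbed by
  Gaussian noise. Objects engaged episodically during the task get a
  recognition boost and lower value noise at the subsequent-memory test,
  which is what produces the choice-type/memory correlations on synthetic
  cohorts.

Reaction times are log-normal with additive effects of deck switching,
uncertainty, and episodic engagement on the log scale.

The generative covariates are deliberately unstandardized (raw dollar and
probability units); the fitting stage z-scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import tasks
from .filters import DESIGN_SIGMA_N, BeliefState, ModelSpec, rb_step, rw_step
from .tasks import DECKS, MemoryTestSet, Session, SessionConfig, TrialContext

#: reference scale for RU in the generative choice logit: the typical mean
#: and SD of the reduced Bayesian filter's relative uncertainty under the
#: task design (hazards 0.05/0.10), so that ``w_oldval_ru`` is a per-SD
#: weight comparable with the other choice weights. The fitting stage
#: z-scores its own covariates and is unaffected by this convention.
RU_CENTER = 0.33
RU_SCALE = 0.09

#: design-typical SD of the signed coded old-object value on old trials
#: (payouts near-uniform on the 20-cent grid, sign by deck). Together with
#: RU_SCALE this puts the uncertainty-arbitration weight ``w_oldval_ru`` in
#: the same standard units in which the fitted combined choice model
#: reports its OldVal x RU coefficient.
OLDVAL_SCALE = 0.31


@dataclass(frozen=True)
class AgentParams:
    """Ground-truth generative parameters of one synthetic subject."""

    learning: ModelSpec = field(
        default_factory=lambda: ModelSpec("RB2H", (0.05, 0.10), beta_temp=8.0)
    )
    # combined-choice weights (generative, unstandardized scale)
    w0: float = 0.0          # deck bias
    w_deck: float = 4.0      # per dollar of value difference
    w_old: float = 0.3       # old-object bias (on the +/-0.5 Old code)
    w_oldval: float = 3.0    # per unit of the +/-0.5 OldVal code
    w_oldval_env: float = 1.0
    w_oldval_ru: float = 1.0  # standard units (per design-SD of OldVal x RU)
    # episodic fidelity
    p_recognize: float = 0.8
    value_noise_sd: float = 15.0  # cents
    fa_rate: float = 0.15
    recog_boost: float = 1.0      # logit-scale hit boost for engaged objects
    engaged_noise_factor: float = 0.5
    # reaction times (log-normal, ms)
    rt_base_ms: float = 750.0
    rt_switch_effect: float = 0.10
    rt_ru_effect: float = 0.04   # per SD of relative uncertainty
    rt_episodic_effect: float = 0.08
    rt_noise_sd: float = 0.20

    def validate(self) -> None:
        if not 0.0 <= self.p_recognize <= 1.0:
            raise ValueError("p_recognize must lie in [0, 1]")
        if not 0.0 <= self.fa_rate <= 1.0:
            raise ValueError("fa_rate must lie in [0, 1]")
        if min(self.value_noise_sd, self.rt_noise_sd) < 0:
            raise ValueError("noise scales must be non-negative")


class Agent:
    """A simulated subject implementing the session policy protocol."""

    def __init__(self, params: AgentParams, rng: np.random.Generator):
        params.validate()
        self.params = params
        self.rng = rng
        self.engaged: dict[str, bool] = {}  # object id -> episodically engaged
        self._state: BeliefState | None = None
        self._rw_B: dict[str, float] = {}
        self._q = 0.5
        self._prev_choice: str | None = None
        self._env = 0.0

    # -- policy protocol ----------------------------------------------------
    def start_task(self, task: str, env_order) -> None:
        self._prev_choice = None
        self._reset_state(env_order[0].env_code)

    def _reset_state(self, env_code: float) -> None:
        spec = self.params.learning
        self._env = env_code
        self._state = BeliefState(H=spec.param_for_env(env_code), sigma_n=spec.sigma_n)
        self._rw_B = {"A": 0.5, "B": 0.5}
        self._q = 0.5

    def _deck_values(self) -> tuple[float, float]:
        fam = self.params.learning.family
        if fam in ("RB1H", "RB2H"):
            return self._state.B["A"], self._state.B["B"]
        if fam in ("RW1A", "RW2A"):
            return self._rw_B["A"], self._rw_B["B"]
        if fam == "RW1Q":
            return self._q, 1.0 - self._q
        raise ValueError(f"agents do not simulate family {fam!r}")

    @property
    def ru(self) -> float:
        return self._state.tau

    def choose(self, ctx: TrialContext) -> tuple[str, float]:
        p = self.params
        if ctx.is_block_start and ctx.env_code != self._env:
            self._reset_state(ctx.env_code)
        vA, vB = self._deck_values()
        ru_c = (self.ru - RU_CENTER) / RU_SCALE

        old_code = 0.0
        oldval_code = 0.0
        episodic = False
        if ctx.old_object_deck is not None:
            if self.rng.random() < p.p_recognize:
                episodic = True
                self.engaged[ctx.old_object_id] = True
                sign = 1.0 if ctx.old_object_deck == "A" else -1.0
                old_code = 0.5 * sign  # +/-0.5 toward the old object's deck
                remembered = ctx.old_object_value_cents + p.value_noise_sd * self.rng.standard_normal()
                # +/-0.5 when worth $1/$0 on deck A (resp. $0/$1 on deck B)
                oldval_code = sign * (np.clip(remembered, 0, 100) / 100.0 - 0.5)
            else:
                self.engaged.setdefault(ctx.old_object_id, False)

        eta = (
            p.w0
            + p.w_deck * (vA - vB)
            + p.w_old * old_code
            + p.w_oldval * oldval_code
            + p.w_oldval_env * oldval_code * ctx.env_code
            + p.w_oldval_ru * (oldval_code / OLDVAL_SCALE) * ru_c
        )
        choice = "A" if self.rng.random() < expit(eta) else "B"

        switch = 0.5 if (self._prev_choice is not None and choice != self._prev_choice) else -0.5
        log_rt = (
            np.log(p.rt_base_ms)
            + p.rt_switch_effect * switch
            + p.rt_ru_effect * ru_c
            + p.rt_episodic_effect * (0.5 if episodic else -0.5)
            + p.rt_noise_sd * self.rng.standard_normal()
        )
        self._prev_choice = choice
        return choice, float(np.exp(log_rt))

    def observe(self, ctx: TrialContext, choice_deck: str, outcome_cents: int) -> None:
        x = outcome_cents / 100.0
        spec = self.params.learning
        fam = spec.family
        if fam in ("RB1H", "RB2H"):
            self._state.H = spec.param_for_env(ctx.env_code)
            self._state = rb_step(self._state, choice_deck, x)
        elif fam in ("RW1A", "RW2A"):
            self._rw_B, _ = rw_step(self._rw_B, choice_deck, x, spec.param_for_env(ctx.env_code))
        elif fam == "RW1Q":
            evidence = x if choice_deck == "A" else 1.0 - x
            self._q += spec.param_for_env(ctx.env_code) * (evidence - self._q)


def simulate_memory_responses(
    agent: Agent, memory_test: MemoryTestSet, rng: np.random.Generator
) -> MemoryTestSet:
    """Fill in recognition / chose / value responses for one agent.

    Old probes are hits with probability ``p_recognize`` (boosted on the
    logit scale for objects the agent engaged episodically in the task);
    new probes are false alarms with probability ``fa_rate``. Remembered
    values are the true value plus Gaussian noise, snapped to the 20-cent
    grid and clipped to [0, 100].
    """
    p = agent.params
    for probe in memory_test.probes:
        if probe.is_old:
            engaged = agent.engaged.get(probe.object_id, False)
            p_hit = float(expit(logit(np.clip(p.p_recognize, 1e-6, 1 - 1e-6))
                                + (p.recog_boost if engaged else 0.0)))
            if rng.random() < p_hit:
                probe.recog_response = "Definitely Old" if rng.random() < 0.5 else "Probably Old"
                probe.chose_response = True
                noise = p.value_noise_sd * (p.engaged_noise_factor if engaged else 1.0)
                raw = probe.true_value_cents + noise * rng.standard_normal()
                probe.value_response_cents = int(np.clip(np.round(raw / 20.0) * 20.0, 0, 100))
            else:
                probe.recog_response = rng.choice(
                    ["Definitely New", "Probably New", "Don't Know"], p=[0.4, 0.4, 0.2]
                )
        else:
            if rng.random() < p.fa_rate:
                probe.recog_response = "Probably Old"
                probe.chose_response = bool(rng.random() < 0.5)
                if probe.chose_response:
                    probe.value_response_cents = int(rng.choice(tasks.OUTCOME_VALUES))
            else:
                probe.recog_response = rng.choice(
                    ["Definitely New", "Probably New", "Don't Know"], p=[0.4, 0.4, 0.2]
                )
    return memory_test


#: transformed-scale sampling for bounded fields of AgentParams
_TRANSFORMS = {
    "p_recognize": "logit",
    "fa_rate": "logit",
}


@dataclass(frozen=True)
class CohortSpec:
    """Group-level generative distributions for a synthetic cohort.

    Each :class:`AgentParams` scalar field varies across subjects as an
    independent Gaussian around the value in ``mean`` with SD from ``sd``
    (on the logit scale for probability fields). Learning parameters vary
    on the logit scale with SDs ``h_sd`` / ``temp_sd``. Counterbalancing
    alternates with subject parity.
    """

    n_subjects: int = 40
    mean: AgentParams = field(default_factory=AgentParams)
    sd: dict = field(default_factory=lambda: {
        "w_deck": 0.5, "w_old": 0.1, "w_oldval": 0.5,
        "w_oldval_env": 0.2, "w_oldval_ru": 0.2,
        "p_recognize": 0.7, "value_noise_sd": 3.0,
    })
    h_sd: float = 0.25   # logit-scale SD of hazard/learning-rate params
    temp_sd: float = 0.2  # log-scale SD of the inverse temperature
    session: SessionConfig = field(default_factory=SessionConfig)

    def draw_params(self, rng: np.random.Generator) -> AgentParams:
        kw = {}
        for name, sd in self.sd.items():
            base = getattr(self.mean, name)
            if _TRANSFORMS.get(name) == "logit":
                val = float(expit(logit(np.clip(base, 1e-6, 1 - 1e-6))
                                  + sd * rng.standard_normal()))
            else:
                val = float(base + sd * rng.standard_normal())
            if name.endswith("_sd") or name in ("rt_base_ms",):
                val = max(val, 0.0)
            kw[name] = val
        spec = self.mean.learning
        learn = tuple(
            float(expit(logit(v) + self.h_sd * rng.standard_normal())) for v in spec.params
        )
        beta = float(np.exp(np.log(spec.beta_temp) + self.temp_sd * rng.standard_normal()))
        kw["learning"] = replace(spec, params=learn, beta_temp=beta)
        return replace(self.mean, **kw)


@dataclass
class SimulatedCohort:
    """trials.csv / memory.csv frames plus the ground-truth parameter table."""

    trials: pd.DataFrame
    memory: pd.DataFrame
    ground_truth: pd.DataFrame
    sessions: list[Session]
    agents: list[Agent]


def simulate_cohort(cohort: CohortSpec, seed: int | np.random.SeedSequence) -> SimulatedCohort:
    """Simulate a full synthetic cohort (both tasks + memory test)."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    trial_frames, memory_frames, gt_rows, sessions, agent_list = [], [], [], [], []
    for i, subj_ss in enumerate(ss.spawn(cohort.n_subjects)):
        s_param, s_agent, s_sess, s_mem = subj_ss.spawn(4)
        sid = f"s{i:03d}"
        params = cohort.draw_params(np.random.default_rng(s_param))
        agent = Agent(params, np.random.default_rng(s_agent))
        scfg = replace(cohort.session, subject_id=sid, counterbalance=i % 2)
        session = tasks.generate_session(scfg, agent, s_sess)
        mem_rng = np.random.default_rng(s_mem)
        memory = tasks.generate_memory_test(session, mem_rng)
        simulate_memory_responses(agent, memory, mem_rng)

        trial_frames.append(session.full_frame())
        memory_frames.append(memory.frame())
        row = {"subject_id": sid, "counterbalance": i % 2}
        spec = params.learning
        row["family"] = spec.family
        for j, name in enumerate(
            ["h_low", "h_high"] if len(spec.params) == 2 else ["h"]
        ):
            row[name] = spec.params[j]
        row["beta_temp"] = spec.beta_temp
        for f in ("w0", "w_deck", "w_old", "w_oldval", "w_oldval_env", "w_oldval_ru",
                  "p_recognize", "value_noise_sd", "fa_rate", "recog_boost",
                  "engaged_noise_factor", "rt_base_ms", "rt_switch_effect",
                  "rt_ru_effect", "rt_episodic_effect", "rt_noise_sd"):
            row[f] = getattr(params, f)
        gt_rows.append(row)
        sessions.append(session)
        agent_list.append(agent)

    return SimulatedCohort(
        trials=pd.concat(trial_frames, ignore_index=True),
        memory=pd.concat(memory_frames, ignore_index=True),
        ground_truth=pd.DataFrame(gt_rows),
        sessions=sessions,
        agents=agent_list,
    )
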