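"""Generative structure of the two-environment reversal-bandit tasks.

Two colored decks of cards pay out 0-100 cents (20-cent grid). At any moment
one deck is "lucky" (expected value 63 cents) and the other "unlucky"
(37 cents); which deck is lucky reverses at unsignaled changepoints. Subjects
play a low-volatility block (8 bouts of 15-24 trials) and a high-volatility
block (16 bouts of 6-14 trials), 160 trials each.

In the combined task every card additionally carries a trial-unique object.
An object that was chosen exactly once may reappear 9-30 trials later on its
original deck, worth exactly what it paid the first time, so that episodic
memory for a single event competes with the incrementally learned deck value.
Reappearance uses a three-step sampler (outcome-list matching, incongruency
preference, running-mean control) designed to keep the mean shown old-object
value near 50 cents and decorrelated from deck value.

This module generates reversal schedules, outcome lists, full sessions driven
by a choice policy, and the 80-probe subsequent-memory test set.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DECKS = ("A", "B")

#: payout grid in cents
OUTCOME_VALUES = (0, 20, 40, 60, 80, 100)

#: multiplicity of each payout value in the lucky deck's 40-outcome pool;
#: chosen so the pool mean is exactly 63 cents. The unlucky pool is its
#: 100-cent complement (mean exactly 37 cents).
LUCKY_POOL_COUNTS = (2, 4, 7, 8, 11, 8)


class ConfigurationError(ValueError):
    """A task configuration violates its feasibility constraints."""


@dataclass(frozen=True)
class EnvironmentConfig:
    """One volatility environment: a 160-trial block of reversal bouts."""

    volatility_label: str  # "low" or "high"
    n_trials: int = 160
    n_bouts: int = 8
    bout_min: int = 15
    bout_max: int = 24
    env_code: float = -0.5

    def validate(self) -> None:
        if self.volatility_label not in ("low", "high"):
            raise ConfigurationError(f"unknown volatility label {self.volatility_label!r}")
        if self.env_code not in (-0.5, 0.5):
            raise ConfigurationError("env_code must be -0.5 (low) or +0.5 (high)")
        if self.bout_min > self.bout_max:
            raise ConfigurationError("bout_min must not exceed bout_max")
        if not self.n_bouts * self.bout_min <= self.n_trials <= self.n_bouts * self.bout_max:
            raise ConfigurationError(
                f"{self.n_bouts} bouts of {self.bout_min}-{self.bout_max} trials "
                f"cannot sum to {self.n_trials}"
            )


LOW_VOLATILITY = EnvironmentConfig("low", 160, 8, 15, 24, -0.5)
HIGH_VOLATILITY = EnvironmentConfig("high", 160, 16, 6, 14, +0.5)


@dataclass(frozen=True)
class ReversalSchedule:
    """Bout lengths and per-trial deck luckiness for one environment block.

    ``reversal_trials`` holds every bout onset (0-based within the block),
    including trial 0: the luckiness (re)assignment at block onset counts as
    one reversal event, so the number of reversals equals the number of
    bouts. Reversal-aligned analyses use the interior boundaries only
    (:attr:`interior_reversals`).
    """

    bout_lengths: tuple[int, ...]
    reversal_trials: tuple[int, ...]
    lucky_deck_by_trial: tuple[str, ...]

    @property
    def interior_reversals(self) -> tuple[int, ...]:
        return self.reversal_trials[1:]


def generate_reversal_schedule(
    cfg: EnvironmentConfig, rng: np.random.Generator, first_lucky: str | None = None
) -> ReversalSchedule:
    """Draw bout lengths uniformly in [bout_min, bout_max], repair the sum.

    Lengths are drawn independently, then nudged by +/-1 steps (respecting
    the bounds) until they sum to ``cfg.n_trials``, and finally shuffled.
    Deck luckiness alternates at every bout boundary.
    """
    cfg.validate()
    lengths = rng.integers(cfg.bout_min, cfg.bout_max + 1, size=cfg.n_bouts)
    deficit = cfg.n_trials - int(lengths.sum())
    step = 1 if deficit > 0 else -1
    while deficit != 0:
        adjustable = np.flatnonzero(
            (lengths + step >= cfg.bout_min) & (lengths + step <= cfg.bout_max)
        )
        idx = rng.choice(adjustable)
        lengths[idx] += step
        deficit -= step
    rng.shuffle(lengths)

    if first_lucky is None:
        first_lucky = DECKS[rng.integers(2)]
    onsets = np.concatenate([[0], np.cumsum(lengths)[:-1]])
    lucky = []
    for i, n in enumerate(lengths):
        deck = first_lucky if i % 2 == 0 else _other(first_lucky)
        lucky.extend([deck] * int(n))
    return ReversalSchedule(
        bout_lengths=tuple(int(x) for x in lengths),
        reversal_trials=tuple(int(x) for x in onsets),
        lucky_deck_by_trial=tuple(lucky),
    )


def _other(deck: str) -> str:
    return "B" if deck == "A" else "A"


def make_pool_values(pool_counts: tuple[int, ...] = LUCKY_POOL_COUNTS, lucky: bool = True) -> list[int]:
    """Expand pool multiplicities into a list of payout values (cents)."""
    counts = pool_counts if lucky else pool_counts[::-1]
    vals: list[int] = []
    for v, c in zip(OUTCOME_VALUES, counts):
        vals.extend([v] * c)
    return vals


def validate_pool(pool_counts: tuple[int, ...], target_mean: float = 63.0) -> None:
    vals = make_pool_values(pool_counts, lucky=True)
    if not vals:
        raise ConfigurationError("empty outcome pool")
    mean = sum(vals) / len(vals)
    if abs(mean - target_mean) > 1e-12:
        raise ConfigurationError(
            f"pool composition {pool_counts} has mean {mean:.4f}, needs exactly {target_mean}"
        )


class DeckOutcomeList:
    """Without-replacement outcome pools for both decks.

    Each deck holds a pre-shuffled copy of the 40-value pool matching its
    current luckiness. Pools are rebuilt (with roles swapped as needed) at
    every reversal. Choosing a reappearing old card consumes the matching
    outcome from its deck's pool, which is what keeps old-object payouts
    from skewing the deck's realized value.
    """

    def __init__(
        self,
        rng: np.random.Generator,
        pool_counts: tuple[int, ...] = LUCKY_POOL_COUNTS,
    ):
        validate_pool(pool_counts)
        self.pool_counts = pool_counts
        self.rng = rng
        self.remaining: dict[str, list[int]] = {d: [] for d in DECKS}

    def repopulate(self, lucky_deck: str) -> None:
        for deck in DECKS:
            vals = make_pool_values(self.pool_counts, lucky=(deck == lucky_deck))
            self.rng.shuffle(vals)
            self.remaining[deck] = vals

    def draw(self, deck: str) -> int:
        if not self.remaining[deck]:
            raise ConfigurationError("outcome pool exhausted within a bout")
        return self.remaining[deck].pop()

    def consume_value(self, deck: str, value: int) -> None:
        self.remaining[deck].remove(value)

    def contains(self, deck: str, value: int) -> bool:
        return value in self.remaining[deck]


@dataclass
class ObjectRecord:
    """Lifecycle of one trial-unique object across a session."""

    object_id: str
    deck: str
    env_code: float
    first_trial: int  # session-wide trial counter at first showing
    value_cents: int | None = None  # fixed at first choice
    first_choice_trial: int | None = None
    chosen_count: int = 0
    shown_count: int = 1
    reshown: bool = False


@dataclass
class TrialRecord:
    subject_id: str
    task: str  # "deck_only" or "deck_memory"
    env_code: float
    trial_index: int  # 0-based within task
    is_reversal: bool
    object_id: str | None
    object_is_old: bool
    object_value_cents: int | None
    object_deck: str | None
    choice_deck: str
    outcome_cents: int
    rt_ms: float
    lucky_deck: str = ""
    within_block_index: int = 0
    chosen_object_id: str | None = None  # object on the chosen deck


@dataclass
class Session:
    """All generated material for one subject."""

    subject_id: str
    trials: list[TrialRecord]
    objects: dict[str, ObjectRecord]
    schedules: dict[tuple[str, float], ReversalSchedule]
    counterbalance: int
    n_eligible_trials: int = 0
    n_gate_fired: int = 0

    def trials_frame(self) -> pd.DataFrame:
        cols = [
            "subject_id", "task", "env_code", "trial_index", "is_reversal",
            "object_id", "object_is_old", "object_value_cents", "object_deck",
            "choice_deck", "outcome_cents", "rt_ms",
        ]
        df = pd.DataFrame([t.__dict__ for t in self.trials])
        return df[cols]

    def full_frame(self) -> pd.DataFrame:
        """Trial table including generator-internal columns (true luckiness)."""
        return pd.DataFrame([t.__dict__ for t in self.trials])


@dataclass
class TrialContext:
    """What a choice policy sees before choosing on one trial."""

    task: str
    env_code: float
    trial_index: int
    within_block_index: int
    is_block_start: bool
    old_object_deck: str | None
    old_object_value_cents: int | None
    old_object_id: str | None


class RandomPolicy:
    """Structure-only chooser: picks either deck with probability 1/2."""

    def __init__(self, rng: np.random.Generator, rt_base_ms: float = 800.0):
        self.rng = rng
        self.rt_base_ms = rt_base_ms

    def start_task(self, task: str, env_order: list[EnvironmentConfig]) -> None:
        pass

    def choose(self, ctx: TrialContext) -> tuple[str, float]:
        deck = DECKS[self.rng.integers(2)]
        rt = float(self.rt_base_ms * np.exp(0.2 * self.rng.standard_normal()))
        return deck, rt

    def observe(self, ctx: TrialContext, choice_deck: str, outcome_cents: int) -> None:
        pass


@dataclass(frozen=True)
class SessionConfig:
    """Session-level generation settings."""

    subject_id: str = "s000"
    gate_probability: float = 0.6
    lag_min: int = 9
    lag_max: int = 30
    pool_counts: tuple[int, ...] = LUCKY_POOL_COUNTS
    low: EnvironmentConfig = LOW_VOLATILITY
    high: EnvironmentConfig = HIGH_VOLATILITY
    counterbalance: int = 0  # combined task: 0 = low->high, 1 = high->low
    include_deck_only: bool = True


def eligible_old_candidates(
    objects: dict[str, ObjectRecord],
    pools: DeckOutcomeList,
    session_trial: int,
    lag_min: int,
    lag_max: int,
) -> list[ObjectRecord]:
    """Step (i): once-chosen objects from the lag window whose payout is
    still available in their deck's current outcome list."""
    out = []
    for obj in objects.values():
        if obj.chosen_count != 1 or obj.reshown or obj.first_choice_trial is None:
            continue
        lag = session_trial - obj.first_choice_trial
        if not (lag_min <= lag <= lag_max):
            continue
        if obj.value_cents is None or not pools.contains(obj.deck, obj.value_cents):
            continue
        out.append(obj)
    return out


def select_old_object(
    candidates: list[ObjectRecord],
    lucky_deck: str,
    shown_old_values: list[int],
    rng: np.random.Generator,
) -> ObjectRecord:
    """Steps (ii)-(iii) of the reappearance sampler.

    (ii) narrow to objects incongruent with their deck's current expected
    value when any exist; (iii) if the running mean of old-object values
    shown so far exceeds 50 cents, show the lowest-valued candidate,
    otherwise sample uniformly.
    """
    incongruent = [
        o for o in candidates
        if (o.value_cents > 50 and o.deck != lucky_deck)
        or (o.value_cents < 50 and o.deck == lucky_deck)
    ]
    pool = incongruent if incongruent else candidates
    if shown_old_values and float(np.mean(shown_old_values)) > 50.0:
        low = min(o.value_cents for o in pool)
        pool = [o for o in pool if o.value_cents == low]
        return pool[int(rng.integers(len(pool)))]
    return pool[int(rng.integers(len(pool)))]


def generate_session(
    cfg: SessionConfig,
    policy,
    seed: int | np.random.SeedSequence,
) -> Session:
    """Generate a full session (deck-only task, then combined task).

    The deck-only task always runs low-volatility then high-volatility; the
    combined task order follows ``cfg.counterbalance``. The supplied policy
    makes every choice; pass :class:`RandomPolicy` for structure-only runs.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)

    session = Session(
        subject_id=cfg.subject_id,
        trials=[],
        objects={},
        schedules={},
        counterbalance=cfg.counterbalance,
    )
    obj_counter = [0]
    session_trial = [0]  # session-wide counter for reappearance lags

    tasks = (["deck_only"] if cfg.include_deck_only else []) + ["deck_memory"]
    for task in tasks:
        if task == "deck_only" or cfg.counterbalance == 0:
            env_order = [cfg.low, cfg.high]
        else:
            env_order = [cfg.high, cfg.low]
        _generate_task(task, env_order, cfg, policy, rng, session, obj_counter, session_trial)
    return session


def _generate_task(task, env_order, cfg, policy, rng, session, obj_counter, session_trial):
    policy.start_task(task, env_order)
    with_objects = task == "deck_memory"
    shown_old_values: list[int] = []
    trial_index = 0
    for env in env_order:
        schedule = generate_reversal_schedule(env, rng)
        session.schedules[(task, env.env_code)] = schedule
        pools = DeckOutcomeList(rng, cfg.pool_counts)
        for wb_idx in range(env.n_trials):
            lucky = schedule.lucky_deck_by_trial[wb_idx]
            is_rev = wb_idx in schedule.reversal_trials
            if is_rev:
                pools.repopulate(lucky)

            old_obj: ObjectRecord | None = None
            if with_objects:
                cands = eligible_old_candidates(
                    session.objects, pools, session_trial[0], cfg.lag_min, cfg.lag_max
                )
                if cands:
                    session.n_eligible_trials += 1
                    if rng.random() < cfg.gate_probability:
                        session.n_gate_fired += 1
                        old_obj = select_old_object(cands, lucky, shown_old_values, rng)
                        old_obj.reshown = True
                        old_obj.shown_count += 1
                        shown_old_values.append(old_obj.value_cents)
                # the deck without an old object shows a fresh object
                new_objs: dict[str, ObjectRecord] = {}
                for deck in DECKS:
                    if old_obj is not None and old_obj.deck == deck:
                        continue
                    oid = f"obj{obj_counter[0]:05d}"
                    obj_counter[0] += 1
                    new_objs[deck] = ObjectRecord(
                        object_id=oid, deck=deck, env_code=env.env_code,
                        first_trial=session_trial[0],
                    )
                    session.objects[oid] = new_objs[deck]

            ctx = TrialContext(
                task=task,
                env_code=env.env_code,
                trial_index=trial_index,
                within_block_index=wb_idx,
                is_block_start=wb_idx == 0,
                old_object_deck=old_obj.deck if old_obj else None,
                old_object_value_cents=old_obj.value_cents if old_obj else None,
                old_object_id=old_obj.object_id if old_obj else None,
            )
            choice, rt_ms = policy.choose(ctx)

            if old_obj is not None and choice == old_obj.deck:
                outcome = old_obj.value_cents
                pools.consume_value(choice, outcome)
                old_obj.chosen_count += 1
            else:
                outcome = pools.draw(choice)

            rec_obj: ObjectRecord | None = None
            if with_objects:
                chosen_new = new_objs.get(choice)  # None when the old object was chosen
                if chosen_new is not None:
                    chosen_new.value_cents = outcome
                    chosen_new.first_choice_trial = session_trial[0]
                    chosen_new.chosen_count += 1
                # the trial record's object slot: the old object when one was
                # shown (it is what the analyses condition on), else the
                # newly chosen object
                rec_obj = old_obj if old_obj is not None else chosen_new
                chosen_obj = old_obj if (old_obj is not None and choice == old_obj.deck) else chosen_new

            policy.observe(ctx, choice, outcome)
            session.trials.append(
                TrialRecord(
                    subject_id=cfg.subject_id,
                    task=task,
                    env_code=env.env_code,
                    trial_index=trial_index,
                    is_reversal=is_rev,
                    object_id=rec_obj.object_id if rec_obj else None,
                    object_is_old=old_obj is not None,
                    object_value_cents=rec_obj.value_cents if rec_obj else None,
                    object_deck=rec_obj.deck if rec_obj else None,
                    choice_deck=choice,
                    outcome_cents=int(outcome),
                    rt_ms=float(rt_ms),
                    lucky_deck=lucky,
                    within_block_index=wb_idx,
                    chosen_object_id=chosen_obj.object_id if with_objects else None,
                )
            )
            trial_index += 1
            session_trial[0] += 1


@dataclass
class MemoryProbe:
    subject_id: str
    object_id: str
    is_old: bool
    true_value_cents: int | None
    source_env: float | None
    recog_response: str | None = None
    chose_response: bool | None = None
    value_response_cents: int | None = None


@dataclass
class MemoryTestSet:
    probes: list[MemoryProbe]

    def frame(self) -> pd.DataFrame:
        cols = [
            "subject_id", "object_id", "is_old", "true_value_cents", "source_env",
            "recog_response", "chose_response", "value_response_cents",
        ]
        return pd.DataFrame([p.__dict__ for p in self.probes])[cols]


class MemoryTestDeficitError(ValueError):
    """The session cannot supply the required old-probe composition."""


def generate_memory_test(
    session: Session,
    rng: np.random.Generator | int,
    n_old_per_cell: int = 4,
    n_new: int = 32,
) -> MemoryTestSet:
    """Compose the 80-probe subsequent-memory test.

    48 old probes: for each environment, ``n_old_per_cell`` objects per
    payout value, drawn from objects the subject chose in the combined task.
    Cells short of objects are backfilled from the nearest-value cell in the
    same environment (with a logged warning). 32 new probes use fresh ids.
    Probe order is shuffled.
    """
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    chosen = [
        o for o in session.objects.values()
        if o.chosen_count >= 1 and o.value_cents is not None
    ]
    if not chosen:
        raise MemoryTestDeficitError("session contains no chosen objects to probe")

    probes: list[MemoryProbe] = []
    for env_code in (-0.5, 0.5):
        by_val: dict[int, list[ObjectRecord]] = {v: [] for v in OUTCOME_VALUES}
        for o in chosen:
            if o.env_code == env_code:
                by_val[o.value_cents].append(o)
        for v in by_val:
            by_val[v] = list(by_val[v])
            rng.shuffle(by_val[v])
        picked: list[ObjectRecord] = []
        deficits = []
        for v in OUTCOME_VALUES:
            cell = by_val[v][:n_old_per_cell]
            by_val[v] = by_val[v][len(cell):]
            need = n_old_per_cell - len(cell)
            if need:
                deficits.append((env_code, v, need))
                # nearest-value backfill within the same environment
                for alt in sorted(OUTCOME_VALUES, key=lambda a: (abs(a - v), a)):
                    while need and by_val[alt]:
                        cell.append(by_val[alt].pop())
                        need -= 1
                    if not need:
                        break
            picked.extend(cell)
        if len(picked) < n_old_per_cell * len(OUTCOME_VALUES):
            raise MemoryTestDeficitError(
                f"environment {env_code:+.1f} supplies only {len(picked)} old probes; "
                f"deficits by value: {deficits}"
            )
        if deficits:
            logger.warning("memory-test backfill applied for cells %s", deficits)
        probes.extend(
            MemoryProbe(
                subject_id=session.subject_id,
                object_id=o.object_id,
                is_old=True,
                true_value_cents=o.value_cents,
                source_env=o.env_code,
            )
            for o in picked
        )

    for i in range(n_new):
        probes.append(
            MemoryProbe(
                subject_id=session.subject_id,
                object_id=f"new{i:04d}_{session.subject_id}",
                is_old=False,
                true_value_cents=None,
                source_env=None,
            )
        )
    order = rng.permutation(len(probes))
    return MemoryTestSet(probes=[probes[i] for i in order])
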