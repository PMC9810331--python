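"""Behavioral derivations and the regression catalog.

Everything downstream of the learning filters lives here: subject
exclusions, incongruent-trial labeling and the episodic-based choice index
(EBCI), the per-subject incremental-noise covariate, reversal-aligned
codings, relative-uncertainty analyses, signal-detection memory metrics,
and the combined episodic+incremental choice models.

Key codings
-----------
Env
    -0.5 low-volatility, +0.5 high-volatility.
Old / OldVal
    On old-object trials, Old is +/-0.5 toward the deck carrying the old
    object; OldVal is the signed coded object value, +0.5 when the object
    was worth $1 on deck A (or $0 on deck B) through -0.5 at the opposite
    extreme.
Incongruent trial
    The old object is high-valued (>50c) on the model-unlucky deck or
    low-valued (<50c) on the model-lucky deck, luckiness defined by the
    fitted filter's value estimates (ties and exactly-50c objects are
    excluded).
EBCI
    1 when the "correct" episodic response was given on an incongruent
    trial (high-valued object chosen / low-valued object avoided), 0 when
    the incremental response was given.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .inference import (
    BayesianMixedModel,
    RegressionSpec,
    SamplerConfig,
    compare_models,
    fit_mixed_glm,
)

logger = logging.getLogger(__name__)

V_LUCKY_C, V_UNLUCKY_C = 63.0, 37.0


# ---------------------------------------------------------------------------
# exclusions
# ---------------------------------------------------------------------------

@dataclass
class ExclusionReport:
    """Per-subject exclusion bookkeeping; ``retained`` passes all criteria."""

    frame: pd.DataFrame

    @property
    def retained_subjects(self) -> list:
        return self.frame.index[self.frame["retained"]].tolist()

    def counts_by_criterion(self) -> dict:
        f = self.frame
        return {
            "too_few_responses": int(f["fail_responses"].sum()),
            "too_fast": int(f["fail_rt"].sum()),
            "volatility_insensitive": int(f["fail_b1"].sum()),
        }


def post_reversal_frame(deck_only: pd.DataFrame, max_dist: int = 5) -> pd.DataFrame:
    """Trials 1..max_dist after each reversal event in the deck-only task,
    with ChooseLucky and the TSinceRev x Env regressor."""
    rows = []
    for (sid, env), grp in deck_only.groupby(["subject_id", "env_code"]):
        grp = grp.sort_values("trial_index")
        rev = grp.index[grp["is_reversal"].astype(bool)].tolist()
        pos = {idx: i for i, idx in enumerate(grp.index)}
        for r in rev:
            p = pos[r]
            for d in range(1, max_dist + 1):
                if p + d >= len(grp):
                    break
                row = grp.iloc[p + d]
                if row["is_reversal"]:
                    break
                rows.append({
                    "subject_id": sid,
                    "env_code": env,
                    "choose_lucky": float(row["choice_deck"] == row["lucky_deck"]),
                    "tsincerev_env": d * env,
                })
    return pd.DataFrame(rows)


def apply_exclusions(
    trials: pd.DataFrame,
    sampler: SamplerConfig | None = None,
    seed: int = 0,
) -> ExclusionReport:
    """The three-part exclusion rule.

    A subject is excluded for (i) fewer responses than the group mean minus
    1 SD, (ii) mean RT below the group mean minus 1 SD, or (iii) a
    non-positive random slope b1 in
    p(ChooseLucky) = sigma(b0_s + TSinceRev x Env * (beta1 + b1_s)) fit to
    post-reversal trials 1-5 of the deck-only task.
    """
    deck_only = trials[trials["task"] == "deck_only"]
    if deck_only["subject_id"].nunique() < 2:
        raise ValueError("need at least 2 subjects for the mean - 1 SD rules")
    per_subj = deck_only.groupby("subject_id").agg(
        n_responses=("trial_index", "size"), mean_rt=("rt_ms", "mean")
    )
    thr_resp = per_subj["n_responses"].mean() - per_subj["n_responses"].std(ddof=0)
    thr_rt = per_subj["mean_rt"].mean() - per_subj["mean_rt"].std(ddof=0)
    report = per_subj.copy()
    report["fail_responses"] = per_subj["n_responses"] < thr_resp
    report["fail_rt"] = per_subj["mean_rt"] < thr_rt

    pr = post_reversal_frame(deck_only)
    spec = RegressionSpec(
        outcome="choose_lucky", terms=("tsincerev_env",), random=("tsincerev_env",),
        link="logistic",
    )
    model = fit_mixed_glm(spec, pr, sampler=sampler, seed=seed)
    b1 = model.random_effect_means("tsincerev_env") + np.median(
        model.fixed_effect_draws("tsincerev_env")
    )
    report["b1"] = b1.reindex(report.index)
    report["fail_b1"] = ~(report["b1"] > 0)
    report["retained"] = ~(report["fail_responses"] | report["fail_rt"] | report["fail_b1"])
    return ExclusionReport(frame=report)


# ---------------------------------------------------------------------------
# the analysis table
# ---------------------------------------------------------------------------

def label_incongruent(df: pd.DataFrame) -> pd.Series:
    """Incongruent-trial flags from model-derived deck values.

    Requires ``deckval_A``/``deckval_B`` columns. Old-object trials where
    the object is >50c on the model-unlucky deck or <50c on the model-lucky
    deck are incongruent; 50c objects and value-tied trials are excluded.
    """
    if df[["deckval_A", "deckval_B"]].isna().all().all():
        raise ValueError("model-derived deck values are missing")
    v = df["object_value_cents"].astype(float)
    on_A = df["object_deck"] == "A"
    tied = df["deckval_A"] == df["deckval_B"]
    lucky_is_A = df["deckval_A"] > df["deckval_B"]
    on_lucky = np.where(on_A, lucky_is_A, ~lucky_is_A)
    incongruent = (
        df["object_is_old"].astype(bool)
        & ~tied
        & (((v > 50) & ~on_lucky) | ((v < 50) & on_lucky))
    )
    return incongruent.astype(bool)


def compute_ebci(df: pd.DataFrame) -> pd.Series:
    """EBCI on incongruent trials: 1 if the episodic response was given."""
    if "incongruent" not in df.columns or not df["incongruent"].all():
        raise ValueError("EBCI is defined on incongruent trials only")
    v = df["object_value_cents"].astype(float)
    chose_object_deck = df["choice_deck"] == df["object_deck"]
    return (((v > 50) & chose_object_deck) | ((v < 50) & ~chose_object_deck)).astype(float)


def _reversal_distance(grp: pd.DataFrame, max_dist: int = 4) -> np.ndarray:
    """Signed distance (clipped to [-max, +max], NaN outside) from the
    nearest interior reversal; post-reversal wins ties."""
    n = len(grp)
    onsets = np.flatnonzero(grp["is_reversal"].to_numpy(dtype=bool))
    onsets = onsets[onsets > 0]  # interior boundaries only
    dist = np.full(n, np.nan)
    best = np.full(n, np.inf)
    for r in onsets:
        for d in range(-max_dist, max_dist + 1):
            t = r + d
            if 0 <= t < n:
                score = abs(d) - (0.25 if d >= 0 else 0.0)
                if score < best[t]:
                    best[t] = score
                    dist[t] = d
    return dist


def build_analysis_table(
    trials: pd.DataFrame,
    series: pd.DataFrame,
    env_noise: pd.Series | None = None,
) -> pd.DataFrame:
    """Join combined-task trials with a filter's series and derive all
    per-trial covariates used by the regression catalog.

    ``trials`` must be the generator's full frame (with ``lucky_deck``);
    ``series`` a filter output for the same rows (e.g., from
    :func:`epinc.inference.transfer_subject_params`).
    """
    t = trials[trials["task"] == "deck_memory"].copy()
    s = series[series["task"] == "deck_memory"] if "task" in series.columns else series
    df = t.merge(s, on=["subject_id", "task", "trial_index"], how="left",
                 validate="1:1", suffixes=("", "_flt"))

    df["choose_A"] = (df["choice_deck"] == "A").astype(float)
    df["Env"] = df["env_code"].astype(float)
    df["DeckVal"] = df["deckval_A"] - df["deckval_B"]
    df["RU"] = df["ru"] - df["ru"].mean()
    df["RU_sq"] = df["RU"] ** 2

    old = df["object_is_old"].astype(bool)
    sign = np.where(df["object_deck"] == "A", 1.0, -1.0)
    val_c = df["object_value_cents"].astype(float) / 100.0 - 0.5
    df["Old"] = np.where(old, 0.5 * sign, 0.0)
    df["OldVal"] = np.where(old, sign * val_c, 0.0)
    df["OldVal_Env"] = df["OldVal"] * df["Env"]
    df["OldVal_RU"] = df["OldVal"] * df["RU"]

    # ChooseOld model codings (old trials only; NaN elsewhere)
    df["choose_old"] = np.where(old, (df["choice_deck"] == df["object_deck"]).astype(float), np.nan)
    df["OldVal_centered"] = np.where(old, val_c, np.nan)
    obj_on_lucky = df["object_deck"] == df["lucky_deck"]
    df["TrueDeckVal"] = np.where(
        old, np.where(obj_on_lucky, V_LUCKY_C - 50.0, V_UNLUCKY_C - 50.0) / 100.0, np.nan
    )

    # reversal-aligned codings (true luckiness)
    df["choose_lucky"] = (df["choice_deck"] == df["lucky_deck"]).astype(float)
    lucky_sign = np.where(obj_on_lucky, 1.0, -1.0)
    df["OldVal_lucky"] = np.where(old, lucky_sign * val_c, 0.0)
    dist = np.full(len(df), np.nan)
    for _, grp in df.groupby(["subject_id", "env_code"]):
        grp = grp.sort_values("trial_index")
        dist[df.index.get_indexer(grp.index)] = _reversal_distance(grp)
    df["rev_dist"] = dist
    for d in range(-4, 5):
        tag = f"T{'m' if d < 0 else 'p'}{abs(d)}" if d != 0 else "T0"
        df[tag] = (df["rev_dist"] == d).astype(float)
        df[f"{tag}_OldVal"] = df[tag] * df["OldVal_lucky"]

    # incongruent trials and EBCI
    df["incongruent"] = label_incongruent(df)
    df["EBCI"] = np.nan
    inc = df["incongruent"]
    df.loc[inc, "EBCI"] = compute_ebci(df[inc])
    df["EBCI_c"] = df["EBCI"] - 0.5  # +/-0.5 coding for RT / memory models

    # RT-model covariates
    prev = df.groupby(["subject_id", "task"])["choice_deck"].shift()
    df["Switch"] = np.where(prev.isna(), -0.5, np.where(df["choice_deck"] != prev, 0.5, -0.5))
    true_ev = np.where(df["choice_deck"] == df["lucky_deck"], V_LUCKY_C, V_UNLUCKY_C) / 100.0
    df["ChosenVal"] = np.where(
        df["EBCI"] == 1.0, df["object_value_cents"].astype(float) / 100.0, true_ev
    )

    # encoding-time series joined at the object's first choice (the trial
    # its payout was revealed)
    enc = _encoding_series(df)
    df = df.join(enc, on=["subject_id", "object_id"])
    df["RU_enc"] = df["RU_enc_raw"] - df["RU_enc_raw"].mean()
    df["RU_enc_sq"] = df["RU_enc"] ** 2
    df["OldVal_RU_enc"] = df["OldVal"] * df["RU_enc"]

    if env_noise is not None:
        df["EnvNoise"] = df["subject_id"].map(env_noise)
    return df


def _encoding_series(df: pd.DataFrame) -> pd.DataFrame:
    """Per (subject, object): filter quantities at the object's encoding
    trial (its first choice). Uses the generator's chosen-object column
    when present; otherwise falls back to first-appearance rows."""
    if "chosen_object_id" in df.columns and df["chosen_object_id"].notna().any():
        src = df.dropna(subset=["chosen_object_id"]).sort_values(
            ["subject_id", "trial_index"]
        ).drop_duplicates(["subject_id", "chosen_object_id"], keep="first")
        enc = src.set_index(["subject_id", "chosen_object_id"])[["ru_post", "cpp", "ape"]]
    else:
        first = df[~df["object_is_old"].astype(bool) & df["object_id"].notna()]
        enc = first.set_index(["subject_id", "object_id"])[["ru_post", "cpp", "ape"]]
    enc.columns = ["RU_enc_raw", "CPP_enc", "APE_enc"]
    enc.index.names = ["subject_id", "object_id"]
    return enc


def ru_difference_table(table: pd.DataFrame, max_dist: int = 4) -> pd.DataFrame:
    """Post-reversal RU change: RU on trials 0..+4 after each interior
    reversal minus the mean RU of the four preceding trials."""
    rows = []
    for (sid, env), grp in table.groupby(["subject_id", "env_code"]):
        grp = grp.sort_values("trial_index")
        ru = grp["ru"].to_numpy()
        onsets = np.flatnonzero(grp["is_reversal"].to_numpy(dtype=bool))
        for r in onsets[onsets > 0]:
            if r < 4:
                continue
            pre = np.nanmean(ru[r - 4:r])
            for d in range(0, max_dist + 1):
                if r + d >= len(grp):
                    break
                row = {"subject_id": sid, "env_code": env,
                       "ru_difference": ru[r + d] - pre}
                for dd in range(0, max_dist + 1):
                    row[f"T{dd}"] = float(dd == d)
                rows.append(row)
    return pd.DataFrame(rows)


def compute_env_noise(
    table: pd.DataFrame, sampler: SamplerConfig | None = None, seed: int = 0,
    min_trials: int = 20,
) -> pd.Series:
    """Per-subject incremental-noise index.

    The random slope of DeckVal x Env from
    p(ChooseA) ~ DeckVal + Env + DeckVal x Env, fit to combined-task trials
    with no old object: more negative values mean noisier value-based
    choice in the high-volatility environment.
    """
    sub = table[~table["object_is_old"].astype(bool)].copy()
    counts = sub.groupby("subject_id").size()
    ok = counts[counts >= min_trials].index
    dropped = set(counts.index) - set(ok)
    if dropped:
        logger.warning("EnvNoise: dropping subjects with too few object-free trials: %s",
                       sorted(dropped))
    sub = sub[sub["subject_id"].isin(ok)]
    sub["DeckVal_Env"] = sub["DeckVal"] * sub["Env"]
    spec = RegressionSpec(
        outcome="choose_A",
        terms=("DeckVal", "Env", "DeckVal_Env"),
        random=("DeckVal", "Env", "DeckVal_Env"),
        zscore=("DeckVal",),
        link="logistic",
    )
    model = fit_mixed_glm(spec, sub, sampler=sampler, seed=seed)
    return model.random_effect_means("DeckVal_Env")


# ---------------------------------------------------------------------------
# the regression catalog
# ---------------------------------------------------------------------------

_REV_TERMS = tuple(
    [f"T{'m' if d < 0 else 'p'}{abs(d)}" if d else "T0" for d in range(-4, 5)]
) + tuple(
    [f"{'T' + ('m' if d < 0 else 'p') + str(abs(d)) if d else 'T0'}_OldVal" for d in range(-4, 5)]
)

CATALOG_SPECS: dict[str, dict] = {
    "choose_old": dict(
        spec=RegressionSpec(
            outcome="choose_old", terms=("OldVal_centered", "TrueDeckVal"),
            random=("OldVal_centered", "TrueDeckVal"), link="logistic",
        ),
        subset="old",
    ),
    "reversal_accuracy": dict(
        spec=RegressionSpec(
            outcome="choose_lucky", terms=_REV_TERMS, random=_REV_TERMS,
            link="logistic", add_intercept=False,
        ),
        subset="rev_window",
    ),
    "ebci_env": dict(
        spec=RegressionSpec(
            outcome="EBCI", terms=("EnvNoise", "Env"), random=("Env",),
            link="logistic",
        ),
        subset="incongruent",
    ),
    "ebci_ru": dict(
        spec=RegressionSpec(
            outcome="EBCI", terms=("RU", "RU_sq"), random=("RU", "RU_sq"),
            link="logistic",
        ),
        subset="incongruent",
    ),
    "ebci_ru_encoding": dict(
        spec=RegressionSpec(
            outcome="EBCI", terms=("RU_enc", "RU_enc_sq"), random=("RU_enc", "RU_enc_sq"),
            link="logistic",
        ),
        subset="incongruent",
    ),
    "rt_ebci": dict(
        spec=RegressionSpec(
            outcome="rt_ms", terms=("EBCI_c", "Switch", "ChosenVal", "RU"),
            random=("EBCI_c", "Switch", "ChosenVal", "RU"), link="identity",
        ),
        subset="incongruent",
    ),
    "rt_ru": dict(
        spec=RegressionSpec(
            outcome="rt_ms", terms=("RU",), random=("RU",), link="identity",
        ),
        subset="all",
    ),
    "ru_env": dict(
        spec=RegressionSpec(
            outcome="ru", terms=("Env",), random=("Env",), link="identity",
        ),
        subset="all",
    ),
}


def _catalog_subset(table: pd.DataFrame, subset: str) -> pd.DataFrame:
    if subset == "all":
        return table
    if subset == "old":
        return table[table["object_is_old"].astype(bool)]
    if subset == "incongruent":
        return table[table["incongruent"].astype(bool)]
    if subset == "rev_window":
        return table[table["rev_dist"].notna()]
    raise ValueError(subset)


def regression_catalog(
    table: pd.DataFrame,
    entries: list[str] | None = None,
    sampler: SamplerConfig | None = None,
    seed: int = 0,
) -> dict[str, BayesianMixedModel]:
    """Fit the behavioral regressions; entries with unmet data requirements
    are skipped with a logged reason."""
    out: dict[str, BayesianMixedModel] = {}
    names = entries or list(CATALOG_SPECS) + ["ru_difference"]
    for i, name in enumerate(names):
        if name == "ru_difference":
            sub = ru_difference_table(table)
            spec = RegressionSpec(
                outcome="ru_difference", terms=tuple(f"T{d}" for d in range(5)),
                random=tuple(f"T{d}" for d in range(5)), link="identity",
                add_intercept=False,
            )
        else:
            entry = CATALOG_SPECS[name]
            spec = entry["spec"]
            sub = _catalog_subset(table, entry["subset"])
        missing = [c for c in (spec.outcome, *spec.terms) if c not in sub.columns]
        usable = sub.dropna(subset=[c for c in (spec.outcome, *spec.terms) if c in sub.columns])
        if missing or not len(usable):
            logger.warning("catalog entry %r skipped: missing %s, %d usable rows",
                           name, missing, len(usable))
            continue
        out[name] = fit_mixed_glm(spec, usable, sampler=sampler, seed=seed + 13 * i)
    return out


def combined_choice_spec(variant: str, deckval: str = "DeckVal") -> RegressionSpec:
    """The combined choice model for one learning-model variant.

    ``variant`` in {RW1A, RW2A, RB1H, RB2H, CI, RW1Q, RB2H+RU,
    RB2H+RU+ENC}: the base terms are DeckVal, Old, OldVal, OldVal x Env;
    the +RU variant adds OldVal x RU (retrieval time), the +ENC variant
    additionally OldVal x RU at encoding. Predictors are z-scored.
    ``deckval`` selects which model's deck-value column feeds the DeckVal
    term (the comparison fits each learning model's series).
    """
    terms = [deckval, "Old", "OldVal", "OldVal_Env"]
    if variant.endswith("+RU") or variant.endswith("+RU+ENC"):
        terms.append("OldVal_RU")
    if variant.endswith("+ENC"):
        terms.append("OldVal_RU_enc")
    return RegressionSpec(
        outcome="choose_A", terms=tuple(terms), random=tuple(terms),
        zscore=tuple(terms), link="logistic",
    )


# ---------------------------------------------------------------------------
# subsequent memory
# ---------------------------------------------------------------------------

OLD_RESPONSES = ("Probably Old", "Definitely Old")


def dprime_loglinear(n_hit: int, n_old: int, n_fa: int, n_new: int) -> float:
    """d' with the log-linear correction for extreme proportions:
    z((hits + 0.5) / (n_old + 1)) - z((fas + 0.5) / (n_new + 1))."""
    if n_old <= 0 or n_new <= 0:
        raise ValueError("need at least one old and one new probe")
    h = (n_hit + 0.5) / (n_old + 1.0)
    f = (n_fa + 0.5) / (n_new + 1.0)
    return float(norm.ppf(h) - norm.ppf(f))


def memory_table(memory: pd.DataFrame) -> pd.DataFrame:
    """Per-probe indicators: hit / false alarm under the conservative
    collapse (Don't Know counts as a 'new' response)."""
    df = memory.copy()
    df["said_old"] = df["recog_response"].isin(OLD_RESPONSES)
    df["hit"] = np.where(df["is_old"], df["said_old"].astype(float), np.nan)
    df["fa"] = np.where(~df["is_old"].astype(bool), df["said_old"].astype(float), np.nan)
    return df


def subject_dprime(memory: pd.DataFrame) -> pd.DataFrame:
    """Overall and per-environment d' (shared false-alarm rate) by subject."""
    df = memory_table(memory)
    rows = []
    for sid, grp in df.groupby("subject_id"):
        old = grp[grp["is_old"].astype(bool)]
        new = grp[~grp["is_old"].astype(bool)]
        n_fa = int(new["said_old"].sum())
        row = {"subject_id": sid,
               "dprime": dprime_loglinear(int(old["said_old"].sum()), len(old), n_fa, len(new))}
        for env, tag in ((-0.5, "low"), (0.5, "high")):
            env_old = old[old["source_env"] == env]
            if len(env_old):
                row[f"dprime_{tag}"] = dprime_loglinear(
                    int(env_old["said_old"].sum()), len(env_old), n_fa, len(new)
                )
        rows.append(row)
    return pd.DataFrame(rows).set_index("subject_id")


def memory_analysis_table(memory: pd.DataFrame, table: pd.DataFrame) -> pd.DataFrame:
    """Join probes to the choice-time analysis table.

    Adds, per old probe: hit, remembered/true value (dollars), source Env,
    the EBCI of the object's second (incongruent) appearance where defined,
    and the encoding-time RU/CPP/APE of its first appearance.
    """
    df = memory_table(memory)
    old_rows = table[table["object_is_old"].astype(bool)]
    ebci = old_rows.set_index(["subject_id", "object_id"])["EBCI_c"]
    df = df.join(ebci, on=["subject_id", "object_id"])
    enc = _encoding_series(table).rename(columns={"RU_enc_raw": "RU_enc"})
    df = df.join(enc, on=["subject_id", "object_id"])
    n_unmatched = int(df["is_old"].astype(bool).sum() - df["RU_enc"].notna().sum())
    if n_unmatched:
        logger.info("memory probes without encoding-series match: %d", n_unmatched)
    df["Env"] = df["source_env"].astype(float)
    df["TrueVal"] = df["true_value_cents"].astype(float) / 100.0
    df["Value"] = df["value_response_cents"].astype(float) / 100.0
    df["TrueVal_Env"] = df["TrueVal"] * df["Env"]
    df["TrueVal_EBCI"] = df["TrueVal"] * df["EBCI_c"]
    df["AbsVal"] = (df["true_value_cents"].astype(float) - 50.0).abs() / 100.0
    if "RU_enc" in df.columns:
        df["RU_enc"] = df["RU_enc"] - df["RU_enc"].mean()
    return df


def memory_models(
    mem_table: pd.DataFrame,
    sampler: SamplerConfig | None = None,
    seed: int = 0,
    elpd_k: int = 5,
) -> dict:
    """Subsequent-memory regressions and the encoding-variable comparison.

    Fits Hit ~ EBCI, Value ~ TrueVal x Env, Value ~ TrueVal x EBCI, and the
    three encoding models Hit ~ {RU|CPP|APE} + |value|; the latter are
    compared by leave-subjects-out ELPD.
    """
    out: dict = {}
    olds = mem_table[mem_table["is_old"].astype(bool)]

    specs = {
        "hit_ebci": (RegressionSpec(outcome="hit", terms=("EBCI_c",), random=("EBCI_c",),
                                    link="logistic"),
                     olds.dropna(subset=["EBCI_c"])),
        "value_trueval_env": (RegressionSpec(outcome="Value",
                                             terms=("TrueVal", "Env", "TrueVal_Env"),
                                             random=("TrueVal", "Env", "TrueVal_Env"),
                                             link="identity"),
                              olds.dropna(subset=["Value"])),
        "value_trueval_ebci": (RegressionSpec(outcome="Value",
                                              terms=("TrueVal", "EBCI_c", "TrueVal_EBCI"),
                                              random=("TrueVal", "EBCI_c", "TrueVal_EBCI"),
                                              link="identity"),
                               olds.dropna(subset=["Value", "EBCI_c"])),
    }
    for i, (name, (spec, data)) in enumerate(specs.items()):
        if not len(data):
            logger.warning("memory model %r skipped: no usable rows", name)
            continue
        out[name] = fit_mixed_glm(spec, data, sampler=sampler, seed=seed + i)

    enc_data = olds.dropna(subset=["RU_enc", "CPP_enc", "APE_enc", "hit"])
    if len(enc_data) and enc_data["subject_id"].nunique() >= elpd_k:
        variants = {}
        for var in ("RU_enc", "CPP_enc", "APE_enc"):
            spec = RegressionSpec(outcome="hit", terms=(var, "AbsVal"),
                                  random=(var,), zscore=(var,), link="logistic")
            variants[var] = (
                lambda train, spec=spec: fit_mixed_glm(spec, train, sampler=sampler, seed=seed)
            )
        out["encoding_comparison"] = compare_models(
            variants, enc_data, k=elpd_k, seed=seed
        )
    return out
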