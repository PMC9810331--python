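"""Behavioral derivations: exclusions, EBCI, d', memory models."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from epinc.agents import AgentParams, CohortSpec, simulate_cohort
from epinc.analyses import (
    apply_exclusions,
    build_analysis_table,
    compute_ebci,
    compute_env_noise,
    dprime_loglinear,
    label_incongruent,
    memory_analysis_table,
    memory_models,
    regression_catalog,
    ru_difference_table,
    subject_dprime,
)
from epinc.filters import ModelSpec
from epinc.inference import SamplerConfig, fit_mixed_glm, RegressionSpec

from oracles import dprime_reference

TINY = SamplerConfig(n_chains=2, n_warmup=250, n_draws=250)


# ---------------------------------------------------------------------------
# d-prime
# ---------------------------------------------------------------------------

def test_dprime_basic_properties():
    # equal hit and false-alarm proportions: d' = 0
    assert dprime_loglinear(10, 20, 10, 20) == pytest.approx(0.0)
    # extreme proportions stay finite under the correction
    assert np.isfinite(dprime_loglinear(0, 20, 0, 20))
    assert np.isfinite(dprime_loglinear(20, 20, 0, 20))
    with pytest.raises(ValueError):
        dprime_loglinear(0, 0, 0, 20)


def test_dprime_hand_example():
    from scipy.stats import norm
    expected = norm.ppf(18.5 / 21) - norm.ppf(4.5 / 21)
    assert dprime_loglinear(18, 20, 4, 20) == pytest.approx(expected, abs=1e-12)


def test_dprime_matches_oracle_on_random_tables():
    rng = np.random.default_rng(0)
    for _ in range(1000):
        n_old, n_new = int(rng.integers(1, 60)), int(rng.integers(1, 60))
        h, f = int(rng.integers(0, n_old + 1)), int(rng.integers(0, n_new + 1))
        assert dprime_loglinear(h, n_old, f, n_new) == pytest.approx(
            dprime_reference(h, n_old, f, n_new), abs=1e-10
        )


# ---------------------------------------------------------------------------
# incongruent labeling and EBCI
# ---------------------------------------------------------------------------

def _mini_trials():
    return pd.DataFrame({
        "object_is_old": [True, True, True, True, True],
        "object_value_cents": [80, 80, 50, 20, 80],
        "object_deck": ["A", "A", "A", "B", "B"],
        "choice_deck": ["A", "B", "A", "B", "B"],
        # deck A is model-lucky in rows 0..3; tied values in row 4
        "deckval_A": [0.7, 0.7, 0.7, 0.7, 0.5],
        "deckval_B": [0.3, 0.3, 0.3, 0.3, 0.5],
    })


def test_incongruent_labeling_cases():
    flags = label_incongruent(_mini_trials())
    # 80c on lucky deck A: congruent; 50c: excluded; 20c on unlucky B:
    # congruent-low... actually low value on unlucky deck = congruent
    assert list(flags) == [False, False, False, False, False]
    df = _mini_trials()
    df.loc[0, "object_deck"] = "B"  # 80c on model-unlucky deck -> incongruent
    df.loc[3, "object_deck"] = "A"  # 20c on model-lucky deck -> incongruent
    flags = label_incongruent(df)
    assert list(flags) == [True, False, False, True, False]


def test_incongruent_requires_deck_values():
    df = _mini_trials()
    df["deckval_A"] = np.nan
    df["deckval_B"] = np.nan
    with pytest.raises(ValueError):
        label_incongruent(df)


def test_ebci_definition_and_guard():
    df = _mini_trials()
    df.loc[0, "object_deck"] = "B"
    df.loc[3, "object_deck"] = "A"
    df["incongruent"] = label_incongruent(df)
    inc = df[df["incongruent"]].copy()
    # row 0: 80c old object on unlucky deck B, subject chose A (deck response)
    # -> EBCI 0; row 3: 20c on lucky A, subject chose B (avoided) -> EBCI 1
    assert list(compute_ebci(inc)) == [0.0, 1.0]
    with pytest.raises(ValueError):
        compute_ebci(df)  # congruent rows present


def test_ebci_invariant_to_deck_label_permutation():
    df = _mini_trials()
    df.loc[0, "object_deck"] = "B"
    df.loc[3, "object_deck"] = "A"
    df["incongruent"] = label_incongruent(df)
    swap = {"A": "B", "B": "A"}
    df2 = df.copy()
    df2["object_deck"] = df2["object_deck"].map(swap)
    df2["choice_deck"] = df2["choice_deck"].map(swap)
    df2[["deckval_A", "deckval_B"]] = df[["deckval_B", "deckval_A"]].to_numpy()
    df2["incongruent"] = label_incongruent(df2)
    pd.testing.assert_series_equal(df["incongruent"], df2["incongruent"])
    inc, inc2 = df[df["incongruent"]], df2[df2["incongruent"]]
    pd.testing.assert_series_equal(compute_ebci(inc), compute_ebci(inc2))


def test_labeling_is_idempotent(table40):
    again = label_incongruent(table40)
    pd.testing.assert_series_equal(
        table40["incongruent"], again.rename("incongruent"), check_names=False
    )


# ---------------------------------------------------------------------------
# exclusions
# ---------------------------------------------------------------------------

def test_identical_subjects_never_fail_dispersion_rules(small_cohort):
    one = small_cohort.trials[small_cohort.trials["subject_id"] == "s000"]
    clones = []
    for i in range(4):
        c = one.copy()
        c["subject_id"] = f"c{i}"
        clones.append(c)
    report = apply_exclusions(pd.concat(clones), sampler=TINY, seed=0)
    assert not report.frame["fail_responses"].any()
    assert not report.frame["fail_rt"].any()
    assert set(report.counts_by_criterion()) == {
        "too_few_responses", "too_fast", "volatility_insensitive"
    }


def test_volatility_slope_criterion_tracks_hazard_adaptation():
    """The random-slope filter's b1 must increase with an agent's true
    hazard adaptation.

    Reduced Bayesian agents adapt their learning rate through changepoint
    probability even with equal hazards, so equal-H agents are only mildly
    insensitive behaviorally; the validity check is that the estimated
    post-reversal slope orders strongly-adapting agents above equal-H and
    reversed-adaptation agents.
    """
    def cohort(h, seed, tag):
        spec = CohortSpec(n_subjects=16,
                          mean=AgentParams(learning=ModelSpec("RB2H", h, beta_temp=8.0)),
                          h_sd=0.05)
        t = simulate_cohort(spec, seed).trials.copy()
        t["subject_id"] = tag + t["subject_id"]
        return t

    trials = pd.concat([
        cohort((0.02, 0.30), 200, "s"),    # strongly volatility-sensitive
        cohort((0.075, 0.075), 201, "e"),  # equal hazards
        cohort((0.20, 0.03), 202, "r"),    # adaptation in the wrong direction
    ])
    report = apply_exclusions(trials, sampler=TINY, seed=200)
    f = report.frame
    mean_b1 = {tag: f.loc[[i for i in f.index if i.startswith(tag)], "b1"].mean()
               for tag in "ser"}
    assert mean_b1["s"] > mean_b1["e"] > mean_b1["r"]
    # retention favors the truly sensitive group
    fail = {tag: f.loc[[i for i in f.index if i.startswith(tag)], "fail_b1"].mean()
            for tag in "ser"}
    assert fail["s"] < fail["r"]
    assert fail["s"] <= fail["e"]


def test_exclusions_need_two_subjects(small_cohort):
    one = small_cohort.trials[small_cohort.trials["subject_id"] == "s000"]
    with pytest.raises(ValueError):
        apply_exclusions(one)


# ---------------------------------------------------------------------------
# analysis table structure
# ---------------------------------------------------------------------------

def test_analysis_table_codings(table40):
    t = table40
    assert set(t["Env"].unique()) == {-0.5, 0.5}
    old = t[t["object_is_old"].astype(bool)]
    assert old["OldVal"].between(-0.5, 0.5).all()
    assert set(old["Old"].unique()) <= {-0.5, 0.5}
    assert (t.loc[~t["object_is_old"].astype(bool), "OldVal"] == 0).all()
    # EBCI only on incongruent trials
    assert t.loc[~t["incongruent"], "EBCI"].isna().all()
    assert t.loc[t["incongruent"], "EBCI"].isin([0.0, 1.0]).all()
    # reversal-window dummies one-hot
    win = t[t["rev_dist"].notna()]
    dums = [f"T{'m' if d < 0 else 'p'}{abs(d)}" if d else "T0" for d in range(-4, 5)]
    assert (win[dums].sum(axis=1) == 1.0).all()
    # switch coding
    assert set(t["Switch"].unique()) <= {-0.5, 0.5}
    # encoding-time series attach to old-object trials
    assert old["RU_enc_raw"].notna().mean() > 0.95


def test_ru_difference_table_structure(table40):
    rd = ru_difference_table(table40)
    assert (rd[[f"T{d}" for d in range(5)]].sum(axis=1) == 1.0).all()
    # the average post-reversal RU jump is positive at t+1
    t1 = rd[rd["T1"] == 1.0]["ru_difference"]
    assert t1.mean() > 0


def test_env_noise_centered_for_uniform_temperature(table40):
    noise = compute_env_noise(table40, sampler=TINY, seed=0)
    # agents share one inverse temperature across environments: the
    # DeckVal x Env random slopes should straddle zero
    assert abs(noise.mean()) < 0.5
    assert len(noise) == table40["subject_id"].nunique()


def test_catalog_skips_entries_with_missing_columns(table40, caplog):
    sub = table40[table40["incongruent"]].head(500)
    out = regression_catalog(sub.drop(columns=["EnvNoise"], errors="ignore"),
                             entries=["ebci_env"], sampler=TINY, seed=0)
    assert out == {}


# ---------------------------------------------------------------------------
# memory models
# ---------------------------------------------------------------------------

def test_perfect_value_recall_recovers_unit_slope(cohort40, table40):
    mem = cohort40.memory.copy()
    mem_t = memory_analysis_table(mem, table40)
    olds = mem_t[mem_t["is_old"].astype(bool)].copy()
    olds["Value"] = olds["TrueVal"]  # pretend recall is perfect
    spec = RegressionSpec(outcome="Value", terms=("TrueVal", "Env", "TrueVal_Env"),
                          random=("TrueVal",), link="identity")
    m = fit_mixed_glm(spec, olds, sampler=TINY, seed=3)
    s = m.summary_
    assert s.loc["TrueVal", "ci_lo"] < 1.0 < s.loc["TrueVal", "ci_hi"] or \
        abs(s.loc["TrueVal", "median"] - 1.0) < 0.02
    assert abs(s.loc["Env", "median"]) < 0.02
    assert abs(s.loc["TrueVal_Env", "median"]) < 0.05


def test_memory_models_run_and_report(cohort40, table40):
    mem_t = memory_analysis_table(cohort40.memory, table40)
    out = memory_models(mem_t, sampler=TINY, seed=1, elpd_k=4)
    assert {"hit_ebci", "value_trueval_env", "value_trueval_ebci"} <= set(out)
    # the cohort's recognition memory is far above chance
    d = subject_dprime(cohort40.memory)
    assert d["dprime"].mean() > 0.5
    # per-environment d' computed with a shared false-alarm rate
    assert {"dprime_low", "dprime_high"} <= set(d.columns)
    # value recall tracks true value in the fitted model
    s = out["value_trueval_env"].summary_
    assert s.loc["TrueVal", "ci_lo"] > 0
    if "encoding_comparison" in out:
        tab = out["encoding_comparison"].table
        assert tab["delta"].iloc[0] == 0.0
        assert (tab["se"] >= 0).all()
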