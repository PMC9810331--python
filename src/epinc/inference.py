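"""Hierarchical Bayesian estimation and model comparison.

Two estimator families:

* :class:`HierarchicalLearningModel` fits a learning-model family
  (RW1A/RW2A/RB1H/RB2H/CI/RW1Q) to deck-only choice data with group-level
  priors regularizing subject-level parameters (partial pooling). Learning
  rates and hazard rates are sampled on the logit scale, inverse
  temperatures on the log scale, each with Normal group distributions whose
  location and scale carry Normal / inverse-gamma hyperpriors.
* :class:`BayesianMixedModel` fits mixed-effects regressions (logistic or
  linear) with by-subject random effects, the workhorse behind every
  behavioral analysis and the combined episodic+incremental choice models.

Fitted subject-level learning parameters transfer out-of-sample to the
combined task via :func:`transfer_subject_params`, which runs the filters
forward to produce trial-wise value and uncertainty series.

Out-of-sample predictive fit is scored by k-fold leave-subjects-out
expected log pointwise predictive density (ELPD); held-out subjects are
evaluated at the group level by Monte-Carlo marginalization of the random
effects over the group distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import expit, logsumexp
from sklearn.base import BaseEstimator

from ._kernels import FAM_RB2H
from .filters import DESIGN_SIGMA_N, FAMILIES, FAMILY_IDS, ModelSpec, run_filter
from .samplers import (
    FAST_SAMPLER,
    GroupPrior,
    SamplerConfig,
    _pointwise_loglik,
    sample_hierarchical_learning,
    sample_mixed_glm,
)

__all__ = [
    "PriorConfig", "SamplerConfig", "FAST_SAMPLER",
    "HierarchicalLearningModel", "BayesianMixedModel", "RegressionSpec",
    "fit_learning_model_hierarchical", "fit_mixed_glm",
    "transfer_subject_params", "kfold_elpd", "compare_models", "ModelComparison",
]

RHAT_THRESHOLD = 1.01

#: transformed-scale parameter layout per family: (name, transform) pairs,
#: transform in {"logit", "log"}; the natural scale is recovered with
#: expit/exp. Every family also carries an inverse temperature.
_PARAM_LAYOUT = {
    "RW1A": [("alpha", "logit")],
    "RW2A": [("alpha_low", "logit"), ("alpha_high", "logit")],
    "RB1H": [("h", "logit")],
    "RB2H": [("h_low", "logit"), ("h_high", "logit")],
    "CI": [("h", "logit")],
    "RW1Q": [("alpha", "logit")],
}


@dataclass(frozen=True)
class PriorConfig:
    """Group-level priors on the transformed scales.

    ``loc_learn``/``scale_learn`` apply to every logit-scale learning
    parameter; ``loc_temp``/``scale_temp`` to the log inverse temperature;
    ``a0``/``b0`` are the inverse-gamma hyperprior on group variances.
    """

    loc_learn: float = -2.2      # logit scale, ~0.1 on the natural scale
    scale_learn: float = 1.5
    loc_temp: float = 1.6        # log scale, ~5 on the natural scale
    scale_temp: float = 1.0
    a0: float = 2.5
    b0: float = 1.0

    def __post_init__(self):
        if self.scale_learn <= 0 or self.scale_temp <= 0 or self.b0 <= 0:
            raise ValueError("prior scales must be positive")

    def group_prior(self, family: str) -> GroupPrior:
        names = _PARAM_LAYOUT[family]
        m0 = np.array([self.loc_learn] * len(names) + [self.loc_temp])
        s0 = np.array([self.scale_learn] * len(names) + [self.scale_temp])
        return GroupPrior(m0=m0, s0=s0, a0=self.a0, b0=self.b0)


def _to_natural_factory(family: str):
    two = family in ("RW2A", "RB2H")

    def theta_to_natural(theta: np.ndarray) -> np.ndarray:
        nat = np.empty((theta.shape[0], 4))
        nat[:, 0] = expit(theta[:, 0])
        nat[:, 1] = expit(theta[:, 1]) if two else nat[:, 0]
        nat[:, 2] = np.exp(np.clip(theta[:, -1], -10.0, 8.0))
        nat[:, 3] = 0.0
        return nat

    return theta_to_natural


def _stack_subject_arrays(trials: pd.DataFrame):
    """Sort by subject and flatten the columns the kernels need."""
    df = trials.sort_values(["subject_id", "task", "trial_index"], kind="stable")
    subject_ids = df["subject_id"].unique().tolist()
    counts = df.groupby("subject_id", sort=False).size().to_numpy()
    ptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
    choices = (df["choice_deck"].to_numpy() == "B").astype(np.int8)
    outcomes = df["outcome_cents"].to_numpy(dtype=np.float64) / 100.0
    env_high = (df["env_code"].to_numpy(dtype=float) > 0).astype(np.int8)
    return subject_ids, ptr, choices, outcomes, env_high


class HierarchicalLearningModel(BaseEstimator):
    """Hierarchical Bayesian fit of one learning-model family.

    Parameters
    ----------
    family:
        One of ``RW1A, RW2A, RB1H, RB2H, CI, RW1Q``.
    priors, sampler:
        See :class:`PriorConfig` and :class:`SamplerConfig`.
    seed:
        Seed for the chains; a fixed seed reproduces every draw.

    Fitted attributes
    -----------------
    ``draws_`` (transformed-scale chain draws), ``subject_ids_``,
    ``param_names_``, ``summary_`` (group-level natural-scale medians and
    95% intervals), ``rhat_``, ``ess_``, ``converged_``.
    """

    def __init__(self, family: str = "RB2H", priors: PriorConfig | None = None,
                 sampler: SamplerConfig | None = None, seed: int = 0,
                 sigma_n: float = DESIGN_SIGMA_N):
        self.family = family
        self.priors = priors
        self.sampler = sampler
        self.seed = seed
        self.sigma_n = sigma_n

    def fit(self, trials: pd.DataFrame, y=None):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        priors = self.priors or PriorConfig()
        cfg = self.sampler or SamplerConfig()
        layout = _PARAM_LAYOUT[self.family]
        self.param_names_ = [n for n, _ in layout] + ["beta_temp"]

        subject_ids, ptr, choices, outcomes, env_high = _stack_subject_arrays(trials)
        self.subject_ids_ = subject_ids
        self.draws_ = sample_hierarchical_learning(
            FAMILY_IDS[self.family], _to_natural_factory(self.family),
            choices, outcomes, env_high, ptr,
            priors.group_prior(self.family), cfg, self.seed, self.sigma_n,
        )
        self._diagnose()
        return self

    def _diagnose(self):
        idata = az.from_dict(posterior={"mu": self.draws_["mu"], "sigma": self.draws_["sigma"]})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rhat = az.rhat(idata)
            ess = az.ess(idata)
        self.rhat_ = float(max(rhat["mu"].values.max(), rhat["sigma"].values.max()))
        self.ess_ = float(min(ess["mu"].values.min(), ess["sigma"].values.min()))
        self.converged_ = bool(self.rhat_ < RHAT_THRESHOLD) if np.isfinite(self.rhat_) else True
        if not self.converged_:
            warnings.warn(
                f"{self.family}: max R-hat {self.rhat_:.3f} >= {RHAT_THRESHOLD}; "
                "treat posterior summaries with caution", stacklevel=2,
            )
        self.summary_ = self._summary()

    def _natural_group_draws(self) -> dict[str, np.ndarray]:
        """Group-location draws mapped to the natural scale."""
        mu = self.draws_["mu"].reshape(-1, self.draws_["mu"].shape[-1])
        out = {}
        for k, name in enumerate(self.param_names_):
            out[name] = np.exp(mu[:, k]) if name == "beta_temp" else expit(mu[:, k])
        return out

    def _summary(self) -> pd.DataFrame:
        rows = []
        for name, d in self._natural_group_draws().items():
            lo, med, hi = np.percentile(d, [2.5, 50, 97.5])
            rows.append({"param": name, "median": med, "ci_lo": lo, "ci_hi": hi})
        return pd.DataFrame(rows).set_index("param")

    def subject_params(self, point: str = "mean") -> pd.DataFrame:
        """Per-subject natural-scale point estimates (posterior mean/median)."""
        theta = self.draws_["theta"].reshape(
            -1, len(self.subject_ids_), len(self.param_names_)
        )
        nat = np.empty_like(theta)
        for k, name in enumerate(self.param_names_):
            nat[..., k] = np.exp(np.clip(theta[..., k], -10, 8)) if name == "beta_temp" \
                else expit(theta[..., k])
        agg = np.mean(nat, axis=0) if point == "mean" else np.median(nat, axis=0)
        return pd.DataFrame(agg, index=pd.Index(self.subject_ids_, name="subject_id"),
                            columns=self.param_names_)

    def subject_spec(self, subject_id, point: str = "mean") -> ModelSpec:
        row = self.subject_params(point).loc[subject_id]
        learn = tuple(row[n] for n, _ in _PARAM_LAYOUT[self.family])
        return ModelSpec(self.family, learn, beta_temp=float(row["beta_temp"]),
                         sigma_n=self.sigma_n)


def fit_learning_model_hierarchical(
    family: str, deck_only_data: pd.DataFrame,
    priors: PriorConfig | None = None, sampler: SamplerConfig | None = None,
    seed: int = 0,
) -> HierarchicalLearningModel:
    return HierarchicalLearningModel(family, priors, sampler, seed).fit(deck_only_data)


def transfer_subject_params(
    model: HierarchicalLearningModel, trials: pd.DataFrame, point: str = "mean",
) -> pd.DataFrame:
    """Run each subject's fitted filter forward on new (combined-task) data.

    Subject-level point estimates (posterior means by default) drive
    :func:`epinc.filters.run_filter`; output rows align with ``trials``.
    Raises if a subject in ``trials`` was not in the fit.
    """
    params = model.subject_params(point)
    missing = set(trials["subject_id"].unique()) - set(params.index)
    if missing:
        raise KeyError(f"subjects absent from the fitted posterior: {sorted(missing)}")
    parts = []
    for sid, grp in trials.groupby("subject_id", sort=False):
        spec = model.subject_spec(sid, point)
        parts.append(run_filter(spec, grp.sort_values("trial_index")))
    return pd.concat(parts)


# ---------------------------------------------------------------------------
# mixed-effects regressions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegressionSpec:
    """A mixed-effects regression over precomputed covariate columns.

    ``terms`` are column names of the design (use ``add_intercept`` for the
    constant); ``random`` lists the terms that get by-subject random
    effects; ``zscore`` the ones standardized (pooled) before fitting.
    """

    outcome: str
    terms: tuple[str, ...]
    random: tuple[str, ...] = ()
    zscore: tuple[str, ...] = ()
    link: str = "logistic"
    add_intercept: bool = True
    random_intercept: bool = True
    group: str = "subject_id"

    def __post_init__(self):
        if self.link not in ("logistic", "identity"):
            raise ValueError(f"unknown link {self.link!r}")
        unknown = set(self.random) - set(self.terms)
        if unknown:
            raise ValueError(f"random terms not among terms: {sorted(unknown)}")


class BayesianMixedModel(BaseEstimator):
    """Mixed-effects Bayesian GLM behind every behavioral regression.

    Fitted attributes: ``draws_``, ``columns_``, ``random_columns_``,
    ``subject_ids_``, ``summary_`` (fixed-effect posterior medians and 95%
    credible intervals), ``rhat_``, ``converged_``.
    """

    def __init__(self, spec: RegressionSpec, sampler: SamplerConfig | None = None,
                 seed: int = 0):
        self.spec = spec
        self.sampler = sampler
        self.seed = seed

    # -- design handling ----------------------------------------------------
    def _design(self, df: pd.DataFrame, fit: bool):
        spec = self.spec
        cols = (["Intercept"] if spec.add_intercept else []) + list(spec.terms)
        X = np.empty((len(df), len(cols)))
        for j, c in enumerate(cols):
            X[:, j] = 1.0 if c == "Intercept" else df[c].to_numpy(dtype=float)
        if fit:
            self.scale_means_ = {}
            self.scale_sds_ = {}
            for c in spec.zscore:
                j = cols.index(c)
                m, s = X[:, j].mean(), X[:, j].std()
                if s == 0:
                    raise ValueError(f"cannot z-score constant column {c!r}")
                self.scale_means_[c], self.scale_sds_[c] = m, s
        for c in spec.zscore:
            j = cols.index(c)
            X[:, j] = (X[:, j] - self.scale_means_[c]) / self.scale_sds_[c]
        rand = set(spec.random) | ({"Intercept"} if spec.add_intercept and spec.random_intercept else set())
        random_mask = np.array([c in rand for c in cols])
        return cols, X, random_mask

    def fit(self, df: pd.DataFrame, y=None):
        spec = self.spec
        cfg = self.sampler or SamplerConfig()
        df = df.dropna(subset=[spec.outcome, *spec.terms]).sort_values(spec.group, kind="stable")
        if not len(df):
            raise ValueError("no complete-case rows to fit")
        self.columns_, X, random_mask = self._design(df, fit=True)
        self.random_columns_ = [c for c, r in zip(self.columns_, random_mask) if r]
        y_arr = df[spec.outcome].to_numpy(dtype=float)
        if spec.link == "logistic" and (y_arr.min() == y_arr.max()):
            warnings.warn("degenerate binary outcome (all 0 or all 1); "
                          "priors keep the posterior proper", stacklevel=2)
        subj_codes, uniques = pd.factorize(df[spec.group])
        self.subject_ids_ = list(uniques)
        counts = np.bincount(subj_codes, minlength=len(uniques))
        ptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
        self.draws_ = sample_mixed_glm(
            y_arr, X, subj_codes.astype(np.int64), ptr, random_mask,
            spec.link, cfg, self.seed,
        )
        self.n_obs_ = len(df)
        self._diagnose()
        return self

    def _diagnose(self):
        post = {}
        if self.draws_["beta"].shape[-1]:
            post["beta"] = self.draws_["beta"]
        if self.draws_["gamma"].shape[-1]:
            post["gamma"] = self.draws_["gamma"]
        idata = az.from_dict(posterior=post)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rhat = az.rhat(idata)
        vals = [float(rhat[k].values.max()) for k in post]
        self.rhat_ = max(vals) if vals else 1.0
        self.converged_ = bool(self.rhat_ < RHAT_THRESHOLD) if np.isfinite(self.rhat_) else True
        self.summary_ = self._summary()

    def fixed_effect_draws(self, term: str) -> np.ndarray:
        """Flattened posterior draws of a fixed effect (random-term center
        or shared coefficient)."""
        if term in self.random_columns_:
            j = self.random_columns_.index(term)
            return self.draws_["beta"][..., j].ravel()
        fixed_only = [c for c in self.columns_ if c not in self.random_columns_]
        j = fixed_only.index(term)
        return self.draws_["gamma"][..., j].ravel()

    def random_effect_means(self, term: str) -> pd.Series:
        """Posterior-mean subject deviations b_s for a random term."""
        j = self.random_columns_.index(term)
        theta = self.draws_["theta"][..., j].reshape(-1, len(self.subject_ids_))
        beta = self.draws_["beta"][..., j].reshape(-1, 1)
        return pd.Series((theta - beta).mean(axis=0),
                         index=pd.Index(self.subject_ids_, name="subject_id"), name=term)

    def _summary(self) -> pd.DataFrame:
        rows = []
        for c in self.columns_:
            d = self.fixed_effect_draws(c)
            lo, med, hi = np.percentile(d, [2.5, 50, 97.5])
            rows.append({"term": c, "median": med, "ci_lo": lo, "ci_hi": hi,
                         "excludes_zero": bool(lo > 0 or hi < 0)})
        return pd.DataFrame(rows).set_index("term")

    # -- held-out prediction -------------------------------------------------
    def heldout_pointwise_lppd(self, df: pd.DataFrame, seed: int = 0,
                               max_draws: int = 200) -> np.ndarray:
        """log p(y_i) for new subjects, marginalizing random effects.

        For each retained posterior draw, subject-level coefficients for the
        held-out subjects are sampled from that draw's group distribution
        Normal(beta, diag(sigma^2)); the pointwise predictive density is the
        average across draws.
        """
        spec = self.spec
        df = df.dropna(subset=[spec.outcome, *spec.terms]).sort_values(spec.group, kind="stable")
        cols, X, random_mask = self._design(df, fit=False)
        y = df[spec.outcome].to_numpy(dtype=float)
        subj_codes, uniques = pd.factorize(df[spec.group])
        rng = np.random.default_rng(np.random.SeedSequence((self.seed, seed, 9173)))

        def _flat(key):
            d = self.draws_[key]
            return d.reshape(d.shape[0] * d.shape[1], -1)

        beta, sigma, gamma = _flat("beta"), _flat("sigma"), _flat("gamma")
        sigma_e = self.draws_["sigma_e"].reshape(-1)
        n_total = sigma_e.shape[0]
        keep = np.linspace(0, n_total - 1, min(max_draws, n_total)).astype(int)

        r_cols = np.flatnonzero(random_mask)
        f_cols = np.flatnonzero(~random_mask)
        ll = np.empty((len(keep), len(df)))
        for i, d in enumerate(keep):
            theta_s = beta[d][None, :] + sigma[d][None, :] * rng.standard_normal(
                (len(uniques), len(r_cols)))
            eta = X[:, f_cols] @ gamma[d] if len(f_cols) else np.zeros(len(df))
            for j, c in enumerate(r_cols):
                eta = eta + X[:, c] * theta_s[subj_codes, j]
            ll[i] = _pointwise_loglik(spec.link, y, eta, sigma_e[d])
        return logsumexp(ll, axis=0) - np.log(len(keep))


def series_from_param_table(family: str, params: pd.DataFrame,
                            trials: pd.DataFrame) -> pd.DataFrame:
    """Filter series from a saved subject-parameter table (as written by
    ``HierarchicalLearningModel.subject_params``), for CLI-style transfer."""
    layout = [n for n, _ in _PARAM_LAYOUT[family]]
    parts = []
    for sid, grp in trials.groupby("subject_id", sort=False):
        row = params.loc[sid]
        spec = ModelSpec(family, tuple(float(row[n]) for n in layout),
                         beta_temp=float(row["beta_temp"]))
        parts.append(run_filter(spec, grp.sort_values("trial_index")))
    return pd.concat(parts)


def fit_mixed_glm(spec: RegressionSpec, data: pd.DataFrame,
                  sampler: SamplerConfig | None = None, seed: int = 0) -> BayesianMixedModel:
    return BayesianMixedModel(spec, sampler, seed).fit(data)


# ---------------------------------------------------------------------------
# k-fold leave-subjects-out model comparison
# ---------------------------------------------------------------------------

@dataclass
class ModelComparison:
    """Per-model ELPD estimates, standard errors, and deltas to the best."""

    table: pd.DataFrame

    @property
    def best(self) -> str:
        return self.table.index[0]

    def is_decisive(self, margin_se: float = 1.0) -> pd.Series:
        """Whether each delta exceeds ``margin_se`` combined standard errors."""
        return self.table["delta"].abs() > margin_se * self.table["se"]


def assign_folds(subject_ids, k: int, seed: int) -> dict:
    """Deterministic subject -> fold assignment shared across model variants."""
    subject_ids = list(subject_ids)
    if k > len(subject_ids):
        raise ValueError(f"k={k} exceeds the {len(subject_ids)} available subjects")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 2741)))
    order = rng.permutation(len(subject_ids))
    folds = {}
    for pos, idx in enumerate(order):
        folds[subject_ids[idx]] = pos % k
    return folds


def kfold_elpd(fit_fn, data: pd.DataFrame, k: int = 20, seed: int = 0,
               group: str = "subject_id", folds: dict | None = None) -> tuple[float, float, np.ndarray]:
    """k-fold leave-N/k-subjects-out ELPD of one model variant.

    ``fit_fn(train_df) -> BayesianMixedModel``. Returns (elpd, se,
    pointwise lppd); ELPD is the sum of held-out pointwise values and the
    SE is ``sqrt(N * var(lppd_i))``.
    """
    subjects = data[group].unique()
    folds = folds or assign_folds(subjects, k, seed)
    pointwise = []
    for fold in range(k):
        test_subjects = [s for s in subjects if folds[s] == fold]
        if not test_subjects:
            continue
        train = data[~data[group].isin(test_subjects)]
        test = data[data[group].isin(test_subjects)]
        model = fit_fn(train)
        pointwise.append(model.heldout_pointwise_lppd(test, seed=seed + fold))
    lppd = np.concatenate(pointwise)
    elpd = float(lppd.sum())
    se = float(np.sqrt(len(lppd) * lppd.var()))
    return elpd, se, lppd


def compare_models(variants: dict, data: pd.DataFrame, k: int = 20, seed: int = 0,
                   group: str = "subject_id") -> ModelComparison:
    """ELPD comparison across model variants with a shared fold assignment."""
    folds = assign_folds(data[group].unique(), k, seed)
    rows = {}
    for name, fit_fn in variants.items():
        elpd, se, _ = kfold_elpd(fit_fn, data, k=k, seed=seed, group=group, folds=folds)
        rows[name] = {"elpd": elpd, "se": se}
    table = pd.DataFrame(rows).T.sort_values("elpd", ascending=False)
    table["delta"] = table["elpd"] - table["elpd"].iloc[0]
    table.index.name = "model"
    return ModelComparison(table=table)
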