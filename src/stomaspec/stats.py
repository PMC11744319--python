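"""Choice statistics for the grey-card experiment.

Covers the analysis stage of the three-choice paradigm: per-group success
rates, the stage-progression and inclusion rules, the chi-square
goodness-of-fit test against the 1/3 random-choice expectation, and a
binomial logit mixed model (random intercept per individual) relating choice
outcome to illumination condition, distractor combination and choice
position.

Reinforcement trials and no-choice trials never enter success-rate
denominators or the model; natural-light performance gates inclusion of an
individual's coloured-illumination data.

The mixed model is fitted by maximum likelihood with Gauss-Hermite
quadrature over the random intercept (statsmodels provides only
variational/MAP Bayes for binomial mixed models, whose intervals are
slightly anticonservative at these design sizes); a variational-Bayes fit is
available as ``method='vb'`` for cross-checking.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import optimize, special, stats as sps

#: random-choice success probability of the one-target / two-distractor test
CHANCE = 1.0 / 3.0


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Half-up rounding (reporting convention for percentages)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Success rates


@dataclass(frozen=True)
class GroupSummary:
    """Success-rate (and optional chi-square) summary of one group x condition cell."""

    group: str
    condition: str
    n_individuals: int
    n_trials: int
    n_correct: int
    success_rate: float | None  # percent, 2 dp; None when no qualifying trials
    chi_square: float | None = None
    p_value: float | None = None

    @property
    def empty(self) -> bool:
        return self.n_trials == 0


def _qualifying(records: pd.DataFrame) -> pd.DataFrame:
    """Analysable choice trials: a choice was made and it is not reinforcement."""
    mask = pd.Series(True, index=records.index)
    if "reinforcement" in records:
        mask &= ~records["reinforcement"].astype(bool)
    if "choice_pos" in records:
        mask &= records["choice_pos"].notna()
    return records[mask & records["correct"].notna()]


def success_rate(dataset, group: str | None = None, illumination: str | None = None,
                 stage: str | None = "testing", where=None,
                 with_chi_square: bool = False) -> GroupSummary:
    """Percentage of correct first choices among qualifying trials.

    ``where`` may be a callable DataFrame predicate for ad-hoc filters.
    An empty cell yields an explicit empty summary (``success_rate=None``),
    never a spurious 0%.
    """
    df = dataset.records if hasattr(dataset, "records") else dataset
    sub = df
    if stage is not None and "stage" in sub:
        sub = sub[sub["stage"] == stage]
    if group is not None:
        sub = sub[sub["group"] == group]
    if illumination is not None:
        sub = sub[sub["illumination"] == illumination]
    if where is not None:
        sub = sub[where(sub)]
    sub = _qualifying(sub)
    n = len(sub)
    n_ind = sub["individual"].nunique() if "individual" in sub and n else 0
    if n == 0:
        return GroupSummary(group or "all", illumination or "all", 0, 0, 0, None)
    n_correct = int(sub["correct"].astype(bool).sum())
    rate = round_half_up(100.0 * n_correct / n)
    chi = p = None
    if with_chi_square:
        chi, p = chi_square_random_choice(n_correct, n)
    return GroupSummary(group or "all", illumination or "all", n_ind, n, n_correct, rate, chi, p)


def trainability_percent(n_passed: int, n_trained: int) -> float:
    """Share of trained individuals that reached reliable testing performance."""
    if n_trained <= 0:
        raise ValueError("n_trained must be positive")
    return round_half_up(100.0 * n_passed / n_trained)


# ---------------------------------------------------------------------------
# Chi-square goodness of fit vs random choice


def chi_square_random_choice(n_correct: int, n_total: int) -> tuple[float, float]:
    """Pearson goodness-of-fit of (correct, incorrect) counts vs (n/3, 2n/3).

    df = 1, upper-tail p, no continuity correction.
    """
    if not 0 <= n_correct <= n_total or n_total < 1:
        raise ValueError(f"invalid counts ({n_correct}/{n_total})")
    observed = [n_correct, n_total - n_correct]
    expected = [n_total * CHANCE, n_total * (1 - CHANCE)]
    stat, p = sps.chisquare(observed, f_exp=expected)
    return float(stat), float(p)


# ---------------------------------------------------------------------------
# Stage progression / inclusion rules


#: decision labels returned by :func:`inclusion_filter`
PROMOTE, CONTINUE, REMOVE, INCLUDE, EXCLUDE = "promote", "continue", "remove", "include", "exclude"


def inclusion_filter(history, stage: str, *, priming_window: int = 5,
                     training_window: int = 6) -> str:
    """Stage-progression decision from an ordered outcome history.

    ``history`` is a time-ordered boolean sequence: participation flags for
    priming, correct-choice flags for training, natural-light correct-choice
    flags for testing.  A pure function: the same history always yields the
    same decision.

    * priming — promote at >= 80% participation over the last
      ``priming_window`` trials; remove below 50% overall participation.
    * training — promote at > 80% success over the last ``training_window``
      trials (5/6 ~ 83% promotes); remove below 30% overall; otherwise
      continue.
    * testing — include the individual's coloured-illumination data only when
      natural-light success exceeds 50%.
    """
    h = [bool(x) for x in history]
    if stage == "priming":
        if len(h) < priming_window:
            return CONTINUE
        if np.mean(h[-priming_window:]) >= 0.8:
            return PROMOTE
        if np.mean(h) < 0.5:
            return REMOVE
        return CONTINUE
    if stage == "training":
        if len(h) < training_window:
            return CONTINUE
        if np.mean(h[-training_window:]) > 0.8:
            return PROMOTE
        if np.mean(h) < 0.3:
            return REMOVE
        return CONTINUE
    if stage == "testing":
        if not h:
            return EXCLUDE
        return INCLUDE if np.mean(h) > 0.5 else EXCLUDE
    raise ValueError(f"unknown stage {stage!r}")


# ---------------------------------------------------------------------------
# Binomial logit mixed model (random intercept per individual)


@dataclass
class ChoiceModelFit:
    """Fixed-effect estimates of the binomial logit choice model."""

    params: pd.DataFrame  # index term; columns coef, se, p_value
    random_intercept_sd: float
    loglike: float | None
    converged: bool
    separation: bool
    n_obs: int
    n_individuals: int
    method: str

    def coef(self, term: str) -> float:
        return float(self.params.loc[term, "coef"])

    def conf_int(self, term: str, level: float = 0.95) -> tuple[float, float]:
        z = sps.norm.ppf(0.5 + level / 2)
        c, s = self.params.loc[term, "coef"], self.params.loc[term, "se"]
        return float(c - z * s), float(c + z * s)

    def to_dict(self) -> dict:
        return {
            "terms": {t: {"coef": float(r["coef"]), "se": float(r["se"]),
                          "p_value": float(r["p_value"])}
                      for t, r in self.params.iterrows()},
            "random_intercept_sd": self.random_intercept_sd,
            "loglike": self.loglike,
            "converged": self.converged,
            "separation": self.separation,
            "n_obs": self.n_obs,
            "n_individuals": self.n_individuals,
            "method": self.method,
        }


def _design_matrix(df: pd.DataFrame, fixed_effects) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(df))]
    names = ["Intercept"]
    for eff in fixed_effects:
        if eff not in df or df[eff].nunique() < 2:
            continue  # constant factor carries no information
        levels = sorted(df[eff].dropna().unique(), key=str)
        for lev in levels[1:]:  # treatment coding, first level is reference
            cols.append((df[eff] == lev).to_numpy(dtype=float))
            names.append(f"{eff}[{lev}]")
    return np.column_stack(cols), names


def _glmm_loglike(beta: np.ndarray, log_sd: float, X: np.ndarray, y: np.ndarray,
                  groups: np.ndarray, nodes: np.ndarray, log_w: np.ndarray) -> float:
    """Marginal log-likelihood, Gauss-Hermite quadrature over the intercept."""
    sd = math.exp(log_sd)
    eta = X @ beta
    # log p(y_t | eta_t + sd*z_k) for each obs x node
    shift = eta[:, None] + sd * nodes[None, :]
    sign = np.where(y[:, None] > 0, 1.0, -1.0)
    logp = -np.logaddexp(0.0, -sign * shift)  # log sigmoid
    n_groups = groups.max() + 1
    per_group = np.zeros((n_groups, len(nodes)))
    np.add.at(per_group, groups, logp)
    return float(np.sum(special.logsumexp(per_group + log_w[None, :], axis=1)))


def fit_choice_model(dataset, fixed_effects=("illumination", "combination", "choice_pos"),
                     random_effect: str = "individual", method: str = "ml",
                     n_quad: int = 21) -> ChoiceModelFit:
    """Fit correct ~ fixed effects + (1 | individual), binomial logit.

    Qualifying testing-stage trials only (choice made, not reinforcement).
    ``method='ml'`` (default) maximizes the Gauss-Hermite marginal
    likelihood; ``method='vb'`` delegates to statsmodels'
    BinomialBayesMixedGLM as an independent route.
    """
    df = dataset.records if hasattr(dataset, "records") else dataset
    if "stage" in df:
        df = df[df["stage"] == "testing"]
    df = _qualifying(df).copy()
    if df.empty:
        raise ValueError("no qualifying trials to fit")
    if df[random_effect].nunique() < 2:
        raise ValueError("random intercept needs >= 2 individuals")
    y = df["correct"].astype(bool).to_numpy(dtype=float)
    X, names = _design_matrix(df, fixed_effects)
    groups, _ = pd.factorize(df[random_effect])

    if method == "vb":
        return _fit_vb(df, y, fixed_effects, random_effect)
    if method != "ml":
        raise ValueError(f"unknown method {method!r}")

    # Gauss-Hermite nodes for N(0,1): x_k*sqrt(2), w_k/sqrt(pi)
    gh_x, gh_w = np.polynomial.hermite.hermgauss(n_quad)
    nodes = gh_x * math.sqrt(2.0)
    log_w = np.log(gh_w) - 0.5 * math.log(math.pi)

    # start at the ordinary logistic fit, sd = 0.5
    beta0, *_ = np.linalg.lstsq(X, (y - 0.5) * 4.0, rcond=None)
    theta0 = np.concatenate([beta0, [math.log(0.5)]])

    def negll(theta):
        return -_glmm_loglike(theta[:-1], theta[-1], X, y, groups, nodes, log_w)

    opt = optimize.minimize(negll, theta0, method="BFGS",
                            options={"maxiter": 500, "gtol": 1e-6})
    theta = opt.x
    ll = -float(opt.fun)
    from statsmodels.tools.numdiff import approx_hess

    converged = bool(opt.success or np.linalg.norm(opt.jac) < 1e-3)
    separation = bool(np.any(np.abs(theta[:-1]) > 10.0))
    try:
        hess = approx_hess(theta, negll)
        cov = np.linalg.inv(hess)
        se_all = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        converged = False
        se_all = np.full(len(theta), np.nan)
    se = se_all[:-1]
    coefs = theta[:-1]
    zval = np.divide(coefs, se, out=np.full_like(coefs, np.nan), where=se > 0)
    pvals = 2.0 * sps.norm.sf(np.abs(zval))
    params = pd.DataFrame({"coef": coefs, "se": se, "p_value": pvals}, index=names)
    return ChoiceModelFit(params, float(math.exp(theta[-1])), ll,
                          converged and not separation, separation,
                          len(y), int(groups.max() + 1), "ml")


def _fit_vb(df: pd.DataFrame, y: np.ndarray, fixed_effects, random_effect) -> ChoiceModelFit:
    from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

    terms = [f"C({e})" for e in fixed_effects if e in df and df[e].nunique() >= 2]
    formula = "correct ~ " + (" + ".join(terms) if terms else "1")
    data = df.copy()
    data["correct"] = y
    model = BinomialBayesMixedGLM.from_formula(
        formula, {random_effect: f"0 + C({random_effect})"}, data)
    res = model.fit_vb()
    names = list(res.model.exog_names)
    k = len(names)
    coefs = np.asarray(res.fe_mean[:k])
    se = np.asarray(res.fe_sd[:k])
    pvals = 2.0 * sps.norm.sf(np.abs(coefs / se))
    params = pd.DataFrame({"coef": coefs, "se": se, "p_value": pvals}, index=names)
    separation = bool(np.any(np.abs(coefs) > 10.0))
    sd = float(np.exp(res.vcp_mean[0])) if len(res.vcp_mean) else float("nan")
    return ChoiceModelFit(params, sd, None, not separation, separation,
                          len(y), int(data[random_effect].nunique()), "vb")


# ---------------------------------------------------------------------------
# Whole-experiment report


@dataclass
class ExperimentReport:
    group_summaries: pd.DataFrame
    inclusion_ledger: pd.DataFrame
    model_fits: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({
            "group_summaries": self.group_summaries.to_dict(orient="records"),
            "inclusion_ledger": self.inclusion_ledger.to_dict(orient="records"),
            "model_fits": self.model_fits,
        }, indent=2, default=_jsonable)

    @classmethod
    def from_json(cls, text: str) -> "ExperimentReport":
        d = json.loads(text)
        return cls(pd.DataFrame(d["group_summaries"]),
                   pd.DataFrame(d["inclusion_ledger"]), d.get("model_fits", {}))


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.bool_):
        return bool(x)
    raise TypeError(f"not JSON-serializable: {type(x)}")


def summarize_experiment(dataset, fates: pd.DataFrame | None = None,
                         fit_model: bool = False) -> ExperimentReport:
    """Per group x illumination summaries plus the inclusion ledger.

    ``fates`` (individual, group, fate) comes from the simulator; when absent
    the ledger is reconstructed from the individuals present in the records.
    Empty cells are omitted from the summary table rather than reported as 0%.
    """
    df = dataset.records if hasattr(dataset, "records") else dataset
    rows = []
    test = df[df["stage"] == "testing"] if "stage" in df else df
    for (group, illum), _ in test.groupby(["group", "illumination"]):
        s = success_rate(df, group=group, illumination=illum, with_chi_square=True)
        if s.empty:
            continue
        rows.append({"group": s.group, "illumination": s.condition,
                     "n_individuals": s.n_individuals, "n_trials": s.n_trials,
                     "n_correct": s.n_correct, "success_rate": s.success_rate,
                     "chi_square": s.chi_square, "p_value": s.p_value})
    summaries = pd.DataFrame(rows)

    ledger_rows = []
    if fates is not None and len(fates):
        for group, sub in fates.groupby("group"):
            n_trained = int((sub["fate"] != "removed_priming").sum())
            n_passed = int((sub["fate"] == "included").sum())
            n_excluded = int((sub["fate"] == "excluded").sum())
            ledger_rows.append({
                "group": group, "n_trained": n_trained, "n_passed": n_passed,
                "n_excluded": n_excluded,
                "trainability_percent": (trainability_percent(n_passed, n_trained)
                                         if n_trained else None)})
    ledger = pd.DataFrame(ledger_rows)

    fits = {}
    if fit_model:
        for group in test["group"].unique():
            try:
                fit = fit_choice_model(test[test["group"] == group])
                fits[str(group)] = fit.to_dict()
            except ValueError as exc:
                fits[str(group)] = {"error": str(exc)}
    return ExperimentReport(summaries, ledger, fits)
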