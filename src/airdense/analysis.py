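"""Statistical analysis of mammographic breast density (MBD) against exposure.

Implements the study-style chain: BI-RADS density dichotomization, Cohen's
kappa between two radiologists, univariable screens (t-test / ANOVA /
Pearson chi-square), multivariable logistic regression (non-stepwise and
stepwise over the six pollutants), three nested confounder models,
menopause/age-stratified fits with a moderator (interaction) test, odds
ratio rescaling to a Δ-unit increment, and the two-proportion sample-size
calculation.

Odds ratios use Wald confidence intervals, ``exp(coef ± z * SE)``, which
are symmetric on the log scale.  Stepwise selection is forward entry with
backward pruning on likelihood-ratio p-values (entry 0.05, removal 0.10).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.inter_rater import cohens_kappa as _sm_cohens_kappa
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

BIRADS_LOW = frozenset({"a", "b"})
BIRADS_HIGH = frozenset({"c", "d"})
BIRADS_ORDER = ("a", "b", "c", "d")


class SeparationError(RuntimeError):
    """Perfect separation: the MLE does not exist; no silent estimates returned."""


class ConvergenceError(RuntimeError):
    """The logistic fit failed to converge."""


def dichotomize(birads: str) -> str:
    """Collapse a 4-level BI-RADS density rating to ``low`` (a, b) or ``high`` (c, d)."""
    if birads in BIRADS_LOW:
        return "low"
    if birads in BIRADS_HIGH:
        return "high"
    raise ValueError(f"invalid BI-RADS density category: {birads!r}")


@dataclass(frozen=True)
class AgreementResult:
    kappa: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int


def cohens_kappa(ratings_a, ratings_b, alpha: float = 0.05) -> AgreementResult:
    """Unweighted Cohen's kappa between two raters over a categorical scale.

    κ = (p_o - p_e) / (1 - p_e) with p_e from marginal products; the CI is
    the large-sample asymptotic one with normal quantiles.  Raises if both
    raters are constant and identical (p_e = 1, κ undefined).
    """
    a = pd.Series(list(ratings_a))
    b = pd.Series(list(ratings_b))
    if len(a) != len(b):
        raise ValueError("rating vectors must have equal length")
    if len(a) < 2:
        raise ValueError("need at least 2 paired ratings")
    cats = sorted(set(a) | set(b))
    table = pd.crosstab(
        pd.Categorical(a, categories=cats), pd.Categorical(b, categories=cats),
        dropna=False,
    ).to_numpy()
    n = table.sum()
    p_e = float((table.sum(0) / n) @ (table.sum(1) / n))
    if p_e >= 1.0 - 1e-15:
        raise ValueError("kappa undefined: both raters constant and equal (p_e = 1)")
    res = _sm_cohens_kappa(table, return_results=True)
    z = stats.norm.ppf(1 - alpha / 2)
    return AgreementResult(
        kappa=float(res.kappa),
        ci_low=float(res.kappa - z * res.std_kappa),
        ci_high=float(res.kappa + z * res.std_kappa),
        p_value=float(res.pvalue_two_sided),
        n=int(n),
    )


def univariable_compare(
    cohort: pd.DataFrame,
    variable: str,
    group: str = "density",
    continuous: bool | None = None,
) -> dict:
    """Univariable comparison of one variable across outcome groups.

    Continuous variables: two-sided t-test for 2 groups, one-way ANOVA for
    more.  Categorical variables: Pearson chi-square without continuity
    correction.  Returns ``{"test", "statistic", "p_value"}``.
    """
    sub = cohort[[variable, group]].dropna()
    if continuous is None:
        continuous = pd.api.types.is_numeric_dtype(sub[variable]) and (
            sub[variable].nunique() > 2
        )
    groups = [g[variable].to_numpy() for _, g in sub.groupby(group, observed=True)]
    if any(len(g) == 0 for g in groups) or len(groups) < 2:
        raise ValueError(f"empty group when comparing {variable!r} by {group!r}")
    if continuous:
        if len(groups) == 2:
            stat, p = stats.ttest_ind(*groups)
            return {"test": "t", "statistic": float(stat), "p_value": float(p)}
        stat, p = stats.f_oneway(*groups)
        return {"test": "anova", "statistic": float(stat), "p_value": float(p)}
    table = pd.crosstab(sub[variable], sub[group])
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return {"test": "chi2", "statistic": float(stat), "p_value": float(p)}


@dataclass
class ModelResult:
    """A fitted logistic model: per-term OR with 95% CI and p-value."""

    label: str
    terms: list[str]
    odds_ratios: pd.DataFrame  # index=term, columns: or, ci_low, ci_high, p_value, coef, se
    n: int
    llf: float
    trace: list[dict] = field(default_factory=list)

    def term_or(self, term: str) -> float:
        return float(self.odds_ratios.loc[term, "or"])

    def summary_frame(self) -> pd.DataFrame:
        return self.odds_ratios.copy()


def _fit_result(y, X, label: str, alpha: float = 0.05) -> ModelResult:
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
        except (PerfectSeparationError, PerfectSeparationWarning) as exc:
            raise SeparationError(str(exc)) from exc
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular design in model {label!r}") from exc
    if not fit.mle_retvals.get("converged", False):
        raise ConvergenceError(f"logistic fit did not converge for model {label!r}")
    z = stats.norm.ppf(1 - alpha / 2)
    coefs = fit.params
    ses = fit.bse
    frame = pd.DataFrame(
        {
            "coef": coefs,
            "se": ses,
            "or": np.exp(coefs),
            "ci_low": np.exp(coefs - z * ses),
            "ci_high": np.exp(coefs + z * ses),
            "p_value": fit.pvalues,
        }
    )
    terms = [t for t in X.columns if t != "const"]
    return ModelResult(
        label=label, terms=terms, odds_ratios=frame, n=int(len(y)), llf=float(fit.llf)
    )


def fit_logistic(
    cohort: pd.DataFrame,
    terms: list[str],
    outcome: str = "high_density",
    label: str = "logistic",
) -> ModelResult:
    """Maximum-likelihood logistic regression of a binary outcome on ``terms``.

    Complete-case analysis: rows with a missing outcome or term are dropped.
    Raises :class:`SeparationError` on perfect separation and
    :class:`ConvergenceError` on non-convergence rather than returning
    silent estimates.
    """
    data = cohort[[outcome] + list(terms)].dropna()
    y = data[outcome].astype(float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError(f"outcome {outcome!r} must be binary 0/1")
    if len(data) <= len(terms):
        raise ValueError("need more observations than model terms")
    X = sm.add_constant(data[list(terms)].astype(float), has_constant="add")
    return _fit_result(y, X, label)


def _lr_pvalue(llf_full: float, llf_reduced: float, df: int = 1) -> float:
    lr = 2.0 * (llf_full - llf_reduced)
    return float(stats.chi2.sf(max(lr, 0.0), df))


def stepwise_logistic(
    cohort: pd.DataFrame,
    candidates: list[str],
    outcome: str = "high_density",
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    label: str = "stepwise",
) -> ModelResult:
    """Forward selection with backward pruning on likelihood-ratio p-values.

    At each step the candidate with the smallest LR p-value enters if below
    ``p_enter``; any included term whose LR p-value (against the model
    without it) exceeds ``p_remove`` is then dropped.  The entry/removal
    trace is recorded on the returned :class:`ModelResult`.  With no term
    passing entry the result is the intercept-only model.
    """
    data = cohort[[outcome] + list(candidates)].dropna()
    trace: list[dict] = []
    included: list[str] = []

    def fit_terms(terms):
        y = data[outcome].astype(float)
        X = sm.add_constant(
            data[list(terms)].astype(float) if terms else data[[]], has_constant="add"
        )
        return _fit_result(y, X, label)

    current = fit_terms(included)
    while True:
        changed = False
        # forward step
        remaining = [c for c in candidates if c not in included]
        best_p, best_term, best_fit = np.inf, None, None
        for term in remaining:
            try:
                cand = fit_terms(included + [term])
            except (SeparationError, ConvergenceError):
                continue  # an unfittable candidate cannot enter
            p = _lr_pvalue(cand.llf, current.llf)
            if p < best_p:
                best_p, best_term, best_fit = p, term, cand
        if best_term is not None and best_p < p_enter:
            included.append(best_term)
            current = best_fit
            trace.append({"action": "enter", "term": best_term, "p_value": best_p})
            changed = True
        # backward step
        while len(included) > 1:
            worst_p, worst_term = -np.inf, None
            for term in included:
                reduced = fit_terms([t for t in included if t != term])
                p = _lr_pvalue(current.llf, reduced.llf)
                if p > worst_p:
                    worst_p, worst_term = p, term
            if worst_term is not None and worst_p > p_remove:
                included.remove(worst_term)
                current = fit_terms(included)
                trace.append({"action": "remove", "term": worst_term, "p_value": worst_p})
                changed = True
            else:
                break
        if not changed:
            break
    current.trace = trace
    current.label = label
    return current


MODEL2_COVARIATES = [
    "age",
    "bmi",
    "smoking",
    "ocp_history",
    "menopause",
    "parity",
    "breast_disease_history",
]
MODEL3_EXTRA = ["metformin", "aspirin", "vitamin_d", "calcium"]


def confounder_models(
    cohort: pd.DataFrame,
    exposures: list[str] = ("co", "no2"),
    outcome: str = "high_density",
) -> dict[str, ModelResult]:
    """Three nested logistic models of density on the retained pollutants.

    * Model 1: exposures only.
    * Model 2: + age, BMI, smoking, OCP history, menopause, parity and
      breast-disease history.
    * Model 3: Model 2 + metformin, aspirin, vitamin D and calcium use.
    """
    exposures = list(exposures)
    m1 = fit_logistic(cohort, exposures, outcome, label="model1")
    m2 = fit_logistic(cohort, exposures + MODEL2_COVARIATES, outcome, label="model2")
    m3 = fit_logistic(
        cohort, exposures + MODEL2_COVARIATES + MODEL3_EXTRA, outcome, label="model3"
    )
    return {"model1": m1, "model2": m2, "model3": m3}


def stratified_and_moderator(
    cohort: pd.DataFrame,
    exposures: list[str] = ("co", "no2"),
    stratum: str = "menopause",
    outcome: str = "high_density",
    covariates: list[str] | None = None,
) -> dict:
    """Per-stratum Model-3-style fits plus an exposure x stratum interaction test.

    The stratum variable must be binary (dichotomize age at the cohort
    median first if stratifying on age).  The moderator test is a
    likelihood-ratio test of all exposure x stratum interaction terms in
    the pooled model.  Strata smaller than 10 observations per model term
    draw a warning.
    """
    exposures = list(exposures)
    if covariates is None:
        covariates = [
            c for c in MODEL2_COVARIATES + MODEL3_EXTRA
            if c != stratum and c in cohort.columns
        ]
    levels = sorted(cohort[stratum].dropna().unique())
    if len(levels) != 2:
        raise ValueError(f"stratum {stratum!r} must be binary, got levels {levels}")
    strata_results = {}
    terms = exposures + covariates
    for level in levels:
        sub = cohort[cohort[stratum] == level]
        if len(sub) < 10 * (len(terms) + 1):
            warnings.warn(
                f"stratum {stratum}={level}: only {len(sub)} observations for "
                f"{len(terms)} terms",
                stacklevel=2,
            )
        strata_results[level] = fit_logistic(
            sub, terms, outcome, label=f"{stratum}={level}"
        )
    # pooled interaction model
    pooled = cohort[[outcome, stratum] + terms].dropna().copy()
    for e in exposures:
        pooled[f"{e}_x_{stratum}"] = pooled[e] * pooled[stratum].astype(float)
    base_terms = terms + [stratum]
    inter_terms = base_terms + [f"{e}_x_{stratum}" for e in exposures]
    base = fit_logistic(pooled, base_terms, outcome, label="pooled")
    full = fit_logistic(pooled, inter_terms, outcome, label="pooled+interaction")
    p_inter = _lr_pvalue(full.llf, base.llf, df=len(exposures))
    return {
        "strata": strata_results,
        "interaction_model": full,
        "interaction_p_value": p_inter,
    }


def rescale_or(or_per_unit: float, delta: float) -> float:
    """Rescale a per-unit odds ratio to a delta-unit increment: OR^delta."""
    if or_per_unit <= 0:
        raise ValueError("odds ratio must be positive")
    return float(or_per_unit ** delta)


def sample_size_two_proportions(
    p0: float,
    or_assumed: float,
    power: float = 0.80,
    alpha: float = 0.05,
    ratio: float = 1.0,
) -> dict:
    """Total sample size to detect an odds ratio between two groups.

    The exposed-group proportion is derived from the control proportion and
    the odds ratio: ``p1 = OR * p0 / (1 + p0 * (OR - 1))``.  Returns both
    the uncorrected normal-approximation total and the continuity-corrected
    (Fleiss/Casagrande-Pike-Smith) total; the corrected figure is the
    headline value (key ``"total"``).  ``ratio`` is n1/n0.
    """
    if not (0 < p0 < 1 and 0 < power < 1 and 0 < alpha < 1):
        raise ValueError("p0, power and alpha must lie in (0, 1)")
    if or_assumed <= 0:
        raise ValueError("odds ratio must be positive")
    if abs(or_assumed - 1.0) < 1e-12:
        raise ValueError("odds ratio of 1 implies no effect; sample size unbounded")
    p1 = or_assumed * p0 / (1 + p0 * (or_assumed - 1))
    if not (0 < p1 < 1):
        raise ValueError(f"derived p1={p1} outside (0,1)")
    d = abs(p1 - p0)
    z_a = stats.norm.ppf(1 - alpha / 2)
    z_b = stats.norm.ppf(power)
    r = ratio
    p_bar = (p0 + r * p1) / (1 + r)
    q_bar = 1 - p_bar
    # n0 = control-group size; n1 = r * n0; var(p1_hat - p0_hat) decomposition
    n0 = (
        z_a * np.sqrt(p_bar * q_bar * (r + 1) / r)
        + z_b * np.sqrt(p0 * (1 - p0) + p1 * (1 - p1) / r)
    ) ** 2 / d ** 2
    # Casagrande-Pike-Smith continuity correction (Fleiss); r=1 reduces to
    # n' = (n/4) * (1 + sqrt(1 + 4/(n*d)))^2
    n0_cc = (n0 / 4.0) * (1.0 + np.sqrt(1.0 + 2.0 * (r + 1) / (r * n0 * d))) ** 2
    n_total = int(np.ceil(n0)) + int(np.ceil(r * n0))
    n_total_cc = int(np.ceil(n0_cc)) + int(np.ceil(r * n0_cc))
    return {
        "p1": float(p1),
        "n_per_group_uncorrected": float(n0),
        "total_uncorrected": n_total,
        "n_per_group": float(n0_cc),
        "total": n_total_cc,
    }
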