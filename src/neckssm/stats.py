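"""Case-control statistics: group comparisons, logistic models, ROC.

Mirrors the analysis plan of the underlying case-control design:
continuous variables are compared with the Mann-Whitney U test,
3-level category variables with the Fisher exact test, and discrimination
is assessed with three logistic regression models — shape-model scores
only, conventional measurements only, and both combined — all predictors
entered simultaneously (the "enter" method, no stepwise selection).
Predicted probabilities feed an ROC curve; sensitivity and specificity are
read off at the 0.5 probability cut-off.  Reported metrics are in-sample
(apparent), as is conventional for this design; a cross-validated variant
can be enabled explicitly.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from scipy.special import gammaln
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve as _sk_roc_curve
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from neckssm.errors import InvalidParameterError
from neckssm.ssm import PCScores

__all__ = [
    "GroupComparison",
    "LogisticModel",
    "DiscriminationResult",
    "mann_whitney",
    "fisher_exact",
    "fit_logistic",
    "roc_metrics",
    "run_models",
]

CONVENTIONAL_PREDICTORS = [
    "neck_length_mm",
    "neck_diameter_mm",
    "suprarenal_deg",
    "infrarenal_deg",
    "calcification_cat",
    "thrombus_cat",
]


@dataclass
class GroupComparison:
    """One variable's case-vs-control comparison (median/quartile summary)."""

    variable: str
    median_a: float
    q1_a: float
    q3_a: float
    median_b: float
    q1_b: float
    q3_b: float
    u_statistic: float
    p_value: float
    test_name: str


@dataclass
class LogisticModel:
    """A fitted logistic regression ('enter' method: all predictors in)."""

    label: str  # SSM | conventional | combined
    predictor_names: list[str]
    coefficients: np.ndarray
    intercept: float
    probabilities: np.ndarray
    separation_flag: bool = False

    def predict(self, X: np.ndarray) -> np.ndarray:
        z = np.asarray(X, dtype=float) @ self.coefficients + self.intercept
        return 1.0 / (1.0 + np.exp(-z))


@dataclass
class DiscriminationResult:
    """ROC summary of one model's predicted probabilities."""

    label: str
    auc: float
    sensitivity: float
    specificity: float
    threshold: float
    fpr: np.ndarray = field(repr=False, default=None)
    tpr: np.ndarray = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# group comparison tests
# ---------------------------------------------------------------------------


def _exact_mannwhitney_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exact two-sided permutation p of the U statistic (handles ties).

    Enumerates all labelings of the pooled sample; feasible for
    n1 + n2 <= 12 (at most C(12,6) = 924 labelings).
    """
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)  # midranks
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    combos = list(itertools.combinations(range(n1 + n2), n1))
    u_perm = np.array([ranks[list(c)].sum() for c in combos]) - n1 * (n1 + 1) / 2.0
    p = float(np.mean(np.abs(u_perm - mu) >= abs(u_obs - mu) - 1e-9))
    return u_obs, p


def mann_whitney(
    a, b, variable: str = "", exact_max_n: int = 12
) -> GroupComparison:
    """Two-sided Mann-Whitney U comparison of two samples.

    Uses exact enumeration over labelings when n1 + n2 <= ``exact_max_n``
    (valid under ties), otherwise the tie-corrected normal approximation
    (no continuity correction).  If every pooled value is identical the
    comparison is degenerate and p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise InvalidParameterError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        u = len(a) * len(b) / 2.0
        p = 1.0
        test = "mann-whitney (degenerate: all values identical)"
    elif len(pooled) <= exact_max_n:
        u, p = _exact_mannwhitney_p(a, b)
        test = "mann-whitney exact"
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                               use_continuity=False)
        u, p = float(res.statistic), float(res.pvalue)
        test = "mann-whitney asymptotic"
    qa = np.percentile(a, [25, 50, 75])
    qb = np.percentile(b, [25, 50, 75])
    return GroupComparison(
        variable=variable,
        median_a=float(qa[1]), q1_a=float(qa[0]), q3_a=float(qa[2]),
        median_b=float(qb[1]), q1_b=float(qb[0]), q3_b=float(qb[2]),
        u_statistic=float(u), p_value=float(min(p, 1.0)), test_name=test,
    )


def _log_table_prob(col0: np.ndarray, row_sums: np.ndarray, c0: int, n: int) -> float:
    """Log multivariate-hypergeometric probability of an r x 2 table given
    its margins (col0 = first-column counts per row)."""

    def logc(n_, k_):
        return gammaln(n_ + 1) - gammaln(k_ + 1) - gammaln(n_ - k_ + 1)

    return float(np.sum(logc(row_sums, col0)) - logc(n, c0))


def fisher_exact(
    table, enumeration_budget: int = 1_000_000, mc_draws: int = 100_000, seed: int = 0
) -> float:
    """Two-sided Fisher exact p for an r x 2 table (r = 2 or 3).

    2 x 2 uses the standard hypergeometric two-sided rule (sum of table
    probabilities <= the observed one).  3 x 2 is the Freeman-Halton
    extension by full enumeration over tables with the observed margins;
    above ``enumeration_budget`` candidate tables a seeded Monte-Carlo
    estimate over ``mc_draws`` margin-preserving draws is used instead.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2 or t.shape[1] != 2 or t.shape[0] not in (2, 3):
        raise InvalidParameterError("table must be 2x2 or 3x2")
    if (t < 0).any():
        raise InvalidParameterError("counts must be non-negative")
    if t.shape[0] == 2:
        return float(sps.fisher_exact(t, alternative="two-sided")[1])

    row_sums = t.sum(axis=1)
    c0 = int(t[:, 0].sum())
    n = int(t.sum())
    if n == 0:
        return 1.0
    logp_obs = _log_table_prob(t[:, 0], row_sums, c0, n)
    tol = 1e-7

    n_candidates = int(np.prod(row_sums[:-1] + 1))
    if n_candidates <= enumeration_budget:
        p = 0.0
        for a1 in range(max(0, c0 - row_sums[1] - row_sums[2]), min(row_sums[0], c0) + 1):
            for a2 in range(max(0, c0 - a1 - row_sums[2]), min(row_sums[1], c0 - a1) + 1):
                a3 = c0 - a1 - a2
                lp = _log_table_prob(np.array([a1, a2, a3]), row_sums, c0, n)
                if lp <= logp_obs + tol:
                    p += np.exp(lp)
        return float(min(p, 1.0))

    rng = np.random.default_rng(seed)
    draws = rng.multivariate_hypergeometric(row_sums, c0, size=mc_draws)
    lps = np.array([_log_table_prob(d, row_sums, c0, n) for d in draws])
    return float(np.mean(lps <= logp_obs + tol))


# ---------------------------------------------------------------------------
# logistic models and ROC
# ---------------------------------------------------------------------------


def fit_logistic(
    features: np.ndarray,
    labels: np.ndarray,
    predictor_names: list[str] | None = None,
    label: str = "",
) -> LogisticModel:
    """Maximum-likelihood logistic regression, all predictors entered.

    Fitting runs on internally standardized predictors (the MLE's
    predicted probabilities are invariant to affine predictor rescaling);
    coefficients are reported on the original scale.  Complete or
    quasi-complete separation is detected and resolved by an L2-ridge
    refit with penalty 1e-6 * n, flagged on the returned model.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(labels, dtype=float)
    if X.shape[0] != len(y):
        raise InvalidParameterError("features and labels length mismatch")
    n, p = X.shape
    if len(np.unique(y)) < 2:
        raise InvalidParameterError("both classes must be present")
    if n <= p:
        raise InvalidParameterError(f"n={n} subjects cannot support {p} predictors")
    if predictor_names is None:
        predictor_names = [f"x{j}" for j in range(p)]

    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd

    beta_s = None
    separated = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, sm.add_constant(Xs, has_constant="add")).fit(
                disp=0, maxiter=100, tol=1e-8
            )
            if fit.mle_retvals.get("converged", False) and np.all(np.abs(fit.params) < 1e3):
                beta_s = fit.params
            else:
                separated = True
        except (PerfectSeparationError, np.linalg.LinAlgError):
            separated = True

    if beta_s is None:
        separated = True
        ridge = LogisticRegression(C=1.0 / (1e-6 * n), solver="lbfgs", max_iter=5000)
        ridge.fit(Xs, y)
        beta_s = np.concatenate([ridge.intercept_, ridge.coef_.ravel()])

    b0_s, b_s = beta_s[0], beta_s[1:]
    coef = b_s / sd
    intercept = float(b0_s - np.sum(b_s * mu / sd))
    model = LogisticModel(
        label=label,
        predictor_names=list(predictor_names),
        coefficients=coef,
        intercept=intercept,
        probabilities=np.empty(0),
        separation_flag=separated,
    )
    model.probabilities = model.predict(X)
    return model


def roc_metrics(probabilities, labels, threshold: float = 0.5, label: str = "") -> DiscriminationResult:
    """Empirical ROC of predicted probabilities, with the 0.5-cut-off
    sensitivity/specificity.

    AUC is the trapezoid over all unique thresholds, which equals the
    midrank Mann-Whitney statistic U/(n1*n2) of the probabilities.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    if ((p < 0) | (p > 1)).any():
        raise InvalidParameterError("probabilities must lie in [0, 1]")
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise InvalidParameterError("both classes must be present")
    fpr, tpr, _ = _sk_roc_curve(y, p, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    pred = p >= threshold
    tp = int(np.sum(pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    return DiscriminationResult(
        label=label,
        auc=auc,
        sensitivity=tp / n1,
        specificity=tn / n0,
        threshold=threshold,
        fpr=fpr,
        tpr=tpr,
    )


# ---------------------------------------------------------------------------
# the three-model comparison
# ---------------------------------------------------------------------------


def run_models(
    scores: PCScores,
    measures: pd.DataFrame,
    labels: np.ndarray | None = None,
    threshold: float = 0.5,
    alpha: float = 0.05,
    category_coding: str = "ordinal",
) -> dict:
    """Fit the three discrimination models and the per-variable screens.

    Parameters
    ----------
    scores
        Retained shape-mode scores with subject ids and group labels.
    measures
        Table with columns ``subject_id``, ``group`` and the six
        conventional predictors (see ``CONVENTIONAL_PREDICTORS``).
    labels
        Optional explicit 0/1 case labels; defaults to ``group == 'case'``.
    category_coding
        ``"ordinal"`` enters calcification/thrombus as integers 0/1/2;
        ``"dummy"`` expands them into indicator columns.

    Returns a dict with keys ``models`` (label -> LogisticModel),
    ``results`` (label -> DiscriminationResult), ``pc_tests`` and
    ``measure_tests`` (lists of GroupComparison), ``category_tests``
    (variable -> Fisher p), and ``significant_pcs`` (indices, 1-based,
    with p < alpha).
    """
    ids_scores = list(scores.subject_ids)
    ids_meas = list(measures["subject_id"])
    missing = sorted(set(ids_scores) ^ set(ids_meas))
    if missing:
        raise InvalidParameterError(f"subjects missing from one input: {missing}")
    meas = measures.set_index("subject_id").loc[ids_scores].reset_index()

    if labels is None:
        labels = np.array([1 if g == "case" else 0 for g in scores.groups], dtype=int)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise InvalidParameterError("both groups must be present")

    S = scores.scores
    k = S.shape[1]
    pc_names = [f"pc{j + 1}" for j in range(k)]

    cont_names = CONVENTIONAL_PREDICTORS[:4]
    cat_names = CONVENTIONAL_PREDICTORS[4:]
    if category_coding == "ordinal":
        conv = meas[CONVENTIONAL_PREDICTORS].to_numpy(dtype=float)
        conv_names = list(CONVENTIONAL_PREDICTORS)
    elif category_coding == "dummy":
        blocks = [meas[cont_names].to_numpy(dtype=float)]
        conv_names = list(cont_names)
        for c in cat_names:
            d = pd.get_dummies(meas[c].astype(int)).reindex(columns=[0, 1, 2], fill_value=0)
            blocks.append(d[[1, 2]].to_numpy(dtype=float))
            conv_names += [f"{c}_1", f"{c}_2"]
        conv = np.hstack(blocks)
    else:
        raise InvalidParameterError("category_coding must be 'ordinal' or 'dummy'")

    feature_sets = {
        "SSM": (S, pc_names),
        "conventional": (conv, conv_names),
        "combined": (np.hstack([S, conv]), pc_names + conv_names),
    }
    models: dict[str, LogisticModel] = {}
    results: dict[str, DiscriminationResult] = {}
    for name, (X, cols) in feature_sets.items():
        m = fit_logistic(X, labels, predictor_names=cols, label=name)
        models[name] = m
        results[name] = roc_metrics(m.probabilities, labels, threshold=threshold, label=name)

    case = labels == 1
    pc_tests = [
        mann_whitney(S[case, j], S[~case, j], variable=pc_names[j]) for j in range(k)
    ]
    measure_tests = [
        mann_whitney(
            meas.loc[case, v].to_numpy(dtype=float),
            meas.loc[~case, v].to_numpy(dtype=float),
            variable=v,
        )
        for v in cont_names
    ]
    category_tests = {}
    for v in cat_names:
        counts = np.zeros((3, 2), dtype=int)
        vals = meas[v].to_numpy(dtype=int)
        for cat in range(3):
            counts[cat, 0] = int(np.sum(case & (vals == cat)))
            counts[cat, 1] = int(np.sum(~case & (vals == cat)))
        category_tests[v] = fisher_exact(counts)

    significant = [j + 1 for j, t in enumerate(pc_tests) if t.p_value < alpha]
    return {
        "models": models,
        "results": results,
        "pc_tests": pc_tests,
        "measure_tests": measure_tests,
        "category_tests": category_tests,
        "significant_pcs": significant,
    }
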