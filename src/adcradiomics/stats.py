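"""Cohort-level statistics for two-group imaging-biomarker studies.

Covers the full statistical stage of a recurrence-prediction analysis:

* normality-routed two-group comparison (Shapiro-Wilk -> Welch t or
  Mann-Whitney U),
* empirical ROC analysis with DeLong (or Hanley-McNeil) confidence intervals
  and a Youden-optimal cutoff,
* accuracy reconstruction from per-group sensitivity/specificity rates,
* Dunn-Sidak familywise correction,
* forward stepwise logistic regression with likelihood-ratio entry tests,
* contingency rate comparison (chi-square with continuity correction, Fisher
  exact for sparse tables),
* inter-observer ICC(2,1) with its F-based 95% CI.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ComparisonResult",
    "RocResult",
    "IccResult",
    "StepwiseResult",
    "ContingencyResult",
    "compare_groups",
    "empirical_auc",
    "roc_analysis",
    "accuracy_from_rates",
    "sidak_adjust",
    "stepwise_logistic",
    "contingency_rates",
    "icc_two_observers",
    "binormal_auc_simulation",
    "UndefinedRocError",
]


class UndefinedRocError(ValueError):
    """Raised when ROC analysis is requested with only one class present."""


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupSummary:
    n: int
    mean: float
    sd: float
    median: float
    q1: float
    q3: float


@dataclass(frozen=True)
class ComparisonResult:
    feature: str
    test: str  # 'welch_t' or 'mann_whitney'
    p_value: float
    group1: GroupSummary
    group2: GroupSummary
    shapiro_p: tuple[float, float]
    zero_variance: bool = False


def _summarize(x: np.ndarray) -> GroupSummary:
    return GroupSummary(
        n=len(x),
        mean=float(np.mean(x)),
        sd=float(np.std(x, ddof=1)) if len(x) > 1 else 0.0,
        median=float(np.median(x)),
        q1=float(np.percentile(x, 25)),
        q3=float(np.percentile(x, 75)),
    )


def compare_groups(group1, group2, feature: str = "", alpha_normality: float = 0.05) -> ComparisonResult:
    """Compare two independent samples, routing the test by normality.

    Shapiro-Wilk is run on each group at ``alpha_normality``; if both pass,
    a Welch (unequal-variance) two-sample t-test is used, otherwise the
    two-sided Mann-Whitney U test. A zero-variance group cannot be tested for
    normality, so it is routed to Mann-Whitney and flagged.
    """
    x = np.asarray(group1, float)
    y = np.asarray(group2, float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("need at least 3 observations per group")

    zero_var = np.ptp(x) == 0 or np.ptp(y) == 0
    if zero_var:
        sw = (float("nan"), float("nan"))
        normal = False
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sw = (float(sps.shapiro(x).pvalue), float(sps.shapiro(y).pvalue))
        normal = sw[0] > alpha_normality and sw[1] > alpha_normality

    if normal:
        test = "welch_t"
        p = float(sps.ttest_ind(x, y, equal_var=False).pvalue)
    else:
        test = "mann_whitney"
        p = float(sps.mannwhitneyu(x, y, alternative="two-sided").pvalue)

    return ComparisonResult(
        feature=feature,
        test=test,
        p_value=p,
        group1=_summarize(x),
        group2=_summarize(y),
        shapiro_p=sw,
        zero_variance=zero_var,
    )


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------


def empirical_auc(scores, labels) -> float:
    """Tie-corrected empirical AUC: P(score+ > score-) + 0.5 P(tie).

    Identical to U/(n1*n2) for the Mann-Whitney U statistic on the same data.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedRocError("both classes must be present")
    ranks = sps.rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def _delong_ci(scores_pos, scores_neg, auc: float, level: float) -> tuple[float, float]:
    """DeLong variance of the empirical AUC via structural components."""
    m, n = len(scores_pos), len(scores_neg)
    # placement values
    psi = (scores_pos[:, None] > scores_neg[None, :]).astype(float)
    psi += 0.5 * (scores_pos[:, None] == scores_neg[None, :])
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    se = math.sqrt(s10 / m + s01 / n)
    z = sps.norm.ppf(0.5 + level / 2)
    return max(0.0, auc - z * se), min(1.0, auc + z * se)


def _hanley_mcneil_ci(m: int, n: int, auc: float, level: float) -> tuple[float, float]:
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    var = (auc * (1 - auc) + (m - 1) * (q1 - auc**2) + (n - 1) * (q2 - auc**2)) / (m * n)
    z = sps.norm.ppf(0.5 + level / 2)
    se = math.sqrt(max(var, 0.0))
    return max(0.0, auc - z * se), min(1.0, auc + z * se)


@dataclass(frozen=True)
class RocResult:
    auc: float
    auc_ci_low: float
    auc_ci_high: float
    cutoff: float  # in feature units
    sensitivity: float  # percent
    specificity: float  # percent
    accuracy: float  # percent
    positive_on_low: bool  # True when low feature values predict the event
    ci_method: str = "delong"


def roc_analysis(scores, labels, ci: str = "delong", ci_level: float = 0.95) -> RocResult:
    """Empirical ROC analysis with auto-orientation and a Youden cutoff.

    ``labels`` marks the event class (e.g. recurrence). The AUC is computed
    tie-corrected and oriented so it is >= 0.5, recording whether low or high
    values predict the event. The cutoff is the Youden-optimal threshold
    (midpoint between adjacent distinct scores); sensitivity/specificity are
    the event/non-event correct-classification rates at that cutoff and
    accuracy is the overall correct fraction.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    auc = empirical_auc(scores, labels)
    positive_on_low = auc < 0.5
    oriented = -scores if positive_on_low else scores
    if positive_on_low:
        auc = 1.0 - auc

    pos = oriented[labels]
    neg = oriented[~labels]

    # candidate cutoffs: midpoints between adjacent distinct scores plus the ends
    uniq = np.unique(oriented)
    if len(uniq) == 1:
        cands = np.array([uniq[0]])
    else:
        cands = np.concatenate(([uniq[0] - 1], (uniq[:-1] + uniq[1:]) / 2, [uniq[-1] + 1]))
    sens = (pos[None, :] > cands[:, None]).mean(axis=1)
    spec = (neg[None, :] <= cands[:, None]).mean(axis=1)
    youden = sens + spec - 1
    best = int(np.argmax(youden))
    cutoff = float(cands[best])
    if positive_on_low:
        cutoff = -cutoff
    accuracy = (sens[best] * len(pos) + spec[best] * len(neg)) / (len(pos) + len(neg))

    if ci == "delong":
        lo, hi = _delong_ci(pos, neg, auc, ci_level)
    elif ci == "hanley_mcneil":
        lo, hi = _hanley_mcneil_ci(len(pos), len(neg), auc, ci_level)
    else:
        raise ValueError("ci must be 'delong' or 'hanley_mcneil'")

    return RocResult(
        auc=float(auc),
        auc_ci_low=float(lo),
        auc_ci_high=float(hi),
        cutoff=cutoff,
        sensitivity=float(sens[best] * 100),
        specificity=float(spec[best] * 100),
        accuracy=float(accuracy * 100),
        positive_on_low=bool(positive_on_low),
        ci_method=ci,
    )


def accuracy_from_rates(rate1: float, rate2: float, n1: int, n2: int) -> float:
    """Overall accuracy (%) reconstructed from two per-group correct rates.

    Per-group correct counts are recovered by rounding rate*n/100 to the
    nearest integer (half rounds up), then pooled.
    """
    if not (0 <= rate1 <= 100 and 0 <= rate2 <= 100):
        raise ValueError("rates must be in [0, 100]")
    if n1 < 1 or n2 < 1:
        raise ValueError("group sizes must be >= 1")
    k1 = math.floor(rate1 * n1 / 100 + 0.5)
    k2 = math.floor(rate2 * n2 / 100 + 0.5)
    return (k1 + k2) / (n1 + n2) * 100.0


def sidak_adjust(alpha: float, m: int) -> float:
    """Dunn-Sidak adjusted per-test significance level 1 - (1-alpha)^(1/m)."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return 1.0 - (1.0 - alpha) ** (1.0 / m)


# ---------------------------------------------------------------------------
# stepwise logistic regression
# ---------------------------------------------------------------------------


@dataclass
class _LogitFit:
    params: np.ndarray
    cov: np.ndarray
    llf: float
    separation: bool


def _fit_logit(X: np.ndarray, y: np.ndarray, ridge: float = 0.0) -> _LogitFit:
    """Newton-fitted logistic regression (intercept in column 0).

    A small L2 penalty on the non-intercept coefficients stabilises fits under
    (quasi-)separation; ``separation`` is flagged when the unpenalized fit ran
    away and the ridge fallback was used.
    """
    import statsmodels.api as sm

    if ridge == 0.0:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(y, X).fit(disp=0, maxiter=200, warn_convergence=False)
            if res.mle_retvals.get("converged", False) and np.max(np.abs(res.params)) < 30:
                return _LogitFit(
                    params=np.asarray(res.params),
                    cov=np.asarray(res.cov_params()),
                    llf=float(res.llf),
                    separation=False,
                )
        except Exception:
            pass
        return _fit_logit(X, y, ridge=1e-3)

    # penalized Newton fallback
    k = X.shape[1]
    pen = np.full(k, ridge)
    pen[0] = 0.0  # do not penalize the intercept
    beta = np.zeros(k)
    for _ in range(100):
        eta = np.clip(X @ beta, -30, 30)
        p = 1 / (1 + np.exp(-eta))
        w = p * (1 - p)
        g = X.T @ (y - p) - 2 * pen * beta
        H = (X * w[:, None]).T @ X + 2 * np.diag(pen)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0]
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    eta = np.clip(X @ beta, -30, 30)
    p = np.clip(1 / (1 + np.exp(-eta)), 1e-12, 1 - 1e-12)
    llf = float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))
    w = p * (1 - p)
    H = (X * w[:, None]).T @ X + 2 * np.diag(pen)
    cov = np.linalg.pinv(H)
    return _LogitFit(params=beta, cov=cov, llf=llf, separation=True)


@dataclass
class StepwiseResult:
    selected: list[str]
    wald_p: dict[str, float]
    coef: dict[str, float]
    p_enter: float
    p_remove: float
    separation: bool
    entry_order: list[str] = field(default_factory=list)


def stepwise_logistic(
    candidates: pd.DataFrame,
    labels,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
) -> StepwiseResult:
    """Forward stepwise logistic regression with likelihood-ratio entry tests.

    Candidate features are standardized internally. At each step the feature
    whose addition gives the smallest likelihood-ratio p-value enters if that
    p-value is below ``p_enter``; after each entry, included features whose
    drop test exceeds ``p_remove`` are removed. The final model's Wald
    p-values and (standardized-scale) coefficients are reported.
    """
    if candidates.isna().any().any():
        raise ValueError("candidate features contain missing values")
    if candidates.shape[1] < 2:
        raise ValueError("need at least 2 candidate features")
    y = np.asarray(labels, float)
    names = list(candidates.columns)
    Z = (candidates - candidates.mean()) / candidates.std(ddof=0).replace(0, 1.0)
    Z = Z.to_numpy(float)
    n = len(y)

    def design(cols: list[str]) -> np.ndarray:
        idx = [names.index(c) for c in cols]
        return np.column_stack([np.ones(n)] + [Z[:, i] for i in idx])

    separation = False
    selected: list[str] = []
    entry_order: list[str] = []
    current = _fit_logit(design([]), y)

    def lr_p(fit_big: _LogitFit, fit_small: _LogitFit) -> float:
        stat = max(0.0, 2 * (fit_big.llf - fit_small.llf))
        return float(sps.chi2.sf(stat, df=1))

    changed = True
    while changed:
        changed = False
        # forward step
        best_name, best_fit, best_p = None, None, 1.0
        for c in names:
            if c in selected:
                continue
            try:
                fit = _fit_logit(design(selected + [c]), y)
            except Exception:
                continue
            p = lr_p(fit, current)
            if p < best_p:
                best_name, best_fit, best_p = c, fit, p
        if best_name is not None and best_p < p_enter:
            selected.append(best_name)
            entry_order.append(best_name)
            current = best_fit
            separation |= best_fit.separation
            changed = True
            # backward check
            removed = True
            while removed and len(selected) > 1:
                removed = False
                worst_name, worst_p = None, 0.0
                for s in selected:
                    rest = [c for c in selected if c != s]
                    fit_rest = _fit_logit(design(rest), y)
                    p = lr_p(current, fit_rest)
                    if p > worst_p:
                        worst_name, worst_p = s, p
                if worst_name is not None and worst_p > p_remove:
                    selected.remove(worst_name)
                    current = _fit_logit(design(selected), y)
                    removed = True

    wald_p: dict[str, float] = {}
    coef: dict[str, float] = {}
    if selected:
        for i, name in enumerate(selected, start=1):
            b = current.params[i]
            se = math.sqrt(max(current.cov[i, i], 0.0))
            z = b / se if se > 0 else float("inf")
            wald_p[name] = float(2 * sps.norm.sf(abs(z)))
            coef[name] = float(b)
        separation |= current.separation

    return StepwiseResult(
        selected=selected,
        wald_p=wald_p,
        coef=coef,
        p_enter=p_enter,
        p_remove=p_remove,
        separation=separation,
        entry_order=entry_order,
    )


# ---------------------------------------------------------------------------
# contingency rates
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ContingencyResult:
    rate1: float  # percent
    rate2: float  # percent
    p_value: float
    test: str  # 'chi2' or 'fisher'


def contingency_rates(k1: int, n1: int, k2: int, n2: int) -> ContingencyResult:
    """Event rates in two groups with a two-sided comparison p-value.

    Uses the chi-square test with continuity correction, switching to
    Fisher's exact test when any expected cell count falls below 5.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if not (0 <= k <= n) or n < 1:
            raise ValueError("require 0 <= k <= n and n >= 1")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]])
    rate1 = k1 / n1 * 100.0
    rate2 = k2 / n2 * 100.0
    if k1 == k2 == 0 or (n1 - k1) == (n2 - k2) == 0:
        return ContingencyResult(rate1, rate2, 1.0, "degenerate")
    res = sps.chi2_contingency(table, correction=True)
    if (res.expected_freq < 5).any():
        p = float(sps.fisher_exact(table, alternative="two-sided")[1])
        test = "fisher"
    else:
        p = float(res.pvalue)
        test = "chi2"
    return ContingencyResult(rate1, rate2, p, test)


# ---------------------------------------------------------------------------
# inter-observer agreement
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IccResult:
    icc: float
    ci_low: float
    ci_high: float
    model: str = "ICC(2,1) two-way random effects, absolute agreement, single measure"
    degenerate: bool = False


def icc_two_observers(ratings_obs1, ratings_obs2) -> IccResult:
    """ICC(2,1) between two observers rating the same subjects.

    Two-way random-effects, absolute-agreement, single-measure ICC with its
    F-distribution 95% CI. Zero between-subject variance leaves the ICC
    undefined; the result is then NaN with ``degenerate=True``.
    """
    import pingouin as pg

    x = np.asarray(ratings_obs1, float)
    y = np.asarray(ratings_obs2, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("ratings must be paired 1-D arrays")
    n = len(x)
    if n < 5:
        raise ValueError("need at least 5 subjects")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        return IccResult(float("nan"), float("nan"), float("nan"), degenerate=True)
    df = pd.DataFrame(
        {
            "subject": np.tile(np.arange(n), 2),
            "rater": np.repeat(["obs1", "obs2"], n),
            "rating": np.concatenate([x, y]),
        }
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = pg.intraclass_corr(df, targets="subject", raters="rater", ratings="rating")
    # pingouin labels ICC(2,1) either 'ICC2' or 'ICC(A,1)' depending on version
    sel = res[res["Type"].isin(["ICC2", "ICC(A,1)"])]
    row = sel.iloc[0]
    ci_col = "CI95%" if "CI95%" in res.columns else "CI95"
    icc = float(row["ICC"])
    lo, hi = (float(v) for v in row[ci_col])
    if not np.isfinite(icc):
        return IccResult(float("nan"), float("nan"), float("nan"), degenerate=True)
    return IccResult(icc=icc, ci_low=lo, ci_high=hi)


# ---------------------------------------------------------------------------
# binormal simulation
# ---------------------------------------------------------------------------


def binormal_auc_simulation(
    mean_neg: float,
    sd_neg: float,
    n_neg: int,
    mean_pos: float,
    sd_pos: float,
    n_pos: int,
    n_replicates: int = 2000,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Mean empirical AUC over replicated two-group Gaussian draws.

    Each replicate draws the 'negative' (higher-valued, e.g. nonrecurrence)
    group from Normal(mean_neg, sd_neg) and the 'positive' group from
    Normal(mean_pos, sd_pos), then computes the tie-corrected empirical AUC
    oriented as P(negative-group score > positive-group score). The replicate
    mean converges to the binormal value Phi(dmu / sqrt(sd1^2 + sd2^2)).
    """
    rng = np.random.default_rng(rng)
    labels = np.concatenate([np.ones(n_neg, bool), np.zeros(n_pos, bool)])
    aucs = np.empty(n_replicates)
    for r in range(n_replicates):
        scores = np.concatenate(
            [rng.normal(mean_neg, sd_neg, n_neg), rng.normal(mean_pos, sd_pos, n_pos)]
        )
        aucs[r] = empirical_auc(scores, labels)
    return float(aucs.mean())
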