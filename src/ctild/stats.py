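"""Cohort statistics: correlation/regression, inter-reader ICC, group
comparisons, and ROC analysis with a criterion table.

The ROC machinery follows the classical criterion-table layout: every
distinct score value (plus one value below the minimum) is a candidate
criterion, a case is called positive when its score is strictly greater
than the criterion, the AUC is the trapezoidal area with a Hanley-McNeil
standard error, and the optimal cutoff maximizes sensitivity +
specificity (Youden), taking the smallest criterion on ties.  Confidence
intervals for sensitivity/specificity and predictive values are exact
Clopper-Pearson; likelihood-ratio intervals use the log method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import (
    DegenerateICCError,
    UndefinedCorrelationError,
    ValidationError,
)

# ---------------------------------------------------------------------------
# correlation / regression


@dataclass(frozen=True)
class RegressionResult:
    r: float
    slope: float
    intercept: float
    p_value: float
    n: int


def pearson_regression(x, y) -> RegressionResult:
    """Pearson product-moment correlation with the least-squares line.

    The two-sided p-value comes from the t transform with n-2 degrees of
    freedom.  Zero variance in either series raises
    :class:`~ctild.errors.UndefinedCorrelationError`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("paired series must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValidationError("need at least 3 pairs")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("paired series must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance in x or y")
    lin = sps.linregress(x, y)
    return RegressionResult(
        r=float(lin.rvalue),
        slope=float(lin.slope),
        intercept=float(lin.intercept),
        p_value=float(lin.pvalue),
        n=int(x.size),
    )


# ---------------------------------------------------------------------------
# intraclass correlation


def icc_two_way(ratings, form: str = "agreement") -> float:
    """Single-measure two-way random-effects ICC from an
    ``n_subjects x n_raters`` matrix with no missing cells.

    ``form="agreement"`` gives ICC(2,1) (absolute agreement, the default);
    ``form="consistency"`` gives the consistency coefficient ICC(C,1).
    """
    m = np.asarray(ratings, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2:
        raise ValidationError("ratings must be an n_subjects x n_raters matrix, k >= 2")
    if not np.isfinite(m).all():
        raise ValidationError("ratings must have no missing cells")
    n, k = m.shape
    if n < 2:
        raise ValidationError("need at least 2 subjects")

    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_total = ((m - grand) ** 2).sum()
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_error = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_error / ((n - 1) * (k - 1))

    if msr <= 0 or np.isclose(msr, 0.0):
        raise DegenerateICCError("no between-subject variance; ICC undefined")

    if form == "agreement":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    elif form == "consistency":
        denom = msr + (k - 1) * mse
    else:
        raise ValidationError(f"unknown ICC form {form!r}")
    if denom == 0:
        raise DegenerateICCError("degenerate ICC denominator")
    return float((msr - mse) / denom)


# ---------------------------------------------------------------------------
# group comparisons


def compare_groups(a, b, kind: str = "t_test") -> tuple[float, float]:
    """Two-group comparison.

    ``t_test``: classical two-sample Student t with pooled variance on raw
    values.  ``chi_square``: Pearson chi-square (no continuity correction) on
    a contingency table whose rows are the per-group category counts.
    """
    if kind == "t_test":
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if a.size < 2 or b.size < 2:
            raise ValidationError("t-test needs at least 2 values per group")
        if np.ptp(np.concatenate([a, b])) == 0:
            raise ValidationError("zero pooled variance")
        res = sps.ttest_ind(a, b, equal_var=True)
        return float(res.statistic), float(res.pvalue)
    if kind == "chi_square":
        table = np.asarray([a, b], dtype=float)
        if table.shape != (2, 2):
            raise ValidationError("chi-square expects two per-group count pairs")
        chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
        return float(chi2), float(p)
    raise ValidationError(f"unknown comparison kind {kind!r}")


# ---------------------------------------------------------------------------
# ROC analysis


@dataclass(frozen=True)
class CriterionRow:
    """One row of the criterion table: the criterion classifies score >
    criterion as positive.  Interval fields are (low, high) percentages or
    ratios; LR/PV fields are None when undefined at that criterion."""

    criterion: float
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity_pct: float
    sensitivity_ci: tuple[float, float]
    specificity_pct: float
    specificity_ci: tuple[float, float]
    lr_pos: float | None
    lr_pos_ci: tuple[float, float] | None
    lr_neg: float | None
    lr_neg_ci: tuple[float, float] | None
    ppv_pct: float | None
    ppv_ci: tuple[float, float] | None
    npv_pct: float | None
    npv_ci: tuple[float, float] | None


@dataclass(frozen=True)
class ROCResult:
    auc: float
    auc_se: float
    thresholds: np.ndarray
    sensitivities: np.ndarray  # fraction of positives with score > threshold
    specificities: np.ndarray  # fraction of negatives with score <= threshold
    optimal_threshold: float
    n_positive: int
    n_negative: int
    confusion: np.ndarray  # per-threshold rows (tp, fp, tn, fn)


def clopper_pearson(successes: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact binomial confidence interval, as a (low, high) proportion."""
    if not 0 <= successes <= n or n <= 0:
        raise ValidationError("need 0 <= successes <= n, n > 0")
    low = 0.0 if successes == 0 else float(sps.beta.ppf(alpha / 2, successes, n - successes + 1))
    high = 1.0 if successes == n else float(sps.beta.ppf(1 - alpha / 2, successes + 1, n - successes))
    return low, high


def hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    """Hanley-McNeil standard error of a trapezoidal AUC."""
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n_pos - 1) * (q1 - auc**2)
        + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    return float(np.sqrt(max(var, 0.0)))


def roc_analysis(scores, labels) -> ROCResult:
    """ROC analysis of a continuous score against binary labels.

    Candidate criteria are all distinct score values plus one value below
    the minimum; score > criterion is classified positive.  Raises
    :class:`~ctild.errors.ValidationError` when only one class is present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValidationError("scores and labels must be equal-length 1-D vectors")
    if not np.isfinite(scores).all():
        raise ValidationError("scores must be finite")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("both classes must be present for ROC analysis")

    distinct = np.unique(scores)
    thresholds = np.concatenate([[distinct[0] - 1.0], distinct])

    pos_scores = scores[labels]
    neg_scores = scores[~labels]
    tp = (pos_scores[None, :] > thresholds[:, None]).sum(axis=1)
    fp = (neg_scores[None, :] > thresholds[:, None]).sum(axis=1)
    fn = n_pos - tp
    tn = n_neg - fp
    sens = tp / n_pos
    spec = tn / n_neg

    # trapezoidal area over (FPR, TPR); thresholds ascending => FPR descending
    fpr = 1.0 - spec
    auc = float(np.trapezoid(sens[::-1], fpr[::-1]))
    se = hanley_mcneil_se(auc, n_pos, n_neg)

    youden = sens + spec
    best = int(np.argmax(youden))  # first (smallest) threshold on ties
    confusion = np.stack([tp, fp, tn, fn], axis=1)
    return ROCResult(
        auc=auc,
        auc_se=se,
        thresholds=thresholds,
        sensitivities=sens,
        specificities=spec,
        optimal_threshold=float(thresholds[best]),
        n_positive=n_pos,
        n_negative=n_neg,
        confusion=confusion,
    )


def _lr_ci(
    lr: float, a: int, n1: int, b: int, n2: int, alpha: float = 0.05
) -> tuple[float, float] | None:
    """Log-method CI for a likelihood ratio (a/n1) / (b/n2)."""
    if a == 0 or b == 0:
        return None
    z = sps.norm.ppf(1 - alpha / 2)
    se = np.sqrt(1.0 / a - 1.0 / n1 + 1.0 / b - 1.0 / n2)
    return float(lr * np.exp(-z * se)), float(lr * np.exp(z * se))


def criterion_table(roc: ROCResult, alpha: float = 0.05) -> list[CriterionRow]:
    """Per-criterion sensitivity/specificity, likelihood ratios and
    predictive values with 95% confidence intervals.

    The positive likelihood ratio is omitted at 100% specificity; predictive
    values come from the observed confusion counts.
    """
    rows: list[CriterionRow] = []
    n_pos, n_neg = roc.n_positive, roc.n_negative
    for threshold, (tp, fp, tn, fn) in zip(roc.thresholds, roc.confusion):
        tp, fp, tn, fn = int(tp), int(fp), int(tn), int(fn)
        sens = tp / n_pos
        spec = tn / n_neg
        sens_ci = clopper_pearson(tp, n_pos, alpha)
        spec_ci = clopper_pearson(tn, n_neg, alpha)

        if fp == 0:  # specificity 100%: +LR undefined
            lr_pos, lr_pos_ci = None, None
        else:
            lr_pos = sens / (1.0 - spec)
            lr_pos_ci = _lr_ci(lr_pos, tp, n_pos, fp, n_neg, alpha)
        if tn == 0:  # specificity 0%: -LR undefined
            lr_neg, lr_neg_ci = None, None
        else:
            lr_neg = (1.0 - sens) / spec
            lr_neg_ci = _lr_ci(lr_neg, fn, n_pos, tn, n_neg, alpha)

        if tp + fp > 0:
            ppv = 100.0 * tp / (tp + fp)
            ppv_ci_p = clopper_pearson(tp, tp + fp, alpha)
            ppv_ci = (100.0 * ppv_ci_p[0], 100.0 * ppv_ci_p[1])
        else:
            ppv, ppv_ci = None, None
        if tn + fn > 0:
            npv = 100.0 * tn / (tn + fn)
            npv_ci_p = clopper_pearson(tn, tn + fn, alpha)
            npv_ci = (100.0 * npv_ci_p[0], 100.0 * npv_ci_p[1])
        else:
            npv, npv_ci = None, None

        rows.append(
            CriterionRow(
                criterion=float(threshold),
                tp=tp,
                fp=fp,
                tn=tn,
                fn=fn,
                sensitivity_pct=100.0 * sens,
                sensitivity_ci=(100.0 * sens_ci[0], 100.0 * sens_ci[1]),
                specificity_pct=100.0 * spec,
                specificity_ci=(100.0 * spec_ci[0], 100.0 * spec_ci[1]),
                lr_pos=lr_pos,
                lr_pos_ci=lr_pos_ci,
                lr_neg=lr_neg,
                lr_neg_ci=lr_neg_ci,
                ppv_pct=ppv,
                ppv_ci=ppv_ci,
                npv_pct=npv,
                npv_ci=npv_ci,
            )
        )
    return rows
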