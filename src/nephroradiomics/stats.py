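"""Statistical inference: DeLong paired AUC test, contingency tests, and
two-group comparisons.

The DeLong test is implemented from scratch with the fast placement-value
(structural components) estimator and midrank tie handling; the paired
design (both models scored on the same subjects) is what makes the AUC
difference variance estimable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.stats import rankdata

from .errors import DegenerateInputError


@dataclass(frozen=True)
class DeLongResult:
    auc_a: float
    auc_b: float
    z: float
    p_value: float


def _midrank_placements(scores: np.ndarray, pos: np.ndarray):
    """Placement values V10 (per positive) and V01 (per negative) and AUC."""
    x, yneg = scores[pos], scores[~pos]
    m, n = len(x), len(yneg)
    all_ranks = rankdata(np.concatenate([x, yneg]))
    rx = rankdata(x)
    ry = rankdata(yneg)
    v10 = (all_ranks[:m] - rx) / n
    v01 = 1.0 - (all_ranks[m:] - ry) / m
    auc = v10.mean()
    return v10, v01, float(auc)


def delong_auc_variance(labels, scores) -> tuple[float, float]:
    """(AUC, DeLong variance of the AUC) for a single model."""
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise DegenerateInputError("labels must contain two classes")
    pos = y == classes.max()
    v10, v01, auc = _midrank_placements(np.asarray(scores, float), pos)
    m, n = len(v10), len(v01)
    var = v10.var(ddof=1) / m + v01.var(ddof=1) / n
    return auc, float(var)


def delong_test(labels, scores_a, scores_b) -> DeLongResult:
    """Two-sided paired DeLong test comparing two models' AUCs.

    When the variance of the AUC difference is zero the p-value is 1 for
    equal AUCs; unequal AUCs with zero variance indicate a deterministic
    difference and are reported with p = 0 and a warning.
    """
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise DegenerateInputError("labels must contain two classes")
    a = np.asarray(scores_a, dtype=np.float64)
    b = np.asarray(scores_b, dtype=np.float64)
    if not (len(a) == len(b) == len(y)):
        raise DegenerateInputError("scores and labels must have equal length")
    pos = y == classes.max()
    v10a, v01a, auc_a = _midrank_placements(a, pos)
    v10b, v01b, auc_b = _midrank_placements(b, pos)
    m, n = int(pos.sum()), int((~pos).sum())
    # with a single positive or negative the component covariance is
    # inestimable (ddof=1); treat it as zero spread in that class
    s10 = np.nan_to_num(np.cov(np.stack([v10a, v10b]), ddof=1)) if m > 1 else np.zeros((2, 2))
    s01 = np.nan_to_num(np.cov(np.stack([v01a, v01b]), ddof=1)) if n > 1 else np.zeros((2, 2))
    s = s10 / m + s01 / n
    var_diff = s[0, 0] + s[1, 1] - 2 * s[0, 1]
    if not np.isfinite(var_diff) or var_diff <= 0:
        if np.isclose(auc_a, auc_b):
            return DeLongResult(auc_a, auc_b, 0.0, 1.0)
        warnings.warn("zero variance with unequal AUCs: deterministic difference")
        return DeLongResult(auc_a, auc_b, np.inf if auc_a > auc_b else -np.inf, 0.0)
    z = (auc_a - auc_b) / np.sqrt(var_diff)
    p = 2.0 * stats.norm.sf(abs(z))
    return DeLongResult(auc_a, auc_b, float(z), float(min(p, 1.0)))


@dataclass(frozen=True)
class ContingencyResult:
    statistic: float | None
    p_value: float
    method: str


def contingency_test(table) -> ContingencyResult:
    """Pearson chi-square (no continuity correction) when all expected
    counts are >= 5, else the two-sided Fisher exact test."""
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2 or (t < 0).any() or t.sum() == 0:
        raise DegenerateInputError("need a nonnegative 2D count table")
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise DegenerateInputError("empty margin makes the test undefined")
    expected = np.outer(rows, cols) / t.sum()
    if (expected >= 5).all():
        res = stats.chi2_contingency(t, correction=False)
        return ContingencyResult(float(res.statistic), float(res.pvalue), "chi-square")
    if t.shape != (2, 2):
        res = stats.chi2_contingency(t, correction=False)
        return ContingencyResult(float(res.statistic), float(res.pvalue), "chi-square")
    _, p = stats.fisher_exact(t, alternative="two-sided")
    return ContingencyResult(None, float(p), "fisher")


def group_compare(values, group_labels) -> tuple[float, str]:
    """Two-group comparison with a Shapiro-Wilk normality gate at 0.05.

    Both groups normal: Welch unpaired t-test; otherwise Mann-Whitney U
    with the normal approximation and midrank tie correction. All-tied
    data in both groups yields p = 1 with a warning.
    """
    v = np.asarray(values, dtype=np.float64)
    g = np.asarray(group_labels)
    groups = np.unique(g)
    if groups.size != 2:
        raise DegenerateInputError("need exactly two groups")
    a, b = v[g == groups[0]], v[g == groups[1]]
    if min(len(a), len(b)) < 2:
        raise DegenerateInputError("need >= 2 observations per group")
    if np.ptp(np.concatenate([a, b])) == 0:
        warnings.warn("all observations tied; p set to 1")
        return 1.0, "mann-whitney"
    def _normal(x):
        if np.ptp(x) == 0 or len(x) < 3:
            return False
        return stats.shapiro(x).pvalue >= 0.05
    if _normal(a) and _normal(b):
        res = stats.ttest_ind(a, b, equal_var=False)
        return float(res.pvalue), "welch-t"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.pvalue), "mann-whitney"


def clinical_comparison_report(clinical, flag_names, class_column="class_label"):
    """Per-flag contingency tests between the two classes (count layout:
    rows = class, columns = flag present/absent)."""
    import pandas as pd

    classes = sorted(clinical[class_column].unique())
    rows = []
    for flag in flag_names:
        cells = []
        for cls in classes:
            sub = clinical[clinical[class_column] == cls][flag]
            cells.append([int(sub.sum()), int((1 - sub).sum())])
        t = np.asarray(cells)
        try:
            res = contingency_test(t)
            p, method, stat = res.p_value, res.method, res.statistic
        except DegenerateInputError:
            p, method, stat = np.nan, "undefined", None
        row = {"flag": flag, "p_value": p, "method": method, "statistic": stat}
        for cls, (k, nk) in zip(classes, cells):
            row[f"count_{cls}"] = k
            row[f"rate_{cls}"] = k / (k + nk)
        rows.append(row)
    return pd.DataFrame(rows)
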