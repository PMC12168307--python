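"""Staged feature-selection cascade with cross-validation voting.

The cascade mirrors a common radiomics-platform recipe: z-normalization,
a label-correlation screen (point-biserial p < 0.05), univariate logistic
regression (Wald p < 0.10), multivariate logistic regression (Wald
p < 0.05), and L1-penalized logistic regression (penalty strength 0.05).
It runs independently on each training split of a stratified 5-fold
partition; a feature's voting count is the number of folds in which it
survives the whole cascade, and the final set keeps features with at
least ``vote_threshold`` (default 4) votes.

Normalization statistics are fit on each training fold only, so the
voting is leakage-free.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .errors import DegenerateInputError

logger = logging.getLogger(__name__)

STAGES = ("correlation", "univariate", "multivariate", "lasso")


@dataclass(frozen=True)
class SelectionConfig:
    corr_p: float = 0.05
    uni_p: float = 0.10
    multi_p: float = 0.05
    lasso_alpha: float = 0.05
    n_folds: int = 5
    vote_threshold: int = 4
    fold_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("corr_p", "uni_p", "multi_p"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.vote_threshold > self.n_folds:
            raise ValueError("vote_threshold cannot exceed n_folds")


@dataclass
class SelectionReport:
    per_fold: list[dict[str, list[str]]]
    voting_count: dict[str, int]
    final_set: list[str]
    config: SelectionConfig
    dropped_constant: list[str] = field(default_factory=list)

    def to_jsonable(self) -> dict:
        return {
            "per_fold": self.per_fold,
            "voting_count": self.voting_count,
            "final_set": self.final_set,
            "dropped_constant": self.dropped_constant,
            "config": vars(self.config),
        }


def znormalize(table: pd.DataFrame, stats_from: pd.DataFrame | None = None):
    """Standardize each column to mean 0, SD 1 (sample SD, n-1).

    Zero-variance columns are dropped with a logged warning. When
    ``stats_from`` is given, its column means/SDs are used (train-fold
    statistics applied to a test fold).
    """
    ref = table if stats_from is None else stats_from
    mu = ref.mean(axis=0)
    sd = ref.std(axis=0, ddof=1)
    keep = sd > 0
    dropped = list(sd.index[~keep])
    if dropped:
        logger.warning("dropping %d constant feature(s): %s ...", len(dropped), dropped[:3])
    out = (table.loc[:, keep] - mu[keep]) / sd[keep]
    return out, dropped


def _check_binary(labels) -> np.ndarray:
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise DegenerateInputError("labels must contain exactly two classes")
    return (y == classes.max()).astype(int)


def correlation_filter(table: pd.DataFrame, labels, p: float = 0.05) -> list[str]:
    """Keep features whose point-biserial correlation with the binary label
    has two-sided p below the threshold."""
    y = _check_binary(labels)
    X = table.to_numpy(dtype=np.float64)
    n = len(y)
    yc = y - y.mean()
    xc = X - X.mean(axis=0)
    denom = np.sqrt((xc**2).sum(axis=0) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, xc.T @ yc / denom, 0.0)
        r = np.clip(r, -1.0, 1.0)
        t = r * np.sqrt((n - 2) / np.clip(1.0 - r**2, 1e-300, None))
    pvals = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    pvals = np.where(np.abs(r) >= 1.0, 0.0, pvals)
    return [c for c, pv in zip(table.columns, pvals) if pv < p]


def _wald_p_single(x: np.ndarray, y: np.ndarray) -> float:
    """Wald p for the slope of a single-feature logistic fit; falls back to
    a ridge-penalized fit when the MLE separates."""
    X = sm.add_constant(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=100)
            if _mle_trustworthy(res):
                return float(res.pvalues[1])
        except Exception:
            pass
    z = _penalized_wald(x.reshape(-1, 1), y)[0]
    return float(2.0 * stats.norm.sf(z))


# on z-scored inputs an MLE slope beyond ~10 (odds ratio > e^10 per SD) or a
# standard error beyond ~20 signals (quasi-)separation, not a real effect
_MAX_SANE_COEF = 10.0
_MAX_SANE_SE = 20.0


def _mle_trustworthy(res) -> bool:
    if not res.mle_retvals.get("converged", False):
        return False
    if not (np.all(np.isfinite(res.bse)) and np.all(np.isfinite(res.params))):
        return False
    return bool(
        np.all(np.abs(res.params[1:]) < _MAX_SANE_COEF)
        and np.all(res.bse[1:] < _MAX_SANE_SE)
    )


def _penalized_wald(X: np.ndarray, y: np.ndarray, maxiter: int = 100) -> np.ndarray:
    """Absolute Wald z-statistics from a Firth (Jeffreys-prior) logistic fit.

    Used when the unpenalized likelihood separates: the Firth score
    correction keeps estimates finite without the over-shrinkage of a
    ridge penalty, so Wald tests stay close to nominal.
    """
    logger.info("perfect separation detected; switching to a Firth penalized fit")
    Xc = np.column_stack([np.ones(len(y)), X])
    beta = np.zeros(Xc.shape[1])
    iinv = np.eye(Xc.shape[1])
    for _ in range(maxiter):
        eta = np.clip(Xc @ beta, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1 - p)
        xw = Xc * w[:, None]
        info = Xc.T @ xw
        iinv = np.linalg.pinv(info)
        h = np.einsum("ij,jk,ik->i", xw, iinv, Xc)
        score = Xc.T @ (y - p + h * (0.5 - p))
        step = iinv @ score
        beta = beta + step
        if np.max(np.abs(step)) < 1e-8:
            break
    se = np.sqrt(np.clip(np.diag(iinv), 1e-300, None))
    z = beta / se
    return np.abs(z[1:])


def univariate_logistic_filter(table: pd.DataFrame, labels, p: float = 0.10) -> list[str]:
    """Single-feature logistic fits; keep Wald slope p < threshold."""
    y = _check_binary(labels)
    out = []
    for c in table.columns:
        if _wald_p_single(table[c].to_numpy(dtype=np.float64), y) < p:
            out.append(c)
    return out


def _drop_collinear(table: pd.DataFrame, tol: float = 1.0 - 1e-8) -> pd.DataFrame:
    """Drop columns perfectly correlated with an earlier kept column."""
    if table.shape[1] < 2:
        return table
    corr = np.corrcoef(table.to_numpy(dtype=np.float64), rowvar=False)
    kept: list[int] = []
    for k in range(table.shape[1]):
        if all(abs(corr[k, j]) < tol for j in kept):
            kept.append(k)
    return table.iloc[:, kept]


def multivariate_logistic_filter(
    table: pd.DataFrame, labels, p: float = 0.05, redundancy_r: float = 0.90
) -> list[str]:
    """Joint logistic fit of all candidates; keep Wald p < threshold.

    Radiomics banks are massively redundant, which makes joint Wald tests
    uninformative; candidates correlated above ``redundancy_r`` with a
    better-ranked candidate (by univariate p, ties broken by name) are
    pruned first, and the joint fit is capped at n/10 features (events per
    variable ~ 10 in a balanced design). Wald statistics are referred to t
    with residual degrees of freedom as a small-sample correction, which
    keeps the null retention at its nominal level.
    """
    y = _check_binary(labels)
    if table.shape[1] == 0:
        return []
    ranked = sorted(
        table.columns,
        key=lambda c: (_wald_p_single(table[c].to_numpy(np.float64), y), c),
    )
    table = table.loc[:, ranked]
    table = _drop_collinear(table, tol=redundancy_r)
    n = len(y)
    max_feats = max(1, n // 10)
    table = table.iloc[:, :max_feats]
    X = table.to_numpy(dtype=np.float64)
    cols = list(table.columns)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, sm.add_constant(X)).fit(disp=0, maxiter=200)
            if _mle_trustworthy(res):
                zstat = np.abs(np.asarray(res.params)[1:] / np.asarray(res.bse)[1:])
            else:
                zstat = _penalized_wald(X, y)
        except Exception:
            zstat = _penalized_wald(X, y)
    df_resid = max(1, n - X.shape[1] - 1)
    pvals = 2.0 * stats.t.sf(zstat, df=df_resid)
    return [c for c, pv in zip(cols, pvals) if pv < p]


def lasso_select(table: pd.DataFrame, labels, alpha: float = 0.05) -> list[str]:
    """L1-penalized logistic regression at penalty strength ``alpha``.

    The objective is mean log-loss + alpha * ||w||_1 (so the sklearn
    inverse-regularization is C = 1/(n*alpha)); features with nonzero
    coefficients are retained.
    """
    y = _check_binary(labels)
    if table.shape[1] == 0:
        return []
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    X = table.to_numpy(dtype=np.float64)
    C = 1.0 / (len(y) * alpha)
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            clf = LogisticRegression(
                l1_ratio=1.0, solver="liblinear", C=C, max_iter=10000, tol=1e-6
            )
            clf.fit(X, y)
        except ConvergenceWarning as exc:  # pragma: no cover - diagnostic path
            raise RuntimeError(
                f"LASSO did not converge in {10000} iterations (alpha={alpha})"
            ) from exc
    coef = clf.coef_.ravel()
    return [c for c, b in zip(table.columns, coef) if b != 0.0]


def run_cascade(table: pd.DataFrame, labels, cfg: SelectionConfig) -> dict[str, list[str]]:
    """Run the four filter stages in order on one (training) table.

    The table is standardized first; each stage sees only the previous
    stage's survivors, so the survivor sets are nested by construction.
    """
    z, _ = znormalize(table)
    stages: dict[str, list[str]] = {}
    surv = correlation_filter(z, labels, cfg.corr_p)
    stages["correlation"] = sorted(surv)
    surv = univariate_logistic_filter(z.loc[:, surv], labels, cfg.uni_p)
    stages["univariate"] = sorted(surv)
    surv = multivariate_logistic_filter(z.loc[:, stages["univariate"]], labels, cfg.multi_p)
    stages["multivariate"] = sorted(surv)
    surv = lasso_select(z.loc[:, stages["multivariate"]], labels, cfg.lasso_alpha)
    stages["lasso"] = sorted(surv)
    return stages


def cv_feature_voting(table: pd.DataFrame, labels, cfg: SelectionConfig | None = None) -> SelectionReport:
    """Cascade inside stratified k-fold CV; vote = folds surviving all stages."""
    cfg = cfg or SelectionConfig()
    y = _check_binary(labels)
    counts = np.bincount(y)
    if counts.min() < cfg.n_folds:
        raise DegenerateInputError(
            f"need >= {cfg.n_folds} subjects per class for stratified folds"
        )
    _, dropped = znormalize(table)
    skf = StratifiedKFold(n_splits=cfg.n_folds, shuffle=True, random_state=cfg.fold_seed)
    per_fold = []
    votes: dict[str, int] = {c: 0 for c in table.columns}
    for train_idx, _ in skf.split(table, y):
        stages = run_cascade(table.iloc[train_idx], y[train_idx], cfg)
        per_fold.append(stages)
        for c in stages["lasso"]:
            votes[c] += 1
    final = sorted(c for c, v in votes.items() if v >= cfg.vote_threshold)
    return SelectionReport(
        per_fold=per_fold,
        voting_count={c: v for c, v in votes.items() if v > 0},
        final_set=final,
        config=cfg,
        dropped_constant=dropped,
    )


def combined_voting(
    t2_table: pd.DataFrame,
    adc_table: pd.DataFrame,
    labels,
    t2_report: SelectionReport,
    adc_report: SelectionReport,
    cfg: SelectionConfig | None = None,
) -> SelectionReport:
    """Combined-model selection: the union of the two single-model final
    sets, with voting counts recomputed by rerunning the cascade on the
    pooled (prefixed) two-sequence table."""
    cfg = cfg or SelectionConfig()
    pooled = pd.concat(
        [t2_table.add_prefix("t2w__"), adc_table.add_prefix("adc__")], axis=1
    )
    report = cv_feature_voting(pooled, labels, cfg)
    union = [f"t2w__{c}" for c in t2_report.final_set] + [
        f"adc__{c}" for c in adc_report.final_set
    ]
    return SelectionReport(
        per_fold=report.per_fold,
        voting_count={c: report.voting_count.get(c, 0) for c in union},
        final_set=sorted(union),
        config=cfg,
        dropped_constant=report.dropped_constant,
    )


def report_table(report: SelectionReport, sequence_of: dict[str, str] | None = None) -> pd.DataFrame:
    """Flat summary of the final features: name, provenance, voting count."""
    rows = []
    for name in report.final_set:
        base = name.split("__", 1)[-1]
        parts = base.split("_")
        rows.append(
            {
                "feature": name,
                "sequence": (sequence_of or {}).get(name, ""),
                "image_type": parts[0] if len(parts) > 2 else "",
                "family": parts[1] if len(parts) > 2 else "",
                "voting_count": report.voting_count.get(name, 0),
            }
        )
    return pd.DataFrame(rows)
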