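"""8-preprocessor x 13-classifier model grid with cross-validated ROC.

Every pipeline is fitted on each training fold of one shared stratified
5-fold partition (preprocessors fit on the training split only) and scored
on the held-out fold. Metrics per fold: AUC, plus accuracy / sensitivity /
specificity at the Youden-optimal threshold of that fold's ROC. The best
pipeline maximizes mean test AUC, ties broken by mean accuracy and then
enumeration order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.ensemble import (
    AdaBoostClassifier,
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression, SGDClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import (
    FunctionTransformer,
    MinMaxScaler,
    RobustScaler,
    StandardScaler,
)
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .errors import ConfigurationError, DegenerateInputError


class PLSDAClassifier(BaseEstimator, ClassifierMixin):
    """Partial least squares discriminant analysis: PLS regression on the
    0/1 label, thresholded at the midpoint; decision scores are the PLS
    predictions."""

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y):
        y = np.asarray(y, dtype=float)
        self.classes_ = np.unique(y)
        ncomp = int(min(self.n_components, X.shape[1], max(1, X.shape[0] - 1)))
        self._pls = PLSRegression(n_components=ncomp)
        self._pls.fit(X, y)
        return self

    def decision_function(self, X):
        return self._pls.predict(X).ravel() - 0.5

    def predict(self, X):
        return (self.decision_function(X) > 0).astype(int)


PREPROCESSOR_NAMES = (
    "identity", "zscore", "minmax", "robust",
    "identity+pca", "zscore+pca", "minmax+pca", "robust+pca",
)
CLASSIFIER_NAMES = (
    "logistic", "random_forest", "gbdt", "knn", "plsda", "qda", "sgd", "svm",
    "decision_tree", "extra_trees", "adaboost", "gaussian_nb", "lda",
)


def _make_preprocessor(name: str, seed: int):
    scalers = {
        "identity": FunctionTransformer(),
        "zscore": StandardScaler(),
        "minmax": MinMaxScaler(),
        "robust": RobustScaler(),
    }
    base = name.removesuffix("+pca")
    steps = [("scale", scalers[base])]
    if name.endswith("+pca"):
        steps.append(("pca", PCA(n_components=0.95, svd_solver="full", random_state=seed)))
    return Pipeline(steps)


def _make_classifier(name: str, seed: int):
    table = {
        "logistic": LogisticRegression(max_iter=2000),
        "random_forest": RandomForestClassifier(n_estimators=100, random_state=seed),
        "gbdt": GradientBoostingClassifier(random_state=seed),
        "knn": KNeighborsClassifier(n_neighbors=5),
        "plsda": PLSDAClassifier(n_components=2),
        "qda": QuadraticDiscriminantAnalysis(reg_param=0.1),
        "sgd": SGDClassifier(loss="log_loss", max_iter=2000, random_state=seed),
        "svm": SVC(kernel="rbf", random_state=seed),
        "decision_tree": DecisionTreeClassifier(random_state=seed),
        "extra_trees": ExtraTreesClassifier(n_estimators=100, random_state=seed),
        "adaboost": AdaBoostClassifier(random_state=seed),
        "gaussian_nb": GaussianNB(),
        "lda": LinearDiscriminantAnalysis(),
    }
    return table[name]


@dataclass(frozen=True)
class GridConfig:
    preprocessors: tuple[str, ...] = PREPROCESSOR_NAMES
    classifiers: tuple[str, ...] = CLASSIFIER_NAMES
    n_folds: int = 5
    seed: int = 0
    n_bootstrap: int = 2000

    def __post_init__(self) -> None:
        if len(set(self.preprocessors)) != len(self.preprocessors):
            raise ConfigurationError("duplicate preprocessor names")
        if len(set(self.classifiers)) != len(self.classifiers):
            raise ConfigurationError("duplicate classifier names")


def enumerate_pipelines(cfg: GridConfig) -> list[tuple[str, str]]:
    """Cartesian product in preprocessor-major order (default 8x13 = 104)."""
    return [(p, c) for p in cfg.preprocessors for c in cfg.classifiers]


def roc_auc(scores, labels):
    """ROC points and AUC by the Mann-Whitney convention (ties count 1/2).

    Returns (fpr, tpr, auc) with monotone nondecreasing ROC points.
    """
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=np.float64)
    if not np.all(np.isfinite(s)):
        raise DegenerateInputError("scores must be finite")
    classes = np.unique(y)
    if classes.size != 2:
        raise DegenerateInputError("both classes must be present")
    pos = y == classes.max()
    n1, n0 = int(pos.sum()), int((~pos).sum())
    ranks = rankdata(s)
    auc = (ranks[pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
    order = np.argsort(-s, kind="stable")
    sorted_pos = pos[order]
    sorted_s = s[order]
    tp = np.cumsum(sorted_pos)
    fp = np.cumsum(~sorted_pos)
    distinct = np.r_[sorted_s[1:] != sorted_s[:-1], True]
    tpr = np.r_[0.0, tp[distinct] / n1]
    fpr = np.r_[0.0, fp[distinct] / n0]
    return fpr, tpr, float(auc)


def youden_metrics(scores, labels):
    """Accuracy/sensitivity/specificity at the Youden-optimal threshold."""
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=np.float64)
    classes = np.unique(y)
    pos = y == classes.max()
    fpr, tpr, auc = roc_auc(s, y)
    youden = tpr - fpr
    k = int(np.argmax(youden))
    # threshold = k-th largest distinct score; recompute the confusion counts
    thresholds = np.r_[np.inf, np.sort(np.unique(s))[::-1]]
    thr = thresholds[k]
    pred = s >= thr
    tp = int((pred & pos).sum())
    tn = int((~pred & ~pos).sum())
    sens = tp / max(1, int(pos.sum()))
    spec = tn / max(1, int((~pos).sum()))
    acc = (tp + tn) / len(y)
    return {"auc": auc, "accuracy": acc, "sensitivity": sens, "specificity": spec}


def _scores_of(model, X):
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    return model.decision_function(X)


@dataclass
class GridResult:
    fold_metrics: pd.DataFrame
    summary: pd.DataFrame
    fold_scores: dict[tuple[str, str], list[tuple[np.ndarray, np.ndarray]]]
    failed: list[tuple[str, str]]
    config: GridConfig


def fit_evaluate_grid(table: pd.DataFrame, labels, cfg: GridConfig | None = None) -> GridResult:
    """Fit and score every pipeline on one shared stratified partition."""
    cfg = cfg or GridConfig()
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise DegenerateInputError("need a two-class label vector")
    X = table.to_numpy(dtype=np.float64)
    if np.unique(y, return_counts=True)[1].min() < cfg.n_folds:
        raise DegenerateInputError(
            f"need >= {cfg.n_folds} subjects per class for stratified folds"
        )
    skf = StratifiedKFold(n_splits=cfg.n_folds, shuffle=True, random_state=cfg.seed)
    folds = list(skf.split(X, y))
    rows = []
    fold_scores: dict[tuple[str, str], list] = {}
    failed = []
    rng = np.random.default_rng(cfg.seed)
    for pre_name, clf_name in enumerate_pipelines(cfg):
        per_fold = []
        try:
            for fold_id, (tr, te) in enumerate(folds):
                pre = _make_preprocessor(pre_name, cfg.seed)
                clf = clone(_make_classifier(clf_name, cfg.seed))
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    Xtr = pre.fit_transform(X[tr])
                    clf.fit(Xtr, y[tr])
                    s = _scores_of(clf, pre.transform(X[te]))
                m = youden_metrics(s, y[te])
                m.update(pipeline=f"{pre_name}|{clf_name}", preprocessor=pre_name,
                         classifier=clf_name, fold=fold_id)
                per_fold.append((m, (s, y[te])))
        except Exception:
            failed.append((pre_name, clf_name))
            continue
        rows += [m for m, _ in per_fold]
        fold_scores[(pre_name, clf_name)] = [sc for _, sc in per_fold]
    if not rows:
        raise DegenerateInputError("all pipelines failed")
    fm = pd.DataFrame(rows)
    agg = fm.groupby(["pipeline", "preprocessor", "classifier"], sort=False).agg(
        mean_auc=("auc", "mean"),
        mean_accuracy=("accuracy", "mean"),
        mean_sensitivity=("sensitivity", "mean"),
        mean_specificity=("specificity", "mean"),
    ).reset_index()
    los, his = [], []
    for pipe in agg.pipeline:
        aucs = fm.loc[fm.pipeline == pipe, "auc"].to_numpy()
        boot = rng.choice(aucs, size=(cfg.n_bootstrap, len(aucs))).mean(axis=1)
        lo, hi = np.percentile(boot, [2.5, 97.5])
        los.append(lo)
        his.append(hi)
    agg["auc_ci_lo"] = los
    agg["auc_ci_hi"] = his
    return GridResult(fold_metrics=fm, summary=agg, fold_scores=fold_scores,
                      failed=failed, config=cfg)


def select_best(result: GridResult) -> pd.Series:
    """Argmax of mean test AUC; ties by mean accuracy, then grid order."""
    if result.summary.empty:
        raise DegenerateInputError("no successful pipelines to select from")
    s = result.summary.reset_index(drop=True)
    order = s.index.to_numpy()
    ranked = s.assign(_order=order).sort_values(
        by=["mean_auc", "mean_accuracy", "_order"], ascending=[False, False, True],
        kind="stable",
    )
    return ranked.iloc[0].drop(labels="_order")
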