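"""Classification and evaluation machinery.

Repeated stratified 10-fold cross-validation with the feature-selection
stage nested inside every outer training set, random-forest and SVM
classifiers, accuracy/sensitivity/specificity/recall and rank-based AUC,
exhaustive grid search over the selection/classifier hyperparameters
(p0, N, t), a full-pipeline label-permutation test, a DeLong comparison of
two AUCs (paired and unpaired), cross-dataset validation, and a
scanner-confound check on the selected features.

Everything stochastic is driven by explicit integer seeds: a run with the
same inputs and seed is bit-identical.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import ConfigurationError, FoldError, ThalradError
from .selection import SelectionConfig, select_features

__all__ = [
    "CvConfig", "ClassifierSpec", "EvaluationResult", "PermutationResult",
    "make_folds", "metrics", "roc_auc", "run_repeated_cv", "grid_search",
    "permutation_test", "delong_test", "cross_dataset_validate",
    "scanner_confound_check", "cv_accuracy_pipeline",
]

log = logging.getLogger(__name__)

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "recall", "auc")


@dataclass(frozen=True)
class CvConfig:
    """Outer cross-validation design (defaults: 10 folds x 100 repeats)."""

    outer_folds: int = 10
    repeats: int = 100
    seed: int = 0
    stratified: bool = True

    def __post_init__(self):
        if self.outer_folds < 2:
            raise ConfigurationError("outer_folds must be >= 2")
        if self.repeats < 1:
            raise ConfigurationError("repeats must be >= 1")


@dataclass(frozen=True)
class ClassifierSpec:
    """Classifier choice: random forest with t trees, or an SVM."""

    kind: str = "random_forest"           # or "svm"
    n_trees: int = 50
    svm_kernel: str = "linear"
    svm_c: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("random_forest", "svm"):
            raise ConfigurationError(f"unknown classifier kind {self.kind!r}")
        if self.kind == "random_forest" and self.n_trees < 1:
            raise ConfigurationError("n_trees must be >= 1")

    def build(self, seed: Optional[int] = None) -> Pipeline:
        s = (self.seed if seed is None else seed) & 0x7FFFFFFF
        if self.kind == "random_forest":
            clf = RandomForestClassifier(
                n_estimators=self.n_trees, random_state=s
            )
        else:
            clf = SVC(kernel=self.svm_kernel, C=self.svm_c, random_state=s)
        return Pipeline([("scale", StandardScaler()), ("clf", clf)])


@dataclass(frozen=True)
class EvaluationResult:
    """Per-test-fold metrics with mean +/- SD aggregates across all repeats."""

    per_fold: pd.DataFrame                 # columns: repeat, fold, METRIC_NAMES
    aggregate: dict[str, tuple[float, float]]
    selected_features_per_fold: tuple[tuple[str, ...], ...]

    @staticmethod
    def from_folds(rows: list[dict], selected: list[tuple[str, ...]]
                   ) -> "EvaluationResult":
        df = pd.DataFrame(rows)
        agg = {
            m: (float(np.nanmean(df[m])), float(np.nanstd(df[m], ddof=1))
                if df[m].notna().sum() > 1 else 0.0)
            for m in METRIC_NAMES
        }
        return EvaluationResult(df, agg, tuple(selected))


@dataclass(frozen=True)
class PermutationResult:
    """Observed metric against a label-permutation null distribution."""

    observed_metric: float
    null_metrics: tuple[float, ...]
    p_value: float


# --------------------------------------------------------------------------
# folds and elementary metrics
# --------------------------------------------------------------------------

def make_folds(
    n_subjects: int,
    config: CvConfig,
    labels: Optional[np.ndarray] = None,
    repeat: int = 0,
) -> np.ndarray:
    """Assign each subject a fold id 0..outer_folds-1.

    Fold sizes differ by at most one. With ``stratified`` (and labels given)
    each fold's class ratio is within one subject of the global ratio.
    Without stratification, a fold containing a single class triggers a
    warning and a bounded number of reshuffles.
    """
    k = config.outer_folds
    if n_subjects < k:
        raise FoldError(f"{n_subjects} subjects cannot fill {k} folds")
    rng = np.random.default_rng(
        [config.seed & 0x7FFFFFFF, 0x0F01D5, repeat]
    )
    if config.stratified and labels is not None:
        y = np.asarray(labels)
        folds = np.empty(n_subjects, dtype=int)
        start = 0
        for cls in np.unique(y):
            idx = np.flatnonzero(y == cls)
            rng.shuffle(idx)
            # deal class members round-robin, rotating the starting fold so
            # remainders spread across folds rather than piling on fold 0
            folds[idx] = (np.arange(len(idx)) + start) % k
            start += len(idx)
        return folds

    for attempt in range(20):
        perm = rng.permutation(n_subjects)
        folds = np.empty(n_subjects, dtype=int)
        folds[perm] = np.arange(n_subjects) % k
        if labels is None:
            return folds
        y = np.asarray(labels)
        if all(len(np.unique(y[folds == f])) > 1 for f in range(k)):
            return folds
        log.warning("fold %d drew a single-class fold; reshuffling", attempt)
    raise FoldError("could not build folds with both classes present")


def metrics(tp: int, fn: int, tn: int, fp: int) -> dict[str, float]:
    """Accuracy, sensitivity, specificity and recall from a confusion matrix.

    Undefined ratios (an empty class in the test fold) are reported as NaN,
    never coerced to 0.
    """
    if min(tp, fn, tn, fp) < 0:
        raise ThalradError("counts must be nonnegative")
    total = tp + fn + tn + fp
    if total == 0:
        raise ThalradError("empty confusion matrix")
    sens = tp / (tp + fn) if (tp + fn) else math.nan
    spec = tn / (tn + fp) if (tn + fp) else math.nan
    return {
        "accuracy": (tp + tn) / total,
        "sensitivity": sens,
        "specificity": spec,
        "recall": sens,
    }


def roc_auc(
    scores: Sequence[float], labels: Sequence[int]
) -> tuple[pd.DataFrame, float]:
    """ROC curve and the tie-corrected rank AUC.

    AUC equals the fraction of cross-class pairs in which the positive
    subject outscores the negative one, ties counted half.
    """
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) != 2:
        raise ThalradError("AUC needs both classes present")
    pos, neg = s[y == 1], s[y == 0]
    ranks = stats.rankdata(s)
    auc = (ranks[y == 1].sum() - len(pos) * (len(pos) + 1) / 2) / (
        len(pos) * len(neg)
    )
    fpr, tpr, thr = _sk_roc_curve(y, s)
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return curve, float(auc)


# --------------------------------------------------------------------------
# repeated CV with nested selection
# --------------------------------------------------------------------------

def _fit_and_score(
    table: pd.DataFrame,
    y: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    sel_config: SelectionConfig,
    clf: ClassifierSpec,
    fit_seed: int,
) -> tuple[dict[str, float], tuple[str, ...]]:
    """Select features on the training side only, fit, score the test fold."""
    result = select_features(table.iloc[train_idx], y[train_idx], sel_config)
    feats = list(result.selected)
    if not feats:
        feats = list(result.screened)
        log.warning("empty selected set; falling back to %d screened "
                    "features", len(feats))
    xtr = table.iloc[train_idx][feats].to_numpy(dtype=float)
    xte = table.iloc[test_idx][feats].to_numpy(dtype=float)
    model = clf.build(seed=fit_seed)
    model.fit(xtr, y[train_idx])
    pred = model.predict(xte)
    if hasattr(model, "predict_proba"):
        score = model.predict_proba(xte)[:, 1]
    else:
        score = model.decision_function(xte)
    yt = y[test_idx]
    row = metrics(
        tp=int(((pred == 1) & (yt == 1)).sum()),
        fn=int(((pred == 0) & (yt == 1)).sum()),
        tn=int(((pred == 0) & (yt == 0)).sum()),
        fp=int(((pred == 1) & (yt == 0)).sum()),
    )
    row["auc"] = (
        roc_auc(score, yt)[1] if len(np.unique(yt)) == 2 else math.nan
    )
    return row, tuple(feats)


def run_repeated_cv(
    table: pd.DataFrame,
    labels: Sequence[int],
    sel_config: SelectionConfig,
    clf: ClassifierSpec,
    cv: CvConfig,
) -> EvaluationResult:
    """Repeated k-fold CV with selection nested inside each training set."""
    y = np.asarray(labels).astype(int)
    rows: list[dict] = []
    selected: list[tuple[str, ...]] = []
    for r in range(cv.repeats):
        folds = make_folds(len(y), cv, labels=y, repeat=r)
        for f in range(cv.outer_folds):
            test_idx = np.flatnonzero(folds == f)
            train_idx = np.flatnonzero(folds != f)
            sel = replace(
                sel_config,
                seed=(sel_config.seed * 10007 + r * 101 + f) & 0x7FFFFFFF,
            )
            row, feats = _fit_and_score(
                table, y, train_idx, test_idx, sel, clf,
                fit_seed=(clf.seed * 7919 + r * 103 + f) & 0x7FFFFFFF,
            )
            row.update({"repeat": r, "fold": f})
            rows.append(row)
            selected.append(feats)
    return EvaluationResult.from_folds(rows, selected)


def grid_search(
    table: pd.DataFrame,
    labels: Sequence[int],
    cv: CvConfig,
    clf_kind: str = "random_forest",
    p0_grid: Sequence[float] = tuple(round(0.01 * i, 2) for i in range(1, 11)),
    n_grid: Sequence[int] = tuple(range(1, 11)),
    t_grid: Sequence[int] = tuple(range(5, 101, 5)),
    base_selection: SelectionConfig = SelectionConfig(),
) -> tuple[tuple[float, int, int], EvaluationResult, pd.DataFrame]:
    """Exhaustive search over (p0, N, t), maximizing mean CV accuracy.

    Ties break toward the sparser/cheaper model: smaller N, then smaller t,
    then smaller p0. Returns the winning triple, its evaluation, and the
    full grid table. Selection stays nested inside the outer training folds;
    the grid is scored on the outer test folds, so the winning accuracy is
    an optimistic estimate for the winner itself.
    """
    if not (len(p0_grid) and len(n_grid) and len(t_grid)):
        raise ConfigurationError("grids must be nonempty")
    records = []
    best = None
    for p0 in p0_grid:
        for n_occ in n_grid:
            sel = replace(base_selection, p0=float(p0),
                          min_occurrence=int(n_occ))
            for t in t_grid:
                spec = ClassifierSpec(kind=clf_kind, n_trees=int(t))
                res = run_repeated_cv(table, labels, sel, spec, cv)
                acc = res.aggregate["accuracy"][0]
                records.append(
                    {"p0": p0, "N": n_occ, "t": t, "accuracy": acc}
                )
                key = (-acc, n_occ, t, p0)
                if best is None or key < best[0]:
                    best = (key, (float(p0), int(n_occ), int(t)), res)
    return best[1], best[2], pd.DataFrame(records)


# --------------------------------------------------------------------------
# permutation test
# --------------------------------------------------------------------------

def cv_accuracy_pipeline(
    sel_config: SelectionConfig, clf: ClassifierSpec, cv: CvConfig
) -> Callable[[pd.DataFrame, np.ndarray], float]:
    """The full pipeline (screen + selection + fit + CV) as one metric.

    Returns a callable suitable for :func:`permutation_test`: given a
    feature table and labels it returns the aggregate CV accuracy.
    """

    def run(table: pd.DataFrame, labels: np.ndarray) -> float:
        return run_repeated_cv(
            table, labels, sel_config, clf, cv
        ).aggregate["accuracy"][0]

    return run


def permutation_test(
    pipeline: Callable[[pd.DataFrame, np.ndarray], float],
    table: pd.DataFrame,
    labels: Sequence[int],
    m: int = 1000,
    seed: int = 0,
) -> PermutationResult:
    """Group-label permutation test over the entire pipeline.

    The pipeline (screening, selection, fitting — everything) is rerun under
    each of ``m`` permuted labelings; the add-one p-value
    ``(1 + #{null >= observed}) / (1 + m)`` can never reach zero.
    """
    if m < 1:
        raise ConfigurationError("m must be >= 1")
    y = np.asarray(labels)
    observed = float(pipeline(table, y))
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 0x9E12])
    null = np.array([
        float(pipeline(table, rng.permutation(y))) for _ in range(m)
    ])
    p = (1.0 + float((null >= observed).sum())) / (1.0 + m)
    return PermutationResult(observed, tuple(null), p)


# --------------------------------------------------------------------------
# DeLong comparison of AUCs
# --------------------------------------------------------------------------

def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")

def _delong_components(scores: np.ndarray, labels: np.ndarray):
    """AUC and its positive/negative structural components (DeLong 1988)."""
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    pos, neg = s[y == 1], s[y == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ThalradError("DeLong needs both classes present")
    tz = _midrank(np.concatenate([pos, neg]))
    tx = _midrank(pos)
    ty = _midrank(neg)
    auc = (tz[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (tz[:m] - tx) / n                      # per-positive component
    v01 = 1.0 - (tz[m:] - ty) / m                # per-negative component
    return float(auc), v10, v01


def _delong_var(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    auc, v10, v01 = _delong_components(scores, labels)
    var = (
        np.var(v10, ddof=1) / len(v10) + np.var(v01, ddof=1) / len(v01)
    )
    return auc, float(var)


def delong_test(
    scores_a: Sequence[float],
    labels_a: Sequence[int],
    scores_b: Sequence[float],
    labels_b: Optional[Sequence[int]] = None,
    paired: bool = False,
) -> dict[str, float]:
    """Two-sided DeLong comparison of two AUCs.

    ``paired=True`` requires both score lists on the same subjects
    (``labels_b`` ignored) and uses the DeLong covariance; otherwise the two
    ROC curves come from independent cohorts and the variances add. A
    degenerate total variance with a nonzero AUC difference is reported as
    non-computable (NaN p), never as 0.
    """
    sa = np.asarray(scores_a, dtype=float)
    ya = np.asarray(labels_a)
    if paired:
        sb = np.asarray(scores_b, dtype=float)
        if len(sb) != len(sa):
            raise ThalradError("paired comparison needs equal-length scores")
        auc_a, v10a, v01a = _delong_components(sa, ya)
        auc_b, v10b, v01b = _delong_components(sb, ya)
        s10 = np.cov(np.stack([v10a, v10b]), ddof=1)
        s01 = np.cov(np.stack([v01a, v01b]), ddof=1)
        cov = s10 / len(v10a) + s01 / len(v01a)
        var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    else:
        if labels_b is None:
            raise ThalradError("unpaired comparison needs labels_b")
        yb = np.asarray(labels_b)
        auc_a, var_a = _delong_var(sa, ya)
        auc_b, var_b = _delong_var(np.asarray(scores_b, dtype=float), yb)
        var = var_a + var_b
    diff = auc_a - auc_b
    if var <= 0 or not np.isfinite(var):
        p = 1.0 if diff == 0 else math.nan
        z = 0.0 if diff == 0 else math.nan
        if math.isnan(p):
            log.warning("degenerate DeLong variance; p non-computable")
    else:
        z = diff / math.sqrt(var)
        p = 2.0 * stats.norm.sf(abs(z))
    return {"auc_a": auc_a, "auc_b": auc_b, "z": float(z), "p_value": float(p)}


# --------------------------------------------------------------------------
# cross-dataset validation and confound checks
# --------------------------------------------------------------------------

def cross_dataset_validate(
    table: pd.DataFrame,
    labels: Sequence[int],
    dataset_ids: Sequence[int],
    mode: str,
    sel_config: SelectionConfig,
    clf: ClassifierSpec = ClassifierSpec(kind="svm"),
    seed: int = 0,
    test_fraction: float = 0.2,
) -> EvaluationResult:
    """Intra- (pooled 80/20) or inter-dataset (train on one, test on the
    other) validation, selection refit on the training side only.

    ``mode`` is one of ``intra``, ``inter_1to2``, ``inter_2to1``.
    """
    y = np.asarray(labels).astype(int)
    ds = np.asarray(dataset_ids)
    present = set(np.unique(ds))
    if mode == "intra":
        rng = np.random.default_rng([seed & 0x7FFFFFFF, 0x171A])
        test_idx = []
        for cls in np.unique(y):
            idx = np.flatnonzero(y == cls)
            rng.shuffle(idx)
            n_test = int(math.ceil(test_fraction * len(idx)))
            test_idx.append(idx[:n_test])
        test_idx = np.sort(np.concatenate(test_idx))
        train_idx = np.setdiff1d(np.arange(len(y)), test_idx)
    elif mode in ("inter_1to2", "inter_2to1"):
        if present != {1, 2}:
            raise ThalradError(
                "inter-dataset validation needs both datasets present"
            )
        train_ds = 1 if mode == "inter_1to2" else 2
        train_idx = np.flatnonzero(ds == train_ds)
        test_idx = np.flatnonzero(ds != train_ds)
    else:
        raise ConfigurationError(f"unknown mode {mode!r}")

    row, feats = _fit_and_score(
        table, y, train_idx, test_idx, sel_config, clf,
        fit_seed=(clf.seed * 7919 + seed) & 0x7FFFFFFF,
    )
    row.update({"repeat": 0, "fold": 0})
    return EvaluationResult.from_folds([row], [feats])


def scanner_confound_check(
    table: pd.DataFrame,
    selected: Sequence[str],
    dataset_ids: Sequence[int],
    class_labels: Sequence[int],
) -> pd.DataFrame:
    """Welch t-test per selected feature between the two datasets within
    each class; flags scanner-driven differences in the features the model
    relies on.

    Returns a tidy frame (feature, class, p_value). The p-values are not
    multiplicity-adjusted; with k features and two classes, expect about
    0.05 * 2k false flags at the 0.05 level under the null.
    """
    ds = np.asarray(dataset_ids)
    y = np.asarray(class_labels)
    if len(np.unique(ds)) != 2:
        raise ThalradError("confound check needs two datasets")
    rows = []
    for cls in np.unique(y):
        in_cls = y == cls
        if min((ds[in_cls] == 1).sum(), (ds[in_cls] == 2).sum()) < 2:
            raise ThalradError(
                f"class {cls} has <2 subjects in one dataset"
            )
        for f in selected:
            x1 = table.loc[in_cls & (ds == 1), f].to_numpy(dtype=float)
            x2 = table.loc[in_cls & (ds == 2), f].to_numpy(dtype=float)
            p = _welch_or_none(x1, x2)
            rows.append({"feature": f, "class": int(cls), "p_value": p})
    return pd.DataFrame(rows)


def _welch_or_none(x1: np.ndarray, x2: np.ndarray) -> float:
    if x1.std() == 0 and x2.std() == 0:
        return 1.0 if x1.mean() == x2.mean() else 0.0
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(stats.ttest_ind(x1, x2, equal_var=False).pvalue)
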