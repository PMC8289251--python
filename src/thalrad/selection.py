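"""Occurrence-thresholded cross-validated LASSO feature selection.

The procedure, run strictly inside a training set:

1. (optional) univariate screen — keep features whose two-sample Welch
   p-value against the class label falls below ``p0``;
2. split the training subjects into ``inner_folds`` groups; leaving out each
   group in turn, fit a squared-error LASSO of the 0/1 label on the
   remaining groups, with the penalty chosen as the largest value whose
   cross-validated MSE stays within one standard error of the minimum
   (the "1SE" rule, i.e. the sparsest model statistically tied with the
   best);
3. count, for every feature, in how many of the ``inner_folds`` repetitions
   its coefficient was nonzero (its *occurrence*), and keep the features
   occurring at least ``min_occurrence`` times.

The occurrence threshold is a stability-selection criterion: features that
survive the L1 penalty under many perturbations of the training subjects are
retained, one-off survivors are dropped. Features are z-scored with
statistics of the data passed in (never of any held-out test fold).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import KFold

from .errors import ConfigurationError, FoldError, ScreeningError

__all__ = ["SelectionConfig", "SelectionResult", "univariate_screen",
           "cv_lasso_select", "select_features"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectionConfig:
    """Knobs of the selection stage.

    p0
        Screening threshold: a feature enters the LASSO stage only if its
        Welch p-value is below ``p0`` (set ``use_screen=False`` to skip).
    min_occurrence
        The stability threshold N: minimum number of inner repetitions (out
        of ``inner_folds``) in which a feature must be selected.
    screen_top_k
        Optional cap on the screened set (sure-independence-screening
        style): when more than ``screen_top_k`` features pass the p0
        threshold, only the ``screen_top_k`` smallest p-values go forward.
        Off (None) by default; useful when a strong global effect lets
        thousands of correlated features through the screen.
    """

    p0: float = 0.05
    min_occurrence: int = 10
    inner_folds: int = 10
    seed: int = 0
    use_screen: bool = True
    screen_top_k: int | None = None
    lambda_cv_folds: int = 5
    max_iter: int = 5000
    n_alphas: int = 30
    path_eps: float = 0.01      # alpha_min/alpha_max of the penalty path
    tol: float = 1e-3

    def __post_init__(self):
        if not 0.0 < self.p0 <= 1.0:
            raise ConfigurationError("p0 must lie in (0, 1]")
        if not 1 <= self.min_occurrence <= self.inner_folds:
            raise ConfigurationError(
                "min_occurrence must lie in 1..inner_folds"
            )
        if self.inner_folds < 2:
            raise ConfigurationError("inner_folds must be >= 2")


@dataclass(frozen=True)
class SelectionResult:
    """Occurrence counts and the surviving feature list for one training set."""

    occurrence: dict[str, int]
    selected: tuple[str, ...]
    lambda_per_fold: tuple[float, ...]
    screened: tuple[str, ...]

    def selected_at(self, min_occurrence: int) -> tuple[str, ...]:
        """The (nested) selected set for any other occurrence threshold."""
        return tuple(
            f for f in self.occurrence if self.occurrence[f] >= min_occurrence
        )


def univariate_screen(
    table: pd.DataFrame, labels: np.ndarray, p0: float,
    top_k: int | None = None,
) -> tuple[str, ...]:
    """Features whose two-sample Welch p-value is below ``p0``, in table order.

    With ``top_k`` set, at most the ``top_k`` smallest p-values survive.
    Returns an empty tuple when nothing survives (callers fall back to the
    full set with a logged warning).
    """
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ScreeningError("screening needs exactly two classes")
    x0 = table.to_numpy(dtype=float)[y == classes[0]]
    x1 = table.to_numpy(dtype=float)[y == classes[1]]
    if len(x0) < 2 or len(x1) < 2:
        raise ScreeningError("screening needs >= 2 subjects per class")
    from scipy import stats

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = stats.ttest_ind(x0, x1, axis=0, equal_var=False).pvalue
    p = np.where(np.isfinite(p), p, 1.0)   # zero-variance columns -> keep out
    keep = p < p0
    if top_k is not None and keep.sum() > top_k:
        cutoff = np.sort(p[keep])[top_k - 1]
        keep &= p <= cutoff
        n_excess = int(keep.sum()) - top_k
        if n_excess > 0:                    # ties at the cutoff: stable trim
            tied = np.flatnonzero(keep & (p == cutoff))
            keep[tied[len(tied) - n_excess:]] = False
    return tuple(np.asarray(table.columns)[keep])


def _lambda_1se(model: LassoCV) -> float:
    """Largest penalty whose CV MSE is within one SE of the minimum."""
    mean_mse = model.mse_path_.mean(axis=1)
    se = model.mse_path_.std(axis=1, ddof=1) / np.sqrt(model.mse_path_.shape[1])
    i_min = int(np.argmin(mean_mse))
    threshold = mean_mse[i_min] + se[i_min]
    # alphas_ is sorted descending: the first qualifying index is the
    # largest (sparsest) penalty within one SE
    for i, a in enumerate(model.alphas_):
        if mean_mse[i] <= threshold:
            return float(a)
    return float(model.alphas_[i_min])


def cv_lasso_select(
    table: pd.DataFrame, labels: np.ndarray, config: SelectionConfig
) -> SelectionResult:
    """Run the occurrence-thresholded CV-LASSO on one training table."""
    y = np.asarray(labels, dtype=float)
    if len(table) != len(y):
        raise ConfigurationError("table and labels disagree in length")
    if len(table) < config.inner_folds:
        raise FoldError(
            f"{len(table)} subjects cannot fill {config.inner_folds} folds"
        )
    cols = list(table.columns)
    x = table.to_numpy(dtype=float)
    sd = x.std(axis=0)
    dead = sd == 0
    if dead.any():
        log.warning("excluding %d zero-variance features", int(dead.sum()))
        keep = ~dead
        cols = [c for c, k in zip(cols, keep) if k]
        x = x[:, keep]
        sd = sd[keep]
    x = (x - x.mean(axis=0)) / sd

    occurrence = {c: 0 for c in cols}
    lambdas: list[float] = []
    outer = KFold(
        n_splits=config.inner_folds, shuffle=True,
        random_state=config.seed & 0x7FFFFFFF,
    )
    for j, (rest_idx, _held) in enumerate(outer.split(x)):
        xr, yr = x[rest_idx], y[rest_idx]
        n_lambda_folds = min(config.lambda_cv_folds, len(xr))
        if n_lambda_folds < 2:
            raise FoldError("too few subjects for the penalty-selection CV")
        inner_cv = KFold(
            n_splits=n_lambda_folds, shuffle=True,
            random_state=(config.seed * 1009 + j) & 0x7FFFFFFF,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            path = LassoCV(
                cv=inner_cv, max_iter=config.max_iter,
                alphas=config.n_alphas, eps=config.path_eps,
                tol=config.tol,
            ).fit(xr, yr)
            lam = _lambda_1se(path)
            fit = Lasso(
                alpha=lam, max_iter=config.max_iter, tol=config.tol
            ).fit(xr, yr)
        lambdas.append(lam)
        for c, coef in zip(cols, fit.coef_):
            if coef != 0.0:
                occurrence[c] += 1

    selected = tuple(
        c for c in cols if occurrence[c] >= config.min_occurrence
    )
    return SelectionResult(occurrence, selected, tuple(lambdas), tuple(cols))


def select_features(
    table: pd.DataFrame, labels: np.ndarray, config: SelectionConfig
) -> SelectionResult:
    """Screen (optionally) then run the CV-LASSO; the standard entry point.

    If the screen removes everything, selection falls back to the full
    feature set with a logged warning.
    """
    if config.use_screen:
        screened = univariate_screen(table, labels, config.p0,
                                     top_k=config.screen_top_k)
        if not screened:
            log.warning("screen at p0=%g removed every feature; "
                        "falling back to the full set", config.p0)
            screened = tuple(table.columns)
        table = table[list(screened)]
    return cv_lasso_select(table, labels, config)
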