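"""Chronosensitivity: does the circadian clock shape a drug's response?

Cell lines are split at the median of a drug-sensitivity metric (GR_inf,
GR50, GR_AOC, GEC50, Hill coefficient, or an external IC50) into low-
and high-sensitivity groups, and a single-component linear discriminant
analysis (LDA) asks how well circadian features (or clock-gene
expression) separate the two groups.  Separation quality is summarized
by the chronosensitivity index: the ratio of the between-cluster
distance (BCD, distance between class means on LD1) to the
within-cluster distance (WCD, mean distance of members to their class
mean).  An index above 2 — class centers at least twice as far apart as
the typical member scatter — marks effective, clock-driven
discrimination.  Leave-one-out cross-validation (LDA or logistic
regression) and regularized regressions on the continuous metric provide
validation accuracies.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import Lasso, LogisticRegression, Ridge

from .exceptions import ConfigurationError
from .phenotyping import minmax_scale

EFFECTIVE_INDEX = 2.0


@dataclass
class ChronosensitivityResult:
    ld1_scores: pd.Series
    groups: pd.Series                      # 'below' / 'above' the median
    contributions_pct: pd.Series           # non-negative, sums to 100
    bcd: float
    wcd: float
    index: float
    effective: bool
    loocv_accuracy: float = np.nan
    logistic_accuracy: float = np.nan
    class_sizes: Dict[str, int] = field(default_factory=dict)


def binarize_by_median(values: pd.Series) -> pd.Series:
    """Median-split into 'below' and 'above' sensitivity groups.

    Values strictly below the median go to 'below'; values at or above
    (including the median line itself for odd counts, and duplicated
    medians) go to 'above'.
    """
    v = values.dropna()
    if len(v) < 4:
        raise ConfigurationError("median binarization needs at least 4 values")
    if v.nunique() == 1:
        raise ConfigurationError("all metric values identical: no separation possible")
    med = float(v.median())
    labels = pd.Series(np.where(v < med, "below", "above"), index=v.index, name="group")
    if labels.nunique() == 1:
        # duplicated median dominating: put the strictly smallest values below
        labels[v == v.min()] = "below"
    return labels


def lda_discriminate(
    predictors: pd.DataFrame,
    labels: pd.Series,
    scale: bool = True,
) -> Tuple[pd.Series, pd.Series, LinearDiscriminantAnalysis]:
    """Single-component LDA scores and per-predictor contributions.

    Predictors are min-max scaled (so coefficient magnitudes are
    comparable); contribution of predictor j is |w_j| / sum|w| * 100.
    A singular within-class scatter triggers a ridge-regularized
    (shrinkage) fallback with a warning.
    """
    common = predictors.index.intersection(labels.index)
    if len(common) < 3:
        raise ConfigurationError("LDA needs more than 2 lines with predictors and labels")
    X_df = predictors.loc[common]
    y = labels.loc[common]
    if y.nunique() != 2:
        raise ConfigurationError("LDA expects exactly two classes")
    X = (minmax_scale(X_df) if scale else X_df).to_numpy(float)

    lda = LinearDiscriminantAnalysis(solver="svd", n_components=1)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        lda.fit(X, y.to_numpy())
        collinear = any("collinear" in str(w.message).lower() for w in caught)
    if collinear:
        warnings.warn("singular within-class scatter; using shrinkage-regularized LDA coefficients")
        lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
        lda.fit(X, y.to_numpy())
        scores = X @ lda.coef_.ravel()
    else:
        scores = lda.transform(X).ravel()
    w = np.abs(lda.coef_.ravel())
    total = w.sum()
    contrib = pd.Series(
        (w / total * 100.0) if total > 0 else np.full(len(w), 100.0 / len(w)),
        index=X_df.columns, name="contribution_pct",
    )
    return pd.Series(scores, index=common, name="LD1"), contrib, lda


def chronosensitivity_index(
    ld1_scores: pd.Series, labels: pd.Series
) -> Tuple[float, float, float, bool]:
    """BCD, WCD, their ratio, and the effectiveness flag (index > 2).

    BCD is the distance between the two class means on LD1; WCD is the
    average distance of members to their own class mean.  A degenerate
    WCD of 0 with positive BCD yields an infinite index.
    """
    classes = labels.unique()
    if len(classes) != 2:
        raise ConfigurationError("index needs exactly two classes")
    groups = [ld1_scores[labels == c] for c in classes]
    if any(len(g) == 0 for g in groups):
        raise ConfigurationError("both classes must be non-empty")
    if all(len(g) < 2 for g in groups):
        raise ConfigurationError("at least one class needs >= 2 members")
    means = [g.mean() for g in groups]
    bcd = float(abs(means[0] - means[1]))
    deviations = np.concatenate([np.abs(g - m) for g, m in zip(groups, means)])
    wcd = float(deviations.mean())
    index = bcd / wcd if wcd > 0 else (math.inf if bcd > 0 else 0.0)
    return bcd, wcd, float(index), bool(index > EFFECTIVE_INDEX)


def validate(
    predictors: pd.DataFrame,
    target: pd.Series,
    method: str = "lda",
    scale: bool = True,
    agreement: str = "mad",
) -> float:
    """Leave-one-out validation accuracy for a prediction method.

    Classification methods ('lda', 'logistic') take binary labels and
    return the fraction of held-out lines classified correctly (folds
    whose training set lacks a class are skipped with a warning).
    Regression methods ('ridge', 'lasso'; regularization 1.0 and 0.1)
    keep the continuous metric and score held-out agreement as
    1 - mean|pred - true| / observed range (``agreement="mad"``) or
    1 - normalized RMSE (``agreement="nrmse"``).
    """
    common = predictors.index.intersection(target.index)
    X_df = predictors.loc[common]
    y = target.loc[common]
    X = (minmax_scale(X_df) if scale else X_df).to_numpy(float)

    def make_model():
        if method == "lda":
            return LinearDiscriminantAnalysis(solver="svd")
        if method == "logistic":
            return LogisticRegression(max_iter=1000)
        if method == "ridge":
            return Ridge(alpha=1.0)
        if method == "lasso":
            return Lasso(alpha=0.1, max_iter=10000)
        raise ConfigurationError(f"unknown method {method!r}")

    classification = method in ("lda", "logistic")
    preds, truths = [], []
    skipped = 0
    yv = y.to_numpy()
    for i in range(len(common)):
        train = np.ones(len(common), bool)
        train[i] = False
        if classification and len(np.unique(yv[train])) < 2:
            skipped += 1
            continue
        model = make_model()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(X[train], yv[train])
            preds.append(model.predict(X[i : i + 1])[0])
        truths.append(yv[i])
    if skipped:
        warnings.warn(f"{skipped} LOOCV folds skipped (single-class training set)")
    if not truths:
        return np.nan
    preds = np.asarray(preds)
    truths = np.asarray(truths)
    if classification:
        return float(np.mean(preds == truths))
    rng = np.ptp(y.to_numpy(float))
    if rng == 0:
        return np.nan
    if agreement == "nrmse":
        return float(1.0 - np.sqrt(np.mean((preds - truths) ** 2)) / rng)
    return float(1.0 - np.mean(np.abs(preds - truths)) / rng)


def analyze_drug(
    predictors: pd.DataFrame,
    metric: pd.Series,
    run_validation: bool = True,
) -> ChronosensitivityResult:
    """Full chronosensitivity analysis of one drug's sensitivity metric."""
    labels = binarize_by_median(metric)
    scores, contrib, _ = lda_discriminate(predictors, labels)
    labels = labels.loc[scores.index]
    bcd, wcd, index, effective = chronosensitivity_index(scores, labels)
    result = ChronosensitivityResult(
        ld1_scores=scores,
        groups=labels,
        contributions_pct=contrib,
        bcd=bcd,
        wcd=wcd,
        index=index,
        effective=effective,
        class_sizes=labels.value_counts().to_dict(),
    )
    if run_validation:
        result.loocv_accuracy = validate(predictors, labels, method="lda")
        result.logistic_accuracy = validate(predictors, labels, method="logistic")
    return result


def rank_drugs(
    predictors: pd.DataFrame,
    sensitivity: pd.DataFrame,
    run_validation: bool = False,
) -> pd.DataFrame:
    """Chronosensitivity index ranking across a drug sensitivity table.

    ``sensitivity`` holds one metric column per drug; returns a table
    ranked by index with the effectiveness cut-off flag (index > 2).
    """
    rows = []
    for drug in sensitivity.columns:
        res = analyze_drug(predictors, sensitivity[drug], run_validation=run_validation)
        rows.append(
            dict(drug=drug, index=res.index, bcd=res.bcd, wcd=res.wcd,
                 effective=res.effective, loocv_accuracy=res.loocv_accuracy)
        )
    return (
        pd.DataFrame(rows).sort_values("index", ascending=False).reset_index(drop=True)
    )
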