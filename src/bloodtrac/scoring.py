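"""Composite transcript scores and diagnostic evaluation.

The composite score expresses each panel transcript as a ratio to its
mean expression across the cohort and averages the ratios per sample, so
highly expressed transcripts are not over-represented. Discriminant
ability is summarized by the empirical C-statistic (Mann–Whitney AUC) and
a confusion matrix; PLS-DA with stratified N-fold validation covers the
wide-matrix classifier, and an additive clinical risk-point model covers
the conventional comparator.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import yaml
from sklearn.cross_decomposition import PLSRegression
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .datatypes import (
    ExpressionMatrix,
    GeneSet,
    SampleRecord,
    ValidationError,
    normalize_symbol,
)

__all__ = [
    "Orientation",
    "CompositeScore",
    "ConfusionMatrix",
    "RiskPointTable",
    "composite_score",
    "c_statistic",
    "confusion_metrics",
    "confusion_from_predictive_values",
    "confusion_at_threshold",
    "clinical_risk",
    "load_risk_table",
    "pls_da",
    "score_on_covariate",
    "combined_model_auc",
]


class Orientation(str, enum.Enum):
    lower_is_disease = "lower_is_disease"
    higher_is_disease = "higher_is_disease"


@dataclass
class CompositeScore:
    """Per-sample composite panel score (≈ 1 at the cohort average)."""

    scores: pd.Series
    panel: GeneSet
    orientation: Orientation = Orientation.lower_is_disease

    def oriented(self) -> pd.Series:
        """Scores flipped so that larger always means more disease-like."""
        if self.orientation is Orientation.lower_is_disease:
            return -self.scores
        return self.scores


def composite_score(
    m: ExpressionMatrix,
    panel: GeneSet,
    symbols: Mapping[str, str] | None = None,
    orientation: Orientation = Orientation.lower_is_disease,
) -> CompositeScore:
    """Mean over panel transcripts of (expression / cohort-mean expression).

    ``symbols`` maps transcript id → gene symbol when matrix rows are not
    already symbols; each panel member must resolve to exactly one row.
    The cohort mean of each per-transcript ratio is 1 by construction.
    """
    if symbols is not None:
        sym_to_id: dict[str, str] = {}
        for tid, sym in symbols.items():
            sym_to_id.setdefault(normalize_symbol(sym), tid)
        rows = {sym: sym_to_id.get(sym) for sym in panel.members}
    else:
        idx = set(m.transcript_ids)
        rows = {sym: (sym if sym in idx else None) for sym in panel.members}
    missing = sorted(s for s, r in rows.items() if r is None)
    if missing:
        raise ValidationError(f"panel symbols not in matrix: {', '.join(missing)}")
    sub = m.values.loc[[rows[s] for s in sorted(rows)]]
    means = sub.mean(axis=1)
    if (means == 0).any():
        bad = means.index[means == 0][0]
        raise ValidationError(f"panel transcript {bad!r} has zero cohort mean")
    ratios = sub.div(means, axis=0)
    return CompositeScore(
        scores=ratios.mean(axis=0), panel=panel, orientation=orientation
    )


def c_statistic(
    scores: Sequence[float],
    labels: Sequence[int],
    orientation: Orientation | str = Orientation.higher_is_disease,
) -> float:
    """Empirical AUC (Mann–Whitney U / n₁n₀, ties counted ½).

    ``labels`` are 1 = disease, 0 = not; scores are oriented so the
    disease direction is positive before ranking.
    """
    y = np.asarray(labels, dtype=int)
    x = np.asarray(scores, dtype=float)
    if len(set(y.tolist())) != 2:
        raise ValidationError("c_statistic needs both classes present")
    if Orientation(orientation) is Orientation.lower_is_disease:
        x = -x
    return float(roc_auc_score(y, x))


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValidationError("confusion counts must be ≥ 0")


def confusion_metrics(cm: ConfusionMatrix) -> dict[str, float | None]:
    """Sensitivity, specificity, PPV, NPV, accuracy as fractions.

    A metric whose denominator is zero is reported as None (missing),
    never as 0.
    """
    def _ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    total = cm.tp + cm.fp + cm.fn + cm.tn
    return {
        "sensitivity": _ratio(cm.tp, cm.tp + cm.fn),
        "specificity": _ratio(cm.tn, cm.tn + cm.fp),
        "ppv": _ratio(cm.tp, cm.tp + cm.fp),
        "npv": _ratio(cm.tn, cm.tn + cm.fn),
        "accuracy": _ratio(cm.tp + cm.tn, total),
    }


def confusion_from_predictive_values(
    ppv: float, npv: float, n_pred_pos: int, n_pred_neg: int
) -> ConfusionMatrix:
    """Invert printed PPV/NPV over known prediction totals into counts."""
    if not (0 <= ppv <= 1 and 0 <= npv <= 1):
        raise ValidationError("ppv and npv must be in [0, 1]")
    if n_pred_pos < 0 or n_pred_neg < 0:
        raise ValidationError("prediction counts must be ≥ 0")
    tp = round(ppv * n_pred_pos)
    tn = round(npv * n_pred_neg)
    return ConfusionMatrix(tp=tp, fp=n_pred_pos - tp, fn=n_pred_neg - tn, tn=tn)


def confusion_at_threshold(
    scores: Sequence[float],
    labels: Sequence[int],
    threshold: float | None = None,
    orientation: Orientation | str = Orientation.higher_is_disease,
) -> ConfusionMatrix:
    """Classify at a score threshold (default: cohort median) and count.

    Scores are oriented disease-positive first; a sample is called
    positive when its oriented score is ≥ the threshold.
    """
    y = np.asarray(labels, dtype=int)
    x = np.asarray(scores, dtype=float)
    if Orientation(orientation) is Orientation.lower_is_disease:
        x = -x
    if threshold is None:
        threshold = float(np.median(x))
    pred = x >= threshold
    return ConfusionMatrix(
        tp=int(np.sum(pred & (y == 1))),
        fp=int(np.sum(pred & (y == 0))),
        fn=int(np.sum(~pred & (y == 1))),
        tn=int(np.sum(~pred & (y == 0))),
    )


# ---------------------------------------------------------------------------
# additive clinical risk points
# ---------------------------------------------------------------------------

@dataclass
class RiskPointTable:
    """Additive risk points per clinical factor level, plus class cutpoints.

    ``points``: factor → either {level: points} for categorical/flag
    factors or a list of [lower_bound, points] bands (ascending) for
    numeric factors such as age. ``cutpoints``: ascending totals mapping
    to ``classes`` (len(classes) = len(cutpoints) + 1).
    """

    points: dict
    cutpoints: list[float]
    classes: list[str]

    def __post_init__(self) -> None:
        if sorted(self.cutpoints) != list(self.cutpoints):
            raise ValidationError("cutpoints must be strictly increasing")
        if len(self.classes) != len(self.cutpoints) + 1:
            raise ValidationError("need one more class than cutpoints")

    def factor_points(self, factor: str, value) -> int:
        rule = self.points[factor]
        if isinstance(rule, dict):
            return int(rule.get(str(value), rule.get(value, 0)))
        pts = 0
        for lower, p in rule:  # ascending numeric bands
            if float(value) >= float(lower):
                pts = int(p)
        return pts

    def classify(self, total: float) -> str:
        k = sum(total >= c for c in self.cutpoints)
        return self.classes[k]


def load_risk_table(path) -> RiskPointTable:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return RiskPointTable(
        points=raw["points"], cutpoints=list(raw["cutpoints"]),
        classes=list(raw["classes"]),
    )


def clinical_risk(
    patients: Sequence[SampleRecord], table: RiskPointTable
) -> pd.DataFrame:
    """Sum risk points per patient and map the total to a risk class.

    Purely additive; a patient missing any required covariate gets a
    missing result (NaN points, empty class) with a warning column rather
    than a silent zero.
    """
    rows = []
    for p in patients:
        missing = [f for f in table.points if p.covariates.get(f) is None]
        if missing:
            rows.append({"sample_id": p.sample_id, "points": np.nan,
                         "risk_class": "", "missing": ",".join(sorted(missing))})
            continue
        total = sum(
            table.factor_points(f, p.covariates[f]) for f in table.points
        )
        rows.append({"sample_id": p.sample_id, "points": float(total),
                     "risk_class": table.classify(total), "missing": ""})
    return pd.DataFrame(rows).set_index("sample_id")


# ---------------------------------------------------------------------------
# PLS-DA
# ---------------------------------------------------------------------------

def pls_da(
    X: np.ndarray | pd.DataFrame,
    labels: Sequence[int],
    n_components: int = 2,
    n_folds: int = 5,
    seed: int = 0,
) -> dict:
    """Partial least squares discriminant analysis with N-fold validation.

    Components are extracted by iterative deflation (NIPALS) on
    standardized predictors against a ±1 class code; a sample is assigned
    the positive class when its fitted response is > 0. Folds are
    stratified by class and reproducible under ``seed``. Returns training
    and cross-validated accuracy, overall and per class.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels, dtype=int)
    if set(y.tolist()) != {0, 1}:
        raise ValidationError("labels must contain exactly the classes 0 and 1")
    rank_cap = min(X.shape[0] - 1, X.shape[1])
    if not (1 <= n_components <= rank_cap):
        raise ValidationError(
            f"n_components must be in [1, {rank_cap}] for this matrix"
        )
    code = 2.0 * y - 1.0

    def _fit_predict(train, test) -> np.ndarray:
        model = PLSRegression(n_components=n_components, scale=True)
        model.fit(X[train], code[train])
        return (model.predict(X[test]).ravel() > 0).astype(int)

    all_idx = np.arange(len(y))
    train_pred = _fit_predict(all_idx, all_idx)

    cv_pred = np.empty_like(y)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    for train, test in skf.split(X, y):
        cv_pred[test] = _fit_predict(train, test)

    def _accuracy(pred: np.ndarray) -> dict:
        return {
            "overall": float(np.mean(pred == y)),
            "class0": float(np.mean(pred[y == 0] == 0)),
            "class1": float(np.mean(pred[y == 1] == 1)),
        }

    return {"train": _accuracy(train_pred), "cv": _accuracy(cv_pred),
            "n_components": n_components, "n_folds": n_folds}


def score_on_covariate(
    scores: Sequence[float], covariate: Sequence[float]
) -> dict[str, float]:
    """OLS simple regression of a score on one covariate.

    Returns slope, intercept, r_squared and the two-sided p of the slope.
    """
    x = np.asarray(covariate, dtype=float)
    y = np.asarray(scores, dtype=float)
    if len(x) < 3:
        raise ValidationError("need n ≥ 3")
    if np.ptp(x) == 0:
        raise ValidationError("covariate has zero variance")
    fit = scipy.stats.linregress(x, y)
    return {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "r_squared": float(fit.rvalue ** 2),
        "p": float(fit.pvalue),
        "n": len(x),
    }


def combined_model_auc(
    composite: Sequence[float],
    age: Sequence[float],
    labels: Sequence[int],
    seed: int = 0,
) -> float:
    """C-statistic of a logistic combination of age and the composite score.

    Convenience comparator (standard maximum-likelihood logistic fit on
    two predictors), not a bespoke algorithm.
    """
    X = np.column_stack([np.asarray(composite, float), np.asarray(age, float)])
    y = np.asarray(labels, dtype=int)
    model = LogisticRegression(penalty=None, max_iter=1000, random_state=seed)
    model.fit(X, y)
    return float(roc_auc_score(y, model.decision_function(X)))
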