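"""Model selection and evaluation: metrics, Youden-index cutoff,
stratified cross-validation, and random hyperparameter search."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import clone
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)


@dataclass
class MetricReport:
    """Binary classification metrics with the stated positive class.

    ``confusion`` is ``[[TN, FP], [FN, TP]]``.  Ratios with a zero
    denominator are reported as 0 and recorded in ``undefined``.
    """

    accuracy: float
    precision: float
    recall: float
    f1: float
    confusion: np.ndarray
    positive_class: object
    undefined: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy, "precision": self.precision,
            "recall": self.recall, "f1": self.f1,
            "positive_class": str(self.positive_class),
        }


def compute_metrics(y_true, y_pred, positive_class) -> MetricReport:
    """Accuracy, precision, recall and F1 (harmonic mean) for two classes."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    pos_t = y_true == positive_class
    pos_p = y_pred == positive_class
    tp = int(np.sum(pos_t & pos_p))
    fp = int(np.sum(~pos_t & pos_p))
    fn = int(np.sum(pos_t & ~pos_p))
    tn = int(np.sum(~pos_t & ~pos_p))
    undefined: list[str] = []
    accuracy = (tp + tn) / len(y_true)
    if tp + fp == 0:
        precision = 0.0
        undefined.append("precision")
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        recall = 0.0
        undefined.append("recall")
    else:
        recall = tp / (tp + fn)
    if precision + recall == 0:
        f1 = 0.0
        undefined.append("f1")
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return MetricReport(accuracy=accuracy, precision=precision, recall=recall, f1=f1,
                        confusion=np.array([[tn, fp], [fn, tp]]),
                        positive_class=positive_class, undefined=undefined)


def select_cutoff(scores, y_true_binary) -> float:
    """Probability threshold maximizing Youden's J = sensitivity + specificity - 1.

    Candidates are the observed scores (rule: ``score >= t`` predicts
    positive) plus ``+inf`` (predict none).  Ties are broken toward the
    candidate closest to 0.5.  Degenerate inputs (best J <= 0, or all
    scores equal) return with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y_true_binary).astype(int)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("select_cutoff requires both classes present")
    candidates = np.unique(scores)
    best_j = -np.inf
    best_t = candidates[0]
    for t in np.append(candidates, np.inf):
        pred = scores >= t
        sens = np.sum(pred & (y == 1)) / n_pos
        spec = np.sum(~pred & (y == 0)) / n_neg
        j = sens + spec - 1.0
        if j > best_j + 1e-12 or (abs(j - best_j) <= 1e-12 and abs(t - 0.5) < abs(best_t - 0.5)):
            best_j, best_t = j, t
    if len(candidates) == 1:
        warnings.warn("all scores identical; Youden cutoff is degenerate")
        return float(candidates[0])
    if best_j <= 0:
        warnings.warn("maximal Youden index <= 0; scores carry no (or inverted) signal")
    if not np.isfinite(best_t):
        best_t = float(candidates[-1])
    return float(best_t)


def stratified_folds(y, n_splits: int = 5, seed: int = 0):
    """Disjoint class-stratified (train, validation) index pairs."""
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(y)), y))


@dataclass
class CvResult:
    config: dict
    fold_metrics: list[MetricReport]
    mean_metrics: dict
    n_parameters: int


def cross_validate(estimator, X, y, positive_class, n_splits: int = 5, seed: int = 0) -> CvResult:
    """Stratified k-fold evaluation; early stopping monitors each fold's
    validation loss."""
    X = np.asarray(X)
    y = np.asarray(y)
    reports = []
    n_params = 0
    for tr, va in stratified_folds(y, n_splits=n_splits, seed=seed):
        est = clone(estimator)
        try:
            est.fit(X[tr], y[tr], validation_data=(X[va], y[va]))
        except TypeError:
            est.fit(X[tr], y[tr])
        n_params = getattr(est, "n_parameters_", 0)
        reports.append(compute_metrics(y[va], est.predict(X[va]), positive_class))
    mean = {m: float(np.mean([getattr(r, m) for r in reports]))
            for m in ("accuracy", "precision", "recall", "f1")}
    return CvResult(config=estimator.get_params(deep=False), fold_metrics=reports,
                    mean_metrics=mean, n_parameters=n_params)


def random_search(estimator, X, y, search_space: dict, n_draws: int,
                  positive_class, seed: int = 0, n_splits: int = 5):
    """Random hyperparameter search scored by stratified k-fold CV.

    ``search_space`` maps parameter names to lists of candidate values;
    each draw picks one value per parameter uniformly.  The winner has
    the highest mean validation accuracy; ties break toward higher mean
    F1, then fewer trainable parameters.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if not search_space:
        raise ValueError("search space is empty")
    rng = np.random.default_rng(seed)
    results: list[CvResult] = []
    for draw in range(n_draws):
        cfg = {k: v[rng.integers(len(v))] for k, v in search_space.items()}
        est = clone(estimator).set_params(**cfg)
        res = cross_validate(est, X, y, positive_class, n_splits=n_splits,
                             seed=int(rng.integers(2**31)))
        res.config = {**res.config, **cfg}
        results.append(res)
        logger.info("random_search draw %d/%d: %s -> acc %.4f",
                    draw + 1, n_draws, cfg, res.mean_metrics["accuracy"])
    best = max(results, key=lambda r: (r.mean_metrics["accuracy"],
                                       r.mean_metrics["f1"], -r.n_parameters))
    return best, results
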