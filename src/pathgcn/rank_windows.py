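"""Rank-windowed logistic-regression validation of importance rankings.

If a ranking is informative, classifiers built from the genes of
highly ranked windows should beat classifiers built from the genes of
lowly ranked windows.  Windows are consecutive, disjoint blocks of the
ranking — blocks of pathways (gene union, deduplicated) or blocks of
individual genes — each fitted independently with an L2-regularized
logistic regression; the trend of F1 against window index summarizes
the decay.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .attribution import ImportanceTable
from .gene_sets import GeneSetCollection
from .selection import MetricReport, compute_metrics


@dataclass
class RankWindowResult:
    window_index: int
    selector: str
    member_genes: list[str]
    n_genes: int
    metrics: MetricReport


def select_gene_windows(importance: ImportanceTable, sets: GeneSetCollection | None,
                        mode: str, window_size: int) -> list[list[str]]:
    """Split the importance ranking into consecutive gene windows.

    ``mode="pathways"``: blocks of ``window_size`` pathways by rank;
    each window's genes are the union of member genes (a gene shared by
    two pathways of one window counts once; windows are independent
    models, so a gene may reappear in a later window).  ``mode="genes"``:
    blocks of ``window_size`` genes by rank.
    """
    if mode == "pathways":
        if importance.level != "pathway":
            raise ValueError("pathway windows need a pathway-level importance table")
        if sets is None:
            raise ValueError("pathway windows need the gene-set collection")
        ranked = importance.ids
        if window_size > len(ranked):
            warnings.warn("window_size exceeds the pathway universe; single clipped window")
            window_size = len(ranked)
        windows = []
        for start in range(0, len(ranked), window_size):
            block = ranked[start:start + window_size]
            genes: dict[str, None] = {}
            for pid in block:
                for g in sets[pid]:
                    genes.setdefault(g, None)
            windows.append(list(genes))
        return windows
    if mode == "genes":
        if importance.level != "gene":
            raise ValueError("gene windows need a gene-level importance table")
        ranked = importance.ids
        if window_size > len(ranked):
            warnings.warn("window_size exceeds the gene universe; single clipped window")
            window_size = len(ranked)
        return [ranked[s:s + window_size] for s in range(0, len(ranked), window_size)]
    raise ValueError(f"unknown mode {mode!r}")


def fit_window_classifier(X_train, y_train, X_test, y_test, gene_ids: list[str],
                          genes: list[str], positive_class, l2_c: float = 1.0,
                          seed: int = 0) -> MetricReport:
    """L2 logistic regression on a gene subset, scored on the test set.

    Class-balanced sample weighting mirrors the GCN's weighted loss;
    the regularization strength is held fixed across windows so the
    comparison varies only the feature set.
    """
    pos = {g: i for i, g in enumerate(gene_ids)}
    missing = [g for g in genes if g not in pos]
    if missing:
        raise ValueError(f"genes absent from the aligned universe: {missing[:5]}")
    cols = [pos[g] for g in genes]
    Xtr = np.asarray(X_train, dtype=float)[:, cols]
    Xte = np.asarray(X_test, dtype=float)[:, cols]
    if not np.any(Xtr):
        raise ValueError("feature submatrix is all zeros; nothing to fit")
    # default penalty is the ridge (L2) term; strength 1/l2_c
    clf = LogisticRegression(C=l2_c, class_weight="balanced",
                             max_iter=5000, random_state=seed)
    clf.fit(Xtr, y_train)
    return compute_metrics(np.asarray(y_test), clf.predict(Xte), positive_class)


def run_rank_validation(importance: ImportanceTable, sets: GeneSetCollection | None,
                        mode: str, window_size: int, X_train, y_train, X_test, y_test,
                        gene_ids: list[str], positive_class, l2_c: float = 1.0,
                        seed: int = 0, max_windows: int | None = None) -> list[RankWindowResult]:
    """Fit one logistic regression per rank window, in rank order."""
    windows = select_gene_windows(importance, sets, mode, window_size)
    if max_windows is not None:
        windows = windows[:max_windows]
    results = []
    for i, genes in enumerate(windows):
        report = fit_window_classifier(X_train, y_train, X_test, y_test, gene_ids,
                                       genes, positive_class, l2_c=l2_c, seed=seed)
        results.append(RankWindowResult(
            window_index=i + 1,
            selector=f"{mode}-window of {window_size}",
            member_genes=genes, n_genes=len(genes), metrics=report,
        ))
    return results


def trend_report(results: list[RankWindowResult]) -> tuple[float, pd.DataFrame]:
    """OLS slope of F1 against window index, plus the per-window table."""
    if len(results) < 2:
        raise ValueError("need at least two windows for a trend")
    idx = np.array([r.window_index for r in results], dtype=float)
    f1 = np.array([r.metrics.f1 for r in results])
    slope = float(np.polyfit(idx, f1, deg=1)[0])
    table = pd.DataFrame({
        "window_index": [r.window_index for r in results],
        "n_genes": [r.n_genes for r in results],
        "accuracy": [r.metrics.accuracy for r in results],
        "precision": [r.metrics.precision for r in results],
        "recall": [r.metrics.recall for r in results],
        "f1": f1,
    })
    return slope, table
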