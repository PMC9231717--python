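"""Shapley-value feature importance at the pooling layer (pathways) and
the input layer (genes).

The explained quantity is always the pre-softmax logit margin
``logit(positive) - logit(negative)``.  For the plain GCN the head is a
single linear layer, so pooling-layer Shapley values are exact in
closed form:

    phi_i = w_i * (z_i - E_bg[z_i]),    base = w . E_bg[z] + (b_pos - b_neg),

where ``w`` is the head's margin weight vector and the expectation runs
over a background (reference) set of pooled activations.  For nonlinear
heads (GCN-MLP) a permutation-sampling estimator is used; its additive
decomposition telescopes, so local accuracy ``sum(phi) + base = margin``
holds exactly for the sampled estimate as well.  Gene-level attribution
uses expected gradients (integrated gradients averaged over background
references).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .graphs import PathwayGraph

logger = logging.getLogger(__name__)


@dataclass
class ImportanceTable:
    """Ranked mean-absolute-Shapley importance at pathway or gene level.

    ``entries`` rows are ``(id, mean_abs_shap, rank)`` sorted descending
    by importance (stable in original order on ties, so an all-zero
    attribution preserves input order).  ``per_sample_values`` holds the
    signed Shapley values, samples x features, where features are the
    ``K * pool_channels`` pooled outputs at pathway level or the G genes
    at gene level.
    """

    level: str
    entries: pd.DataFrame
    per_sample_values: np.ndarray
    feature_ids: list[str]
    base_value: float = 0.0

    @property
    def ids(self) -> list[str]:
        return list(self.entries["id"])

    def top(self, n: int) -> list[str]:
        return list(self.entries["id"].iloc[:n])

    def to_tsv(self, path) -> None:
        self.entries.to_csv(path, sep="\t", index=False)


def exact_linear_shap(weights: np.ndarray, bias: float, Z: np.ndarray,
                      Z_background: np.ndarray) -> tuple[np.ndarray, float]:
    """Exact Shapley values for a linear function of independent features.

    For ``f(z) = w . z + b`` with reference distribution given by the
    background rows, ``phi_i = w_i (z_i - mean_bg z_i)`` for every
    coalition ordering, so the Shapley value is exact, and
    ``sum_i phi_i + base = f(z)`` with ``base = w . mean_bg + b``.
    """
    mu = Z_background.mean(axis=0)
    phi = (Z - mu[None, :]) * weights[None, :]
    base = float(weights @ mu + bias)
    return phi, base


def sampled_shap(f, Z: np.ndarray, Z_background: np.ndarray, n_permutations: int = 32,
                 seed: int = 0) -> tuple[np.ndarray, float]:
    """Permutation-sampling Shapley values for an arbitrary ``f``.

    For each explained row, each permutation and each background row,
    features are switched one at a time from the reference value to the
    explained value along the permutation; the marginal change in ``f``
    is credited to the switched feature.  Contributions telescope to
    ``f(z) - f(r)`` within every permutation, so the averaged estimate
    satisfies local accuracy exactly: ``sum(phi) + mean_r f(r) = f(z)``.
    """
    rng = np.random.default_rng(seed)
    n, d = Z.shape
    n_bg = Z_background.shape[0]
    phi = np.zeros((n, d))
    base = float(np.mean(f(Z_background)))
    for s in range(n):
        z = Z[s]
        acc = np.zeros(d)
        for _ in range(n_permutations):
            perm = rng.permutation(d)
            # walk the permutation for all background rows at once
            cur = Z_background.copy()            # (n_bg, d)
            f_cur = f(cur)
            for j in perm:
                cur[:, j] = z[j]
                f_next = f(cur)
                acc[j] += np.mean(f_next - f_cur)
                f_cur = f_next
        phi[s] = acc / n_permutations
    return phi, base


def pooled_feature_ids(graphs: list[PathwayGraph], pool_channels: int) -> list[str]:
    return [f"{g.pathway_id}|{c}" for g in graphs for c in range(pool_channels)]


def shap_pooling(model, X, background: np.ndarray | None = None,
                 background_size: int | None = None, n_permutations: int = 32,
                 seed: int = 0) -> tuple[np.ndarray, float]:
    """Shapley values of the logit margin w.r.t. the pooled pathway outputs.

    ``background`` defaults to the explained samples' own pooled
    activations; ``background_size`` optionally subsamples it.  Returns
    ``(per_sample_values, base_value)`` with local accuracy
    ``per_sample_values.sum(1) + base = decision_function(X)``.
    """
    Z = model.pooled_transform(X)
    if background is None:
        Z_bg = Z
    else:
        Z_bg = model.pooled_transform(background)
    if background_size is not None:
        if background_size > Z_bg.shape[0]:
            raise ValueError(
                f"background_size {background_size} exceeds available samples {Z_bg.shape[0]}"
            )
        idx = np.random.default_rng(seed).choice(Z_bg.shape[0], background_size, replace=False)
        Z_bg = Z_bg[idx]

    head = model.network_.head
    if model.head_is_linear:
        lin = head.layers[0]
        w = lin.params["W"][:, 1] - lin.params["W"][:, 0]
        b = float(lin.params["b"][1] - lin.params["b"][0])
        return exact_linear_shap(w, b, Z, Z_bg)

    def margin(pooled):
        rng = np.random.default_rng(0)
        logits = head.forward(pooled, training=False, rng=rng)
        return logits[:, 1] - logits[:, 0]

    return sampled_shap(margin, Z, Z_bg, n_permutations=n_permutations, seed=seed)


def aggregate_pathway_importance(per_sample_values: np.ndarray,
                                 graphs: list[PathwayGraph],
                                 base_value: float = 0.0) -> ImportanceTable:
    """Mean |Shapley| per pathway over its pool channels and all samples."""
    K = len(graphs)
    n, f = per_sample_values.shape
    if f % K != 0:
        raise ValueError(f"{f} pooled features do not divide into {K} pathways")
    p = f // K
    absvals = np.abs(per_sample_values).reshape(n, K, p)
    importance = absvals.mean(axis=(0, 2))
    order = np.argsort(-importance, kind="stable")
    entries = pd.DataFrame({
        "id": [graphs[k].pathway_id for k in order],
        "mean_abs_shap": importance[order],
        "rank": np.arange(1, K + 1),
    })
    return ImportanceTable(level="pathway", entries=entries,
                           per_sample_values=per_sample_values,
                           feature_ids=pooled_feature_ids(graphs, p),
                           base_value=base_value)


def pathway_importance(model, X, graphs: list[PathwayGraph], **kwargs) -> ImportanceTable:
    """Convenience: pooling-layer Shapley values aggregated per pathway."""
    values, base = shap_pooling(model, X, **kwargs)
    return aggregate_pathway_importance(values, graphs, base_value=base)


def shap_genes(model, X, background: np.ndarray | None = None,
               background_size: int = 25, n_steps: int = 25,
               seed: int = 0) -> ImportanceTable:
    """Gene-level attribution of the logit margin by expected gradients.

    For each explained sample the margin gradient is integrated along
    straight paths from background references to the sample (midpoint
    rule with ``n_steps`` points, averaged over up to
    ``background_size`` references drawn with ``seed``), then multiplied
    by the input difference.  Features that are constant across samples
    and references (e.g. zero-filled unmeasured genes) receive exactly
    zero.
    """
    X = np.asarray(X, dtype=float)
    refs = X if background is None else np.asarray(background, dtype=float)
    if background_size < refs.shape[0]:
        idx = np.random.default_rng(seed).choice(refs.shape[0], background_size, replace=False)
        refs = refs[idx]
    n, G = X.shape
    R = refs.shape[0]
    alphas = (np.arange(n_steps) + 0.5) / n_steps
    phi = np.zeros((n, G))
    for s in range(n):
        diff = X[s][None, :] - refs                      # (R, G)
        # all interpolation points for this sample in one batch
        points = (refs[None, :, :] + alphas[:, None, None] * diff[None, :, :]).reshape(R * n_steps, G)
        grads = _margin_input_gradient(model, points).reshape(n_steps, R, G)
        phi[s] = (grads.mean(axis=0) * diff).mean(axis=0)
    base = float(np.mean(model.decision_function(refs)))

    importance = np.abs(phi).mean(axis=0)
    order = np.argsort(-importance, kind="stable")
    gene_ids = list(model.gene_ids) if getattr(model, "gene_ids", None) is not None \
        else [f"x{j}" for j in range(G)]
    entries = pd.DataFrame({
        "id": [gene_ids[j] for j in order],
        "mean_abs_shap": importance[order],
        "rank": np.arange(1, G + 1),
    })
    return ImportanceTable(level="gene", entries=entries, per_sample_values=phi,
                           feature_ids=gene_ids, base_value=base)


def _margin_input_gradient(model, X: np.ndarray) -> np.ndarray:
    """d(logit margin)/d(input) in evaluation mode."""
    net = model.network_
    rng = np.random.default_rng(0)
    logits = net.forward(X, training=False, rng=rng)
    dlogits = np.tile(np.array([-1.0, 1.0]), (X.shape[0], 1))
    return net.backward(dlogits)


@dataclass
class OverlapReport:
    top_n: int
    shap_top: list[str]
    gsea_top: list[str]
    overlap: list[str]
    spearman_rho: float
    spearman_p: float


def compare_rankings(table: ImportanceTable, enrichment_results, top_n: int) -> OverlapReport:
    """Compare the Shapley ranking with a GSEA ranking by |NES|.

    Reports the two top-n sets, their intersection, and the Spearman
    correlation between mean-absolute-Shapley and |NES| over the shared
    pathway universe.
    """
    gsea = {r.pathway_id: r for r in enrichment_results}
    shared = [pid for pid in table.ids if pid in gsea]
    if not shared:
        raise ValueError("no shared pathways between the two rankings")
    if top_n > len(shared):
        warnings.warn(f"top_n {top_n} exceeds universe size {len(shared)}; clipping")
        top_n = len(shared)
    shap_rank = [pid for pid in table.ids if pid in gsea]
    gsea_rank = sorted(shared, key=lambda pid: -abs(gsea[pid].nes))
    shap_top = shap_rank[:top_n]
    gsea_top = gsea_rank[:top_n]
    overlap = [pid for pid in shap_top if pid in set(gsea_top)]
    imp = table.entries.set_index("id")["mean_abs_shap"]
    rho, pval = spearmanr([imp[pid] for pid in shared],
                          [abs(gsea[pid].nes) for pid in shared])
    return OverlapReport(top_n=top_n, shap_top=shap_top, gsea_top=gsea_top,
                         overlap=overlap, spearman_rho=float(rho), spearman_p=float(pval))
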