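"""Gene set enrichment analysis with the weighted Kolmogorov–Smirnov
running-sum statistic and phenotype-permutation null.

Genes are ranked by the signal-to-noise ratio between the two classes;
each gene set's enrichment score (ES) is the signed maximum deviation of
a running sum that steps up by ``|score|^p / sum(|score|^p over hits)``
at member genes and down by ``1 / (N - |S|)`` at non-members.  The
normalized enrichment score (NES), nominal p-value and FDR q-value are
estimated from phenotype permutations, following the standard GSEA
procedure (sign-stratified normalization and tail ratios).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .gene_sets import GeneSetCollection

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    pathway_id: str
    es: float
    nes: float
    p_value: float
    fdr_q: float
    direction: str          # "class0-enriched" (es > 0) or "class1-enriched"
    n_genes_matched: int
    computable: bool = True


def signal_to_noise(values: np.ndarray, y: np.ndarray, sd_floor_frac: float = 0.2) -> np.ndarray:
    """Per-gene (mean0 - mean1) / (sd0 + sd1) with GSEA's SD floor.

    Each class SD is floored at ``sd_floor_frac * |class mean|``; a gene
    whose denominator is still zero (identical constants in both
    classes) scores 0.  ``values`` is samples x genes; ``y`` holds 0/1.
    """
    v0 = values[y == 0]
    v1 = values[y == 1]
    if v0.shape[0] < 2 or v1.shape[0] < 2:
        raise ValueError("signal-to-noise needs >=2 samples in each class")
    m0, m1 = v0.mean(axis=0), v1.mean(axis=0)
    s0 = np.maximum(v0.std(axis=0, ddof=1), sd_floor_frac * np.abs(m0))
    s1 = np.maximum(v1.std(axis=0, ddof=1), sd_floor_frac * np.abs(m1))
    denom = s0 + s1
    out = np.zeros_like(m0)
    np.divide(m0 - m1, denom, out=out, where=denom > 0)
    return out


def rank_genes(values: np.ndarray, y: np.ndarray, gene_ids: list[str]) -> list[tuple[str, float]]:
    """Genes with signal-to-noise scores, sorted descending (stable on ties)."""
    scores = signal_to_noise(values, y)
    order = np.argsort(-scores, kind="stable")
    return [(gene_ids[i], float(scores[i])) for i in order]


def enrichment_score(ranked_genes: list[str], ranked_scores: np.ndarray,
                     gene_set: set[str] | list[str], weight_p: float = 1.0):
    """Weighted KS enrichment score and the full running sum.

    ``ranked_genes``/``ranked_scores`` must already be sorted by
    decreasing score.  Raises if the set shares no gene with the ranking.
    """
    member = np.array([g in set(gene_set) for g in ranked_genes])
    if not member.any():
        raise ValueError("gene set has no gene in the ranked list")
    running = _running_sum(np.asarray(ranked_scores, dtype=float), member, weight_p)
    idx = int(np.argmax(np.abs(running)))
    return float(running[idx]), running


def _running_sum(sorted_scores: np.ndarray, member: np.ndarray, weight_p: float) -> np.ndarray:
    n = len(sorted_scores)
    n_hits = int(member.sum())
    w = np.abs(sorted_scores) ** weight_p
    hit_w = np.where(member, w, 0.0)
    total = hit_w.sum()
    if total == 0:         # all member scores zero: fall back to equal steps
        hit_w = member.astype(float)
        total = float(n_hits)
    inc = hit_w / total
    if n_hits < n:
        inc = inc - np.where(member, 0.0, 1.0 / (n - n_hits))
    return np.cumsum(inc)


def _es_all_sets(sorted_scores: np.ndarray, member_sorted: np.ndarray,
                 weight_p: float) -> np.ndarray:
    """ES for every set (columns of ``member_sorted``) on one ordering."""
    n, n_sets = member_sorted.shape
    w = np.abs(sorted_scores) ** weight_p
    hit_w = member_sorted * w[:, None]
    totals = hit_w.sum(axis=0)
    n_hits = member_sorted.sum(axis=0)
    # degenerate all-zero-score sets: equal hit steps
    zero = totals == 0
    if zero.any():
        hit_w[:, zero] = member_sorted[:, zero]
        totals[zero] = n_hits[zero]
    inc = hit_w / totals[None, :]
    misses = n - n_hits
    miss_step = np.divide(1.0, misses, out=np.zeros_like(totals, dtype=float), where=misses > 0)
    inc = inc - (1.0 - member_sorted) * miss_step[None, :]
    cs = np.cumsum(inc, axis=0)
    idx = np.argmax(np.abs(cs), axis=0)
    return cs[idx, np.arange(n_sets)]


def permutation_stats(values: np.ndarray, y: np.ndarray, gene_ids: list[str],
                      sets: GeneSetCollection, n_perm: int = 1000, seed: int = 0,
                      weight_p: float = 1.0) -> list[EnrichmentResult]:
    """Phenotype-permutation ES/NES/p/FDR for every set in the collection.

    NES divides each ES by the mean |null ES| of matching sign for that
    set; the nominal p-value is the fraction of same-sign null ES at
    least as extreme (1.0 when ES = 0 or no same-sign null exists).
    FDR q is the GSEA tail ratio — the fraction of all same-sign null
    NES at least as extreme over the fraction of observed same-sign NES
    at least as extreme — clipped to [0, 1].  Sets with no measured gene
    are returned flagged not-computable.
    """
    if n_perm < 10:
        raise ValueError("n_perm must be >= 10")
    values = np.asarray(values, dtype=float)
    y = np.asarray(y).astype(int)
    rng = np.random.default_rng(seed)

    universe = set(gene_ids)
    pids = sets.pathway_ids
    member_masks = np.zeros((len(gene_ids), len(pids)), dtype=float)
    computable = []
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    for j, pid in enumerate(pids):
        matched = [g for g in sets[pid] if g in universe]
        for g in matched:
            member_masks[gene_pos[g], j] = 1.0
        computable.append(len(matched) > 0)
    computable = np.asarray(computable)
    usable = np.flatnonzero(computable)
    if usable.size == 0:
        raise ValueError("no gene set overlaps the measured genes")
    masks = member_masks[:, usable]

    def es_for_labels(labels: np.ndarray) -> np.ndarray:
        scores = signal_to_noise(values, labels)
        order = np.argsort(-scores, kind="stable")
        return _es_all_sets(scores[order], masks[order], weight_p)

    es_obs = es_for_labels(y)
    null_es = np.empty((n_perm, usable.size))
    for t in range(n_perm):
        perm = rng.permutation(y)
        # permuting labels preserves class counts; both classes stay populated
        null_es[t] = es_for_labels(perm)

    # sign-stratified normalization
    pos_mean = np.array([null_es[null_es[:, j] > 0, j].mean() if (null_es[:, j] > 0).any() else np.nan
                         for j in range(usable.size)])
    neg_mean = np.array([np.abs(null_es[null_es[:, j] < 0, j]).mean() if (null_es[:, j] < 0).any() else np.nan
                         for j in range(usable.size)])

    def normalize(es: np.ndarray) -> np.ndarray:
        nes = np.zeros_like(es)
        pos = es > 0
        neg = es < 0
        with np.errstate(invalid="ignore"):
            nes[pos] = es[pos] / pos_mean[pos]
            nes[neg] = es[neg] / neg_mean[neg]
        return np.nan_to_num(nes, nan=0.0)

    nes_obs = normalize(es_obs)
    null_nes = np.vstack([normalize(null_es[t]) for t in range(n_perm)])

    results: list[EnrichmentResult] = []
    pos_null_nes = null_nes[null_nes > 0]
    neg_null_nes = null_nes[null_nes < 0]
    pos_obs_nes = nes_obs[nes_obs > 0]
    neg_obs_nes = nes_obs[nes_obs < 0]

    stats_by_pid: dict[str, EnrichmentResult] = {}
    for jj, j in enumerate(usable):
        pid = pids[j]
        es = float(es_obs[jj])
        nes = float(nes_obs[jj])
        col = null_es[:, jj]
        if es > 0:
            same = col[col > 0]
            p = float(np.mean(same >= es)) if same.size else 1.0
            num = float(np.mean(pos_null_nes >= nes)) if pos_null_nes.size else 0.0
            den = float(np.mean(pos_obs_nes >= nes)) if pos_obs_nes.size else 1.0
        elif es < 0:
            same = col[col < 0]
            p = float(np.mean(same <= es)) if same.size else 1.0
            num = float(np.mean(neg_null_nes <= nes)) if neg_null_nes.size else 0.0
            den = float(np.mean(neg_obs_nes <= nes)) if neg_obs_nes.size else 1.0
        else:
            p, num, den = 1.0, 0.0, 1.0
        fdr = min(1.0, num / den) if den > 0 else 1.0
        direction = "class0-enriched" if es > 0 else "class1-enriched"
        stats_by_pid[pid] = EnrichmentResult(
            pathway_id=pid, es=es, nes=nes, p_value=p, fdr_q=fdr,
            direction=direction, n_genes_matched=int(masks[:, jj].sum()),
        )

    for j, pid in enumerate(pids):
        if computable[j]:
            results.append(stats_by_pid[pid])
        else:
            logger.warning("gene set %s shares no gene with the data; flagged", pid)
            results.append(EnrichmentResult(pathway_id=pid, es=float("nan"),
                                            nes=float("nan"), p_value=float("nan"),
                                            fdr_q=float("nan"), direction="class0-enriched",
                                            n_genes_matched=0, computable=False))
    return results
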