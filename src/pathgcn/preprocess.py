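"""Expression preprocessing: probe collapse, log2 cutoff, per-sample
standardization, and alignment to the pathway gene universe.

The fixed pipeline order is collapse -> log2-with-cutoff -> per-sample
standardize -> align-to-universe.  Alignment happens *after*
standardization, so genes injected as unmeasured stay exactly zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .gene_sets import GeneSetCollection

logger = logging.getLogger(__name__)


@dataclass
class ExpressionDataset:
    """Samples x genes expression matrix with binary class labels.

    ``values[i, j]`` is the expression of ``gene_ids[j]`` in
    ``sample_ids[i]``.  ``labels`` holds one of the two ``class_names``
    per sample; ``class_names[1]`` is conventionally the positive class.
    """

    sample_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray
    labels: np.ndarray
    class_names: tuple[str, str]
    zero_filled_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.values.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.gene_ids)} genes"
            )
        if self.labels.shape[0] != len(self.sample_ids):
            raise ValueError("one label per sample required")
        extra = set(np.unique(self.labels)) - set(self.class_names)
        if extra:
            raise ValueError(f"labels outside class_names: {sorted(extra)}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def y(self) -> np.ndarray:
        """Integer labels: 0 for ``class_names[0]``, 1 for ``class_names[1]``."""
        return (self.labels == self.class_names[1]).astype(int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)


def collapse_probes(
    probe_table: pd.DataFrame,
    probe_to_gene: dict[str, str],
    method: str = "mean",
) -> pd.DataFrame:
    """Collapse a probes x samples table to genes x samples.

    Probes mapping to the same gene symbol are combined by the
    arithmetic mean (or the max with ``method="max"``); probes without a
    mapping are dropped.
    """
    if method not in {"mean", "max"}:
        raise ValueError(f"unknown collapse method {method!r}")
    genes = probe_table.index.to_series().map(probe_to_gene)
    mapped = probe_table.loc[genes.notna().to_numpy()]
    if mapped.empty:
        raise ValueError("no probe in the table maps to a gene symbol")
    grouped = mapped.groupby(genes.dropna().to_numpy(), sort=False)
    return grouped.mean() if method == "mean" else grouped.max()


def log2_with_cutoff(values: np.ndarray, cutoff: float = 1.0) -> np.ndarray:
    """Return ``log2(max(v, cutoff))`` elementwise; non-negative for cutoff 1."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    return np.log2(np.maximum(np.asarray(values, dtype=float), cutoff))


def standardize_per_sample(values: np.ndarray) -> np.ndarray:
    """Standardize each sample (row) to mean 0, population variance 1.

    A constant row cannot be standardized and raises, naming the row.
    """
    v = np.asarray(values, dtype=float)
    mean = v.mean(axis=1, keepdims=True)
    sd = v.std(axis=1, keepdims=True)  # population (1/N) convention
    # relative threshold: a row constant up to rounding noise is constant
    tiny = 1e-12 * np.maximum(1.0, np.abs(mean))
    bad = np.flatnonzero((sd <= tiny).ravel())
    if bad.size:
        raise ValueError(f"sample row(s) {bad.tolist()} are constant and cannot be standardized")
    return (v - mean) / sd


def align_to_universe(ds: ExpressionDataset, sets: GeneSetCollection) -> ExpressionDataset:
    """Reindex to the pathway gene universe, zero-filling unmeasured genes.

    Output gene order is the union of all set genes in first-appearance
    order.  Genes absent from the measured data get exact zeros in every
    sample (applied after standardization, so the zeros survive); measured
    genes outside every set are dropped.  Counts are logged.
    """
    universe = sets.gene_universe()
    col = {g: j for j, g in enumerate(ds.gene_ids)}
    out = np.zeros((ds.n_samples, len(universe)))
    injected: list[str] = []
    for j, g in enumerate(universe):
        if g in col:
            out[:, j] = ds.values[:, col[g]]
        else:
            injected.append(g)
    n_dropped = len(set(ds.gene_ids) - set(universe))
    logger.info(
        "align_to_universe: %d genes zero-filled, %d measured genes dropped",
        len(injected), n_dropped,
    )
    return ExpressionDataset(
        sample_ids=list(ds.sample_ids),
        gene_ids=universe,
        values=out,
        labels=ds.labels.copy(),
        class_names=ds.class_names,
        zero_filled_genes=injected,
    )


def preprocess_pipeline(
    ds: ExpressionDataset,
    sets: GeneSetCollection,
    log_transform: bool = True,
    cutoff: float = 1.0,
) -> ExpressionDataset:
    """Run log2-cutoff (optional, for linear-scale intensities) ->
    per-sample standardization -> universe alignment."""
    v = log2_with_cutoff(ds.values, cutoff) if log_transform else ds.values
    v = standardize_per_sample(v)
    standardized = ExpressionDataset(
        sample_ids=list(ds.sample_ids), gene_ids=list(ds.gene_ids),
        values=v, labels=ds.labels.copy(), class_names=ds.class_names,
    )
    return align_to_universe(standardized, sets)


# ---------------------------------------------------------------------------
# TSV interfaces


def read_expression(path: str | Path, samples_as_rows: bool = False) -> pd.DataFrame:
    """Read an expression TSV (first column gene_id, remaining columns
    samples) into a genes x samples frame.  ``samples_as_rows`` transposes."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.T if samples_as_rows else df


def write_expression(df: pd.DataFrame, path: str | Path, index_name: str = "gene_id") -> None:
    df = df.copy()
    df.index.name = index_name
    df.to_csv(path, sep="\t")


def read_labels(
    path: str | Path,
    class_names: tuple[str, str],
) -> pd.Series:
    """Read a two-column TSV (sample_id, label); samples with labels
    outside the two configured classes (e.g. 'unclassifiable') are
    excluded with a logged count."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample_id", "label"], dtype=str)
    if df.iloc[0, 0] in {"sample_id", "sample"}:
        df = df.iloc[1:]
    keep = df["label"].isin(class_names)
    n_excluded = int((~keep).sum())
    if n_excluded:
        logger.info("read_labels: excluded %d samples with out-of-class labels", n_excluded)
    df = df[keep]
    return pd.Series(df["label"].to_numpy(), index=df["sample_id"].to_numpy())


def dataset_from_files(
    expr_path: str | Path,
    labels_path: str | Path,
    class_names: tuple[str, str],
    samples_as_rows: bool = False,
) -> ExpressionDataset:
    """Assemble an :class:`ExpressionDataset` from expression + label TSVs,
    keeping only labelled samples present in both files."""
    expr = read_expression(expr_path, samples_as_rows=samples_as_rows)
    labels = read_labels(labels_path, class_names)
    common = [s for s in expr.columns if s in labels.index]
    if not common:
        raise ValueError("no overlap between expression samples and labelled samples")
    expr = expr[common]
    return ExpressionDataset(
        sample_ids=common,
        gene_ids=list(expr.index),
        values=expr.to_numpy().T,
        labels=labels.loc[common].to_numpy(),
        class_names=class_names,
    )
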