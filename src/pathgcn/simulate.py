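"""Synthetic gene sets, pathway edge lists, and two-class expression data
with planted pathway-level signal.

The generator emulates the structure of a two-subtype expression study:
a few hundred to a few thousand genes organized into overlapping
pathways with sparse within-pathway edges (Erdős–Rényi at a target
density), and a small number of informative pathways carrying class
signal of two kinds:

``mean_shift``
    Member genes differ in mean between classes — detectable by any
    per-gene statistic, including the GSEA ranking metric.

``correlation_flip``
    Member genes share a latent factor whose loading signs depend on
    the class (all positive in class 0, alternating in class 1).  The
    per-gene marginals are identical across classes by construction, so
    per-gene statistics are blind to it, while the class-dependent
    gene–gene correlation remains learnable by a model that aggregates
    over pathway neighbors.

Values are drawn on a log2-intensity-like scale (baseline mean 7) so
the standard preprocessing (per-sample standardization, universe
alignment) applies unchanged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .gene_sets import GeneSetCollection, write_gmt
from .graphs import write_edge_list
from .preprocess import ExpressionDataset, write_expression


@dataclass
class FixtureSpec:
    """Parameters of the synthetic study.

    Defaults give 40 pathways of 25–35 genes (10% shared with the next
    pathway), edge density 0.15, 100 samples per class in independent
    train and test sets, and 4 informative pathways: 2 with a per-gene
    mean shift of 1 noise-SD and 2 with a correlation flip of |r| = 0.8.
    """

    n_pathways: int = 40
    genes_per_pathway: tuple[int, int] = (25, 35)
    overlap_fraction: float = 0.1
    edge_density: float = 0.15
    n_samples_per_class: int = 100
    n_informative_pathways: int = 4
    mean_shift: float = 1.0
    correlation_flip_r: float = 0.8
    noise_sd: float = 1.0
    baseline_mean: float = 7.0
    class_names: tuple[str, str] = ("GCB", "ABC")
    seed: int = 0
    informative_effects: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_informative_pathways > self.n_pathways:
            raise ValueError("more informative pathways than pathways")
        if self.n_informative_pathways and \
                3 * (self.n_informative_pathways - 1) >= self.n_pathways:
            raise ValueError(
                "informative pathways are spaced every 3rd set; "
                f"{self.n_informative_pathways} informative need at least "
                f"{3 * (self.n_informative_pathways - 1) + 1} pathways"
            )
        if not 0 < self.edge_density <= 1:
            raise ValueError("edge_density must be in (0, 1]")
        if not 0 <= self.overlap_fraction < 1:
            raise ValueError("overlap_fraction must be in [0, 1)")
        if not self.informative_effects:
            # alternate the two effect kinds over the informative pathways
            self.informative_effects = [
                "mean_shift" if i % 2 == 0 else "correlation_flip"
                for i in range(self.n_informative_pathways)
            ]
        if len(self.informative_effects) != self.n_informative_pathways:
            raise ValueError("one effect kind per informative pathway required")

    def informative_pathway_ids(self) -> list[str]:
        """Informative pathways are spread out (every 3rd id from the
        start) so that no two informative pathways share overlap genes."""
        return [f"PW{3 * i:03d}" for i in range(self.n_informative_pathways)]


def make_pathways(spec: FixtureSpec) -> tuple[GeneSetCollection, dict[str, list[tuple[str, str]]]]:
    """Generate overlapping gene sets and Erdős–Rényi within-pathway edges."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.genes_per_pathway
    sets: dict[str, list[str]] = {}
    next_gene = 0
    prev: list[str] = []
    for k in range(spec.n_pathways):
        size = int(rng.integers(lo, hi + 1))
        n_shared = min(int(round(spec.overlap_fraction * size)), len(prev))
        if n_shared > size:
            raise ValueError("overlap larger than pathway size is infeasible")
        # share the previous pathway's newest genes so overlap stays
        # strictly between neighbors instead of chaining through all sets
        genes = list(prev[len(prev) - n_shared:])
        for _ in range(size - n_shared):
            genes.append(f"G{next_gene:05d}")
            next_gene += 1
        sets[f"PW{k:03d}"] = genes
        prev = genes
    collection = GeneSetCollection(sets=sets, source_name="synthetic")

    edges: dict[str, list[tuple[str, str]]] = {}
    for pid, genes in sets.items():
        pairs = []
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                if rng.random() < spec.edge_density:
                    a, b = genes[i], genes[j]
                    pairs.append((a, b) if a <= b else (b, a))
        edges[pid] = sorted(pairs)
    return collection, edges


def _draw_expression(spec: FixtureSpec, sets: GeneSetCollection,
                     rng: np.random.Generator, tag: str) -> ExpressionDataset:
    universe = sets.gene_universe()
    gene_pos = {g: i for i, g in enumerate(universe)}
    n_per = spec.n_samples_per_class
    n = 2 * n_per
    y = np.array([0] * n_per + [1] * n_per)
    values = spec.baseline_mean + spec.noise_sd * rng.standard_normal((n, len(universe)))

    informative = spec.informative_pathway_ids()
    lam = np.sqrt(abs(spec.correlation_flip_r))
    for pid, effect in zip(informative, spec.informative_effects):
        cols = np.array([gene_pos[g] for g in sets[pid]])
        if effect == "mean_shift":
            # symmetric between-class shift of `mean_shift` noise-SDs per gene
            delta = spec.mean_shift * spec.noise_sd
            values[np.ix_(y == 0, cols)] += delta / 2.0
            values[np.ix_(y == 1, cols)] -= delta / 2.0
        elif effect == "correlation_flip":
            # shared latent factor; loading signs depend on the class so the
            # per-gene marginal N(baseline, noise_sd^2) is identical in both
            factor = rng.standard_normal(n)
            signs0 = np.ones(len(cols))
            signs1 = np.where(np.arange(len(cols)) % 2 == 0, 1.0, -1.0)
            resid = np.sqrt(1.0 - lam ** 2)
            fresh = rng.standard_normal((n, len(cols)))
            for s in range(n):
                signs = signs0 if y[s] == 0 else signs1
                values[s, cols] = spec.baseline_mean + spec.noise_sd * (
                    lam * signs * factor[s] + resid * fresh[s]
                )
        else:
            raise ValueError(f"unknown effect {effect!r}")

    labels = np.asarray([spec.class_names[c] for c in y])
    sample_ids = [f"{tag}{i:04d}" for i in range(n)]
    return ExpressionDataset(sample_ids=sample_ids, gene_ids=universe,
                             values=values, labels=labels, class_names=spec.class_names)


def make_expression(spec: FixtureSpec, sets: GeneSetCollection
                    ) -> tuple[ExpressionDataset, ExpressionDataset]:
    """Independent train and test datasets with the planted signals."""
    rng = np.random.default_rng(spec.seed + 1)
    train = _draw_expression(spec, sets, rng, tag="TR")
    test = _draw_expression(spec, sets, rng, tag="TE")
    return train, test


def end_to_end_fixture(spec: FixtureSpec, out_dir: str | Path) -> dict:
    """Write GMT, edge list, train/test expression and labels, plus a
    manifest recording the planted truth.  Returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sets, edges = make_pathways(spec)
    train, test = make_expression(spec, sets)

    write_gmt(sets, out / "pathways.gmt")
    write_edge_list(edges, out / "edges.tsv")
    for name, ds in [("train", train), ("test", test)]:
        write_expression(ds.to_frame().T, out / f"expression_{name}.tsv")
        with (out / f"labels_{name}.tsv").open("w") as fh:
            for sid, lab in zip(ds.sample_ids, ds.labels):
                fh.write(f"{sid}\t{lab}\n")

    manifest = {
        "informative_pathways": spec.informative_pathway_ids(),
        "effects": dict(zip(spec.informative_pathway_ids(), spec.informative_effects)),
        "n_pathways": spec.n_pathways,
        "n_genes": len(sets.gene_universe()),
        "n_samples_per_class": spec.n_samples_per_class,
        "class_names": list(spec.class_names),
        "seed": spec.seed,
    }
    with (out / "manifest.json").open("w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def paper_scale_spec(seed: int = 0) -> FixtureSpec:
    """Preset at the real study's pathway count (186 pathways)."""
    return FixtureSpec(n_pathways=186, genes_per_pathway=(40, 100),
                       n_samples_per_class=200, n_informative_pathways=8, seed=seed)
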