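"""Shared fixtures: tiny hand-built pathway collections and the default
synthetic study (generated once per session and reused by the slower
end-to-end tests)."""

from __future__ import annotations

import numpy as np
import pytest

from pathgcn import (
    FixtureSpec,
    GeneSetCollection,
    PathwayGCNClassifier,
    build_graphs,
    make_expression,
    make_pathways,
    pathway_importance,
    permutation_stats,
)
from pathgcn.preprocess import preprocess_pipeline


@pytest.fixture
def tiny_sets() -> GeneSetCollection:
    return GeneSetCollection({
        "P1": ["A", "B", "C"],
        "P2": ["B", "D"],
        "P3": ["E"],
    })


@pytest.fixture
def tiny_graphs(tiny_sets):
    edges = {"P1": [("A", "B"), ("B", "C")], "P2": [("B", "D")], "P3": []}
    return build_graphs(tiny_sets, edges)


class StudyBundle:
    """Default synthetic study: fixture spec, preprocessed data, graphs,
    a trained GCN, its pathway importance and the GSEA comparator."""

    def __init__(self):
        self.spec = FixtureSpec(seed=0)
        self.sets, self.edges = make_pathways(self.spec)
        train_raw, test_raw = make_expression(self.spec, self.sets)
        self.train = preprocess_pipeline(train_raw, self.sets, log_transform=False)
        self.test = preprocess_pipeline(test_raw, self.sets, log_transform=False)
        self.graphs = build_graphs(self.sets, self.edges)
        self.model = PathwayGCNClassifier(
            graphs=self.graphs, gene_ids=self.train.gene_ids, seed=0
        ).fit(self.train.values, self.train.labels)
        self.importance = pathway_importance(self.model, self.train.values, self.graphs)
        self.gsea = permutation_stats(
            self.train.values, self.train.y, self.train.gene_ids, self.sets,
            n_perm=1000, seed=7,
        )
        self.planted = set(self.spec.informative_pathway_ids())
        self.flip_pathways = {
            pid for pid, eff in zip(self.spec.informative_pathway_ids(),
                                    self.spec.informative_effects)
            if eff == "correlation_flip"
        }


@pytest.fixture(scope="session")
def study() -> StudyBundle:
    return StudyBundle()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
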