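import numpy as np
import pytest

import pathgcn.nn as nn
from pathgcn import (
    EarlyStopping,
    ExpressionMLPClassifier,
    FixtureSpec,
    GCNMLPClassifier,
    PathwayGCNClassifier,
    build_graph,
    build_graphs,
    build_model,
    graph_conv_layer,
    make_expression,
    make_pathways,
)
from pathgcn.preprocess import preprocess_pipeline


class TestGraphConvLayer:
    def test_isolated_node_is_relu_of_weighted_input(self):
        g = build_graph("P", ["A"], [])
        assert graph_conv_layer(g, [[-2.0]], [[1.0]])[0, 0] == 0.0
        assert graph_conv_layer(g, [[3.0]], [[1.0]])[0, 0] == 3.0

    def test_two_node_edge_averages_without_activation(self):
        g = build_graph("P", ["A", "B"], [("A", "B")])
        out = graph_conv_layer(g, [[1.0], [3.0]], [[1.0]], activation=False)
        np.testing.assert_allclose(out, [[2.0], [2.0]])

    def test_zero_weights_annihilate(self, rng):
        g = build_graph("P", ["A", "B", "C"], [("A", "B")])
        out = graph_conv_layer(g, rng.standard_normal((3, 2)), np.zeros((2, 4)))
        np.testing.assert_array_equal(out, np.zeros((3, 4)))

    def test_dimension_mismatch_raises(self):
        g = build_graph("P", ["A", "B"], [])
        with pytest.raises(ValueError, match="channel mismatch"):
            graph_conv_layer(g, np.ones((2, 3)), np.ones((2, 2)))


def small_problem(seed=0, n_pathways=6, n_per_class=20):
    spec = FixtureSpec(n_pathways=n_pathways, genes_per_pathway=(5, 8),
                       n_samples_per_class=n_per_class,
                       n_informative_pathways=2,
                       informative_effects=["mean_shift", "mean_shift"], seed=seed)
    sets, edges = make_pathways(spec)
    train, _ = make_expression(spec, sets)
    ds = preprocess_pipeline(train, sets, log_transform=False)
    graphs = build_graphs(sets, edges)
    return ds, graphs


class TestForward:
    def test_pooled_width_is_pathways_times_channels(self):
        ds, graphs = small_problem()
        m = PathwayGCNClassifier(graphs=graphs, gene_ids=ds.gene_ids,
                                 pool_channels=10, max_epochs=1, seed=0)
        m.fit(ds.values, ds.labels)
        pooled = m.pooled_transform(ds.values[:3])
        assert pooled.shape == (3, len(graphs) * 10)

    def test_all_zero_input_gives_bias_softmax(self):
        """With zero input, identity batch-norm statistics and zero beta,
        the pooled vector is zero and the probabilities are the softmax
        of the head bias."""
        ds, graphs = small_problem()
        m = PathwayGCNClassifier(graphs=graphs, gene_ids=ds.gene_ids,
                                 max_epochs=1, seed=0)
        m.fit(ds.values, ds.labels)
        trunk = m.network_.trunk
        trunk.bn1.running_mean[:] = 0.0
        trunk.bn1.running_var[:] = 1.0 - trunk.bn1.eps
        trunk.bn1.params["beta"][:] = 0.0
        head = m.network_.head.layers[0]
        head.params["b"][:] = [0.3, -0.2]
        x = np.zeros((1, len(ds.gene_ids)))
        logits, pooled = m._forward_eval(x, return_pooled=True)
        np.testing.assert_allclose(pooled, 0.0, atol=1e-12)
        np.testing.assert_allclose(nn.softmax(logits)[0],
                                   nn.softmax(np.array([[0.3, -0.2]]))[0], atol=1e-12)

    def test_probabilities_sum_to_one(self, rng):
        ds, graphs = small_problem()
        m = PathwayGCNClassifier(graphs=graphs, gene_ids=ds.gene_ids,
                                 max_epochs=2, seed=0).fit(ds.values, ds.labels)
        proba = m.predict_proba(rng.standard_normal((7, len(ds.gene_ids))))
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(proba >= 0)

    def test_permutation_equivariance_within_graph(self, rng):
        """Permuting a graph's node order (with consistent adjacency rows
        and columns) leaves the pooled output unchanged."""
        ds, graphs = small_problem()
        m = PathwayGCNClassifier(graphs=graphs, gene_ids=ds.gene_ids,
                                 max_epochs=2, dropout_rate=0.0, seed=0)
        m.fit(ds.values, ds.labels)
        x = ds.values[:4]
        pooled_before = m.pooled_transform(x)

        g0 = graphs[0]
        perm = rng.permutation(g0.n_nodes)
        permuted = build_graph(
            g0.pathway_id,
            [g0.nodes[i] for i in perm],
            [(g0.nodes[i], g0.nodes[j]) for i in range(g0.n_nodes)
             for j in range(i + 1, g0.n_nodes) if g0.adjacency[i, j]],
        )
        m2 = PathwayGCNClassifier(graphs=[permuted] + graphs[1:], gene_ids=ds.gene_ids,
                                  max_epochs=2, dropout_rate=0.0, seed=0)
        m2.fit(ds.values, ds.labels)
        # transplant the trained weights so only the node order differs
        m2.network_.set_state(m.network_.get_state())
        np.testing.assert_allclose(m2.pooled_transform(x), pooled_before, atol=1e-10)


class TestLoss:
    def test_perfect_prediction_zero_loss(self):
        logits = np.array([[100.0, -100.0]])
        loss, _ = nn.weighted_cross_entropy(logits, np.array([0]), np.ones(1))
        assert loss == pytest.approx(0.0, abs=1e-9)

    def test_even_split_is_ln2(self):
        loss, _ = nn.weighted_cross_entropy(np.zeros((1, 2)), np.array([1]), np.ones(1))
        assert loss == pytest.approx(np.log(2))

    def test_balanced_classes_equal_weights(self):
        from pathgcn.models import class_weights_from_labels
        w = class_weights_from_labels(np.array([0, 0, 1, 1]))
        np.testing.assert_allclose(w, 1.0)
        w = class_weights_from_labels(np.array([0, 0, 0, 1]))
        assert w[3] == pytest.approx(3 * w[0])
        assert w.mean() == pytest.approx(1.0)

    def test_l2_penalty_counts_weights_only(self):
        ds, graphs = small_problem()
        m = PathwayGCNClassifier(graphs=graphs, gene_ids=ds.gene_ids,
                                 max_epochs=1, seed=0).fit(ds.values, ds.labels)
        net = m.network_
        expected = sum(
            float(np.sum(layer.params[name] ** 2))
            for layer, name in net.iter_params() if name == "W"
        )
        assert net.l2_penalty(0.5) == pytest.approx(0.5 * expected)


class TestEarlyStopping:
    def test_stops_after_patience_without_new_minimum(self):
        stopper = EarlyStopping(patience=5)
        losses = [1.0, 0.9, 0.91, 0.92, 0.93, 0.94, 0.95]
        stops = [stopper.update(v) for v in losses]
        assert stops == [False, False, False, False, False, False, True]
        assert stopper.best_epoch == 2

    def test_strictly_decreasing_never_stops(self):
        stopper = EarlyStopping(patience=5)
        assert not any(stopper.update(1.0 / (t + 1)) for t in range(50))

    def test_matches_brute_force_on_random_sequences(self, rng):
        """Oracle: scan the sequence directly for the first epoch with
        `patience` consecutive non-improvements of the running minimum."""
        for _ in range(50):
            losses = rng.random(30).tolist()
            patience = int(rng.integers(1, 6))
            stopper = EarlyStopping(patience)
            stop_epoch = None
            for i, v in enumerate(losses, start=1):
                if stopper.update(v):
                    stop_epoch = i
                    break
            best = np.inf
            bad = 0
            expected_stop = None
            for i, v in enumerate(losses, start=1):
                if v < best:
                    best, bad = v, 0
                else:
                    bad += 1
                if bad >= patience:
                    expected_stop = i
                    break
            assert stop_epoch == expected_stop
            if losses:
                assert stopper.best_loss == min(losses[: stop_epoch or len(losses)])


class TestTraining:
    def test_same_seed_reproduces_weights(self):
        ds, graphs = small_problem()
        kw = dict(graphs=graphs, gene_ids=ds.gene_ids, max_epochs=5, seed=42)
        m1 = PathwayGCNClassifier(**kw).fit(ds.values, ds.labels)
        m2 = PathwayGCNClassifier(**kw).fit(ds.values, ds.labels)
        for a, b in zip(m1.network_.get_state(), m2.network_.get_state()):
            np.testing.assert_array_equal(a, b)
        assert m1.cutoff_ == m2.cutoff_

    def test_divergence_raises(self, monkeypatch):
        ds, graphs = small_problem()
        m = PathwayGCNClassifier(graphs=graphs, gene_ids=ds.gene_ids,
                                 max_epochs=3, seed=0)
        real = nn.weighted_cross_entropy

        def poisoned(logits, y, w):
            loss, d = real(logits, y, w)
            return float("nan"), d

        monkeypatch.setattr(nn, "weighted_cross_entropy", poisoned)
        with pytest.raises(RuntimeError, match="diverged"):
            m.fit(ds.values, ds.labels)

    def test_planted_signal_reaches_high_training_accuracy(self):
        ds, graphs = small_problem(n_per_class=30)
        m = PathwayGCNClassifier(graphs=graphs, gene_ids=ds.gene_ids,
                                 max_epochs=50, seed=0).fit(ds.values, ds.labels)
        acc = float(np.mean(m.predict(ds.values) == ds.labels))
        assert acc > 0.95

    def test_single_class_raises(self):
        ds, graphs = small_problem()
        m = PathwayGCNClassifier(graphs=graphs, gene_ids=ds.gene_ids, max_epochs=1)
        with pytest.raises(ValueError):
            m.fit(ds.values, np.array(["a"] * ds.n_samples))


class TestParameterCounts:
    def test_gcn_grows_only_through_head(self):
        """Conv weights are shared across graphs: adding pathways adds
        exactly pool_channels * 2 head parameters per pathway."""
        h, p = 4, 10
        counts = {}
        for n_pathways in (5, 9):
            ds, graphs = small_problem(n_pathways=n_pathways)
            m = PathwayGCNClassifier(graphs=graphs, gene_ids=ds.gene_ids,
                                     hidden_channels=h, pool_channels=p,
                                     max_epochs=1, seed=0).fit(ds.values, ds.labels)
            counts[n_pathways] = m.n_parameters_
            K = len(graphs)
            # 1*h conv1 + h*p conv2 + 2h batch-norm + head (K*p*2 + 2)
            assert m.n_parameters_ == h + h * p + 2 * h + K * p * 2 + 2
        assert counts[9] - counts[5] == 4 * p * 2

    def test_mlp_parameter_count_formula(self):
        ds, _ = small_problem()
        G = len(ds.gene_ids)
        a, b = 16, 8
        m = ExpressionMLPClassifier(mlp_hidden=(a, b), max_epochs=1, seed=0)
        m.fit(ds.values, ds.labels)
        linear = G * a + a + a * b + b + b * 2 + 2
        batchnorm = 2 * a + 2 * b
        assert m.n_parameters_ == linear + batchnorm


class TestBaselines:
    def test_gcn_mlp_shares_conv_trunk(self):
        """With identical trunk weights, GCN and GCN-MLP produce identical
        pooled activations."""
        ds, graphs = small_problem()
        kw = dict(graphs=graphs, gene_ids=ds.gene_ids, max_epochs=2, seed=0)
        gcn = PathwayGCNClassifier(**kw).fit(ds.values, ds.labels)
        hybrid = GCNMLPClassifier(**kw, mlp_hidden=(8, 4)).fit(ds.values, ds.labels)
        src, dst = gcn.network_.trunk, hybrid.network_.trunk
        for layer_s, layer_d in [(src.lin1, dst.lin1), (src.lin2, dst.lin2),
                                 (src.bn1, dst.bn1)]:
            for name in layer_s.params:
                layer_d.params[name] = layer_s.params[name].copy()
        dst.bn1.running_mean = src.bn1.running_mean.copy()
        dst.bn1.running_var = src.bn1.running_var.copy()
        x = ds.values[:5]
        np.testing.assert_allclose(hybrid.pooled_transform(x),
                                   gcn.pooled_transform(x), atol=1e-12)

    def test_build_model_dispatch(self):
        ds, graphs = small_problem()
        kw = dict(graphs=graphs, gene_ids=ds.gene_ids)
        assert isinstance(build_model("gcn", **kw), PathwayGCNClassifier)
        assert isinstance(build_model("gcn-mlp", **kw), GCNMLPClassifier)
        assert isinstance(build_model("mlp", **kw), ExpressionMLPClassifier)
        assert not isinstance(build_model("gcn", **kw), GCNMLPClassifier)
        with pytest.raises(ValueError):
            build_model("transformer")


def test_block_diagonal_forward_matches_per_graph_loop(rng):
    """Contract: the stacked block-diagonal propagation equals looping
    over the graphs one at a time with the shared weights."""
    ds, graphs = small_problem()
    m = PathwayGCNClassifier(graphs=graphs, gene_ids=ds.gene_ids,
                             dropout_rate=0.0, max_epochs=2, seed=0)
    m.fit(ds.values, ds.labels)
    trunk = m.network_.trunk
    x = ds.values[:3]
    pooled = m.pooled_transform(x)

    W0 = trunk.lin1.params["W"]
    W1 = trunk.lin2.params["W"]
    gamma, beta = trunk.bn1.params["gamma"], trunk.bn1.params["beta"]
    mu, var = trunk.bn1.running_mean, trunk.bn1.running_var
    col = {g: j for j, g in enumerate(ds.gene_ids)}
    for s in range(x.shape[0]):
        offset = 0
        for k, g in enumerate(graphs):
            h0 = np.array([[x[s, col[gene]]] for gene in g.nodes])
            a1 = graph_conv_layer(g, h0, W0, activation=True)
            a1 = gamma * (a1 - mu) / np.sqrt(var + trunk.bn1.eps) + beta
            a2 = graph_conv_layer(g, a1, W1, activation=True)
            np.testing.assert_allclose(
                pooled[s, k * trunk.pool_channels:(k + 1) * trunk.pool_channels],
                a2.mean(axis=0), atol=1e-10,
            )
            offset += g.n_nodes
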