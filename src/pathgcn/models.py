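"""Expression-to-phenotype classifiers built on per-pathway graph convolution.

Three scikit-learn style estimators share one training engine:

``PathwayGCNClassifier``
    Two shared-weight graph-convolution layers over all pathway graphs,
    per-graph average pooling (``pool_channels`` values per pathway),
    and a single linear layer to two-class softmax.  Because the conv
    weights are shared across graphs, the trainable parameter count
    grows with the number of pathways K only through the head.

``GCNMLPClassifier``
    The same convolution trunk, but three fully connected layers between
    the pooling layer and the softmax.

``ExpressionMLPClassifier``
    Three fully connected layers straight from the aligned gene vector.

Training uses Adam on class-weighted cross-entropy with L2 on the
weight matrices, early stopping with best-state restoration, and a
Youden-index probability cutoff selected on the training scores.
All randomness (init, shuffling, dropout) flows from ``seed``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from . import nn
from .graphs import PathwayGraph
from .selection import select_cutoff


def class_weights_from_labels(y: np.ndarray) -> np.ndarray:
    """Per-sample weights, inverse class frequency normalized to mean 1."""
    classes, counts = np.unique(y, return_counts=True)
    inv = {c: 1.0 / n for c, n in zip(classes, counts)}
    w = np.asarray([inv[v] for v in y])
    return w / w.mean()


class _NNClassifierBase(BaseEstimator, ClassifierMixin):
    """Shared fit/predict machinery; subclasses define the architecture."""

    def _build_network(self, n_genes: int, rng: np.random.Generator) -> nn.Network:
        raise NotImplementedError

    # -- helpers -----------------------------------------------------------

    def _encode(self, y: np.ndarray) -> np.ndarray:
        return (np.asarray(y) == self.positive_class_).astype(int)

    def fit(self, X, y, validation_data=None):
        """Train the network.

        Parameters
        ----------
        X : array (n_samples, n_genes)
            Standardized expression aligned to the pathway gene universe.
        y : array (n_samples,)
            Two-class labels.
        validation_data : (X_val, y_val), optional
            When given, early stopping monitors the validation
            cross-entropy instead of the training loss.
        """
        X, y = check_X_y(X, y, dtype=float)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError(f"exactly two classes required, got {list(self.classes_)}")
        if self.positive_class is not None:
            if self.positive_class not in self.classes_:
                raise ValueError(f"positive_class {self.positive_class!r} not among {list(self.classes_)}")
            self.positive_class_ = self.positive_class
        else:
            self.positive_class_ = self.classes_[1]
        y_int = self._encode(y)
        if min(np.bincount(y_int, minlength=2)) < 2:
            raise ValueError("need at least 2 samples per class")

        rng = np.random.default_rng(self.seed)
        net = self._build_network(X.shape[1], rng)
        self.network_ = net
        self.n_parameters_ = net.n_parameters()

        sample_w = class_weights_from_labels(y_int)
        w_by_class = np.array([sample_w[y_int == 0][0], sample_w[y_int == 1][0]])

        if validation_data is not None:
            X_val = check_array(np.asarray(validation_data[0]), dtype=float)
            y_val = self._encode(np.asarray(validation_data[1]))
            w_val = w_by_class[y_val]
        else:
            X_val = y_val = w_val = None

        opt = nn.Adam(net, lr=self.learning_rate)
        n = X.shape[0]
        batch = min(self.batch_size, n)
        stopper = nn.EarlyStopping(self.patience)
        best_state = net.get_state()
        self.training_log_ = []

        for epoch in range(1, self.max_epochs + 1):
            order = rng.permutation(n)
            for start in range(0, n, batch):
                idx = order[start:start + batch]
                logits = net.forward(X[idx], training=True, rng=rng)
                loss, dlogits = nn.weighted_cross_entropy(logits, y_int[idx], sample_w[idx])
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"training diverged (non-finite loss) at epoch {epoch}; "
                        f"lr={self.learning_rate}, l2={self.l2_lambda}"
                    )
                net.backward(dlogits)
                net.add_l2_grads(self.l2_lambda)
                opt.step()

            # epoch-end monitoring in evaluation mode
            train_logits = net.forward(X, training=False, rng=rng)
            train_loss, _ = nn.weighted_cross_entropy(train_logits, y_int, sample_w)
            train_loss += net.l2_penalty(self.l2_lambda)
            if X_val is not None:
                val_logits = net.forward(X_val, training=False, rng=rng)
                monitored, _ = nn.weighted_cross_entropy(val_logits, y_val, w_val)
            else:
                monitored = train_loss
            self.training_log_.append({"epoch": epoch, "train_loss": train_loss,
                                       "monitored_loss": monitored})
            stop = stopper.update(monitored)
            if stopper.improved:
                best_state = net.get_state()
            if stop:
                break

        net.set_state(best_state)
        self.best_epoch_ = stopper.best_epoch
        self.n_epochs_ = len(self.training_log_)

        scores = self._positive_proba(X)
        self.cutoff_ = select_cutoff(scores, y_int)
        if not 0.0 < self.cutoff_ < 1.0:
            self.cutoff_ = 0.5
        return self

    def _forward_eval(self, X, return_pooled=False):
        rng = np.random.default_rng(0)  # unused in eval mode
        return self.network_.forward(np.asarray(X, dtype=float), training=False,
                                     rng=rng, return_pooled=return_pooled)

    def _positive_proba(self, X) -> np.ndarray:
        logits = self._forward_eval(X)
        return nn.softmax(logits)[:, 1]

    def predict_proba(self, X):
        """Class probabilities, columns in ``classes_`` order."""
        check_is_fitted(self, "network_")
        X = check_array(X, dtype=float)
        p_pos = self._positive_proba(X)
        proba = np.column_stack([1.0 - p_pos, p_pos])
        if self.positive_class_ != self.classes_[1]:
            proba = proba[:, ::-1]
        return proba

    def decision_function(self, X):
        """Pre-softmax logit margin toward the positive class."""
        check_is_fitted(self, "network_")
        X = check_array(X, dtype=float)
        logits = self._forward_eval(X)
        return logits[:, 1] - logits[:, 0]

    def predict(self, X):
        """Thresholded prediction using the fitted Youden cutoff."""
        check_is_fitted(self, "network_")
        X = check_array(X, dtype=float)
        p_pos = self._positive_proba(X)
        neg = self.classes_[self.classes_ != self.positive_class_][0]
        return np.where(p_pos >= self.cutoff_, self.positive_class_, neg)


class PathwayGCNClassifier(_NNClassifierBase):
    """Graph-convolutional classifier with a linear softmax head.

    Parameters
    ----------
    graphs : list of PathwayGraph
        One graph per pathway; defines the convolution operators.
    gene_ids : list of str
        Aligned gene universe; column order of the input matrix.
    hidden_channels : int
        Output width of the first convolution.
    pool_channels : int
        Output width of the second convolution = values per pathway
        after average pooling (default 10).
    """

    def __init__(self, graphs=None, gene_ids=None, hidden_channels=8,
                 pool_channels=10, dropout_rate=0.1, l2_lambda=1e-4,
                 learning_rate=0.01, batch_size=32, max_epochs=200,
                 patience=5, seed=0, positive_class=None):
        self.graphs = graphs
        self.gene_ids = gene_ids
        self.hidden_channels = hidden_channels
        self.pool_channels = pool_channels
        self.dropout_rate = dropout_rate
        self.l2_lambda = l2_lambda
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.seed = seed
        self.positive_class = positive_class

    def _build_trunk(self, n_genes: int, rng: np.random.Generator) -> nn.GraphConvTrunk:
        if not self.graphs:
            raise ValueError("graphs must be provided")
        if self.gene_ids is None or len(self.gene_ids) != n_genes:
            raise ValueError("gene_ids must match the input matrix columns")
        return nn.GraphConvTrunk(self.graphs, list(self.gene_ids), self.hidden_channels,
                                 self.pool_channels, self.dropout_rate, rng)

    def _build_network(self, n_genes, rng):
        trunk = self._build_trunk(n_genes, rng)
        head = nn.Sequential([nn.Linear(trunk.n_pooled, 2, rng)])
        return nn.Network(trunk, head)

    def pooled_transform(self, X):
        """Pooling-layer activations (n_samples, K * pool_channels) in
        evaluation mode — the features the pathway-level Shapley values
        explain."""
        check_is_fitted(self, "network_")
        X = check_array(X, dtype=float)
        _, pooled = self._forward_eval(X, return_pooled=True)
        return pooled

    @property
    def head_is_linear(self) -> bool:
        return True


def _mlp_stack(sizes: list[int], dropout_rate: float, rng: np.random.Generator) -> nn.Sequential:
    """Hidden linear blocks (linear -> ReLU -> batch-norm -> dropout),
    then a bare linear output layer."""
    layers: list[nn.Layer] = []
    for n_in, n_out in zip(sizes[:-2], sizes[1:-1]):
        layers += [nn.Linear(n_in, n_out, rng), nn.ReLU(),
                   nn.BatchNorm(n_out), nn.Dropout(dropout_rate)]
    layers.append(nn.Linear(sizes[-2], sizes[-1], rng))
    return nn.Sequential(layers)


class GCNMLPClassifier(PathwayGCNClassifier):
    """Graph-convolution trunk + three fully connected layers before softmax."""

    def __init__(self, graphs=None, gene_ids=None, hidden_channels=8,
                 pool_channels=10, mlp_hidden=(64, 16), dropout_rate=0.1,
                 l2_lambda=1e-4, learning_rate=0.01, batch_size=32,
                 max_epochs=200, patience=5, seed=0, positive_class=None):
        super().__init__(graphs=graphs, gene_ids=gene_ids,
                         hidden_channels=hidden_channels, pool_channels=pool_channels,
                         dropout_rate=dropout_rate, l2_lambda=l2_lambda,
                         learning_rate=learning_rate, batch_size=batch_size,
                         max_epochs=max_epochs, patience=patience, seed=seed,
                         positive_class=positive_class)
        self.mlp_hidden = mlp_hidden

    def _build_network(self, n_genes, rng):
        trunk = self._build_trunk(n_genes, rng)
        sizes = [trunk.n_pooled, *self.mlp_hidden, 2]
        return nn.Network(trunk, _mlp_stack(sizes, self.dropout_rate, rng))

    @property
    def head_is_linear(self) -> bool:
        return False


class ExpressionMLPClassifier(_NNClassifierBase):
    """Baseline: three fully connected layers on the raw aligned gene vector."""

    def __init__(self, mlp_hidden=(64, 16), dropout_rate=0.1, l2_lambda=1e-4,
                 learning_rate=0.01, batch_size=32, max_epochs=200,
                 patience=5, seed=0, positive_class=None):
        self.mlp_hidden = mlp_hidden
        self.dropout_rate = dropout_rate
        self.l2_lambda = l2_lambda
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.seed = seed
        self.positive_class = positive_class

    def _build_network(self, n_genes, rng):
        sizes = [n_genes, *self.mlp_hidden, 2]
        return nn.Network(None, _mlp_stack(sizes, self.dropout_rate, rng))


def build_model(arch: str, **kwargs):
    """Dispatch ``gcn`` / ``mlp`` / ``gcn-mlp`` to the matching estimator."""
    arch = arch.lower().replace("_", "-")
    if arch == "gcn":
        kwargs.pop("mlp_hidden", None)
        return PathwayGCNClassifier(**kwargs)
    if arch == "gcn-mlp":
        return GCNMLPClassifier(**kwargs)
    if arch == "mlp":
        for key in ("graphs", "gene_ids", "hidden_channels", "pool_channels"):
            kwargs.pop(key, None)
        return ExpressionMLPClassifier(**kwargs)
    raise ValueError(f"unknown architecture {arch!r}")
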