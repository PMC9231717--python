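"""Minimal NumPy neural-network core used by the pathway classifiers.

Implements exactly the pieces the models need — dense layers, ReLU,
batch normalization, inverted dropout, a shared-weight graph-convolution
trunk over a block-diagonal normalized adjacency, softmax cross-entropy
with class weights and L2, and Adam — with hand-derived backward passes.
Everything is deterministic given a :class:`numpy.random.Generator`.

Shapes: dense layers operate on 2-D ``(batch, features)`` arrays.  The
graph trunk stacks all pathway graphs into one node axis of length
``M = sum_k N_k`` and treats ``(n_samples * M, channels)`` as the batch
for its per-channel layers, so batch statistics pool over samples and
nodes alike.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .graphs import PathwayGraph


def graph_conv_layer(g: PathwayGraph, H: np.ndarray, W: np.ndarray,
                     activation: bool = True) -> np.ndarray:
    """One graph-convolution step on a single pathway graph.

    Computes ``sigma(S H W)`` with ``S`` the graph's symmetric-normalized
    adjacency; ``sigma`` is ReLU when ``activation`` is set, identity
    otherwise.  ``H`` is nodes x in-channels, ``W`` in x out-channels.
    """
    H = np.atleast_2d(np.asarray(H, dtype=float))
    W = np.atleast_2d(np.asarray(W, dtype=float))
    if H.shape[0] != g.n_nodes:
        raise ValueError(f"H has {H.shape[0]} rows but the graph has {g.n_nodes} nodes")
    if H.shape[1] != W.shape[0]:
        raise ValueError(f"channel mismatch: H is {H.shape}, W is {W.shape}")
    out = g.norm_adjacency @ H @ W
    return np.maximum(out, 0.0) if activation else out


class EarlyStopping:
    """Stop when the monitored loss fails to set a new minimum for
    ``patience`` consecutive epochs; remembers the best epoch."""

    def __init__(self, patience: int):
        if patience < 1:
            raise ValueError("patience must be >= 1")
        self.patience = patience
        self.best_loss = np.inf
        self.best_epoch = 0
        self.bad_epochs = 0
        self.epoch = 0

    def update(self, loss: float) -> bool:
        """Record an epoch's loss; return True when training should stop."""
        self.epoch += 1
        if loss < self.best_loss:
            self.best_loss = loss
            self.best_epoch = self.epoch
            self.bad_epochs = 0
            return False
        self.bad_epochs += 1
        return self.bad_epochs >= self.patience

    @property
    def improved(self) -> bool:
        return self.bad_epochs == 0


class Layer:
    """A differentiable module with parameters and cached activations."""

    params: dict[str, np.ndarray]
    grads: dict[str, np.ndarray]

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray, training: bool, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def l2_penalty_params(self) -> list[str]:
        """Names of parameters that enter the L2 penalty (weights only)."""
        return []


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        # Glorot-uniform initialization
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.params["W"] = rng.uniform(-limit, limit, size=(n_in, n_out))
        self.has_bias = bias
        if bias:
            self.params["b"] = np.zeros(n_out)

    def forward(self, x, training, rng):
        self._x = x
        y = x @ self.params["W"]
        if self.has_bias:
            y = y + self.params["b"]
        return y

    def backward(self, dy):
        self.grads["W"] = self._x.T @ dy
        if self.has_bias:
            self.grads["b"] = dy.sum(axis=0)
        return dy @ self.params["W"].T

    def l2_penalty_params(self):
        return ["W"]


class ReLU(Layer):
    def forward(self, x, training, rng):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0)


class BatchNorm(Layer):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, n_channels: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.params["gamma"] = np.ones(n_channels)
        self.params["beta"] = np.zeros(n_channels)
        self.running_mean = np.zeros(n_channels)
        self.running_var = np.ones(n_channels)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, training, rng):
        if training:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mu, var = self.running_mean, self.running_var
        self._inv_sd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv_sd
        self._training = training
        self._n = x.shape[0]
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, dy):
        self.grads["gamma"] = (dy * self._xhat).sum(axis=0)
        self.grads["beta"] = dy.sum(axis=0)
        dxhat = dy * self.params["gamma"]
        if not self._training:
            return dxhat * self._inv_sd
        n = self._n
        return (self._inv_sd / n) * (
            n * dxhat - dxhat.sum(axis=0) - self._xhat * (dxhat * self._xhat).sum(axis=0)
        )


class Dropout(Layer):
    """Inverted dropout: identity at evaluation time."""

    def __init__(self, rate: float):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, training, rng):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        super().__init__()
        self.layers = layers

    def forward(self, x, training, rng):
        for layer in self.layers:
            x = layer.forward(x, training, rng)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def iter_params(self):
        for layer in self.layers:
            if isinstance(layer, Sequential):
                yield from layer.iter_params()
            else:
                for name in layer.params:
                    yield layer, name


class GraphConvTrunk(Layer):
    """Two shared-weight graph convolutions over all pathway graphs,
    followed by per-graph average pooling.

    The K pathway graphs are assembled once into a block-diagonal
    normalized adjacency ``S`` of shape (M, M).  For a batch of
    ``n`` samples the member-gene expression is gathered into
    ``H0`` of shape (n, M); each convolution computes ``S H W`` with a
    single weight matrix shared by every graph.  Block order per layer:
    conv -> ReLU -> batch-norm -> dropout after conv1; conv -> ReLU
    after conv2 (pooling follows immediately).  Average pooling yields
    ``pool_channels`` values per graph, concatenated in pathway order.
    """

    def __init__(
        self,
        graphs: list[PathwayGraph],
        gene_ids: list[str],
        hidden_channels: int,
        pool_channels: int,
        dropout_rate: float,
        rng: np.random.Generator,
    ):
        super().__init__()
        self.graphs = graphs
        self.K = len(graphs)
        self.pool_channels = pool_channels
        self.hidden_channels = hidden_channels

        col = {g: j for j, g in enumerate(gene_ids)}
        node_idx: list[int] = []
        for g in graphs:
            for gene in g.nodes:
                if gene not in col:
                    raise ValueError(
                        f"graph {g.pathway_id!r} gene {gene!r} missing from the aligned universe"
                    )
                node_idx.append(col[gene])
        self.node_idx = np.asarray(node_idx, dtype=np.intp)
        self.M = len(node_idx)
        self.n_genes = len(gene_ids)

        self.S = sp.block_diag([sp.csr_matrix(g.norm_adjacency) for g in graphs], format="csr")
        # per-graph averaging matrix P (K, M): row k has 1/N_k on k's nodes
        rows, cols, vals = [], [], []
        offset = 0
        for k, g in enumerate(graphs):
            n = g.n_nodes
            rows.extend([k] * n)
            cols.extend(range(offset, offset + n))
            vals.extend([1.0 / n] * n)
            offset += n
        self.P = sp.csr_matrix((vals, (rows, cols)), shape=(self.K, self.M))

        self.lin1 = Linear(1, hidden_channels, rng, bias=False)
        self.relu1 = ReLU()
        self.bn1 = BatchNorm(hidden_channels)
        self.drop1 = Dropout(dropout_rate)
        self.lin2 = Linear(hidden_channels, pool_channels, rng, bias=False)
        self.relu2 = ReLU()

    @property
    def n_pooled(self) -> int:
        return self.K * self.pool_channels

    def _propagate(self, h: np.ndarray) -> np.ndarray:
        """Apply the block-diagonal operator along the node axis.

        ``h`` has shape (n, M, c); returns S @ h per sample and channel.
        """
        n, m, c = h.shape
        flat = h.transpose(1, 0, 2).reshape(m, n * c)
        out = self.S @ flat
        return out.reshape(m, n, c).transpose(1, 0, 2)

    def forward(self, x, training, rng):
        n = x.shape[0]
        h0 = x[:, self.node_idx][:, :, None]          # (n, M, 1)
        c1 = self._propagate(h0)                      # (n, M, 1)
        a1 = self.lin1.forward(c1.reshape(-1, 1), training, rng)
        a1 = self.relu1.forward(a1, training, rng)
        a1 = self.bn1.forward(a1, training, rng)
        a1 = self.drop1.forward(a1, training, rng)
        h1 = a1.reshape(n, self.M, self.hidden_channels)
        c2 = self._propagate(h1)                      # (n, M, h)
        a2 = self.lin2.forward(c2.reshape(-1, self.hidden_channels), training, rng)
        a2 = self.relu2.forward(a2, training, rng)
        h2 = a2.reshape(n, self.M, self.pool_channels)
        # average pooling per graph -> (n, K, p) -> (n, K*p), pathway-major
        flat = h2.transpose(1, 0, 2).reshape(self.M, n * self.pool_channels)
        pooled = (self.P @ flat).reshape(self.K, n, self.pool_channels).transpose(1, 0, 2)
        self._n = n
        return pooled.reshape(n, self.n_pooled)

    def backward(self, dy):
        n = self._n
        dpooled = dy.reshape(n, self.K, self.pool_channels)
        flat = dpooled.transpose(1, 0, 2).reshape(self.K, n * self.pool_channels)
        dh2 = (self.P.T @ flat).reshape(self.M, n, self.pool_channels).transpose(1, 0, 2)
        da2 = self.relu2.backward(dh2.reshape(-1, self.pool_channels))
        dc2 = self.lin2.backward(da2).reshape(n, self.M, self.hidden_channels)
        dh1 = self._propagate(dc2)                    # S symmetric
        da1 = self.drop1.backward(dh1.reshape(-1, self.hidden_channels))
        da1 = self.bn1.backward(da1)
        da1 = self.relu1.backward(da1)
        dc1 = self.lin1.backward(da1).reshape(n, self.M, 1)
        dh0 = self._propagate(dc1)[:, :, 0]           # (n, M)
        dx = np.zeros((n, self.n_genes))
        np.add.at(dx, (np.arange(n)[:, None], self.node_idx[None, :]), dh0)
        return dx

    def iter_params(self):
        for layer in (self.lin1, self.bn1, self.lin2):
            for name in layer.params:
                yield layer, name


class Network:
    """Trunk (optional) + head, with weighted softmax cross-entropy loss."""

    def __init__(self, trunk: GraphConvTrunk | None, head: Sequential):
        self.trunk = trunk
        self.head = head

    def iter_params(self):
        if self.trunk is not None:
            yield from self.trunk.iter_params()
        yield from self.head.iter_params()

    def n_parameters(self) -> int:
        return sum(layer.params[name].size for layer, name in self.iter_params())

    def get_state(self) -> list[np.ndarray]:
        state = [layer.params[name].copy() for layer, name in self.iter_params()]
        for bn in self._batchnorms():
            state.append(bn.running_mean.copy())
            state.append(bn.running_var.copy())
        return state

    def set_state(self, state: list[np.ndarray]) -> None:
        params = list(self.iter_params())
        for (layer, name), value in zip(params, state[: len(params)]):
            layer.params[name] = value.copy()
        rest = state[len(params):]
        for i, bn in enumerate(self._batchnorms()):
            bn.running_mean = rest[2 * i].copy()
            bn.running_var = rest[2 * i + 1].copy()

    def _batchnorms(self) -> list[BatchNorm]:
        out = []
        if self.trunk is not None:
            out.append(self.trunk.bn1)

        def walk(seq):
            for layer in seq.layers:
                if isinstance(layer, Sequential):
                    walk(layer)
                elif isinstance(layer, BatchNorm):
                    out.append(layer)

        walk(self.head)
        return out

    def forward(self, x: np.ndarray, training: bool, rng: np.random.Generator,
                return_pooled: bool = False):
        z = x if self.trunk is None else self.trunk.forward(x, training, rng)
        logits = self.head.forward(z, training, rng)
        if return_pooled:
            return logits, z
        return logits

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        dz = self.head.backward(dlogits)
        if self.trunk is not None:
            return self.trunk.backward(dz)
        return dz

    def l2_penalty(self, l2_lambda: float) -> float:
        total = 0.0
        for layer, name in self.iter_params():
            if name in layer.l2_penalty_params():
                total += float(np.sum(layer.params[name] ** 2))
        return l2_lambda * total

    def add_l2_grads(self, l2_lambda: float) -> None:
        for layer, name in self.iter_params():
            if name in layer.l2_penalty_params():
                layer.grads[name] = layer.grads.get(name, 0.0) + 2.0 * l2_lambda * layer.params[name]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def weighted_cross_entropy(
    logits: np.ndarray, y: np.ndarray, sample_weights: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean weighted cross-entropy and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits)
    eps = 1e-12
    loss = float(np.mean(sample_weights * -np.log(p[np.arange(n), y] + eps)))
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    dlogits *= sample_weights[:, None] / n
    return loss, dlogits


class Adam:
    """Adam optimizer with bias correction over a Network's parameters."""

    def __init__(self, network: Network, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.network = network
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {id(layer) * 1000 + i: np.zeros_like(layer.params[name])
                  for i, (layer, name) in enumerate(network.iter_params())}
        self.v = {k: np.zeros_like(v) for k, v in self.m.items()}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (layer, name) in enumerate(self.network.iter_params()):
            key = id(layer) * 1000 + i
            g = layer.grads[name]
            self.m[key] = b1 * self.m[key] + (1 - b1) * g
            self.v[key] = b2 * self.v[key] + (1 - b2) * g * g
            mhat = self.m[key] / (1 - b1 ** self.t)
            vhat = self.v[key] / (1 - b2 ** self.t)
            layer.params[name] = layer.params[name] - self.lr * mhat / (np.sqrt(vhat) + self.eps)
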