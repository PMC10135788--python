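"""Signaling-informed sparse feed-forward classifier.

Architecture: input (one node per gene) -> signaling-informed layer (one
node per effector circuit) -> dense encoding layer -> optional second dense
layer -> softmax over cell types.  The first layer's kernel is the Hadamard
product ``W_S = W * I_S`` with the binary gene x circuit indicator, so a
circuit node only ever sees the genes of its own circuit.  Hidden layers
use ReLU; training minimizes categorical cross-entropy with Adam, with the
held-out validation split driving early stopping.

The mask is enforced by re-projection: masked gradient entries are zeroed
and ``W <- W * I_S`` is re-applied after every optimizer step, so masked
weights are exactly zero at every checkpoint regardless of optimizer
internals.

Implemented directly in NumPy: the network is small (a few hundred genes by
a few dozen circuits in typical masks), parameters live in float32 by
default, and a pure-NumPy implementation keeps single-threaded runs
bit-reproducible under a seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from .pathways import IndicatorMatrix

logger = logging.getLogger(__name__)


def relu(z):
    """Rectified linear unit, max(0, z), elementwise."""
    return np.maximum(z, 0)


def softmax(z):
    """Row-wise exp-normalization, stabilized by max subtraction."""
    z = np.asarray(z)
    shifted = z - z.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(y, p, eps: float = 1e-12):
    """Mean categorical cross-entropy, -sum_j y_ij log p_ij, floored at eps."""
    y = np.asarray(y)
    p = np.asarray(p)
    if y.shape != p.shape:
        raise ValueError(f"shape mismatch: targets {y.shape} vs probabilities {p.shape}")
    return float(-(y * np.log(np.maximum(p, eps))).sum(axis=-1).mean())


@dataclass
class NetworkConfig:
    n_genes: int
    n_circuits: int
    n_classes: int
    encoding_dim: int = 128
    extra_hidden: int = 0  # 1 adds a second dense layer after the encoding layer
    epochs: int = 100
    batch_size: int = 10
    early_stop_patience: int = 10
    learning_rate: float = 1e-3
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self):
        for name in ("n_genes", "n_circuits", "n_classes", "encoding_dim", "epochs", "batch_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.extra_hidden not in (0, 1):
            raise ValueError("extra_hidden must be 0 or 1")


@dataclass
class InformedNetwork:
    config: NetworkConfig
    mask: np.ndarray = field(repr=False)  # uint8, n_genes x n_circuits
    params: dict = field(repr=False)
    class_labels: list = field(default_factory=list)
    gene_ids: list = field(default_factory=list)
    circuit_ids: list = field(default_factory=list)

    @property
    def masked_kernel(self) -> np.ndarray:
        """W_S = W * I_S (identically W after re-projection)."""
        return self.params["W1"] * self.mask

    def copy_params(self) -> dict:
        return {k: v.copy() for k, v in self.params.items()}


def _glorot(rng, fan_in, fan_out, dtype):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out)).astype(dtype)


def init_network(
    cfg: NetworkConfig,
    indicator: IndicatorMatrix,
    class_labels=None,
    seed=None,
) -> InformedNetwork:
    """Glorot-uniform initialization followed by masking; zero biases.

    Glorot fans use the full (unmasked) kernel shape; the mask is applied
    immediately after drawing, so a weight tied to a gene outside the circuit
    starts, and stays, at exactly zero.
    """
    if indicator.shape != (cfg.n_genes, cfg.n_circuits):
        raise ValueError(
            f"indicator shape {indicator.shape} does not match config "
            f"({cfg.n_genes} genes x {cfg.n_circuits} circuits)"
        )
    dtype = np.dtype(cfg.dtype)
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    mask = indicator.values.astype(dtype)
    params = {
        "W1": _glorot(rng, cfg.n_genes, cfg.n_circuits, dtype) * mask,
        "b1": np.zeros(cfg.n_circuits, dtype=dtype),
        "W2": _glorot(rng, cfg.n_circuits, cfg.encoding_dim, dtype),
        "b2": np.zeros(cfg.encoding_dim, dtype=dtype),
    }
    if cfg.extra_hidden:
        params["W2e"] = _glorot(rng, cfg.encoding_dim, cfg.encoding_dim, dtype)
        params["b2e"] = np.zeros(cfg.encoding_dim, dtype=dtype)
    params["W3"] = _glorot(rng, cfg.encoding_dim, cfg.n_classes, dtype)
    params["b3"] = np.zeros(cfg.n_classes, dtype=dtype)
    labels = list(class_labels) if class_labels is not None else [f"class_{i}" for i in range(cfg.n_classes)]
    if len(labels) != cfg.n_classes:
        raise ValueError("class_labels length must equal n_classes")
    return InformedNetwork(
        config=cfg,
        mask=indicator.values.copy(),
        params=params,
        class_labels=labels,
        gene_ids=list(indicator.genes),
        circuit_ids=list(indicator.circuits),
    )


def forward(net: InformedNetwork, X) -> tuple:
    """Propagate cells x genes input; return (signaling activations, encodings, probabilities).

    The encoding is the activation of the last hidden layer — the features
    handed to the novelty detector.
    """
    X = np.asarray(X, dtype=net.params["W1"].dtype)
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in network input")
    p = net.params
    a1 = relu(X @ p["W1"] + p["b1"])
    a2 = relu(a1 @ p["W2"] + p["b2"])
    enc = relu(a2 @ p["W2e"] + p["b2e"]) if net.config.extra_hidden else a2
    probs = softmax(enc @ p["W3"] + p["b3"])
    return a1, enc, probs


def encode(net: InformedNetwork, X) -> np.ndarray:
    """Activations of the encoding (last hidden) layer."""
    return forward(net, X)[1]


def signaling_activity(net: InformedNetwork, X) -> np.ndarray:
    """Activations of the signaling-informed layer: a functional, per-circuit
    representation of each cell (columns ordered as ``net.circuit_ids``)."""
    return forward(net, X)[0]


def _loss_and_grads(net: InformedNetwork, X, y):
    """Cross-entropy loss and analytic gradients; masked W1 entries get zero gradient."""
    p = net.params
    cfg = net.config
    X = np.asarray(X, dtype=p["W1"].dtype)
    y = np.asarray(y, dtype=p["W1"].dtype)
    n = X.shape[0]

    z1 = X @ p["W1"] + p["b1"]
    a1 = relu(z1)
    z2 = a1 @ p["W2"] + p["b2"]
    a2 = relu(z2)
    if cfg.extra_hidden:
        z2e = a2 @ p["W2e"] + p["b2e"]
        enc = relu(z2e)
    else:
        enc = a2
    z3 = enc @ p["W3"] + p["b3"]
    probs = softmax(z3)
    loss = cross_entropy(y, probs)

    grads = {}
    dz3 = (probs - y) / n
    grads["W3"] = enc.T @ dz3
    grads["b3"] = dz3.sum(axis=0)
    denc = dz3 @ p["W3"].T
    if cfg.extra_hidden:
        dz2e = denc * (z2e > 0)
        grads["W2e"] = a2.T @ dz2e
        grads["b2e"] = dz2e.sum(axis=0)
        da2 = dz2e @ p["W2e"].T
    else:
        da2 = denc
    dz2 = da2 * (z2 > 0)
    grads["W2"] = a1.T @ dz2
    grads["b2"] = dz2.sum(axis=0)
    da1 = dz2 @ p["W2"].T
    dz1 = da1 * (z1 > 0)
    grads["W1"] = (X.T @ dz1) * net.mask  # gradient locality: masked entries never move
    grads["b1"] = dz1.sum(axis=0)
    return loss, grads


def train(
    net: InformedNetwork,
    learn: tuple,
    valid: tuple,
    cfg: NetworkConfig | None = None,
) -> tuple:
    """Adam minimization of the cross-entropy with validation early stopping.

    After every gradient step the mask is re-applied (``W1 <- W1 * I_S``) so
    masked entries are exactly zero at every checkpoint.  Stops when the
    validation loss has not improved for ``early_stop_patience`` epochs and
    restores the best-validation-loss weights.  Returns ``(net, history)``
    with per-epoch learning/validation losses.
    """
    cfg = cfg or net.config
    Xl, yl = learn
    Xv, yv = valid
    Xl = np.asarray(Xl, dtype=net.params["W1"].dtype)
    yl = np.asarray(yl, dtype=net.params["W1"].dtype)
    if yl.shape[1] != cfg.n_classes:
        raise ValueError("one-hot target width must equal n_classes")
    present = yl.sum(axis=0) > 0
    if not present.all():
        missing = [net.class_labels[i] for i in np.flatnonzero(~present)]
        raise ValueError(f"classes missing from learning set: {missing}")

    rng = np.random.default_rng(cfg.seed)
    m_state = {k: np.zeros_like(v) for k, v in net.params.items()}
    v_state = {k: np.zeros_like(v) for k, v in net.params.items()}
    t = 0
    best_loss = np.inf
    best_params = net.copy_params()
    best_epoch = -1
    history = {"learn_loss": [], "valid_loss": []}
    n = Xl.shape[0]
    mask = net.mask.astype(net.params["W1"].dtype)

    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            _, grads = _loss_and_grads(net, Xl[batch], yl[batch])
            t += 1
            for k, g in grads.items():
                m_state[k] = cfg.adam_beta1 * m_state[k] + (1 - cfg.adam_beta1) * g
                v_state[k] = cfg.adam_beta2 * v_state[k] + (1 - cfg.adam_beta2) * g * g
                mhat = m_state[k] / (1 - cfg.adam_beta1**t)
                vhat = v_state[k] / (1 - cfg.adam_beta2**t)
                net.params[k] = net.params[k] - cfg.learning_rate * mhat / (np.sqrt(vhat) + cfg.adam_eps)
            net.params["W1"] *= mask  # re-project onto the sparsity pattern
        learn_loss = cross_entropy(yl, forward(net, Xl)[2])
        valid_loss = cross_entropy(np.asarray(yv), forward(net, Xv)[2])
        history["learn_loss"].append(learn_loss)
        history["valid_loss"].append(valid_loss)
        if valid_loss < best_loss:
            best_loss = valid_loss
            best_params = net.copy_params()
            best_epoch = epoch
        elif epoch - best_epoch >= cfg.early_stop_patience:
            logger.info("early stop at epoch %d (best %d, val loss %.4f)", epoch, best_epoch, best_loss)
            break
    net.params = best_params
    history["best_epoch"] = best_epoch
    history["best_valid_loss"] = best_loss
    return net, history


def one_hot(labels, class_order) -> np.ndarray:
    """Encode labels as one-hot rows in the given class order."""
    index = {c: i for i, c in enumerate(class_order)}
    out = np.zeros((len(labels), len(class_order)))
    for i, lab in enumerate(labels):
        if lab not in index:
            raise ValueError(f"label {lab!r} not in class order {list(class_order)}")
        out[i, index[lab]] = 1.0
    return out
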