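"""Feature attention block, neural predictor, loss and the joint training loop.

The attention block is a bank of g independent scalar subnetworks (one per
feature dimension, shared across rows): each maps one embedding entry through
a small hidden layer to a sigmoid gate in (0, 1).  Gating the embedding
matrix element-wise and feeding it to a one-hidden-layer classifier gives the
association probability.  Everything runs on NumPy with hand-derived
gradients and plain constant-step gradient descent, so training is exactly
reproducible on a single CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .neighbor_embedding import EmbeddingMatrix

EPS_CLIP = 1e-7


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class TrainConfig:
    """Training hyperparameters; defaults follow the published setup."""

    learning_rate: float = 0.9
    batch_size: int = 3000
    epochs: int = 2000
    l2_lambda: float = 2e-4
    seed: int = 0
    hidden_predictor: int = 64
    hidden_attention: int = 8
    attention_enabled: bool = True
    softmax_head: bool = False

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.batch_size, self.epochs) <= 0:
            raise ValueError("learning_rate, batch_size and epochs must be positive")
        if self.l2_lambda < 0:
            raise ValueError("l2_lambda must be nonnegative")


@dataclass
class AttentionBlock:
    """g per-feature scalar subnetworks: x -> sigmoid(V . relu(U x + c) + d)."""

    U: np.ndarray  # (g, h)
    c: np.ndarray  # (g, h)
    V: np.ndarray  # (g, h)
    d: np.ndarray  # (g,)

    @property
    def g(self) -> int:
        return self.U.shape[0]

    def gates(self, E: np.ndarray) -> np.ndarray:
        """Attention matrix M with M[r, i] = subnetwork_i(E[r, i]); all in (0,1)."""
        Z = E[:, :, None] * self.U[None, :, :] + self.c[None, :, :]
        A = np.maximum(Z, 0.0)
        S = np.einsum("kgh,gh->kg", A, self.V) + self.d[None, :]
        return _sigmoid(S)


@dataclass
class PredictorNet:
    """g -> hidden (ReLU) -> 2 output neurons (sigmoid); P is neuron 0."""

    W1: np.ndarray  # (g, H)
    b1: np.ndarray  # (H,)
    W2: np.ndarray  # (H, 2)
    b2: np.ndarray  # (2,)
    softmax_head: bool = False

    def forward(self, F: np.ndarray) -> np.ndarray:
        Z1 = F @ self.W1 + self.b1
        Z2 = np.maximum(Z1, 0.0) @ self.W2 + self.b2
        if self.softmax_head:
            Z2 = Z2 - Z2.max(axis=1, keepdims=True)
            ex = np.exp(Z2)
            return ex[:, 0] / ex.sum(axis=1)
        return _sigmoid(Z2)[:, 0]


@dataclass
class TrainState:
    epoch: int
    loss_trace: list[float] = field(default_factory=list)


@dataclass
class Model:
    """Trained attention + predictor bundle operating on embedding matrices."""

    attention: AttentionBlock | None
    predictor: PredictorNet
    config: TrainConfig

    def score(self, E: EmbeddingMatrix | np.ndarray) -> np.ndarray:
        X = E.values if isinstance(E, EmbeddingMatrix) else np.asarray(E, dtype=float)
        M = self.attention.gates(X) if self.attention is not None else np.ones_like(X)
        return self.predictor.forward(X * M)


def attend(
    E: EmbeddingMatrix | np.ndarray, block: AttentionBlock
) -> tuple[np.ndarray, np.ndarray]:
    """Attention matrix M and the gated feature matrix F = E * M."""
    X = E.values if isinstance(E, EmbeddingMatrix) else np.asarray(E, dtype=float)
    if X.shape[1] != block.g:
        raise ValueError(f"feature count {X.shape[1]} != attention width {block.g}")
    M = block.gates(X)
    return M, X * M


def predict(F: np.ndarray, net: PredictorNet) -> np.ndarray:
    F = np.asarray(F, dtype=float)
    if F.shape[1] != net.W1.shape[0]:
        raise ValueError(f"feature count {F.shape[1]} != net input {net.W1.shape[0]}")
    return net.forward(F)


def loss(
    P: np.ndarray, Y: np.ndarray, params: list[np.ndarray], l2_lambda: float
) -> float:
    """Mean binary cross-entropy plus lambda * ||theta||_2^2, clipped for safety."""
    P = np.clip(np.asarray(P, dtype=float), EPS_CLIP, 1.0 - EPS_CLIP)
    Y = np.asarray(Y, dtype=float)
    bce = -np.mean(Y * np.log(P) + (1.0 - Y) * np.log(1.0 - P))
    reg = l2_lambda * sum(float(np.sum(p * p)) for p in params)
    return float(bce + reg)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    s = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-s, s, size=shape)


def init_model(g: int, config: TrainConfig, rng: np.random.Generator) -> Model:
    h, H = config.hidden_attention, config.hidden_predictor
    attention = None
    if config.attention_enabled:
        attention = AttentionBlock(
            U=_glorot(rng, 1, h, (g, h)),
            c=np.zeros((g, h)),
            V=_glorot(rng, h, 1, (g, h)),
            d=np.zeros(g),
        )
    predictor = PredictorNet(
        W1=_glorot(rng, g, H, (g, H)),
        b1=np.zeros(H),
        W2=_glorot(rng, H, 2, (H, 2)),
        b2=np.zeros(2),
        softmax_head=config.softmax_head,
    )
    return Model(attention=attention, predictor=predictor, config=config)


def _params(model: Model) -> list[np.ndarray]:
    ps = [model.predictor.W1, model.predictor.b1, model.predictor.W2, model.predictor.b2]
    if model.attention is not None:
        ps += [model.attention.U, model.attention.c, model.attention.V, model.attention.d]
    return ps


def _forward_backward(
    model: Model, E: np.ndarray, Y: np.ndarray, l2_lambda: float
) -> tuple[float, list[np.ndarray]]:
    """Loss and gradients in the order of ``_params``; fully vectorized."""
    att, net = model.attention, model.predictor
    k = E.shape[0]
    if att is not None:
        Z = E[:, :, None] * att.U[None] + att.c[None]
        A = np.maximum(Z, 0.0)
        S = np.einsum("kgh,gh->kg", A, att.V) + att.d[None, :]
        M = _sigmoid(S)
        F = E * M
    else:
        F = E
    Z1 = F @ net.W1 + net.b1
    A1 = np.maximum(Z1, 0.0)
    Z2 = A1 @ net.W2 + net.b2
    if net.softmax_head:
        Zs = Z2 - Z2.max(axis=1, keepdims=True)
        ex = np.exp(Zs)
        P = ex[:, 0] / ex.sum(axis=1)
        dZ2 = np.zeros_like(Z2)
        dZ2[:, 0] = (P - Y) / k
        dZ2[:, 1] = -(P - Y) / k
    else:
        O = _sigmoid(Z2)
        P = O[:, 0]
        dZ2 = np.zeros_like(Z2)
        dZ2[:, 0] = (P - Y) / k
    total = loss(P, Y, _params(model), l2_lambda)

    lam2 = 2.0 * l2_lambda
    gW2 = A1.T @ dZ2 + lam2 * net.W2
    gb2 = dZ2.sum(axis=0) + lam2 * net.b2
    dZ1 = (dZ2 @ net.W2.T) * (Z1 > 0)
    gW1 = F.T @ dZ1 + lam2 * net.W1
    gb1 = dZ1.sum(axis=0) + lam2 * net.b1
    grads = [gW1, gb1, gW2, gb2]
    if att is not None:
        dF = dZ1 @ net.W1.T
        dS = (dF * E) * M * (1.0 - M)
        gd = dS.sum(axis=0) + lam2 * att.d
        gV = np.einsum("kg,kgh->gh", dS, A) + lam2 * att.V
        dZatt = dS[:, :, None] * att.V[None] * (Z > 0)
        gU = np.einsum("kgh,kg->gh", dZatt, E) + lam2 * att.U
        gc = dZatt.sum(axis=(0,)) + lam2 * att.c
        grads += [gU, gc, gV, gd]
    return total, grads


def train(
    E_train: EmbeddingMatrix | np.ndarray,
    Y_train: np.ndarray,
    config: TrainConfig = TrainConfig(),
) -> tuple[Model, TrainState]:
    """Jointly optimize attention and predictor by minibatch gradient descent.

    Shuffling is drawn from a generator seeded by ``config.seed``, so the
    whole loss trace is reproducible bit-for-bit.  Divergence (non-finite
    loss) aborts with a diagnostic.
    """
    X = E_train.values if isinstance(E_train, EmbeddingMatrix) else np.asarray(E_train, dtype=float)
    Y = np.asarray(Y_train, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("embedding/label count mismatch")
    if not (Y.min() < 0.5 < Y.max()):
        raise ValueError("training set needs at least one positive and one negative")
    rng = np.random.default_rng(config.seed)
    model = init_model(X.shape[1], config, rng)
    params = _params(model)
    state = TrainState(epoch=0)
    k = X.shape[0]
    for epoch in range(config.epochs):
        order = rng.permutation(k)
        epoch_losses = []
        for start in range(0, k, config.batch_size):
            idx = order[start : start + config.batch_size]
            batch_loss, grads = _forward_backward(
                model, X[idx], Y[idx], config.l2_lambda
            )
            if not np.isfinite(batch_loss):
                raise RuntimeError(
                    f"training diverged at epoch {epoch} (loss={batch_loss}); "
                    "try a lower learning rate"
                )
            for p, gr in zip(params, grads):
                p -= config.learning_rate * gr
            epoch_losses.append(batch_loss)
        state.epoch = epoch + 1
        state.loss_trace.append(float(np.mean(epoch_losses)))
    return model, state
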