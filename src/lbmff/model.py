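"""Two-layer GCN encoder with layer attention and a bilinear decoder.

The encoder propagates node features over the normalized block graph,

    H^{l+1} = ReLU( D~^{-1/2} A_H D~^{-1/2} H^l W^l ),

starting from H^0 = [[0, A], [A^T, 0]] built from the *training*
association matrix (test-fold associations are zeroed before anything
else happens).  A layer-attention step forms the final embedding
E = Σ_l a_l H^l with coefficients initialized to 1/(l+1) and learned
jointly with the weights; the first m rows of E are drug embeddings E_r,
the rest disease embeddings E_d.  The decoder scores every pair with
A'_ij = sigmoid(e_i^T W e_j) (implemented as E_r W E_d^T, which is the
dimensionally consistent reading of the bilinear form).

Training minimizes full-matrix binary cross-entropy with positives
up-weighted by the negative/positive ratio, using Adam.  Everything is
plain numpy with hand-derived gradients — the graphs are small and this
keeps runs exactly reproducible from a seed; gradients are checked
against finite differences in the test suite.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .io_data import AssociationMatrix, ValidationError
from .fusion import FeatureGraph, laplacian_normalize

__all__ = [
    "TrainConfig",
    "GCNModel",
    "init_embeddings",
    "gcn_layer",
    "layer_attention",
    "decode",
    "train",
    "predict",
    "save_model",
    "load_model",
]


@dataclass
class TrainConfig:
    """Training hyperparameters.

    ``embedding_dim=None`` means use m+n, which lets the input
    representation H^0 participate in layer attention (it is an
    (m+n)-wide matrix); a fixed smaller dim restricts attention to the
    GCN layer outputs.
    """

    embedding_dim: int | None = None
    n_layers: int = 2
    learning_rate: float = 0.01
    epochs: int = 1000
    dropout: float = 0.1
    dropout_mode: str = "layer"  # "layer": layer outputs; "edge": adjacency
    pos_weight: float | None = None  # None -> (#negatives / #positives)
    attend_input: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 0:
            raise ValidationError("epochs must be >= 0")
        if not (0 <= self.dropout < 1):
            raise ValidationError("dropout must be in [0, 1)")
        if self.dropout_mode not in ("layer", "edge"):
            raise ValidationError("dropout_mode must be 'layer' or 'edge'")
        if self.n_layers < 1:
            raise ValidationError("need at least one GCN layer")


@dataclass
class GCNModel:
    """Learned parameters plus enough bookkeeping to score new pairs."""

    weights: list[np.ndarray]      # W^l, l = 0..L-1
    attention: np.ndarray          # a_l over the attended representations
    decoder: np.ndarray            # bilinear W, d x d
    config: TrainConfig
    m: int
    n: int
    attends_input: bool
    loss_trajectory: list[float] = field(default_factory=list)

    def check_finite(self) -> None:
        for p in [*self.weights, self.attention, self.decoder]:
            if not np.isfinite(p).all():
                raise RuntimeError("model contains non-finite parameters")


# ---------------------------------------------------------------------------
# building blocks (each usable standalone, mirrored by oracles in tests)


def init_embeddings(A_train: AssociationMatrix | np.ndarray) -> np.ndarray:
    """H^0 = [[0, A], [A^T, 0]] from the training association matrix."""
    A = A_train.values if isinstance(A_train, AssociationMatrix) else np.asarray(A_train)
    A = A.astype(float)
    m, n = A.shape
    H0 = np.zeros((m + n, m + n))
    H0[:m, m:] = A
    H0[m:, :m] = A.T
    return H0


def gcn_layer(H: np.ndarray, A_H: np.ndarray, W: np.ndarray) -> np.ndarray:
    """One propagation step ReLU(D~^{-1/2} A_H D~^{-1/2} H W)."""
    out = laplacian_normalize(A_H) @ H @ W
    if not np.isfinite(out).all():
        raise RuntimeError("non-finite values in GCN layer output")
    return np.maximum(out, 0.0)


def layer_attention(H_list: list[np.ndarray], a: np.ndarray) -> np.ndarray:
    """Weighted sum E = Σ_l a_l H^l of same-shaped representations."""
    a = np.asarray(a, dtype=float)
    if len(H_list) != len(a):
        raise ValidationError("one attention coefficient per representation")
    shape = H_list[0].shape
    if any(h.shape != shape for h in H_list):
        raise ValidationError("attended representations must share a shape")
    E = np.zeros(shape)
    for coeff, h in zip(a, H_list):
        E += coeff * h
    return E


def initial_attention(n_reps: int, attends_input: bool) -> np.ndarray:
    """1/(l+1) initialization; l starts at 0 when H^0 is attended."""
    start = 0 if attends_input else 1
    return np.array([1.0 / (l + 1) for l in range(start, start + n_reps)])


def decode(E_r: np.ndarray, E_d: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Bilinear sigmoid scores, A'_ij = sigmoid(e_i^T W e_j), in (0, 1)."""
    if E_r.shape[1] != W.shape[0] or W.shape[1] != E_d.shape[1]:
        raise ValidationError(
            f"decoder shapes do not chain: {E_r.shape} x {W.shape} x {E_d.shape}^T"
        )
    return _sigmoid(E_r @ W @ E_d.T)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


# ---------------------------------------------------------------------------
# forward / backward


def _forward(model: GCNModel, a_hat: np.ndarray, H0: np.ndarray,
             dropout_masks: list[np.ndarray] | None = None):
    """Full forward pass; returns logits and the cache backprop needs."""
    reps = [H0]          # post-dropout representation entering each layer
    Zs: list[np.ndarray] = []
    masks: list[np.ndarray | None] = []
    H = H0
    for i, W in enumerate(model.weights):
        Z = a_hat @ H @ W
        Hl = np.maximum(Z, 0.0)
        mask = dropout_masks[i] if dropout_masks is not None else None
        if mask is not None:
            Hl = Hl * mask
        Zs.append(Z)
        masks.append(mask)
        reps.append(Hl)
        H = Hl
    attended = reps if model.attends_input else reps[1:]
    E = layer_attention(attended, model.attention)
    E_r, E_d = E[: model.m], E[model.m:]
    logits = E_r @ model.decoder @ E_d.T
    return logits, (reps, Zs, masks, E_r, E_d)


def _backward(model: GCNModel, a_hat: np.ndarray, cache, G: np.ndarray):
    """Gradients of the loss given dL/dlogits = G (m x n)."""
    reps, Zs, masks, E_r, E_d = cache
    W_dec = model.decoder
    g_dec = E_r.T @ G @ E_d
    dE = np.vstack([G @ E_d @ W_dec.T, G.T @ E_r @ W_dec])

    attended = reps if model.attends_input else reps[1:]
    g_att = np.array([float(np.sum(dE * h)) for h in attended])

    dreps = [np.zeros_like(h) for h in reps]
    offset = 0 if model.attends_input else 1
    for idx, coeff in enumerate(model.attention):
        dreps[idx + offset] += coeff * dE

    g_weights = [np.zeros_like(W) for W in model.weights]
    for i in range(len(model.weights) - 1, -1, -1):
        dH = dreps[i + 1]
        if masks[i] is not None:
            dH = dH * masks[i]
        dZ = dH * (Zs[i] > 0)
        AH = a_hat @ reps[i]
        g_weights[i] = AH.T @ dZ
        dreps[i] += a_hat @ dZ @ model.weights[i].T  # a_hat is symmetric
    return g_weights, g_att, g_dec


def _weighted_bce(logits: np.ndarray, Y: np.ndarray, w: np.ndarray):
    """Stable weighted BCE from logits; returns (loss, dL/dlogits)."""
    wsum = w.sum()
    loss = float(np.sum(w * (np.logaddexp(0.0, logits) - Y * logits)) / wsum)
    G = w * (_sigmoid(logits) - Y) / wsum
    return loss, G


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def _init_model(m: int, n: int, config: TrainConfig) -> GCNModel:
    rng = np.random.default_rng(config.seed)
    N = m + n
    d = config.embedding_dim if config.embedding_dim is not None else N
    attends_input = config.attend_input and d == N
    if config.attend_input and d != N:
        warnings.warn(
            f"embedding_dim={d} != m+n={N}: input representation cannot join "
            "layer attention; attending GCN layer outputs only"
        )
    dims = [N] + [d] * config.n_layers
    weights = [_glorot(rng, dims[i], dims[i + 1]) for i in range(config.n_layers)]
    n_reps = config.n_layers + (1 if attends_input else 0)
    attention = initial_attention(n_reps, attends_input)
    decoder = _glorot(rng, d, d)
    return GCNModel([w for w in weights], attention, decoder, config, m, n, attends_input)


def train(
    graph: FeatureGraph,
    A_train: AssociationMatrix | np.ndarray,
    config: TrainConfig | None = None,
) -> GCNModel:
    """Fit the GCN on a training-fold graph; deterministic given the seed.

    The loss is weighted binary cross-entropy over all m*n cells of the
    training matrix (no negative sampling); positives are up-weighted by
    the class ratio unless ``config.pos_weight`` overrides it.  Divergence
    (non-finite loss) raises; a rising trailing-window loss only warns.
    """
    config = config or TrainConfig()
    A = A_train.values if isinstance(A_train, AssociationMatrix) else np.asarray(A_train)
    Y = A.astype(float)
    m, n = Y.shape
    if (graph.m, graph.n) != (m, n):
        raise ValidationError("graph and association shapes disagree")

    model = _init_model(m, n, config)
    if config.epochs == 0:
        return model

    n_pos = Y.sum()
    if n_pos == 0:
        raise ValidationError("training matrix has no positives")
    pos_weight = (
        config.pos_weight if config.pos_weight is not None else (Y.size - n_pos) / n_pos
    )
    w = 1.0 + (pos_weight - 1.0) * Y

    a_hat = graph.a_hat
    H0 = init_embeddings(Y)
    rng = np.random.default_rng(config.seed + 1)

    params = [*model.weights, model.attention, model.decoder]
    adam_m = [np.zeros_like(p) for p in params]
    adam_v = [np.zeros_like(p) for p in params]
    b1, b2, eps = 0.9, 0.999, 1e-8
    lr = config.learning_rate

    for epoch in range(1, config.epochs + 1):
        masks = None
        a_hat_epoch = a_hat
        if config.dropout > 0:
            keep = 1.0 - config.dropout
            if config.dropout_mode == "layer":
                masks = [
                    (rng.random((m + n, W.shape[1])) < keep) / keep
                    for W in model.weights
                ]
            else:  # symmetric edge dropout on the normalized adjacency
                em = np.triu(rng.random((m + n, m + n)) < keep)
                em = (em | em.T) / keep
                a_hat_epoch = a_hat * em
        logits, cache = _forward(model, a_hat_epoch, H0, masks)
        loss, G = _weighted_bce(logits, Y, w)
        if not np.isfinite(loss):
            raise RuntimeError(
                f"loss diverged at epoch {epoch}; try a lower learning rate"
            )
        model.loss_trajectory.append(loss)

        g_weights, g_att, g_dec = _backward(model, a_hat_epoch, cache, G)
        grads = [*g_weights, g_att, g_dec]
        for p, g, mm, vv in zip(params, grads, adam_m, adam_v):
            mm += (1 - b1) * (g - mm)
            vv += (1 - b2) * (g * g - vv)
            mhat = mm / (1 - b1**epoch)
            vhat = vv / (1 - b2**epoch)
            p -= lr * mhat / (np.sqrt(vhat) + eps)

    traj = np.array(model.loss_trajectory)
    window = max(10, len(traj) // 10)
    if len(traj) >= 2 * window and traj[-window:].mean() > traj[-2 * window:-window].mean():
        warnings.warn("training loss increased over the trailing window")
    model.check_finite()
    return model


def predict(
    model: GCNModel,
    graph: FeatureGraph,
    A_train: AssociationMatrix | np.ndarray | None = None,
) -> np.ndarray:
    """Score every drug-disease pair; entries strictly in (0, 1).

    ``A_train`` defaults to the association block stored in the graph
    (both must be the training matrix the model was fitted on).
    """
    if A_train is None:
        H0 = init_embeddings(graph.association_block)
    else:
        H0 = init_embeddings(A_train)
    logits, _ = _forward(model, graph.a_hat, H0, None)
    return _sigmoid(logits)


# ---------------------------------------------------------------------------
# serialization


def save_model(model: GCNModel, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    arrays = {f"W{i}": w for i, w in enumerate(model.weights)}
    arrays["attention"] = model.attention
    arrays["decoder"] = model.decoder
    np.savez(out / "weights.npz", **arrays)
    meta = {
        "config": asdict(model.config),
        "m": model.m,
        "n": model.n,
        "attends_input": model.attends_input,
        "loss_trajectory": model.loss_trajectory,
    }
    (out / "model.json").write_text(json.dumps(meta, indent=2))


def load_model(model_dir: str | Path) -> GCNModel:
    d = Path(model_dir)
    meta = json.loads((d / "model.json").read_text())
    arrays = np.load(d / "weights.npz")
    weights = [arrays[f"W{i}"] for i in range(meta["config"]["n_layers"])]
    return GCNModel(
        weights=weights,
        attention=arrays["attention"],
        decoder=arrays["decoder"],
        config=TrainConfig(**meta["config"]),
        m=meta["m"],
        n=meta["n"],
        attends_input=meta["attends_input"],
        loss_trajectory=list(meta["loss_trajectory"]),
    )
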