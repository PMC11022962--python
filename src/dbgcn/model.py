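"""The DBGCN classifier: BiLSTM node encoder + graph convolution + softmax head.

Per segment, each channel contributes a length-t sequence of d-dimensional
band features.  A single shared-weight bidirectional LSTM reads every
channel's sequence and concatenates its final forward and backward hidden
states into the node-feature matrix H (n x 2*hidden).  Stacked graph
convolutions then mix information along the correlation network,

    H^{l+1} = sigma( S H^l W^l ),    S = D_tilde^{-1/2} (A' + I) D_tilde^{-1/2},

with sigma a bounded ReLU (min(max(x, 0), cap)), each convolution followed by
50% pooling that halves the node count via the precomputed coarsening
hierarchy.  The pooled features are flattened through dropout into a dense
softmax layer for the binary control/depressed decision.  The training loss
is mean cross-entropy plus an L2 penalty lambda * sum(w^2 + b^2) over every
trainable weight and bias.

Everything here is plain NumPy.  Gradients are derived analytically
(backpropagation through time for the LSTM; matrix calculus for the graph
stack) and are validated against finite differences in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .graph import BrainGraph, PoolingLevel, build_pooling_hierarchy, propagation_matrix

__all__ = [
    "ModelConfig",
    "GraphStack",
    "build_graph_stack",
    "init_params",
    "brelu",
    "gcn_layer",
    "spectral_pool",
    "bilstm_encode",
    "forward",
    "loss",
    "loss_and_grads",
]

_EPS = 1e-12  # log clamp in the cross-entropy


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``bilstm_hidden`` is the per-direction LSTM width, so node features have
    dimension d' = 2 * bilstm_hidden.  ``gcn_channels`` gives the output width
    of each graph convolution; its length fixes the number of GCN layers and
    pooling steps.
    """

    n_channels: int
    t_subwindows: int = 4
    d_bands: int = 4
    bilstm_hidden: int = 16
    gcn_channels: tuple[int, ...] = (32, 64)
    brelu_cap: float = 6.0
    dropout: float = 0.5
    n_classes: int = 2
    l2_lambda: float = 1e-4
    pool_reducer: str = "max"

    def __post_init__(self) -> None:
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.brelu_cap <= 0:
            raise ValueError("brelu_cap must be positive")
        if min((self.n_channels, self.t_subwindows, self.d_bands,
                self.bilstm_hidden, self.n_classes, *self.gcn_channels)) < 1:
            raise ValueError("all size parameters must be positive")

    @property
    def n_gcn_layers(self) -> int:
        return len(self.gcn_channels)

    def node_counts(self) -> list[int]:
        """Node count entering each GCN layer, plus the final pooled count."""
        counts = [self.n_channels]
        for _ in self.gcn_channels:
            counts.append(math.ceil(counts[-1] / 2))
        return counts


@dataclass
class GraphStack:
    """Per-depth propagation operators and pooling groups for one brain graph."""

    S_list: list[np.ndarray]
    levels: list[PoolingLevel]

    @property
    def groups_list(self) -> list[list[np.ndarray]]:
        return [lev.groups for lev in self.levels]


def build_graph_stack(g: BrainGraph, n_layers: int, signed_policy: str = "abs") -> GraphStack:
    """Propagation matrix at every depth plus the coarsening hierarchy."""
    levels = build_pooling_hierarchy(g, levels=n_layers, signed_policy=signed_policy)
    S_list = [propagation_matrix(g.adjacency, signed_policy=signed_policy)]
    for lev in levels[:-1]:
        S_list.append(propagation_matrix(lev.coarse_adjacency, signed_policy=signed_policy))
    return GraphStack(S_list=S_list, levels=levels)


# ---------------------------------------------------------------------------
# parameters


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape: tuple[int, ...]) -> np.ndarray:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def init_params(cfg: ModelConfig, seed: int) -> dict[str, np.ndarray]:
    """Glorot-uniform initialization from a seeded generator (reproducible)."""
    rng = np.random.default_rng(seed)
    h, d = cfg.bilstm_hidden, cfg.d_bands
    params: dict[str, np.ndarray] = {}
    for direction in ("fw", "bw"):
        params[f"lstm_{direction}_Wx"] = _glorot(rng, d, 4 * h, (d, 4 * h))
        params[f"lstm_{direction}_Wh"] = _glorot(rng, h, 4 * h, (h, 4 * h))
        params[f"lstm_{direction}_b"] = np.zeros(4 * h)
    d_in = 2 * h
    for l, d_out in enumerate(cfg.gcn_channels):
        params[f"gcn{l}_W"] = _glorot(rng, d_in, d_out, (d_in, d_out))
        d_in = d_out
    flat_dim = cfg.node_counts()[-1] * cfg.gcn_channels[-1]
    params["dense_W"] = _glorot(rng, flat_dim, cfg.n_classes, (flat_dim, cfg.n_classes))
    params["dense_b"] = np.zeros(cfg.n_classes)
    return params


# ---------------------------------------------------------------------------
# elementary blocks


def brelu(x: np.ndarray | float, cap: float = 6.0) -> np.ndarray | float:
    """Bounded rectified linear unit: min(max(x, 0), cap), elementwise."""
    if cap <= 0:
        raise ValueError("cap must be positive")
    return np.clip(x, 0.0, cap)


def gcn_layer(H: np.ndarray, S: np.ndarray, W: np.ndarray, activation=None) -> np.ndarray:
    """One graph convolution: activation(S @ H @ W).

    ``H`` may be (n, d_in) for a single sample or (B, n, d_in) batched; ``S``
    is (n, n) and ``W`` is (d_in, d_out).
    """
    H = np.asarray(H, dtype=np.float64)
    n = S.shape[0]
    if S.shape != (n, n) or H.shape[-2] != n or H.shape[-1] != W.shape[0]:
        raise ValueError(
            f"incompatible shapes: S {S.shape}, H {H.shape}, W {W.shape} "
            f"(need S (n,n), H (...,n,d_in), W (d_in,d_out))"
        )
    Z = S @ H @ W
    return Z if activation is None else activation(Z)


def spectral_pool(H: np.ndarray, level: PoolingLevel, reducer: str = "max") -> np.ndarray:
    """Coarsen node features: each group of (at most two) nodes becomes one.

    ``H`` is (n_fine, d) or (B, n_fine, d); the coarse feature is the
    elementwise max (default) or mean over the group's rows.
    """
    H = np.asarray(H, dtype=np.float64)
    single = H.ndim == 2
    if single:
        H = H[None]
    if H.shape[1] != level.n_fine:
        raise ValueError(f"H has {H.shape[1]} nodes but the pooling level expects {level.n_fine}")
    out, _ = _pool_forward(H, level.groups, reducer)
    return out[0] if single else out


def _pool_forward(H: np.ndarray, groups: list[np.ndarray], reducer: str):
    B, _, dft = H.shape
    nc = len(groups)
    out = np.empty((B, nc, dft))
    argidx = np.empty((B, nc, dft), dtype=np.int64) if reducer == "max" else None
    for ci, g in enumerate(groups):
        sub = H[:, g, :]
        if reducer == "max":
            am = sub.argmax(axis=1)
            out[:, ci, :] = np.take_along_axis(sub, am[:, None, :], axis=1)[:, 0, :]
            argidx[:, ci, :] = g[am]
        elif reducer == "mean":
            out[:, ci, :] = sub.mean(axis=1)
        else:
            raise ValueError(f"unknown reducer {reducer!r}; use 'max' or 'mean'")
    return out, argidx


def _pool_backward(dOut: np.ndarray, groups: list[np.ndarray], argidx, n_fine: int, reducer: str):
    B, _, dft = dOut.shape
    dH = np.zeros((B, n_fine, dft))
    if reducer == "max":
        b_idx = np.arange(B)[:, None, None]
        f_idx = np.arange(dft)[None, None, :]
        np.add.at(dH, (np.broadcast_to(b_idx, argidx.shape), argidx,
                       np.broadcast_to(f_idx, argidx.shape)), dOut)
    else:
        for ci, g in enumerate(groups):
            dH[:, g, :] += dOut[:, ci:ci + 1, :] / len(g)
    return dH


# ---------------------------------------------------------------------------
# BiLSTM

def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _lstm_forward(x: np.ndarray, Wx: np.ndarray, Wh: np.ndarray, b: np.ndarray):
    """Run an LSTM over (batch, T, d); return the final hidden state and cache.

    Gate layout along the 4h axis: input, forget, candidate, output.
    """
    batch, T, _ = x.shape
    h = Wh.shape[0]
    h_t = np.zeros((batch, h))
    c_t = np.zeros((batch, h))
    cache = []
    for step in range(T):
        xt = x[:, step, :]
        z = xt @ Wx + h_t @ Wh + b
        i = _sigmoid(z[:, :h])
        f = _sigmoid(z[:, h:2 * h])
        g = np.tanh(z[:, 2 * h:3 * h])
        o = _sigmoid(z[:, 3 * h:])
        c_new = f * c_t + i * g
        tc = np.tanh(c_new)
        cache.append((xt, h_t, c_t, i, f, g, o, tc))
        h_t = o * tc
        c_t = c_new
    return h_t, cache


def _lstm_backward(dh_last: np.ndarray, cache, Wx: np.ndarray, Wh: np.ndarray):
    """Backpropagation through time from the gradient at the final hidden state."""
    dWx = np.zeros_like(Wx)
    dWh = np.zeros_like(Wh)
    db = np.zeros(Wx.shape[1])
    dh = dh_last
    dc = np.zeros_like(dh_last)
    for xt, h_prev, c_prev, i, f, g, o, tc in reversed(cache):
        do = dh * tc
        dc = dc + dh * o * (1.0 - tc * tc)
        di = dc * g
        df = dc * c_prev
        dg = dc * i
        dz = np.concatenate(
            [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g), do * o * (1 - o)], axis=1
        )
        dWx += xt.T @ dz
        dWh += h_prev.T @ dz
        db += dz.sum(axis=0)
        dh = dz @ Wh.T
        dc = dc * f
    return dWx, dWh, db


def bilstm_encode(X: np.ndarray, params: dict[str, np.ndarray], return_cache: bool = False):
    """Encode per-channel band-feature sequences into graph node features.

    ``X`` is (n, t, d) for one segment or (B, n, t, d) batched.  One
    shared-weight BiLSTM runs over every channel's sequence; the output per
    channel concatenates the final forward and final backward hidden states,
    giving H of shape (..., n, 2 * hidden).
    """
    X = np.asarray(X, dtype=np.float64)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in the feature tensor")
    single = X.ndim == 3
    if single:
        X = X[None]
    B, n, t, d = X.shape
    seq = X.reshape(B * n, t, d)
    h_fw, cache_fw = _lstm_forward(seq, params["lstm_fw_Wx"], params["lstm_fw_Wh"], params["lstm_fw_b"])
    h_bw, cache_bw = _lstm_forward(seq[:, ::-1, :], params["lstm_bw_Wx"], params["lstm_bw_Wh"], params["lstm_bw_b"])
    H = np.concatenate([h_fw, h_bw], axis=1).reshape(B, n, -1)
    if single:
        H = H[0]
    if return_cache:
        return H, (cache_fw, cache_bw)
    return H


# ---------------------------------------------------------------------------
# full network


def _forward_full(X, stack: GraphStack, params, cfg: ModelConfig, train: bool, rng):
    """Forward pass with every intermediate cached for backprop."""
    single = np.asarray(X).ndim == 3
    Xb = np.asarray(X, dtype=np.float64)
    if single:
        Xb = Xb[None]
    B = Xb.shape[0]
    H, lstm_caches = bilstm_encode(Xb, params, return_cache=True)
    cache = {"lstm": lstm_caches, "gcn": []}
    for l in range(cfg.n_gcn_layers):
        S = stack.S_list[l]
        W = params[f"gcn{l}_W"]
        SH = S @ H
        Z = SH @ W
        A = np.clip(Z, 0.0, cfg.brelu_cap)
        groups = stack.levels[l].groups
        P, argidx = _pool_forward(A, groups, cfg.pool_reducer)
        cache["gcn"].append({"H_in": H, "SH": SH, "Z": Z, "argidx": argidx,
                             "groups": groups, "n_fine": A.shape[1]})
        H = P
    flat = H.reshape(B, -1)
    if train and cfg.dropout > 0:
        if rng is None:
            raise ValueError("training-mode forward with dropout needs an rng")
        mask = (rng.random(flat.shape) >= cfg.dropout) / (1.0 - cfg.dropout)
    else:
        mask = None
    dropped = flat if mask is None else flat * mask
    logits = dropped @ params["dense_W"] + params["dense_b"]
    logits = logits - logits.max(axis=1, keepdims=True)
    expl = np.exp(logits)
    probs = expl / expl.sum(axis=1, keepdims=True)
    cache.update({"flat": flat, "mask": mask, "dropped": dropped, "probs": probs,
                  "single": single, "B": B})
    return probs, cache


def forward(X, stack: GraphStack, params, cfg: ModelConfig, train: bool = False, rng=None) -> np.ndarray:
    """Class-probability vector(s) for one segment (n,t,d) or a batch (B,n,t,d).

    In evaluation mode (default) dropout is disabled and the output is a
    deterministic function of the inputs and parameters.
    """
    probs, cache = _forward_full(X, stack, params, cfg, train, rng)
    return probs[0] if cache["single"] else probs


def loss(probs: np.ndarray, one_hot: np.ndarray, params: dict[str, np.ndarray], l2_lambda: float) -> float:
    """Mean cross-entropy plus L2 penalty over all weights and biases.

    loss = mean_batch( -sum_c y_c log p_c ) + lambda * sum_theta theta^2,
    with log probabilities clamped at 1e-12 to keep perfect predictions finite.
    """
    probs = np.atleast_2d(np.asarray(probs, dtype=np.float64))
    one_hot = np.atleast_2d(np.asarray(one_hot, dtype=np.float64))
    if l2_lambda < 0:
        raise ValueError("l2_lambda must be non-negative")
    data = -np.sum(one_hot * np.log(np.clip(probs, _EPS, None)), axis=1).mean()
    reg = sum(float(np.sum(p * p)) for p in params.values())
    return float(data + l2_lambda * reg)


def loss_and_grads(X, y, stack: GraphStack, params, cfg: ModelConfig, rng=None,
                   train: bool = True, class_weight: np.ndarray | None = None):
    """Loss and analytic gradients for a labeled batch.

    ``y`` holds integer class labels (0/1).  Returns (loss_value, grads) with
    ``grads`` keyed like ``params``.  The L2 term contributes 2*lambda*theta
    to every gradient.  ``class_weight`` optionally reweights each sample's
    cross-entropy by its class (e.g. inverse class frequency); weights are
    renormalized to mean 1 over the batch.
    """
    y = np.asarray(y, dtype=np.int64).ravel()
    probs, cache = _forward_full(X, stack, params, cfg, train=train, rng=rng)
    B = cache["B"]
    one_hot = np.zeros_like(probs)
    one_hot[np.arange(B), y] = 1.0
    if class_weight is not None:
        w = np.asarray(class_weight, dtype=np.float64)[y]
        w = w * (B / w.sum())
    else:
        w = np.ones(B)
    data = -(w * np.sum(one_hot * np.log(np.clip(probs, _EPS, None)), axis=1)).mean()
    reg = sum(float(np.sum(p * p)) for p in params.values())
    loss_val = float(data + cfg.l2_lambda * reg)

    grads = {k: None for k in params}
    dlogits = w[:, None] * (probs - one_hot) / B
    grads["dense_W"] = cache["dropped"].T @ dlogits
    grads["dense_b"] = dlogits.sum(axis=0)
    dflat = dlogits @ params["dense_W"].T
    if cache["mask"] is not None:
        dflat = dflat * cache["mask"]
    n_last = cfg.node_counts()[-1]
    dH = dflat.reshape(B, n_last, cfg.gcn_channels[-1])

    for l in range(cfg.n_gcn_layers - 1, -1, -1):
        c = cache["gcn"][l]
        dA = _pool_backward(dH, c["groups"], c["argidx"], c["n_fine"], cfg.pool_reducer)
        dZ = dA * ((c["Z"] > 0) & (c["Z"] < cfg.brelu_cap))
        W = params[f"gcn{l}_W"]
        grads[f"gcn{l}_W"] = np.einsum("bni,bnj->ij", c["SH"], dZ)
        S = stack.S_list[l]
        dH = (S.T @ dZ) @ W.T

    # into the BiLSTM: dH is (B, n, 2h) at the finest level
    h = cfg.bilstm_hidden
    dh_cat = dH.reshape(B * cfg.n_channels, 2 * h)
    cache_fw, cache_bw = cache["lstm"]
    dWx, dWh, db = _lstm_backward(dh_cat[:, :h], cache_fw, params["lstm_fw_Wx"], params["lstm_fw_Wh"])
    grads["lstm_fw_Wx"], grads["lstm_fw_Wh"], grads["lstm_fw_b"] = dWx, dWh, db
    dWx, dWh, db = _lstm_backward(dh_cat[:, h:], cache_bw, params["lstm_bw_Wx"], params["lstm_bw_Wh"])
    grads["lstm_bw_Wx"], grads["lstm_bw_Wh"], grads["lstm_bw_b"] = dWx, dWh, db

    lam2 = 2.0 * cfg.l2_lambda
    for k in params:
        grads[k] = grads[k] + lam2 * params[k]
    return loss_val, grads
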