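"""The attention-based CNN-BiGRU yield regressor.

Architecture (full variant): a stack of valid 1D convolutions with ReLU over
the 5-stage sequence (the first layer is length-preserving by default), a
16-unit dense bottleneck applied per timestep, two stacked bidirectional GRU
layers whose forward/backward states are combined by learned per-feature
weights, softmax attention pooling over timesteps, and a linear head mapping
the attentive context to yield in t/ha.

The 15 dynamic variables are the sequence channels; the 9 periodic variables
are broadcast to every timestep, giving 24 input channels over 5 steps.

Ablation flags in :class:`~maizeyield.config.NetworkConfig` yield the
variants used by the ablation harness: ``no_cnn`` feeds inputs straight into
the BiGRU, ``drop_one_gru_layer`` removes one bidirectional layer, and
``no_attention`` replaces the attentive context with the last combined
hidden state.
"""

from __future__ import annotations

import io
import json

import numpy as np

from .autodiff import Adam, Tensor, concat, softmax, stack
from .config import NetworkConfig
from .panel import FeaturePanel, N_STAGES


class ShapeError(ValueError):
    """Input sequence is too short for the configured conv stack."""


class DivergenceError(RuntimeError):
    """Training loss became non-finite."""

    def __init__(self, epoch: int):
        super().__init__(f"non-finite loss at epoch {epoch}")
        self.epoch = epoch


# -- parameters ----------------------------------------------------------------


def _glorot(rng, shape, fan_in, fan_out):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def gru_input_dim(config: NetworkConfig) -> int:
    return config.input_channels if config.no_cnn else config.bottleneck_units


def n_gru_layers(config: NetworkConfig) -> int:
    return config.gru_layers - 1 if config.drop_one_gru_layer else config.gru_layers


def combined_dim(config: NetworkConfig) -> int:
    return 2 * config.gru_hidden if config.bigru_combine == "concat" else config.gru_hidden


def init_params(config: NetworkConfig, rng=None) -> dict[str, Tensor]:
    """Seeded parameter tree for the configured variant.

    Weight matrices use uniform Glorot fan-based initialization; biases start
    at zero; the bidirectional combination weights start at alpha=beta=0.5.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    K = config.kernel_size
    p: dict[str, np.ndarray] = {}
    if not config.no_cnn:
        c_in = config.input_channels
        for k, f in enumerate(config.conv_filters):
            p[f"conv{k}_W"] = _glorot(rng, (K, c_in, f), K * c_in, f)
            p[f"conv{k}_b"] = np.zeros(f)
            c_in = f
        p["dense_W"] = _glorot(rng, (c_in, config.bottleneck_units),
                               c_in, config.bottleneck_units)
        p["dense_b"] = np.zeros(config.bottleneck_units)
    d_in = gru_input_dim(config)
    H = config.gru_hidden
    for layer in range(n_gru_layers(config)):
        for direction in ("fw", "bw"):
            pref = f"gru{layer}_{direction}"
            for gate in ("z", "r", "h"):
                p[f"{pref}_W{gate}"] = _glorot(rng, (d_in, H), d_in, H)
                p[f"{pref}_U{gate}"] = _glorot(rng, (H, H), H, H)
                p[f"{pref}_b{gate}"] = np.zeros(H)
        if config.bigru_combine == "weighted":
            p[f"gru{layer}_alpha"] = np.full(H, 0.5)
            p[f"gru{layer}_beta"] = np.full(H, 0.5)
            p[f"gru{layer}_bcomb"] = np.zeros(H)
        d_in = combined_dim(config)
    D = combined_dim(config)
    if not config.no_attention:
        p["attn_Wd"] = _glorot(rng, (D, D), D, D)
        p["attn_b"] = np.zeros(D)
        p["attn_u"] = _glorot(rng, (D, 1), D, 1)
    p["head_W"] = _glorot(rng, (D, 1), D, 1)
    p["head_b"] = np.zeros(1)
    return {k: Tensor(v, requires_grad=True) for k, v in p.items()}


def build_variant(config: NetworkConfig, rng=None) -> dict[str, Tensor]:
    """Alias of :func:`init_params`; the config's ablation flags select the
    model graph (validated by NetworkConfig itself)."""
    return init_params(config, rng=rng)


def count_parameters(params: dict[str, Tensor]) -> int:
    return sum(p.data.size for p in params.values())


# -- forward graph -------------------------------------------------------------


def conv_output_length(config: NetworkConfig) -> int:
    n_valid = len(config.conv_filters) - (1 if config.conv_same_pad_first else 0)
    return config.sequence_length - n_valid * (config.kernel_size - 1)


def _conv1d(x: Tensor, W: Tensor, b: Tensor, same_pad: bool) -> Tensor:
    """Valid 1D convolution over axis 1 of (batch, length, channels)."""
    K = W.data.shape[0]
    if same_pad and K > 1:
        zeros = Tensor(np.zeros((x.shape[0], K - 1, x.shape[2])))
        x = concat([x, zeros], axis=1)
    L_out = x.shape[1] - K + 1
    out = x[:, 0:L_out, :] @ W[0]
    for tap in range(1, K):
        out = out + x[:, tap:tap + L_out, :] @ W[tap]
    return out + b


def _gru_direction(seq: Tensor, params, prefix: str, reverse: bool) -> Tensor:
    """Run one GRU direction over (batch, T, features); returns (batch, T, H).

    Update gate  z_t = sigmoid(W_z x_t + U_z h_{t-1} + b_z)
    Reset gate   r_t = sigmoid(W_r x_t + U_r h_{t-1} + b_r)
    Candidate    c_t = tanh(W_h x_t + r_t * (U_h h_{t-1}) + b_h)
    Hidden       h_t = (1 - z_t) * h_{t-1} + z_t * c_t
    """
    B, T, _ = seq.shape
    H = params[f"{prefix}_Uz"].shape[0]
    h = Tensor(np.zeros((B, H)))
    # input-side projections for all steps at once (the recurrent side must
    # stay in the loop)
    xz = seq @ params[f"{prefix}_Wz"] + params[f"{prefix}_bz"]
    xr = seq @ params[f"{prefix}_Wr"] + params[f"{prefix}_br"]
    xh = seq @ params[f"{prefix}_Wh"] + params[f"{prefix}_bh"]
    outs = []
    steps = range(T - 1, -1, -1) if reverse else range(T)
    for t in steps:
        z = (xz[:, t, :] + h @ params[f"{prefix}_Uz"]).sigmoid()
        r = (xr[:, t, :] + h @ params[f"{prefix}_Ur"]).sigmoid()
        c = (xh[:, t, :] + r * (h @ params[f"{prefix}_Uh"])).tanh()
        h = (1.0 - z) * h + z * c
        outs.append(h)
    if reverse:
        outs.reverse()
    return stack(outs, axis=1)


def _bigru_layer(seq: Tensor, params, layer: int, config: NetworkConfig) -> Tensor:
    fw = _gru_direction(seq, params, f"gru{layer}_fw", reverse=False)
    bw = _gru_direction(seq, params, f"gru{layer}_bw", reverse=True)
    if config.bigru_combine == "concat":
        return concat([fw, bw], axis=2)
    return (params[f"gru{layer}_alpha"] * fw + params[f"gru{layer}_beta"] * bw
            + params[f"gru{layer}_bcomb"])


def _attention(seq: Tensor, params) -> tuple[Tensor, Tensor]:
    """Softmax attention pooling: returns (context (B, D), weights (B, T))."""
    mu = (seq @ params["attn_Wd"] + params["attn_b"]).tanh()
    scores = mu @ params["attn_u"]           # (B, T, 1)
    a = softmax(scores, axis=1)
    context = (a * seq).sum(axis=1)
    return context, a.reshape(a.shape[0], a.shape[1])


def forward_graph(params: dict[str, Tensor], config: NetworkConfig,
                  X: np.ndarray) -> Tensor:
    """Differentiable forward pass over a (batch, T, channels) input block."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 3 or X.shape[2] != config.input_channels:
        raise ShapeError(
            f"expected input (batch, {config.sequence_length}, "
            f"{config.input_channels}), got {X.shape}"
        )
    h = Tensor(X)
    if not config.no_cnn:
        n_valid = len(config.conv_filters) - (1 if config.conv_same_pad_first else 0)
        min_len = n_valid * (config.kernel_size - 1) + 1
        if X.shape[1] < min_len:
            raise ShapeError(
                f"sequence length {X.shape[1]} too short; conv stack needs >= {min_len}"
            )
        for k in range(len(config.conv_filters)):
            same = config.conv_same_pad_first and k == 0
            h = _conv1d(h, params[f"conv{k}_W"], params[f"conv{k}_b"], same).relu()
        h = (h @ params["dense_W"] + params["dense_b"]).relu()
    for layer in range(n_gru_layers(config)):
        h = _bigru_layer(h, params, layer, config)
    if config.no_attention:
        context = h[:, h.shape[1] - 1, :]
    else:
        context, _ = _attention(h, params)
    out = context @ params["head_W"] + params["head_b"]
    return out.reshape(out.shape[0])


def forward_batch(params, config: NetworkConfig, X: np.ndarray) -> np.ndarray:
    """Forward pass returning plain predictions."""
    return forward_graph(params, config, X).data.copy()


def attention_weights(params, config: NetworkConfig, X: np.ndarray) -> np.ndarray:
    """Per-record attention weights over the (post-conv) timesteps."""
    if config.no_attention:
        raise ValueError("variant has no attention layer")
    X = np.asarray(X, dtype=float)
    h = Tensor(X)
    if not config.no_cnn:
        for k in range(len(config.conv_filters)):
            same = config.conv_same_pad_first and k == 0
            h = _conv1d(h, params[f"conv{k}_W"], params[f"conv{k}_b"], same).relu()
        h = (h @ params["dense_W"] + params["dense_b"]).relu()
    for layer in range(n_gru_layers(config)):
        h = _bigru_layer(h, params, layer, config)
    _, a = _attention(h, params)
    return a.data.copy()


# -- functional single-step helpers (public, numpy) ----------------------------


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def gru_cell_step(x_t, h_prev, p: dict) -> np.ndarray:
    """One GRU cell step on plain arrays; `p` holds Wz,Uz,bz,Wr,Ur,br,Wh,Uh,bh."""
    x_t = np.asarray(x_t, dtype=float)
    h_prev = np.asarray(h_prev, dtype=float)
    z = _sigmoid(x_t @ p["Wz"] + h_prev @ p["Uz"] + p["bz"])
    r = _sigmoid(x_t @ p["Wr"] + h_prev @ p["Ur"] + p["br"])
    c = np.tanh(x_t @ p["Wh"] + r * (h_prev @ p["Uh"]) + p["bh"])
    return (1.0 - z) * h_prev + z * c


def attention_pool(h_seq, Wd, b, u) -> tuple[np.ndarray, np.ndarray]:
    """Attention pooling on a plain (T, d) hidden sequence.

    Returns (context (d,), weights (T,)); weights are a softmax over the
    tanh-projected scores and sum to one.
    """
    h_seq = np.asarray(h_seq, dtype=float)
    mu = np.tanh(h_seq @ np.asarray(Wd) + np.asarray(b))
    scores = mu @ np.asarray(u, dtype=float).reshape(-1)
    e = np.exp(scores - scores.max())
    a = e / e.sum()
    return a @ h_seq, a


# -- training ------------------------------------------------------------------


def panel_to_inputs(panel: FeaturePanel) -> np.ndarray:
    """(n, 5, 24) network input: dynamic channels + broadcast periodic."""
    per = np.repeat(panel.periodic[:, None, :], N_STAGES, axis=1)
    return np.concatenate([panel.dynamic, per], axis=2)


def _clip_gradients(params: dict[str, Tensor], max_norm: float) -> None:
    total = np.sqrt(sum(float((p.grad**2).sum())
                        for p in params.values() if p.grad is not None))
    if total > max_norm:
        scale = max_norm / total
        for p in params.values():
            if p.grad is not None:
                p.grad *= scale


def _loss_graph(pred: Tensor, y: np.ndarray, kind: str) -> Tensor:
    d = pred - Tensor(y)
    if kind == "mae":
        return d.abs().mean()
    if kind == "mse":
        return (d * d).mean()
    raise ValueError(f"unknown loss {kind!r}")


def train(
    panel_train: FeaturePanel,
    panel_val: FeaturePanel | None,
    config: NetworkConfig,
) -> tuple[dict[str, Tensor], dict[str, list]]:
    """Train the configured variant with Adam on (by default) MAE loss.

    Expects panels with already-normalized features and observed yields.
    Returns the final-epoch parameters and a per-epoch history of train/val
    loss (validation loss uses the same loss kind, computed full-batch).
    """
    if panel_train is None or len(panel_train) == 0:
        raise ValueError("empty training set")
    X = panel_to_inputs(panel_train)
    y = panel_train.yields
    if np.isnan(y).any():
        raise ValueError("training records must have observed yields")
    X_val = y_val = None
    if panel_val is not None and len(panel_val):
        X_val, y_val = panel_to_inputs(panel_val), panel_val.yields
    rng = np.random.default_rng(config.seed)
    params = init_params(config, rng=rng)
    opt = Adam(params.values(), lr=config.learning_rate)
    n = len(y)
    history: dict[str, list] = {"train_loss": [], "val_loss": []}
    for epoch in range(config.epochs):
        opt.lr = config.learning_rate * config.lr_decay**epoch
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            pred = forward_graph(params, config, X[idx])
            loss = _loss_graph(pred, y[idx], config.loss)
            if not np.isfinite(loss.data):
                raise DivergenceError(epoch)
            opt.zero_grad()
            loss.backward()
            if config.grad_clip_norm is not None:
                _clip_gradients(params, config.grad_clip_norm)
            opt.step()
            losses.append(float(loss.data))
        history["train_loss"].append(float(np.mean(losses)))
        if X_val is not None:
            vp = forward_batch(params, config, X_val)
            vd = vp - y_val
            vl = np.abs(vd).mean() if config.loss == "mae" else (vd**2).mean()
            history["val_loss"].append(float(vl))
        else:
            history["val_loss"].append(float("nan"))
    return params, history


def predict(params, config: NetworkConfig, panel: FeaturePanel,
            chunk: int = 2048) -> np.ndarray:
    """Vectorized, order-preserving prediction over a panel."""
    X = panel_to_inputs(panel)
    return np.concatenate([
        forward_batch(params, config, X[i:i + chunk])
        for i in range(0, len(X), chunk)
    ]) if len(X) else np.empty(0)


# -- serialization -------------------------------------------------------------

_FORMAT_VERSION = 1


def save_model(path, params: dict[str, Tensor], config: NetworkConfig) -> None:
    """Single-archive serialization with the config embedded."""
    meta = json.dumps({"version": _FORMAT_VERSION,
                       "config": {**config.__dict__,
                                  "conv_filters": list(config.conv_filters)}})
    arrays = {k: v.data for k, v in params.items()}
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)


def load_model(path) -> tuple[dict[str, Tensor], NetworkConfig]:
    with np.load(path if isinstance(path, io.IOBase) else str(path)) as zf:
        meta = json.loads(bytes(zf["__meta__"]).decode())
        if meta.get("version") != _FORMAT_VERSION:
            raise ValueError(f"unsupported model archive version {meta.get('version')}")
        config = NetworkConfig(**meta["config"])
        params = {k: Tensor(zf[k], requires_grad=True)
                  for k in zf.files if k != "__meta__"}
    return params, config
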