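"""Independent, loop-based re-implementation of the network forward pass.

This module deliberately avoids the autodiff engine and all vectorized
shortcuts: every convolution, gate, combination and attention step is written
as explicit Python loops over indices, directly transcribing the layer
equations.  It exists solely as a cross-check oracle for the vectorized
implementation in :mod:`maizeyield.network` and is far too slow for real use.
"""

from __future__ import annotations

import math

from .config import NetworkConfig


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def _matvec(W, x):
    # W indexed [in][out]
    n_in = len(W)
    n_out = len(W[0])
    return [sum(W[i][j] * x[i] for i in range(n_in)) for j in range(n_out)]


def _conv_layer(seq, W, b, same_pad: bool):
    """seq: list over time of channel lists; W[tap][in][out]; returns ReLU maps."""
    K = len(W)
    n_in = len(W[0])
    n_out = len(W[0][0])
    if same_pad and K > 1:
        seq = seq + [[0.0] * n_in for _ in range(K - 1)]
    L_out = len(seq) - K + 1
    out = []
    for t in range(L_out):
        row = []
        for j in range(n_out):
            acc = b[j]
            for tap in range(K):
                for i in range(n_in):
                    acc += seq[t + tap][i] * W[tap][i][j]
            row.append(max(0.0, acc))
        out.append(row)
    return out


def _gru_pass(seq, p, prefix, reverse: bool):
    H = len(p[f"{prefix}_bz"])
    h = [0.0] * H
    order = range(len(seq) - 1, -1, -1) if reverse else range(len(seq))
    outs = {}
    for t in order:
        x = seq[t]
        zx = _matvec(p[f"{prefix}_Wz"], x)
        zh = _matvec(p[f"{prefix}_Uz"], h)
        rx = _matvec(p[f"{prefix}_Wr"], x)
        rh = _matvec(p[f"{prefix}_Ur"], h)
        cx = _matvec(p[f"{prefix}_Wh"], x)
        ch = _matvec(p[f"{prefix}_Uh"], h)
        h_new = []
        for j in range(H):
            z = _sigmoid(zx[j] + zh[j] + p[f"{prefix}_bz"][j])
            r = _sigmoid(rx[j] + rh[j] + p[f"{prefix}_br"][j])
            c = math.tanh(cx[j] + r * ch[j] + p[f"{prefix}_bh"][j])
            h_new.append((1.0 - z) * h[j] + z * c)
        h = h_new
        outs[t] = h
    return [outs[t] for t in range(len(seq))]


def forward_single(params, config: NetworkConfig, x) -> float:
    """Forward pass for one record; `x` is a (T, channels) nested sequence,
    `params` a name->array mapping (arrays are indexed, never vectorized)."""
    p = {k: (v.data if hasattr(v, "data") else v).tolist() for k, v in params.items()}
    seq = [list(map(float, row)) for row in x]
    if not config.no_cnn:
        for k in range(len(config.conv_filters)):
            same = config.conv_same_pad_first and k == 0
            seq = _conv_layer(seq, p[f"conv{k}_W"], p[f"conv{k}_b"], same)
        seq = [
            [max(0.0, v + p["dense_b"][j])
             for j, v in enumerate(_matvec(p["dense_W"], row))]
            for row in seq
        ]
    n_layers = config.gru_layers - 1 if config.drop_one_gru_layer else config.gru_layers
    for layer in range(n_layers):
        fw = _gru_pass(seq, p, f"gru{layer}_fw", reverse=False)
        bw = _gru_pass(seq, p, f"gru{layer}_bw", reverse=True)
        if config.bigru_combine == "concat":
            seq = [fw[t] + bw[t] for t in range(len(seq))]
        else:
            a, b_, bias = p[f"gru{layer}_alpha"], p[f"gru{layer}_beta"], p[f"gru{layer}_bcomb"]
            seq = [
                [a[j] * fw[t][j] + b_[j] * bw[t][j] + bias[j]
                 for j in range(len(a))]
                for t in range(len(seq))
            ]
    if config.no_attention:
        context = seq[-1]
    else:
        scores = []
        for row in seq:
            mu = [math.tanh(v + p["attn_b"][j])
                  for j, v in enumerate(_matvec(p["attn_Wd"], row))]
            scores.append(sum(mu[j] * p["attn_u"][j][0] for j in range(len(mu))))
        m = max(scores)
        expo = [math.exp(s - m) for s in scores]
        total = sum(expo)
        weights = [e / total for e in expo]
        D = len(seq[0])
        context = [sum(weights[t] * seq[t][j] for t in range(len(seq)))
                   for j in range(D)]
    out = p["head_b"][0]
    for j in range(len(context)):
        out += context[j] * p["head_W"][j][0]
    return out
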