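"""Brute-force dense recomputations of the network's building blocks.

Plain-loop numpy implementations, independent of the autodiff layers,
used to verify the vectorized forward passes element by element.
"""

import numpy as np


def gcn_static_oracle(x, a, mu):
    """Per-frame relu(A · X_t · mu) with X_t the (V, C) frame matrix."""
    B, C, T, V = x.shape
    out = np.zeros((B, mu.shape[1], T, V))
    for b in range(B):
        for t in range(T):
            frame = x[b, :, t, :].T              # (V, C)
            out[b, :, t, :] = np.maximum(a @ frame @ mu, 0.0).T
    return out


def gcn_dynamic_oracle(x, gd, mu):
    """Per-frame Gd · X_t · mu, no activation; gd (V,V) or (B,T,V,V)."""
    B, C, T, V = x.shape
    out = np.zeros((B, mu.shape[1], T, V))
    for b in range(B):
        for t in range(T):
            g = gd if gd.ndim == 2 else gd[b, t]
            out[b, :, t, :] = (g @ x[b, :, t, :].T @ mu).T
    return out


def _conv1x1(x, w, b=None):
    out = np.einsum("bctv,co->botv", x, w)
    if b is not None:
        out += b[None, :, None, None]
    return out


def _temporal_conv(x, w, b, dilation):
    """3x1 temporal conv, symmetric zero padding, by explicit loops."""
    B, C, T, V = x.shape
    k, _, c_out = w.shape
    pad = dilation * (k - 1) // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (0, 0)))
    out = np.zeros((B, c_out, T, V))
    for tap in range(k):
        out += np.einsum("bctv,co->botv",
                         xp[:, :, tap * dilation: tap * dilation + T, :],
                         w[tap])
    return out + b[None, :, None, None]


def _temporal_maxpool3(x):
    B, C, T, V = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (0, 0)),
                constant_values=-np.inf)
    return np.max(np.stack([xp[:, :, s:s + T, :] for s in range(3)]), axis=0)


def _batchnorm_train(x, gamma, beta, eps=1e-5):
    axes = tuple(i for i in range(x.ndim) if i != 1)
    mean = x.mean(axis=axes, keepdims=True)
    var = x.var(axis=axes, keepdims=True)
    shape = tuple(-1 if i == 1 else 1 for i in range(x.ndim))
    return ((x - mean) / np.sqrt(var + eps) * gamma.reshape(shape)
            + beta.reshape(shape))


def mstcn_oracle(layer, x):
    """Dense recomputation of MultiScaleTCN.forward in training mode."""
    outs = []
    for bott, conv in zip(layer.dilated_in, layer.dilated):
        y = np.maximum(_conv1x1(x, bott.lin.weight.data,
                                bott.lin.bias.data), 0.0)
        outs.append(_temporal_conv(y, conv.weight.data, conv.bias.data,
                                   conv.dilation))
    outs.append(_conv1x1(x, layer.frame_conv.lin.weight.data,
                         layer.frame_conv.lin.bias.data))
    pooled_in = np.maximum(_conv1x1(x, layer.pool_in.lin.weight.data,
                                    layer.pool_in.lin.bias.data), 0.0)
    outs.append(_temporal_maxpool3(pooled_in))
    outs.append(_conv1x1(x, layer.res_branch.lin.weight.data,
                         layer.res_branch.lin.bias.data))
    merged = _batchnorm_train(np.concatenate(outs, axis=1),
                              layer.bn.gamma.data, layer.bn.beta.data,
                              layer.bn.eps)
    res = x if layer.module_res is None else _conv1x1(
        x, layer.module_res.lin.weight.data)
    return np.maximum(merged + res, 0.0)


def attention_oracle(layer, x):
    """Dense recomputation of InterTemporalAttention.forward (training)."""
    B, C, T, V = x.shape
    g_elec = x.max(axis=2)                       # (B, C, V)
    g_frame = x.max(axis=3)                      # (B, C, T)
    compact = np.concatenate([g_elec, g_frame], axis=2)   # (B, C, V+T)
    w, b = layer.shared.weight.data, layer.shared.bias.data
    pre = np.einsum("bcp,ch->bhp", compact, w) + b[None, :, None]
    bn = _batchnorm_train(pre, layer.bn.gamma.data, layer.bn.beta.data,
                          layer.bn.eps)
    squeezed = bn * (1.0 / (1.0 + np.exp(-bn)))   # swish
    elec_part, frame_part = squeezed[:, :, :V], squeezed[:, :, V:]

    def fc_sigmoid(part, lin):
        pre = (np.einsum("bhp,hc->bcp", part, lin.weight.data)
               + lin.bias.data[None, :, None])
        return 1.0 / (1.0 + np.exp(-pre))

    elec_scores = fc_sigmoid(elec_part, layer.elec_fc)     # (B, C, V)
    frame_scores = fc_sigmoid(frame_part, layer.frame_fc)  # (B, C, T)
    att = frame_scores[:, :, :, None] * elec_scores[:, :, None, :]
    return x * att
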