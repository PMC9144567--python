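"""The attention-guided spatiotemporal GCN for 5-class sleep staging.

The model consumes temporal-context blocks of differential-entropy
features, laid out as (batch, channels C, frames T, electrodes V), and
stacks ST-GCN modules.  Each module:

1. aggregates spatially with two graph-convolution branches — a static
   branch over the normalized physical adjacency plus a trainable mask,
   λ((Gp_norm+Gm)·X_t·μ), and a dynamic branch over a per-sample graph
   computed from the module input, Gd·X_t·μ′ — fused as
   ``dynamic + φ·static``;
2. aggregates temporally with a seven-branch multi-scale temporal
   convolution (four dilated 3×1 convs behind 1×1 bottlenecks, a plain
   1×1 conv, a 3×1 max-pool branch, and a residual branch);
3. reweights the result with an inter-temporal attention block that
   max-pools over frames and electrodes, squeezes the pooled descriptors
   through a shared FC (Swish), re-expands them with two independent FCs
   (sigmoid), and applies their per-channel outer product to the input.

A global-average-pool + linear + softmax head scores the five AASM
stages of the final epoch in the context window.

Everything is built on the package's own autodiff tensors, so each
operation is differentiable end to end; gradients are validated against
finite differences in the tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .autodiff import Tensor, concatenate, maximum_over, pairwise_edge_scores
from .graph import SleepGraph, normalize_adjacency

__all__ = [
    "NetworkConfig",
    "SleepStageNetwork",
    "gcn_static",
    "gcn_dynamic",
    "gcn_fuse",
    "contexts_to_input",
    "save_checkpoint",
    "load_checkpoint",
]

STAGES = ("W", "N1", "N2", "N3", "R")


# ---------------------------------------------------------------------------
# functional graph-convolution primitives
# ---------------------------------------------------------------------------

def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))


def _channel_map(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Apply a (C_in, C_out) matrix along the channel axis of (..., C, T, V)."""
    xm = x.moveaxis(-3, -1)        # (..., T, V, C_in)
    out = xm @ w
    if b is not None:
        out = out + b
    return out.moveaxis(-1, -3)


def gcn_static(X, gp_norm, gm, mu, activation: bool = True):
    """Static-branch graph convolution λ((Gp_norm + Gm)·X_t·μ), per frame.

    ``X`` is (..., C_in, T, V); ``gp_norm`` and ``gm`` are (V, V); ``mu``
    is (C_in, C_out).  No bias.  λ is ReLU.
    """
    x, a = _as_tensor(X), _as_tensor(gp_norm) + _as_tensor(gm)
    mu = _as_tensor(mu)
    xm = x.moveaxis(-3, -1)              # (..., T, V, C_in)
    out = (a @ xm) @ mu                  # (V,V)@(...,T,V,C) broadcasts over T
    out = out.moveaxis(-1, -3)
    if activation:
        out = out.relu()
    return out if isinstance(X, Tensor) else out.data


def gcn_dynamic(X, gd, mu_prime):
    """Dynamic-branch graph convolution Gd·X_t·μ′, per frame, no activation.

    ``gd`` is (V, V) shared across frames or (..., T, V, V) per frame.
    """
    x, g, mu = _as_tensor(X), _as_tensor(gd), _as_tensor(mu_prime)
    xm = x.moveaxis(-3, -1)              # (..., T, V, C_in)
    out = ((g @ xm) @ mu).moveaxis(-1, -3)
    return out if isinstance(X, Tensor) else out.data


def gcn_fuse(static_out, dynamic_out, phi: float):
    """Weighted fusion: dynamic + φ·static, with φ ∈ [0, 1]."""
    if not 0.0 <= phi <= 1.0:
        raise ValueError(f"phi must lie in [0, 1], got {phi}")
    s, d = _as_tensor(static_out), _as_tensor(dynamic_out)
    out = d + float(phi) * s
    if isinstance(static_out, Tensor) or isinstance(dynamic_out, Tensor):
        return out
    return out.data


def contexts_to_input(values: np.ndarray) -> np.ndarray:
    """(batch, electrodes N, bands F, frames Tn) -> (batch, F, Tn, N)."""
    return np.ascontiguousarray(np.transpose(values, (0, 2, 3, 1)))


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class _Layer:
    """Base class: recursive parameter collection over attributes."""

    def parameters(self) -> list[Tensor]:
        out: list[Tensor] = []
        for value in vars(self).values():
            if isinstance(value, Tensor) and value.requires_grad:
                out.append(value)
            elif isinstance(value, _Layer):
                out.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, _Layer):
                        out.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        out.append(item)
        return out

    def state(self, prefix: str = "") -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor):
                out[key] = value.data
            elif isinstance(value, np.ndarray):
                out[key] = value
            elif isinstance(value, _Layer):
                out.update(value.state(key + "."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, _Layer):
                        out.update(item.state(f"{key}.{i}."))
        return out

    def load_state(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor) and key in state:
                value.data = np.array(state[key], dtype=float)
            elif isinstance(value, np.ndarray) and key in state:
                setattr(self, name, np.array(state[key], dtype=float))
            elif isinstance(value, _Layer):
                value.load_state(state, key + ".")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, _Layer):
                        item.load_state(state, f"{key}.{i}.")


class Linear(_Layer):
    """Affine map along the last axis."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 bias: bool = True):
        scale = np.sqrt(2.0 / c_in)
        self.weight = Tensor(rng.normal(0.0, scale, (c_in, c_out)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Conv1x1(_Layer):
    """Pointwise channel projection on (..., C, T, V)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 bias: bool = True):
        self.lin = Linear(c_in, c_out, rng, bias=bias)

    def forward(self, x: Tensor) -> Tensor:
        return _channel_map(x, self.lin.weight, self.lin.bias)


class TemporalConv(_Layer):
    """3×1 temporal convolution with dilation, zero-padded to keep T."""

    def __init__(self, c_in: int, c_out: int, dilation: int,
                 rng: np.random.Generator, kernel: int = 3):
        scale = np.sqrt(2.0 / (c_in * kernel))
        self.weight = Tensor(rng.normal(0.0, scale, (kernel, c_in, c_out)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)
        self.dilation = int(dilation)
        self.kernel = int(kernel)

    def forward(self, x: Tensor) -> Tensor:
        d, k = self.dilation, self.kernel
        pad = d * (k - 1) // 2
        xp = x.pad_axis(-2, pad, pad)          # pad the frame axis
        t_len = x.shape[-2]
        taps = []
        for tap in range(k):
            sl = [slice(None)] * xp.ndim
            sl[-2] = slice(tap * d, tap * d + t_len)
            taps.append(_channel_map(xp[tuple(sl)],
                                     self.weight[tap]))
        out = taps[0]
        for t in taps[1:]:
            out = out + t
        return out + self.bias.reshape((-1, 1, 1))


class TemporalMaxPool(_Layer):
    """3×1 temporal max-pool, stride 1, -inf padding keeps T."""

    def forward(self, x: Tensor) -> Tensor:
        xp = x.pad_axis(-2, 1, 1, value=-np.inf)
        t_len = x.shape[-2]
        shifts = []
        for tap in range(3):
            sl = [slice(None)] * xp.ndim
            sl[-2] = slice(tap, tap + t_len)
            shifts.append(xp[tuple(sl)])
        return maximum_over(shifts)


class BatchNorm(_Layer):
    """Batch normalization over all axes except the channel axis (dim 1)."""

    def __init__(self, channels: int, momentum: float = 0.1,
                 eps: float = 1e-5):
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor, training: bool) -> Tensor:
        axes = tuple(i for i in range(x.ndim) if i != 1)
        shape = tuple(1 if i != 1 else -1 for i in range(x.ndim))
        if training:
            mean = x.mean(axis=axes, keepdims=True)
            var = ((x - mean) ** 2.0).mean(axis=axes, keepdims=True)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean
                                 + m * mean.data.reshape(-1))
            self.running_var = ((1 - m) * self.running_var
                                + m * var.data.reshape(-1))
            xhat = (x - mean) * (var + self.eps) ** -0.5
        else:
            mean = Tensor(self.running_mean.reshape(shape))
            var = Tensor(self.running_var.reshape(shape))
            xhat = (x - mean) * (var + self.eps) ** -0.5
        return xhat * self.gamma.reshape(shape) + self.beta.reshape(shape)


def _dropout(x: Tensor, p: float, training: bool,
             rng: np.random.Generator | None) -> Tensor:
    if not training or p <= 0.0:
        return x
    if rng is None:
        raise ValueError("dropout in training mode needs an rng")
    mask = (rng.random(x.shape) >= p) / (1.0 - p)
    return x * Tensor(mask)


# ---------------------------------------------------------------------------
# network blocks
# ---------------------------------------------------------------------------

class GCNBlock(_Layer):
    """Fused static/dynamic graph convolution with batch norm.

    The static branch uses the precomputed normalized physical adjacency
    plus the trainable mask Gm (initialized to zero, so training starts
    at the physical topology).  The dynamic branch scores per-frame
    adjacency from the block's own input features via a learned weight
    vector over channels.
    """

    def __init__(self, c_in: int, c_out: int, graph: SleepGraph, phi: float,
                 rng: np.random.Generator, static_norm: str = "pre",
                 gd_mode: str = "frame"):
        if static_norm not in ("none", "pre", "post"):
            raise ValueError(f"unknown static_norm {static_norm!r}")
        if gd_mode not in ("frame", "mean"):
            raise ValueError(f"unknown gd_mode {gd_mode!r}")
        if not 0.0 <= phi <= 1.0:
            raise ValueError("phi must lie in [0, 1]")
        self.static_norm = static_norm
        self.gd_mode = gd_mode
        self.phi = float(phi)
        base = {"none": graph.gp, "pre": graph.gp_norm,
                "post": graph.gp}[static_norm]
        self.gp_base = np.array(base, dtype=float)
        self.gm = Tensor(np.zeros_like(graph.gp), requires_grad=True)
        scale = np.sqrt(2.0 / c_in)
        self.mu = Tensor(rng.normal(0.0, scale, (c_in, c_out)),
                         requires_grad=True)
        self.mu_prime = Tensor(rng.normal(0.0, scale, (c_in, c_out)),
                               requires_grad=True)
        # dynamic edge-scoring weights: positive start keeps the ReLU
        # scores live so the graph can differentiate from the first step
        self.w_dyn = Tensor(np.abs(rng.normal(0.0, 1.0 / np.sqrt(c_in),
                                              c_in)), requires_grad=True)
        self.bn = BatchNorm(c_out)

    def _static_adjacency(self) -> Tensor:
        a = Tensor(self.gp_base) + self.gm
        if self.static_norm == "post":
            # degree-normalize the mask-perturbed graph itself
            a_t = a + Tensor(np.eye(a.shape[0]))
            d = a_t.sum(axis=1, keepdims=True)
            return a_t * d ** -0.5 * (d.reshape((1, -1))) ** -0.5
        return a

    def dynamic_adjacency(self, x: Tensor) -> Tensor:
        """Per-frame Gd from (B, C, T, V) input: (B, T, V, V) rows sum to 1."""
        xm = x.moveaxis(1, -1)                        # (B, T, V, C)
        gd = pairwise_edge_scores(xm, self.w_dyn).softmax(axis=-1)
        if self.gd_mode == "mean":
            gd = gd.mean(axis=1, keepdims=True)       # shared across frames
        return gd

    def forward(self, x: Tensor, training: bool) -> Tensor:
        a_static = self._static_adjacency()
        xm = x.moveaxis(1, -1)                        # (B, T, V, C_in)
        stat = ((a_static @ xm) @ self.mu).relu()
        gd = self.dynamic_adjacency(x)
        dyn = (gd @ xm) @ self.mu_prime
        fused = (dyn + self.phi * stat).moveaxis(-1, 1)
        return self.bn.forward(fused, training)


class MultiScaleTCN(_Layer):
    """Seven parallel temporal branches concatenated on the channel axis.

    Four bottleneck→dilated-3×1-conv branches, one 1×1 branch for
    within-frame features, one bottleneck→3×1-max-pool branch, and a 1×1
    residual branch.  Each of the six transform branches owns
    ⌊C_out/7⌋ channels; the residual branch carries the remainder.  A
    module-level residual (identity when shapes match, else 1×1) wraps
    the concatenation.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 dilations: tuple[int, ...] = (1, 2, 3, 4)):
        if c_out < 7:
            raise ValueError("multi-scale TCN needs at least 7 output channels")
        if len(dilations) != 4:
            raise ValueError("expected 4 dilation factors")
        bc = c_out // 7
        self.branch_channels = bc
        self.res_channels = c_out - 6 * bc
        self.dilated_in = [Conv1x1(c_in, bc, rng) for _ in dilations]
        self.dilated = [TemporalConv(bc, bc, d, rng) for d in dilations]
        self.frame_conv = Conv1x1(c_in, bc, rng)
        self.pool_in = Conv1x1(c_in, bc, rng)
        self.pool = TemporalMaxPool()
        self.res_branch = Conv1x1(c_in, self.res_channels, rng)
        self.bn = BatchNorm(c_out)
        self.module_res = (None if c_in == c_out
                           else Conv1x1(c_in, c_out, rng, bias=False))

    def forward(self, x: Tensor, training: bool) -> Tensor:
        outs = []
        for bottleneck, conv in zip(self.dilated_in, self.dilated):
            outs.append(conv.forward(bottleneck.forward(x).relu()))
        outs.append(self.frame_conv.forward(x))
        outs.append(self.pool.forward(self.pool_in.forward(x).relu()))
        outs.append(self.res_branch.forward(x))
        merged = self.bn.forward(concatenate(outs, axis=1), training)
        res = x if self.module_res is None else self.module_res.forward(x)
        return (merged + res).relu()


class InterTemporalAttention(_Layer):
    """Joint frame×electrode reweighting of (B, C, T, V) features.

    Max-pool over frames gives an electrode descriptor (C×V); max-pool
    over electrodes gives a frame descriptor (C×T).  Both are
    concatenated along the pooled axis, squeezed channel-wise C→C/r by a
    shared FC with Swish (and batch norm), split back, re-expanded to C
    by two independent FCs with sigmoid, and combined per channel as the
    outer product frame-scores ⊗ electrode-scores, which multiplies the
    input elementwise.  Both score maps live in (0,1), so the output is
    elementwise bounded by the input.
    """

    def __init__(self, channels: int, reduction: int,
                 rng: np.random.Generator):
        hidden = channels // reduction
        if hidden < 1:
            raise ValueError(
                f"reduction ratio {reduction} too large for {channels} channels")
        self.shared = Linear(channels, hidden, rng)
        self.bn = BatchNorm(hidden)
        self.frame_fc = Linear(hidden, channels, rng)
        self.elec_fc = Linear(hidden, channels, rng)

    def forward(self, x: Tensor, training: bool) -> Tensor:
        b, c, t, v = x.shape
        g_elec = x.max(axis=2)                     # (B, C, V) pooled over T
        g_frame = x.max(axis=3)                    # (B, C, T) pooled over V
        compact = concatenate([g_elec, g_frame], axis=2)   # (B, C, V+T)
        # squeeze: shared FC, then batch norm, then Swish (FC-BN-activation)
        squeezed = self.shared.forward(compact.moveaxis(1, -1)).moveaxis(-1, 1)
        squeezed = self.bn.forward(squeezed, training).swish()
        elec_part = squeezed[:, :, :v].moveaxis(1, -1)     # (B, V, C/r)
        frame_part = squeezed[:, :, v:].moveaxis(1, -1)    # (B, T, C/r)
        elec_scores = self.elec_fc.forward(elec_part).sigmoid()
        frame_scores = self.frame_fc.forward(frame_part).sigmoid()
        # per-channel outer product: (B,C,T,1) * (B,C,1,V)
        frame_scores = frame_scores.moveaxis(-1, 1).reshape((b, c, t, 1))
        elec_scores = elec_scores.moveaxis(-1, 1).reshape((b, c, 1, v))
        return x * (frame_scores * elec_scores)


class STGCNModule(_Layer):
    """One network stage: GCN fusion → multi-scale TCN → attention → dropout."""

    def __init__(self, c_in: int, c_out: int, graph: SleepGraph,
                 cfg: "NetworkConfig", rng: np.random.Generator):
        self.gcn = GCNBlock(c_in, c_out, graph, cfg.phi, rng,
                            static_norm=cfg.static_norm, gd_mode=cfg.gd_mode)
        self.tcn = MultiScaleTCN(c_out, c_out, rng, dilations=cfg.dilations)
        self.att = (InterTemporalAttention(c_out, cfg.reduction, rng)
                    if cfg.attention else None)
        self.dropout_p = cfg.dropout

    def forward(self, x: Tensor, training: bool,
                rng: np.random.Generator | None) -> Tensor:
        out = self.gcn.forward(x, training)
        out = self.tcn.forward(out, training)
        if self.att is not None:
            out = self.att.forward(out, training)
        return _dropout(out, self.dropout_p, training, rng)


# ---------------------------------------------------------------------------
# configuration and full model
# ---------------------------------------------------------------------------

@dataclass
class NetworkConfig:
    """Architecture hyperparameters.

    The default channel plan stacks nine modules (66×3, 132×3, 264×3);
    reduced plans (e.g. ``(16, 16, 32)``) give a desk-scale model for
    experiments on synthetic data.  ``phi`` balances the static graph
    branch against the dynamic one; ``reduction`` is the attention
    squeeze ratio (hidden width = C // reduction).
    """

    n_electrodes: int
    n_bands: int = 5
    context_len: int = 5
    channel_plan: tuple[int, ...] = (66, 66, 66, 132, 132, 132, 264, 264, 264)
    n_classes: int = 5
    attention: bool = True
    phi: float = 0.5
    reduction: int = 4
    dropout: float = 0.2
    dilations: tuple[int, ...] = (1, 2, 3, 4)
    static_norm: str = "pre"
    gd_mode: str = "frame"

    def __post_init__(self) -> None:
        self.channel_plan = tuple(int(c) for c in self.channel_plan)
        self.dilations = tuple(int(d) for d in self.dilations)
        if not 0.0 <= self.phi <= 1.0:
            raise ValueError("phi must lie in [0, 1]")
        for c in self.channel_plan:
            if c < 7:
                raise ValueError("each module needs >= 7 channels")
            if c // self.reduction < 1:
                raise ValueError("reduction ratio exceeds channel count")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        return cls(**d)


class SleepStageNetwork(_Layer):
    """The full ST-GCN stack plus softmax classifier head.

    Input layout: (batch, n_bands, context_len, n_electrodes).
    """

    def __init__(self, config: NetworkConfig, graph: SleepGraph,
                 seed: int = 0):
        if len(graph.montage) != config.n_electrodes:
            raise ValueError("graph montage size != configured electrodes")
        self.config = config
        self.graph = graph
        rng = np.random.default_rng(seed)
        self.modules: list[STGCNModule] = []
        c_in = config.n_bands
        for c_out in config.channel_plan:
            self.modules.append(STGCNModule(c_in, c_out, graph, config, rng))
            c_in = c_out
        self.head = Linear(c_in, config.n_classes, rng)

    def forward(self, x, training: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        """Logits for a (B, C, T, V) input batch."""
        out = _as_tensor(x)
        if out.ndim == 3:
            out = out.reshape((1,) + out.shape)
        for module in self.modules:
            out = module.forward(out, training, rng)
        pooled = out.mean(axis=(2, 3))             # global average over T, V
        return self.head.forward(pooled)

    def classify(self, x) -> np.ndarray:
        """Stage probabilities (rows sum to 1) in evaluation mode."""
        logits = self.forward(x, training=False)
        return logits.softmax(axis=-1).data

    def predict(self, x, batch_size: int = 256) -> np.ndarray:
        """Most likely stage index per sample, evaluated in minibatches."""
        x = np.asarray(x, dtype=float)
        preds = []
        for lo in range(0, x.shape[0], batch_size):
            logits = self.forward(x[lo:lo + batch_size], training=False)
            preds.append(np.argmax(logits.data, axis=-1))
        return np.concatenate(preds) if preds else np.empty(0, dtype=int)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path: str | Path, model: SleepStageNetwork) -> Path:
    """Single-file checkpoint: config echo + montage + all tensors."""
    path = Path(path)
    state = model.state()
    np.savez(path,
             __config__=json.dumps(model.config.to_dict()),
             __montage__=json.dumps(model.graph.montage),
             __gp__=model.graph.gp,
             **state)
    return path if path.suffix == ".npz" else path.with_suffix(
        path.suffix + ".npz")


def load_checkpoint(path: str | Path) -> SleepStageNetwork:
    with np.load(path, allow_pickle=False) as data:
        config = NetworkConfig.from_dict(json.loads(str(data["__config__"])))
        montage = json.loads(str(data["__montage__"]))
        gp = np.array(data["__gp__"])
        state = {k: np.array(v) for k, v in data.items()
                 if not k.startswith("__")}
    graph = SleepGraph(montage=montage, gp=gp,
                       gp_norm=normalize_adjacency(gp),
                       gm_init=np.zeros_like(gp))
    model = SleepStageNetwork(config, graph)
    model.load_state(state)
    return model
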