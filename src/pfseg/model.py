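"""PFSNet: an attention-gated, nested residual-U segmentation network.

The network segments single-channel thermograms into foot / background.  Its
layout, from input to output:

1. **Input stem** — a 7x7 stride-2 convolution, batch norm, ReLU and a 3x3
   stride-2 max pool (GoogLeNet-style), reducing each spatial side by 4 so
   the residual-U ladder operates on a manageable grid.
2. **Encoder** — five stages of residual U-blocks (RSU).  An RSU-L applies a
   local transform F1 to its input and, in parallel, sends F1 through an
   internal L-level U-shaped sub-network U; the stage output is the sum
   F1(x) + U(F1(x)).  Deeper stages use shallower internal ladders; the last
   stage is the dilated "4F" variant whose internal maps all keep the input
   resolution (dilations 1, 2, 4, ... replace pooling).
3. **Nested dense skip decoder** — UNet++-style grid nodes X(i, j): node
   (i, j>0) concatenates all same-row predecessors X(i, 0..j-1) with the
   2x-up-sampled output of X(i+1, j-1), passes the stack through a CBAM
   attention gate (channel attention then spatial attention, both
   multiplicative) and then through a row-resolution RSU.
4. **Multi-side-output fusion (MSOF)** — 3x3 heads turn nine grid nodes into
   full-resolution logits; 1x1 fusion convolutions combine the top decoder
   row into Y(0,5), the encoder column into Y(5,0), and those two into the
   final map Y(5,5).  All eleven sigmoid maps are returned and each can carry
   a supervision weight during training.

Everything is driven by :class:`NetworkConfig`; ``NetworkConfig.scaled``
produces width-multiplied, depth-clamped variants small enough to train on a
CPU while preserving every structural contract.
"""

from __future__ import annotations

import hashlib
import json
from collections import OrderedDict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np

from . import autograd as ag
from .autograd import Tensor

__all__ = [
    "RsuSpec",
    "NetworkConfig",
    "SideOutputs",
    "PFSNet",
    "Module",
    "Conv2d",
    "BatchNorm2d",
    "RSU",
    "CBAM",
    "ConfigurationError",
    "save_checkpoint",
    "load_checkpoint",
    "SIDE_OUTPUT_NAMES",
]

#: The eleven saliency maps produced per forward pass, in report order.
SIDE_OUTPUT_NAMES = (
    "Y01", "Y02", "Y03", "Y04", "Y05",
    "Y10", "Y20", "Y30", "Y40", "Y50",
    "Y55",
)
#: Maps that receive a supervision loss term besides the fused map.
SUPERVISED_SIDE_NAMES = SIDE_OUTPUT_NAMES[:-1]
FUSED_NAME = "Y55"


class ConfigurationError(ValueError):
    """Architecture configuration incompatible with the input geometry."""


# ---------------------------------------------------------------------------
# Module / layer infrastructure
# ---------------------------------------------------------------------------

class Module:
    """Barebones parameter container with deterministic traversal order."""

    def __init__(self) -> None:
        object.__setattr__(self, "_params", OrderedDict())
        object.__setattr__(self, "_buffers", OrderedDict())
        object.__setattr__(self, "_children", OrderedDict())

    def __setattr__(self, name: str, value) -> None:
        if isinstance(value, Tensor) and value.requires_grad:
            self._params[name] = value
        elif isinstance(value, Module):
            self._children[name] = value
        elif isinstance(value, (list, tuple)) and value and all(isinstance(v, Module) for v in value):
            for k, v in enumerate(value):
                self._children[f"{name}.{k}"] = v
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, p in self._params.items():
            yield f"{prefix}{name}", p
        for cname, child in self._children.items():
            yield from child.named_parameters(f"{prefix}{cname}.")

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name, b in self._buffers.items():
            yield f"{prefix}{name}", b
        for cname, child in self._children.items():
            yield from child.named_buffers(f"{prefix}{cname}.")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


class Conv2d(Module):
    """Convolution layer with He-normal weight initialization."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int,
        rng: np.random.Generator,
        stride: int = 1,
        padding: int = 0,
        dilation: int = 1,
        bias: bool = True,
    ) -> None:
        super().__init__()
        self.stride, self.padding, self.dilation = stride, padding, dilation
        std = np.sqrt(2.0 / (c_in * kernel * kernel))
        self.weight = Tensor(rng.normal(0.0, std, (c_out, c_in, kernel, kernel)), requires_grad=True)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return ag.conv2d(x, self.weight, self.bias, self.stride, self.padding, self.dilation)


class BatchNorm2d(Module):
    """Batch normalization with a conservative eps.

    Thermal frames are dominated by a near-constant background, so early
    feature channels can have tiny batch variance; eps = 1e-3 caps the
    resulting amplification and keeps SGD stable at practical step sizes.
    """

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-3) -> None:
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.gamma = Tensor(np.ones(c), requires_grad=True)
        self.beta = Tensor(np.zeros(c), requires_grad=True)
        self.register_buffer("running_mean", np.zeros(c))
        self.register_buffer("running_var", np.ones(c))

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        return ag.batchnorm2d(
            x, self.gamma, self.beta, self.running_mean, self.running_var,
            training, self.momentum, self.eps,
        )


class ConvBnRelu(Module):
    """3x3 conv -> batch norm -> ReLU, the RSU building brick."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, dilation: int = 1) -> None:
        super().__init__()
        self.conv = Conv2d(c_in, c_out, 3, rng, padding=dilation, dilation=dilation)
        self.bn = BatchNorm2d(c_out)

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        return ag.relu(self.bn(self.conv(x), training))


# ---------------------------------------------------------------------------
# RSU residual U-blocks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RsuSpec:
    """Geometry of one residual U-block."""

    L: int
    c_in: int
    m: int
    c_out: int
    dilated: bool = False

    def __post_init__(self) -> None:
        if self.L < 2:
            raise ValueError("RSU depth L must be >= 2")
        if min(self.c_in, self.m, self.c_out) < 1:
            raise ValueError("channel counts must be positive")


class RSU(Module):
    """Residual U-block: out = F1(x) + U(F1(x)).

    The plain variant pools L-1 times inside U (needs spatial size >=
    2^(L-1)); the dilated variant replaces pooling with dilations 1, 2, 4,
    ... so every internal map keeps the input resolution.
    """

    def __init__(self, spec: RsuSpec, rng: np.random.Generator) -> None:
        super().__init__()
        self.spec = spec
        L, m = spec.L, spec.m
        self.conv_in = ConvBnRelu(spec.c_in, spec.c_out, rng)
        if spec.dilated:
            self.enc = [ConvBnRelu(spec.c_out if k == 0 else m, m, rng, dilation=2 ** k) for k in range(L)]
            self.bottom = ConvBnRelu(m, m, rng, dilation=2 ** L)
            self.dec = [
                ConvBnRelu(2 * m, m if k > 0 else spec.c_out, rng, dilation=2 ** k)
                for k in reversed(range(L))
            ]  # dec[0] handles the deepest level, dec[-1] the shallowest
        else:
            self.enc = [ConvBnRelu(spec.c_out if k == 0 else m, m, rng) for k in range(L)]
            self.bottom = ConvBnRelu(m, m, rng, dilation=2)
            self.dec = [ConvBnRelu(2 * m, m if k < L - 1 else spec.c_out, rng) for k in range(L)]
            # dec[k] consumes the concat at encoder level L-1-k

    def u_path_modules(self) -> list[Module]:
        """Every module except the local F1 transform (for residual checks)."""
        return [*self.enc, self.bottom, *self.dec]

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        spec = self.spec
        h, w = x.data.shape[2], x.data.shape[3]
        if not spec.dilated and min(h, w) < 2 ** (spec.L - 1):
            raise ConfigurationError(
                f"RSU-{spec.L} needs spatial size >= {2 ** (spec.L - 1)}, got {h}x{w}"
            )
        hxin = self.conv_in(x, training)
        if spec.dilated:
            feats = [self.enc[0](hxin, training)]
            for k in range(1, spec.L):
                feats.append(self.enc[k](feats[-1], training))
            d = self.bottom(feats[-1], training)
            for k, layer in enumerate(self.dec):
                d = layer(ag.concat([d, feats[spec.L - 1 - k]]), training)
            return ag.add(d, hxin)
        feats = [self.enc[0](hxin, training)]
        sizes = [feats[0].data.shape[2:]]
        for k in range(1, spec.L):
            pooled = ag.maxpool2d(feats[-1], kernel=2, stride=2)
            feats.append(self.enc[k](pooled, training))
            sizes.append(feats[-1].data.shape[2:])
        d = self.bottom(feats[-1], training)
        for k, layer in enumerate(self.dec):
            lvl = spec.L - 1 - k
            d = layer(ag.concat([d, feats[lvl]]), training)
            if lvl > 0:
                d = ag.upsample_bilinear(d, tuple(sizes[lvl - 1]))
        return ag.add(d, hxin)


# ---------------------------------------------------------------------------
# CBAM attention
# ---------------------------------------------------------------------------

class CBAM(Module):
    """Convolutional block attention: channel gate then spatial gate.

    Channel attention: a shared two-layer MLP scores global average- and
    max-pooled channel descriptors; the sigmoid of their sum scales each
    channel.  Spatial attention: a 7x7 convolution over the channel-wise mean
    and max maps yields a sigmoid gate applied per pixel.  Both gates lie in
    (0, 1), so attention can only attenuate, never amplify.
    """

    def __init__(self, c: int, rng: np.random.Generator, reduction: int = 16) -> None:
        super().__init__()
        hidden = max(c // reduction, 1)
        std1 = np.sqrt(2.0 / c)
        std2 = np.sqrt(2.0 / hidden)
        self.w1 = Tensor(rng.normal(0.0, std1, (c, hidden)), requires_grad=True)
        self.b1 = Tensor(np.zeros(hidden), requires_grad=True)
        self.w2 = Tensor(rng.normal(0.0, std2, (hidden, c)), requires_grad=True)
        self.b2 = Tensor(np.zeros(c), requires_grad=True)
        self.spatial_conv = Conv2d(2, 1, 7, rng, padding=3)

    def _mlp(self, desc: Tensor) -> Tensor:
        return ag.linear(ag.relu(ag.linear(desc, self.w1, self.b1)), self.w2, self.b2)

    def channel_gate(self, x: Tensor) -> Tensor:
        score = ag.add(self._mlp(ag.mean_spatial(x)), self._mlp(ag.max_spatial(x)))
        n, c = score.data.shape
        return ag.reshape(ag.sigmoid(score), (n, c, 1, 1))

    def spatial_gate(self, x: Tensor) -> Tensor:
        stacked = ag.concat([ag.mean_channel(x), ag.max_channel(x)], axis=1)
        return ag.sigmoid(self.spatial_conv(stacked))

    def __call__(self, x: Tensor) -> Tensor:
        x = ag.mul(x, self.channel_gate(x))
        return ag.mul(x, self.spatial_gate(x))


# ---------------------------------------------------------------------------
# Network configuration
# ---------------------------------------------------------------------------

def _scaled_channels(base: tuple[int, ...], mult: float) -> tuple[int, ...]:
    return tuple(max(1, int(round(c * mult))) for c in base)


@dataclass(frozen=True)
class NetworkConfig:
    """Complete architectural description of a PFSNet instance.

    ``rows`` gives, top to bottom, one spec per encoder stage; the last row
    is the dilated variant.  ``input_size`` is the (height, width) the
    network expects; its forward pass rejects anything else.
    """

    input_size: tuple[int, int] = (512, 512)
    stem_channels: int = 32
    rows: tuple[RsuSpec, ...] = ()
    cbam_reduction: int = 16
    width_mult: float = 1.0
    seed: int = 0

    # Full-scale reference geometry (depth, mid channels, out channels/row).
    BASE_L = (7, 6, 5, 4, 4)
    BASE_MID = (32, 32, 64, 128, 256)
    BASE_OUT = (64, 128, 256, 512, 512)
    BASE_STEM = 32

    def __post_init__(self) -> None:
        if not self.rows:
            object.__setattr__(self, "rows", self._default_rows())
        if len(self.rows) != 5:
            raise ValueError("PFSNet uses exactly five encoder rows")

    def _default_rows(self) -> tuple[RsuSpec, ...]:
        mid = _scaled_channels(self.BASE_MID, self.width_mult)
        out = _scaled_channels(self.BASE_OUT, self.width_mult)
        c_in = self.stem_channels
        rows = []
        for i in range(5):
            rows.append(RsuSpec(L=self.BASE_L[i], c_in=c_in, m=mid[i], c_out=out[i], dilated=(i == 4)))
            c_in = out[i]
        return tuple(rows)

    @classmethod
    def scaled(cls, input_size: tuple[int, int] = (512, 512), width_mult: float = 1.0,
               seed: int = 0, cbam_reduction: int = 16) -> "NetworkConfig":
        """Width-multiplied config with RSU depths clamped to the resolution.

        Row ``i`` operates at ``input/4/2^i``; a plain RSU-L needs at least
        ``2^(L-1)`` pixels per side, so L is reduced where the row grid is
        too coarse for the full-scale depth (small desk-scale inputs).
        """
        stem = max(1, int(round(cls.BASE_STEM * width_mult)))
        mid = _scaled_channels(cls.BASE_MID, width_mult)
        out = _scaled_channels(cls.BASE_OUT, width_mult)
        rows = []
        c_in = stem
        for i in range(5):
            res = min(input_size) // 4 // (2 ** i)
            if res < 1:
                raise ConfigurationError(f"input {input_size} too small for a five-row grid")
            if i == 4:
                L = cls.BASE_L[i]
            else:
                max_l = max(2, int(np.floor(np.log2(max(res, 2)))) + 1)
                L = min(cls.BASE_L[i], max_l)
            rows.append(RsuSpec(L=L, c_in=c_in, m=mid[i], c_out=out[i], dilated=(i == 4)))
            c_in = out[i]
        return cls(
            input_size=tuple(input_size), stem_channels=stem, rows=tuple(rows),
            cbam_reduction=cbam_reduction, width_mult=width_mult, seed=seed,
        )

    @property
    def m_side(self) -> int:
        """Number of supervised side outputs besides the fused map."""
        return len(SUPERVISED_SIDE_NAMES)

    def to_json(self) -> str:
        payload = {
            "input_size": list(self.input_size),
            "stem_channels": self.stem_channels,
            "rows": [
                {"L": r.L, "c_in": r.c_in, "m": r.m, "c_out": r.c_out, "dilated": r.dilated}
                for r in self.rows
            ],
            "cbam_reduction": self.cbam_reduction,
            "width_mult": self.width_mult,
            "seed": self.seed,
        }
        return json.dumps(payload, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "NetworkConfig":
        d = json.loads(text)
        rows = tuple(RsuSpec(**r) for r in d["rows"])
        return cls(
            input_size=tuple(d["input_size"]), stem_channels=d["stem_channels"], rows=rows,
            cbam_reduction=d["cbam_reduction"], width_mult=d["width_mult"], seed=d["seed"],
        )

    def arch_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Side outputs container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SideOutputs:
    """The eleven sigmoid saliency maps from one forward pass.

    ``maps`` is ordered as :data:`SIDE_OUTPUT_NAMES`; every map has the
    network input's spatial shape and values in [0, 1].  ``fused`` is the
    final map Y(5,5).
    """

    maps: "OrderedDict[str, np.ndarray]"

    def __post_init__(self) -> None:
        if tuple(self.maps.keys()) != SIDE_OUTPUT_NAMES:
            raise ValueError("side outputs must carry the canonical eleven maps in order")

    @property
    def fused(self) -> np.ndarray:
        return self.maps[FUSED_NAME]

    @property
    def side_maps(self) -> list[np.ndarray]:
        return [self.maps[name] for name in SUPERVISED_SIDE_NAMES]


# ---------------------------------------------------------------------------
# PFSNet
# ---------------------------------------------------------------------------

class PFSNet(Module):
    """The full segmentation network; see the module docstring for layout."""

    GRID_ROWS = 5

    def __init__(self, config: NetworkConfig) -> None:
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        c0 = config.stem_channels
        # input stem: 7x7/2 conv + BN + ReLU + 3x3/2 max pool
        self.stem_conv = Conv2d(1, c0, 7, rng, stride=2, padding=3)
        self.stem_bn = BatchNorm2d(c0)
        # encoder column X(i, 0)
        self.encoders = [RSU(spec, rng) for spec in config.rows]
        out_ch = [spec.c_out for spec in config.rows]
        # decoder grid nodes X(i, j), j >= 1, i + j <= 4, with CBAM at each
        self.dec_nodes: dict[tuple[int, int], RSU] = {}
        self.cbam_nodes: dict[tuple[int, int], CBAM] = {}
        dec_modules: list[Module] = []
        cbam_modules: list[Module] = []
        self._grid_keys: list[tuple[int, int]] = []
        for j in range(1, self.GRID_ROWS):
            for i in range(0, self.GRID_ROWS - j):
                cat_ch = j * out_ch[i] + out_ch[i + 1]
                spec = config.rows[i]
                node_spec = RsuSpec(L=spec.L, c_in=cat_ch, m=spec.m, c_out=spec.c_out,
                                    dilated=spec.dilated)
                rsu = RSU(node_spec, rng)
                cb = CBAM(cat_ch, rng, reduction=config.cbam_reduction)
                self.dec_nodes[(i, j)] = rsu
                self.cbam_nodes[(i, j)] = cb
                dec_modules.append(rsu)
                cbam_modules.append(cb)
                self._grid_keys.append((i, j))
        self.dec_list = dec_modules
        self.cbam_list = cbam_modules
        # side-output heads: 3x3 conv to one channel, then resize to input
        self._head_keys = [(0, 0), (1, 0), (2, 0), (3, 0), (4, 0), (0, 1), (0, 2), (0, 3), (0, 4)]
        self.heads = [Conv2d(out_ch[i], 1, 3, rng, padding=1) for (i, j) in self._head_keys]
        # fusion 1x1 convolutions
        self.fuse_top = Conv2d(4, 1, 1, rng)      # Y(0,5) from Y(0,1..4)
        self.fuse_col = Conv2d(5, 1, 1, rng)      # Y(5,0) from Y(0..4,0)
        self.fuse_final = Conv2d(2, 1, 1, rng)    # Y(5,5) from Y(5,0), Y(0,5)

    # -- forward ------------------------------------------------------------

    def forward_logits(self, x: np.ndarray | Tensor, training: bool = False) -> "OrderedDict[str, Tensor]":
        """Full-resolution logits for every named output map."""
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float64))
        if x.data.ndim == 2:
            x = Tensor(x.data[None, None])
        elif x.data.ndim == 3:
            x = Tensor(x.data[:, None])
        n, c, h, w = x.data.shape
        if c != 1:
            raise ValueError("PFSNet expects single-channel input")
        if (h, w) != tuple(self.config.input_size):
            raise ValueError(
                f"input {h}x{w} does not match configured size {self.config.input_size}"
            )
        stem = ag.relu(self.stem_bn(self.stem_conv(x), training))
        stem = ag.maxpool2d(stem, kernel=3, stride=2, padding=1)
        grid: dict[tuple[int, int], Tensor] = {}
        cur = stem
        for i, enc in enumerate(self.encoders):
            if i > 0:
                cur = ag.maxpool2d(grid[(i - 1, 0)], kernel=2, stride=2)
            grid[(i, 0)] = enc(cur, training)
        for (i, j) in self._grid_keys:
            row_size = grid[(i, 0)].data.shape[2:]
            below = ag.upsample_bilinear(grid[(i + 1, j - 1)], tuple(row_size))
            stacked = ag.concat([grid[(i, k)] for k in range(j)] + [below], axis=1)
            gated = self.cbam_nodes[(i, j)](stacked)
            grid[(i, j)] = self.dec_nodes[(i, j)](gated, training)
        logits: OrderedDict[str, Tensor] = OrderedDict()
        head_logits: dict[tuple[int, int], Tensor] = {}
        for (key, head) in zip(self._head_keys, self.heads):
            z = head(grid[key])
            head_logits[key] = ag.upsample_bilinear(z, (h, w))
        f05 = self.fuse_top(ag.concat([head_logits[(0, j)] for j in (1, 2, 3, 4)], axis=1))
        f50 = self.fuse_col(ag.concat([head_logits[(i, 0)] for i in range(5)], axis=1))
        f55 = self.fuse_final(ag.concat([f50, f05], axis=1))
        logits["Y01"] = head_logits[(0, 1)]
        logits["Y02"] = head_logits[(0, 2)]
        logits["Y03"] = head_logits[(0, 3)]
        logits["Y04"] = head_logits[(0, 4)]
        logits["Y05"] = f05
        logits["Y10"] = head_logits[(1, 0)]
        logits["Y20"] = head_logits[(2, 0)]
        logits["Y30"] = head_logits[(3, 0)]
        logits["Y40"] = head_logits[(4, 0)]
        logits["Y50"] = f50
        logits["Y55"] = f55
        return logits

    def forward(self, x: np.ndarray, training: bool = False) -> SideOutputs:
        """Run the network and return sigmoid saliency maps (batch dim dropped
        for single images)."""
        single = np.asarray(x).ndim == 2
        logits = self.forward_logits(x, training=training)
        maps: OrderedDict[str, np.ndarray] = OrderedDict()
        for name in SIDE_OUTPUT_NAMES:
            s = 1.0 / (1.0 + np.exp(-np.clip(logits[name].data, -500, 500)))
            maps[name] = s[0, 0] if single else s[:, 0]
        return SideOutputs(maps=maps)

    __call__ = forward

    def supervision_loss(
        self, x: np.ndarray, target: np.ndarray, weights: np.ndarray | None = None
    ) -> Tensor:
        """Deep-supervision loss tensor over a batch (per-pixel-mean BCE).

        ``weights`` holds the ten side weights followed by the fusion
        weight; defaults to all ones.
        """
        logits = self.forward_logits(x, training=True)
        y = np.asarray(target, dtype=np.float64)
        if y.ndim == 2:
            y = y[None]
        y = y[:, None]  # (N, 1, H, W)
        if weights is None:
            weights = np.ones(len(SUPERVISED_SIDE_NAMES) + 1)
        weights = np.asarray(weights, dtype=np.float64)
        if weights.size != len(SUPERVISED_SIDE_NAMES) + 1:
            raise ValueError("need one weight per supervised side output plus the fusion weight")
        terms = [
            ag.bce_with_logits(logits[name], y, weight=float(wm))
            for name, wm in zip(SUPERVISED_SIDE_NAMES, weights[:-1])
        ]
        terms.append(ag.bce_with_logits(logits[FUSED_NAME], y, weight=float(weights[-1])))
        return ag.add_scalars(terms)


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(path: str | Path, net: PFSNet) -> None:
    """Serialize weights, buffers and the architecture hash to ``.npz``."""
    payload: dict[str, np.ndarray] = {}
    for name, p in net.named_parameters():
        payload[f"param/{name}"] = p.data
    for name, b in net.named_buffers():
        payload[f"buffer/{name}"] = b
    payload["meta/config_json"] = np.array(net.config.to_json())
    payload["meta/arch_hash"] = np.array(net.config.arch_hash())
    np.savez(Path(path), **payload)


def load_checkpoint(path: str | Path, config: NetworkConfig | None = None) -> PFSNet:
    """Rebuild a network from a checkpoint; refuses an architecture mismatch."""
    with np.load(Path(path), allow_pickle=False) as data:
        stored_cfg = NetworkConfig.from_json(str(data["meta/config_json"]))
        stored_hash = str(data["meta/arch_hash"])
        if config is not None and config.arch_hash() != stored_hash:
            raise ValueError(
                f"architecture hash mismatch: checkpoint {stored_hash}, requested {config.arch_hash()}"
            )
        net = PFSNet(stored_cfg)
        for name, p in net.named_parameters():
            p.data = np.array(data[f"param/{name}"], dtype=np.float64)
        for name, b in net.named_buffers():
            b[...] = data[f"buffer/{name}"]
    return net
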