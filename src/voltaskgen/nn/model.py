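"""Volumetric encoder-decoder with attention-gated skip connections.

The generator maps a K-channel voxel-to-ROI connectome volume to C task
contrast maps on the same grid.  It is a 3D U-Net: encoder blocks
(conv + batch norm + ReLU) separated by 2x max pooling, a mirrored decoder
with trilinear upsampling, and an additive attention gate on every skip
connection (skip and gating features projected to an intermediate channel
count, summed, ReLU, 1-channel sigmoid map multiplying the skip features).
The final output layer is a 1x1x1 convolution whose per-contrast channel
slices can be extracted and replaced independently — the basis of the
head-swap transfer protocol.

Inputs whose spatial dims are not divisible by ``2**depth`` are zero-padded
symmetrically and the output cropped back.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .layers import (
    Adam,
    BatchNorm3d,
    Conv3d,
    Layer,
    MaxPool3d,
    Param,
    ReLU,
    Sigmoid,
    Upsample3d,
)

__all__ = ["NetworkSpec", "AttentionUNet3D", "build_model"]


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture hyperparameters.

    in_channels
        K, the number of connectome channels.
    out_channels
        C, one output channel per task contrast in the battery.
    depth
        Number of pooling levels; spatial dims halve per level.
    base_channels
        Feature maps at the first level; doubled per level by default.
    """

    in_channels: int
    out_channels: int
    depth: int = 2
    base_channels: int = 16
    channel_growth: int = 2
    kernel_size: int = 3
    attention: bool = True

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.base_channels < 1:
            raise ValueError("base_channels must be >= 1")
        if self.in_channels < 1 or self.out_channels < 1:
            raise ValueError("channel counts must be >= 1")

    def channels_at(self, level: int) -> int:
        return self.base_channels * self.channel_growth**level

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkSpec":
        return cls(**d)


class _ConvBlock(Layer):
    """conv -> batch norm -> ReLU."""

    def __init__(self, cin: int, cout: int, k: int, rng, name: str):
        self.conv = Conv3d(cin, cout, k, rng, name=f"{name}.conv")
        self.bn = BatchNorm3d(cout, name=f"{name}.bn")
        self.relu = ReLU()

    def params(self):
        return self.conv.params() + self.bn.params()

    def forward(self, x, train=False):
        return self.relu.forward(
            self.bn.forward(self.conv.forward(x, train), train), train)

    def backward(self, grad_out):
        return self.conv.backward(self.bn.backward(self.relu.backward(grad_out)))


class _AttentionGate(Layer):
    """Additive attention gate: out = skip * sigmoid(psi(relu(theta(skip) + phi(gate))))."""

    def __init__(self, skip_ch: int, gate_ch: int, inter_ch: int, rng, name: str):
        self.theta = Conv3d(skip_ch, inter_ch, 1, rng, bias=False, name=f"{name}.theta")
        self.phi = Conv3d(gate_ch, inter_ch, 1, rng, bias=True, name=f"{name}.phi")
        self.relu = ReLU()
        self.psi = Conv3d(inter_ch, 1, 1, rng, bias=True, name=f"{name}.psi")
        self.sigmoid = Sigmoid()
        self._cache = None

    def params(self):
        return self.theta.params() + self.phi.params() + self.psi.params()

    def forward(self, skip, gate, train=False):
        f = self.relu.forward(
            self.theta.forward(skip, train) + self.phi.forward(gate, train), train)
        attn = self.sigmoid.forward(self.psi.forward(f, train), train)
        if train:
            self._cache = (skip, attn)
        return skip * attn

    def backward(self, grad_out):
        skip, attn = self._cache
        self._cache = None
        g_attn = (grad_out * skip).sum(axis=1, keepdims=True)
        g_sum = self.relu.backward(self.psi.backward(self.sigmoid.backward(g_attn)))
        g_skip = grad_out * attn + self.theta.backward(g_sum)
        g_gate = self.phi.backward(g_sum)
        return g_skip, g_gate


class AttentionUNet3D:
    """The volumetric contrast-map generator.

    Parameters are split into a *backbone* (everything before the output
    layer) and a *head* (the final 1x1x1 projection); the head's channel
    slices are contrast-specific and swappable.
    """

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        d, k = spec.depth, spec.kernel_size
        ch = [spec.channels_at(l) for l in range(d + 1)]

        self.enc_blocks = [_ConvBlock(spec.in_channels, ch[0], k, rng, "enc0")]
        self.pools: list[MaxPool3d] = []
        for l in range(1, d + 1):
            self.pools.append(MaxPool3d())
            self.enc_blocks.append(_ConvBlock(ch[l - 1], ch[l], k, rng, f"enc{l}"))

        self.ups: list[Upsample3d] = []
        self.gates: list[_AttentionGate | None] = []
        self.dec_blocks: list[_ConvBlock] = []
        # decode step i goes from level (depth - i) up to level (depth - i - 1)
        for i, l in enumerate(range(d, 0, -1)):
            self.ups.append(Upsample3d())
            if spec.attention:
                inter = max(ch[l - 1] // 2, 1)
                self.gates.append(
                    _AttentionGate(ch[l - 1], ch[l], inter, rng, f"gate{i}"))
            else:
                self.gates.append(None)
            self.dec_blocks.append(
                _ConvBlock(ch[l] + ch[l - 1], ch[l - 1], k, rng, f"dec{i}"))

        self.head = Conv3d(ch[0], spec.out_channels, 1, rng, name="head")
        self._pad = None
        self._skip_grads = None

    # -- parameter bookkeeping ------------------------------------------------

    def backbone_params(self) -> list[Param]:
        out: list[Param] = []
        for blk in self.enc_blocks:
            out += blk.params()
        for gate in self.gates:
            if gate is not None:
                out += gate.params()
        for blk in self.dec_blocks:
            out += blk.params()
        return out

    def head_params(self) -> list[Param]:
        return self.head.params()

    def params(self) -> list[Param]:
        return self.backbone_params() + self.head_params()

    def _bn_layers(self) -> list[tuple[str, BatchNorm3d]]:
        out = []
        for i, blk in enumerate(self.enc_blocks):
            out.append((f"enc{i}.bn", blk.bn))
        for i, blk in enumerate(self.dec_blocks):
            out.append((f"dec{i}.bn", blk.bn))
        return out

    def backbone_state(self) -> dict[str, np.ndarray]:
        state = {p.name: p.data.copy() for p in self.backbone_params()}
        for name, bn in self._bn_layers():
            state[f"{name}.running_mean"] = bn.running_mean.copy()
            state[f"{name}.running_var"] = bn.running_var.copy()
        return state

    def head_state(self) -> dict[str, np.ndarray]:
        return {p.name: p.data.copy() for p in self.head_params()}

    def state_dict(self) -> dict[str, np.ndarray]:
        return {**self.backbone_state(), **self.head_state()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        by_name = {p.name: p for p in self.params()}
        for name, arr in state.items():
            if name in by_name:
                by_name[name].data[...] = arr
            elif name.endswith(".running_mean") or name.endswith(".running_var"):
                layer_name, attr = name.rsplit(".", 1)
                bn = dict(self._bn_layers())[layer_name]
                setattr(bn, attr, np.asarray(arr, dtype=np.float32).copy())
            else:
                raise KeyError(f"unknown parameter {name!r} in state dict")

    # -- per-contrast head addressing ----------------------------------------

    def get_head_slice(self, channel: int) -> tuple[np.ndarray, np.ndarray]:
        """Copy of the output layer's (weight, bias) for one contrast channel."""
        return (self.head.weight.data[channel].copy(),
                self.head.bias.data[channel].copy())

    def set_head_slice(self, channel: int, weight: np.ndarray,
                       bias: np.ndarray) -> None:
        self.head.weight.data[channel] = weight
        self.head.bias.data[channel] = bias

    # -- forward / backward ---------------------------------------------------

    def _pad_input(self, x: np.ndarray):
        m = 2**self.spec.depth
        pads = []
        for dim in x.shape[2:]:
            total = (-dim) % m
            pads.append((total // 2, total - total // 2))
        if any(p != (0, 0) for p in pads):
            x = np.pad(x, ((0, 0), (0, 0), *pads))
        return x, pads

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Map (N, K, nx, ny, nz) connectomes to (N, C, nx, ny, nz) maps."""
        x = np.asarray(x)
        if x.dtype != np.float64:  # float64 inputs propagate for gradient checks
            x = x.astype(np.float32)
        squeeze = x.ndim == 4
        if squeeze:
            x = x[None]
        x, pads = self._pad_input(x)
        if train:
            self._pad = pads

        feats = []
        h = self.enc_blocks[0].forward(x, train)
        feats.append(h)
        for l in range(1, self.spec.depth + 1):
            h = self.enc_blocks[l].forward(self.pools[l - 1].forward(h, train), train)
            feats.append(h)

        for i, l in enumerate(range(self.spec.depth, 0, -1)):
            up = self.ups[i].forward(h, train)
            skip = feats[l - 1]
            if self.gates[i] is not None:
                skip = self.gates[i].forward(skip, up, train)
            h = self.dec_blocks[i].forward(
                np.concatenate([up, skip], axis=1), train)

        y = self.head.forward(h, train)
        y = y[(slice(None), slice(None),
               *(slice(p0, y.shape[2 + ax] - p1)
                 for ax, (p0, p1) in enumerate(pads)))]
        return y[0] if squeeze else y

    def backward(self, grad_out: np.ndarray) -> None:
        """Accumulate parameter gradients from d(loss)/d(output)."""
        g = np.asarray(grad_out)
        if g.dtype != np.float64:
            g = g.astype(np.float32)
        if g.ndim == 4:
            g = g[None]
        pads = self._pad
        if any(p != (0, 0) for p in pads):
            g = np.pad(g, ((0, 0), (0, 0), *pads))

        d = self.spec.depth
        ch = [self.spec.channels_at(l) for l in range(d + 1)]
        skip_grads: dict[int, np.ndarray] = {}

        gh = self.head.backward(g)
        for i in range(d - 1, -1, -1):
            l = d - i
            gcat = self.dec_blocks[i].backward(gh)
            g_up, g_skip = gcat[:, : ch[l]], gcat[:, ch[l]:]
            if self.gates[i] is not None:
                g_skip, g_gate = self.gates[i].backward(g_skip)
                g_up = g_up + g_gate
            skip_grads[l - 1] = g_skip
            gh = self.ups[i].backward(g_up)

        for l in range(d, 0, -1):
            gh = self.pools[l - 1].backward(self.enc_blocks[l].backward(gh))
            gh = gh + skip_grads[l - 1]
        self.enc_blocks[0].backward(gh)
        self._pad = None

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Deterministic evaluation-mode forward pass."""
        return self.forward(x, train=False)

    def zero_grad(self) -> None:
        for p in self.params():
            p.zero_grad()


def build_model(spec: NetworkSpec, seed: int = 0) -> AttentionUNet3D:
    """Construct a generator with seeded parameter initialization."""
    return AttentionUNet3D(spec, seed=seed)
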