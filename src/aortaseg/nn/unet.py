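"""3D encoder-decoder segmentation network with additive attention gates.

The contraction path halves resolution and doubles channels per level; the
expansion path mirrors it, restoring detail through skip connections merged
by concatenation.  When attention is enabled, each skip connection first
passes through a gate: the skip features and the coarser-scale gating signal
are linearly projected, added, rectified, projected to a coefficient map and
squashed to [0, 1]; the skip features are multiplied element-wise by the
(upsampled) coefficients before concatenation, letting the network suppress
irrelevant context.  With attention disabled the architecture reduces to a
generic 3D U-Net.  The final 1x1x1 convolution emits per-class scores
normalised to a probability simplex per voxel.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .layers import (
    Adam,
    AvgPool2,
    Conv3d,
    InstanceNorm,
    Layer,
    MaxPool2,
    ReLU,
    Sigmoid,
    Softmax,
    Upsample2,
)

F32 = np.float32


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and training hyper-parameters.

    ``out_classes`` is 3 for contrast volumes (background / lumen /
    wall+thrombus) and 2 for the single-class non-contrast and ROI stages.
    ``attention_per_channel`` switches the gate coefficients from one value
    per voxel to one per voxel *and* channel.
    """

    depth: int = 3
    base_channels: int = 8
    in_channels: int = 1
    out_classes: int = 3
    attention: bool = True
    attention_per_channel: bool = False
    patch_size: int = 32
    learning_rate: float = 1e-3
    epochs: int = 30
    batch_size: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.out_classes < 2:
            raise ValueError("out_classes must be >= 2")
        if self.patch_size % 2 ** (self.depth - 1) != 0:
            raise ValueError(
                f"patch_size {self.patch_size} not divisible by "
                f"2^(depth-1) = {2 ** (self.depth - 1)}")


class ConvBlock(Layer):
    """conv3 -> instance norm -> ReLU, twice."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.ops = [Conv3d(cin, cout, 3, rng), InstanceNorm(cout), ReLU(),
                    Conv3d(cout, cout, 3, rng), InstanceNorm(cout), ReLU()]

    def sublayers(self):
        return self.ops

    def forward(self, x):
        for op in self.ops:
            x = op.forward(x)
        return x

    def backward(self, g):
        for op in reversed(self.ops):
            g = op.backward(g)
        return g


class AttentionGate(Layer):
    """Additive attention gate on a skip connection.

    ``alpha = sigmoid(psi(relu(Wx * pool(skip) + Wg * gate)))`` computed at
    the coarse resolution, upsampled to the skip resolution, and multiplied
    element-wise into the skip features.
    """

    def __init__(self, c_skip: int, c_gate: int, rng: np.random.Generator,
                 per_channel: bool = False):
        inter = max(c_skip // 2, 1)
        self.pool = AvgPool2()
        self.wx = Conv3d(c_skip, inter, 1, rng)
        self.wg = Conv3d(c_gate, inter, 1, rng)
        self.relu = ReLU()
        self.psi = Conv3d(inter, c_skip if per_channel else 1, 1, rng)
        self.sig = Sigmoid()
        self.up = Upsample2()
        self.alpha: np.ndarray | None = None  # last coefficients, inspectable

    def sublayers(self):
        return [self.wx, self.wg, self.psi]

    def forward(self, skip: np.ndarray, gate: np.ndarray) -> np.ndarray:
        if tuple(gate.shape[1:]) != tuple(s // 2 for s in skip.shape[1:]):
            raise ValueError(
                f"gate spatial shape {gate.shape[1:]} is not half of skip "
                f"{skip.shape[1:]}")
        xs = self.pool.forward(skip)
        q = self.relu.forward(self.wx.forward(xs) + self.wg.forward(gate))
        a = self.sig.forward(self.psi.forward(q))
        self.alpha = self.up.forward(a)
        self._skip = skip
        return self.alpha * skip

    def backward(self, g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        dskip = g * self.alpha
        if self.alpha.shape[0] == 1:
            dalpha = (g * self._skip).sum(axis=0, keepdims=True)
        else:
            dalpha = g * self._skip
        da = self.up.backward(dalpha.astype(F32))
        dq = self.relu.backward(self.psi.backward(self.sig.backward(da)))
        dxs = self.wx.backward(dq)
        dgate = self.wg.backward(dq)
        dskip = dskip + self.pool.backward(dxs)
        self._skip = None
        return dskip.astype(F32), dgate


class AttentionUNet3D:
    """The segmentation network; single-sample forward/backward."""

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        ch = [cfg.base_channels * 2**l for l in range(cfg.depth)]
        self.channels = ch
        self.encoders: list[ConvBlock] = []
        self.pools: list[MaxPool2] = []
        cin = cfg.in_channels
        for l in range(cfg.depth - 1):
            self.encoders.append(ConvBlock(cin, ch[l], rng))
            self.pools.append(MaxPool2())
            cin = ch[l]
        self.bottleneck = ConvBlock(cin, ch[-1], rng)
        self.ups: list[Upsample2] = []
        self.gates: list[AttentionGate | None] = []
        self.decoders: list[ConvBlock] = []
        for l in reversed(range(cfg.depth - 1)):
            self.ups.append(Upsample2())
            gate = (AttentionGate(ch[l], ch[l + 1], rng,
                                  cfg.attention_per_channel)
                    if cfg.attention else None)
            self.gates.append(gate)
            self.decoders.append(ConvBlock(ch[l + 1] + ch[l], ch[l], rng))
        self.head = Conv3d(ch[0], cfg.out_classes, 1, rng)
        self.softmax = Softmax()

    # -- parameter plumbing -------------------------------------------
    def _layers(self) -> list[Layer]:
        out: list[Layer] = []
        for b in self.encoders:
            out += b.sublayers()
        out += self.bottleneck.sublayers()
        for g in self.gates:
            if g is not None:
                out += g.sublayers()
        for b in self.decoders:
            out += b.sublayers()
        out.append(self.head)
        return out

    def make_optimizer(self, lr: float | None = None) -> Adam:
        return Adam(self._layers(), lr=lr if lr is not None else self.cfg.learning_rate)

    # -- forward / backward -------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        """(in_channels, D, H, W) float32 -> (out_classes, D, H, W) probs."""
        if x.ndim == 3:
            x = x[None]
        x = x.astype(F32, copy=False)
        div = 2 ** (self.cfg.depth - 1)
        if any(s % div for s in x.shape[1:]):
            raise ValueError(f"spatial dims {x.shape[1:]} not divisible by {div}")
        skips = []
        for enc, pool in zip(self.encoders, self.pools):
            x = enc.forward(x)
            skips.append(x)
            x = pool.forward(x)
        x = self.bottleneck.forward(x)
        self._n_levels = len(skips)
        for up, gate, dec, skip in zip(self.ups, self.gates, self.decoders,
                                       reversed(skips)):
            gated = gate.forward(skip, x) if gate is not None else skip
            x = up.forward(x)
            self._concat_split = gated.shape[0]
            x = np.concatenate([gated, x], axis=0)
            x = dec.forward(x)
        logits = self.head.forward(x)
        return self.softmax.forward(logits)

    def backward(self, dprobs: np.ndarray) -> None:
        g = self.softmax.backward(dprobs.astype(F32))
        g = self.head.backward(g)
        # decoder stages were applied coarse -> fine; walk them in reverse
        dskips: list[np.ndarray] = []  # collected finest level first
        for up, gate, dec in zip(reversed(self.ups), reversed(self.gates),
                                 reversed(self.decoders)):
            g = dec.backward(g)
            c_skip = dec.ops[0].cout  # concat was [gated skip | upsampled]
            dgated, dup = g[:c_skip], g[c_skip:]
            g = up.backward(dup)
            if gate is not None:
                dskip, dgate = gate.backward(dgated)
                g = g + dgate
            else:
                dskip = dgated
            dskips.append(dskip)
        g = self.bottleneck.backward(g)
        # encoder unwind runs coarsest first; dskips[-1] is the coarsest
        for enc, pool, dskip in zip(reversed(self.encoders), reversed(self.pools),
                                    reversed(dskips)):
            g = pool.backward(g)
            g = g + dskip
            g = enc.backward(g)

    # -- persistence ---------------------------------------------------
    def state_arrays(self) -> list[np.ndarray]:
        return [p for lay in self._layers() for p in lay.params()]

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        arrays = {f"p{i}": a for i, a in enumerate(self.state_arrays())}
        arrays["config_json"] = np.frombuffer(
            json.dumps(asdict(self.cfg)).encode(), dtype=np.uint8)
        np.savez(path, **arrays)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "AttentionUNet3D":
        with np.load(path) as z:
            cfg = ModelConfig(**json.loads(bytes(z["config_json"].tobytes()).decode()))
            model = cls(cfg)
            for i, p in enumerate(model.state_arrays()):
                p[...] = z[f"p{i}"]
        return model


def build_model(cfg: ModelConfig) -> AttentionUNet3D:
    """Construct the (attention) U-Net described by ``cfg``."""
    return AttentionUNet3D(cfg)
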