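"""Segmentation network architectures built from declarative specs.

The central object is :class:`ArchitectureSpec`, a declarative description
of a symmetric encoder–decoder ("U") network: channel widths double at each
of ``depth`` downsampling stages and halve back up the decoder, with skip
concatenation at matching resolutions.  The same spec drives both
:func:`build_model` (the trainable network) and the analytic bookkeeping in
:mod:`uwunet.complexity`, so parameter counts can be cross-checked against
an enumeration of the built model's trainable arrays.

Shipped presets:

========== ============ ===== ========== =================
name       base_width   depth activation trainable scalars
========== ============ ===== ========== =================
uwunet     24           2     relu       263,257
uwunet-leaky 24         2     leaky_relu 263,257
small-unet 32           2     relu       467,233
unet       64           4     relu       31,042,369
========== ============ ===== ========== =================

Block conventions (fixed for all presets): every 3x3 convolution carries a
bias and is followed by batch normalization (2 learned scalars per channel)
and the activation; upsampling is a biased 2x2 stride-2 transposed
convolution that halves the channel count; the output head is a biased 1x1
convolution producing one logit map.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import nn

__all__ = [
    "ArchitectureSpec",
    "UNet",
    "build_model",
    "build_resnet18_unet",
    "PRESETS",
    "get_preset",
    "spec_to_config",
    "spec_from_config",
]

_ACTIVATIONS = ("relu", "leaky_relu")

#: initial output-head bias: the logit of a ~5% foreground prior
PRIOR_LOGIT = -3.0
_UPSAMPLE_MODES = ("transposed_conv",)


@dataclass(frozen=True)
class ArchitectureSpec:
    """Declarative description of a symmetric U-shaped segmentation network.

    Parameters
    ----------
    name:
        Human-readable label used in reports.
    in_channels:
        Input channels (1 for grayscale MRI).
    base_width:
        Channels produced by the first double-convolution block; stage ``k``
        has ``base_width * 2**k`` channels.
    depth:
        Number of down/up stages; input height and width must be divisible
        by ``2**depth``.
    activation:
        ``"relu"`` or ``"leaky_relu"`` (negative slope 0.01).
    upsample:
        Decoder upsampling mode; only ``"transposed_conv"`` is defined.
    out_channels:
        Output logit channels (1 for binary segmentation).
    """

    name: str
    in_channels: int = 1
    base_width: int = 24
    depth: int = 2
    activation: str = "relu"
    upsample: str = "transposed_conv"
    out_channels: int = 1

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.base_width < 1 or self.in_channels < 1 or self.out_channels < 1:
            raise ValueError("channel counts must be >= 1")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"activation must be one of {_ACTIVATIONS}")
        if self.upsample not in _UPSAMPLE_MODES:
            raise ValueError(f"upsample must be one of {_UPSAMPLE_MODES}")

    def width(self, stage: int) -> int:
        """Channel width at encoder stage ``stage`` (0 = after input block)."""
        return self.base_width * 2 ** stage

    def check_input_size(self, height: int, width: int) -> None:
        f = 2 ** self.depth
        if height % f or width % f:
            raise ValueError(
                f"input {height}x{width} not divisible by 2^depth = {f} "
                f"(required by {self.depth} pooling stages)"
            )


PRESETS: dict[str, ArchitectureSpec] = {
    "uwunet": ArchitectureSpec("uwunet", base_width=24, depth=2),
    "uwunet-leaky": ArchitectureSpec("uwunet-leaky", base_width=24, depth=2,
                                     activation="leaky_relu"),
    "small-unet": ArchitectureSpec("small-unet", base_width=32, depth=2),
    "unet": ArchitectureSpec("unet", base_width=64, depth=4),
}


def get_preset(name: str, activation: str | None = None) -> ArchitectureSpec:
    """Look up a preset spec by name, optionally overriding the activation."""
    try:
        spec = PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown architecture {name!r}; choose from {sorted(PRESETS)}")
    if activation is not None:
        spec = replace(spec, activation=activation)
    return spec


# --- plain-text (key: value) round-trip, used by the CLI ---

_CONFIG_FIELDS = ("name", "in_channels", "base_width", "depth",
                  "activation", "upsample", "out_channels")


def spec_to_config(spec: ArchitectureSpec) -> str:
    return "".join(f"{k}: {getattr(spec, k)}\n" for k in _CONFIG_FIELDS)


def spec_from_config(text: str) -> ArchitectureSpec:
    kv: dict[str, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition(":")
        kv[key.strip()] = value.strip()
    ints = {"in_channels", "base_width", "depth", "out_channels"}
    kwargs = {k: (int(v) if k in ints else v) for k, v in kv.items() if k in _CONFIG_FIELDS}
    return ArchitectureSpec(**kwargs)


def _make_activation(spec: ArchitectureSpec) -> nn.Module:
    return nn.ReLU() if spec.activation == "relu" else nn.LeakyReLU(0.01)


def _double_conv(spec: ArchitectureSpec, in_ch: int, out_ch: int,
                 rng: np.random.Generator) -> nn.Sequential:
    return nn.Sequential(
        nn.Conv2d(in_ch, out_ch, 3, pad=1, rng=rng),
        nn.BatchNorm2d(out_ch),
        _make_activation(spec),
        nn.Conv2d(out_ch, out_ch, 3, pad=1, rng=rng),
        nn.BatchNorm2d(out_ch),
        _make_activation(spec),
    )


class UNet(nn.Module):
    """Symmetric encoder–decoder network built from an :class:`ArchitectureSpec`.

    Fully convolutional: the same weights run at any input size divisible by
    ``2**depth``, and the output logit map matches the input spatial shape.

    Stage names (for Grad-CAM and introspection) run ``inc``,
    ``down1..downD``, ``up1..upD`` (``up1`` is the deepest decoder stage,
    ``upD`` the finest), and ``outc``.  After a ``forward``/``backward``
    pair, per-stage activations and gradients are available in
    ``stage_outputs`` / ``stage_grads``.
    """

    def __init__(self, spec: ArchitectureSpec, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.spec = spec
        self.inc = _double_conv(spec, spec.in_channels, spec.width(0), rng)
        self.downs: list[tuple[nn.MaxPool2x2, nn.Sequential]] = []
        for k in range(1, spec.depth + 1):
            self.downs.append((nn.MaxPool2x2(),
                               _double_conv(spec, spec.width(k - 1), spec.width(k), rng)))
        self.ups: list[tuple[nn.ConvTranspose2x2, nn.Sequential]] = []
        for k in range(spec.depth, 0, -1):
            up = nn.ConvTranspose2x2(spec.width(k), spec.width(k - 1), rng=rng)
            dc = _double_conv(spec, 2 * spec.width(k - 1), spec.width(k - 1), rng)
            self.ups.append((up, dc))
        self.outc = nn.Conv2d(spec.width(0), spec.out_channels, 1, rng=rng)
        # small-foreground prior: start the output head predicting mostly
        # background (sigmoid(-3) ~ 5%), which skips the early epochs a
        # zero-init head spends learning the class imbalance
        self.outc.bias.data[:] = PRIOR_LOGIT
        self.stage_outputs: dict[str, np.ndarray] = {}
        self.stage_grads: dict[str, np.ndarray] = {}

    # -- parameter bookkeeping -------------------------------------------
    def parameters(self) -> list[nn.Parameter]:
        params = list(self.inc.parameters())
        for pool, dc in self.downs:
            params += dc.parameters()
        for up, dc in self.ups:
            params += up.parameters() + dc.parameters()
        params += self.outc.parameters()
        return params

    def num_parameters(self) -> int:
        """Total trainable scalar count, by enumeration."""
        return sum(p.size for p in self.parameters())

    def stage_names(self) -> list[str]:
        d = self.spec.depth
        return (["inc"] + [f"down{j}" for j in range(1, d + 1)]
                + [f"up{i}" for i in range(1, d + 1)] + ["outc"])

    def get_weights(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(weights) != len(params):
            raise ValueError("weight list does not match model parameters")
        for p, w in zip(params, weights):
            p.data[...] = w

    def state_arrays(self) -> dict[str, np.ndarray]:
        """Parameters plus batch-norm running statistics, for checkpointing."""
        out = {f"param_{i}": p.data for i, p in enumerate(self.parameters())}
        for i, bn in enumerate(self._batchnorms()):
            out[f"bn_{i}_mean"] = bn.running_mean
            out[f"bn_{i}_var"] = bn.running_var
        return out

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.parameters()):
            p.data[...] = arrays[f"param_{i}"]
        for i, bn in enumerate(self._batchnorms()):
            bn.running_mean[...] = arrays[f"bn_{i}_mean"]
            bn.running_var[...] = arrays[f"bn_{i}_var"]

    def _batchnorms(self) -> list[nn.BatchNorm2d]:
        seqs = [self.inc] + [dc for _, dc in self.downs] + [dc for _, dc in self.ups]
        return [l for s in seqs for l in s.layers if isinstance(l, nn.BatchNorm2d)]

    # -- forward / backward ----------------------------------------------
    # Public arrays are (N, C, H, W); layers run channel-major (C, N, H, W),
    # so the boundary transposes here are the only layout conversions.
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self.spec.check_input_size(x.shape[-2], x.shape[-1])
        d = self.spec.depth
        self.stage_outputs = {}
        x = np.ascontiguousarray(np.asarray(x).transpose(1, 0, 2, 3))
        x = self.inc.forward(x, train=train)
        self.stage_outputs["inc"] = x
        skips = [x]
        for j, (pool, dc) in enumerate(self.downs):
            x = dc.forward(pool.forward(x, train=train), train=train)
            self.stage_outputs[f"down{j + 1}"] = x
            if j < d - 1:
                skips.append(x)
        for i, (up, dc) in enumerate(self.ups):
            u = up.forward(x, train=train)
            s = skips[d - 1 - i]
            x = dc.forward(np.concatenate([s, u], axis=0), train=train)
            self.stage_outputs[f"up{i + 1}"] = x
        x = self.outc.forward(x, train=train)
        self.stage_outputs["outc"] = x
        return np.ascontiguousarray(x.transpose(1, 0, 2, 3))

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        d = self.spec.depth
        grad_out = np.ascontiguousarray(np.asarray(grad_out).transpose(1, 0, 2, 3))
        self.stage_grads = {"outc": grad_out}
        g = self.outc.backward(grad_out)
        skip_grads: list[np.ndarray | None] = [None] * d
        for i in range(d - 1, -1, -1):
            up, dc = self.ups[i]
            self.stage_grads[f"up{i + 1}"] = g
            g = dc.backward(g)
            cs = self.spec.width(d - 1 - i)
            skip_grads[d - 1 - i] = g[:cs]
            g = up.backward(np.ascontiguousarray(g[cs:]))
        for j in range(d - 1, -1, -1):
            pool, dc = self.downs[j]
            self.stage_grads[f"down{j + 1}"] = g
            g = pool.backward(dc.backward(g))
            g = g + skip_grads[j]
        self.stage_grads["inc"] = g
        g = self.inc.backward(g)
        return np.ascontiguousarray(g.transpose(1, 0, 2, 3))


def build_model(spec: ArchitectureSpec, rng: np.random.Generator | None = None) -> UNet:
    """Build the trainable network described by ``spec``.

    The returned model maps a float32 batch ``(N, in_channels, H, W)`` to a
    logit batch of identical spatial shape, for any H, W divisible by
    ``2**spec.depth``.  ``rng`` seeds the He-normal weight initialization.
    """
    return UNet(spec, rng=rng)


# ---------------------------------------------------------------------------
# Approximate ResNet18-encoder U-Net
# ---------------------------------------------------------------------------

class _BasicBlock(nn.Module):
    """Residual block: two 3x3 conv-BN units with identity (or 1x1-projected)
    shortcut and post-add ReLU."""

    def __init__(self, in_ch: int, out_ch: int, stride: int, rng: np.random.Generator):
        self.conv1 = nn.Conv2d(in_ch, out_ch, 3, stride=stride, pad=1, rng=rng)
        self.bn1 = nn.BatchNorm2d(out_ch)
        self.act1 = nn.ReLU()
        self.conv2 = nn.Conv2d(out_ch, out_ch, 3, pad=1, rng=rng)
        self.bn2 = nn.BatchNorm2d(out_ch)
        self.act2 = nn.ReLU()
        if stride != 1 or in_ch != out_ch:
            self.proj = nn.Sequential(nn.Conv2d(in_ch, out_ch, 1, stride=stride, rng=rng),
                                      nn.BatchNorm2d(out_ch))
        else:
            self.proj = None

    def parameters(self):
        params = (self.conv1.parameters() + self.bn1.parameters()
                  + self.conv2.parameters() + self.bn2.parameters())
        if self.proj is not None:
            params += self.proj.parameters()
        return params

    def forward(self, x, train=False):
        identity = x if self.proj is None else self.proj.forward(x, train=train)
        y = self.act1.forward(self.bn1.forward(self.conv1.forward(x, train=train),
                                               train=train), train=train)
        y = self.bn2.forward(self.conv2.forward(y, train=train), train=train)
        return self.act2.forward(y + identity, train=train)

    def backward(self, grad_out):
        g = self.act2.backward(grad_out)
        g_id = g
        g = self.conv1.backward(self.bn1.backward(self.act1.backward(
            self.conv2.backward(self.bn2.backward(g)))))
        if self.proj is not None:
            g_id = self.proj.backward(g_id)
        return g + g_id


class ResNet18UNet(nn.Module):
    """U-Net with a residual-18 style encoder and a transposed-conv decoder.

    Approximate convenience model: the decoder is one reasonable
    reconstruction (transposed conv + double conv over the four skip levels,
    then a final upsampling stage back to input resolution) and carries no
    analytic complexity guarantees.  Input H, W must be divisible by 32.
    """

    def __init__(self, in_channels: int = 1, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        spec = ArchitectureSpec("resnet18-unet", in_channels=in_channels, base_width=64,
                                depth=2)  # only used for block construction helpers
        self.stem = nn.Sequential(nn.Conv2d(in_channels, 64, 7, stride=2, pad=3, rng=rng),
                                  nn.BatchNorm2d(64), nn.ReLU())
        self.pool = nn.MaxPool2x2()
        widths = [64, 128, 256, 512]
        self.layers: list[list[_BasicBlock]] = []
        in_ch = 64
        for li, w in enumerate(widths):
            stride = 1 if li == 0 else 2
            self.layers.append([_BasicBlock(in_ch, w, stride, rng),
                                _BasicBlock(w, w, 1, rng)])
            in_ch = w
        # decoder over skips: stem (64, /2), layer1 (64, /4), layer2 (128, /8),
        # layer3 (256, /16); bottleneck layer4 (512, /32)
        skip_ch = [256, 128, 64, 64]
        self.ups = []
        ch = 512
        for sc in skip_ch:
            up = nn.ConvTranspose2x2(ch, sc, rng=rng)
            dc = _double_conv(spec, 2 * sc, sc, rng)
            self.ups.append((up, dc))
            ch = sc
        self.final_up = nn.ConvTranspose2x2(64, 32, rng=rng)
        self.final_dc = _double_conv(spec, 32, 32, rng)
        self.outc = nn.Conv2d(32, 1, 1, rng=rng)
        self.outc.bias.data[:] = PRIOR_LOGIT

    def parameters(self):
        params = list(self.stem.parameters())
        for layer in self.layers:
            for block in layer:
                params += block.parameters()
        for up, dc in self.ups:
            params += up.parameters() + dc.parameters()
        params += self.final_up.parameters() + self.final_dc.parameters()
        params += self.outc.parameters()
        return params

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def forward(self, x, train=False):
        h, w = x.shape[-2:]
        if h % 32 or w % 32:
            raise ValueError(f"input {h}x{w} not divisible by 32")
        x = np.ascontiguousarray(np.asarray(x).transpose(1, 0, 2, 3))
        x = self.stem.forward(x, train=train)
        skips = [x]
        x = self.pool.forward(x, train=train)
        for li, layer in enumerate(self.layers):
            for block in layer:
                x = block.forward(x, train=train)
            if li < 3:
                skips.append(x)
        for (up, dc), s in zip(self.ups, reversed(skips)):
            u = up.forward(x, train=train)
            x = dc.forward(np.concatenate([s, u], axis=0), train=train)
        x = self.final_dc.forward(self.final_up.forward(x, train=train), train=train)
        x = self.outc.forward(x, train=train)
        return np.ascontiguousarray(x.transpose(1, 0, 2, 3))

    def backward(self, grad_out):
        grad_out = np.ascontiguousarray(np.asarray(grad_out).transpose(1, 0, 2, 3))
        g = self.outc.backward(grad_out)
        g = self.final_up.backward(self.final_dc.backward(g))
        skip_grads = []
        for up, dc in reversed(self.ups):
            g = dc.backward(g)
            cs = g.shape[0] // 2
            skip_grads.append(g[:cs])
            g = up.backward(np.ascontiguousarray(g[cs:]))
        # reversed(ups) visits finest-first, so the list is already ordered
        # [stem, layer1, layer2, layer3]
        for li in range(3, -1, -1):
            for block in reversed(self.layers[li]):
                g = block.backward(g)
            if li > 0:
                g = g + skip_grads[li]
        g = self.pool.backward(g)
        g = self.stem.backward(g + skip_grads[0])
        return np.ascontiguousarray(g.transpose(1, 0, 2, 3))


def build_resnet18_unet(in_channels: int = 1,
                        rng: np.random.Generator | None = None) -> ResNet18UNet:
    """Build the approximate residual-encoder U-Net (no golden complexity numbers)."""
    return ResNet18UNet(in_channels=in_channels, rng=rng)
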