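"""Six-stage green-making classifier: MobileNetV3-large backbone with three
optional modifications.

The backbone is the canonical MobileNetV3-large stack of fifteen
inverted-residual bottlenecks ("Bnecks").  Three switchable changes produce
the full T-GSR model:

* **adaptive residual branches** — bottlenecks that canonically have no skip
  connection (stride 2, or stride 1 with a channel change) receive a parallel
  branch: a 1x1 convolution (no bias) + batch norm, preceded by a 2x2
  stride-2 max pool when the main path downsamples;
* **GELU** — the ReLU of the first six bottlenecks is replaced by the exact
  (erf-form) GELU; bottlenecks 7-15 keep hard-swish;
* **ICA** — squeeze-and-excitation at the eight attention positions is
  replaced by a coordinate attention that first concatenates a YCrCb
  (BT.601) transform of the leading three feature channels, pools along
  height and width separately, and gates the input with two sigmoid maps.

All three disabled reproduce the unmodified MobileNetV3-large with a
6-class head; all three enabled is T-GSR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import tensor as T
from .nn.tensor import Tensor

__all__ = [
    "BneckSpec", "NetworkVariant", "VARIANTS", "EXPANSION_SIZES",
    "ATTENTION_BLOCKS", "bneck_specs", "build_model", "make_divisible",
    "SqueezeExcite", "CoordColorAttention", "YCrCbMix", "Bneck", "TGSRNet",
    "save_checkpoint", "load_checkpoint",
]

# Canonical MobileNetV3-large bottleneck table:
# (kernel, expansion, out_channels, attention?, stride).  Blocks 1-6 use
# ReLU (or GELU), blocks 7-15 hard-swish.
_BACKBONE = [
    (3, 16, 16, False, 1),
    (3, 64, 24, False, 2),
    (3, 72, 24, False, 1),
    (5, 72, 40, True, 2),
    (5, 120, 40, True, 1),
    (5, 120, 40, True, 1),
    (3, 240, 80, False, 2),
    (3, 200, 80, False, 1),
    (3, 184, 80, False, 1),
    (3, 184, 80, False, 1),
    (3, 480, 112, True, 1),
    (3, 672, 112, True, 1),
    (5, 672, 160, True, 2),
    (5, 960, 160, True, 1),
    (5, 960, 160, True, 1),
]

EXPANSION_SIZES = tuple(row[1] for row in _BACKBONE)
ATTENTION_BLOCKS = tuple(i for i, row in enumerate(_BACKBONE, 1) if row[3])

# BT.601 RGB -> YCrCb (Y; Cr = 0.713 (R - Y); Cb = 0.564 (B - Y)).
_BT601 = np.array([
    [0.299, 0.587, 0.114],
    [0.5, -0.418688, -0.081312],
    [-0.168736, -0.331264, 0.5],
], dtype=np.float32)
_YCRCB_OFFSET = np.array([0.0, 0.5, 0.5], dtype=np.float32)


def make_divisible(value: float, divisor: int = 8) -> int:
    """Round channel counts to a multiple of ``divisor`` (never below 90%)."""
    new = max(divisor, int(value + divisor / 2) // divisor * divisor)
    if new < 0.9 * value:
        new += divisor
    return new


@dataclass(frozen=True)
class NetworkVariant:
    """Which of the three backbone modifications are enabled."""

    adaptive_residual: bool = False
    gelu: bool = False
    ica: bool = False
    num_classes: int = 6
    input_size: int = 224

    @property
    def name(self) -> str:
        if not (self.adaptive_residual or self.gelu or self.ica):
            return "baseline"
        bits = [b for b, on in (("residual", self.adaptive_residual),
                                ("gelu", self.gelu), ("ica", self.ica)) if on]
        if len(bits) == 3:
            return "tgsr"
        return "+".join(bits)


VARIANTS: dict[str, NetworkVariant] = {
    "baseline": NetworkVariant(False, False, False),
    "residual": NetworkVariant(True, False, False),
    "gelu": NetworkVariant(False, True, False),
    "ica": NetworkVariant(False, False, True),
    "tgsr": NetworkVariant(True, True, True),
}


@dataclass(frozen=True)
class BneckSpec:
    """One bottleneck row, with the variant's choices resolved."""

    index: int                     # 1-based position
    kernel: int
    in_channels: int
    expansion_channels: int
    out_channels: int
    attention: str                 # 'none' | 'SE' | 'ICA'
    activation: str                # 'ReLU' | 'GELU' | 'hard-swish'
    stride: int


def bneck_specs(variant: NetworkVariant) -> list[BneckSpec]:
    """Resolve the 15 bottleneck rows for a variant."""
    specs, cin = [], 16
    for i, (k, exp, out, att, stride) in enumerate(_BACKBONE, 1):
        if i <= 6:
            act = "GELU" if variant.gelu else "ReLU"
        else:
            act = "hard-swish"
        attention = "none"
        if att:
            attention = "ICA" if variant.ica else "SE"
        specs.append(BneckSpec(i, k, cin, exp, out, attention, act, stride))
        cin = out
    return specs


def _act(name: str) -> nn.Module:
    return {"ReLU": nn.ReLU, "GELU": nn.GELU, "hard-swish": nn.Hardswish}[name]()


class YCrCbMix(nn.Module):
    """Fixed BT.601 colour mix of the first three channels (parameter-free).

    Feature maps are treated as pseudo-RGB on a [0, 1]-like scale, so the
    chroma channels carry a neutral offset of 0.5.
    """

    def __init__(self):
        super().__init__()
        self._w = Tensor(_BT601.reshape(3, 3, 1, 1))
        self._b = Tensor(_YCRCB_OFFSET)

    def forward(self, x):
        if x.shape[1] < 3:
            raise ValueError(
                f"YCrCb mix needs >= 3 channels, got {x.shape[1]}")
        rgb = T.getitem(x, (slice(None), slice(0, 3)))
        return T.conv2d(rgb, self._w, self._b)


class SqueezeExcite(nn.Module):
    """Standard squeeze-and-excitation with a hard-sigmoid gate."""

    def __init__(self, channels: int, *, reduction: int = 4,
                 rng: np.random.Generator | None = None):
        super().__init__()
        squeeze = make_divisible(channels // reduction, 8)
        self.pool = nn.GlobalAvgPool()
        self.fc1 = nn.Conv2d(channels, squeeze, 1, bias=True, rng=rng)
        self.act = nn.ReLU()
        self.fc2 = nn.Conv2d(squeeze, channels, 1, bias=True, rng=rng)
        self.gate = nn.Hardsigmoid()
        self.squeeze = squeeze

    def forward(self, x):
        s = self.gate(self.fc2(self.act(self.fc1(self.pool(x)))))
        return T.mul(x, s)


def _bilinear_resize(x: np.ndarray, h: int, w: int) -> np.ndarray:
    """Bilinear resize of an (N, C, H0, W0) array (align-corners=False)."""
    n, c, h0, w0 = x.shape
    if (h0, w0) == (h, w):
        return x
    ys = np.clip((np.arange(h) + 0.5) * h0 / h - 0.5, 0, h0 - 1)
    xs = np.clip((np.arange(w) + 0.5) * w0 / w - 0.5, 0, w0 - 1)
    y0 = np.floor(ys).astype(int)
    x0 = np.floor(xs).astype(int)
    y1 = np.minimum(y0 + 1, h0 - 1)
    x1 = np.minimum(x0 + 1, w0 - 1)
    fy = (ys - y0).astype(np.float32)[:, None]
    fx = (xs - x0).astype(np.float32)[None, :]
    g = x[:, :, y0][:, :, :, x0] * (1 - fy) * (1 - fx) \
        + x[:, :, y0][:, :, :, x1] * (1 - fy) * fx \
        + x[:, :, y1][:, :, :, x0] * fy * (1 - fx) \
        + x[:, :, y1][:, :, :, x1] * fy * fx
    return g.astype(np.float32)


class CoordColorAttention(nn.Module):
    """Coordinate attention over RGB+YCrCb features (the ICA module).

    The input is concatenated with three YCrCb channels (BT.601),
    average-pooled along height and width separately, fused by a shared
    1x1 down-projection (no bias) + BN + hard-swish at width
    ``max(8, (C+3)//r)`` with r = 32, then split and up-projected (with
    bias) to two sigmoid gates that rescale the input along each axis.

    ``color_source`` picks what the YCrCb transform reads: the first three
    feature channels treated as pseudo-RGB (default, parameter-free), or
    the network's RGB input image bilinearly resized to the host block's
    spatial size (``"input"``; the hosting network deposits the image in
    ``input_image`` before the blocks run).  Both are budget-neutral.
    """

    def __init__(self, channels: int, *, reduction: int = 32,
                 color_source: str = "features",
                 rng: np.random.Generator | None = None):
        super().__init__()
        if color_source not in ("features", "input"):
            raise ValueError(f"unknown color_source {color_source!r}")
        mid = max(8, (channels + 3) // reduction)
        self.color_source = color_source
        self.input_image: np.ndarray | None = None
        self.mix = YCrCbMix()
        self.pool_h = nn.DirectionalAvgPool(axis=3)   # -> (N, C+3, H, 1)
        self.pool_w = nn.DirectionalAvgPool(axis=2)   # -> (N, C+3, 1, W)
        self.down = nn.Conv2d(channels + 3, mid, 1, bias=False, rng=rng)
        self.bn = nn.BatchNorm2d(mid)
        self.act = nn.Hardswish()
        self.up_h = nn.Conv2d(mid, channels, 1, bias=True, rng=rng)
        self.up_w = nn.Conv2d(mid, channels, 1, bias=True, rng=rng)
        self.gate_h = nn.Sigmoid()
        self.gate_w = nn.Sigmoid()
        self.mid = mid
        self.channels = channels

    def forward(self, x):
        n, c, h, w = x.shape
        if c != self.channels:
            raise ValueError(
                f"ICA built for {self.channels} channels, got {c}")
        if self.color_source == "input":
            if self.input_image is None:
                raise ValueError(
                    "color_source='input' but no input image was deposited")
            resized = _bilinear_resize(self.input_image, h, w)
            ycc = self.mix(Tensor(resized))      # constant w.r.t. parameters
        else:
            ycc = self.mix(x)
        z = T.concat([x, ycc], axis=1)
        ph = self.pool_h(z)                            # (N, C+3, H, 1)
        pw = T.transpose(self.pool_w(z), 2, 3)         # (N, C+3, W, 1)
        f = T.concat([ph, pw], axis=2)                 # (N, C+3, H+W, 1)
        f = self.act(self.bn(self.down(f)))
        fh = T.getitem(f, (slice(None), slice(None), slice(0, h)))
        fw = T.transpose(
            T.getitem(f, (slice(None), slice(None), slice(h, h + w))), 2, 3)
        gh = self.gate_h(self.up_h(fh))                # (N, C, H, 1)
        gw = self.gate_w(self.up_w(fw))                # (N, C, 1, W)
        return T.mul(T.mul(x, gh), gw)


class Bneck(nn.Module):
    """Inverted-residual bottleneck with optional adaptive residual branch."""

    def __init__(self, spec: BneckSpec, variant: NetworkVariant, *,
                 ica_color_source: str = "features",
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.spec = spec
        cin, exp, out = spec.in_channels, spec.expansion_channels, spec.out_channels
        if exp != cin:
            self.expand = nn.Sequential(
                nn.Conv2d(cin, exp, 1, bias=False, rng=rng),
                nn.BatchNorm2d(exp), _act(spec.activation))
        else:
            self.expand = nn.Identity()
        self.depthwise = nn.Sequential(
            nn.Conv2d(exp, exp, spec.kernel, stride=spec.stride,
                      padding=spec.kernel // 2, groups=exp, bias=False,
                      rng=rng),
            nn.BatchNorm2d(exp), _act(spec.activation))
        if spec.attention == "SE":
            self.attention = SqueezeExcite(exp, rng=rng)
        elif spec.attention == "ICA":
            self.attention = CoordColorAttention(
                exp, color_source=ica_color_source, rng=rng)
        else:
            self.attention = nn.Identity()
        self.project = nn.Sequential(
            nn.Conv2d(exp, out, 1, bias=False, rng=rng),
            nn.BatchNorm2d(out))

        # Residual wiring.
        self.identity_residual = spec.stride == 1 and cin == out
        self.branch = None
        if variant.adaptive_residual and not self.identity_residual:
            mods: list[nn.Module] = []
            if spec.stride == 2:
                mods.append(nn.MaxPool2x2())
            mods += [nn.Conv2d(cin, out, 1, bias=False, rng=rng),
                     nn.BatchNorm2d(out)]
            self.branch = nn.Sequential(*mods)

    def forward(self, x):
        y = self.project(self.attention(self.depthwise(self.expand(x))))
        if self.identity_residual:
            return T.add(y, x)
        if self.branch is not None:
            return T.add(y, self.branch(x))
        return y


class TGSRNet(nn.Module):
    """Stem + 15 bottlenecks + MobileNetV3-large classification head."""

    def __init__(self, variant: NetworkVariant, *, seed: int = 0,
                 ica_color_source: str = "features"):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.variant = variant
        self.specs = bneck_specs(variant)
        self.ica_color_source = ica_color_source
        self.stem = nn.Sequential(
            nn.Conv2d(3, 16, 3, stride=2, padding=1, bias=False, rng=rng),
            nn.BatchNorm2d(16), nn.Hardswish())
        self.blocks = nn.Sequential(
            *[Bneck(s, variant, ica_color_source=ica_color_source, rng=rng)
              for s in self.specs])
        self.head_conv = nn.Sequential(
            nn.Conv2d(160, 960, 1, bias=False, rng=rng),
            nn.BatchNorm2d(960), nn.Hardswish())
        self.pool = nn.GlobalAvgPool()
        self.fc1 = nn.Linear(960, 1280, rng=rng)
        self.fc_act = nn.Hardswish()
        self.drop = nn.Dropout(0.2, seed=seed)
        self.fc2 = nn.Linear(1280, variant.num_classes, rng=rng)

    def forward(self, x):
        if self.ica_color_source == "input":
            for _, m in self.named_modules():
                if isinstance(m, CoordColorAttention):
                    m.input_image = x.data
        x = self.head_conv(self.blocks(self.stem(x)))
        x = self.pool(x)
        x = T.reshape(x, (x.shape[0], x.shape[1]))
        x = self.drop(self.fc_act(self.fc1(x)))
        return self.fc2(x)

    def predict(self, images: np.ndarray, batch_size: int = 16) -> np.ndarray:
        """Argmax class ids (0-based) for an (N, 3, H, W) float array."""
        self.eval()
        out = []
        for i in range(0, len(images), batch_size):
            logits = self(Tensor(images[i:i + batch_size]))
            out.append(np.argmax(logits.data, axis=1))
        return np.concatenate(out) if out else np.empty(0, dtype=int)


def build_model(variant: NetworkVariant | str, *, seed: int = 0,
                ica_color_source: str = "features") -> TGSRNet:
    """Build a network for a :class:`NetworkVariant` or a variant name."""
    if isinstance(variant, str):
        try:
            variant = VARIANTS[variant]
        except KeyError:
            raise ValueError(
                f"unknown variant {variant!r}; choose from {sorted(VARIANTS)}"
            ) from None
    return TGSRNet(variant, seed=seed, ica_color_source=ica_color_source)


def save_checkpoint(net: TGSRNet, path) -> None:
    state = {f"param/{k}": v for k, v in net.state_dict().items()}
    state["meta/variant"] = np.array([
        net.variant.adaptive_residual, net.variant.gelu, net.variant.ica,
        net.variant.num_classes, net.variant.input_size], dtype=np.int64)
    np.savez(path, **state)


def load_checkpoint(path) -> TGSRNet:
    with np.load(path) as data:
        meta = data["meta/variant"]
        variant = NetworkVariant(bool(meta[0]), bool(meta[1]), bool(meta[2]),
                                 int(meta[3]), int(meta[4]))
        net = build_model(variant)
        net.load_state_dict(
            {k[len("param/"):]: v for k, v in data.items()
             if k.startswith("param/")})
    return net
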