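"""The phi_{k,f0} U-Net family and the cascaded W-Net.

A U-Net here is fully specified by the number of depth levels ``k`` and the base
filter count ``f0``: the encoder widths are f0, 2*f0, ..., 2^(k-1)*f0 (filters
double at each level, all convolutions are 3x3), so the architecture is a pure
function of the pair (k, f0) plus input/output channel counts.  A W-Net is two
such U-Nets in cascade: the second consumes the input image concatenated with
the first's per-class probability map, Phi(x) = phi2(x, phi1(x)), and both
subnet outputs are exposed because training penalizes them jointly.

Block micro-structure (fixed; the printed parameter counts of the little models
are the oracle for it):

* ConvBlock(c_in -> c_out): [3x3 conv (bias) -> ReLU -> BN] x2, plus a residual
  shortcut [1x1 conv (no bias) -> BN] added to the block output.
* Encoder: k ConvBlocks; blocks 2..k preceded by 2x2 max-pooling
  (k depth levels means k-1 down/upsamplings).
* Decoder per level: 2x2 stride-2 transposed conv halving channels; the
  matching encoder skip passes through a channel-preserving "bridge"
  (3x3 conv -> ReLU -> BN) before concatenation; then ConvBlock(2c -> c).
* Head: 1x1 conv (bias) to n_classes; sigmoid for 1 class, softmax otherwise.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass

import numpy as np

from . import nn


@dataclass(frozen=True)
class ArchSpec:
    """Architecture parametrization (k, f0) plus channel counts.

    ``k`` counts depth levels (the encoder has k resolutions, hence k-1
    poolings); widths double per level starting at ``f0``.
    """

    k: int
    f0: int
    in_channels: int = 3
    n_classes: int = 1

    def __post_init__(self):
        if not (isinstance(self.k, int) and self.k >= 2):
            raise ValueError(f"k must be an integer >= 2, got {self.k!r}")
        if not (isinstance(self.f0, int) and self.f0 >= 1):
            raise ValueError(f"f0 must be a positive integer, got {self.f0!r}")
        if self.in_channels < 1 or self.n_classes < 1:
            raise ValueError("in_channels and n_classes must be positive")

    @property
    def widths(self) -> list[int]:
        return [self.f0 * 2 ** i for i in range(self.k)]

    @property
    def divisor(self) -> int:
        """Spatial sizes must be divisible by 2^(k-1)."""
        return 2 ** (self.k - 1)

    def to_dict(self) -> dict:
        return {"k": self.k, "f0": self.f0, "in_channels": self.in_channels,
                "n_classes": self.n_classes}


class ConvBlock(nn.Module):
    """Two conv->ReLU->BN stages with a 1x1-conv residual shortcut."""

    def __init__(self, c_in: int, c_out: int, rng, shortcut_relu: bool = True):
        super().__init__()
        self.conv1 = nn.Conv2d(c_in, c_out, 3, bias=True, rng=rng)
        self.bn1 = nn.BatchNorm2d(c_out)
        self.conv2 = nn.Conv2d(c_out, c_out, 3, bias=True, rng=rng)
        self.bn2 = nn.BatchNorm2d(c_out)
        self.shortcut = nn.Conv2d(c_in, c_out, 1, bias=False, rng=rng)
        self.bn_sc = nn.BatchNorm2d(c_out)
        self.shortcut_relu = shortcut_relu

    def forward(self, x):
        h = self.bn1(nn.relu(self.conv1(x)))
        h = self.bn2(nn.relu(self.conv2(h)))
        out = nn.add(h, self.bn_sc(self.shortcut(x)))
        return nn.relu(out) if self.shortcut_relu else out


class Bridge(nn.Module):
    """Channel-preserving 3x3 conv -> ReLU -> BN on an encoder skip."""

    def __init__(self, c: int, rng):
        super().__init__()
        self.conv = nn.Conv2d(c, c, 3, bias=True, rng=rng)
        self.bn = nn.BatchNorm2d(c)

    def forward(self, x):
        return self.bn(nn.relu(self.conv(x)))


class UNet(nn.Module):
    kind = "unet"

    def __init__(self, spec: ArchSpec, rng=None, shortcut_relu: bool = True):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng()
        self.spec = spec
        w = spec.widths
        self.enc = nn.ModuleList(
            ConvBlock(spec.in_channels if i == 0 else w[i - 1], w[i], rng,
                      shortcut_relu) for i in range(spec.k))
        self.up = nn.ModuleList(
            nn.ConvTranspose2d(w[i + 1], w[i], rng=rng)
            for i in reversed(range(spec.k - 1)))
        self.bridges = nn.ModuleList(
            Bridge(w[i], rng) for i in reversed(range(spec.k - 1)))
        self.dec = nn.ModuleList(
            ConvBlock(2 * w[i], w[i], rng, shortcut_relu)
            for i in reversed(range(spec.k - 1)))
        self.head = nn.Conv2d(w[0], spec.n_classes, 1, bias=True, rng=rng)

    def _check_size(self, x):
        h, w = x.data.shape[1], x.data.shape[2]
        d = self.spec.divisor
        if h % d or w % d:
            raise ValueError(
                f"spatial size {h}x{w} not divisible by 2^(k-1)={d}; "
                "pad the input (see the inference module)")

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        self._check_size(x)
        skips = []
        h = x
        for i, block in enumerate(self.enc):
            if i > 0:
                h = nn.maxpool2x2(h)
            h = block(h)
            if i < self.spec.k - 1:
                skips.append(h)
        for up, bridge, block in zip(self.up, self.bridges, self.dec):
            skip = skips.pop()
            h = block(nn.concat_channels(up(h), bridge(skip)))
        logits = self.head(h)
        if self.spec.n_classes == 1:
            return nn.sigmoid(logits)
        return nn.softmax_channels(logits)


class WNet(nn.Module):
    """Two cascaded U-Nets; subnet 2 sees the image stacked with subnet 1's probabilities."""

    kind = "wnet"

    def __init__(self, spec: ArchSpec, rng=None, shortcut_relu: bool = True):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng()
        self.spec = spec
        prob_channels = 1 if spec.n_classes == 1 else spec.n_classes
        spec2 = ArchSpec(spec.k, spec.f0, spec.in_channels + prob_channels,
                         spec.n_classes)
        self.unet1 = UNet(spec, rng=rng, shortcut_relu=shortcut_relu)
        self.unet2 = UNet(spec2, rng=rng, shortcut_relu=shortcut_relu)

    def forward(self, x: nn.Tensor) -> tuple[nn.Tensor, nn.Tensor]:
        p1 = self.unet1(x)
        p2 = self.unet2(nn.concat_channels(x, p1))
        return p1, p2


def build_unet(spec: ArchSpec, seed: int | None = 0,
               shortcut_relu: bool = True) -> UNet:
    """Instantiate phi_{k,f0} with seeded fan-in-scaled initialization."""
    return UNet(spec, rng=np.random.default_rng(seed), shortcut_relu=shortcut_relu)


def build_wnet(spec: ArchSpec, seed: int | None = 0,
               shortcut_relu: bool = True) -> WNet:
    """Instantiate the cascaded W-Net Phi = phi2(x, phi1(x))."""
    return WNet(spec, rng=np.random.default_rng(seed), shortcut_relu=shortcut_relu)


def build_model(spec: ArchSpec, kind: str, seed: int | None = 0,
                shortcut_relu: bool = True):
    if kind == "unet":
        return build_unet(spec, seed, shortcut_relu)
    if kind == "wnet":
        return build_wnet(spec, seed, shortcut_relu)
    raise ValueError(f"unknown model kind {kind!r}")


def count_parameters(model: nn.Module) -> int:
    """Number of trainable scalars (conv weights/biases + BN scale/shift)."""
    return int(sum(p.data.size for p in model.parameters()))


# ---------------------------------------------------------------- checkpoints

def save_checkpoint(model, path, meta: dict | None = None):
    """Serialize weights + ArchSpec + metadata as a zip of .npy arrays and JSON."""
    header = {"spec": model.spec.to_dict(), "kind": model.kind,
              "meta": meta or {}}
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("header.json", json.dumps(header))
        for name, arr in model.state_dict().items():
            buf = io.BytesIO()
            np.save(buf, arr)
            zf.writestr(f"weights/{name}.npy", buf.getvalue())


def load_checkpoint(path):
    """Rebuild a model from :func:`save_checkpoint` output.

    Returns ``(model, meta)``.
    """
    with zipfile.ZipFile(path) as zf:
        header = json.loads(zf.read("header.json"))
        state = {}
        for info in zf.namelist():
            if info.startswith("weights/"):
                name = info[len("weights/"):-len(".npy")]
                state[name] = np.load(io.BytesIO(zf.read(info)))
    model = build_model(ArchSpec(**header["spec"]), header["kind"])
    model.load_state_dict(state)
    return model, header["meta"]
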