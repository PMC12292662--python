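"""U-shaped spinal cord segmentation network built from residual bottlenecks.

The encoder comprises an input module (two plain 3x3 conv+BN+ReLU layers)
followed by four feature-extraction modules; each module stacks two
residual bottleneck blocks, the first at stride 2 with channel doubling.
The decoder mirrors the encoder: four decoding modules, each upsampling
x2, concatenating the matching encoder feature map (skip connection) and
applying two bottleneck blocks that halve the channel count.  A 1x1
convolution plus per-pixel softmax yields nine class-probability maps
(background + 8 cord ROIs).

Channel schedule (defaults): base 32 doubling per stage, so
32 -> 64 -> 128 -> 256 -> 512 at the bottom; each bottleneck squeezes to
``out_ch // bottleneck_reduction`` through its 1x1 convolutions.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .nn import (BatchNorm2d, Conv2d, ConvTranspose2x, Layer, Param, ReLU,
                 Sequential, SoftmaxChannel, UpsampleNearest2x, DTYPE)

NUM_CLASSES = 9


@dataclass
class ModelConfig:
    in_channels: int = 1
    num_classes: int = NUM_CLASSES
    base_channels: int = 32
    depth: int = 4
    bottleneck_reduction: int = 4
    upsample: str = "transpose"   # or "nearest"

    def validate(self) -> "ModelConfig":
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.base_channels < 8:
            raise ValueError("base_channels must be >= 8")
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        if self.bottleneck_reduction < 1:
            raise ValueError("bottleneck_reduction must be >= 1")
        if self.upsample not in ("transpose", "nearest"):
            raise ValueError(f"unknown upsample mode {self.upsample!r}")
        return self


def conv_bn_relu(in_ch: int, out_ch: int, rng: np.random.Generator) -> Sequential:
    # bias omitted: batch norm cancels any per-channel shift
    return Sequential(Conv2d(in_ch, out_ch, k=3, bias=False, rng=rng),
                      BatchNorm2d(out_ch), ReLU())


class BottleneckBlock(Layer):
    """1x1 squeeze -> 3x3 -> 1x1 expand, with an additive shortcut.

    The final ReLU is applied after the residual addition.  The shortcut
    is the identity when input/output shapes match, otherwise a strided
    1x1 projection with its own batch norm.
    """

    def __init__(self, in_ch: int, mid_ch: int, out_ch: int, stride: int = 1,
                 rng: np.random.Generator | None = None):
        if min(in_ch, mid_ch, out_ch) < 1:
            raise ValueError("channel counts must be positive")
        rng = rng if rng is not None else np.random.default_rng(0)
        self.stride = stride
        self.main = Sequential(
            Conv2d(in_ch, mid_ch, k=1, pad=0, bias=False, rng=rng),
            BatchNorm2d(mid_ch), ReLU(),
            Conv2d(mid_ch, mid_ch, k=3, stride=stride, bias=False, rng=rng),
            BatchNorm2d(mid_ch), ReLU(),
            Conv2d(mid_ch, out_ch, k=1, pad=0, bias=False, rng=rng),
            BatchNorm2d(out_ch),
        )
        if in_ch != out_ch or stride != 1:
            self.shortcut = Sequential(
                Conv2d(in_ch, out_ch, k=1, stride=stride, pad=0, bias=False,
                       rng=rng),
                BatchNorm2d(out_ch))
        else:
            self.shortcut = None
        self.relu_out = ReLU()

    def params(self):
        p = self.main.params()
        if self.shortcut is not None:
            p += self.shortcut.params()
        return p

    def buffers(self):
        b = self.main.buffers()
        if self.shortcut is not None:
            b += self.shortcut.buffers()
        return b

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        y = self.main.forward(x, train=train)
        s = x if self.shortcut is None else self.shortcut.forward(x, train=train)
        return self.relu_out.forward(y + s, train=train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dsum = self.relu_out.backward(dy)
        dx = self.main.backward(dsum)
        if self.shortcut is None:
            dx = dx + dsum
        else:
            dx = dx + self.shortcut.backward(dsum)
        return dx

    def macs(self, h: int, w: int) -> tuple[int, int, int]:
        total = 0
        hh, ww = h, w
        for l in self.main.layers:
            if isinstance(l, Conv2d):
                total += l.macs(hh, ww)
                hh, ww = l.out_size(hh, ww)
        if self.shortcut is not None:
            total += self.shortcut.layers[0].macs(h, w)
        return total, hh, ww


class SCSNet(Layer):
    """Encoder-decoder segmentation network with skip connections."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config.validate()
        rng = np.random.default_rng(seed)
        c = config.base_channels
        r = config.bottleneck_reduction
        self.input_module = Sequential(
            *conv_bn_relu(config.in_channels, c, rng).layers,
            *conv_bn_relu(c, c, rng).layers)

        self.enc_stages: list[Sequential] = []
        ch = c
        for _ in range(config.depth):
            mid = max(1, (2 * ch) // r)
            stage = Sequential(
                BottleneckBlock(ch, mid, 2 * ch, stride=2, rng=rng),
                BottleneckBlock(2 * ch, mid, 2 * ch, stride=1, rng=rng))
            self.enc_stages.append(stage)
            ch *= 2

        self.dec_ups: list[Layer] = []
        self.dec_stages: list[Sequential] = []
        for _ in range(config.depth):
            out = ch // 2
            if config.upsample == "transpose":
                up: Layer = ConvTranspose2x(ch, out, bias=False, rng=rng)
            else:
                up = Sequential(UpsampleNearest2x(),
                                Conv2d(ch, out, k=1, pad=0, bias=False,
                                       rng=rng))
            mid = max(1, out // r)
            stage = Sequential(
                BottleneckBlock(2 * out, mid, out, stride=1, rng=rng),
                BottleneckBlock(out, mid, out, stride=1, rng=rng))
            self.dec_ups.append(up)
            self.dec_stages.append(stage)
            ch = out

        self.head = Conv2d(ch, config.num_classes, k=1, pad=0, rng=rng)
        self.softmax = SoftmaxChannel()

    # -- parameter/buffer traversal (fixed order, used by checkpoints) ----
    def _modules(self) -> list[Layer]:
        mods: list[Layer] = [self.input_module]
        mods += self.enc_stages
        for up, st in zip(self.dec_ups, self.dec_stages):
            mods += [up, st]
        mods.append(self.head)
        return mods

    def params(self) -> list[Param]:
        return [p for m in self._modules() for p in m.params()]

    def buffers(self) -> list[np.ndarray]:
        return [b for m in self._modules() for b in m.buffers()]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        h, w = x.shape[2], x.shape[3]
        stride = 2 ** self.config.depth
        if h % stride or w % stride:
            raise ValueError(
                f"input {h}x{w} not divisible by 2^depth = {stride}")
        f = self.input_module.forward(x.astype(DTYPE), train=train)
        skips = [f]
        for stage in self.enc_stages:
            f = stage.forward(f, train=train)
            skips.append(f)
        skips.pop()                       # bottom features are not a skip
        self._skip_ch = [s.shape[1] for s in skips]
        for up, stage in zip(self.dec_ups, self.dec_stages):
            f = up.forward(f, train=train)
            f = np.concatenate([skips.pop(), f], axis=1)
            f = stage.forward(f, train=train)
        logits = self.head.forward(f, train=train)
        return self.softmax.forward(logits, train=train)

    def backward(self, dprobs: np.ndarray) -> np.ndarray:
        """Reverse pass from d(loss)/d(probabilities) to d(loss)/d(input).

        Decoder stage ``j`` consumed skip ``depth-1-j`` during forward, so
        walking the decoder in reverse yields skip gradients shallow-first
        (``dskips[k]`` belongs to encoder level ``k``); each is added back
        where the encoder emitted that feature map.
        """
        dy = self.softmax.backward(dprobs)
        dy = self.head.backward(dy)
        dskips: list[np.ndarray] = []
        for up, stage, ch in zip(reversed(self.dec_ups),
                                 reversed(self.dec_stages), self._skip_ch):
            dcat = stage.backward(dy)
            dskips.append(dcat[:, :ch])
            dy = up.backward(dcat[:, ch:])
        depth = self.config.depth
        for i, stage in enumerate(reversed(self.enc_stages)):
            dy = stage.backward(dy)
            dy = dy + dskips[depth - 1 - i]
        return self.input_module.backward(dy)

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Eval-mode class probabilities for a batch."""
        return self.forward(x, train=False)

    def predict_mask(self, image: np.ndarray) -> np.ndarray:
        """Argmax label mask for a single HxW image (ties -> lowest class)."""
        probs = self.predict(image[None, None].astype(DTYPE))
        return np.argmax(probs[0], axis=0).astype(np.uint8)


def build_scs_net(config: ModelConfig | None = None, seed: int = 0) -> SCSNet:
    """Construct the network with seeded He-normal initialisation."""
    return SCSNet(config if config is not None else ModelConfig(), seed=seed)


def count_complexity(model: SCSNet, input_hw: tuple[int, int] = (128, 128)
                     ) -> tuple[int, int]:
    """Trainable parameter count and MAC-based FLOPs of one forward pass."""
    n_params = sum(p.value.size for p in model.params())
    h, w = input_hw
    macs = 0
    for l in model.input_module.layers:
        if isinstance(l, Conv2d):
            macs += l.macs(h, w)
    for stage in model.enc_stages:
        for blk in stage.layers:
            m, h, w = blk.macs(h, w)
            macs += m
    for up, stage in zip(model.dec_ups, model.dec_stages):
        if isinstance(up, ConvTranspose2x):
            macs += up.macs(h, w)
        else:
            macs += up.layers[1].macs(2 * h, 2 * w)
        h, w = 2 * h, 2 * w
        for blk in stage.layers:
            m, h, w = blk.macs(h, w)
            macs += m
    macs += model.head.macs(h, w)
    return n_params, macs


def vgg19_unet_parameter_count(in_channels: int = 1, num_classes: int = 9) -> int:
    """Parameter count of a standard VGG19-backbone U-shaped network.

    Built from the same conv primitives (weights + biases + BN affine) so
    the comparison with :func:`count_complexity` is like-for-like.
    """
    rng = np.random.default_rng(0)
    layers: list[Layer] = []
    vgg19 = [64, 64, -1, 128, 128, -1, 256, 256, 256, 256, -1,
             512, 512, 512, 512, -1, 512, 512, 512, 512]
    ch = in_channels
    for c in vgg19:
        if c == -1:
            continue
        layers += [Conv2d(ch, c, k=3, rng=rng), BatchNorm2d(c)]
        ch = c
    for skip, out in ((512, 512), (512, 256), (256, 128), (128, 64)):
        layers.append(ConvTranspose2x(ch, out, rng=rng))
        layers += [Conv2d(out + skip, out, k=3, rng=rng), BatchNorm2d(out),
                   Conv2d(out, out, k=3, rng=rng), BatchNorm2d(out)]
        ch = out
    layers.append(Conv2d(ch, num_classes, k=1, pad=0, rng=rng))
    return sum(p.value.size for l in layers for p in l.params())


# ---------------------------------------------------------------------------
# Checkpoints: npz of all parameters/buffers + embedded ModelConfig JSON.
# ---------------------------------------------------------------------------

def save_checkpoint(model: SCSNet, path) -> None:
    arrays = {f"param_{i}": p.value for i, p in enumerate(model.params())}
    arrays.update({f"buffer_{i}": b for i, b in enumerate(model.buffers())})
    arrays["config_json"] = np.frombuffer(
        json.dumps(asdict(model.config)).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path) -> SCSNet:
    with np.load(path) as data:
        cfg = ModelConfig(**json.loads(bytes(data["config_json"]).decode()))
        model = SCSNet(cfg, seed=0)
        for i, p in enumerate(model.params()):
            arr = data[f"param_{i}"]
            if arr.shape != p.value.shape:
                raise ValueError("checkpoint does not match architecture")
            p.value[...] = arr
        for i, b in enumerate(model.buffers()):
            b[...] = data[f"buffer_{i}"]
    return model
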