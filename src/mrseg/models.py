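"""Encoder-decoder segmentation networks.

The flagship configuration is a UNet whose encoder is the initial stages of
a ResNet-style bottleneck network (stages 0-4 emitting a five-level feature
pyramid at /1, /2, /4, /8 and /16 of the input resolution) and whose
decoder upsamples with 2x2 transposed convolutions, concatenates the
matching encoder features through skip connections, applies convolution
blocks and, optionally, an EMA attention block per decoder level. A final
1x1 convolution and per-pixel softmax produce K-class probabilities.

Ablation variants are pure configuration: ``encoder="unet_conv"`` swaps the
residual encoder for plain double-convolution blocks (classic UNet), and
``attention`` selects none / original EMA / improved EMA at any subset of
the four decoder levels. ``width_mult`` and ``encoder_blocks`` scale the
channel widths and bottleneck counts; defaults mirror ResNet50
((3, 4, 6, 3) bottlenecks, base width 64) and standard UNet doubling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from PIL import Image

from . import nn
from .attention import EMA, EMAConfig
from .nn.tensor import Tensor, concat, softmax

__all__ = [
    "ModelConfig",
    "Prediction",
    "SegModel",
    "build_model",
    "predict",
    "freeze_encoder",
    "count_parameters",
    "pad_to_multiple",
    "save_checkpoint",
    "load_checkpoint",
]

ENCODERS = ("resnet50", "unet_conv")
ATTENTION = ("none", "ema_original", "ema_improved")


@dataclass(frozen=True)
class ModelConfig:
    encoder: str = "resnet50"
    attention: str = "ema_improved"
    attention_stages: tuple[int, ...] = (1, 2, 3, 4)
    n_classes: int = 3
    width_mult: float = 1.0
    encoder_blocks: tuple[int, ...] = (3, 4, 6, 3)
    ema_groups: int = 8
    pretrained_encoder: bool = False
    input_size: tuple[int, int] = (512, 512)  # (H, W)

    def __post_init__(self):
        if self.encoder not in ENCODERS:
            raise ValueError(f"unknown encoder {self.encoder!r}")
        if self.attention not in ATTENTION:
            raise ValueError(f"unknown attention {self.attention!r}")
        if not set(self.attention_stages) <= {1, 2, 3, 4}:
            raise ValueError("attention_stages must be a subset of {1, 2, 3, 4}")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.input_size[0] % 16 or self.input_size[1] % 16:
            raise ValueError(
                f"input_size {self.input_size} must be divisible by 16 "
                "(skip-connection shapes would mismatch)"
            )

    @classmethod
    def tiny(cls, **overrides) -> "ModelConfig":
        """Desk-scale preset: 1/8 width, one bottleneck per stage, 64x64."""
        defaults = dict(
            width_mult=0.125,
            encoder_blocks=(1, 1, 1, 1),
            ema_groups=4,
            input_size=(64, 64),
        )
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class Prediction:
    probabilities: np.ndarray  # B x K x H x W, sums to 1 over K
    mask: np.ndarray  # H x W argmax labels at the original image size


def _ch(base: int, mult: float) -> int:
    return max(1, int(round(base * mult)))


def _double_conv(cin: int, cout: int, rng) -> nn.Sequential:
    return nn.Sequential(
        nn.Conv2d(cin, cout, 3, rng, padding=1, bias=False),
        nn.BatchNorm2d(cout),
        nn.ReLU(),
        nn.Conv2d(cout, cout, 3, rng, padding=1, bias=False),
        nn.BatchNorm2d(cout),
        nn.ReLU(),
    )


class Bottleneck(nn.Module):
    """Residual bottleneck learning F(x) = H(x) - x; the projection form
    ("Conv Block") downsamples/reshapes the shortcut, the identity form
    ("Identity Block") adds the input unchanged."""

    def __init__(self, cin: int, mid: int, cout: int, stride: int, rng):
        super().__init__()
        self.conv1 = nn.Conv2d(cin, mid, 1, rng, bias=False)
        self.bn1 = nn.BatchNorm2d(mid)
        self.conv2 = nn.Conv2d(mid, mid, 3, rng, stride=stride, padding=1, bias=False)
        self.bn2 = nn.BatchNorm2d(mid)
        self.conv3 = nn.Conv2d(mid, cout, 1, rng, bias=False)
        self.bn3 = nn.BatchNorm2d(cout)
        self.projection = None
        if stride != 1 or cin != cout:
            self.projection = nn.Sequential(
                nn.Conv2d(cin, cout, 1, rng, stride=stride, bias=False),
                nn.BatchNorm2d(cout),
            )

    def forward(self, x):
        out = self.bn1(self.conv1(x)).relu()
        out = self.bn2(self.conv2(out)).relu()
        out = self.bn3(self.conv3(out))
        shortcut = x if self.projection is None else self.projection(x)
        return (out + shortcut).relu()


class ResNetEncoder(nn.Module):
    """ResNet-style stages 0-4 emitting features at /1, /2, /4, /8, /16."""

    def __init__(self, cfg: ModelConfig, rng):
        super().__init__()
        m = cfg.width_mult
        w0 = _ch(64, m)
        self.stem = nn.Sequential(
            nn.Conv2d(3, w0, 7, rng, stride=1, padding=3, bias=False),
            nn.BatchNorm2d(w0),
            nn.ReLU(),
        )
        self.pool = nn.MaxPool2d(3, 2, 1)
        mids = [_ch(b, m) for b in (64, 128, 256, 512)]
        outs = [c * 4 for c in mids]
        self.stages = []
        cin = w0
        for si, (mid, cout, n_blocks) in enumerate(zip(mids, outs, cfg.encoder_blocks)):
            blocks = [Bottleneck(cin, mid, cout, 1 if si == 0 else 2, rng)]
            blocks += [Bottleneck(cout, mid, cout, 1, rng) for _ in range(n_blocks - 1)]
            self.stages.append(nn.Sequential(*blocks))
            cin = cout
        self.out_channels = [w0] + outs

    def forward(self, x):
        e0 = self.stem(x)
        feats = [e0]
        h = self.pool(e0)
        for stage in self.stages:
            h = stage(h)
            feats.append(h)
        return feats  # scales /1, /2, /4, /8, /16


class UNetEncoder(nn.Module):
    def __init__(self, cfg: ModelConfig, rng):
        super().__init__()
        m = cfg.width_mult
        widths = [_ch(b, m) for b in (64, 128, 256, 512, 1024)]
        self.blocks = []
        cin = 3
        for wch in widths:
            self.blocks.append(_double_conv(cin, wch, rng))
            cin = wch
        self.pool = nn.MaxPool2d(2, 2)
        self.out_channels = widths

    def forward(self, x):
        feats = []
        h = x
        for i, block in enumerate(self.blocks):
            if i > 0:
                h = self.pool(h)
            h = block(h)
            feats.append(h)
        return feats


class DecoderLevel(nn.Module):
    def __init__(self, cin: int, skip_ch: int, cout: int, cfg: ModelConfig, level: int, rng):
        super().__init__()
        self.up = nn.ConvTranspose2d(cin, cout, 2, rng)
        self.conv = _double_conv(cout + skip_ch, cout, rng)
        self.ema = None
        if cfg.attention != "none" and level in cfg.attention_stages:
            variant = "original" if cfg.attention == "ema_original" else "improved"
            groups = min(cfg.ema_groups, cout)
            while cout % groups:
                groups -= 1
            self.ema = EMA(EMAConfig(cout, groups, variant), rng)

    def forward(self, x, skip):
        h = self.up(x)
        h = self.conv(concat([h, skip], axis=1))
        if self.ema is not None:
            h = self.ema(h)
        return h


class SegModel(nn.Module):
    def __init__(self, cfg: ModelConfig, rng):
        super().__init__()
        self.cfg = cfg
        if cfg.pretrained_encoder:
            raise ValueError(
                "pretrained encoder weights are not available in this build; "
                "use pretrained_encoder=False"
            )
        self.encoder = (
            ResNetEncoder(cfg, rng) if cfg.encoder == "resnet50" else UNetEncoder(cfg, rng)
        )
        enc_ch = self.encoder.out_channels  # [e0, e1, e2, e3, e4]
        dec_w = [_ch(b, cfg.width_mult) for b in (64, 128, 256, 512)]  # levels 1..4
        self.decoder = []
        cin = enc_ch[4]
        for level in (4, 3, 2, 1):
            cout = dec_w[level - 1]
            self.decoder.append(DecoderLevel(cin, enc_ch[level - 1], cout, cfg, level, rng))
            cin = cout
        self.head = nn.Conv2d(dec_w[0], cfg.n_classes, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        """B x 3 x H x W -> B x K x H x W class probabilities."""
        if x.shape[2] % 16 or x.shape[3] % 16:
            raise ValueError(f"spatial size {x.shape[2:]} must be divisible by 16")
        feats = self.encoder(x)
        h = feats[4]
        for block, level in zip(self.decoder, (4, 3, 2, 1)):
            h = block(h, feats[level - 1])
        return softmax(self.head(h), axis=1)


def build_model(cfg: ModelConfig, seed: int = 0) -> SegModel:
    return SegModel(cfg, np.random.default_rng(seed))


def count_parameters(model: nn.Module) -> int:
    return sum(p.data.size for p in model.parameters())


def freeze_encoder(model: SegModel, frozen: bool) -> None:
    """Frozen encoder parameters receive no gradient and no optimizer update;
    decoder, attention and head parameters keep training."""
    for p in model.encoder.parameters():
        p.requires_grad = not frozen


def pad_to_multiple(image: np.ndarray, multiple: int = 16) -> np.ndarray:
    """Zero-pad H and W up to the next multiple (e.g. 800x600 -> 800x608)."""
    h, w = image.shape[:2]
    ph = (-h) % multiple
    pw = (-w) % multiple
    if ph == 0 and pw == 0:
        return image
    pad = [(0, ph), (0, pw)] + [(0, 0)] * (image.ndim - 2)
    return np.pad(image, pad)


def image_to_batch(image: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an H x W x 3 RGB image")
    if image.shape[:2] != tuple(size):
        image = np.asarray(
            Image.fromarray(image.astype(np.uint8)).resize((size[1], size[0]), Image.BILINEAR)
        )
    x = image.astype(np.float32) / 255.0
    return x.transpose(2, 0, 1)[None]


def predict(model: SegModel, image: np.ndarray) -> Prediction:
    """Segment one RGB image; deterministic in evaluation mode.

    The image is resized to the model's input size for the forward pass;
    the argmax mask (ties broken toward the lower class index) is resampled
    back to the original image size with nearest-neighbour interpolation.
    """
    was_training = model.training
    model.eval()
    try:
        x = image_to_batch(image, model.cfg.input_size)
        probs = model(Tensor(x)).data
    finally:
        model.train(was_training)
    mask = probs[0].argmax(axis=0).astype(np.int64)
    if mask.shape != image.shape[:2]:
        mask = np.asarray(
            Image.fromarray(mask.astype(np.uint8)).resize(
                (image.shape[1], image.shape[0]), Image.NEAREST
            )
        ).astype(np.int64)
    return Prediction(probs, mask)


# ---------------------------------------------------------------------------
# checkpoints: npz weights + json-encoded config, self-describing


CHECKPOINT_VERSION = 1


def save_checkpoint(path, model: SegModel, extra: dict | None = None) -> None:
    meta = {
        "version": CHECKPOINT_VERSION,
        "config": asdict(model.cfg),
        "extra": extra or {},
    }
    state = model.state_dict()
    np.savez_compressed(path, __meta__=json.dumps(meta), **state)


def load_checkpoint(path) -> tuple[SegModel, dict]:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        state = {k: data[k] for k in data.files if k != "__meta__"}
    if meta.get("version") != CHECKPOINT_VERSION:
        raise ValueError(f"unsupported checkpoint version {meta.get('version')}")
    cfg_dict = meta["config"]
    for key in ("attention_stages", "encoder_blocks", "input_size"):
        cfg_dict[key] = tuple(cfg_dict[key])
    model = build_model(ModelConfig(**cfg_dict))
    model.load_state_dict(state)
    return model, meta["extra"]
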