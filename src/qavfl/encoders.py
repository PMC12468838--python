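"""Modality encoders mapping preprocessed inputs to fixed latent sizes:
text 300 -> 128 (dense + ReLU), image -> 128 (conv backbone + global
average pooling + linear head), signal -> 64 (1-D conv, kernel 3, 64
filters -> ReLU -> max-pool 2 -> global average over time).

Two image backbones are provided: ``tiny-cnn`` (three conv blocks, ~50k
parameters, the desk-scale default that trains on CPU) and
``resnet18-style`` (four stages of two residual basic blocks, 512 final
channels).  Encoders train from random initialization; no pretrained
weights are used anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn

__all__ = [
    "EncoderConfig", "gap", "TextEncoder", "ImageEncoder", "SignalEncoder",
    "encode_text", "encode_image", "encode_signal",
]


@dataclass(frozen=True)
class EncoderConfig:
    backbone: str = "tiny-cnn"          # or "resnet18-style"
    text_in: int = 300
    text_out: int = 128
    image_size: int = 32                # tiny-cnn input side; 224 for resnet18-style
    image_out: int = 128
    signal_out: int = 64
    conv1d_kernel: int = 3
    conv1d_filters: int = 64
    pool: int = 2
    seed: int = 0


def gap(feature_map: np.ndarray) -> np.ndarray:
    """Global average pooling: per channel, the mean over all H*W positions."""
    feature_map = np.asarray(feature_map, dtype=np.float64)
    if feature_map.ndim != 3 or feature_map.size == 0:
        raise ValueError(f"expected nonempty H x W x C map, got shape {feature_map.shape}")
    return feature_map.mean(axis=(0, 1))


class TextEncoder:
    """Dense projection of the document embedding: text_in -> text_out, ReLU."""

    def __init__(self, cfg: EncoderConfig):
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        self.net = nn.Sequential(
            nn.Dense(cfg.text_in, cfg.text_out, rng),
            nn.ReLU(),
        )

    def params(self):
        return self.net.params()

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        x = np.atleast_2d(x)
        if x.shape[1] != self.cfg.text_in:
            raise ValueError(f"expected dim {self.cfg.text_in}, got {x.shape[1]}")
        return self.net.forward(x, train=train)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return self.net.backward(dout)


def _tiny_cnn(cfg: EncoderConfig, rng: np.random.Generator) -> nn.Sequential:
    return nn.Sequential(
        nn.Conv2D(3, 8, 3, rng, input_grad=False), nn.ReLU(), nn.MaxPool2D(2),
        nn.Conv2D(8, 16, 3, rng), nn.ReLU(), nn.MaxPool2D(2),
        nn.Conv2D(16, 32, 3, rng), nn.ReLU(), nn.MaxPool2D(2),
        nn.GAP2D(),
        nn.Dense(32, cfg.image_out, rng),
    )


class _BasicBlock(nn.Layer):
    """Residual basic block: two 3x3 convs with an identity (or strided
    1x1 projection) shortcut."""

    def __init__(self, c_in, c_out, stride, rng):
        self.conv1 = nn.Conv2D(c_in, c_out, 3, rng, stride=stride)
        self.relu1 = nn.ReLU()
        self.conv2 = nn.Conv2D(c_out, c_out, 3, rng)
        self.relu2 = nn.ReLU()
        self.short = nn.Conv2D(c_in, c_out, 1, rng, stride=stride) \
            if (stride != 1 or c_in != c_out) else None

    def params(self):
        p = self.conv1.params() + self.conv2.params()
        if self.short is not None:
            p += self.short.params()
        return p

    def forward(self, x, train=True):
        out = self.relu1.forward(self.conv1.forward(x, train), train)
        out = self.conv2.forward(out, train)
        identity = x if self.short is None else self.short.forward(x, train)
        return self.relu2.forward(out + identity, train)

    def backward(self, dout):
        dsum = self.relu2.backward(dout)
        dx_main = self.conv1.backward(self.relu1.backward(self.conv2.backward(dsum)))
        dx_short = dsum if self.short is None else self.short.backward(dsum)
        return dx_main + dx_short


def _resnet18_style(cfg: EncoderConfig, rng: np.random.Generator) -> nn.Sequential:
    layers: list[nn.Layer] = [
        nn.Conv2D(3, 64, 7, rng, stride=2, input_grad=False), nn.ReLU(), nn.MaxPool2D(2),
    ]
    channels = [(64, 64, 1), (64, 128, 2), (128, 256, 2), (256, 512, 2)]
    for c_in, c_out, stride in channels:
        layers.append(_BasicBlock(c_in, c_out, stride, rng))
        layers.append(_BasicBlock(c_out, c_out, 1, rng))
    layers += [nn.GAP2D(), nn.Dense(512, cfg.image_out, rng)]
    return nn.Sequential(*layers)


class ImageEncoder:
    """Conv backbone -> GAP -> linear head to image_out dimensions."""

    def __init__(self, cfg: EncoderConfig):
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        if cfg.backbone == "tiny-cnn":
            self.net = _tiny_cnn(cfg, rng)
        elif cfg.backbone == "resnet18-style":
            self.net = _resnet18_style(cfg, rng)
        else:
            raise ValueError(f"unknown backbone {cfg.backbone!r}")

    def params(self):
        return self.net.params()

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 3:
            x = x[None]
        s = self.cfg.image_size
        if x.shape[1:] != (s, s, 3):
            raise ValueError(f"expected {s}x{s}x3 images, got {x.shape[1:]}")
        return self.net.forward(x, train=train)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return self.net.backward(dout)


class SignalEncoder:
    """Conv1D(kernel 3, 64 filters) -> ReLU -> MaxPool(2) -> global average
    over time, producing one value per filter (signal_out = filters)."""

    def __init__(self, cfg: EncoderConfig):
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        self.net = nn.Sequential(
            nn.Conv1D(1, cfg.conv1d_filters, cfg.conv1d_kernel, rng),
            nn.ReLU(),
            nn.MaxPool1D(cfg.pool),
            nn.GlobalAvgPool1D(),
        )
        self.head = (
            nn.Dense(cfg.conv1d_filters, cfg.signal_out, rng)
            if cfg.signal_out != cfg.conv1d_filters else None
        )

    def params(self):
        p = self.net.params()
        if self.head is not None:
            p += self.head.params()
        return p

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        if x.shape[1] < self.cfg.conv1d_kernel:
            raise ValueError(
                f"series length {x.shape[1]} shorter than kernel {self.cfg.conv1d_kernel}"
            )
        out = self.net.forward(x[..., None], train=train)
        if self.head is not None:
            out = self.head.forward(out, train=train)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self.head is not None:
            dout = self.head.backward(dout)
        return self.net.backward(dout)


# -- functional wrappers ----------------------------------------------------

def encode_text(feat: np.ndarray, cfg: EncoderConfig, encoder: TextEncoder | None = None) -> np.ndarray:
    enc = encoder if encoder is not None else TextEncoder(cfg)
    return enc.forward(feat, train=False)


def encode_image(image: np.ndarray, cfg: EncoderConfig, encoder: ImageEncoder | None = None) -> np.ndarray:
    enc = encoder if encoder is not None else ImageEncoder(cfg)
    return enc.forward(image, train=False)


def encode_signal(s: np.ndarray, cfg: EncoderConfig, encoder: SignalEncoder | None = None) -> np.ndarray:
    enc = encoder if encoder is not None else SignalEncoder(cfg)
    return enc.forward(s, train=False)
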