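"""Classifier architectures: a plain CNN and ResNet-18/34 built from blocks.

The plain CNN is three conv3x3-ReLU-maxpool stages (base widths 16/32/64)
with one hidden fully connected layer.  The residual families follow the
standard 18/34-layer layouts ([2,2,2,2] and [3,4,6,3] blocks over widths
64/128/256/512) with an input-size-adaptive stem.  A width multiplier scales
every channel count so desk-scale runs finish in minutes; multiplier 1 with
side 776 is the production configuration.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np

from ..errors import ConfigurationError
from .layers import (
    Adam,
    AvgPool2d,
    BatchNorm2d,
    Conv2d,
    Flatten,
    GlobalAvgPool,
    Linear,
    MaxPool2d,
    ReLU,
    ResidualBlock,
    Sequential,
    softmax,
)

FAMILIES = ("plain_cnn", "resnet18", "resnet34")
_RESNET_BLOCKS = {"resnet18": (2, 2, 2, 2), "resnet34": (3, 4, 6, 3)}
_STAGE_WIDTHS = (64, 128, 256, 512)


@dataclass
class ArchitectureSpec:
    family: str = "plain_cnn"
    side: int = 64
    n_classes: int = 2
    width: float = 1.0
    #: plain-CNN pooling: "mean" keeps within-window allele-frequency signal
    #: that a max would saturate away; "max" is the conventional alternative
    pooling: str = "mean"

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ConfigurationError(f"unknown family {self.family!r}")
        if self.side < 8:
            raise ConfigurationError("input side must be >= 8")
        if self.n_classes < 2:
            raise ConfigurationError("need >= 2 classes")
        if self.width <= 0:
            raise ConfigurationError("width multiplier must be positive")
        if self.pooling not in ("mean", "max"):
            raise ConfigurationError("pooling must be 'mean' or 'max'")


def _ch(base: int, width: float) -> int:
    return max(4, int(round(base * width)))


class Model:
    """A network plus bookkeeping: parameter access, prediction, Grad-CAM taps."""

    def __init__(self, net: Sequential, spec: ArchitectureSpec, target_conv: Conv2d,
                 cam_method: str = "elementwise"):
        self.net = net
        self.spec = spec
        #: last convolutional layer of the last block; stores activations and
        #: their gradients for Grad-CAM
        self.target_conv = target_conv
        #: saliency formulation suited to the head: 'channel' (classic, for a
        #: global-average-pool head) or 'elementwise' (fully-connected head)
        self.cam_method = cam_method

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if x.ndim == 3:
            x = x[:, None, :, :]
        return self.net.forward(x.astype(np.float32), train=train)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        return self.net.backward(dlogits)

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        outs = []
        for start in range(0, len(x), batch_size):
            outs.append(softmax(self.forward(x[start : start + batch_size], train=False)))
        return np.concatenate(outs, axis=0)

    def layers(self):
        return list(self.net.iter_layers())

    def param_layers(self):
        return [l for l in self.layers() if l.p]

    def n_parameters(self) -> int:
        return int(sum(p.size for l in self.param_layers() for p in l.p.values()))

    def state(self) -> list:
        return [copy.deepcopy(l.p) for l in self.param_layers()] + [
            (copy.deepcopy(l.running_mean), copy.deepcopy(l.running_var))
            for l in self.layers()
            if isinstance(l, BatchNorm2d)
        ]

    def load_state(self, state: list) -> None:
        pls = self.param_layers()
        for layer, p in zip(pls, state[: len(pls)]):
            layer.p = copy.deepcopy(p)
        bns = [l for l in self.layers() if isinstance(l, BatchNorm2d)]
        for layer, (rm, rv) in zip(bns, state[len(pls) :]):
            layer.running_mean = copy.deepcopy(rm)
            layer.running_var = copy.deepcopy(rv)

    def make_optimizer(self, lr: float, weight_decay: float = 0.0) -> Adam:
        return Adam(self.param_layers(), lr=lr, weight_decay=weight_decay)

    def gradcam_raw(
        self, x: np.ndarray, class_idx=None
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Target-layer activations/gradients, input gradients, class probabilities.

        Gradients are of the chosen class's logit; ``class_idx=None`` uses each
        sample's predicted class.  Batch-norm layers run in inference mode.
        """
        bns = [l for l in self.layers() if isinstance(l, BatchNorm2d)]
        self.target_conv.store_output = True
        for bn in bns:
            bn.frozen = True
        try:
            # train=True caches for backward; frozen BNs use running stats,
            # so the differentiated map is exactly the inference-mode network
            logits = self.forward(x, train=True)
            probs = softmax(logits)
            cls = np.argmax(probs, axis=1) if class_idx is None else np.full(len(x), class_idx)
            dlogits = np.zeros_like(logits)
            dlogits[np.arange(len(x)), cls] = 1.0
            dinput = self.backward(dlogits)
            acts = self.target_conv.last_output
            grads = self.target_conv.last_output_grad
        finally:
            self.target_conv.store_output = False
            self.target_conv.last_output = None
            self.target_conv.last_output_grad = None
            for bn in bns:
                bn.frozen = False
        return acts, grads, dinput[:, 0, :, :], probs


def build_model(spec: ArchitectureSpec, seed: int = 0) -> Model:
    """Construct an initialised classifier for ``spec``; weights drawn from ``seed``."""
    rng = np.random.default_rng(seed)
    if spec.family == "plain_cnn":
        return _build_plain_cnn(spec, rng)
    return _build_resnet(spec, rng)


def _build_plain_cnn(spec: ArchitectureSpec, rng) -> Model:
    w = spec.width
    c1, c2, c3 = _ch(16, w), _ch(32, w), _ch(64, w)
    hidden = _ch(64, w)
    side_out = spec.side // 8
    if side_out < 1:
        raise ConfigurationError(f"side {spec.side} too small for three pooling stages")
    pool = AvgPool2d if spec.pooling == "mean" else MaxPool2d
    last_conv = Conv2d(c2, c3, 3, pad=1, rng=rng)
    net = Sequential(
        Conv2d(1, c1, 3, pad=1, rng=rng),
        ReLU(),
        pool(2),
        Conv2d(c1, c2, 3, pad=1, rng=rng),
        ReLU(),
        pool(2),
        last_conv,
        ReLU(),
        pool(2),
        Flatten(),
        Linear(c3 * side_out * side_out, hidden, rng=rng),
        ReLU(),
        Linear(hidden, spec.n_classes, rng=rng),
    )
    return Model(net, spec, target_conv=last_conv, cam_method="elementwise")


def _build_resnet(spec: ArchitectureSpec, rng) -> Model:
    w = spec.width
    widths = [_ch(b, w) for b in _STAGE_WIDTHS]
    stem_downsample = spec.side >= 128
    min_side = 32 if stem_downsample else 8
    if spec.side < min_side:
        raise ConfigurationError(f"side {spec.side} too small for {spec.family}")
    layers = []
    if stem_downsample:
        layers += [Conv2d(1, widths[0], 7, stride=2, pad=3, bias=False, rng=rng), BatchNorm2d(widths[0]), ReLU(), MaxPool2d(2)]
    else:
        layers += [Conv2d(1, widths[0], 3, stride=1, pad=1, bias=False, rng=rng), BatchNorm2d(widths[0]), ReLU()]
    cin = widths[0]
    last_block = None
    for stage, n_blocks in enumerate(_RESNET_BLOCKS[spec.family]):
        for b in range(n_blocks):
            stride = 2 if (stage > 0 and b == 0) else 1
            block = ResidualBlock(cin, widths[stage], stride=stride, rng=rng)
            layers.append(block)
            cin = widths[stage]
            last_block = block
    layers += [GlobalAvgPool(), Linear(cin, spec.n_classes, rng=rng)]
    net = Sequential(*layers)
    return Model(net, spec, target_conv=last_block.conv2, cam_method="channel")
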