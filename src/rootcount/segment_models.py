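"""Lite-SegNet: a four-block VGG-style encoder-decoder segmenter.

The encoder mirrors VGG-16 truncated to four blocks (2-2-3-3 convolutions,
filters [64, 128, 256, 512]); every convolution is followed by batch norm
and ReLU, every block ends in a 2x2 max-pool whose argmax indices are
recorded.  The decoder upsamples with those indices (max-unpooling), so
each pooled maximum returns to its original location, then convolves.  All
convolutions are depthwise-separable except the very first, which stays
standard to preserve high-detail features.  The final layer is a per-pixel
2-class softmax (background vs storage root).

This network serves two roles: the front end of the segmentation-based
counting baseline, and the judge of GAN output quality (if synthetic images
segment about as well as real ones, they are usable as training data).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from . import data as rcdata
from .modelspec import ConvDesc, ModelSpec, TrainedModel
from .nn import autograd as ag
from .nn.layers import BatchNorm2d, Conv2d, Module, SeparableConv2d
from .nn.optim import Adam

__all__ = ["SegNetSpec", "build_segnet", "instantiate", "train_segmenter", "segment"]


@dataclass(frozen=True)
class SegNetSpec:
    input_width: int = 640
    input_height: int = 480
    filters_per_block: tuple = (64, 128, 256, 512)
    convs_per_block: tuple = (2, 2, 3, 3)      # VGG-16 ladder
    conv_kind: str = "separable"                # all but the first convolution
    n_classes: int = 2

    def __post_init__(self):
        if len(self.filters_per_block) != len(self.convs_per_block):
            raise ValueError("filters_per_block and convs_per_block must align")
        f = 2 ** len(self.filters_per_block)
        if self.input_width % f or self.input_height % f:
            raise ValueError(
                f"input {self.input_width}x{self.input_height} not divisible by 2^"
                f"{len(self.filters_per_block)} = {f}")


def _enumerate_convs(spec: SegNetSpec) -> list[ConvDesc]:
    sep = "separable" if spec.conv_kind == "separable" else "standard"
    convs, ch, first = [], 3, True
    for b, (f, n) in enumerate(zip(spec.filters_per_block, spec.convs_per_block)):
        for i in range(n):
            kind = "standard" if first else sep
            convs.append(ConvDesc(f"enc{b}/conv{i}", 3, ch, f, kind))
            ch, first = f, False
    for b in reversed(range(len(spec.filters_per_block))):
        f_out = spec.filters_per_block[max(b - 1, 0)]
        for i in range(spec.convs_per_block[b]):
            last_of_block = i == spec.convs_per_block[b] - 1
            out = f_out if last_of_block else spec.filters_per_block[b]
            convs.append(ConvDesc(f"dec{b}/conv{i}", 3, ch, out, sep))
            ch = out
    convs.append(ConvDesc("classifier", 1, ch, spec.n_classes, "standard"))
    return convs


def build_segnet(spec: SegNetSpec) -> ModelSpec:
    return ModelSpec(
        kind="litesegnet",
        input_size=(spec.input_height, spec.input_width),
        in_channels=3,
        output_arity=spec.n_classes,
        config=dataclasses.asdict(spec),
        convs=_enumerate_convs(spec),
    )


class _ConvBNReLU(Module):
    def __init__(self, in_ch, out_ch, separable, rng):
        super().__init__()
        if separable:
            self.conv = SeparableConv2d(in_ch, out_ch, 3, pad=1, bias=False, rng=rng)
        else:
            self.conv = Conv2d(in_ch, out_ch, 3, pad=1, bias=False, rng=rng)
        self.bn = BatchNorm2d(out_ch)

    def forward(self, x):
        return ag.relu(self.bn(self.conv(x)))


class LiteSegNet(Module):
    def __init__(self, spec: SegNetSpec, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.spec = spec
        sep = spec.conv_kind == "separable"
        self.enc, ch, first = [], 3, True
        for f, n in zip(spec.filters_per_block, spec.convs_per_block):
            block = []
            for _ in range(n):
                block.append(_ConvBNReLU(ch, f, sep and not first, rng))
                ch, first = f, False
            self.enc.append(block)
        self.dec = []
        for b in reversed(range(len(spec.filters_per_block))):
            f_out = spec.filters_per_block[max(b - 1, 0)]
            block = []
            for i in range(spec.convs_per_block[b]):
                last = i == spec.convs_per_block[b] - 1
                out = f_out if last else spec.filters_per_block[b]
                block.append(_ConvBNReLU(ch, out, sep, rng))
                ch = out
            self.dec.append(block)
        self.classifier = Conv2d(ch, spec.n_classes, 1, rng=rng)
        self.flat_modules = [m for blk in self.enc + self.dec for m in blk] + [self.classifier]

    def parameters(self):
        ps = []
        for m in self.flat_modules:
            ps.extend(m.parameters())
        return ps

    def modules(self):
        out = [self]
        for m in self.flat_modules:
            out.extend(m.modules())
        return out

    def forward(self, x):
        indices = []
        for block in self.enc:
            for m in block:
                x = m(x)
            x, idx = ag.maxpool2x2(x)
            indices.append(idx)
        for block, idx in zip(self.dec, reversed(indices)):
            x = ag.maxunpool2x2(x, idx)
            for m in block:
                x = m(x)
        return self.classifier(x)  # (B, n_classes, H, W) logits


def instantiate(model_spec: ModelSpec, seed: int = 0) -> LiteSegNet:
    cfg = dict(model_spec.config)
    cfg["filters_per_block"] = tuple(cfg["filters_per_block"])
    cfg["convs_per_block"] = tuple(cfg["convs_per_block"])
    return LiteSegNet(SegNetSpec(**cfg), seed=seed)


def train_segmenter(model: ModelSpec, manifest, epochs: int, batch_size: int = 2,
                    seed: int = 0, lr: float = 1e-3) -> TrainedModel:
    """Per-pixel cross-entropy training on binarized ground-truth masks."""
    rng = np.random.default_rng(seed)
    net = instantiate(model, seed=seed)
    hw = model.input_size
    x_tr, rows_tr, m_tr = rcdata.load_split(manifest, "train", hw, with_masks=True)
    x_va, rows_va, m_va = rcdata.load_split(manifest, "val", hw, with_masks=True)
    if len(x_tr) == 0:
        raise ValueError("manifest has no train rows with masks")
    y_tr = m_tr.astype(np.int64)
    y_va = m_va.astype(np.int64)
    opt = Adam(net.parameters(), lr=lr)
    history = {"epoch": [], "train_loss": [], "val_loss": []}
    for epoch in range(epochs):
        net.train()
        losses = []
        for idx in rcdata.iter_batches(len(x_tr), batch_size, rng):
            logits = net(ag.Tensor(x_tr[idx]))
            loss = ag.cross_entropy_logits(logits, y_tr[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history["epoch"].append(epoch)
        history["train_loss"].append(float(np.mean(losses)))
        _recalibrate(net, x_tr, batch_size)
        if len(x_va):
            net.eval()
            vl = []
            for idx in rcdata.iter_batches(len(x_va), batch_size):
                vl.append(float(ag.cross_entropy_logits(net(ag.Tensor(x_va[idx])), y_va[idx]).data) * len(idx))
            history["val_loss"].append(float(np.sum(vl) / len(x_va)))
        else:
            history["val_loss"].append(float("nan"))
    return TrainedModel(spec=model, net=net, history=history)


def _recalibrate(net, x_tr, batch_size):
    """Refresh batch-norm inference statistics on the training images
    (exact average of batch statistics; removes running-average lag)."""
    from .nn.layers import recalibrate_batchnorm
    batches = [x_tr[idx] for idx in rcdata.iter_batches(len(x_tr), batch_size)]
    recalibrate_batchnorm(net, lambda xb: net(ag.Tensor(xb)), batches)


def segment(model: TrainedModel, image: np.ndarray) -> np.ndarray:
    """Per-pixel storage-root probability map in [0, 1] for one HWC image."""
    hw = model.spec.input_size
    x = rcdata.to_nchw(rcdata.resize_image(image, hw)[None])
    model.net.eval()
    logits = model.net(ag.Tensor(x)).data[0]
    probs = ag.softmax(logits, axis=0)
    return probs[1]
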