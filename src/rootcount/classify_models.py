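"""Reduced-parameter DenseNet-style classifiers for age and count prediction.

The age model is a 2-way classifier ("old" vs "young"); the count model is
a direct image-to-count classifier with one softmax output per possible
storage-root count (7 classes for counts 0-6 by default).  Both share one
architecture: a standard convolution stem, four dense blocks whose unit
lengths are cut to [3, 6, 12, 8], transition layers with 0.5 compression,
and a global-average-pool + softmax head.  Every 3x3 convolution inside the
dense blocks is depthwise-separable, which is where the parameter saving
over the standard DenseNet comes from; 1x1 convolutions and the stem stay
standard, since separating a 1x1 adds parameters instead of removing them.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from . import data as rcdata
from .modelspec import ConvDesc, ModelSpec, TrainedModel, separable_param_count, standard_param_count
from .nn import autograd as ag
from .nn.layers import BatchNorm2d, Conv2d, Dense, Module, SeparableConv2d
from .nn.optim import Adam

__all__ = [
    "ClassifierSpec", "AugmentPolicy", "build_classifier", "instantiate",
    "train_classifier", "predict_class", "augment_image",
    "separable_param_count", "standard_param_count",
]


@dataclass(frozen=True)
class ClassifierSpec:
    """Architecture knobs of the reduced DenseNet classifier."""

    input_size: int = 256                 # square input, pixels
    dense_block_lengths: tuple = (3, 6, 12, 8)
    growth_rate: int = 32
    stem_filters: int = 64
    compression: float = 0.5
    output_arity: int = 7
    conv_kind: str = "separable"          # separable | standard

    def __post_init__(self):
        if len(self.dense_block_lengths) != 4:
            raise ValueError("dense_block_lengths must have exactly 4 entries")
        if self.output_arity < 2:
            raise ValueError("output_arity must be >= 2")
        if any(l < 1 for l in self.dense_block_lengths):
            raise ValueError("dense block lengths must be positive")
        if self.conv_kind not in ("separable", "standard"):
            raise ValueError(f"unknown conv_kind {self.conv_kind!r}")


@dataclass(frozen=True)
class AugmentPolicy:
    """Training-time augmentation: zoom, brightness scaling, small rotation,
    horizontal flip."""

    zoom_range: float = 0.2
    brightness_range: tuple = (0.2, 1.0)
    rotation_range: float = 10.0          # degrees
    horizontal_flip: bool = True


def _enumerate_convs(spec: ClassifierSpec) -> list[ConvDesc]:
    sep = "separable" if spec.conv_kind == "separable" else "standard"
    convs = [ConvDesc("stem", 3, 3, spec.stem_filters, "standard")]
    ch = spec.stem_filters
    for b, length in enumerate(spec.dense_block_lengths):
        for u in range(length):
            inter = 4 * spec.growth_rate
            convs.append(ConvDesc(f"block{b}/unit{u}/bottleneck", 1, ch, inter, "standard"))
            convs.append(ConvDesc(f"block{b}/unit{u}/spatial", 3, inter, spec.growth_rate, sep))
            ch += spec.growth_rate
        if b < 3:
            out = max(1, int(ch * spec.compression))
            convs.append(ConvDesc(f"transition{b}", 1, ch, out, "standard"))
            ch = out
    convs.append(ConvDesc("head", 1, ch, spec.output_arity, "standard"))  # dense layer, 1x1-equivalent
    return convs


def build_classifier(spec: ClassifierSpec) -> ModelSpec:
    """Produce the declarative ModelSpec for a classifier."""
    return ModelSpec(
        kind="densenet",
        input_size=(spec.input_size, spec.input_size),
        in_channels=3,
        output_arity=spec.output_arity,
        config=dataclasses.asdict(spec),
        convs=_enumerate_convs(spec),
    )


class _DenseUnit(Module):
    def __init__(self, in_ch, growth, conv_kind, rng):
        super().__init__()
        inter = 4 * growth
        self.bn1 = BatchNorm2d(in_ch)
        self.conv1 = Conv2d(in_ch, inter, 1, bias=False, rng=rng)
        self.bn2 = BatchNorm2d(inter)
        if conv_kind == "separable":
            self.conv2 = SeparableConv2d(inter, growth, 3, pad=1, bias=False, rng=rng)
        else:
            self.conv2 = Conv2d(inter, growth, 3, pad=1, bias=False, rng=rng)

    def forward(self, x):
        y = self.conv1(ag.relu(self.bn1(x)))
        y = self.conv2(ag.relu(self.bn2(y)))
        return ag.concat([x, y], axis=1)


class _Transition(Module):
    def __init__(self, in_ch, out_ch, rng):
        super().__init__()
        self.bn = BatchNorm2d(in_ch)
        self.conv = Conv2d(in_ch, out_ch, 1, bias=False, rng=rng)

    def forward(self, x):
        return ag.avgpool2x2(self.conv(ag.relu(self.bn(x))))


class DenseNetLite(Module):
    """Instantiated reduced DenseNet; forward returns logits (B, arity)."""

    def __init__(self, spec: ClassifierSpec, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.spec = spec
        self.stem = Conv2d(3, spec.stem_filters, 3, stride=2, pad=1, bias=False, rng=rng)
        self.stem_bn = BatchNorm2d(spec.stem_filters)
        ch = spec.stem_filters
        self.blocks = []
        for b, length in enumerate(spec.dense_block_lengths):
            units = []
            for _ in range(length):
                units.append(_DenseUnit(ch, spec.growth_rate, spec.conv_kind, rng))
                ch += spec.growth_rate
            self.blocks.append(units)
            if b < 3:
                out = max(1, int(ch * spec.compression))
                self.blocks.append([_Transition(ch, out, rng)])
                ch = out
        self.flat_modules = [m for grp in self.blocks for m in grp]  # for parameters()
        self.head_bn = BatchNorm2d(ch)
        self.head = Dense(ch, spec.output_arity, rng=rng)

    def forward(self, x):
        x = ag.relu(self.stem_bn(self.stem(x)))
        y, _ = ag.maxpool2x2(x)
        for grp in self.blocks:
            for m in grp:
                y = m(y)
        y = ag.global_avg_pool(ag.relu(self.head_bn(y)))
        return self.head(y)

    def parameters(self):
        ps = self.stem.parameters() + self.stem_bn.parameters()
        for m in self.flat_modules:
            ps.extend(m.parameters())
        return ps + self.head_bn.parameters() + self.head.parameters()

    def modules(self):
        out = [self, self.stem, self.stem_bn]
        for m in self.flat_modules:
            out.extend(m.modules())
        out.extend([self.head_bn, self.head])
        return out


def instantiate(model_spec: ModelSpec, seed: int = 0) -> DenseNetLite:
    cfg = dict(model_spec.config)
    cfg["dense_block_lengths"] = tuple(cfg["dense_block_lengths"])
    return DenseNetLite(ClassifierSpec(**cfg), seed=seed)


# ------------------------------------------------------------- augmentation

def augment_image(img_hw3: np.ndarray, policy: AugmentPolicy, rng: np.random.Generator) -> np.ndarray:
    """Apply one random draw of the augmentation policy to an HWC image."""
    out = img_hw3
    angle = rng.uniform(-policy.rotation_range, policy.rotation_range)
    zoom = 1.0 + rng.uniform(-policy.zoom_range, policy.zoom_range)
    if abs(angle) > 1e-3:
        out = ndi.rotate(out, angle, axes=(0, 1), reshape=False, order=1, mode="nearest")
    if abs(zoom - 1.0) > 1e-3:
        h, w = out.shape[:2]
        zoomed = ndi.zoom(out, (zoom, zoom, 1), order=1)
        zh, zw = zoomed.shape[:2]
        if zoom >= 1.0:  # center crop back
            y0, x0 = (zh - h) // 2, (zw - w) // 2
            out = zoomed[y0:y0 + h, x0:x0 + w]
        else:            # pad back
            pad_y, pad_x = h - zh, w - zw
            out = np.pad(zoomed, ((pad_y // 2, pad_y - pad_y // 2),
                                  (pad_x // 2, pad_x - pad_x // 2), (0, 0)), mode="edge")
    out = out * rng.uniform(*policy.brightness_range)
    if policy.horizontal_flip and rng.random() < 0.5:
        out = out[:, ::-1]
    return np.clip(out, 0.0, 1.0).astype(np.float32)


# ----------------------------------------------------------------- training

def train_classifier(model: ModelSpec, manifest, augment: AugmentPolicy | None,
                     epochs: int, batch_size: int = 32, seed: int = 0,
                     lr: float = 1e-3, label_column: str = "count") -> TrainedModel:
    """Train a classifier on the manifest's train split, validating on val.

    Labels come from ``label_column``: integer counts directly, or age
    strings mapped through ``data.AGE_TO_LABEL``.  Categorical
    cross-entropy on one-hot targets, Adam, fully seeded.
    """
    rng = np.random.default_rng(seed)
    net = instantiate(model, seed=seed)
    hw = model.input_size

    def labels_of(rows):
        if label_column == "age":
            return rows["age"].map(rcdata.AGE_TO_LABEL).to_numpy(dtype=np.int64)
        return rows[label_column].to_numpy(dtype=np.int64)

    x_tr, rows_tr = rcdata.load_split(manifest, "train", hw)
    x_va, rows_va = rcdata.load_split(manifest, "val", hw)
    y_tr, y_va = labels_of(rows_tr), labels_of(rows_va)
    for name, y in (("train", y_tr), ("val", y_va)):
        if y.size and (y.min() < 0 or y.max() >= model.output_arity):
            raise ValueError(
                f"{name} labels outside [0, {model.output_arity}): a count class "
                f"exceeds the model arity (missing-class/arity mismatch)")

    opt = Adam(net.parameters(), lr=lr)
    history = {"epoch": [], "train_loss": [], "train_acc": [], "val_loss": [], "val_acc": []}
    for epoch in range(epochs):
        net.train()
        losses, correct, seen = [], 0, 0
        for idx in rcdata.iter_batches(len(x_tr), batch_size, rng):
            xb = x_tr[idx]
            if augment is not None:
                xb = np.stack([
                    augment_image(im.transpose(1, 2, 0), augment, rng).transpose(2, 0, 1)
                    for im in xb])
            yb = y_tr[idx]
            logits = net(ag.Tensor(xb))
            loss = ag.cross_entropy_logits(logits, yb)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            correct += int((logits.data.argmax(axis=1) == yb).sum())
            seen += len(idx)
        _recalibrate(net, x_tr, batch_size)
        vl, va = _evaluate(net, x_va, y_va, batch_size)
        history["epoch"].append(epoch)
        history["train_loss"].append(float(np.mean(losses)) if losses else float("nan"))
        history["train_acc"].append(correct / max(seen, 1))
        history["val_loss"].append(vl)
        history["val_acc"].append(va)
    return TrainedModel(spec=model, net=net, history=history)


def _recalibrate(net, x_tr, batch_size):
    """Re-estimate batch-norm inference statistics on the (un-augmented)
    training images; cheap and removes the running-average lag after short
    trainings."""
    if len(x_tr) == 0:
        return
    from .nn.layers import recalibrate_batchnorm
    batches = [x_tr[idx] for idx in rcdata.iter_batches(len(x_tr), batch_size)]
    recalibrate_batchnorm(net, lambda xb: net(ag.Tensor(xb)), batches)


def _evaluate(net, x, y, batch_size):
    if len(x) == 0:
        return float("nan"), float("nan")
    net.eval()
    losses, correct = [], 0
    for idx in rcdata.iter_batches(len(x), batch_size):
        logits = net(ag.Tensor(x[idx]))
        losses.append(float(ag.cross_entropy_logits(logits, y[idx]).data) * len(idx))
        correct += int((logits.data.argmax(axis=1) == y[idx]).sum())
    return float(np.sum(losses) / len(x)), correct / len(x)


def predict_class(model: TrainedModel, image: np.ndarray):
    """Predict (label, probs) for one HWC image in [0, 1].

    The label is the argmax with lowest-index tie-break; probs sum to 1.
    """
    hw = model.spec.input_size
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) image, got shape {image.shape}")
    x = rcdata.to_nchw(rcdata.resize_image(image, hw)[None])
    model.net.eval()
    logits = model.net(ag.Tensor(x)).data[0]
    probs = ag.softmax(logits)
    return int(np.argmax(probs)), probs
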