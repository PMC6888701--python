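"""Conditional mask-to-image GAN for synthesizing root images.

A pix2pix-style image-to-image translator: the generator is a U-Net whose
encoder/decoder are two blocks deeper than the original eight (block lists
C64..C512x7 / D512x6-D256-D128-D64), the discriminator is a four-block
PatchGAN whose output grid is the input size divided by 16 (60 x 45 at the
960 x 720 capture resolution).  All convolutions are 4 x 4, stride 2.  The
generator objective combines the adversarial patch loss with a content
(perceptual) reconstruction term weighted by ``lambda_content``; the
content term compares feature maps of a fixed network (VGG when pretrained
weights are available, otherwise a fixed random-weight convolutional
feature extractor) or plain pixels.

Given a trained generator, conditioning masks for a count class absent
from the data are synthesized by combining library masks of other counts
(see :mod:`rootcount.maskops`), which is how missing count classes are
filled with labeled synthetic samples.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np

from . import data as rcdata
from . import maskops
from .modelspec import ConvDesc, ModelSpec, TrainedModel
from .nn import autograd as ag
from .nn.layers import BatchNorm2d, Conv2d, ConvTranspose2d, Module
from .nn.optim import Adam
from .synthdata import Sample

log = logging.getLogger(__name__)

__all__ = [
    "GanSpec", "TrainConfig", "build_generator", "build_discriminator",
    "instantiate_generator", "instantiate_discriminator", "content_loss",
    "train_gan", "generate_for_missing_class",
]

ENCODER_FILTERS = (64, 128, 256, 512, 512, 512, 512, 512, 512, 512)
DECODER_FILTERS = (512, 512, 512, 512, 512, 512, 256, 128, 64)


@dataclass(frozen=True)
class GanSpec:
    encoder_filters: tuple = ENCODER_FILTERS
    decoder_filters: tuple = DECODER_FILTERS
    kernel: int = 4
    stride: int = 2
    disc_filters: tuple = (64, 128, 256, 512)
    dropout_blocks: tuple = (0, 1, 2)       # decoder blocks using dropout
    dropout_rate: float = 0.5
    lambda_content: float = 100.0
    content_net: str = "vgg16_features"     # vgg16_features | vgg19_features | random_features | mse_pixels

    def __post_init__(self):
        if self.content_net not in ("vgg16_features", "vgg19_features",
                                    "random_features", "mse_pixels"):
            raise ValueError(f"unknown content_net {self.content_net!r}")


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 2e-4
    beta1: float = 0.5
    beta2: float = 0.999
    epochs: int = 900
    batch_size: int = 2
    seed: int = 0

    def __post_init__(self):
        if min(self.lr, self.beta1, self.beta2, self.batch_size) <= 0 or self.epochs < 0:
            raise ValueError("invalid training configuration")


def _depth(h: int, w: int, max_blocks: int) -> int:
    """Number of stride-2 encoder blocks applicable before a spatial dim
    stops halving exactly or reaches 1."""
    n = 0
    while n < max_blocks and h % 2 == 0 and w % 2 == 0 and h > 1 and w > 1:
        h //= 2
        w //= 2
        n += 1
    return n


def build_generator(spec: GanSpec, input_size: tuple[int, int]) -> ModelSpec:
    """U-Net generator ModelSpec for masks of ``input_size`` (height, width).

    Encoder depth is capped so every downsampling halves both dims exactly;
    surplus blocks from the configured lists are skipped symmetrically in
    the decoder.
    """
    h, w = input_size
    n_down = _depth(h, w, len(spec.encoder_filters))
    if n_down < 2:
        raise ValueError(f"input {h}x{w} too small or not 2-divisible for a U-Net")
    enc = list(spec.encoder_filters[:n_down])
    dec = list(spec.decoder_filters[len(spec.decoder_filters) - (n_down - 1):])
    k = spec.kernel
    convs, ch = [], 1
    for i, f in enumerate(enc):
        convs.append(ConvDesc(f"enc{i}", k, ch, f, "standard"))
        ch = f
    for i, f in enumerate(dec):
        convs.append(ConvDesc(f"dec{i}", k, ch, f, "transpose"))
        ch = f + enc[n_down - 2 - i]  # skip concatenation
    convs.append(ConvDesc("out", k, ch, 3, "transpose"))
    return ModelSpec(kind="unet_generator", input_size=(h, w), in_channels=1,
                     output_arity=3, config=dataclasses.asdict(spec) | {"n_down": n_down},
                     convs=convs)


def build_discriminator(spec: GanSpec, input_size: tuple[int, int]) -> ModelSpec:
    """PatchGAN ModelSpec: scores (mask, image) pairs patch-wise; the output
    grid is input/2^len(disc_filters) — 60 x 45 for 960 x 720 inputs."""
    h, w = input_size
    f = 2 ** len(spec.disc_filters)
    if h % f or w % f:
        raise ValueError(f"input {h}x{w} not divisible by {f}")
    k = spec.kernel
    convs, ch = [], 4  # 3 image channels + 1 mask channel
    for i, flt in enumerate(spec.disc_filters):
        convs.append(ConvDesc(f"disc{i}", k, ch, flt, "standard"))
        ch = flt
    convs.append(ConvDesc("patch_out", 3, ch, 1, "standard"))
    return ModelSpec(kind="patch_discriminator", input_size=(h, w), in_channels=4,
                     output_arity=1,
                     config=dataclasses.asdict(spec) | {"patch_grid": (h // f, w // f)},
                     convs=convs)


class UNetGenerator(Module):
    """Encoder C-blocks (conv 4x4/s2 - LeakyReLU - BN), decoder CD-blocks
    (transpose conv - dropout - BN - ReLU) with mirror skip connections;
    tanh output rescaled to [0, 1]."""

    def __init__(self, spec: GanSpec, input_size, seed: int = 0):
        super().__init__()
        self.rng = np.random.default_rng(seed)
        ms = build_generator(spec, tuple(input_size))
        self.spec_cfg = spec
        n_down = ms.config["n_down"]
        enc = list(spec.encoder_filters[:n_down])
        dec = list(spec.decoder_filters[len(spec.decoder_filters) - (n_down - 1):])
        rng = self.rng
        self.enc_convs, self.enc_bns = [], []
        ch = 1
        for i, f in enumerate(enc):
            self.enc_convs.append(Conv2d(ch, f, spec.kernel, stride=2, pad=1, rng=rng))
            self.enc_bns.append(BatchNorm2d(f) if i > 0 else None)
            ch = f
        self.dec_convs, self.dec_bns, self.dec_drop = [], [], []
        for i, f in enumerate(dec):
            self.dec_convs.append(ConvTranspose2d(ch, f, spec.kernel, stride=2, pad=1, rng=rng))
            self.dec_bns.append(BatchNorm2d(f))
            self.dec_drop.append(i in spec.dropout_blocks)
            ch = f + enc[n_down - 2 - i]
        self.out_conv = ConvTranspose2d(ch, 3, spec.kernel, stride=2, pad=1, rng=rng)
        self.flat_modules = (self.enc_convs + [b for b in self.enc_bns if b]
                             + self.dec_convs + self.dec_bns + [self.out_conv])

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
        skips = []
        for conv, bn in zip(self.enc_convs, self.enc_bns):
            x = conv(x)
            x = ag.leaky_relu(x, 0.2)
            if bn is not None:
                x = bn(x)
            skips.append(x)
        y = skips[-1]
        n = len(self.enc_convs)
        for i, (conv, bn, drop) in enumerate(zip(self.dec_convs, self.dec_bns, self.dec_drop)):
            y = conv(y)
            if drop:
                y = ag.dropout(y, self.spec_cfg.dropout_rate, self.rng, self.training)
            y = ag.relu(bn(y))
            y = ag.concat([y, skips[n - 2 - i]], axis=1)
        y = ag.tanh(self.out_conv(y))
        return ag.mul(ag.add(y, ag.Tensor(np.ones((), dtype=np.float32))), 0.5)  # [-1,1] -> [0,1]


class PatchDiscriminator(Module):
    def __init__(self, spec: GanSpec, input_size, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.convs, self.bns = [], []
        ch = 4
        for i, f in enumerate(spec.disc_filters):
            self.convs.append(Conv2d(ch, f, spec.kernel, stride=2, pad=1, rng=rng))
            self.bns.append(BatchNorm2d(f) if i > 0 else None)
            ch = f
        self.out_conv = Conv2d(ch, 1, 3, stride=1, pad=1, rng=rng)
        self.flat_modules = self.convs + [b for b in self.bns if b] + [self.out_conv]

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

    def forward(self, mask_and_image):
        x = mask_and_image
        for conv, bn in zip(self.convs, self.bns):
            x = conv(x)
            x = ag.leaky_relu(x, 0.2)
            if bn is not None:
                x = bn(x)
        return self.out_conv(x)  # patch logits (B, 1, H/16, W/16)


def instantiate_generator(model_spec: ModelSpec, seed: int = 0) -> UNetGenerator:
    cfg = {k: v for k, v in model_spec.config.items() if k != "n_down"}
    for key in ("encoder_filters", "decoder_filters", "disc_filters", "dropout_blocks"):
        cfg[key] = tuple(cfg[key])
    return UNetGenerator(GanSpec(**cfg), model_spec.input_size, seed=seed)


def instantiate_discriminator(model_spec: ModelSpec, seed: int = 0) -> PatchDiscriminator:
    cfg = {k: v for k, v in model_spec.config.items() if k != "patch_grid"}
    for key in ("encoder_filters", "decoder_filters", "disc_filters", "dropout_blocks"):
        cfg[key] = tuple(cfg[key])
    return PatchDiscriminator(GanSpec(**cfg), model_spec.input_size, seed=seed)


# -------------------------------------------------------------- content loss

_FEATURE_NET: dict[str, list] = {}


def _random_feature_weights():
    """Fixed random-weight conv stack used as an offline feature extractor."""
    if "random" not in _FEATURE_NET:
        rng = np.random.default_rng(1234567)
        w1 = ag.Tensor(rng.normal(0, np.sqrt(2 / 27), (16, 3, 3, 3)).astype(np.float32))
        w2 = ag.Tensor(rng.normal(0, np.sqrt(2 / 144), (32, 16, 3, 3)).astype(np.float32))
        _FEATURE_NET["random"] = [w1, w2]
    return _FEATURE_NET["random"]


def _random_features(x):
    w1, w2 = _random_feature_weights()
    h = ag.leaky_relu(ag.conv2d(x, w1, stride=2, pad=1), 0.2)
    return ag.leaky_relu(ag.conv2d(h, w2, stride=2, pad=1), 0.2)


def content_loss(real, fake, content_net: str = "mse_pixels"):
    """Reconstruction term of the generator objective.

    ``mse_pixels`` is plain pixel MSE; ``random_features`` compares feature
    maps of a fixed random conv net; the ``vgg*`` options require pretrained
    weights and fall back to ``random_features`` with a warning when those
    cannot be loaded (always the case without a weights file).
    """
    if not isinstance(real, ag.Tensor):
        real = ag.Tensor(np.asarray(real, dtype=np.float32))
    if not isinstance(fake, ag.Tensor):
        fake = ag.Tensor(np.asarray(fake, dtype=np.float32))
    if real.data.shape != fake.data.shape:
        raise ValueError(f"shape mismatch {real.data.shape} vs {fake.data.shape}")
    if content_net in ("vgg16_features", "vgg19_features"):
        log.warning("pretrained %s weights unavailable; falling back to "
                    "random_features for the content loss", content_net)
        content_net = "random_features"
    if content_net == "mse_pixels":
        return ag.mse_loss(fake, real)
    if content_net == "random_features":
        return ag.mse_loss(_random_features(fake), _random_features(real.detach()))
    raise ValueError(f"unknown content_net {content_net!r}")


# ------------------------------------------------------------------ training

def train_gan(gen_model: ModelSpec, disc_model: ModelSpec, manifest,
              train_cfg: TrainConfig, spec: GanSpec):
    """Alternating pix2pix training on (mask, image) pairs from the train
    split.  Returns (generator TrainedModel, discriminator TrainedModel,
    history dict of per-epoch losses)."""
    rng = np.random.default_rng(train_cfg.seed)
    hw = gen_model.input_size
    imgs, rows, masks = rcdata.load_split(manifest, "train", hw, with_masks=True)
    if len(imgs) == 0:
        raise ValueError("manifest has no train rows for GAN training")
    xmask = masks.astype(np.float32)[:, None]  # (N, 1, H, W)

    gen = instantiate_generator(gen_model, seed=train_cfg.seed)
    disc = instantiate_discriminator(disc_model, seed=train_cfg.seed + 1)
    opt_g = Adam(gen.parameters(), lr=train_cfg.lr, beta1=train_cfg.beta1, beta2=train_cfg.beta2)
    opt_d = Adam(disc.parameters(), lr=train_cfg.lr, beta1=train_cfg.beta1, beta2=train_cfg.beta2)

    history = {"epoch": [], "d_loss": [], "g_adv": [], "g_content": [], "g_total": []}
    for epoch in range(train_cfg.epochs):
        gen.train()
        disc.train()
        dl, gadv, gcon, gtot = [], [], [], []
        for idx in rcdata.iter_batches(len(imgs), train_cfg.batch_size, rng):
            xb = ag.Tensor(xmask[idx])
            yb = ag.Tensor(imgs[idx])
            fake = gen(xb)

            # discriminator step
            d_real = disc(ag.concat([xb, yb], axis=1))
            d_fake = disc(ag.concat([xb.detach(), fake.detach()], axis=1))
            d_loss = ag.mul(ag.add(ag.bce_logits(d_real, 1.0), ag.bce_logits(d_fake, 0.0)), 0.5)
            opt_d.zero_grad()
            gen.zero_grad()
            d_loss.backward()
            opt_d.step()

            # generator step (discriminator frozen: its grads are discarded)
            d_on_fake = disc(ag.concat([xb.detach(), fake], axis=1))
            g_adv = ag.bce_logits(d_on_fake, 1.0)
            g_con = content_loss(yb.detach(), fake, spec.content_net)
            g_loss = ag.add(g_adv, ag.mul(g_con, spec.lambda_content))
            opt_g.zero_grad()
            opt_d.zero_grad()
            g_loss.backward()
            opt_g.step()

            dl.append(float(d_loss.data))
            gadv.append(float(g_adv.data))
            gcon.append(float(g_con.data))
            gtot.append(float(g_loss.data))
        history["epoch"].append(epoch)
        history["d_loss"].append(float(np.mean(dl)))
        history["g_adv"].append(float(np.mean(gadv)))
        history["g_content"].append(float(np.mean(gcon)))
        history["g_total"].append(float(np.mean(gtot)))
    return (TrainedModel(spec=gen_model, net=gen, history=history),
            TrainedModel(spec=disc_model, net=disc, history=history),
            history)


def _compatible(hw, n_down) -> bool:
    f = 2 ** n_down
    return hw[0] % f == 0 and hw[1] % f == 0


def generate_image(gen: TrainedModel, mask: np.ndarray) -> np.ndarray:
    """Run the generator on one binary mask; returns an HWC image in [0, 1].

    The U-Net is fully convolutional, so masks of any size whose dims
    survive the encoder's halvings are processed at native resolution;
    incompatible sizes are resized to the training resolution first
    (resizing thin masks can fragment them, so native is preferred).
    """
    m = np.asarray(mask, dtype=bool)
    n_down = gen.spec.config.get("n_down", len(gen.spec.config["encoder_filters"]))
    if not _compatible(m.shape, n_down):
        m = rcdata.resize_image(m.astype(np.float32), gen.spec.input_size) > 0.5
    gen.net.eval()
    x = ag.Tensor(m.astype(np.float32)[None, None])
    img = gen.net(x).data[0]
    return np.clip(img.transpose(1, 2, 0), 0.0, 1.0)


def generate_for_missing_class(gen: TrainedModel, library: maskops.MaskLibrary,
                               target_count: int, n: int, seed: int,
                               age: str = "old") -> list[Sample]:
    """Synthesize ``n`` labeled samples for a count class with no real data.

    Conditioning masks are built by combining library masks whose counts sum
    to ``target_count``; each is passed through the generator and the result
    labeled with that count and provenance ``gan``.
    """
    out = []
    hw = gen.spec.input_size
    n_down = gen.spec.config.get("n_down", len(gen.spec.config["encoder_filters"]))
    for i in range(n):
        # when the library resolution cannot be fed natively, resizing can
        # fragment or merge components; retry combinations until the label
        # stays truthful
        for attempt in range(25):
            sub = int(np.random.SeedSequence(
                [seed, target_count, i, attempt]).generate_state(1)[0] % (2**31))
            m = maskops.combine_masks(library, target_count, sub)
            if not _compatible(m.shape, n_down):
                m = rcdata.resize_image(m.astype(np.float32), hw) > 0.5
            if maskops.count_components(m, library.min_area) == target_count:
                break
        else:
            raise maskops.PlacementError(
                f"could not preserve {target_count} components at the "
                f"generator resolution {hw}")
        img = generate_image(gen, m)
        out.append(Sample(image=img, mask=m, count=target_count, age=age, provenance="gan"))
    return out
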