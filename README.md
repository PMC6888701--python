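# rootcount

Counting cassava storage roots in RGB images.

Cassava (*Manihot esculenta*) yield is reflected in the number and size of
its storage roots — the thickened roots that accumulate starch.  In
aeroponic phenotyping systems the roots are photographed hanging over a
dark background, where a handful of thick, tapered storage roots are
tangled with many thin fibrous roots of similar colour.  Counting them by
hand is slow and error-prone; counting them by segmenting first fails when
roots overlap or the segmentation is imperfect.

`rootcount` implements a **direct image-to-count** pipeline: counting is
posed as classification, with one softmax output per possible count
(0–6 storage roots by default).  Because a classifier needs training
examples of *every* count class, the package also implements a
**conditional GAN** that synthesizes root images from storage-root masks,
so that count classes missing from the data can be filled with labeled
synthetic images whose conditioning masks are built by combining existing
masks (e.g. a 2-root and a 3-root mask, horizontally translated to avoid
overlap, yield a 5-root mask).

## Components

| Module | What it does |
|---|---|
| `rootcount.synthdata` | Procedural generator of root-like images, masks, counts and age labels (the package is fully testable without field data) |
| `rootcount.maskops` | Conditioning-mask synthesis for missing classes, morphological denoising, contour/component counting |
| `rootcount.metrics` | Segmentation scores (pixel accuracy, MeanIoU, average precision/recall from the pixel confusion matrix) and counting scores (PercentAgreement, CountDiff, AbsCountDiff, MSE) |
| `rootcount.classify_models` | Reduced-parameter DenseNet-style classifiers (dense blocks cut to 3-6-12-8 units, depthwise-separable 3×3 convolutions) for 2-way age and 7-way count prediction |
| `rootcount.segment_models` | Lite-SegNet: a four-block VGG-style encoder–decoder with max-pooling-index upsampling, the segmentation-based counting baseline |
| `rootcount.gan` | pix2pix-style conditional GAN (U-Net generator two blocks deeper than the original, 60×45 PatchGAN discriminator at capture resolution, perceptual content loss) |
| `rootcount.pipeline` | Two-stage inference — an age model routes each image to the "old" or "young" count model — plus missing-class augmentation and end-to-end evaluation |
| `rootcount.nn` | The numpy neural-network engine underneath: reverse-mode autograd, conv/transpose-conv/separable-conv/batch-norm/pooling-with-indices ops, Adam |

A key arithmetic fact the classifiers rely on: a k×k standard convolution
with c_in→c_out channels costs `k²·c_in·c_out` weights, while its
depthwise-separable factorization costs `k²·c_in + c_in·c_out` — for a
3×3, 64→64 layer that is 4 672 vs 36 864 parameters (ratio ≈ 1/c_out + 1/k²).

## Worked example

```python
from rootcount import synthdata, maskops

cfg = synthdata.old_preset(160, 120)     # "old" roots: thick, bright
sample = synthdata.generate_sample(cfg, count=3, rng_seed=7)
print(sample.image.shape, sample.mask.sum())
print(maskops.count_components(sample.mask))
```

prints

```
(120, 160, 3) 873
3
```

— a 120×160 RGB image whose ground-truth mask has 873 storage-root
pixels forming exactly the 3 requested components.  Counting the same mask
through the segmentation baseline's pipeline
(`maskops.count_from_segmentation(sample.mask.astype(float))`) recovers 3
as well.

The shell surface mirrors the library (`rootcount synth | split |
train-age | train-count | train-seg | train-gan | gan-generate | segment |
predict | count-seg | evaluate`), e.g.:

```bash
rootcount synth --out ds --seed 3 --width 64 --height 64 --n-per-count 0:2,1:2,2:2
rootcount train-age --manifest ds/manifest.csv --out models/age --epochs 10
```

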