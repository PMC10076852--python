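# radunet

Segmentation of small lung lesions in 2-D CT slices with **RAD-UNet**, a
U-Net variant built from three ingredients:

* a **residual encoder** — four stages of two residual blocks each
  (`ReLU(conv(conv(F)) + F)`), easing optimization of the deep contracting path;
* an **improved ASPP bottleneck** — five parallel branches (a 1×1
  convolution, three 3×3 atrous convolutions at small rates 2/3/4, and
  image-level average pooling) whose outputs are concatenated and
  projected.  Small rates matter because stacked 3×3 atrous layers grow
  the receptive field as `RF_i = RF_{i-1} + (k−1)·r_i`, i.e. 3×3 → 7×7 →
  15×15 at rates (1, 2, 4), which suits few-pixel lesions;
* a **dual-feature cross-fusion (DFCF) decoder** — at each of the four
  upsampling stages, CBAM-style attention fuses the encoder skip (local
  semantic features, LSF) with the upsampled decoder stream (global
  semantic features, GSF): channel weights `σ(MLP(AvgPool F) + MLP(MaxPool F))`
  computed from one stream are applied to the *other*, in both
  directions; each branch then passes spatial attention
  `σ(f₇ₓ₇[AvgPoolc; MaxPoolc])` before the branches are combined.

Training minimizes the class-imbalance-aware compound loss
`L = L_BCE + L_Dice` with `L_Dice = 1 − (2Σyŷ + 1)/(Σy + Σŷ + 1)`, using
Adam.  Evaluation is the full confusion-matrix suite — per-image IoU,
mIoU, recall, precision, F1 — overall and per clinical lesion-size class
(micro nodule d ≤ 5 mm, small nodule 5 < d ≤ 10, nodule 10 < d ≤ 30,
lung mass d > 30).

Because real thoracic CT datasets are large and restricted, the package
ships a **synthetic nodule-phantom generator**: low-contrast disks with
blurred edges on a textured background, with exact ground-truth masks —
enough to exercise and test every stage end to end on a CPU.

The network runs on a small self-contained numpy autodiff core
(`radunet.nn`): stride-1 convolutions with dilation, max pooling,
bilinear upsampling, channel/spatial pooling, and an Adam optimizer, all
with reverse-mode gradients verified against finite differences.

## Worked example

```python
import numpy as np
from radunet import (PhantomSpec, RADUNetConfig, build_radunet,
                     generate_dataset, stacked_receptive_field)
from radunet.train import TrainConfig, evaluate, train

print("receptive fields:", stacked_receptive_field(3, (1, 2, 4)))

spec = PhantomSpec(seed=42)                       # 64x64 low-contrast phantoms
train_set, test_set = generate_dataset(spec, 250, train_fraction=0.8)
print(f"{len(train_set)} train / {len(test_set)} test phantoms")

model = build_radunet(RADUNetConfig(base_channels=8, seed=42))
print(f"model parameters: {model.n_parameters():,}")

model, log = train(model, train_set, TrainConfig(batch_size=8, epochs=12, seed=42))
print(f"epoch-1 loss {log.epoch_loss[0]:.3f} -> epoch-12 loss {log.epoch_loss[-1]:.3f}")

report = evaluate(model, test_set)
print(report.to_frame().round(2).to_string(index=False))
```

Output (about two minutes on one CPU):

```
receptive fields: (3, 7, 15)
200 train / 50 test phantoms
model parameters: 1,083,405
epoch-1 loss 1.130 -> epoch-12 loss 0.098
    category  n  mIoU/%  Recall/%  Precision/%  F1-score/%
         all 50   87.77     92.65        94.65       93.30
micro_nodule  3   83.40     93.14        89.43       90.83
      nodule 12   87.40     89.05        97.92       93.05
small_nodule 35   88.28     93.85        93.98       93.60
```

The loss falls by an order of magnitude over 12 epochs and the trained
model recovers the phantom lesions at ≈88% mean IoU; the per-category
rows break the test set down by lesion-size class (smaller lesions are
harder, mirroring the clinical difficulty).  An untrained model scores
mIoU 0 on the same split.

## Command-line interface

```bash
radunet generate --n 100 --out data/phantoms --seed 7
radunet train    --data data/phantoms --out runs/model.npz --epochs 12 --batch-size 8
radunet evaluate --data data/phantoms --checkpoint runs/model.npz --out runs/metrics.json
radunet segment  --image data/phantoms/images/test_0000.png \
                 --checkpoint runs/model.npz --out mask.png
```

Every subcommand accepts `--config config.yaml` with `phantom`, `window`,
`model` and `train` sections mirroring the config dataclasses.  Real CT
input in Hounsfield units (DICOM/NIfTI) is normalized through a window
(`window: {window_level: 250, window_width: 1490}` is the lung setting
for LIDC-style scans); PNG/TIFF inputs are treated as already in [0, 1].

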