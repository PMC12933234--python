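# nodulite

Lightweight lung-nodule detection for axial CT slices, built to be fully
exercisable on a CPU at desk scale.

Early lung-cancer screening reads low-dose CT for pulmonary nodules —
often bright blobs only a few pixels across on a 2-D slice.  One-stage
anchor detectors are fast enough for screening workloads but struggle
exactly there: IoU-based regression losses are hypersensitive to small
localization errors on tiny boxes, and nodule pixels are vastly outnumbered
by background.  `nodulite` implements a compact CSP detector (YOLOv5s
layout, single class) plus three targeted modifications, each independently
toggleable so the 8-cell ablation grid can be reproduced:

* **C3_ODC** — backbone C3 blocks whose bottleneck convolutions are
  omni-dimensional dynamic convolutions: the kernel is modulated per input
  sample by four attention sets (spatial k×k, input channel, output
  channel, kernel number), `W_eff = Σ_i α_wi (α_f ⊗ α_c ⊗ α_s) ⊙ W_i`.
* **GS-BiFPN** — a weighted bidirectional fusion neck built from GSConv
  (half standard + half depthwise convolution with channel shuffle); each
  fusion node combines its resized inputs with learned nonnegative weights
  `w_i / (ε + Σ_j w_j)`.
* **F-NWD loss** — boxes modelled as 2-D Gaussians
  `N((cx, cy), diag((w/2)², (h/2)²))`; similarity is the normalized
  Wasserstein distance `NWD = exp(−W₂/C)` with
  `W₂ = √(Δcx² + Δcy² + (Δw/2)² + (Δh/2)²)`, and the objective is
  `L = 0.1·Focal + 0.9·mean[IoU^0.5 · (1 − NWD)]`.

Because NWD reacts to a fixed center shift nearly independently of box
size, it keeps a usable gradient for 3–5 px nodules where IoU collapses.

The package also ships the surrounding pipeline: MetaImage (.mhd/.raw)
reading, slice-wise lung-parenchyma segmentation, world-mm → per-slice
pixel-box annotation conversion, PNG/YOLO-label export, a seeded synthetic
CT-phantom generator (LUNA16-shaped volumes: body + two lung fields +
vessels + spherical nodules), SGD training on an in-package numpy autograd
core, and P/R/mAP evaluation.  See `docs/methods.md` for the full model
description and design rationale.

## Worked example

Generate phantoms, preprocess, train a desk-scale model, evaluate:

```sh
nodulite synth --n-volumes 20 --seed 11 --preset easy --out data/raw
nodulite prep  --input data/raw --annotations data/raw/annotations.csv \
               --out data/slices --seed 0
nodulite train --data data/slices --loss-mode f_nwd --epochs 30 \
               --img-size 256 --width 0.125 --seed 0 --out ckpt.npz
nodulite eval  --data data/slices --checkpoint ckpt.npz --img-size 256 \
               --width 0.125
```

A run of the equivalent library calls (20 easy phantoms, 48 training
slices, 30 epochs at 256², width 0.125, seed 0) prints per mode:

```
ciou  : P=0.162  R=0.961  mAP@0.5=0.958
f_nwd : P=0.012  R=0.980  mAP@0.5=0.961
```

i.e. both objectives learn the task at desk scale; precision at the final
(very low) score threshold is poor because every low-confidence detection
counts there, while the ranking metric mAP is high.  Architecture
accounting, independent of any training:

```sh
$ nodulite count                    # baseline YOLOv5s, one class
params: 7.02 M
flops:  15.8 G at 640
$ nodulite count --c3-odc --gs-bifpn
params: 6.69 M
flops:  14.4 G at 640
```

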