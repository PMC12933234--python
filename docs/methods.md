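# Methods

`nodulite` implements a lightweight single-class lung-nodule detector for
axial CT slices, together with the preprocessing, synthetic-data and
evaluation machinery needed to exercise it end-to-end at desk scale on a
CPU.  This note records the models, the tunable parameters that matter, the
numerical choices, and what the synthetic experiments do and do not show.

## Detector architecture

The baseline is the standard small CSP detector (YOLOv5s layout) with depth
multiple 0.33 and width multiple 0.50: a backbone of four C3 stages with an
SPPF tail, a path-aggregation neck, and a three-level anchor head at strides
8/16/32 with the standard anchor set.  With one class it has 7,022,326
trainable parameters and costs 15.8 GFLOPs for a 640×640 forward pass under
the 2-FLOPs-per-multiply-accumulate convention (convolution and linear
layers only; batch norm and activations excluded).  As a replication check,
the same assembly at 80 classes gives 7,235,389 parameters, the well-known
summary figure for this architecture.

Two independent toggles define the improved model:

* **C3_ODC** (`use_c3_odc`): the backbone C3 bottleneck convolutions become
  omni-dimensional dynamic convolutions (ODConv).  An ODConv layer holds
  `N` candidate kernels and predicts, per input sample, four attention sets
  from a global-average-pooled squeeze vector — spatial (k×k), input
  channel, output channel (filter), and kernel number.  The effective
  kernel is `sum_i alpha_w[i] * (alpha_f ⊗ alpha_c ⊗ alpha_s) ⊙ W_i`.  All
  four branches are sigmoid-normalized by default; a softmax option for the
  kernel branch exists for comparability with earlier dynamic-convolution
  designs.  Attention is computed per sample, not shared across the batch.
* **GS-BiFPN** (`use_gs_bifpn`): the neck becomes one bidirectional
  weighted-fusion layer (top-down then bottom-up) whose nodes combine their
  resized inputs with fast normalized weights `w_i / (eps + sum_j w_j)`
  (`w_i >= 0` via ReLU projection, `eps = 1e-4`).  The three-level
  adaptation keeps the two-pass + same-level-skip topology: the skip edge
  sits on P4, the only level with both an intermediate and an output node;
  single-input nodes do not exist in the graph.  All neck convolutions are
  GSConv (half standard, half depthwise, concatenated and interleaved by a
  fixed channel shuffle), the C3-style fuse blocks use GSConv bottlenecks,
  and bottom-up downsampling is a stride-2 GSConv.

### Reference calibration

The published accounting figures this configuration reproduces (6.64 M
parameters, 14.6 GFLOPs) do not pin down every free dimension of ODConv
and GSConv, so the shipped reference configuration fixes them once, by a
joint minimax fit of the two accounting numbers over a small
pre-registered grid, and does not revisit them:

| knob | value | notes |
| --- | --- | --- |
| ODConv kernels `N` | 1 | attention over space/channels/filters retained |
| attention reduction `r` | 3 | squeeze width `max(C/r, 16)` |
| ODConv placement | both bottleneck convs (1×1 and 3×3) | all four backbone stages |
| GSConv depthwise kernel | 9 | stride 1, on the standard-conv half |
| GSC3 bottleneck | GSConv 1×1 → GSConv 3×3, residual | one per block |

This lands at 6.694 M parameters (+0.8 %) and 14.41 GFLOPs (−1.3 %).  With
`N = 1` the kernel-number attention is a learned per-sample gain rather
than a mixture; the four-dimensional attention structure is unchanged, and
larger `N` is one config field away (at ~1.1 M parameters per extra kernel —
the accounting is why the reference uses 1).

## Losses

Boxes are `(cx, cy, w, h)` in continuous pixels, origin top-left.  A box is
modelled as a 2-D Gaussian with mean `(cx, cy)` and diagonal covariance
`((w/2)^2, (h/2)^2)`; for two such Gaussians the 2-Wasserstein distance has
the closed form

    W2 = sqrt((cx1-cx2)^2 + (cy1-cy2)^2 + ((w1-w2)/2)^2 + ((h1-h2)/2)^2)

and the normalized Wasserstein similarity is `NWD = exp(-W2 / C)`.  `C`
shares pixel units with the boxes; the shipped rule sets it per dataset to
the mean of `(w + h)/2` over the training targets (a fixed override is
accepted).  Unlike IoU, NWD reacts to a fixed center shift almost
independently of box size, which is the motivation for using it on nodules
a few pixels across.

The combined objective (`loss_mode="f_nwd"`) is

    L = w_f * Focal + w_n * mean_pairs[ IoU^lambda * (1 - NWD) ]

with `(w_f, w_n) = (0.1, 0.9)` and `lambda = 0.5`.  The focal term is the
standard `-alpha_t (1-p_t)^gamma log(p_t)` with `gamma = 2`, `alpha = 0.25`
(the usual focal-loss defaults), applied to
the objectness logits and normalized by the number of matched pairs.  The
`IoU^lambda` pair weight is treated as a constant (detached) factor,
clamped to `[1e-4, 1]`, since it is described as a sample weight rather
than a gradient path.  The precise composition of the combined loss (what
`IoU^lambda` multiplies, and how each term is normalized) is a genuinely
open design point; the one above is the package's documented choice.  The
baseline objective (`loss_mode="ciou"`) is complete-IoU box
regression (weight 0.05) plus per-level binary cross-entropy objectness
with soft IoU targets and level balance (4.0, 1.0, 0.4).  In both modes the
objectness target at a matched slot is the (detached) predicted IoU, which
keeps confidence rank-calibrated with localization quality.

Focal probabilities are clamped to `[1e-7, 1 - 1e-7]`; the batched logit
form uses the numerically stable `max(z,0) - z y + log(1 + e^-|z|)`.

## Target assignment and evaluation

Assignment is the anchor-ratio rule: an anchor matches a target when
`max(w/aw, aw/w, h/ah, ah/h) < 4.0`, in the target's cell plus the nearest
horizontal and vertical neighbor cells.  Evaluation uses score-sorted
greedy matching at IoU ≥ 0.5 (threshold flag-exposed), precision
`TP/(TP+FP)`, recall `TP/(TP+FN)`, and single-class mAP as the area under
the interpolated P(r) envelope on a 101-point recall grid; an all-points
("continuous") integration is available.  Score ties are broken by higher
best-attainable IoU and then image id, so permuting equal-scored
detections cannot change the result; a detection consumes at most one
ground truth (highest IoU, then lowest index).  With no ground truth at
all, recall is reported as 0 with an explicit flag rather than NaN.

## Compute core

All layers run on an in-package numpy autograd core (`nodulite.nn`):
reverse-mode `Tensor`, convolution as im2col + BLAS matmul (dense and
depthwise), batch norm (eps 1e-3, momentum 0.03), SiLU, max-pool, nearest
upsampling, and momentum SGD.  FLOP accounting instruments the conv/linear
forward path directly, so the reported numbers are exactly the cost of the
executed graph.  Everything is float32; training is deterministic for a
fixed seed and thread configuration.

## CT preprocessing

MetaImage volumes are read via SimpleITK into `(z, y, x)` HU arrays with
`(sz, sy, sx)` mm spacing.  Parenchyma segmentation is slice-wise: median
filter (3×3), HU clip to [−1000, 400], binarize below −320 HU (the
standard aerated-lung/soft-tissue separation; package defaults, all
configurable), drop
border-touching low-density components (outside-body air), keep the two
largest interior components, morphological closing (disk radius 2), hole
filling.  Segmentation is deliberately 2-D per slice to match the
slice-based detector; no 3-D component analysis is attempted.

World-mm annotations become per-slice boxes by `voxel = (world − origin) /
spacing`; a nodule spans integer slices within `z_c ± d/(2 sz)` and on each
spanned slice is a `d/sx × d/sy` box at the in-plane center (no chord
shrink — every spanned slice gets the full-diameter box).  Slices are
exported as 8-bit PNGs under a [−1000, 400] HU window with YOLO-format
labels; by default only nodule-bearing slices ± 1 neighbor are exported.
Series are split 8:2 train/test, deterministically under a stated seed and
always series-disjoint.

## Synthetic phantoms

`synthetic_data` generates LUNA16-shaped volumes: a soft-tissue body
ellipsoid (+40 HU) over air (−1000), two lung ellipsoids (−800), bright
tubular vessels and spherical nodules (+60/+30 HU) inside the lungs, and
Gaussian HU noise (sd 20).  Defaults are 32×128×128 voxels at (2, 1, 1) mm.
The densities were chosen so the −320 HU threshold is exercised
realistically: nodules are *above* the threshold and survive in the mask
only through closing/hole-filling, exactly as in real parenchyma
extraction.  Presets cover the cases of interest: `easy_spec` (10–16 mm
nodules, sparse thin vessels) and `tiny_nodule_spec` (3–5 mm ≈ 3–5 px
nodules, nearer the lung wall).  What phantoms do **not** model: real
nodule texture and spiculation, attachment to vessels/pleura, scanner
physics, lobar anatomy.  Passing the pipeline smoke on phantoms therefore
demonstrates that the plumbing, geometry, losses and optimization work —
not clinical detection performance.

## Desk-scale ("tiny mode") training

Full-scale defaults follow the reference recipe: SGD, lr 0.01, momentum
0.937, weight decay 5e-4, batch 8, 200 epochs, 640×640.  Tiny mode — the
configuration every test and the pipeline smoke use — is the package's own
choice: 30 epochs, 256×256 input, width multiple 0.125, batch 4, lr 0.05.
The larger learning rate compensates for this implementation's mean-reduced
loss (the reference implementation scales its loss by batch size); it was
fixed once during calibration, alongside the smoke data budget (20 easy
phantoms, ≤ 48 training slices).  At these sizes one training run is a few
minutes single-threaded.

## Known limitations

* The parameter/FLOP match to the printed improved-model figures is a
  calibration (see above), exact only for the baseline.
* mAP from a few hundred SGD steps on phantoms has run-to-run spread;
  acceptance checks use margins well above the pass thresholds but a
  pathological seed could still fall short.
* Depthwise/grouped convolution supports `groups = in_channels` only, and
  boxes are axis-aligned 2-D; rotated and 3-D boxes are out of scope.
* The FLOP counter ignores elementwise ops (BN, activations, upsampling,
  fusion sums), consistent with its stated convention.
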