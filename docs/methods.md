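# Methods

## The model

`dcseg` trains a deeply supervised U-Net under two consistency
regularizations that require no input-space perturbation and no teacher
model: the perturbation is architectural (dropout in the prediction
heads, different decoder depths, different pooling scales).

**Backbone.** Four encoder blocks (3×3 convolution + ReLU, 2×2
max-pool), channel widths `w, 2w, 4w, 8w` for base width `w`; a
bottleneck block; four decoder stages that bilinearly upsample
(align-corners off), concatenate the skip features and convolve.  One
convolution per block keeps the CPU cost of a forward pass low; the
classic double-convolution block is a straightforward extension and does
not change any contract.

**Multi-level heads.** Each of the `S = head_levels` deepest decoder
stages carries a head: dropout (rate 0.3) → 1×1 convolution to K classes
→ bilinear upsample to input size → softmax.  `p_1` is emitted by the
deepest stage.  The source text is ambiguous about whether level 1
counts from the deepest or shallowest stage; we follow the coarse/fine
semantics of the coarse–fine consistency term, under which `p_1` must be
the coarsest prediction.  Dropout rate and head widths are our choices —
the lightest head consistent with "convolutional layers with dropout".

**MSC module.** The fine head concatenates the shallowest decoder
features with the 2×- and 4×-upsampled next two stages, reduces to `w`
channels by a 1×1 convolution (our addition, to bound the cost of
full-resolution fusion), then applies parallel average pooling at
windows 1, 2, 3, 5 (stride = window; remainders cropped, branches
resized back bilinearly), concatenates the four branches and fuses with
a 3×3 convolution; a 1×1 convolution + softmax yields `p_0`.  The pooling
type is average (pyramid-pooling convention); max pooling is a config
option.

## Losses

All consistency terms use the same distance convention: squared L2 per
pixel (summed over class channels), averaged over pixels and batch.
Unit-weight rectification then reduces the rectified loss exactly to the
plain hierarchical loss, and the worked single-pixel example
(one (1,0) vs (0,1) pixel in a 2×2 two-class map → 2/4) fixes the
normalization.

* Supervised: `Σ_{s=0..S} α_s (½ CE + ½ Dice)` with all `α_s = 1`; Dice
  uses smoothing 1e-5 and averages over all classes; CE clamps
  probabilities at 1e-8.  The fine level s = 0 is included exactly when
  the MSC head exists (ablations without MSC supervise s = 1..S only).
* Hierarchical consistency: distance of each level to the across-level
  mean `p_avg` (levels 1..S only), averaged over levels.
* Uncertainty rectification: `D_s^i = KL(p_s^i ‖ p_avg^i)` per pixel
  over class channels (the per-level uncertainty *map*), `w = exp(−D)`;
  the per-level loss is the w-weighted pixel average.  The weights are
  computed outside the autodiff tape (treated as constants), the
  standard choice for uncertainty weighting.
* Coarse–fine: `‖p_0 − p_1‖²` with `p_0` gradient-blocked — fine
  predictions act as soft pseudo-labels; a symmetric no-detach mode
  exists for ablations.
* Assembly: `L_unsup = β L_urc + (1−β) L_cr` with β = 0.5;
  `L_total = L_sup + λ(t) L_unsup` with
  `λ(t) = k·exp(−5(1 − t/T)²)`, k = 0.1, t counted in optimizer
  iterations and T = epochs × batches/epoch.  When only one consistency
  arm is enabled, it takes the full unsupervised weight (β collapses to
  1 or 0), so the HC-only arm reproduces the pyramid-consistency
  baseline at full strength.
* Consistency terms are computed on the unlabeled batch part only by
  default; `consistency_on_labeled=True` extends them to the whole
  batch.

## Training

Two-stream batches hold 4 unlabeled images per labeled image; both
pools reshuffle per epoch from the run seed and the smaller pool
cycles.  Optimizer: SGD, momentum 0.9, weight decay 1e-4.
The learning rate is not stated in the source; the default is 0.01,
constant.  Since the backbone has no batch statistics, the labeled and
unlabeled parts run as two forward passes, which is mathematically
identical to one concatenated batch.  One run seed derives the
data-order, weight-init and dropout streams.  The supervised control
(all ablation flags off) trains on labeled batches only, with the same
labeled throughput per iteration as the semi-supervised arms.

## Synthetic data

The generator emulates the two properties of H&E patches the method
actually exploits: (a) foreground regions are irregular, simply
connected blobs with a class-specific color signature; (b) images are
noisy enough that single-head predictions disagree across decoder
depths.  Each blob is an ellipse (aspect 0.7–1.3, random orientation)
whose radius is modulated by three low-frequency angular harmonics
(amplitudes 0.05–0.18); colors come from an H&E-like palette (background
eosin pink 0.88/0.80/0.86, tumor purple 0.58/0.40/0.66, three further
colors for the five-class mode, in which blobs cycle through classes
1–4); each patch gets a global stain jitter (sd 0.04), a blocky
low-frequency texture field and per-pixel Gaussian noise (sd 0.08).

What it does **not** model: nuclei-level structure, stain variation
across slides, blur/fold/pen artifacts, class-dependent textures.
Passing the benchmark therefore shows that the training machinery and
losses behave as designed and that unlabeled data helps on this family
of images — not that the method reaches any particular accuracy on real
histopathology.

## The packaged benchmark

`dcseg.benchmark` fixes one study design: 200 training patches (20 %
labeled), 40 held-out test patches, 2 classes, 300 optimizer iterations,
base width 16, batch 10 (2 labeled + 8 unlabeled, the 4:1 ratio), seeds
0–4, three arms (full / HC-only / supervised control), evaluated by
held-out macro Dice of the finest available head.  Patches are 32×32 —
sized, together with the batch, so the whole 15-run comparison completes
in minutes on a single CPU core while each arm still trains to a
meaningful Dice (≈0.9).  The comparisons are directional (full ≥
supervised control, full ≥ HC-only); at this scale per-seed differences
of less than ~0.01 Dice are within run-to-run noise.  A caveat on the
second comparison: the full method is read out through the MSC fine head
`p_0`, as the method prescribes, and at a few hundred iterations that
head is not yet the model's strongest readout (its shallowest
deep-supervision head scores higher) — so the full-vs-HC-only ordering
may not resolve, or may invert, at short training budgets even when the
full objective is helping the shared backbone.

## Slide tooling

Tiling uses fully-inside 512×512 windows at stride 256 (edge remainders
skipped; a pad-and-include mode is a flag).  A patch is background-
excluded when more than 50 % of its pixels are near-white (dimmest RGB
channel > 0.85 — the usual empty-glass heuristic; threshold
configurable), and tumor-labeled when its tumor-pixel fraction strictly
exceeds 25 %.  Overlapping predictions are stitched by averaging
probabilities before the argmax (last-write-wins behind a flag);
uncovered canvas becomes background with a warning.  Contours are traced
per 8-connected component by Moore boundary following; vertices are
sampled every 15 pixels of arc position along the pixel chain (first
vertex always kept; components with fewer than 3 sampled vertices are
dropped); coordinates are 0-based working-resolution pixels multiplied
by the magnification factor (40×/10× ⇒ 4).  The XML dialect is the ASAP
annotation schema; write→read round-trips preserve vertices exactly
(coordinates serialized with full float precision).

## Numerical choices

* float32 throughout the network; KL and CE clamp at 1e-8; Dice
  smoothing 1e-5.
* Bilinear resize everywhere (align-corners off); nearest is a config
  option.  Pooling remainders are cropped, not padded.
* He-normal weight init; biases zero.
* Metrics: 0/0 ratios (class absent from both masks) are defined as 1;
  multi-class summaries are macro over foreground classes.
* The warm-up clamps t > T to T (relevant when resuming past the nominal
  horizon).

## Known limitations

* The numpy autodiff core is single-threaded and stride-1; it is meant
  for method study at patch sizes ≤ 128, not production training.
* `λ` uses a fixed −5 curvature; other ramps are not implemented.
* The boundary-arc sampling counts chain pixels, not Euclidean arc
  length; for 8-connected chains the two differ by up to √2 per step.
* Checkpoints store raw float32 weights (npz); no versioning beyond the
  embedded config.
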