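# Methods

## Problem and model

The package segments laryngeal endoscopy frames into background (0),
trachea (1) and supraglottis (2). The segmentation network is a
hierarchical vision transformer of the SegFormer family:

* **Overlap patch embedding.** A strided convolution with overlapping
  windows (stage 1: kernel 7, stride 4, padding 3; stages 2–4: kernel 3,
  stride 2, padding 1) followed by token-wise layer normalization. Stage 1
  therefore tokenizes 4×4-pixel patches, and the four stages emit features
  at 1/4, 1/8, 1/16 and 1/32 of the input resolution.
* **Efficient self-attention.** Queries keep the full token length N;
  keys/values are shortened by the reduction ratio R per stage
  (8, 4, 2, 1): the N×C sequence is reshaped to (N/R)×(C·R) and projected
  back to C channels by a learned linear map, then layer-normalized.
  Sequences not divisible by R are zero-padded first. At R = 1 the block
  reduces exactly to standard multi-head attention, which the tests exploit
  as an oracle equivalence.
* **Mix-FFN.** Linear expansion (×4 by default), a depth-wise 3×3
  convolution applied on the 2-D token grid (this leaks relative position,
  replacing explicit positional encodings), GELU, linear contraction, and a
  residual connection. The convolution is depth-wise for efficiency; the
  expansion convolutional variant is a one-line change in `MixFFN`.
* **Blocks** are pre-normalized: `x += Attn(LN(x)); x += FFN(LN(x))`.
* **All-MLP decoder.** Each pyramid level is linearly projected to a common
  width (`decoder_dim`), bilinearly upsampled to the 1/4 grid, concatenated,
  fused by linear → layer norm → GELU, classified to 3 channels, and
  bilinearly upsampled to full resolution. Inputs whose sides are not
  divisible by 32 (e.g. the 400×500 clinical shape) are zero-padded to the
  next multiple and the logits cropped back.

Two capacities are configured: the default
(depths (2,2,2,2), dims (32,64,160,256), heads (1,2,5,8), decoder 256) and
a `micro` variant (depths (1,1,1,1), dims (16,32,64,128), heads (1,2,4,8),
decoder 64, expansion 2) used for CPU-scale experiments and tests.

The network, a small reverse-mode autodiff engine, and AdamW are
implemented directly on NumPy (float32 throughout; truncated-normal
initialization, std 0.02, zero biases, seeded). Every hand-written backward
pass is validated against central finite differences in the test suite.

## Training

Cross-entropy loss `CE = −Σᵢ tᵢ log f(s)ᵢ`, averaged over pixels and batch,
no class weighting (the three-strata scene mix keeps classes represented).
AdamW with learning rate 1e−4, weight decay 1e−2 (decoupled; applied to
weight matrices only, not biases or norm gains), batch size 4, shuffled
mini-batches re-drawn each epoch from a single seed. Early stopping
tolerates 10 consecutive epochs without a *strict* decrease in validation
loss (no min-delta); the returned weights are always those of the
best-validation epoch, not the stopping epoch. Non-finite losses abort with
a diagnostic. Desk-scale runs cap training at 30 epochs of 200 64×64
scenes, which one CPU core completes in about a minute.

## Synthetic scenes

The generator emulates what a laryngoscope sees: a dark elliptical airway
opening inside a brighter annular mucosal ring on a tissue-toned textured
background. Per scene it draws (all from one seed):

* outer (supraglottis) semi-axes: U(0.26, 0.34)·S and U(0.20, 0.28)·S for
  image short side S, clipped to stay inside the frame; centre jittered by
  ±0.04·S; orientation U(−30°, 30°);
* trachea semi-axes: U(0.45, 0.60) of the corresponding outer axes, with
  the minor axis scaled by (1 − 0.95·obstruction) and floored at 1 px so
  the airway class never vanishes and per-class metrics stay defined;
* illumination U(0.6, 1.0) (global multiplicative brightness) and additive
  Gaussian noise with σ ~ U(0.01, 0.05) on [0,1] intensities, clipped;
* colours: mucosa reddish (brightening toward the airway rim), airway dark,
  background mid-tone with a low-frequency sinusoidal texture.

Datasets cycle obstruction through (0.0, 0.5, 0.9) by default — open, mild
and severe narrowing — mirroring balanced frame selection across severity.
Rendering is a pure function of the scene parameters, so ground truth is
exact and every pipeline stage is reproducible bit-for-bit.

What the generator does **not** model: laryngoscope optics and motion blur,
specular highlights, mucus/secretions, temporal coherence of video, or
anatomical shape variation beyond ellipses. Passing the recovery experiment
therefore shows that the architecture, optimizer and pipeline wiring work;
it does not certify clinical-grade accuracy on patient data.

## Pre-processing choices

* Crop detection thresholds luminance at 10/255 and takes the bounding box
  of the largest 8-connected bright component (the scope's content area on
  a black screen-recording canvas).
* Split sizes: |val| = ⌊0.2·n⌋, |test| = ⌊0.1·n⌋, remainder to train, so no
  identifier is ever dropped (340 → 238/68/34). Splitting happens *before*
  augmentation, so augmented copies of held-out images can never leak into
  training.
* Augmentation applies one geometric transform jointly to image (bilinear)
  and mask (nearest-neighbour — no fractional labels); rotation defaults to
  ±15° with zero padding labelled background; "doubling" mode emits exactly
  one augmented copy per original.
* The PCA/t-SNE sanity check embeds images as flattened 32×32 grayscale
  pixel vectors — deliberately model-free, so the check is independent of
  any trained network.

## Post-processing

Per class, in priority order (trachea first): keep the largest 8-connected
component (or components above `min_area_ratio` × largest), fill background
regions fully enclosed by the class (4-connectivity of background against
8-connected foreground), then smooth by morphological opening followed by
closing with a disc. Numerical details worth knowing:

* The structuring element is the Euclidean disc with its four one-pixel
  axis spurs removed (radius 1 degenerates to the 3×3 square): the strict
  raster disc's spurs make opening *preserve* one-pixel spikes instead of
  removing them.
* If opening would remove more than half of a class's pixels (a
  near-closed airway thinner than the disc), the opening step is skipped
  for that class and only closing is applied — gutting a structure is not
  smoothing. This keeps the refinement metric-neutral even on severely
  obstructed scenes.
* Gaps at the interface between the two classes belong to neither class's
  ring exclusively; a final step assigns enclosed background to the class
  occupying most of its boundary ring (priority breaks ties).
* Pixels claimed by a higher-priority class are never overwritten by a
  later one.
* The sweep is iterated to a fixed point (capped at 8 sweeps; 1–2 in
  practice), which makes the full pipeline idempotent even when smoothing
  splits or merges components.
* Default radius 2 px at 128×128, scaled with the image's short side.

## Evaluation conventions

Dice, IoU, F1, precision and recall are computed per class from per-image
confusion counts and macro-averaged over images (a pixel-pooled mode is
also available and tagged in the report). When a class is absent from both
prediction and target the metric is 1; absent from only one, 0. The
identity `dice = 2·iou/(1+iou)` holds exactly on counts and is property-
tested. Timing measures single-image forward passes after warm-up passes on
one thread; the reported FPS is definitionally 1000/duration(ms) and is
hardware-bound, so it is never compared across machines.

## Ablation

The augmentation ablation trains two arms identical in every seed and
configuration field except the augmentation flag, then scores both on a
shift-stressed held-out set: illumination U(0.30, 0.55) (darker than the
training range 0.6–1.0) and orientation ±60° (vs ±30°). With a small
training set (60 scenes) augmentation should close part of this
generalization gap; the experiment asserts only the *direction* (with-aug ≥
without-aug mean Dice), since magnitudes depend on data regime.

## Known limitations

* CPU-bound NumPy training limits practical problem sizes; the default
  experiment uses the micro model at 64×64. The full-size configuration is
  functional but slow to train.
* The attention reduction uses the literal reshape of the token sequence,
  so the tokens merged into one key/value are contiguous in row-major
  order rather than forming a square spatial block; at the grid widths used
  here the difference is immaterial and the R = 1 equivalence is exact.
* Bilinear resampling uses the half-pixel-centre convention; other
  implementations' `align_corners=True` variant will differ at the last
  sub-pixel.
* The synthetic scenes are deliberately minimal (see above); no claim is
  made about transfer to clinical recordings.
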