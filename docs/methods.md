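# Methods

## Problem and model

Graves' orbitopathy (GO) remodels the orbital soft tissues: the extraocular
muscles (EOMs) thicken, the orbital fat compartment expands, and the globe
protrudes (proptosis/exophthalmos). These changes are visible on routine
orbital CT within two narrow Hounsfield-unit (HU) bands — orbital fat at
roughly −110..−10 HU and muscle at 0..40 HU — and they are frequently
*asymmetric* between the two orbits. `orbinet` implements a compact
convolutional classifier built around those two facts:

1. **Three anatomical planes as parallel inputs.** Axial, coronal and
   sagittal stacks carry complementary views of the orbit; each plane gets
   its own convolutional branch and the per-plane embeddings are fused only
   at the final fully connected head.
2. **Binocular comparison via half-depthwise convolution.** After two
   conv + max-pool blocks, each plane's feature map still separates the two
   orbits — along the in-plane width for axial/coronal maps, along the
   slice (channel) axis for sagittal maps, where any single slice contains
   one orbit only. The comparison layer reduces each orbit half to one
   scalar per channel using a depthwise filter whose spatial extent is the
   entire half ("half depthwise"), yielding 16 values per orbit, i.e. a
   16×2 comparison block per plane. In the full model the left- and
   right-orbit filters are separate parameter tensors, which lets the
   network encode inter-orbit *differences* — the signature of unilateral
   disease.

### Architecture

Per plane (input stacks are (height, width, 32) in [0, 1], slices treated
as channels):

| step | operation | axial | coronal | sagittal |
|---|---|---|---|---|
| input | — | 128×128×32 | 64×128×32 | 128×128×32 |
| 1 | 3×3 conv (+ReLU, 2×2 max-pool) | 64×64×16 | 32×64×16 | 64×64×32 |
| 2 | 3×3 depthwise conv (+ReLU, 2×2 max-pool) | 32×32×16 | 16×32×16 | 32×32×32 |
| 3 | half-depthwise binocular comparison | 16×2 | 16×2 | 16×2 |
| 4 | flatten → fully connected | 32 → 4 | 32 → 4 | 32 → 4 |

Head: concatenated embeddings (4 × number of planes) → one sigmoid node
(binary task) or three softmax nodes (3-class task).

The ablation ladder replaces layer 2–3 operators while keeping every
output shape fixed:

* **stage1** — all three layers standard convolutions (layer 3 mixes
  channels over the full half extent, shared across sides);
* **stage2** — layers 2–3 depthwise; layer 3 is one depthwise filter per
  channel evaluated at the two half positions (so for axial/coronal the
  sides share filters; for sagittal every one of the 32 channels keeps its
  own filter);
* **stage3** — half depthwise with one filter set shared by both orbits;
* **proposed** — separate left- and right-orbit filter tensors.

Parameter counts are closed-form functions of the configuration
(e.g. the proposed axial comparison layer has 2 sides × 16 channels ×
(32·16 weights + 1 bias) = 16,416 parameters) and strictly decrease from
stage1 to stage2.

### Choices the architecture description leaves open

* Kernel sizes, strides, padding and activations of layers 1–2 are open;
  3×3 stride-1 'same' kernels with ReLU and 2×2 pooling after layers 1
  and 2 are the minimal choice that reproduces every intermediate size in
  the table above. ReLU is also applied after the comparison layer and
  the per-plane fully connected layer.
* Layer 1 maps the 32 input slices-as-channels to 16 channels
  (axial/coronal) or 32 (sagittal); these counts are forced by the
  post-layer-2 sizes together with 16 filters per orbit at the comparison
  layer.
* The right orbit half is *not* mirrored before filtering
  (`mirror_right=False` by default; the flag exposes the alternative).
  Consequence: the true symmetry of the layer is an equivariance — flipping
  the patient left-right and swapping *and spatially mirroring* the
  per-side filters exchanges the left/right output blocks. With
  `mirror_right=True` and tied filters the layer is symmetric under a pure
  flip. Tests assert both forms.
* Optimizer, learning rate, batch size and loss are unstated; defaults are
  Adam(1e-3), batch 8, binary/categorical cross-entropy, all configurable.
* Weights are returned from the epoch with the best test AUC (learning
  curves on these tasks plateau within the default ten epochs). Because checkpointing on
  the test split is methodologically questionable, `checkpoint="last"`
  provides a strict no-peeking mode.
* Multi-class AUC is macro one-vs-rest over the softmax scores; binary
  decisions threshold at 0.5 (0.5 counts as positive), 3-class decisions
  are argmax with lowest-index tie-break.

## Preprocessing

`reslice → HU window → ROI crop → in-plane resize → slice resample →
min-max normalize`, entirely deterministic:

* **Canonical frame.** All volumes are reoriented so array axes run
  patient right→left, posterior→anterior, inferior→superior. The
  left-right convention (low index = patient right) makes the binocular
  split unambiguous; it is asserted by marker-voxel tests.
* **HU windows** default to the dual fat/muscle bands (−110..−10 and
  0..40 HU, bounds inclusive); everything else becomes background
  (−1000 HU). A merged single window (−100..+40) is available via config.
  Windowing runs before any interpolation so resizing never blends bone
  into the soft-tissue range; the stage order is a package choice.
* **ROI.** Clinical workflows crop the orbit region manually; here a deterministic
  auto-ROI encloses all voxels above −300 HU (tissue vs air), padded by
  5 mm, and is symmetrized about the left-right midline for axial/coronal
  stacks so the orbit split stays centred. A per-case bounding-box override
  is accepted wherever the auto-ROI is used.
* **Resampling.** Slice counts are fixed to 32 by a not-a-knot cubic
  spline over normalized slice position (exact for polynomial intensity
  profiles up to degree 3; identity when the count already matches).
  In-plane resizing is bilinear. Normalization maps each stack's global
  min/max to [0, 1] (per stack, not per slice, preserving inter-slice
  relations; constant stacks map to zero).

## Synthetic phantoms

No patient data ship with the package; every experiment runs on generated
orbital phantoms. Each phantom is schematic: two mirrored ellipsoidal
orbital cavities (fat, −70 ± 15 HU) with 3 mm bony shells (600 ± 50 HU)
open anteriorly, a 12 mm-radius globe (10 ± 5 HU), and four 2 mm-radius
EOM cylinders (25 ± 8 HU) converging toward the apex, on air (−1000 HU),
plus 5 HU global Gaussian noise. Class effects are graded and monotone —
EOM radius ×1.0/1.3/1.8, proptosis 0/1/4 mm, fat-compartment scale
1.00/1.05/1.15 for control/mild/moderate-severe — sized so that "mild" is
a genuinely harder discrimination, mirroring the clinical ordering. With
probability 0.2 a diseased case is unilateral: one orbit receives the
class effects, the other stays at control values, exercising precisely the
asymmetry the comparison layer exists for. The default grid is 96×96×64
voxels at 1 mm, chosen to keep a full simulate→train→evaluate cycle inside
desk-scale CPU budgets.

What the phantoms do *not* emulate: real anatomical shape variation,
scanner artifacts, partial-volume mixtures at tissue boundaries, optic
nerve or lacrimal gland involvement, or demographic confounds. A green
parameter-recovery test therefore establishes that the implementation can
recover a known, strong class signal through the full pipeline — not
clinical performance.

## Evaluation protocol

Repeated holdout: each repetition draws an unstratified 80/20 split
(⌈0.8·N⌉ train) from a seed derived deterministically from the master
seed; every compared model is trained from scratch on the same split, so
per-repetition AUCs are paired and the paired t-test between models
(df = n−1) is valid. Results are summarised as mean ± SD over repetitions.
If a split leaves any class absent from the training *or* test partition
(possible at small N; AUC is undefined without both classes), the split is
retried with an incremented sub-seed, at most 10 times. ROC AUC is the
rank statistic (ties ½). Degenerate paired tests (zero-variance
differences) raise rather than returning ±∞.

## Numerical notes

* The network is pure NumPy/float32. 3×3 convolutions are computed as one
  large channels-last matmul on the zero-padded input followed by nine
  shifted-view accumulations; gradients reuse the same formulation.
  Gradient correctness is pinned by finite-difference tests at build time
  of the suite and by brute-force oracles for the comparison layer.
* Xavier (Glorot) uniform initialisation throughout, seeded; training,
  splitting and generation are deterministic given their seeds, and
  reruns are bit-identical.
* Max-pool ties resolve to the first maximum (argmax order), making the
  backward pass deterministic.
* Stochastic suite sizes: the parameter-recovery and ablation-ordering
  checks run at reduced size (16 and 12 cases per class, 5 repetitions,
  6 epochs with best-epoch checkpointing) to stay inside a CPU-only test
  budget; the protocol itself (shared splits, unstratified 80/20,
  mean ± SD) is the full one, and all sizes are configurable upward.

## Known limitations

* Schematic phantom geometry means filter visualisations are not
  anatomically meaningful.
* The DICOM layer reads only uncompressed explicit-VR little-endian CT
  series with signed 16-bit pixels — enough for interchange with common
  exporters, not a general DICOM implementation (NIfTI is the primary
  interchange format).
* Single-volume reformatting assumes near-isotropic acquisition (1 mm);
  no spacing resampling is performed before reslicing.
* Training is CPU-bound; expect ~0.5–1 s per mini-batch of 8 full
  three-plane cases on one core.
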