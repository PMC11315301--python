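# Methods

This note documents the models, parameters, numerical choices and known
limitations of `ctanomaly`. It is written for users who want to understand
*why* the pipeline is built the way it is, and what its tests do and do not
demonstrate.

## Problem setting and model

The package detects anomalies in 2-D axial brain-CT slices without ever
seeing an annotated lesion. The underlying assumption is distributional: a
generative model trained exclusively on healthy slices can only synthesize
healthy-looking anatomy, so the best healthy explanation `G(z)` of an
abnormal image differs from it precisely where the abnormality sits. CT
makes this harder than MR: the informative soft-tissue signal spans a narrow
intensity band between a very bright skull and dark CSF, so the generator
must reproduce low-contrast interior detail, not just global layout.

### GAN

The generator follows the lightweight few-shot GAN design: a dense
projection of `z` to a 4×4 feature map, then `log2(N) − 2` upsampling blocks
(nearest-neighbour ×2 → 3×3 conv → optional per-block noise injection →
batch norm → GLU), a terminal 3×3 conv with tanh squashed affinely to
[0, 1]. With this parameterization the natural 512×512 instance has seven
blocks — one fewer than the 1024-native original, which is exactly the
"leave one upsampling block out" configuration. Skip-layer-excitation
gates (a low-resolution feature map modulating the channels of the map three
blocks above it) are built when the pyramid is at least four blocks deep,
i.e. from 64×64 upward; at the 32×32 scale used throughout the tests there
is no low/high pair three blocks apart, so the gates do not apply.

The discriminator is a stack of spectral-normalized 4×4 stride-2 convs with
leaky-ReLU down to 4×4, a spectral-normalized 4×4 conv producing one logit,
and an auxiliary decoder head that consumes the 4×4 feature map and
reconstructs an 8×-downsampled copy of the (real) input. Its mean absolute
error is `L_rec` in the discriminator loss; the concrete MAE form is this
package's choice — the self-supervised decoder idea fixes the structure but
not the norm, and MAE is the simplest member of that family. Training is
hinge-loss, alternating one discriminator and one generator step, Adam with
learning rate 2e-4 and betas (0.5, 0.999), batch size 8, latent prior
uniform on [−1, 1]^512. Augmentation defaults: horizontal mirror with
p = 0.5, contrast scaling uniform in [0.8, 1.25] about the image mean,
integer translation up to ±5% of width with zero padding, applied to the
unit-normalized image and re-clamped to [0, 1].

Spectral normalization keeps one power-iteration pair (u, v) per layer as
buffers, updated once per training forward and frozen in evaluation mode;
gradients treat u and v as constants (the standard convention — exact at
power-iteration convergence).

### Encoder

`E` consists of `log2(N) − 1` down-sampling blocks (4×4 stride-2 conv →
batch norm → GLU) — eight at 512×512 — and a dense head with terminal tanh.
The tanh is the package's answer to an otherwise open question: the
generator is only defined on the latent box, so the encoder output must be
confined to it, and tanh matches the box exactly. Training minimizes
`w1·l_percept + w2·l_MSE` (w1 = 1, w2 = 10) with Adam 2e-4 against the
frozen generator. Random erasing (one axis-aligned rectangle, side lengths
uniform in 10–35% of the width, set to background 0, probability 0.25) is
applied to the encoder *input only*; the un-erased image remains the
reconstruction target. This interpretation makes the erase operation an
inpainting pressure rather than a target corruption.

### Perceptual distance

The perceptual term is pluggable through a registry. The default backend is
a fixed-seed stack of three random 3×3 stride-2 convolution layers with
leaky-ReLU; the distance is the LPIPS-style recipe on those features:
unit-normalize across channels, mean squared difference per layer, summed
over layers. Random convolutional features are a recognized baseline for
perceptual metrics and make the package fully self-contained and
deterministic; a learned-feature backend can be registered by the user
(`register_perceptual_backend`) without touching any calling code.

### Restoration

Per-image inversion minimizes the same objective over `z` with Adam
(learning rate 0.01, default betas), starting from `z = 0` and projecting
onto [−1, 1] component-wise after every update. The step count is fixed
rather than tolerance-based (default 8000 at paper scale; the desk-scale
pipeline uses 150 — see below). A constant learning rate is used; an
optional multi-start mode (off by default) can restart from random points
and keep the best final objective.

### Anomaly maps

Residuals are byte-scale (unit difference × 255) so the operating threshold
lives on the familiar 0–255 display scale; binarization is strict
(`r > t`). The closing element is a rasterized disk containing all pixels
within radius + ½ of the origin — at radius 1 this is the full 3×3 square
(so a one-pixel gap closes), at radius 2 a 21-pixel octagonal disk. The
default radius is 2 px at 512×512, scaled proportionally and rounded at
other resolutions (0, i.e. no closing, at 32×32). Each ensemble member is
binarized *before* the majority vote; the mean reconstruction is kept for
display only. Residual-kind defaults: `positive_part` when only hyperdense
(hemorrhage-like) lesions are of interest, `abs` for mixed lesions. The
multi-slice filter labels 26-connected 3-D components across a slice stack
and removes those below a voxel-count or slice-span minimum.

### Evaluation

ROC curves pool pixels across images (the per-image-average alternative is
not computed; the report records the convention). The operating point
maximizes median Dice over an integer byte-scale grid, ties toward the
smaller threshold. Dice of two empty masks is defined as 1.0 and the count
of such pairs is flagged in the report — the case only arises on
artifact-free images. Lesion-level detection computes Dice per connected
reference component against the prediction restricted to a 3-px-dilated
neighborhood of that component, and a lesion counts as detected when that
Dice strictly exceeds 0.1. Paired comparisons between pipeline variants
are delegated to SciPy's Wilcoxon signed-rank test.

## Synthetic phantoms

The phantom emulates the *statistics the method is sensitive to*, not
anatomy: a bright elliptical skull annulus (0.95) around mid-intensity
tissue (0.35) with smooth band-limited structure (sd 0.04) standing in for
the low-contrast sulci/gray-white texture, two darker ventricle ellipses
(0.15), additive Gaussian noise (sd 0.01), and per-sample geometric
variation in skull shape, thickness and ventricle size. Lesions are either
a smooth positive offset (`bright_blob`, hemorrhage-like; hyperdense by
construction) or an offset plus high-frequency texture and optional rim
(`textured_mass`, tumor-like); insertion is exactly local (identity outside
the returned mask) and clamped to [0, 1]. Geometry for sample `i` comes
from the substream `default_rng([seed, split, i])`, so a sample is
independent of how many are requested and splits never share images.

What passing on phantoms does **not** show: phantoms have no partial-volume
skull-base slices, no beam hardening or streak artifacts, no patient-level
slice correlation, and far less anatomical variability than real heads, so
absolute Dice values here do not transfer to clinical data — only the
mechanics (training, inversion, thresholding, voting, evaluation) are
validated.

## Desk-scale study conditions

The shipped defaults run the whole experiment at 32×32 with a 512-d latent
space: 64 training phantoms, three GAN models trained 2000 steps each
(batch 8, ~1.5 min per model on one CPU core), restoration with 150 steps
per image, a threshold sweep on 10 lesioned validation phantoms
(grid 0–255 step 4), and evaluation on 20 lesioned test phantoms plus 8
lesion-free ones for reconstruction statistics. Inserted blobs have radius
8–12% of the image width and intensity offset 0.25–0.40. These sizes were
chosen as the smallest configuration at which the trained generator
reliably reconstructs held-out phantoms (RMSE ≈ 0.06–0.09, comfortably
below the lesion contrast) while a full pipeline run stays in the minutes
range; the paper-scale step counts (100k GAN steps, 20k encoder steps, 8000
restoration steps, 512×512) remain available through the stage configs.

## Numerical and engineering choices

* All arithmetic is float32 in a single-threaded NumPy autodiff engine;
  convolution is im2col + GEMM. Under a fixed seed every stage is
  bit-reproducible, which the pipeline exploits: artifacts are stamped with
  a config hash, stages are cached by that hash, and two uncached runs with
  the same seed produce byte-identical reports.
* Ensemble members use seeds `seed + {0, 1, 2}`.
* Batch norm uses batch statistics during training (momentum 0.1 running
  updates) and running statistics at inference; the generator is always
  evaluated in inference mode during encoder training, restoration and
  detection.
* Constant images min-max-normalize to all zeros (backgrounds are dark
  in CT); DICOM input defaults to the standard brain window
  (center 40 HU, width 80 HU), applied after rescale slope/intercept.
* Degenerate inputs are errors, not silent defaults: empty datasets,
  even-sized ensembles, patients in two splits, lesions outside the brain
  region, non-finite objectives.

## Known limitations

* The 32×32 default resolution is far below the 512×512 the method targets
  on real data; the architecture scales by configuration but the test suite
  never exercises large models.
* Random-feature perceptual distance is weaker than a pretrained-feature
  metric; on real CT a learned backend should be registered.
* The brain-region estimate used for lesion placement is intensity-based
  and specific to the phantom's contrast ordering.
* No 3-D modeling: volumes are processed slice-wise, with only the
  post-hoc connected-component filter linking slices.
* Restoration cost scales linearly with step count (the paper-scale 8000
  steps is ~100× the desk default); the encoder amortizes this at the cost
  of slightly lower accuracy.
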