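# ctanomaly

Unsupervised anomaly detection for axial brain-CT slices by pseudo-healthy
reconstruction.

Radiology workflows need tools that flag *any* deviation from normal anatomy,
not just lesion types seen during training. `ctanomaly` implements the
GAN-based approach to this problem for 2-D CT slice images: a generative
model is trained on healthy slices only, an unseen image is mapped back into
the model's latent space, and whatever the model cannot reproduce — because
it never saw anything like it in healthy anatomy — shows up in the
reconstruction residual and is segmented as an anomaly. Hemorrhages (which
are hyperdense) and tumor-like lesions are the motivating cases, but nothing
in the method is lesion-specific.

## Method

1. **GAN training** — a lightweight convolutional generator `G` maps latent
   codes `z ~ U[-1,1]^L` (default `L = 512`) to slice images, trained
   against a spectral-normalized discriminator `D` with the hinge pair

       L_G = -E[D(G(z))]
       L_D = E[max(0, 1 - D(x))] + E[max(0, 1 + D(G(z)))] + L_rec

   where `L_rec` is the mean absolute error of a small decoder head inside
   `D` that must reconstruct an 8×-downsampled copy of each real input — a
   self-supervision term that keeps the discriminator's features
   image-descriptive. Training data are augmented by random mirroring,
   contrast changes and translation.

2. **Inversion** — two interchangeable routes map an image `x` to a latent
   code:
   * *encoder*: a conv/batch-norm/GLU down-sampling network `E` trained
     (with `G` frozen) to minimize
     `w1·l_percept(x, G(E(x))) + w2·l_MSE(x, G(E(x)))`, `w1 = 1`,
     `w2 = 10`, with random rectangular erasing of the encoder input
     (p = 0.25) so it cannot learn the identity;
   * *restoration*: per-image optimization
     `min_{-1<=z<=1} w1·l_percept(x, G(z)) + w2·l_MSE(x, G(z))` by Adam
     from `z = 0`, clipping `z` component-wise to `[-1, 1]` after every
     step.

3. **Anomaly maps** — the residual `D = rho(x - G(z))` with `rho = |·|`
   (any change) or `rho = max(·, 0)` (hyperdense lesions only) is expressed
   in byte-scale units (×255), thresholded at an operating point chosen on a
   validation split, refined by morphological closing, and combined across
   three independently trained GANs by per-pixel majority vote. For slice
   stacks, small 3-D connected components can be filtered out.

4. **Evaluation** — Dice-vs-threshold sweeps, pixel-pooled ROC curves,
   lesion-level detection (a lesion counts as detected when its Dice
   exceeds 0.1) and reconstruction-error statistics (RMSE, mean ± sd and
   90th-percentile absolute difference on [0, 1]-normalized pairs).

Everything runs on a built-in head-phantom generator (bright skull annulus,
low-contrast tissue, ventricles, insertable lesions with exact ground-truth
masks), so the full pipeline trains and evaluates with no external data.
DICOM (with HU windowing), NIfTI and PNG slices are supported for real data.

The neural-network layer (`ctanomaly.nn`) is a self-contained NumPy
reverse-mode autodiff engine with conv2d, batch norm, GLU, spectral
normalization and Adam — the whole package runs on CPU with no deep-learning
framework.

## Worked example

```python
import dataclasses
from ctanomaly.pipeline import RunConfig, run_experiment

cfg = RunConfig(seed=1)                       # 32x32 phantoms, 3-model ensemble
cfg.data = dataclasses.replace(cfg.data, n_train=64, n_validation=10, n_test=20)
cfg.gan = dataclasses.replace(cfg.gan, total_steps=2000)
cfg.restoration = dataclasses.replace(cfg.restoration, steps=150)
report = run_experiment(cfg, "runs/demo")
print(report["operating_threshold"], report["median_dice"],
      report["lesion_detection_rate"])
```

prints (seed 1):

```
40.0 0.6705128205128206 1.0
```

meaning: the threshold swept on the validation split was 40 byte-scale
units; at that operating point the ensemble segments the inserted
hemorrhage-like blobs on the 20 test phantoms with median Dice 0.67; and
every reference lesion reaches Dice > 0.1, i.e. a 100% detection rate. The
report also carries reconstruction statistics — RMSE 0.083 on lesion-free
test phantoms versus 0.098 on lesioned ones (90th-percentile differences
0.116 vs 0.149), the gap that makes residual thresholding work — and a
pixel-pooled ROC curve (AUC 0.986 here).

The same pipeline is scriptable from the shell:

```sh
ctanomaly run-all --seed 1 --out runs/demo
ctanomaly phantom --n 1200 --out data/           # slices + masks + manifest
ctanomaly train-gan --data data/manifest.tsv --out rundir/
ctanomaly reconstruct --mode restore --model rundir/gen-final.npz \
    --in slice.png --out recon.png
ctanomaly detect --models m1.npz m2.npz m3.npz --rho positive_part \
    --threshold 36 --in slices/ --out masks/
```

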