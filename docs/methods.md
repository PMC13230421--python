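# Methods

## Model

`ct2adc` trains a bidirectional translation between skull-stripped brain CT
slices and diffusion ADC maps with four networks: generators G_MRI (CT→ADC)
and G_CT (ADC→CT) sharing one architecture, and discriminators D_MRI, D_CT
sharing another.  The generator is the canonical encoder / residual /
decoder recipe of cycle-consistent translation: a reflect-padded 7×7 stem,
two stride-2 3×3 convolutions, `n_residual_blocks` residual blocks at the
bottleneck width, two stride-2 transposed 3×3 convolutions (output padding 1,
so the spatial size is restored exactly), a reflect-padded 7×7 output
convolution and tanh.  Instance normalisation (no learned affine) follows
every convolution except the output.  The discriminator is a patch classifier
built from 4×4 stride-2 convolutions with leaky ReLU (slope 0.2); at the
default depth of 3 its receptive field is 70×70 and its output is a spatial
grid of realism scores.  Weights are initialised from a seeded zero-mean
Gaussian with sd 0.02.

The layer counts and filter widths are declared conventions of this package
(the architecture family fixes the topology, not the sizes); they are fully
configurable through `GeneratorConfig` / `DiscriminatorConfig`.

Input images live in [0, 1] on disk and are mapped affinely to [−1, 1] for
the model.  The brain mask is computed from the CT slice of each pair (the
pair is co-registered, so the ADC slice reuses it) by Otsu thresholding over
a 256-bin histogram and dilation with a disk structuring element.  Neither
the kernel shape nor the radius is dictated by the method itself; the default
radius is 3 px at 256×256, scaled proportionally with image size and never
below 1.  The mask enters the model according to `mask_mode`:

- `concat` (the full method): the {0,1} mask is stacked as a second input
  channel of *both* generators, a soft spatial guide.  Concatenating on both
  sides keeps the cycle and identity passes type-consistent; the method only
  prescribes the CT side, so this is a declared package choice.
- `multiply`: hard filter, the model-scale image is multiplied by the mask.
- `none`: plain single-channel input (the baseline arm).

## Objective

Total loss: `L = L_adv + λ₁ L_cyc + λ₂ L_id` with defaults λ₁ = 10, λ₂ = 5
(the conventional cycle/identity ratio of 2:1; the source method does not
publish its weights).  The adversarial term is least-squares by default —
generator term mean((D(fake) − 1)²), discriminator term
½·[mean((D(real) − 1)²) + mean(D(fake)²)] — with a sigmoid cross-entropy
variant selectable.  The printed adversarial equations of the source method
contain typographical inconsistencies (generator symbols where discriminator
terms must appear); this package implements the standard objective of the
architecture lineage rather than silently "fixing" the printed form.

The fidelity loss between two images is the per-element mean of the squared
L2 distance between their feature maps under a frozen extractor φ.  Dividing
by the feature count makes the magnitude independent of the extractor
architecture, which keeps the default λ values meaningful across backends.
The expectation E[·] is realised as the batch mean of per-image means.

The cycle term follows the supervised (paired) definition: the fidelity
between each *one-step* translation and its registered target, summed over
both directions.  A true two-step cycle (G_CT(G_MRI(x_CT)) vs x_CT) is
available behind `two_step_cycle=True` for comparison with the unpaired
formulation; it is off by default because the paired form is what the method
defines.  The identity term feeds each generator the modality it should
leave unchanged (G_CT applied to x_CT, G_MRI applied to x_MRI) and penalises
feature deviation from the input.  The L1 pixel variants of both terms are
retained for the ablation arms.

## Frozen feature extractor

φ must be frozen: gradients flow through it to its input but its parameters
never update (enforced structurally — the layers never accumulate parameter
gradients — and verified by a SHA-256 fingerprint of all weights).  Two
backends share the interface:

- `fixed_random` (default for desk-scale work): three seeded stride-2
  convolutional blocks (widths 8/16/16, leaky ReLU), weights a pure function
  of the seed.  Random convolutional features preserve enough geometry to
  drive a perceptual loss, and the backend needs no downloads.
- `pretrained_radiology`: loads an externally supplied `.npz` weight file of
  the same architecture.  Requesting it without a weight path is an error;
  there is no silent fallback.  Which pretrained radiology backbone and layer
  to use is a configuration decision, not something the package infers.

The test-only layer tag `"input"` makes φ the identity, which reduces every
fidelity loss to a pixel mean-square — the bridge to independent pixel-loop
oracles in the tests.  Minimum input size for the convolutional backends is
8 px per side (three halvings).  Single-channel images are replicated when a
backend expects more channels.

## Training protocol

Per iteration, both generators are updated first (adversarial + weighted
cycle + identity gradients), then both discriminators, each group with its
own Adam instance (β₁ = 0.5, β₂ = 0.999).  Defaults follow the published
protocol: 100 epochs, batch size 8, learning rate 2×10⁻⁴ constant through
epoch 50 then decayed linearly to exactly zero at epoch 100.  Validation MSE
(CT→ADC, [0, 255] scale, mean of per-slice means) is recorded once per
epoch; the best model is the argmin of that curve restricted to epochs after
the 20th (1-based; "after the 20th" = epochs 21…), ties resolved to the
earliest epoch.  No data augmentation is applied and no generated-image
history buffer is used by default (available behind `use_image_buffer`).
Everything — initialisation, data order, pool sampling — derives from
`TrainConfig.seed`, so runs are bit-reproducible on one machine.

Checkpoints store all four networks, both optimiser states, the epoch, the
config and the validation curve in a single versioned `.npz`.

### Desk scale

The package's experiments run on CPU, so `smoke_train_config()` declares a
reduced configuration used by the example, the end-to-end tests and the
acceptance script: 64×64 phantoms, generator base width 8 with 3 residual
blocks, discriminator base width 16 with 2 layers, 5 epochs with decay from
epoch 3, batch size 1 (the reference convention of the architecture lineage
for small datasets), learning rate 2×10⁻⁴.  Phantom smoke datasets use 6
slices per patient.  These sizes are the package's declared smoke-scale
conditions; the full-scale defaults above remain available unchanged.

## Phantom generator

`PhantomSpec` defaults emulate the scale of the paired stroke dataset the
method was developed on: 60 patients, 25 axial slices each, patient-level
random splits.  Each patient has a fixed elliptical anatomy (outer brain
ellipse, inner ventricle ellipse, cortical rim band) jittered slightly per
slice; tissue classes map to distinct monotone intensity levels per modality
(CT: ventricle 0.40 < interior 0.60 < rim 0.80; ADC: rim 0.40 < interior
0.55 < ventricle 0.90), with additive Gaussian noise (sd 0.02 CT / 0.03 ADC)
and everything outside the brain exactly zero (the skull-stripped
convention).  Lesions are random ellipses of 1–5% brain area drawn with
probability `lesion_probability` per slice, fully inside the brain, shifting
CT by −0.03 and ADC by −0.35 (both configurable) — subtle on CT, strongly
hypointense on ADC, the diffusion-restriction signature.

What the phantoms do *not* model: Hounsfield-unit physics, 3-D anatomy and
through-plane continuity, registration error, haemorrhage, scanner noise
statistics.  Tests passing on phantoms therefore demonstrate that the
pipeline's mechanics (masking, losses, optimisation, selection, evaluation)
are correct and that the model can learn a deterministic cross-modality
mapping — not that it reaches clinical-grade translation quality on real
stroke data.

## Evaluation

Metrics are computed on whole slices (zero background included) after linear
rescaling to [0, 255], matching the 8-bit convention under which published
MSE magnitudes and PSNR values for this task are mutually consistent
(10·log10(255²/197.45) ≈ 25.18 dB).  PSNR of identical images is reported as
a capped sentinel (100 dB) and excluded from means with a warning.  SSIM uses
the standard reference parameterisation (Gaussian window σ = 1.5, 11×11,
K1 = 0.01, K2 = 0.03, population covariances) and is reported ×100; the SSIM
difference map is per-pixel 1 − local SSIM clipped to [0, 1].  Confidence
intervals are seeded percentile bootstraps over slices (10 000 resamples by
default) — the CI method for this task is not standardised, so this is a
declared convention.  Method comparisons use the two-sided Wilcoxon
signed-rank test paired by slice, with the exact null after zero-difference
removal for n ≤ 25 and the tie-corrected normal approximation otherwise.
Whether a published mean PSNR is the mean of per-slice PSNRs or the PSNR of
the pooled MSE is ambiguous in general; this package reports the mean of
per-slice values.

## Numerical choices and edge cases

- Layer parameters are float32; loss accounting is float64 scalars.
- Otsu on a constant image raises (no threshold exists); ties in the
  between-class variance resolve to the lowest qualifying threshold.  On
  near-flat variance plateaus the argmax is only determined up to float
  round-off, so oracle tests compare the attained objective value.
- Instance normalisation couples all patches of a discriminator map; the
  strict patch-locality contract therefore holds for the norm-free
  discriminator variant (`use_norm=False`).
- Generator inputs must be divisible by 4 (two stride-2 stages); violations
  raise before any compute.
- A conv bias feeding an instance norm has no effect on the output; such
  biases simply stay near their initial zeros.

## Known limitations

- The NumPy substrate is single-threaded beyond BLAS and intended for
  method-level experiments, not full-resolution training.
- Phantom realism is deliberately minimal (see above).
- Adversarial dynamics at smoke scale are dominated by the strongly
  supervised cycle term; ordering of ablation arms at that scale is noisy
  and is reported, not asserted.
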