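# ct2adc

Brain-mask-guided, fidelity-constrained translation of skull-stripped stroke
CT slices into synthetic diffusion ADC maps.

## The problem

Non-contrast CT is the first-line imaging modality in acute stroke, but early
ischaemic changes on CT are subtle; diffusion MRI — in particular the
apparent-diffusion-coefficient (ADC) map, where acute infarcts appear as
hypointense regions — is far more sensitive yet slower and less available.
`ct2adc` implements a paired image-to-image translation model that synthesises
ADC-like slices from co-registered, skull-stripped CT slices, for researchers
studying cross-modality synthesis in stroke imaging.

## The model

The translator is a cycle-consistent adversarial framework with two
extensions:

1. **Brain-mask soft guide.** A brain mask is extracted from each CT slice by
   Otsu thresholding followed by morphological dilation (disk structuring
   element) and concatenated to the generator input as a second channel — a
   soft spatial prior, in contrast to hard filtering (multiplying the image
   by the mask), which is also implemented as an ablation arm.
2. **Fidelity-constrained loss.** The pixel-wise L1 cycle-consistency and
   identity penalties are replaced by squared L2 distances between frozen
   feature-extractor representations φ(·) of the images (a perceptual loss).

With generators G_MRI (CT→ADC), G_CT (ADC→CT), discriminators D_MRI, D_CT and
paired images (x_CT, x_MRI), the objective is

    L = L_adv + λ₁ L_cyc + λ₂ L_id

    L_cyc = E[ ‖φ(G_MRI(x_CT)) − φ(x_MRI)‖² ] + E[ ‖φ(G_CT(x_MRI)) − φ(x_CT)‖² ]
    L_id  = E[ ‖φ(G_CT(x_CT)) − φ(x_CT)‖² ]  + E[ ‖φ(G_MRI(x_MRI)) − φ(x_MRI)‖² ]

with a least-squares adversarial term, λ₁ = 10, λ₂ = 5 by default.  The
generators are encoder / residual-bottleneck / transposed-convolution-decoder
networks with tanh outputs in [−1, 1]; the discriminators are patch-wise
convolutional classifiers.  Training uses Adam, learning rate 2×10⁻⁴ held
constant for the first half of training and decayed linearly to zero, and the
best model is the epoch with the lowest validation MSE after a burn-in
period.  Evaluation reports per-slice MSE, PSNR and SSIM on the 8-bit
[0, 255] scale with percentile-bootstrap 95% CIs and paired two-sided
Wilcoxon signed-rank comparisons between methods.

The network substrate (convolutions, transposed convolutions, instance
normalisation, Adam, explicit backpropagation) is implemented in NumPy in
`ct2adc.nn`, sized for CPU-scale experiments.

Because real paired CT/ADC stroke data cannot be redistributed, the package
ships a deterministic phantom generator (`ct2adc.phantom`) producing
per-patient stacks of co-registered slice pairs: elliptical brains on exactly
zero backgrounds, distinct tissue compartments with modality-specific
contrast, and optional lesions that are subtle on CT but strongly hypointense
on ADC.  Every stage of the pipeline is exercised end to end on phantoms.

## Worked example

```python
from ct2adc.phantom import PhantomSpec, generate_split
from ct2adc.training import smoke_train_config, train

spec = PhantomSpec(image_size=64, n_patients=10, slices_per_patient=6, seed=0)
train_s, val_s, test_s = generate_split(spec, 8, 1, 1)

cfg = smoke_train_config(seed=0)   # 64x64, narrow nets, 3 residual blocks, 5 epochs
state = train(cfg, train_s, val_s)

print(f"untrained validation MSE: {state.untrained_val_mse:8.1f}")
for ep, v in enumerate(state.val_mse, start=1):
    print(f"epoch {ep}: validation MSE {v:8.1f}")
```

prints

```
untrained validation MSE:  11319.4
epoch 1: validation MSE   1661.8
epoch 2: validation MSE    489.8
epoch 3: validation MSE    363.1
epoch 4: validation MSE    377.3
epoch 5: validation MSE    377.3
```

The validation MSE is the mean per-slice squared error of CT→ADC translations
on the [0, 255] scale: the untrained generator produces a mid-grey field
(MSE ≈ 11300 against mostly-black ADC targets), and five short epochs of the
full method reduce it by ~97% on this phantom family.

The same pipeline is available from the shell:

```
ct2adc synth-generate --patients 10 --image-size 64 --out data/
ct2adc train --data data/ --out run/
ct2adc evaluate --checkpoint run/epoch_005.npz --data data/ --out metrics.csv
ct2adc ablate --data data/ --out ablation/
```

`ablate` trains the five experiment arms (plain CycleGAN baseline, hard-filter
mask, soft-guide mask, fidelity loss alone, full method) under identical
seeds and schedules and writes a comparison table with means, 95% CIs and
pairwise Wilcoxon p-values.

## Layout

- `ct2adc.phantom` — synthetic paired CT/ADC datasets
- `ct2adc.masking` — Otsu brain mask, dilation, concat/multiply combination
- `ct2adc.features` — frozen feature extractor φ (seeded fixed-random backend,
  loadable radiology-pretrained backend)
- `ct2adc.networks` — generators and patch discriminators
- `ct2adc.losses` — adversarial / fidelity / cycle / identity objectives
- `ct2adc.training` — schedule, adversarial training loop, checkpoints,
  best-model selection, ablation presets
- `ct2adc.evaluation` — MSE/PSNR/SSIM, difference maps, bootstrap CIs,
  Wilcoxon comparisons
- `ct2adc.dataio`, `ct2adc.cli` — NIfTI/PNG datasets, YAML configs, CLI

See `docs/methods.md` for the modelling choices and their rationale.
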