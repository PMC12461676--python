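# demsi — self-supervised denoising of mass spectrometry imaging data

Mass spectrometry imaging (MSI) produces a datacube `M (X × Y × H)`: one
ion image per m/z channel, each degraded by missing pixels, hot outliers
and shot noise — and no noise-free reference exists, so ordinary
supervised denoising cannot be trained.

`demsi` implements a two-stage self-supervised workaround that exploits a
chemical redundancy of mass spectrometry. Every molecule appears twice: as
its monoisotopic ion and as the +1 isotopologue 1.003355 Th higher (one
¹³C). In theory the two ion images share the same spatial distribution; in
practice the isotopic image, ~3–10× less abundant, carries far more
missing values and outliers. The package therefore:

1. **mines (isotopic, monoisotopic) channel pairs** from a preprocessed
   cube (m/z spacing within 10 ppm of 1.003355 Th, spatial rank
   correlation ≥ 0.6, abundance ratio ≤ 1), and
2. **trains a U-Net** `f(·|θ)` on those pairs — isotopic image as input,
   monoisotopic image as pseudo ground truth — minimising the mean
   absolute error
   `L_rec = (1/N) Σᵢ |Iᵢ^monoiso − f(Iᵢ^iso|θ)|`,
   then pushes *every* channel of the cube through the trained network.

It also ships everything needed to evaluate the idea without real data: a
synthetic phantom generator with planted isotope pairs and known clean
truth, the Poisson + 20%-missing corruption protocol, masked PSNR/SSIM
metrics, and Gaussian-filter / wavelet-shrinkage baselines. The network,
its backpropagation and Adam are implemented directly on NumPy; gradients
are verified against numerical differentiation in the test suite.

## Worked example

```python
import numpy as np
from demsi import (PhantomConfig, generate_phantom, preprocess_cube,
                   find_pairs, build_training_set, TrainConfig,
                   train_denoiser, denoise_cube, phantom_report)

noisy, truth = generate_phantom(PhantomConfig(shape=(32, 32), seed=1))
prep = preprocess_cube(noisy)            # TIC -> hotspot clip -> [0,1]
pairs = find_pairs(prep)                 # mine isotope pairs
print(phantom_report(truth, pairs))
est = train_denoiser(build_training_set(prep, pairs),
                     TrainConfig.from_preset("desk", seed=1))
denoised = denoise_cube(est, prep)       # all 55 channels
print(f"best val loss {est.best_val_loss_:.4f} at epoch {est.best_epoch_}")
```

prints (desk preset, one CPU core, ~4 min):

```
{'recall': 1.0, 'precision': 1.0, 'n_true': 20, 'n_found': 20, 'empty_report': False}
best val loss 0.0753 at epoch 499
```

i.e. all 20 planted isotope pairs were recovered with no false positives,
and the network reconstructs held-out isotopic images with a mean absolute
error of ~0.08 on the [0, 1] intensity scale.

The same pipeline is scriptable from the shell:

```bash
demsi run --out-dir out --seed 1 --preset desk --evaluate
```

which writes the phantom, preprocessed and denoised cubes, the pair
table, the loss history, and a PSNR/SSIM report comparing the trained
denoiser against the corrupted input and both classical baselines.

The estimator follows scikit-learn conventions (`MSIDenoiser(...).fit(X,
y).transform(X)` on image stacks, `get_params`/`set_params`, fitted
attributes with trailing underscores), so it composes with sklearn
tooling.

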