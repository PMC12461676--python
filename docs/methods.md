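# Methods

## The problem

Mass spectrometry imaging (MSI) produces a datacube `M` of shape
`X × Y × H`: one mass spectrum per pixel, equivalently one ion image per
m/z channel. Ion images are degraded by heterogeneous noise — missing
pixels, hot outlier pixels, shot noise — and no noise-free reference can be
measured, so supervised denoising is not directly applicable.

The method implemented here exploits a chemical redundancy. A molecule is
detected both as its monoisotopic ion and as its +1 isotopologue
1.003355 Th higher (one ¹³C). Both ions share the molecule's spatial
distribution, but the isotopic image, being ~3–10× less abundant, suffers
systematically more missing values and outliers. Pairing the two yields a
self-supervised training set: the isotopic image is the noisy input, the
monoisotopic image the *pseudo ground truth*. A convolutional
encoder–decoder is trained on these pairs by minimising the mean absolute
error

    L_rec = (1/N) Σᵢ | Iᵢ^monoiso − f(Iᵢ^iso | θ) |

and then applied to every channel of the cube.

## Pipeline stages and their assumptions

**Preprocessing** (`demsi.preprocess`). TIC normalisation divides each
pixel's spectrum by its summed intensity, assuming per-pixel acquisition
efficiency is a multiplicative nuisance shared across channels. Hotspot
truncation clips values strictly above 0.99 × the image maximum — the
literal "exceed 99% of the maximum" rule. Note this rule is *not*
idempotent (a second application clips at 0.99² × max); it is applied
exactly once, and on a constant image it clips every pixel, an accepted
edge behaviour of the literal rule. Per-ion max normalisation then maps
each channel to [0, 1], the range the network and the metrics assume. The
per-channel maxima before this step are kept in `meta["channel_max"]` so
abundance ratios can be recovered later. Step order is fixed
(TIC → hotspot → max) so the [0, 1] guarantee is final.

**Pair mining** (`demsi.isopair`). Candidate pairs are channels whose m/z
difference is within 10 ppm (of the monoisotopic m/z) of 1.003355 Th.
Acceptance requires: occupancy (fraction of nonzero mask-true pixels)
≥ 0.05 on both channels; a spatial colocalization of ≥ 0.6, measured as
the **Spearman rank correlation** over jointly nonzero mask-true pixels
(≥ 10 of them); and an abundance ratio mean(iso)/mean(mono) ≤ 1 on the
pre-normalisation scale. Rank correlation was chosen over the
product-moment coefficient deliberately: ion intensities are heavy-tailed
and isotopic images carry hot outliers, and a handful of such pixels can
drive a Pearson coefficient of genuinely colocalized images below any
useful threshold, while leaving ranks nearly unchanged. Each monoisotopic
channel keeps its best isotopic partner (highest correlation, ties broken
by spacing closest to 1.003355 Th), and a channel never serves both roles,
which breaks +2 chains. Only the +1 isotopologue is mined; +2 isotopes are
much weaker for CHNOPS-dominated metabolites and lipids.

**The denoiser** (`demsi.denoiser`, `demsi.nn`). A classic U-Net: per
encoder level two 3×3 conv + ReLU layers then 2×2 max-pooling, channels
doubling from `base_channels`; a bottleneck at `base·2^depth`; a decoder
that mirrors the encoder with bilinear 2× upsampling and
copy-and-concatenate skip connections; a final linear 1×1 convolution.
Weights are initialised from N(0, 0.02), biases at zero; training uses
Adam (default momentum parameters) on the MAE loss, with batches of whole
image pairs. Inputs whose spatial dimensions are not divisible by
`2^depth` are reflect-padded and cropped after the forward pass. A 10%
validation split of the pairs selects the best checkpoint across epochs.
At inference every channel is processed, outputs are clipped to ≥ 0 and
mask-false pixels forced to zero.

The network, its backpropagation and Adam are implemented directly on
NumPy arrays (convolution via im2col, bilinear upsampling as an explicit
linear operator whose adjoint is the backward pass). Gradients are
verified against central-difference numerical differentiation in the test
suite at double precision.

Two presets are shipped. The **paper preset** is the full-scale reference
recipe:
base 64, depth 4 (the 64→1024 channel ladder), learning rate 0.005,
batch 256, 20 000 epochs. The **desk preset** (base 12, depth 2,
500 epochs per run) is sized so one training takes a couple of minutes on
one CPU core at 32 px, and wraps the core recipe in the regularisation a
~20-pair training set needs:

* *dihedral augmentation* — each batch is randomly flipped/rotated,
  identically for input and target;
* *missing-pixel input masking* — a random fraction (up to 0.3) of input
  pixels is zeroed each step, inputs only.  Missing values are the data
  model's dominant degradation (isotopic images carry systematically more
  of them), and masking teaches the network imputation invariance the
  same way denoising autoencoders do;
* *learning rate 0.002 with cosine decay and global-norm gradient
  clipping at 1.0* — at widths ≥ 12 the fixed 0.005 rate is unstable
  under the MAE loss's discontinuous gradients: runs can stall in bad
  optima or produce networks that explode on inputs unlike the training
  set;
* *tail weight averaging* — the final weights are the average of the last
  25% of epochs' iterates, a lower-variance endpoint than any single
  checkpoint;
* *two restarts* — training runs twice from independent initialisations
  and the run with the lower validation MAE is kept; occasional bad runs
  are reliably flagged by the held-out pairs;
* *test-time self-ensemble* — predictions are averaged over the 8
  dihedral transforms of the input.

With ~20 pairs everything fits one batch, so batch 256 means full-batch
training.

A note on parameter count: at base 64 / depth 4 with two convolutions per
level this U-Net has ≈ 31 M parameters. No standard reading of the 64→1024
ladder yields the ~310 M sometimes quoted for such models, so the
parameter count is not treated as a correctness check here.

**Corruption model** (`demsi.corruption`). Quantitative evaluation
corrupts reference images with (1) Poisson resampling — each pixel
replaced by `Poisson(S·v)/S`, with `S = 1` the literal "pixel value as the
mean" reading — and (2) exact random missing data — `floor(0.20·n)` of the
mask-true pixels set to zero, sampled without replacement, applied after
the Poisson step. With intensities already in [0, 1] the `S = 1` draw is
extremely destructive (outputs are small integers), which is accepted as
the literal protocol; `S` is exposed to emulate a pre-normalisation count
scale when a gentler regime is wanted. Poisson corruption is exactly
unbiased and both mechanisms are reproducible per channel from
independent substreams of one seed.

**Metrics** (`demsi.metrics`). PSNR = 10·log₁₀(range²/MSE), with an
infinite sentinel for identical images. SSIM uses the standard Gaussian
window (11 taps, σ 1.5), K1 = 0.01, K2 = 0.03, population covariances, and
reflective filtering; both metrics agree with scikit-image's reference
implementations to 1e-6 (tested) while additionally supporting a pixel
mask, applied when aggregating (local SSIM windows are computed on the
full frame). `data_range` is fixed at 1.0 because preprocessing
guarantees [0, 1].

**Baselines** (`demsi.baselines`). Gaussian filtering (σ = 1 px,
reflective boundary) and multilevel db4 wavelet shrinkage (3 levels,
soft universal threshold σ̂·√(2 ln n), σ̂ from the MAD of the finest
diagonal subband, output clipped to ≥ 0). Neither method has a single
canonical parameterisation; the defaults here are the conventional ones
and are exposed in `BaselineConfig`.

## The synthetic phantom

Real MSI data ships no truth, so the generator builds cubes where truth
exists by construction. `n_regions` organ-like masks are smooth
thresholded Gaussian random fields covering 10–30% of the frame each. A
molecule's clean image is a weighted (U(0.15, 1)) sum of 1–3 region masks
over a weak (0.08) tissue-wide background, multiplied by a two-scale
squared-smooth-field texture and max-normalised — giving the skewed,
high-contrast intensity profiles real ion images show. Monoisotopic
channels get multiplicative lognormal noise (σ 0.2) and 5% missing
pixels; isotopic channels are the clean image scaled by the abundance
ratio (0.3) with the same noise plus 15% extra missing pixels and 2%
outliers at uniform(2, 4) × channel scale, reproducing the degradation
asymmetry the pairing trick relies on. Unpaired singletons and pure-noise
channels provide mining negatives; channel m/z values sit on a 20 Th grid
so no accidental spacing falls near 1.003355 Th. All randomness fans out
from one seed through per-channel substreams.

What the phantom does *not* emulate: spectral peak shapes, isotope fine
structure, mass-accuracy drift, correlated chemical background, and the
true abundance spread of real isotope clusters. Passing the phantom
benchmark therefore demonstrates that the pipeline's machinery works and
that its ordering claims hold under a controlled degradation model — not
that identical margins would be observed on any particular instrument's
data.

## The benchmark protocol

`run_phantom_benchmark` closes the loop: mine pairs from the noisy
phantom, train on them, then corrupt the *noise-free truth* channels
(Poisson + 20% missing), and score each method against the truth over the
monoisotopic channels. Every cube entering evaluation is first put in the
pipeline's canonical form — per-ion hotspot truncation and max
normalisation to [0, 1] — and every method's output is max-normalised the
same way before metrics. This keeps the comparison method-agnostic (all
images live on the one scale the pipeline defines) and matches how the
network sees data at train time. Default desk-scale problem size: 32×32
pixels, 20 planted pairs, ~55 channels, 500 training epochs, three seeds.

## Numerical choices and degenerate inputs

* Zero-TIC pixels, all-zero images and empty masks pass through unchanged
  rather than erroring; missing values are zeros by convention everywhere.
* The MAE subgradient at exact ties is taken as 0.
* Max-pooling ties resolve to the first maximum (argmax order), fixed and
  deterministic.
* Pair mining rejects candidates with fewer than 10 jointly nonzero
  pixels — a rank correlation on fewer points is meaningless.
* The processed-mode imzML reader merges peaks by greedy single-pass
  ±10 ppm binning against a running intensity-weighted bin centre; the
  tolerance is configurable and is a stand-in for a real peak-alignment
  step, which is out of scope.
* Training aborts with a diagnostic on non-finite loss rather than
  continuing silently.

## Known limitations

* The desk preset's network is far smaller than the full-scale reference
  configuration; margins measured at desk scale are qualitative, not
  quantitative, statements about the full-size model.
* Pair mining assumes centroided, aligned channels; profile-mode spectra
  must be peak-picked elsewhere first.
* The corruption benchmark evaluates robustness to exactly two noise
  mechanisms; real MSI noise includes structured components (stripes,
  matrix clusters) that neither the phantom nor the corruption model
  reproduces.
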