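"""The quantitative-evaluation experiment, end to end, on a phantom.

Because noise-free MSI data cannot be measured, the benchmark follows the
simulated-corruption protocol: take reference ion images, corrupt them with
Poisson resampling plus 20% random missing pixels, denoise with each
method, and score PSNR/SSIM against the reference.  On phantoms the
reference is the generator's noise-free truth, so the protocol closes the
loop: pairs are mined from the *noisy* phantom, the network is trained on
them, and evaluation runs on corrupted *clean* channels the training never
saw.

All denoised outputs (and the corrupted input) are put back on the
pipeline's canonical intensity scale — each ion image max-normalised to
[0, 1] — before metrics, matching how every other stage of the pipeline
represents ion images and keeping the comparison method-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .baselines import BaselineConfig, denoise_cube_baseline
from .corruption import CorruptionConfig, corrupt_cube
from .datacube import MSIDataCube
from .denoiser import MSIDenoiser, TrainConfig, denoise_cube, train_denoiser
from .isopair import PairConfig, build_training_set, find_pairs
from .metrics import EvalReport, evaluate_methods
from .phantom import PhantomConfig, generate_phantom, phantom_report
from .preprocess import PreprocessConfig, preprocess_cube

__all__ = ["BenchmarkResult", "run_phantom_benchmark", "max_normalize_cube"]


def max_normalize_cube(cube: MSIDataCube) -> MSIDataCube:
    """Per-channel max normalisation of a whole cube (the canonical scale)."""
    out = cube.copy()
    for k in range(out.n_channels):
        m = out.intensities[:, :, k].max()
        if m > 0:
            out.intensities[:, :, k] /= m
    return out


@dataclass
class BenchmarkResult:
    report: EvalReport
    pair_stats: dict
    estimator: MSIDenoiser
    n_pairs: int
    channels: list = field(default_factory=list)


def run_phantom_benchmark(
    seed: int = 0,
    phantom_cfg: PhantomConfig | None = None,
    train_cfg: TrainConfig | None = None,
    pair_cfg: PairConfig | None = None,
    corruption_cfg: CorruptionConfig | None = None,
    baseline_cfg: BaselineConfig | None = None,
) -> BenchmarkResult:
    """Run the full two-stage pipeline plus corruption benchmark on a phantom.

    Stage 1: generate a noisy phantom, preprocess it, mine isotope pairs.
    Stage 2: train the denoiser on the mined (iso, mono) pairs.
    Evaluation: corrupt the noise-free truth channels (Poisson + missing),
    clip to [0, 1], denoise with the trained network and with the Gaussian /
    wavelet baselines, and score everything against the clean truth over the
    monoisotopic channels.
    """
    phantom_cfg = phantom_cfg or PhantomConfig(shape=(32, 32), seed=seed)
    train_cfg = train_cfg or TrainConfig(seed=seed)
    corruption_cfg = corruption_cfg or CorruptionConfig(seed=seed)
    baseline_cfg = baseline_cfg or BaselineConfig()

    noisy, truth = generate_phantom(phantom_cfg)
    prep = preprocess_cube(noisy, PreprocessConfig())
    pairs = find_pairs(prep, pair_cfg)
    pair_stats = phantom_report(truth, pairs)
    training_set = build_training_set(prep, pairs)
    est = train_denoiser(training_set, train_cfg)

    clean = truth.clean_cube
    mono_channels = [m for m, _ in truth.pair_manifest]
    corrupted = corrupt_cube(clean, corruption_cfg)
    # corrupted images re-enter the pipeline's canonical per-ion form
    # (hotspot truncation + max normalisation, no TIC) before any method
    corrupted = preprocess_cube(corrupted, PreprocessConfig(do_tic=False))

    methods = {
        "de-msi": denoise_cube(est, corrupted),
        "gaussian": denoise_cube_baseline(corrupted, "gaussian", baseline_cfg),
        "wavelet": denoise_cube_baseline(corrupted, "wavelet", baseline_cfg),
    }
    methods = {k: max_normalize_cube(v) for k, v in methods.items()}
    report = evaluate_methods(clean, corrupted, methods, channels=mono_channels)
    return BenchmarkResult(
        report=report,
        pair_stats=pair_stats,
        estimator=est,
        n_pairs=len(pairs),
        channels=mono_channels,
    )
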