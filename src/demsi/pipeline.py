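"""End-to-end pipeline orchestration: preprocess → pairs → train → denoise.

Each stage reads only serialised artifacts of the previous one, so a run is
resumable per stage, and every run writes a resolved-config snapshot and a
pair table / loss history next to its outputs for provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os

import numpy as np
import yaml

from .baselines import BaselineConfig, denoise_cube_baseline
from .benchmark import max_normalize_cube
from .corruption import CorruptionConfig, corrupt_cube
from .datacube import load_cube, write_cube
from .denoiser import TrainConfig, denoise_cube, save_checkpoint, train_denoiser
from .isopair import PairConfig, build_training_set, find_pairs, pairs_to_table
from .metrics import evaluate_methods
from .phantom import PhantomConfig, generate_phantom
from .preprocess import PreprocessConfig, preprocess_cube

logger = logging.getLogger("demsi")

__all__ = ["RunConfig", "run_pipeline"]


class RunConfig:
    """Merged settings for an end-to-end run."""

    def __init__(
        self,
        out_dir: str,
        input_cube: str | None = None,
        phantom: PhantomConfig | None = None,
        preprocess: PreprocessConfig | None = None,
        pairs: PairConfig | None = None,
        train: TrainConfig | None = None,
        corruption: CorruptionConfig | None = None,
        baselines: BaselineConfig | None = None,
        seed: int = 0,
        evaluate: bool = False,
    ):
        if input_cube is None and phantom is None:
            phantom = PhantomConfig(seed=seed)
        self.out_dir = out_dir
        self.input_cube = input_cube
        self.phantom = phantom
        self.preprocess = preprocess or PreprocessConfig()
        self.pairs = pairs or PairConfig()
        self.train = train or TrainConfig(seed=seed)
        self.corruption = corruption or CorruptionConfig(seed=seed)
        self.baselines = baselines or BaselineConfig()
        self.seed = seed
        self.evaluate = evaluate

    def to_dict(self) -> dict:
        def enc(obj):
            if obj is None:
                return None
            if hasattr(obj, "to_dict"):
                return obj.to_dict()
            return {k: (list(v) if isinstance(v, tuple) else v) for k, v in obj.__dict__.items()}

        return {
            "out_dir": self.out_dir,
            "input_cube": self.input_cube,
            "phantom": enc(self.phantom),
            "preprocess": enc(self.preprocess),
            "pairs": enc(self.pairs),
            "train": enc(self.train),
            "corruption": enc(self.corruption),
            "baselines": enc(self.baselines),
            "seed": self.seed,
            "evaluate": self.evaluate,
        }


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full workflow; returns a dict of artifact paths.

    Stages: (simulate) → preprocess → pair mining → training → whole-cube
    denoising → (evaluation against clean truth, phantom runs only).
    Failures propagate with the stage name; artifacts written so far stay.
    """
    os.makedirs(cfg.out_dir, exist_ok=True)
    resolved = cfg.to_dict()
    cfg_text = yaml.safe_dump(resolved, sort_keys=True)
    cfg_hash = hashlib.sha256(cfg_text.encode()).hexdigest()[:12]
    paths = {"config": os.path.join(cfg.out_dir, "config.yaml")}
    with open(paths["config"], "w") as f:
        f.write(f"# config hash: {cfg_hash}\n{cfg_text}")

    truth = None
    if cfg.input_cube is not None:
        logger.info("loading cube from %s", cfg.input_cube)
        cube = load_cube(cfg.input_cube)
    else:
        logger.info("generating phantom (seed=%d)", cfg.phantom.seed)
        cube, truth = generate_phantom(cfg.phantom)
        paths["phantom"] = os.path.join(cfg.out_dir, "phantom.npz")
        write_cube(cube, paths["phantom"])
        paths["clean_truth"] = os.path.join(cfg.out_dir, "clean_truth.npz")
        write_cube(truth.clean_cube, paths["clean_truth"])

    prep = preprocess_cube(cube, cfg.preprocess)
    paths["preprocessed"] = os.path.join(cfg.out_dir, "preprocessed.npz")
    write_cube(prep, paths["preprocessed"])

    pairs = find_pairs(prep, cfg.pairs)
    table = pairs_to_table(pairs)
    paths["pairs"] = os.path.join(cfg.out_dir, "pairs.csv")
    table.to_csv(paths["pairs"], index=False)
    logger.info("mined %d isotope pairs", len(pairs))
    if not pairs:
        raise RuntimeError("pair-mining stage found no isotope pairs; cannot train")

    training_set = build_training_set(prep, pairs)
    est = train_denoiser(training_set, cfg.train)
    paths["checkpoint"] = os.path.join(cfg.out_dir, "model.npz")
    save_checkpoint(est, paths["checkpoint"])
    hist = est.loss_history_
    paths["loss_history"] = os.path.join(cfg.out_dir, "loss_history.csv")
    with open(paths["loss_history"], "w") as f:
        f.write("epoch,train_loss,val_loss\n")
        for e, (tr, va) in enumerate(zip(hist["train"], hist["val"])):
            f.write(f"{e},{tr},{va}\n")

    denoised = denoise_cube(est, prep)
    paths["denoised"] = os.path.join(cfg.out_dir, "denoised.npz")
    write_cube(denoised, paths["denoised"])

    if cfg.evaluate and truth is not None:
        clean = truth.clean_cube
        mono_channels = [m for m, _ in truth.pair_manifest]
        corrupted = corrupt_cube(clean, cfg.corruption)
        corrupted.intensities = np.clip(corrupted.intensities, 0.0, 1.0)
        methods = {
            "de-msi": max_normalize_cube(denoise_cube(est, corrupted)),
            "gaussian": max_normalize_cube(
                denoise_cube_baseline(corrupted, "gaussian", cfg.baselines)
            ),
            "wavelet": max_normalize_cube(
                denoise_cube_baseline(corrupted, "wavelet", cfg.baselines)
            ),
        }
        report = evaluate_methods(clean, corrupted, methods, channels=mono_channels)
        paths["eval_report"] = os.path.join(cfg.out_dir, "eval_report.csv")
        report.per_channel.to_csv(paths["eval_report"], index=False)
        paths["eval_aggregate"] = os.path.join(cfg.out_dir, "eval_aggregate.csv")
        report.aggregate.to_csv(paths["eval_aggregate"])

    return paths
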