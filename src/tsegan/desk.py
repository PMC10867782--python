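"""The desk-scale reference experiment.

A complete train-and-evaluate study sized for a single CPU: 32 phantom pairs
rendered at 96 px, cropped to 64 px, 8 base channels, batch 4, 200
optimisation steps.  Three outcomes summarise it:

* optimisation: median total generator loss over the last 10% of steps
  versus the first 10%;
* fidelity: mean PSNR of a trained checkpoint versus its Xavier
  initialisation on 8 held-out phantoms;
* stiffness recovery: Spearman rank correlation between the true phantom
  score and the blue/green ratio of the generated elastograms over 50
  held-out phantoms (10 per score).

All randomness derives from one integer seed; the training set, the two
held-out sets and the network initialisation use disjoint seed offsets.
"""

from __future__ import annotations

import csv
import dataclasses
from pathlib import Path

import numpy as np
from scipy import stats

from .evaluation import evaluate_model
from .generator import NetworkConfig
from .phantom import PhantomConfig, generate_dataset
from .training import (TrainConfig, build_models, load_checkpoint,
                       run_training, save_checkpoint)

__all__ = ["desk_configs", "run_desk_experiment", "read_loss_log",
           "loss_medians"]

_IMAGE_SIZE = 96
_RADII = (10, 24)
_N_TRAIN = 32
_N_HELDOUT = 8
_N_SCORING_PER_SCORE = 10


def desk_configs(seed: int) -> tuple[TrainConfig, NetworkConfig]:
    return TrainConfig.desk(seed=seed), NetworkConfig.desk(seed=seed)


def _phantom_cfg(seed: int, score: int | str = "random") -> PhantomConfig:
    return PhantomConfig(image_size=_IMAGE_SIZE, nodule_radius_range=_RADII,
                         seed=seed, target_score=score)


def read_loss_log(log_path: str | Path) -> dict[str, np.ndarray]:
    with open(log_path) as fh:
        rows = list(csv.DictReader(fh))
    return {k: np.array([float(r[k]) for r in rows]) for k in rows[0]}


def loss_medians(log_path: str | Path, frac: float = 0.1
                 ) -> tuple[float, float]:
    """Median total generator loss over the first and last `frac` of steps."""
    total = read_loss_log(log_path)["total_g"]
    k = max(int(round(frac * total.size)), 1)
    return float(np.median(total[:k])), float(np.median(total[-k:]))


def run_desk_experiment(seed: int, out_dir: str | Path,
                        max_steps: int | None = None) -> dict:
    """Run the full desk study and return its summary quantities.

    ``max_steps`` overrides the 200-step default only to shorten smoke
    runs; the reference conditions are the defaults.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    train_cfg, net_cfg = desk_configs(seed)
    if max_steps is not None:
        train_cfg = dataclasses.replace(train_cfg, max_steps=max_steps)

    train_manifest = generate_dataset(
        _N_TRAIN, _phantom_cfg(seed), out_dir / "train_data")
    heldout_manifest = generate_dataset(
        _N_HELDOUT, _phantom_cfg(seed + 10_000), out_dir / "heldout_data")
    scoring_dir = out_dir / "scoring_data"
    scoring_manifests = []
    for score in range(1, 6):
        sub = generate_dataset(
            _N_SCORING_PER_SCORE,
            _phantom_cfg(seed + 20_000 + 1_000 * score, score=score),
            scoring_dir / f"score{score}")
        scoring_manifests.append(sub)

    # untrained reference checkpoint (Xavier init, same seed)
    gen0, d1_0, d2_0 = build_models(net_cfg, train_cfg.seed)
    from . import nn
    betas = (train_cfg.adam_beta1, train_cfg.adam_beta2)
    init_ckpt = out_dir / "checkpoint_init.pkl"
    save_checkpoint(init_ckpt, gen0, d1_0, d2_0,
                    nn.Adam(gen0.parameters()), nn.Adam(d1_0.parameters()),
                    nn.Adam(d2_0.parameters()),
                    np.random.default_rng(train_cfg.seed), 0, net_cfg,
                    train_cfg)

    ckpt, log_path = run_training(train_manifest, train_cfg, net_cfg,
                                  out_dir / "run")
    first_med, last_med = loss_medians(log_path)

    rep_trained = evaluate_model(ckpt, heldout_manifest,
                                 out_dir / "eval_trained.csv")
    rep_init = evaluate_model(init_ckpt, heldout_manifest,
                              out_dir / "eval_init.csv")

    true_scores: list[int] = []
    ratios: list[float] = []
    for mf in scoring_manifests:
        rep = evaluate_model(ckpt, mf)
        true_scores += rep.true_scores
        ratios += rep.bg_ratios
    rho = float(stats.spearmanr(true_scores, ratios).statistic)

    return {
        "checkpoint": str(ckpt),
        "loss_log": str(log_path),
        "n_train": _N_TRAIN,
        "n_steps": int(read_loss_log(log_path)["iteration"][-1]),
        "total_g_median_first10pct": first_med,
        "total_g_median_last10pct": last_med,
        "psnr_trained_db": rep_trained.mean_psnr,
        "psnr_init_db": rep_init.mean_psnr,
        "ssim_trained": rep_trained.mean_ssim,
        "mse_trained": rep_trained.mean_mse,
        "score_ratio_spearman": rho,
        "n_scoring": len(true_scores),
    }
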