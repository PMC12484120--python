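"""Training loop, evaluation, and the experiment grids.

Defaults mirror the study conditions: Adam, learning rate 0.001, 200
epochs, batch size 16, Dice loss, no augmentation, no LR scheduling.
The four experiment grids enumerate exactly the published configuration
sets: 5 module combinations, 21 dilation triples, 3 skip-path modes and
5 optimizers.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .data import SegmentationDataset, batches
from .errors import ConfigurationError, ContractError
from .metrics import MetricReport, dice_loss, evaluate, pixel_accuracy
from .network import MAFNet, ModelConfig, build_model, save_checkpoint
from .nn import make_optimizer
from .nn.tensor import Tensor


@dataclass
class TrainConfig:
    optimizer: str = "adam"
    learning_rate: float = 0.001
    epochs: int = 200
    batch_size: int = 16
    seed: int = 0
    device: str = "cpu"
    early_stop_patience: int | None = None
    threshold: float = 0.5

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be positive")
        if self.epochs < 1 or self.batch_size < 1:
            raise ConfigurationError("epochs and batch_size must be positive")
        if self.optimizer.lower() not in nn.OPTIMIZERS:
            raise ConfigurationError(
                f"unknown optimizer {self.optimizer!r}; choose from {sorted(nn.OPTIMIZERS)}")


def _forward_eval(model: MAFNet, images: np.ndarray, batch_size: int = 16) -> np.ndarray:
    """Inference-mode predictions for an array of images."""
    outs = []
    for start in range(0, images.shape[0], batch_size):
        outs.append(model.predict(images[start:start + batch_size]))
    return np.concatenate(outs, axis=0)


def train(model: MAFNet, dataset: SegmentationDataset, cfg: TrainConfig,
          checkpoint_path=None, curves_path=None):
    """Optimize the Dice loss; returns (model, curves DataFrame).

    Logs per-epoch train/val loss and pixel accuracy, and (when
    ``checkpoint_path`` is given) saves the best-validation-loss weights.
    Fully seeded: data order derives from ``cfg.seed``; parameter
    initialization is the caller's responsibility (``build_model(seed=)``).
    """
    for split in ("train", "val"):
        if dataset.n(split) == 0:
            raise ContractError(f"training requires a nonempty {split!r} split")
    opt = make_optimizer(cfg.optimizer, model.parameters(), cfg.learning_rate)
    val_images, val_masks = dataset.images("val"), dataset.masks("val")
    rows = []
    best_val = np.inf
    best_state = None
    patience_left = cfg.early_stop_patience
    step = 0
    for epoch in range(cfg.epochs):
        model.train()
        epoch_losses = []
        epoch_acc = []
        for xb, yb in batches(dataset, "train", cfg.batch_size,
                              shuffle_seed=cfg.seed * 100003 + epoch):
            x = Tensor(xb)
            pred = model(x)
            loss = dice_loss(pred, yb)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}, step {step}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
            epoch_acc.append(pixel_accuracy(pred.data, yb, cfg.threshold))
            step += 1
        val_pred = _forward_eval(model, val_images, cfg.batch_size)
        val_loss = dice_loss(val_pred, val_masks)
        rows.append({
            "epoch": epoch,
            "train_loss": float(np.mean(epoch_losses)),
            "val_loss": float(val_loss),
            "train_accuracy": float(np.mean(epoch_acc)),
            "val_accuracy": pixel_accuracy(val_pred, val_masks, cfg.threshold),
        })
        if val_loss < best_val:
            best_val = val_loss
            best_state = model.state_dict()
            patience_left = cfg.early_stop_patience
        elif cfg.early_stop_patience is not None:
            patience_left -= 1
            if patience_left <= 0:
                break
    if best_state is not None:
        model.load_state_dict(best_state)
    if checkpoint_path is not None:
        save_checkpoint(model, checkpoint_path)
    curves = pd.DataFrame(rows)
    if curves_path is not None:
        curves.to_csv(curves_path, index=False)
    return model, curves


def evaluate_model(model: MAFNet, dataset: SegmentationDataset, split: str = "test",
                   threshold: float = 0.5,
                   aggregation: str = "per_image_mean") -> MetricReport:
    """Deterministic five-metric evaluation of a split."""
    images, masks, ids = dataset._get(split)
    preds = _forward_eval(model, images)
    return evaluate(preds, masks, threshold=threshold,
                    aggregation=aggregation, ids=ids)


# -- experiment grids -------------------------------------------------------

TABLE2_COMBOS = (
    ("baseline", False, False, False),
    ("baseline+mafm", True, False, False),
    ("baseline+daem", False, True, False),
    ("baseline+dseem", False, False, True),
    ("baseline+mafm+daem+dseem", True, True, True),
)

# all strictly increasing triples (1, a, b) with 2 <= a < b <= 8, row order
TABLE5_DILATIONS = tuple(
    (1, a, b) for a in range(2, 8) for b in range(a + 1, 9)
)

TABLE6_PATH_MODES = ("dual", "input1_only", "input2_only")

TABLE7_OPTIMIZERS = ("adam", "adagrad", "adamax", "rmsprop", "sgd")

GRIDS = ("table2", "table5", "table6", "table7")


def grid_configs(grid: str, base_model: ModelConfig, base_train: TrainConfig):
    """Enumerate (label, ModelConfig, TrainConfig) rows of one grid."""
    if grid == "table2":
        for label, m, d, s in TABLE2_COMBOS:
            yield label, replace(base_model, use_mafm=m, use_daem=d, use_dseem=s), base_train
    elif grid == "table5":
        for tri in TABLE5_DILATIONS:
            yield str(tri), replace(base_model, use_mafm=True, mafm_dilations=tri), base_train
    elif grid == "table6":
        for mode in TABLE6_PATH_MODES:
            yield mode, replace(base_model, use_dseem=True, dseem_path_mode=mode), base_train
    elif grid == "table7":
        for opt in TABLE7_OPTIMIZERS:
            yield opt, base_model, replace(base_train, optimizer=opt)
    else:
        raise ConfigurationError(f"unknown grid {grid!r}; choose from {GRIDS}")


def run_ablation_grid(base_model: ModelConfig, base_train: TrainConfig,
                      grid: str, dataset: SegmentationDataset,
                      eval_split: str = "test", out_csv=None) -> pd.DataFrame:
    """Train and evaluate every configuration of one experiment grid.

    Emits one row per configuration with the five metrics in the
    conventional column order (Dice, Mcc, Jaccard, Accuracy, Recall).
    """
    if dataset.n(eval_split) == 0:
        raise ContractError(f"evaluation split {eval_split!r} is empty")
    rows = []
    for label, mcfg, tcfg in grid_configs(grid, base_model, base_train):
        model = build_model(mcfg, seed=tcfg.seed)
        model, _ = train(model, dataset, tcfg)
        report = evaluate_model(model, dataset, split=eval_split,
                                threshold=tcfg.threshold)
        rows.append({
            "config": label,
            "dice": report.aggregate["dice"],
            "mcc": report.aggregate["mcc"],
            "jaccard": report.aggregate["jaccard"],
            "accuracy": report.aggregate["accuracy"],
            "recall": report.aggregate["recall"],
            "parameters": model.num_parameters(),
        })
    df = pd.DataFrame(rows)
    if out_csv is not None:
        df.to_csv(out_csv, index=False)
    return df
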