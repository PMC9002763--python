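"""Optimization loop: Adam, the flat-then-power learning-rate schedule,
median-frequency class weights computed on the training split, checkpointing
and history logging.

The learning rate stays at ``base_lr`` (default 1e-3) for the first
``schedule_switch_iteration`` epochs (default 12) and then decays as

    lr(e) = base_lr · (e − switch + 1)^(−power)        for e > switch

with power 0.5 by default — e.g. epoch 16 gives 1e-3·5^−0.5 ≈ 4.47e-4. The
schedule is epoch-indexed and monotone nonincreasing.

Class weights are always computed from the *training* labels only; the
validation split never leaks into the objective.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .io_nifti import IntensityVolume, LabelVolume
from .losses import ClassWeights, FocalParams, combined_loss, median_frequency_weights
from .metrics import MetricsReport, confusion_all, report_from_counts
from .model import ModelConfig, SegmentationNetwork
from .preprocess import extract_patches, reassemble_patches

__all__ = ["TrainConfig", "lr_schedule", "Adam", "train", "evaluate",
           "predict_volume"]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters (defaults follow the reference setup)."""

    base_lr: float = 0.001
    schedule_switch_iteration: int = 12
    schedule_power: float = 0.5
    batch_size: int = 8
    max_epochs: int = 50
    patience: int = 10            # early stop on validation macro Dice
    lambda_mix: float = 0.5       # Dice vs focal mixing
    focal_gamma: float = 2.0
    eval_every: int = 1           # epochs between validation evaluations
    stop_at_dice: float | None = None  # stop once validation macro Dice reaches this
    seed: int = 0
    deterministic_mode: bool = True  # numpy backend is deterministic either way

    def __post_init__(self):
        if self.base_lr <= 0:
            raise ValueError("base_lr must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not 0.0 <= self.lambda_mix <= 1.0:
            raise ValueError("lambda_mix must be in [0, 1]")


def lr_schedule(iteration: int, cfg: TrainConfig) -> float:
    """Learning rate at a 1-based epoch index; flat then power decay."""
    if iteration < 1:
        raise ValueError("iteration is 1-based")
    if iteration <= cfg.schedule_switch_iteration:
        return cfg.base_lr
    step = iteration - cfg.schedule_switch_iteration + 1
    return cfg.base_lr * step ** (-cfg.schedule_power)


class Adam:
    """Adam with conventional defaults (β₁=0.9, β₂=0.999, ε=1e-8)."""

    def __init__(self, params: dict, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for name, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[name] = b1 * self.m[name] + (1 - b1) * g
            self.v[name] = b2 * self.v[name] + (1 - b2) * g * g
            m_hat = self.m[name] / (1 - b1 ** self.t)
            v_hat = self.v[name] / (1 - b2 ** self.t)
            p.data -= (lr * m_hat / (np.sqrt(v_hat) + self.eps)).astype(p.data.dtype)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


def _patch_array(item) -> tuple[np.ndarray, np.ndarray]:
    img, lab = item
    if isinstance(img, IntensityVolume):
        img = img.voxels
    if isinstance(lab, LabelVolume):
        lab = lab.voxels
    return np.asarray(img, dtype=np.float32), np.asarray(lab)


def train(model_cfg: ModelConfig, train_cfg: TrainConfig, train_data,
          val_data=None, class_weights: ClassWeights | None = None,
          out_dir=None, max_steps: int | None = None,
          progress: bool = False) -> tuple[SegmentationNetwork, list[dict]]:
    """Train a network on (intensity patch, label patch) pairs.

    Parameters
    ----------
    train_data
        Sequence of paired blocks matching ``model_cfg.input_shape``.
    val_data
        Optional sequence of paired *volumes* (any shape); validation is
        patch-wise prediction + reassembly + macro Dice. When absent, the
        training patches themselves are scored, which turns validation Dice
        into a fit (overfit) measure.
    class_weights
        Median-frequency weights; computed from ``train_data`` labels when
        not given (never from the validation split).
    max_steps
        Optional hard cap on optimizer steps for desk-scale runs.

    Returns the network (best-validation parameters restored) and the
    per-epoch history (epoch, lr, mean combined loss, validation macro Dice).
    """
    pairs = [_patch_array(item) for item in train_data]
    if not pairs:
        raise ValueError("empty training set")
    if class_weights is None:
        class_weights = median_frequency_weights([lab for _, lab in pairs],
                                                 n_classes=model_cfg.n_classes)
    focal = FocalParams(gamma=train_cfg.focal_gamma, alpha_t=class_weights)

    net = SegmentationNetwork(model_cfg)
    opt = Adam(net.params)
    rng = np.random.default_rng(train_cfg.seed)

    history: list[dict] = []
    best = {"dice": -1.0, "params": None, "epoch": 0}
    steps = 0
    stop = False

    for epoch in range(1, train_cfg.max_epochs + 1):
        lr = lr_schedule(epoch, train_cfg)
        order = rng.permutation(len(pairs))
        losses = []
        for start in range(0, len(order), train_cfg.batch_size):
            batch = [pairs[i] for i in order[start:start + train_cfg.batch_size]]
            x = np.stack([b[0] for b in batch])[..., None] \
                if batch[0][0].ndim == 3 else np.stack([b[0] for b in batch])
            y = np.stack([b[1] for b in batch])
            probs = net.forward(x, training=True)
            loss = combined_loss(probs, y, class_weights, params=focal,
                                 lambda_mix=train_cfg.lambda_mix)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, step {steps}")
            opt.zero_grad()
            loss.backward()
            opt.step(lr)
            losses.append(loss.item())
            steps += 1
            if max_steps is not None and steps >= max_steps:
                stop = True
                break

        entry = {"epoch": epoch, "lr": lr, "loss": float(np.mean(losses)),
                 "steps": steps}
        if epoch % train_cfg.eval_every == 0 or stop or epoch == train_cfg.max_epochs:
            eval_pairs = val_data if val_data is not None else pairs
            rep = evaluate(net, eval_pairs)
            entry["val_macro_dice"] = rep.macro_average["dice"]
            if entry["val_macro_dice"] > best["dice"]:
                best = {"dice": entry["val_macro_dice"],
                        "params": {k: p.data.copy() for k, p in net.params.items()},
                        "epoch": epoch}
            if (train_cfg.stop_at_dice is not None
                    and entry["val_macro_dice"] >= train_cfg.stop_at_dice):
                stop = True
        history.append(entry)
        if progress:
            print(f"epoch {epoch:4d}  lr {lr:.2e}  loss {entry['loss']:.4f}"
                  + (f"  dice {entry.get('val_macro_dice', float('nan')):.4f}"
                     if "val_macro_dice" in entry else ""))
        if stop:
            break
        evaluated = [h for h in history if "val_macro_dice" in h]
        if (len(evaluated) > 0 and best["epoch"] > 0
                and epoch - best["epoch"] >= train_cfg.patience):
            break

    if best["params"] is not None:
        for k, p in net.params.items():
            p.data = best["params"][k]

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        net.save(out_dir / "checkpoint.npz")
        with open(out_dir / "history.csv", "w", newline="") as f:
            writer = csv.DictWriter(f, fieldnames=["epoch", "lr", "loss", "steps",
                                                   "val_macro_dice"])
            writer.writeheader()
            writer.writerows(history)
        (out_dir / "class_weights.json").write_text(
            json.dumps({"alpha": class_weights.alpha.tolist()}, indent=2))
        (out_dir / "train_config.json").write_text(json.dumps(asdict(train_cfg),
                                                              indent=2))
    return net, history


def predict_volume(net: SegmentationNetwork, vol: IntensityVolume) -> LabelVolume:
    """Segment a whole volume: tile into model-sized patches, predict each,
    reassemble and crop the padding back off."""
    patch = net.cfg.input_shape[0]
    if net.cfg.input_shape[:3] != (patch, patch, patch):
        raise ValueError("predict_volume requires a cubic model input")
    dummy = LabelVolume(voxels=np.zeros(vol.shape, dtype=np.int16), affine=vol.affine)
    stack = extract_patches(vol, dummy, patch_size=patch)
    pred_patches = []
    for (img, _), _origin in zip(stack.patches, stack.grid_origin):
        pred_patches.append((img, net.predict_labels(img)))
    stack.patches = pred_patches
    _, pred = reassemble_patches(stack, crop=True)
    return LabelVolume(voxels=pred.voxels, affine=vol.affine)


def evaluate(net: SegmentationNetwork, volumes,
             include_background_weighted: bool = True) -> MetricsReport:
    """Predict each (intensity, label) pair and report pooled metrics.

    Confusion counts are pooled over all volumes before the metrics are
    formed, i.e. the report scores the collection as one segmentation task.
    """
    n_classes = net.cfg.n_classes
    tp = np.zeros(n_classes, dtype=np.int64)
    fp = np.zeros_like(tp)
    fn = np.zeros_like(tp)
    for img, lab in volumes:
        if not isinstance(img, IntensityVolume):
            img = IntensityVolume(voxels=np.asarray(img, dtype=np.float32))
        lab_arr = lab.voxels if isinstance(lab, LabelVolume) else np.asarray(lab)
        pred = predict_volume(net, img)
        t, f_p, f_n = confusion_all(pred.voxels, lab_arr, n_classes)
        tp += t
        fp += f_p
        fn += f_n
    return report_from_counts(tp, fp, fn,
                              include_background_weighted=include_background_weighted)
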