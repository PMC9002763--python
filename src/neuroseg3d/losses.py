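"""Training objectives for imbalanced multi-class segmentation.

Brain parcellations are severely imbalanced: background dominates, and
structure sizes span orders of magnitude. The objective used here combines

* a **weighted Dice loss** — a single global soft-Dice ratio in which each
  class's intersection and mass terms are scaled by a class weight w_j:

  .. math:: L_D = 1 - \\frac{2 \\sum_j w_j \\sum_i y_{ij} p_{ij}}
                           {\\sum_j w_j \\sum_i (y_{ij} + p_{ij})}

* a **focal loss** — cross-entropy with the easy-voxel contribution
  down-weighted by the modulating factor (1 − p_t)^γ:

  .. math:: L_F = \\operatorname{mean}_i \\, [-\\alpha_{t_i} (1-p_{t_i})^\\gamma
                   \\log p_{t_i}]

mixed convexly, ``λ·L_D + (1−λ)·L_F`` with λ = 0.5 by default.

Class weights come from **median frequency balancing**:
``α_c = median_freq / freq(c)`` where ``freq(c)`` is the voxel count of
class c divided by the total voxels of only those volumes in which c
appears. The weight of the median-frequency class is 1; rarer classes get
larger weights. By default the same weights serve as the Dice w_j and the
focal α_t.

All loss functions accept either plain numpy arrays (returning a float) or
autograd :class:`~neuroseg3d.autograd.Tensor` objects (returning a scalar
Tensor on the tape), so the same code is the evaluator and the training
objective.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .io_nifti import LabelVolume

__all__ = ["ClassWeights", "FocalParams", "median_frequency_weights",
           "weighted_dice_loss", "focal_loss", "combined_loss", "one_hot"]

_EPS = 1e-7  # probability clipping floor, keeps log finite


@dataclass(frozen=True)
class ClassWeights:
    """Per-class positive weights, index-aligned with class IDs."""

    alpha: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "alpha", np.asarray(self.alpha, dtype=np.float64))
        if self.alpha.ndim != 1 or np.any(self.alpha <= 0):
            raise ValueError("class weights must be a 1D array of positive reals")

    def __len__(self) -> int:
        return len(self.alpha)


@dataclass(frozen=True)
class FocalParams:
    """Focal-loss parameters: focusing exponent γ ≥ 0 and per-class α_t."""

    gamma: float = 2.0
    alpha_t: np.ndarray | float = 1.0

    def __post_init__(self):
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")


def median_frequency_weights(label_volumes, n_classes: int | None = None,
                             include_background: bool = True) -> ClassWeights:
    """Median frequency balancing over a collection of label volumes.

    ``freq(c)`` is the total voxel count of class c divided by the total
    voxel count of the volumes where class c appears; the weight is the
    median of these frequencies divided by ``freq(c)``. A class absent from
    every volume is excluded with a warning and given weight 1 so the array
    stays index-aligned.
    """
    arrays = [lv.voxels if isinstance(lv, LabelVolume) else np.asarray(lv)
              for lv in label_volumes]
    if not arrays:
        raise ValueError("need at least one label volume")
    if n_classes is None:
        n_classes = int(max(a.max() for a in arrays)) + 1

    counts = np.zeros(n_classes, dtype=np.int64)
    denom = np.zeros(n_classes, dtype=np.int64)  # voxels of volumes containing c
    for a in arrays:
        c = np.bincount(a.ravel(), minlength=n_classes)[:n_classes]
        counts += c
        denom += np.where(c > 0, a.size, 0)

    first = 0 if include_background else 1
    freq = np.full(n_classes, np.nan)
    present = denom > 0
    freq[present] = counts[present] / denom[present]

    used = present.copy()
    used[:first] = False
    for c in np.flatnonzero(~present[first:]) + first:
        warnings.warn(f"class {c} absent from every volume; weight undefined, "
                      "set to 1", stacklevel=2)
    if not used.any():
        raise ValueError("no class present in any volume")
    median_freq = float(np.median(freq[used]))

    alpha = np.ones(n_classes - first)
    sel = used[first:]
    alpha[sel] = median_freq / freq[first:][sel]
    return ClassWeights(alpha=alpha)


def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    """Integer label array -> trailing-axis one-hot encoding (float32)."""
    labels = np.asarray(labels)
    if labels.min(initial=0) < 0 or labels.max(initial=0) >= n_classes:
        raise ValueError("label IDs out of range for n_classes")
    eye = np.eye(n_classes, dtype=np.float32)
    return eye[labels]


def _check_pair(probs, onehot):
    p_shape = probs.shape if hasattr(probs, "shape") else np.shape(probs)
    y_shape = onehot.shape if hasattr(onehot, "shape") else np.shape(onehot)
    if tuple(p_shape) != tuple(y_shape):
        raise ValueError(f"probs shape {p_shape} != one-hot shape {y_shape}")


def weighted_dice_loss(probs, onehot, weights: ClassWeights | np.ndarray):
    """Global weighted soft-Dice loss (one ratio, not a per-class mean).

    `probs` and `onehot` have the class axis last; `weights` has one entry
    per class along that axis. The value lies in [0, 1], is 0 exactly when
    the prediction equals the one-hot truth, and is invariant to uniform
    rescaling of the weights.
    """
    _check_pair(probs, onehot)
    w = weights.alpha if isinstance(weights, ClassWeights) else np.asarray(weights, dtype=np.float64)
    if np.any(w < 0):
        raise ValueError("class weights must be nonnegative")
    n_classes = probs.shape[-1]
    if len(w) != n_classes:
        raise ValueError(f"got {len(w)} weights for {n_classes} classes")

    axes = tuple(range(probs.ndim - 1))  # all but class axis
    intersection = (probs * onehot).sum(axis=axes)       # per-class Σ_i y p
    mass = (probs + onehot).sum(axis=axes)               # per-class Σ_i (y + p)
    num = 2.0 * (intersection * w).sum()
    den = (mass * w).sum()
    loss = 1.0 - num * den ** -1.0
    return loss if isinstance(loss, Tensor) else float(loss)


def focal_loss(probs, labels, params: FocalParams = FocalParams()):
    """Mean focal loss over voxels.

    ``p_t`` is the predicted probability of each voxel's true class,
    gathered via the one-hot product; probabilities are clipped to
    [eps, 1] before the log. With γ = 0 and α_t = 1 this is exactly the mean
    cross-entropy.
    """
    labels = np.asarray(labels)
    n_classes = probs.shape[-1]
    y = one_hot(labels, n_classes)
    alpha_t = params.alpha_t
    if isinstance(alpha_t, ClassWeights):
        alpha_t = alpha_t.alpha
    if np.ndim(alpha_t) == 1:
        if len(alpha_t) != n_classes:
            raise ValueError(f"alpha_t has {len(alpha_t)} entries for {n_classes} classes")
        alpha_voxel = np.asarray(alpha_t)[labels]
    else:
        alpha_voxel = float(alpha_t)

    p_t = ag.clip((probs * y).sum(axis=-1), _EPS, 1.0)
    term = (1.0 - p_t) ** params.gamma * ag.log(p_t) * -1.0
    loss = (term * alpha_voxel).mean()
    return loss if isinstance(loss, Tensor) else float(loss)


def combined_loss(probs, onehot_or_labels, weights: ClassWeights,
                  params: FocalParams | None = None, lambda_mix: float = 0.5):
    """Convex mix ``λ · weighted Dice + (1 − λ) · focal``.

    `onehot_or_labels` may be the integer label array or its one-hot
    encoding; the focal α_t defaults to the Dice class weights.
    """
    if not 0.0 <= lambda_mix <= 1.0:
        raise ValueError("lambda_mix must be in [0, 1]")
    arr = np.asarray(onehot_or_labels)
    n_classes = probs.shape[-1]
    if arr.ndim == probs.ndim and arr.shape[-1] == n_classes:
        onehot, labels = arr, np.argmax(arr, axis=-1)
    else:
        labels = arr
        onehot = one_hot(labels, n_classes)
    if params is None:
        params = FocalParams(gamma=2.0, alpha_t=weights)
    dl = weighted_dice_loss(probs, onehot, weights)
    fl = focal_loss(probs, labels, params)
    return lambda_mix * dl + (1.0 - lambda_mix) * fl
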