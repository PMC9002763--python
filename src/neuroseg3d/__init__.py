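"""neuroseg3d: 3D brain-structure segmentation with a CNN–Transformer hybrid.

A pooling-free convolutional encoder extracts local features at full spatial
resolution, a multi-head self-attention bottleneck over P³ feature-map tokens
adds global context, and an upsampling decoder with Res-path skip connections
produces per-voxel class probabilities. Training uses a convex mix of a
globally weighted Dice loss and a focal loss, with median-frequency-balanced
class weights against the heavy class imbalance of brain parcellations.

The package is used from Python; see ``examples/`` for narrative scripts
covering each capability.
"""

from .autograd import Tensor
from .io_nifti import IntensityVolume, LabelVolume, read_volume, write_volume
from .losses import (ClassWeights, FocalParams, combined_loss, focal_loss,
                     median_frequency_weights, one_hot, weighted_dice_loss)
from .metrics import (ConfusionCounts, MetricsReport, confusion, dice, iou,
                      precision, recall, report)
from .model import (AttentionParams, ModelConfig, SegmentationNetwork,
                    TokenSequence, mhsa, scaled_dot_attention)
from .phantom import PhantomSpec, ellipsoid_mask, generate_dataset, generate_phantom, save_dataset
from .pipeline import (RunConfig, run_evaluate, run_phantom, run_predict,
                       run_preprocess, run_train)
from .preprocess import (PatchStack, extract_patches, normalize_intensity,
                         reassemble_patches, remap_labels, remove_empty_slices,
                         split_dataset)
from .training import Adam, TrainConfig, evaluate, lr_schedule, predict_volume, train

__version__ = "0.1.0"

__all__ = [
    "Tensor",
    "IntensityVolume", "LabelVolume", "read_volume", "write_volume",
    "ClassWeights", "FocalParams", "combined_loss", "focal_loss",
    "median_frequency_weights", "one_hot", "weighted_dice_loss",
    "ConfusionCounts", "MetricsReport", "confusion", "dice", "iou",
    "precision", "recall", "report",
    "AttentionParams", "ModelConfig", "SegmentationNetwork", "TokenSequence",
    "mhsa", "scaled_dot_attention",
    "PhantomSpec", "ellipsoid_mask", "generate_dataset", "generate_phantom",
    "save_dataset",
    "RunConfig", "run_evaluate", "run_phantom", "run_predict", "run_preprocess",
    "run_train",
    "PatchStack", "extract_patches", "normalize_intensity", "reassemble_patches",
    "remap_labels", "remove_empty_slices", "split_dataset",
    "Adam", "TrainConfig", "evaluate", "lr_schedule", "predict_volume", "train",
]
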