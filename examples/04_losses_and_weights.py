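"""The imbalance-aware objective: median-frequency class weights, weighted
Dice loss, focal loss, and their convex combination."""

import math

import numpy as np

import neuroseg3d as ns
from neuroseg3d.losses import FocalParams, one_hot

# median frequency balancing on a tiny two-structure example
lab = np.zeros((1, 2, 10), dtype=np.int32)
lab[0, :, :4] = np.int32(1)   # structure 1 fills 40% of the volume
lab[0, 0, 4:6] = np.int32(2)  # structure 2 fills 10%
w = ns.median_frequency_weights([lab], include_background=False)
print(f"frequencies 0.4 / 0.1 -> weights ({w.alpha[0]:g}, {w.alpha[1]:g})")
print("  (the rarer structure is upweighted by the ratio of the median"
      " frequency to its own)")

# weighted Dice on a 2-voxel toy, evaluated in closed form
probs = np.array([[0.8, 0.2], [0.4, 0.6]])
onehot = np.array([[1.0, 0.0], [0.0, 1.0]])
print(f"weighted Dice loss on the toy: {ns.weighted_dice_loss(probs, onehot, np.ones(2))}"
      f"  (= 1 - 2*1.4/4.0 = 0.3)")

# focal loss: γ down-weights confident voxels
fl = ns.focal_loss(np.array([[0.5, 0.5]]), np.array([0]),
                   FocalParams(gamma=2.0, alpha_t=1.0))
print(f"focal loss at p_t=0.5, gamma=2: {fl:.5f}  (= 0.25*ln2 = "
      f"{0.25 * math.log(2):.5f})")

# the training objective mixes both; a perfect prediction scores 0
labels = np.array([[[0, 1], [2, 1]]])
perfect = one_hot(labels, 3).astype(np.float64)
cw = ns.ClassWeights(alpha=np.ones(3))
print(f"combined loss at a perfect prediction: "
      f"{ns.combined_loss(perfect, labels, cw):.2e}")
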