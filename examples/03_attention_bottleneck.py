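"""Inspect the transformer bottleneck: token counts, attention weights and
the end-to-end probability contract of a forward pass."""

import numpy as np

import neuroseg3d as ns
from neuroseg3d.model import scaled_dot_attention

# token geometry: a 64³ input with patch resolution P yields (64/P)³ tokens
for p in (8, 16):
    cfg = ns.ModelConfig(input_shape=(64, 64, 64, 1), n_classes=5,
                         patch_resolution=p)
    print(f"P={p:2d}: {cfg.n_tokens:4d} tokens of width {cfg.hidden_size}, "
          f"{cfg.n_heads} heads x {cfg.head_dim} dims each")

# scaled dot-product attention produces row-stochastic weights: with zero
# queries every token attends uniformly, so outputs equal the mean value row
rng = np.random.default_rng(0)
v = rng.normal(size=(6, 4))
out = scaled_dot_attention(np.zeros((3, 8)), rng.normal(size=(6, 8)) * 0, v)
print("uniform attention output equals column mean of V:",
      bool(np.allclose(out, v.mean(axis=0))))

# a full forward pass maps (H,W,D) intensities to per-voxel probabilities
cfg = ns.ModelConfig(input_shape=(32, 32, 32, 1), n_classes=4, seed=0)
net = ns.SegmentationNetwork(cfg)
print(f"network has {net.n_parameters:,} parameters")
probs = net.forward(rng.random((32, 32, 32), dtype=np.float32)).data[0]
print(f"output shape {probs.shape}; per-voxel probability sums within "
      f"{np.abs(probs.sum(-1) - 1).max():.2e} of 1")
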