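"""Preprocess a phantom pair: remap labels, equalize intensities, crop empty
slices, tile into nonoverlapping patches and reassemble losslessly."""

import numpy as np

import neuroseg3d as ns

spec = ns.PhantomSpec(shape=(80, 70, 60), n_structures=4, seed=7)
core_img, core_lab = ns.generate_phantom(spec)

# embed the phantom in an empty scanner field of view, as a real acquisition
# surrounds the head with air slices
fov = np.zeros((100, 90, 80), dtype=np.float32)
fov_lab = np.zeros((100, 90, 80), dtype=np.int16)
fov[10:90, 10:80, 10:70] = core_img.voxels
fov_lab[10:90, 10:80, 10:70] = core_lab.voxels
img = ns.IntensityVolume(voxels=fov)
lab = ns.LabelVolume(voxels=fov_lab)

# histogram equalization + min-max to [0, 1], per volume
norm = ns.normalize_intensity(img)
print(f"normalized range: [{norm.voxels.min()}, {norm.voxels.max()}]")

# crop boundary slices that carry no signal on any axis
cropped_img, cropped_lab = ns.remove_empty_slices(norm, lab)
print(f"shape after empty-slice removal: {cropped_img.shape} (was {img.shape})")

# tile into nonoverlapping 32³ cubes (zero-padded to a multiple of 32)
stack = ns.extract_patches(cropped_img, cropped_lab, patch_size=32)
print(f"{len(stack)} patches of {stack.patch_size}³ covering padded shape "
      f"{stack.padded_shape}")

back_img, back_lab = ns.reassemble_patches(stack)
print("lossless reassembly:",
      bool(np.array_equal(back_img.voxels, cropped_img.voxels)
           and np.array_equal(back_lab.voxels, cropped_lab.voxels)))
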