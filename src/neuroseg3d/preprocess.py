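"""Volume preprocessing: label remapping, intensity normalisation, empty-slice
cropping, nonoverlapping patch extraction/reassembly and the stratified split.

The pipeline order for a raw (image, segmentation) pair is:

1. :func:`remap_labels` — collapse the source parcellation IDs to contiguous
   1..S with 0 as background; unmapped IDs become background.
2. :func:`normalize_intensity` — per-volume histogram equalization followed
   by min-max scaling to [0, 1].
3. :func:`remove_empty_slices` — crop boundary slices that contain no signal,
   on all three axes, keeping the image and labels aligned.
4. :func:`extract_patches` — zero-pad to a multiple of the patch size and
   tile into nonoverlapping cubes (64³ by default); the resulting
   :class:`PatchStack` carries the grid bookkeeping for lossless
   :func:`reassemble_patches`.

Patch stacks are stored one HDF5 container per source volume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from .io_nifti import IntensityVolume, LabelVolume

__all__ = [
    "PatchStack",
    "remap_labels",
    "normalize_intensity",
    "histogram_equalize",
    "remove_empty_slices",
    "extract_patches",
    "reassemble_patches",
    "split_dataset",
    "save_patch_stack",
    "load_patch_stack",
]


# ---------------------------------------------------------------------------
# label remapping
# ---------------------------------------------------------------------------

def remap_labels(lab: LabelVolume, mapping: dict[int, int]) -> LabelVolume:
    """Map source parcellation IDs to contiguous structure IDs.

    Every voxel whose source ID is a key of `mapping` receives the mapped ID;
    every other voxel (including unmapped foreground) becomes background 0.
    The mapping must be injective and must not target 0, which is reserved.
    """
    targets = list(mapping.values())
    if 0 in mapping:
        raise ValueError("source ID 0 is reserved for background and cannot be remapped")
    if 0 in targets:
        raise ValueError("0 is reserved for background and cannot be a remap target")
    if len(set(targets)) != len(targets):
        raise ValueError("mapping targets must be distinct")
    if any(t < 0 for t in targets):
        raise ValueError("mapping targets must be positive")

    src = lab.voxels
    out = np.zeros_like(src)
    for source_id, target_id in mapping.items():
        out[src == source_id] = target_id
    return LabelVolume(voxels=out, affine=lab.affine, id_map=dict(mapping))


# ---------------------------------------------------------------------------
# intensity normalisation
# ---------------------------------------------------------------------------

def histogram_equalize(voxels: np.ndarray, nbins: int = 256) -> np.ndarray:
    """Histogram equalization by bin-CDF lookup.

    Each voxel is assigned to one of `nbins` equal-width bins over the
    volume's own [min, max] range and mapped to the cumulative frequency of
    its bin. The mapping is monotone in bin index, so intensity order is
    preserved up to bin quantization.
    """
    v = np.asarray(voxels, dtype=np.float64)
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        return np.zeros_like(v)
    edges = np.linspace(lo, hi, nbins + 1)
    hist, _ = np.histogram(v, bins=edges)
    cdf = np.cumsum(hist) / v.size
    idx = np.clip(np.digitize(v, edges[1:-1], right=False), 0, nbins - 1)
    return cdf[idx]


def normalize_intensity(vol: IntensityVolume, nbins: int = 256) -> IntensityVolume:
    """Per-volume histogram equalization, then min-max scaling to [0, 1].

    A constant volume carries no contrast to redistribute; it is returned as
    all zeros with a warning.
    """
    eq = histogram_equalize(vol.voxels, nbins=nbins)
    lo, hi = float(eq.min()), float(eq.max())
    if hi == lo:
        warnings.warn("constant-intensity volume normalised to all zeros", stacklevel=2)
        scaled = np.zeros_like(eq)
    else:
        scaled = (eq - lo) / (hi - lo)
    return IntensityVolume(voxels=scaled.astype(np.float32), affine=vol.affine)


# ---------------------------------------------------------------------------
# empty-slice removal
# ---------------------------------------------------------------------------

def remove_empty_slices(vol: IntensityVolume, lab: LabelVolume,
                        threshold: float = 0.0) -> tuple[IntensityVolume, LabelVolume]:
    """Crop boundary slices whose intensities are all ≤ `threshold`.

    Cropping is applied from the leading and trailing ends of each of the
    three axes; interior slices are never removed, so the content stays
    contiguous. The label volume is cropped identically to preserve pairing.
    """
    if vol.shape != lab.shape:
        raise ValueError(f"paired shapes differ: {vol.shape} vs {lab.shape}")
    nonempty = vol.voxels > threshold
    if not nonempty.any():
        raise ValueError("volume is entirely empty at the given threshold")
    slices = []
    for axis in range(3):
        other = tuple(a for a in range(3) if a != axis)
        profile = nonempty.any(axis=other)
        idx = np.flatnonzero(profile)
        slices.append(slice(int(idx[0]), int(idx[-1]) + 1))
    box = tuple(slices)
    return (IntensityVolume(voxels=vol.voxels[box], affine=vol.affine),
            LabelVolume(voxels=lab.voxels[box], affine=lab.affine, id_map=lab.id_map))


# ---------------------------------------------------------------------------
# patch extraction / reassembly
# ---------------------------------------------------------------------------

@dataclass
class PatchStack:
    """Nonoverlapping cubic patches of a volume plus reassembly bookkeeping.

    ``patches[k]`` is an ``(intensity, label)`` pair of ``patch_size``³
    arrays whose origin in the padded volume is ``grid_origin[k]``; patches
    are ordered lexicographically by block index. ``source_shape`` is the
    unpadded shape so reassembly can crop the zero padding back off.
    """

    patches: list[tuple[np.ndarray, np.ndarray]]
    grid_origin: list[tuple[int, int, int]]
    source_shape: tuple[int, int, int]
    padded_shape: tuple[int, int, int]
    patch_size: int
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __len__(self) -> int:
        return len(self.patches)


def extract_patches(vol: IntensityVolume, lab: LabelVolume,
                    patch_size: int = 64, drop_background: bool = False) -> PatchStack:
    """Tile a paired volume into nonoverlapping ``patch_size``³ cubes.

    The volume is zero-padded up to the next multiple of `patch_size` on each
    axis (padded voxels are background, the semantically correct label for
    air). With ``drop_background=True`` patches whose label block is entirely
    background are omitted; reassembly then fills them with zeros.
    """
    if patch_size < 8:
        raise ValueError("patch_size must be >= 8")
    if vol.shape != lab.shape:
        raise ValueError(f"paired shapes differ: {vol.shape} vs {lab.shape}")

    src = vol.shape
    padded = tuple(-(-s // patch_size) * patch_size for s in src)
    pad = [(0, p - s) for p, s in zip(padded, src)]
    img = np.pad(vol.voxels, pad)
    seg = np.pad(lab.voxels, pad)

    patches, origins = [], []
    for i in range(0, padded[0], patch_size):
        for j in range(0, padded[1], patch_size):
            for k in range(0, padded[2], patch_size):
                block_lab = seg[i:i + patch_size, j:j + patch_size, k:k + patch_size]
                if drop_background and not block_lab.any():
                    continue
                block_img = img[i:i + patch_size, j:j + patch_size, k:k + patch_size]
                patches.append((block_img.copy(), block_lab.copy()))
                origins.append((i, j, k))
    return PatchStack(patches=patches, grid_origin=origins, source_shape=src,
                      padded_shape=padded, patch_size=patch_size, affine=vol.affine)


def reassemble_patches(stack: PatchStack, crop: bool = True,
                       allow_missing: bool = False) -> tuple[IntensityVolume, LabelVolume]:
    """Invert :func:`extract_patches` bit-exactly.

    With ``crop=True`` the zero padding is removed so the output has the
    original source shape. A missing block raises with its grid index unless
    ``allow_missing=True`` (for stacks built with ``drop_background``, whose
    absent blocks are refilled as background).
    """
    p = stack.patch_size
    expected = {(i, j, k)
                for i in range(0, stack.padded_shape[0], p)
                for j in range(0, stack.padded_shape[1], p)
                for k in range(0, stack.padded_shape[2], p)}
    present = set(stack.grid_origin)
    stray = present - expected
    if stray:
        raise ValueError(f"patch at grid origin {sorted(stray)[0]} does not lie "
                         "on the patch grid")
    if not allow_missing:
        require_complete(stack)

    img = np.zeros(stack.padded_shape, dtype=stack.patches[0][0].dtype if stack.patches
                   else np.float32)
    seg = np.zeros(stack.padded_shape, dtype=stack.patches[0][1].dtype if stack.patches
                   else np.int16)
    for (block_img, block_lab), (i, j, k) in zip(stack.patches, stack.grid_origin):
        img[i:i + p, j:j + p, k:k + p] = block_img
        seg[i:i + p, j:j + p, k:k + p] = block_lab
    if crop:
        box = tuple(slice(0, s) for s in stack.source_shape)
        img, seg = img[box], seg[box]
    return (IntensityVolume(voxels=img, affine=stack.affine),
            LabelVolume(voxels=seg, affine=stack.affine))


def require_complete(stack: PatchStack) -> None:
    """Raise if any grid position of the padded volume lacks a patch."""
    p = stack.patch_size
    expected = {(i, j, k)
                for i in range(0, stack.padded_shape[0], p)
                for j in range(0, stack.padded_shape[1], p)
                for k in range(0, stack.padded_shape[2], p)}
    missing = expected - set(stack.grid_origin)
    if missing:
        raise ValueError(f"incomplete patch stack: missing block at grid index "
                         f"{sorted(missing)[0]}")


# ---------------------------------------------------------------------------
# dataset splitting
# ---------------------------------------------------------------------------

def split_dataset(volumes: list, ratio: tuple[int, int] = (8, 2),
                  strata: list | None = None, seed: int = 0) -> tuple[list, list]:
    """Stratified train/validation split, 8:2 by default.

    Each stratum (sub-dataset of origin) is split proportionally, and every
    stratum with at least two members contributes at least one validation
    volume. Deterministic for a fixed seed.
    """
    if strata is None:
        strata = [0] * len(volumes)
    if len(strata) != len(volumes):
        raise ValueError("strata must be given for every volume")
    frac_val = ratio[1] / (ratio[0] + ratio[1])
    rng = np.random.default_rng(seed)

    groups: dict = {}
    for idx, s in enumerate(strata):
        groups.setdefault(s, []).append(idx)
    for s, members in groups.items():
        if len(members) == 0:
            raise ValueError(f"stratum {s!r} is empty")

    train_idx, val_idx = [], []
    for s in sorted(groups, key=repr):
        members = np.array(groups[s])
        rng.shuffle(members)
        if len(members) == 1:
            warnings.warn(f"stratum {s!r} has a single member; assigned to training",
                          stacklevel=2)
            n_val = 0
        else:
            n_val = max(1, int(round(frac_val * len(members))))
            n_val = min(n_val, len(members) - 1)  # keep >=1 in training too
        val_idx.extend(members[:n_val].tolist())
        train_idx.extend(members[n_val:].tolist())
    train_idx.sort()
    val_idx.sort()
    return [volumes[i] for i in train_idx], [volumes[i] for i in val_idx]


# ---------------------------------------------------------------------------
# HDF5 persistence
# ---------------------------------------------------------------------------

def save_patch_stack(stack: PatchStack, path) -> None:
    """Store a patch stack as a single HDF5 container."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["patch_size"] = stack.patch_size
        f.attrs["source_shape"] = stack.source_shape
        f.attrs["padded_shape"] = stack.padded_shape
        f.create_dataset("affine", data=stack.affine)
        f.create_dataset("grid_origin", data=np.asarray(stack.grid_origin, dtype=np.int64)
                         if stack.grid_origin else np.zeros((0, 3), dtype=np.int64))
        if stack.patches:
            f.create_dataset("intensity", data=np.stack([p[0] for p in stack.patches]),
                             compression="gzip")
            f.create_dataset("labels", data=np.stack([p[1] for p in stack.patches]),
                             compression="gzip")


def load_patch_stack(path) -> PatchStack:
    path = Path(path)
    with h5py.File(path, "r") as f:
        origins = [tuple(int(x) for x in row) for row in f["grid_origin"][...]]
        patches = []
        if "intensity" in f:
            imgs = f["intensity"][...]
            labs = f["labels"][...]
            patches = [(imgs[i], labs[i]) for i in range(imgs.shape[0])]
        return PatchStack(patches=patches, grid_origin=origins,
                          source_shape=tuple(int(x) for x in f.attrs["source_shape"]),
                          padded_shape=tuple(int(x) for x in f.attrs["padded_shape"]),
                          patch_size=int(f.attrs["patch_size"]),
                          affine=f["affine"][...])
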