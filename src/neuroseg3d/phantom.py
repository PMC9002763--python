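"""Synthetic labeled brain-like volumes for exercising the segmentation stack.

Real training data for this method is a set of T1-weighted MRIs with a
37-structure parcellation whose per-structure voxel counts span orders of
magnitude. The phantom generator reproduces the *statistical* shape of that
problem — many structures, a heavy-tailed class-size distribution, distinct
per-structure intensity distributions, additive noise — with none of the
anatomy: structures are random ellipsoids carved into a background volume.

Structure volumes decay as a rank power law, ``volume(rank) ∝ rank^(-q)``
with ``q = imbalance_exponent`` (default 1.5), which qualitatively matches
the long tail of subcortical/cortical structure sizes. Later placements
overwrite earlier ones at contested voxels so that every voxel carries
exactly one label — the partition property the Dice-style losses and the
evaluation metrics assume.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .io_nifti import IntensityVolume, LabelVolume, write_volume

logger = logging.getLogger(__name__)

__all__ = ["PhantomSpec", "ellipsoid_mask", "generate_phantom", "generate_dataset",
           "save_dataset"]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic volume.

    Parameters
    ----------
    shape
        Voxel grid, default 64³ (use 128³ for integration-scale runs).
    n_structures
        Number of foreground structures S ≥ 0; labels are 1..S with 0 background.
    intensity_means
        Per-class mean intensity in [0, 1], length S+1 (index 0 = background).
        ``None`` chooses background 0.05 and structure means evenly spaced on
        [0.25, 0.95], which keeps classes separable by intensity the way
        distinct tissue types are in a T1 contrast.
    noise_sd
        Standard deviation of additive Gaussian noise (intensity units).
    imbalance_exponent
        Power-law decay of target structure volumes over rank.
    foreground_fraction
        Total fraction of voxels the structures aim to occupy.
    seed
        RNG seed; identical spec + seed gives bit-identical output.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    n_structures: int = 8
    intensity_means: tuple[float, ...] | None = None
    noise_sd: float = 0.05
    imbalance_exponent: float = 1.5
    foreground_fraction: float = 0.3
    seed: int = 0
    max_placement_tries: int = 25

    def __post_init__(self):
        if len(self.shape) != 3 or any(s <= 0 for s in self.shape):
            raise ValueError(f"shape must be three positive ints, got {self.shape}")
        if self.n_structures < 0:
            raise ValueError("n_structures must be >= 0")
        if self.intensity_means is not None and len(self.intensity_means) != self.n_structures + 1:
            raise ValueError("intensity_means must have length n_structures + 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 < self.foreground_fraction < 1:
            raise ValueError("foreground_fraction must be in (0, 1)")

    def class_means(self) -> np.ndarray:
        if self.intensity_means is not None:
            return np.asarray(self.intensity_means, dtype=np.float64)
        if self.n_structures == 0:
            return np.array([0.05])
        return np.concatenate([[0.05], np.linspace(0.25, 0.95, self.n_structures)])


def ellipsoid_mask(shape: tuple[int, int, int], center: np.ndarray,
                   semi_axes: np.ndarray, rotation: np.ndarray | None = None) -> np.ndarray:
    """Boolean mask of the (optionally rotated) solid ellipsoid.

    A voxel at integer coordinates v is inside iff ``|A R (v - c)| <= 1``
    where A = diag(1/semi_axes) and R is the rotation applied to offsets.
    """
    center = np.asarray(center, dtype=np.float64)
    semi = np.asarray(semi_axes, dtype=np.float64)
    if np.any(semi <= 0):
        raise ValueError("semi-axes must be positive")
    grids = np.meshgrid(*(np.arange(s, dtype=np.float64) for s in shape), indexing="ij")
    offsets = np.stack([g - c for g, c in zip(grids, center)], axis=-1)  # (H,W,D,3)
    if rotation is not None:
        offsets = offsets @ np.asarray(rotation, dtype=np.float64).T
    normed = offsets / semi
    return (normed ** 2).sum(axis=-1) <= 1.0


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random 3D rotation via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _target_volumes(spec: PhantomSpec) -> np.ndarray:
    """Rank power-law target voxel counts summing to the foreground budget."""
    ranks = np.arange(1, spec.n_structures + 1, dtype=np.float64)
    raw = ranks ** (-spec.imbalance_exponent)
    budget = spec.foreground_fraction * float(np.prod(spec.shape))
    return raw / raw.sum() * budget


def generate_phantom(spec: PhantomSpec) -> tuple[IntensityVolume, LabelVolume]:
    """Generate one (intensity, label) phantom pair.

    Structures are placed from largest to smallest; a later structure
    overwrites any earlier one at contested voxels, so labels always
    partition the volume. A structure whose ellipsoid cannot be placed with
    its center inside the volume after ``max_placement_tries`` attempts is
    skipped with a warning (its label simply never appears) — never silently
    mislabeled.
    """
    rng = np.random.default_rng(spec.seed)
    labels = np.zeros(spec.shape, dtype=np.int16)
    means = spec.class_means()

    if spec.n_structures > 0:
        targets = _target_volumes(spec)
        # largest first: small, later structures find free space easily, and
        # the low-overlap acceptance below bounds what they carve out of the
        # earlier big ones — realised volumes then track the rank targets
        for sid in range(1, spec.n_structures + 1):
            vol = targets[sid - 1]
            best_mask = None
            best_overlap = np.inf
            for _ in range(spec.max_placement_tries):
                # draw anisotropy, then scale to hit the target volume
                aniso = rng.uniform(0.6, 1.4, size=3)
                scale = (3.0 * vol / (4.0 * np.pi * np.prod(aniso))) ** (1.0 / 3.0)
                semi = aniso * scale
                if np.any(2 * semi >= np.array(spec.shape)):
                    continue  # cannot fit along some axis
                center = np.array([rng.uniform(s, dim - s)
                                   for s, dim in zip(semi, spec.shape)])
                mask = ellipsoid_mask(spec.shape, center, semi, _random_rotation(rng))
                if not mask.any():
                    continue
                # prefer placements that carve little out of earlier structures
                overlap = np.count_nonzero(labels[mask]) / mask.sum()
                if overlap < best_overlap:
                    best_mask, best_overlap = mask, overlap
                if overlap <= 0.05:
                    break
            if best_mask is not None:
                labels[best_mask] = sid
            else:
                warnings.warn(f"structure {sid} could not be placed in shape "
                              f"{spec.shape}; skipped", stacklevel=2)
                logger.warning("phantom structure %d skipped (no valid placement)", sid)

    intensities = means[labels].astype(np.float64)
    if spec.noise_sd > 0:
        intensities = intensities + rng.normal(0.0, spec.noise_sd, size=spec.shape)
    intensities = np.clip(intensities, 0.0, 1.0).astype(np.float32)

    affine = np.eye(4)
    return (IntensityVolume(voxels=intensities, affine=affine),
            LabelVolume(voxels=labels, affine=affine))


def generate_dataset(spec: PhantomSpec, n_volumes: int,
                     seed: int | None = None) -> list[tuple[IntensityVolume, LabelVolume]]:
    """Generate `n_volumes` independent phantoms with per-volume derived seeds.

    The master seed (``seed`` if given, else ``spec.seed``) spawns one child
    seed per volume through ``np.random.SeedSequence``, so the collection is
    deterministic as a whole and each member is independent.
    """
    if n_volumes < 1:
        raise ValueError("n_volumes must be >= 1")
    master = spec.seed if seed is None else seed
    children = np.random.SeedSequence(master).generate_state(n_volumes)
    out = []
    for child in children:
        sub = _replace_seed(spec, int(child) % (2 ** 31))
        out.append(generate_phantom(sub))
    return out


def _replace_seed(spec: PhantomSpec, seed: int) -> PhantomSpec:
    d = asdict(spec)
    d["seed"] = seed
    if d["intensity_means"] is not None:
        d["intensity_means"] = tuple(d["intensity_means"])
    d["shape"] = tuple(d["shape"])
    return PhantomSpec(**d)


def save_dataset(pairs, out_dir, spec: PhantomSpec | None = None,
                 prefix: str = "phantom") -> Path:
    """Write paired ``*_img.nii.gz`` / ``*_lab.nii.gz`` files plus a JSON manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, (img, lab) in enumerate(pairs):
        img_path = out_dir / f"{prefix}_{i:03d}_img.nii.gz"
        lab_path = out_dir / f"{prefix}_{i:03d}_lab.nii.gz"
        write_volume(img, img_path)
        write_volume(lab, lab_path)
        entries.append({"image": img_path.name, "label": lab_path.name})
    manifest = {"pairs": entries}
    if spec is not None:
        d = asdict(spec)
        d["shape"] = list(d["shape"])
        if d["intensity_means"] is not None:
            d["intensity_means"] = list(d["intensity_means"])
        manifest["spec"] = d
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path
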