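"""NIfTI reading/writing with the in-memory volume containers.

Volumes are kept in stored (H, W, D) axis order with no reorientation — the
patching pipeline is orientation-agnostic — and the affine rides along
untouched so world coordinates survive the round trip. Voxel indices are
0-based; patch ranges are half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["IntensityVolume", "LabelVolume", "read_volume", "write_volume"]


@dataclass
class IntensityVolume:
    """A rank-3 real-valued image with spatial metadata."""

    voxels: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected rank-3 volume, got shape {self.voxels.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("intensity volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def spacing(self) -> tuple[float, float, float]:
        """mm per voxel along each axis, from the affine's column norms."""
        return tuple(np.linalg.norm(self.affine[:3, :3], axis=0))


@dataclass
class LabelVolume:
    """A rank-3 integer class map; 0 is background, 1..S are structures."""

    voxels: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    id_map: dict[int, int] | None = None  # source label ID -> contiguous ID

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected rank-3 volume, got shape {self.voxels.shape}")
        if not np.issubdtype(self.voxels.dtype, np.integer):
            raise TypeError("label voxels must have an integer dtype")
        if self.voxels.size and self.voxels.min() < 0:
            raise ValueError("label IDs must be nonnegative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def spacing(self) -> tuple[float, float, float]:
        return tuple(np.linalg.norm(self.affine[:3, :3], axis=0))

    @property
    def n_classes(self) -> int:
        """Number of classes including background (max ID + 1)."""
        return int(self.voxels.max()) + 1 if self.voxels.size else 1


def _squeeze_trailing(data: np.ndarray, path) -> np.ndarray:
    if data.ndim == 4 and data.shape[3] == 1:
        warnings.warn(f"{path}: 4D volume with trailing singleton squeezed to 3D",
                      stacklevel=3)
        return data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    return data


def read_volume(path, kind: str = "auto") -> IntensityVolume | LabelVolume:
    """Read a NIfTI-1/2 volume.

    Parameters
    ----------
    path
        ``.nii`` or ``.nii.gz`` file.
    kind
        ``"intensity"``, ``"label"``, or ``"auto"`` (integer on-disk dtype
        means label). A label file stored as float with integral values is
        coerced to integer with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
    except Exception as exc:  # nibabel raises a zoo of header errors
        raise ValueError(f"could not read NIfTI file {path}: {exc}") from exc
    data = _squeeze_trailing(data, path)
    affine = img.affine

    is_int = np.issubdtype(data.dtype, np.integer)
    if kind == "auto":
        kind = "label" if is_int else "intensity"
    if kind == "label":
        if not is_int:
            if not np.all(np.isfinite(data)) or not np.all(data == np.round(data)):
                raise ValueError(f"{path}: float data is not integral; cannot "
                                 "interpret as labels")
            warnings.warn(f"{path}: float-typed label volume coerced to integer",
                          stacklevel=2)
            data = np.round(data).astype(np.int32)
        return LabelVolume(voxels=data, affine=affine)
    if kind == "intensity":
        return IntensityVolume(voxels=data.astype(np.float32, copy=False), affine=affine)
    raise ValueError(f"unknown kind {kind!r}; expected 'auto', 'intensity' or 'label'")


def write_volume(vol: IntensityVolume | LabelVolume, path) -> None:
    """Write a volume as NIfTI; gzip-compressed when the path ends ``.nii.gz``.

    Labels keep an integer on-disk dtype so any conforming reader recovers
    them as integers.
    """
    path = Path(path)
    if isinstance(vol, LabelVolume):
        data = vol.voxels.astype(np.int16 if vol.voxels.max(initial=0) < 2 ** 15
                                 else np.int32)
    elif isinstance(vol, IntensityVolume):
        data = vol.voxels.astype(np.float32, copy=False)
    else:
        raise TypeError(f"expected IntensityVolume or LabelVolume, got {type(vol)}")
    img = nib.Nifti1Image(data, vol.affine)
    img.header.set_data_dtype(data.dtype)
    try:
        nib.save(img, str(path))
    except OSError as exc:
        raise OSError(f"failed to write NIfTI volume to {path}: {exc}") from exc
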