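"""Core image containers and their NIfTI round-trip.

Arrays are indexed ``(i, j, k)`` in the same order as the NIfTI voxel axes;
``spacing`` gives the physical voxel size in mm along each array axis.  All
geometry downstream (ring construction, shape features, LoG scales) is
expressed in mm, never voxel counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "CTVolume",
    "ROIMask",
    "DegenerateROIError",
    "DegenerateTextureError",
    "load_volume",
    "load_mask",
    "save_volume",
    "save_mask",
]


class DegenerateROIError(ValueError):
    """Raised when an ROI is empty or becomes unusable for feature extraction."""


class DegenerateTextureError(DegenerateROIError):
    """Raised when a texture family cannot be formed (e.g. no voxel pairs)."""


@dataclass
class CTVolume:
    """A 3D CT scalar grid in Hounsfield units with physical spacing."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"CTVolume must be 3D, got shape {self.values.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("CTVolume contains non-finite values")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class ROIMask:
    """A binary region-of-interest aligned to a :class:`CTVolume` grid.

    ``role`` records whether the mask is the tumor interior
    (``"intratumoral"``) or the peritumoral ring (``"peritumoral"``).
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    role: str = "intratumoral"

    _ROLES = ("intratumoral", "peritumoral")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3:
            raise ValueError(f"ROIMask must be 3D, got shape {self.values.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        if self.role not in self._ROLES:
            raise ValueError(f"role must be one of {self._ROLES}, got {self.role!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def voxel_count(self) -> int:
        return int(self.values.sum())

    def is_empty(self) -> bool:
        return not bool(self.values.any())


def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def save_volume(volume: CTVolume, path) -> None:
    img = nib.Nifti1Image(volume.values.astype(np.float32), _affine(volume.spacing, volume.origin))
    nib.save(img, str(path))


def save_mask(mask: ROIMask, path) -> None:
    img = nib.Nifti1Image(mask.values.astype(np.uint8), _affine(mask.spacing, (0, 0, 0)))
    nib.save(img, str(path))


def load_volume(path) -> CTVolume:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(x) for x in np.asarray(img.affine)[:3, 3])
    return CTVolume(np.asarray(img.dataobj, dtype=np.float64), spacing, origin)


def load_mask(path, role: str = "intratumoral") -> ROIMask:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return ROIMask(np.asarray(img.dataobj) > 0, spacing, role)
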