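"""Scalar 3-D image volumes with world-space affines.

A :class:`ScalarVolume` is the in-memory substrate for both modalities
handled by this package: FET-PET standardised-uptake-value (SUV) maps
(dimensionless) and apparent-diffusion-coefficient (ADC) maps
(reported throughout in 10^-6 mm^2/s).  Volumes carry a 4x4 affine
mapping 0-based voxel indices (voxel-centre convention) to world
millimetres in a RAS-like frame; for phantoms the mid-sagittal plane
sits at world x = 0.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["ScalarVolume"]

_MODALITIES = ("SUV", "ADC")


@dataclasses.dataclass
class ScalarVolume:
    """A 3-D scalar grid (SUV or ADC) with an invertible affine.

    Parameters
    ----------
    data:
        3-D float array of voxel values.
    affine:
        4x4 voxel-index -> world-mm map (RAS orientation).
    modality:
        ``"SUV"`` or ``"ADC"``.
    grid_id:
        Label identifying the grid; voxel-index containers
        (:class:`~fetadc.segmentation.LesionVOI`) reference it so that
        indices are never applied to the wrong volume.
    """

    data: np.ndarray
    affine: np.ndarray
    modality: str
    grid_id: str = "grid"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D volume, got shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        if self.modality not in _MODALITIES:
            raise ValueError(f"modality must be one of {_MODALITIES}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_size_mm(self) -> np.ndarray:
        """Per-axis voxel spacing in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map (N, 3) voxel indices to (N, 3) world-mm coordinates."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Map (N, 3) world-mm coordinates to fractional voxel indices."""
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    @classmethod
    def from_nifti(cls, path: str | Path, modality: str, grid_id: str | None = None) -> "ScalarVolume":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"volume file not found: {path}")
        img = nib.load(str(path))
        return cls(
            data=np.asarray(img.get_fdata(), dtype=float),
            affine=np.asarray(img.affine, dtype=float),
            modality=modality,
            grid_id=grid_id if grid_id is not None else path.stem,
        )

    def to_nifti(self, path: str | Path, dtype=np.float32) -> Path:
        path = Path(path)
        img = nib.Nifti1Image(self.data.astype(dtype), self.affine)
        nib.save(img, str(path))
        return path
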