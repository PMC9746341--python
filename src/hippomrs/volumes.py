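"""Integer label volumes (segmentations, hippocampus masks) backed by NIfTI."""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np

__all__ = ["LabelVolume", "LABELS", "EmptyMaskError"]

#: Canonical label coding for the phantom / segmentation volumes.
LABELS = {
    "background": 0,
    "GM": 1,
    "WM": 2,
    "CSF": 3,
    "hippoL": 4,
    "hippoR": 5,
}


class EmptyMaskError(ValueError):
    """A mask with zero labelled cells where at least one is required."""


@dataclass
class LabelVolume:
    """3-D integer label grid with a world affine (index -> mm, NIfTI
    convention: the affine maps a voxel index to the centre of that cell)."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("label volume must be 3-D")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("label volume must hold integer labels")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape(self):
        return self.data.shape

    @property
    def voxel_size_mm(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def cell_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def world_coords(self, indices: np.ndarray) -> np.ndarray:
        """Map an (N, 3) array of voxel indices to world mm coordinates."""
        indices = np.atleast_2d(indices)
        return indices @ self.affine[:3, :3].T + self.affine[:3, 3]

    def label_coords_mm(self, label: int) -> np.ndarray:
        """World coordinates of the centres of all cells carrying ``label``."""
        idx = np.argwhere(self.data == label)
        return self.world_coords(idx) if idx.size else idx.reshape(0, 3).astype(float)

    def mask(self, label: int) -> "LabelVolume":
        """Binary volume (0/1) selecting one label."""
        return LabelVolume((self.data == label).astype(np.int16), self.affine)

    def count(self, label: int) -> int:
        return int((self.data == label).sum())

    # NIfTI round trip -----------------------------------------------------
    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.data.astype(np.int16), self.affine)

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path) -> "LabelVolume":
        img = nib.load(str(path))
        return cls(np.asarray(img.dataobj).astype(np.int16), img.affine)
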