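"""In-memory containers for volumes and masks, plus NIfTI I/O.

Conventions
-----------
Arrays are indexed ``(x, y, z)`` with 0-based voxel indices; the axial
slice index is the **last** axis. ``spacing`` is millimetres per voxel
along each axis, so the physical volume of a mask is
``mask.sum() * prod(spacing)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

#: Label codes used in companion label volumes.
LABEL_CODES = {
    "background": 0,
    "csf": 1,
    "gm": 2,
    "wm": 3,
    "ventricle": 4,
    "vrs": 5,
}


@dataclass
class ImageVolume:
    """A 3-D scalar intensity grid with anisotropic voxel spacing (mm)."""

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D array, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        """Physical volume of a single voxel in mm^3."""
        return float(np.prod(self.spacing))

    def save(self, path: str | Path) -> Path:
        """Write as NIfTI with a diagonal affine built from the spacing."""
        path = Path(path)
        affine = np.diag([*self.spacing, 1.0])
        nib.save(nib.Nifti1Image(np.asarray(self.data), affine), str(path))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "ImageVolume":
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(data=data, spacing=spacing)


def save_labels(
    labels: np.ndarray,
    spacing: tuple[float, float, float],
    path: str | Path,
    dtype=np.uint8,
) -> Path:
    """Write an integer label volume as NIfTI.

    ``dtype`` defaults to uint8 (tissue label codes); pass a wider type
    for component maps with more than 255 labels.
    """
    path = Path(path)
    labels = np.asarray(labels)
    if labels.max(initial=0) > np.iinfo(dtype).max:
        dtype = np.int32
    affine = np.diag([*spacing, 1.0])
    nib.save(nib.Nifti1Image(labels.astype(dtype), affine), str(path))
    return path


@dataclass
class TissueMasks:
    """Binary brain / tissue masks on a shared grid.

    Invariants: ``wm``, ``gm``, ``csf`` are pairwise disjoint, their union
    is contained in ``brain``, and ``ventricle`` is contained in ``csf``.
    ``source`` records whether the masks came from a label volume
    (``"labels"``) or from intensity clustering (``"estimated"``).
    """

    brain: np.ndarray
    wm: np.ndarray
    gm: np.ndarray
    csf: np.ndarray
    ventricle: np.ndarray
    source: str = "estimated"

    def validate(self) -> None:
        """Raise ``ValueError`` if any mask invariant is violated."""
        for name in ("brain", "wm", "gm", "csf", "ventricle"):
            m = getattr(self, name)
            if m.dtype != bool or m.shape != self.brain.shape:
                raise ValueError(f"mask {name!r} must be boolean and share the grid")
        if np.any(self.wm & self.gm) or np.any(self.wm & self.csf) or np.any(self.gm & self.csf):
            raise ValueError("wm/gm/csf masks are not pairwise disjoint")
        union = self.wm | self.gm | self.csf
        if np.any(union & ~self.brain):
            raise ValueError("tissue masks extend outside the brain mask")
        if np.any(self.ventricle & ~self.csf):
            raise ValueError("ventricle mask is not contained in the CSF mask")

    @classmethod
    def from_labels(cls, labels: np.ndarray) -> "TissueMasks":
        """Build masks from a label volume (see :data:`LABEL_CODES`).

        Planted perivascular-space voxels (code 5) lie inside white matter,
        so the WM mask is the union of the WM and VRS codes.
        """
        labels = np.asarray(labels)
        csf = (labels == LABEL_CODES["csf"]) | (labels == LABEL_CODES["ventricle"])
        wm = (labels == LABEL_CODES["wm"]) | (labels == LABEL_CODES["vrs"])
        gm = labels == LABEL_CODES["gm"]
        ventricle = labels == LABEL_CODES["ventricle"]
        brain = csf | wm | gm
        return cls(brain=brain, wm=wm, gm=gm, csf=csf, ventricle=ventricle, source="labels")


@dataclass
class ROIMask:
    """Supraventricular white-matter region of interest.

    ``z_level`` is the axial slice index of the ventricular level; every
    voxel of ``mask`` lies on a slice with index >= ``z_level`` and inside
    the white-matter mask it was derived from.
    """

    mask: np.ndarray
    z_level: int
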