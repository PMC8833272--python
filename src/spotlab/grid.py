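"""Voxel grids on patient axes.

A :class:`DoseGrid` is the one container used for dose (cGy(RBE)), mass
density (g/cc) and binary masks alike: a 3D scalar field with isotropic or
anisotropic spacing and a world-space origin.  Axes follow the patient
convention used throughout the package: x = right-left (RL), y =
anterior-posterior (AP), z = superior-inferior (SI).  Array index order is
(ix, iy, iz), i.e. ``values[i, j, k]`` sits at world position
``origin + (i, j, k) * spacing`` (voxel centres).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import SimpleITK as sitk

AXIS_NAMES = ("RL", "AP", "SI")


@dataclass
class DoseGrid:
    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("DoseGrid expects a 3D array")
        if np.isscalar(self.spacing):
            self.spacing = (float(self.spacing),) * 3
        else:
            self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("grid spacing must be > 0")
        self.origin = tuple(float(o) for o in self.origin)

    # -- geometry -----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_volume_cc(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates (mm) of voxel centres along one axis."""
        n = self.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return np.meshgrid(*(self.axis_coords(a) for a in range(3)), indexing="ij")

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Continuous (fractional) index coordinates of world points (N, 3)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    def contains(self, points: np.ndarray) -> np.ndarray:
        idx = self.world_to_index(points)
        upper = np.asarray(self.shape) - 1
        return np.all((idx >= 0) & (idx <= upper), axis=1)

    def like(self, values: np.ndarray) -> "DoseGrid":
        """New grid with the same geometry and different values."""
        if values.shape != self.shape:
            raise ValueError("shape mismatch")
        return replace(self, values=values)

    def zeros_like(self, dtype=np.float64) -> "DoseGrid":
        return self.like(np.zeros(self.shape, dtype=dtype))

    # -- I/O ----------------------------------------------------------------
    def to_sitk(self) -> sitk.Image:
        # SimpleITK arrays are (z, y, x); our arrays are (x, y, z)
        img = sitk.GetImageFromArray(np.ascontiguousarray(self.values.T))
        img.SetSpacing(tuple(self.spacing))
        img.SetOrigin(tuple(self.origin))
        return img

    def save_nrrd(self, path) -> None:
        sitk.WriteImage(self.to_sitk(), str(path), useCompression=True)

    @classmethod
    def from_sitk(cls, img: sitk.Image) -> "DoseGrid":
        values = sitk.GetArrayFromImage(img).T.copy()
        return cls(values, tuple(img.GetSpacing()), tuple(img.GetOrigin()))

    @classmethod
    def load_nrrd(cls, path) -> "DoseGrid":
        return cls.from_sitk(sitk.ReadImage(str(path)))
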