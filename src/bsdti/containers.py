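"""Grid geometry and the in-memory diffusion dataset container.

All spatial reasoning in this package happens in world (scanner/laboratory)
millimetre coordinates, obtained from a NIfTI-style 4x4 affine.  Voxel indices
are only an addressing scheme; two grids with different resolutions agree on
the physics wherever their world coordinates overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import nibabel as nib
import numpy as np


@dataclass(frozen=True)
class Geometry:
    """A regular 3D grid: array shape plus voxel-to-world affine (mm)."""

    shape: tuple[int, int, int]
    affine: np.ndarray  # (4, 4)

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        object.__setattr__(self, "affine", aff)

    @classmethod
    def centered(cls, shape, voxel_size) -> "Geometry":
        """Axis-aligned grid with the given voxel size, centered on the world origin."""
        shape = tuple(int(s) for s in shape)
        vs = np.broadcast_to(np.asarray(voxel_size, float), (3,))
        aff = np.eye(4)
        aff[:3, :3] = np.diag(vs)
        aff[:3, 3] = -vs * (np.asarray(shape) - 1) / 2.0
        return cls(shape, aff)

    @property
    def voxel_size(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of every voxel center, shape ``(*shape, 3)``."""
        idx = np.indices(self.shape, dtype=float)  # (3, X, Y, Z)
        ijk = np.moveaxis(idx, 0, -1)
        return self.apply_affine(ijk)

    def apply_affine(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        """Continuous voxel indices for world points (inverse affine)."""
        inv = np.linalg.inv(self.affine)
        xyz = np.asarray(xyz, dtype=float)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def matches(self, other: "Geometry", tol: float = 1e-8) -> bool:
        return self.shape == other.shape and bool(
            np.allclose(self.affine, other.affine, atol=tol)
        )

    def world_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Axis-aligned world bounding box of the voxel centers (lo, hi)."""
        corners = np.array(
            [[i, j, k] for i in (0, self.shape[0] - 1)
             for j in (0, self.shape[1] - 1)
             for k in (0, self.shape[2] - 1)],
            dtype=float,
        )
        pts = self.apply_affine(corners)
        return pts.min(axis=0), pts.max(axis=0)


@dataclass
class DwiDataset:
    """A 4D diffusion-weighted acquisition.

    signals has shape ``(*geometry.shape, n_dwi)`` and is ordered like the
    gradient scheme's entries.  ``mask`` marks voxels with usable signal
    (inside the phantom or brain).
    """

    geometry: Geometry
    signals: np.ndarray
    scheme: "object"  # GradientScheme; untyped to avoid a circular import
    mask: Optional[np.ndarray] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.shape[:3] != self.geometry.shape:
            raise ValueError("signal grid does not match geometry")
        if self.signals.shape[3] != len(self.scheme):
            raise ValueError("number of volumes does not match gradient scheme")
        if self.mask is None:
            self.mask = np.ones(self.geometry.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.geometry.shape:
                raise ValueError("mask grid does not match geometry")

    def subset(self, scheme_name: str) -> "DwiDataset":
        """Restrict to a named protocol subset of this dataset's scheme."""
        sub, idx = self.scheme.subset(scheme_name)
        return DwiDataset(
            geometry=self.geometry,
            signals=self.signals[..., idx],
            scheme=sub,
            mask=self.mask,
            metadata=dict(self.metadata),
        )

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.signals.astype(np.float32), self.geometry.affine)


def save_volume(path, data: np.ndarray, geometry: Geometry, dtype=np.float32) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data).astype(dtype), geometry.affine), str(path))


def load_volume(path) -> tuple[np.ndarray, Geometry]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    geom = Geometry(tuple(data.shape[:3]), img.affine)
    return data, geom
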