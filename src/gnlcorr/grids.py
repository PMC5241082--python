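"""Spatial grids and image geometry in the magnet (AP, RL, SI) frame.

All spatial quantities in this package live in a right-handed patient/magnet
coordinate frame with axes ordered (AP, RL, SI) and the magnet isocenter at
the origin.  Units are millimeters throughout.  Axis conventions:

* AP — anterior/posterior axis, positive toward posterior;
* RL — right/left axis, positive toward left;
* SI — inferior/superior axis (the bore axis), positive toward superior.

`GridSpec` describes the regular grid a nonlinearity tensor or corrector
field is sampled on; `ImageGeometry` describes an acquired image volume via
a 4x4 voxel-index -> mm affine, which may permute and offset axes (e.g. a
coronal stack with slices along AP).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

AXES = ("AP", "RL", "SI")


@dataclass(frozen=True)
class GridSpec:
    """Regular sampling grid symmetric about the magnet isocenter.

    Parameters
    ----------
    origin : (3,) float
        Coordinates (mm) of grid node (0, 0, 0), axis order (AP, RL, SI).
    spacing : (3,) float
        Node spacing per axis in mm; strictly positive.
    shape : (3,) int
        Number of nodes per axis; at least 2.
    """

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        if len(self.origin) != 3 or len(self.spacing) != 3 or len(self.shape) != 3:
            raise ValueError("origin, spacing and shape must be 3-vectors")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("grid spacing must be positive")
        if any(n < 2 for n in self.shape):
            raise ValueError("grid needs at least 2 nodes per axis")

    @classmethod
    def centered(cls, fov_mm: float = 600.0, spacing_mm: float = 5.0) -> "GridSpec":
        """Isocenter-symmetric cube, default 600 mm field of view on a 5-mm grid."""
        n = int(round(fov_mm / spacing_mm)) + 1
        half = spacing_mm * (n - 1) / 2.0
        return cls((-half, -half, -half), (spacing_mm,) * 3, (n, n, n))

    @property
    def extent(self) -> np.ndarray:
        """(3, 2) array of [min, max] coordinate per axis."""
        o = np.asarray(self.origin, float)
        hi = o + np.asarray(self.spacing, float) * (np.asarray(self.shape) - 1)
        return np.stack([o, hi], axis=1)

    def axis_coords(self, axis: int) -> np.ndarray:
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def meshgrid(self) -> np.ndarray:
        """(nx, ny, nz, 3) array of node coordinates."""
        ax = [self.axis_coords(i) for i in range(3)]
        return np.stack(np.meshgrid(*ax, indexing="ij"), axis=-1)

    def contains(self, points: np.ndarray, atol: float = 1e-9) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, float))
        ext = self.extent
        return np.all(
            (pts >= ext[:, 0] - atol) & (pts <= ext[:, 1] + atol), axis=-1
        )

    def isocenter_index(self, atol: float = 1e-6) -> tuple[int, int, int]:
        """Index of the node at the isocenter; raises if no node sits there."""
        idx = []
        for ax in range(3):
            frac = -self.origin[ax] / self.spacing[ax]
            i = int(round(frac))
            if not (0 <= i < self.shape[ax]) or abs(frac - i) > atol:
                raise ValueError(
                    "grid has no node at the magnet isocenter "
                    f"(axis {AXES[ax]}: fractional index {frac:.6g})"
                )
            idx.append(i)
        return tuple(idx)

    def to_index(self, points: np.ndarray) -> np.ndarray:
        """Continuous (fractional) grid indices of physical points."""
        pts = np.asarray(points, float)
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)


@dataclass(frozen=True)
class ImageGeometry:
    """Image-volume geometry: voxel index (i, j, k) -> (AP, RL, SI) mm affine."""

    affine: np.ndarray  # (4, 4)
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        aff = np.asarray(self.affine, float)
        if aff.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        object.__setattr__(self, "affine", aff)
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))

    @classmethod
    def from_origin_spacing(
        cls,
        origin: tuple[float, float, float],
        spacing: tuple[float, float, float],
        shape: tuple[int, int, int],
        axis_map: tuple[int, int, int] = (0, 1, 2),
    ) -> "ImageGeometry":
        """Axis-aligned geometry; ``axis_map[d]`` is the magnet axis of data axis d."""
        aff = np.zeros((4, 4))
        aff[3, 3] = 1.0
        for d in range(3):
            aff[axis_map[d], d] = spacing[d]
            aff[axis_map[d], 3] = origin[d]
        return cls(aff, shape)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def voxel_to_mm(self, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx, float)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def mm_to_voxel(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, float)
        inv = np.linalg.inv(self.affine[:3, :3])
        return (pts - self.affine[:3, 3]) @ inv.T

    def voxel_centers_mm(self) -> np.ndarray:
        """(ni, nj, nk, 3) physical coordinates of every voxel center."""
        idx = np.stack(
            np.meshgrid(*[np.arange(n, dtype=float) for n in self.shape], indexing="ij"),
            axis=-1,
        )
        return self.voxel_to_mm(idx)

    def matches(self, other: "ImageGeometry", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )
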