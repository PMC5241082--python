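"""b-value corrector maps from nonlinearity tensor fields.

For a diffusion gradient along unit vector u_k the achieved weighting at r
deviates from nominal by the scalar

    C_k(r) = || (L u_k)(L u_k)^T ||_F = |L(r) u_k|^2,

the Frobenius norm of the rank-1 dyadic of the achieved gradient direction.
For an isotropic medium scanned with an orthonormal three-direction schema
the direction-averaged corrector C_av = mean_k C_k multiplies the effective
b-value, so corrected ADC = measured ADC / C_av.  C_av is schema-invariant
for orthonormal triads (sum_k |L u_k|^2 = ||L||_F^2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grids import GridSpec, ImageGeometry
from .tensor import NonlinearityTensorField

_UNIT_TOL = 1e-3  # accepted deviation of |u| from 1 (DICOM-style rounding)

#: orthogonal schema along the primary magnet axes
LAB_SCHEMA_U = np.eye(3)
#: oblique orthonormal triad used by some systems (columns are directions)
NONLAB_SCHEMA_U = np.array(
    [
        [-1.0 / 3.0, 2.0 / 3.0, 2.0 / 3.0],
        [-2.0 / 3.0, -2.0 / 3.0, 1.0 / 3.0],
        [-2.0 / 3.0, 1.0 / 3.0, -2.0 / 3.0],
    ]
)


@dataclass(frozen=True)
class DirectionSchema:
    """Three diffusion directions as unit columns of U in (AP, RL, SI)."""

    name: str
    U: np.ndarray

    def __post_init__(self) -> None:
        U = np.asarray(self.U, float)
        if U.shape != (3, 3):
            raise ValueError("U must be 3x3 (directions as columns)")
        norms = np.linalg.norm(U, axis=0)
        if np.any(np.abs(norms - 1.0) > _UNIT_TOL):
            raise ValueError("schema directions must be unit vectors")
        object.__setattr__(self, "U", U)

    @classmethod
    def lab(cls) -> "DirectionSchema":
        return cls("LAB", LAB_SCHEMA_U)

    @classmethod
    def nonlab(cls) -> "DirectionSchema":
        return cls("non-LAB", NONLAB_SCHEMA_U)

    def is_orthonormal(self, tol: float = 1e-9) -> bool:
        return bool(np.abs(self.U.T @ self.U - np.eye(3)).max() < tol)

    @property
    def directions(self) -> list[np.ndarray]:
        return [self.U[:, k] for k in range(3)]


@dataclass(frozen=True)
class CorrectorMap:
    """Dimensionless multiplicative b-value bias field.

    ``kind`` is "direction" for a per-direction C_k or "average" for the
    schema-averaged C_av; exactly one of ``grid`` (regular magnet-frame
    grid) and ``geometry`` (image geometry after resampling) is set.
    """

    values: np.ndarray
    kind: str
    grid: GridSpec | None = None
    geometry: ImageGeometry | None = None
    schema: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if (self.grid is None) == (self.geometry is None):
            raise ValueError("exactly one of grid/geometry must be given")
        shape = self.grid.shape if self.grid is not None else self.geometry.shape
        if v.shape != shape:
            raise ValueError("corrector values do not match the grid shape")
        if not np.isfinite(v).all() or np.any(v <= 0):
            raise ValueError("corrector values must be finite and positive")
        object.__setattr__(self, "values", v)


def _check_isocenter_unity(values: np.ndarray, grid: GridSpec) -> None:
    c0 = values[grid.isocenter_index()]
    if abs(c0 - 1.0) > 1e-9:
        raise ValueError(f"corrector at isocenter is {c0!r}, expected 1")


def corrector_for_direction(
    L: NonlinearityTensorField, u: np.ndarray
) -> CorrectorMap:
    """Per-direction corrector C_k(r) = |L(r) u|^2 on the tensor grid.

    ``u`` must already be a unit vector (no silent renormalization).
    """
    u = np.asarray(u, float)
    if u.shape != (3,):
        raise ValueError("direction must be a 3-vector")
    if abs(np.linalg.norm(u) - 1.0) > _UNIT_TOL:
        raise ValueError(f"direction is not a unit vector (|u|={np.linalg.norm(u):.6g})")
    lu = L.tensor @ u
    values = np.einsum("...i,...i->...", lu, lu)
    _check_isocenter_unity(values, L.grid)
    return CorrectorMap(values, "direction", grid=L.grid)


def schema_average_corrector(
    L: NonlinearityTensorField, schema: DirectionSchema
) -> CorrectorMap:
    """Direction-averaged corrector C_av = mean_k C_k for a schema."""
    name = schema.name
    if not schema.is_orthonormal():
        warnings.warn(
            f"schema {schema.name!r} is not orthonormal; averaging anyway "
            "(tagged 'custom')",
            stacklevel=2,
        )
        name = "custom"
    values = np.mean(
        [corrector_for_direction(L, u).values for u in schema.directions], axis=0
    )
    _check_isocenter_unity(values, L.grid)
    return CorrectorMap(values, "average", grid=L.grid, schema=name)


def resample_to_image(C: CorrectorMap, geometry: ImageGeometry) -> CorrectorMap:
    """Trilinear resampling of a grid corrector onto image voxel centers."""
    if C.grid is None:
        raise ValueError("corrector is already in image space")
    centers = geometry.voxel_centers_mm()
    inside = C.grid.contains(centers.reshape(-1, 3))
    if not inside.all():
        bad = centers.reshape(-1, 3)[~inside]
        lo, hi = bad.min(axis=0), bad.max(axis=0)
        raise ValueError(
            "image voxels fall outside the corrector field of view: "
            f"offending extent AP/RL/SI min={np.round(lo, 1).tolist()} "
            f"max={np.round(hi, 1).tolist()} mm, grid extent "
            f"{np.round(C.grid.extent, 1).tolist()} mm"
        )
    idx = C.grid.to_index(centers).reshape(-1, 3).T
    vals = ndimage.map_coordinates(C.values, idx, order=1, mode="nearest")
    return CorrectorMap(
        vals.reshape(geometry.shape), C.kind, geometry=geometry, schema=C.schema
    )
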