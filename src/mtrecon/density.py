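"""Cubic 3D density grids and the real-space transforms applied to them.

Conventions (shared by every module and stated once here):

* ``DensityMap.values`` is a cubic numpy array indexed ``[ix, iy, iz]``.
* The map origin is the geometric box center: voxel index ``i`` maps to the
  physical coordinate ``(i - (n-1)/2) * voxel_size_A`` along each axis.
* The MT axis lies along z in the model frame.
* Euler angles (rot, tilt, psi) are ZYZ, degrees, rotating the reference
  into the image frame: ``R = Rz(psi) @ Ry(tilt) @ Rz(rot)``.
* Interpolation is trilinear (spline order 1) everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["DensityMap", "euler_matrix", "rotate_map", "screw_transform_map", "ncc"]


@dataclass
class DensityMap:
    """A cubic scalar density grid with voxel size in Angstrom."""

    values: np.ndarray
    voxel_size_A: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 3 or len(set(v.shape)) != 1:
            raise ValueError(f"density grid must be cubic 3D, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("density grid contains non-finite values")
        if self.voxel_size_A <= 0:
            raise ValueError("voxel_size_A must be > 0")
        self.values = np.asarray(v, dtype=np.float64)

    @property
    def box_px(self) -> int:
        return self.values.shape[0]

    @property
    def extent_A(self) -> float:
        return self.box_px * self.voxel_size_A

    def center_px(self) -> float:
        return (self.box_px - 1) / 2.0

    def copy(self) -> "DensityMap":
        return DensityMap(self.values.copy(), self.voxel_size_A)

    def coordinate_grid_A(self):
        """Physical (x, y, z) coordinate arrays of the voxel centers."""
        ax = (np.arange(self.box_px) - self.center_px()) * self.voxel_size_A
        return np.meshgrid(ax, ax, ax, indexing="ij")


def euler_matrix(rot_deg: float, tilt_deg: float, psi_deg: float) -> np.ndarray:
    """ZYZ rotation matrix Rz(psi) @ Ry(tilt) @ Rz(rot)."""
    r, t, p = np.deg2rad([rot_deg, tilt_deg, psi_deg])

    def rz(a):
        c, s = np.cos(a), np.sin(a)
        return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])

    def ry(a):
        c, s = np.cos(a), np.sin(a)
        return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])

    return rz(p) @ ry(t) @ rz(r)


def _affine(values: np.ndarray, matrix: np.ndarray, offset: np.ndarray) -> np.ndarray:
    return ndimage.affine_transform(
        values, matrix, offset=offset, order=1, mode="constant", cval=0.0
    )


def rotate_map(mapp: DensityMap, rot_deg: float, tilt_deg: float, psi_deg: float) -> DensityMap:
    """Rotate the density by R(rot, tilt, psi) about the box center.

    The output satisfies rho_out(r) = rho_in(R^T r).
    """
    r = euler_matrix(rot_deg, tilt_deg, psi_deg)
    c = np.full(3, mapp.center_px())
    # affine_transform: in_coord = M @ out_coord + offset; we need in = R^T(out-c)+c
    m = r.T
    return DensityMap(_affine(mapp.values, m, c - m @ c), mapp.voxel_size_A)


def screw_transform_map(mapp: DensityMap, angle_deg: float, dz_A: float) -> DensityMap:
    """Apply the helical screw operation (rotate about z, translate along z).

    rho_out(r) = rho_in(S^-1 r) with S = Rz(angle) followed by +dz z-hat, so a
    feature at angle 0 moves to ``angle_deg`` and up by ``dz_A``.
    """
    a = np.deg2rad(angle_deg)
    c_, s_ = np.cos(a), np.sin(a)
    rz = np.array([[c_, -s_, 0.0], [s_, c_, 0.0], [0.0, 0.0, 1.0]])
    m = rz.T
    c = np.full(3, mapp.center_px())
    shift_px = np.array([0.0, 0.0, dz_A / mapp.voxel_size_A])
    offset = c - m @ (c + shift_px)
    return DensityMap(_affine(mapp.values, m, offset), mapp.voxel_size_A)


def ncc(a: np.ndarray, b: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Normalized cross-correlation of two equally-shaped arrays."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if mask is not None:
        sel = np.asarray(mask).ravel() > 0.5
        a, b = a[sel], b[sel]
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))
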