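"""Decorated-MT density volumes and their 2D projections.

The synthetic specimen is a sum of isotropic Gaussian blobs: one per
tubulin monomer (alpha and beta can differ in amplitude so the seam and
dimer repeat are visible), plus optional motor and tail blobs bound one
per dimer at larger cylinder radii, drawn with Bernoulli occupancies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage

from mtrecon.density import DensityMap, euler_matrix
from mtrecon.lattice import LatticeSpec, helical_params_from_spec, lattice_positions

__all__ = ["DensitySpec", "build_volume", "project", "add_gaussian_blob"]


@dataclass(frozen=True)
class BlobSpec:
    amplitude: float = 1.0
    sigma_A: float = 8.0


@dataclass(frozen=True)
class DensitySpec:
    """Parameters of the Gaussian-blob specimen model."""

    voxel_size_A: float = 4.0
    box_px: int = 96
    alpha: BlobSpec = field(default_factory=lambda: BlobSpec(1.0, 8.0))
    beta: BlobSpec = field(default_factory=lambda: BlobSpec(0.8, 8.0))
    motor: BlobSpec = field(default_factory=lambda: BlobSpec(1.2, 10.0))
    tail: BlobSpec = field(default_factory=lambda: BlobSpec(0.9, 9.0))
    motor_occupancy: float = 1.0
    tail_occupancy: float = 0.0
    motor_radius_offset_A: float = 30.0
    tail_radius_offset_A: float = 55.0

    def __post_init__(self) -> None:
        if self.voxel_size_A <= 0:
            raise ValueError("voxel_size_A must be > 0")
        if self.box_px < 8:
            raise ValueError("box_px too small")
        for name in ("motor_occupancy", "tail_occupancy"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


def add_gaussian_blob(
    values: np.ndarray,
    voxel_size_A: float,
    center_A: np.ndarray,
    amplitude: float,
    sigma_A: float,
) -> None:
    """Accumulate one isotropic 3D Gaussian in-place (evaluated to 4 sigma).

    ``center_A`` is in physical coordinates with the origin at box center.
    """
    n = values.shape[0]
    c_px = (n - 1) / 2.0
    ctr = np.asarray(center_A, dtype=float) / voxel_size_A + c_px
    half = int(np.ceil(4.0 * sigma_A / voxel_size_A))
    lo = np.maximum(np.floor(ctr).astype(int) - half, 0)
    hi = np.minimum(np.floor(ctr).astype(int) + half + 1, n)
    if np.any(lo >= hi):
        return
    ax = [np.arange(lo[d], hi[d]) - ctr[d] for d in range(3)]
    s_px = sigma_A / voxel_size_A
    gx = np.exp(-0.5 * (ax[0] / s_px) ** 2)
    gy = np.exp(-0.5 * (ax[1] / s_px) ** 2)
    gz = np.exp(-0.5 * (ax[2] / s_px) ** 2)
    values[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] += (
        amplitude * gx[:, None, None] * gy[None, :, None] * gz[None, None, :]
    )


def build_volume(
    lattice: LatticeSpec,
    dens: DensitySpec,
    seed: int,
    n_dimer_repeats: int | None = None,
):
    """Build a decorated MT volume plus its occupancy ground truth.

    Returns ``(DensityMap, occupancy)`` where ``occupancy`` is a DataFrame
    with one row per dimer site (pf_index, dimer_index, motor_occupied,
    tail_occupied). The lattice fills the box axially; radially every blob
    must fit inside the box or a ValueError naming the site is raised.
    """
    rng = np.random.default_rng(seed)
    extent = dens.box_px * dens.voxel_size_A
    half = extent / 2.0
    # radial containment check
    worst = {
        "alpha": (lattice.radius_A, dens.alpha.sigma_A),
        "beta": (lattice.radius_A, dens.beta.sigma_A),
    }
    if dens.motor_occupancy > 0:
        worst["motor"] = (lattice.radius_A + dens.motor_radius_offset_A, dens.motor.sigma_A)
    if dens.tail_occupancy > 0:
        worst["tail"] = (lattice.radius_A + dens.tail_radius_offset_A, dens.tail.sigma_A)
    for species, (r, sig) in worst.items():
        if r + 3.0 * sig > half:
            raise ValueError(
                f"{species} blobs (radius {r:.1f} + 3sigma {3 * sig:.1f} A) "
                f"extend outside the {extent:.0f} A box"
            )

    dimer_A = 2.0 * lattice.monomer_rise_A
    if n_dimer_repeats is None:
        n_dimer_repeats = int(np.ceil(extent / dimer_A)) + 2

    hp = helical_params_from_spec(lattice)
    sites = lattice_positions(lattice, n_dimer_repeats)
    values = np.zeros((dens.box_px,) * 3)

    zcut = half + 4.0 * max(dens.alpha.sigma_A, dens.motor.sigma_A, dens.tail.sigma_A)
    rows = []
    # monomer blobs
    for s in sites:
        if abs(s.position[2]) > zcut:
            continue
        blob = dens.alpha if s.kind == "alpha" else dens.beta
        add_gaussian_blob(values, dens.voxel_size_A, s.position, blob.amplitude, blob.sigma_A)
    # one motor (and optional tail) site per dimer, at the dimer midpoint
    by_col: dict[int, list] = {}
    for s in sites:
        by_col.setdefault(s.pf_index, []).append(s)
    for j, col in by_col.items():
        col.sort(key=lambda s: s.axial_index)
        for d in range(len(col) // 2):
            a, b = col[2 * d], col[2 * d + 1]
            mid = (a.position + b.position) / 2.0
            r_unit = np.array([mid[0], mid[1], 0.0])
            r_unit /= np.linalg.norm(r_unit)
            motor_occ = bool(rng.random() < dens.motor_occupancy)
            tail_occ = bool(rng.random() < dens.tail_occupancy)
            if abs(mid[2]) <= zcut:
                if motor_occ:
                    add_gaussian_blob(
                        values,
                        dens.voxel_size_A,
                        mid + r_unit * dens.motor_radius_offset_A,
                        dens.motor.amplitude,
                        dens.motor.sigma_A,
                    )
                if tail_occ:
                    add_gaussian_blob(
                        values,
                        dens.voxel_size_A,
                        mid + r_unit * dens.tail_radius_offset_A,
                        dens.tail.amplitude,
                        dens.tail.sigma_A,
                    )
            rows.append(
                {
                    "pf_index": j,
                    "dimer_index": d,
                    "z_A": mid[2],
                    "motor_occupied": motor_occ,
                    "tail_occupied": tail_occ,
                }
            )
    occupancy = pd.DataFrame(rows)
    return DensityMap(values, dens.voxel_size_A), occupancy


def project(
    mapp: DensityMap,
    euler_deg: tuple[float, float, float] = (0.0, 0.0, 0.0),
    shift_A: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Project the rotated, shifted map along the beam (z) axis.

    The map is rotated by R(rot, tilt, psi) about its center, translated
    in-plane by ``shift_A``, and integrated along z; the returned image is
    indexed [ix, iy] and carries the line-integral scaling (sum * voxel).
    Linear in the map by construction.
    """
    r = euler_matrix(*euler_deg)
    c = np.full(3, mapp.center_px())
    s3 = np.array([shift_A[0], shift_A[1], 0.0]) / mapp.voxel_size_A
    m = r.T
    offset = c - m @ (c + s3)
    rot = ndimage.affine_transform(
        mapp.values, m, offset=offset, order=1, mode="constant", cval=0.0
    )
    return rot.sum(axis=2) * mapp.voxel_size_A
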