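"""Microtubule lattice geometry.

Microtubules (MTs) are hollow cylinders of 11-16 protofilaments (PFs),
longitudinal columns of alpha/beta-tubulin dimers. Laterally adjacent
monomers are related by a screw operation: a rotation about the MT axis
(the lateral twist) combined with a small axial rise. For an N-PF,
S-start monomer helix the per-subunit helical parameters are

    twist = handedness * 360 / N          (degrees)
    rise  = S * monomer_rise / N          (Angstrom)

so that stepping N times laterally returns to the starting column,
S monomers up. The dimer repeat along a PF is two monomer rises
(~82 A for tubulin). True helical symmetry of the *dimer* lattice is
broken at the seam, the lateral interface where alpha contacts beta;
here the seam is modelled as a single PF column with swapped
alpha/beta register.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import List

import numpy as np

__all__ = [
    "LatticeSpec",
    "HelicalParams",
    "MonomerSite",
    "helical_params_from_spec",
    "lattice_positions",
    "pf_symmetry_transform",
    "RigidTransform",
]


@dataclass(frozen=True)
class LatticeSpec:
    """Geometry of an ideal N-protofilament microtubule monomer lattice.

    Parameters
    ----------
    n_pf : number of protofilaments (11-16).
    start_number : number of starts of the lateral monomer helix (3 for MTs).
    monomer_rise_A : axial spacing of monomers along one PF (A). The default
        40.95 A gives the canonical ~82 A tubulin dimer repeat.
    radius_A : cylinder radius to monomer centers (A).
    pf_skew_deg : PF skew per monomer (deg); 0 for an ideal unsupertwisted MT.
    seam_index : PF column carrying the alpha/beta register break.
    handedness : sign of the lateral twist (+1 or -1; -1 = left-handed).
    """

    n_pf: int = 14
    start_number: int = 3
    monomer_rise_A: float = 40.95
    radius_A: float = 110.0
    pf_skew_deg: float = 0.0
    seam_index: int = 0
    handedness: int = -1

    def __post_init__(self) -> None:
        if not (11 <= self.n_pf <= 16):
            raise ValueError(f"n_pf must be in [11, 16], got {self.n_pf}")
        if self.monomer_rise_A <= 0:
            raise ValueError("monomer_rise_A must be > 0")
        if self.radius_A <= 0:
            raise ValueError("radius_A must be > 0")
        if not (0 <= self.seam_index < self.n_pf):
            raise ValueError("seam_index must satisfy 0 <= seam_index < n_pf")
        if self.handedness not in (-1, 1):
            raise ValueError("handedness must be +1 or -1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "LatticeSpec":
        return cls(**d)


@dataclass(frozen=True)
class HelicalParams:
    """Per-lateral-subunit helical parameters: twist (deg) and rise (A)."""

    twist_deg: float
    rise_A: float

    def __post_init__(self) -> None:
        if self.rise_A <= 0:
            raise ValueError("rise_A must be > 0")
        if abs(self.twist_deg) > 360.0 / 11 + 1e-9:
            raise ValueError("|twist_deg| must not exceed 360/11")


@dataclass
class MonomerSite:
    """One tubulin monomer position on the lattice, with decoration flags."""

    pf_index: int
    axial_index: int
    kind: str  # "alpha" | "beta"
    position: np.ndarray  # (x, y, z) in A, MT axis along z
    motor_occupied: bool = False
    tail_occupied: bool = False


def helical_params_from_spec(spec: LatticeSpec) -> HelicalParams:
    """Helical twist/rise of the monomer lattice implied by a LatticeSpec."""
    twist = spec.handedness * 360.0 / spec.n_pf
    rise = spec.start_number * spec.monomer_rise_A / spec.n_pf
    return HelicalParams(twist_deg=twist, rise_A=rise)


def lattice_positions(spec: LatticeSpec, n_dimer_repeats: int) -> List[MonomerSite]:
    """Monomer sites of ``n_dimer_repeats`` axial dimer repeats on every PF.

    Site (pf j, axial i) sits at azimuth j*twist + i*pf_skew, height
    j*rise + i*monomer_rise; stepping one PF laterally applies the helical
    screw operation exactly. Kinds alternate alpha/beta along each PF;
    the seam column's register is swapped. Positions are centered so the
    stack's axial midpoint is z = 0.
    """
    if n_dimer_repeats < 1:
        raise ValueError("n_dimer_repeats must be >= 1")
    hp = helical_params_from_spec(spec)
    n_axial = 2 * n_dimer_repeats
    # center the stack so that a dimer midpoint of column 0 sits exactly at
    # z = 0: downstream per-dimer bookkeeping (protofilament particle
    # anchors) then lands on lattice sites instead of between them
    z_raw = ((n_axial - 1) * spec.monomer_rise_A + (spec.n_pf - 1) * hp.rise_A) / 2.0
    d_star = np.round((z_raw - 0.5 * spec.monomer_rise_A) / (2.0 * spec.monomer_rise_A))
    z_mid = (2.0 * d_star + 0.5) * spec.monomer_rise_A
    sites: List[MonomerSite] = []
    for j in range(spec.n_pf):
        swap = j == spec.seam_index
        for i in range(n_axial):
            theta = np.deg2rad(j * hp.twist_deg + i * spec.pf_skew_deg)
            z = j * hp.rise_A + i * spec.monomer_rise_A - z_mid
            pos = np.array(
                [spec.radius_A * np.cos(theta), spec.radius_A * np.sin(theta), z]
            )
            parity = (i + (1 if swap else 0)) % 2
            sites.append(
                MonomerSite(
                    pf_index=j,
                    axial_index=i,
                    kind="alpha" if parity == 0 else "beta",
                    position=pos,
                )
            )
    return sites


@dataclass(frozen=True)
class RigidTransform:
    """Rotation about z by ``angle_deg`` composed with translation ``dz_A``."""

    angle_deg: float
    dz_A: float

    @property
    def matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix (A units)."""
        a = np.deg2rad(self.angle_deg)
        m = np.eye(4)
        m[0, 0] = np.cos(a)
        m[0, 1] = -np.sin(a)
        m[1, 0] = np.sin(a)
        m[1, 1] = np.cos(a)
        m[2, 3] = self.dz_A
        return m

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        """Apply to points of shape (..., 3)."""
        xyz = np.asarray(xyz, dtype=float)
        a = np.deg2rad(self.angle_deg)
        c, s = np.cos(a), np.sin(a)
        out = np.empty_like(xyz)
        out[..., 0] = c * xyz[..., 0] - s * xyz[..., 1]
        out[..., 1] = s * xyz[..., 0] + c * xyz[..., 1]
        out[..., 2] = xyz[..., 2] + self.dz_A
        return out

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        return RigidTransform(self.angle_deg + other.angle_deg, self.dz_A + other.dz_A)


def pf_symmetry_transform(params: HelicalParams, k: int) -> RigidTransform:
    """Screw operation relating PF j to PF j+k: rotate k*twist, rise k*rise."""
    return RigidTransform(angle_deg=k * params.twist_deg, dz_A=k * params.rise_A)
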