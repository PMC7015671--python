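"""Helical (rise, twist) estimation and N-fold symmetrized averaging.

The per-subunit lattice parameters are found by maximizing the
real-space correlation between a map and its screw-transformed copy
inside a cylindrical mask — the self-consistency criterion IHRSR uses —
followed by parabolic refinement about the grid optimum. Symmetrizing
averages the k = 0..N-1 screw-related copies; axial translations are
wrapped into the lattice z-period (N*rise, one full start repeat) to
keep copies inside the box.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from mtrecon.density import DensityMap, ncc, screw_transform_map
from mtrecon.lattice import HelicalParams

__all__ = ["HelicalEstimate", "estimate_helical_params", "symmetrize", "cylinder_mask"]


def cylinder_mask(
    mapp: DensityMap,
    r_min_A: float = 0.0,
    r_max_A: float | None = None,
    z_margin_A: float = 0.0,
) -> np.ndarray:
    """Boolean cylindrical mask (axis z) with an optional axial margin."""
    x, y, z = mapp.coordinate_grid_A()
    r = np.hypot(x, y)
    if r_max_A is None:
        r_max_A = mapp.extent_A / 2.0
    m = (r >= r_min_A) & (r <= r_max_A)
    if z_margin_A > 0:
        m &= np.abs(z) <= (mapp.extent_A / 2.0 - z_margin_A)
    return m


@dataclass
class HelicalEstimate:
    params: HelicalParams
    score: float
    flat_surface: bool = False
    on_boundary: bool = False


def _self_correlation(mapp, twist, rise, mask):
    moved = screw_transform_map(mapp, twist, rise)
    return ncc(mapp.values, moved.values, mask)


def estimate_helical_params(
    mapp: DensityMap,
    guess: HelicalParams,
    twist_range_deg: tuple[float, float],
    rise_range_A: tuple[float, float],
    grid_step: tuple[float, float] = (0.2, 0.1),
    r_min_A: float = 0.0,
    r_max_A: float | None = None,
) -> HelicalEstimate:
    """Grid-search the screw parameters maximizing map self-correlation.

    ``grid_step`` is (twist step deg, rise step A). Degenerate cases are
    flagged: a flat correlation surface returns the guess with
    ``flat_surface`` set, and an optimum on the search-range edge sets
    ``on_boundary``.
    """
    t_lo, t_hi = twist_range_deg
    r_lo, r_hi = rise_range_A
    if not (t_hi > t_lo and r_hi > r_lo):
        raise ValueError("empty search range")
    if not (t_lo <= guess.twist_deg <= t_hi and r_lo <= guess.rise_A <= r_hi):
        raise ValueError("ranges must bracket the guess")
    dt, dr = grid_step
    twists = np.arange(t_lo, t_hi + dt / 2, dt)
    rises = np.arange(r_lo, r_hi + dr / 2, dr)
    if r_max_A is None:
        # stay inside the inscribed cylinder: rotations pull zero-padding
        # in through the box corners
        r_max_A = mapp.extent_A / 2.0 - 2.0 * mapp.voxel_size_A
    mask = cylinder_mask(mapp, r_min_A, r_max_A, z_margin_A=abs(r_hi) + mapp.voxel_size_A)
    scores = np.empty((len(twists), len(rises)))
    for i, t in enumerate(twists):
        for j, r in enumerate(rises):
            scores[i, j] = _self_correlation(mapp, t, r, mask)
    # correlation variation below ~1e-3 is interpolation noise, not signal
    if scores.max() - scores.min() < 1e-3:
        return HelicalEstimate(guess, float(scores.max()), flat_surface=True)
    i, j = np.unravel_index(np.argmax(scores), scores.shape)
    boundary = i in (0, len(twists) - 1) or j in (0, len(rises) - 1)

    def _parab(ym, y0, yp, step):
        d = ym - 2 * y0 + yp
        if d >= 0:
            return 0.0
        return float(np.clip(0.5 * (ym - yp) / d, -0.5, 0.5)) * step

    t_best = twists[i]
    r_best = rises[j]
    if 0 < i < len(twists) - 1:
        t_best += _parab(scores[i - 1, j], scores[i, j], scores[i + 1, j], dt)
    if 0 < j < len(rises) - 1:
        r_best += _parab(scores[i, j - 1], scores[i, j], scores[i, j + 1], dr)
    return HelicalEstimate(
        HelicalParams(twist_deg=float(t_best), rise_A=float(r_best)),
        float(scores[i, j]),
        on_boundary=boundary,
    )


def symmetrize(
    mapp: DensityMap,
    params: HelicalParams,
    n_pf: int,
    wrap_z: bool = True,
) -> DensityMap:
    """Average the N screw-related copies of the map.

    With ``wrap_z`` the axial translation of copy k is wrapped into
    (-N*rise/2, N*rise/2]; a pure N*rise translation is a lattice
    symmetry (one full start repeat, rotation = 360 deg), so wrapping
    changes nothing for a true helix but keeps copies inside the box.
    """
    period = n_pf * params.rise_A
    acc = np.zeros_like(mapp.values)
    for k in range(n_pf):
        dz = k * params.rise_A
        if wrap_z:
            dz = dz - period * np.round(dz / period)
        moved = screw_transform_map(mapp, k * params.twist_deg, dz)
        acc += moved.values
    return DensityMap(acc / n_pf, mapp.voxel_size_A)
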