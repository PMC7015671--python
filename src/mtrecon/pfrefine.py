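"""Protofilament (PF) refinement by wedge-mask signal subtraction.

To refine a single PF out of an N-PF microtubule, the symmetrized MT
volume is multiplied by the complement of a soft angular wedge mask
keeping PF j, projected with the segment's alignment, and subtracted
from the experimental image. Under a linear projection this equals the
projection of the wedge-masked (single-PF) volume plus the image noise,
so one subtracted, re-centered particle per PF per segment can be
refined locally and classified for motor/tail occupancy. Subtracting the
projected complement once per target PF is mathematically equivalent to
rotating-and-subtracting a PF-deleted volume N-1 times, without double
counting overlapping wedges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from mtrecon.density import DensityMap, ncc
from mtrecon.lattice import HelicalParams, LatticeSpec, helical_params_from_spec
from mtrecon.simulate.volume import project

__all__ = [
    "WedgeMaskSpec",
    "make_wedge_mask",
    "subtract_other_pfs",
    "ProtofilamentParticleSet",
    "extract_pf_particles",
    "single_pf_reference",
    "local_refine_pf",
    "ClassifyResult",
    "focused_classify",
]


@dataclass(frozen=True)
class WedgeMaskSpec:
    """Soft angular wedge keeping one PF inside a radial annulus."""

    n_pf: int
    pf_index: int
    radial_inner_A: float
    radial_outer_A: float
    angular_width_deg: float | None = None  # default 360/n_pf
    soft_edge_deg: float = 5.0
    handedness: int = -1
    center_offset_deg: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.pf_index < self.n_pf):
            raise ValueError("pf_index must satisfy 0 <= pf_index < n_pf")
        if self.radial_inner_A >= self.radial_outer_A:
            raise ValueError("radial_inner_A must be < radial_outer_A")
        if self.soft_edge_deg < 0:
            raise ValueError("soft_edge_deg must be >= 0")

    @property
    def width_deg(self) -> float:
        return 360.0 / self.n_pf if self.angular_width_deg is None else self.angular_width_deg

    @property
    def center_deg(self) -> float:
        return self.handedness * self.pf_index * 360.0 / self.n_pf + self.center_offset_deg


def make_wedge_mask(grid_like: DensityMap, spec: WedgeMaskSpec) -> DensityMap:
    """Wedge mask in [0, 1] keeping PF ``pf_index``.

    The angular profile is a raised-cosine crossfade of half-width
    ``soft_edge_deg`` about the nominal wedge edges, so the N single-PF
    masks sum to exactly 1 inside the annulus (partition of unity), and
    mask(j+1) is mask(j) rotated by one PF step.
    """
    if spec.radial_outer_A > grid_like.extent_A / 2.0:
        raise ValueError("radial annulus extends outside the box")
    x, y, z = grid_like.coordinate_grid_A()
    r = np.hypot(x, y)
    theta = np.rad2deg(np.arctan2(y, x))
    d = np.abs((theta - spec.center_deg + 180.0) % 360.0 - 180.0)
    w = spec.width_deg / 2.0
    s = spec.soft_edge_deg
    if s == 0:
        ang = (d <= w).astype(float)
    else:
        ang = np.clip((d - (w - s)) / (2.0 * s), 0.0, 1.0)
        ang = 0.5 * (1.0 + np.cos(np.pi * ang))
    annulus = (r >= spec.radial_inner_A) & (r <= spec.radial_outer_A)
    return DensityMap(ang * annulus, grid_like.voxel_size_A)


def subtract_other_pfs(
    image: np.ndarray,
    mapp: DensityMap,
    euler_deg,
    shift_A,
    spec: WedgeMaskSpec,
) -> np.ndarray:
    """image - project(map * (1 - wedge_j)) for the segment's alignment.

    For noiseless synthetic input the residual equals the projection of
    the single-PF masked volume by linearity of the projector.
    """
    mask = make_wedge_mask(mapp, spec)
    complement = DensityMap(mapp.values * (1.0 - mask.values), mapp.voxel_size_A)
    return image - project(complement, euler_deg, shift_A)


@dataclass
class ProtofilamentParticleSet:
    """Signal-subtracted per-PF particles with provenance and alignments."""

    images: np.ndarray  # (n_particles, box, box)
    meta: pd.DataFrame  # segment_id, pf_index, rot/tilt/psi, shift, cc, class
    box_px: int
    voxel_size_A: float


def _pf_anchor_points(lattice: LatticeSpec, params: HelicalParams) -> np.ndarray:
    """Model-frame dimer-midpoint anchors of each PF, wrapped near z = 0.

    The anchor of PF j is the screw image of PF 0's midpoint with the
    axial part wrapped modulo the dimer repeat (a pure dimer-repeat
    translation is itself a lattice symmetry), keeping anchors inside
    the box.
    """
    dimer = 2.0 * lattice.monomer_rise_A
    q = np.empty((lattice.n_pf, 3))
    # PF 0 dimer midpoint closest to z=0 in the canonical volume
    q0 = np.array([lattice.radius_A, 0.0, 0.0])
    for j in range(lattice.n_pf):
        a = np.deg2rad(j * params.twist_deg)
        dz = j * params.rise_A
        dz -= dimer * np.round(dz / dimer)
        q[j] = [
            np.cos(a) * q0[0] - np.sin(a) * q0[1],
            np.sin(a) * q0[0] + np.cos(a) * q0[1],
            q0[2] + dz,
        ]
    return q


def extract_pf_particles(
    stack: np.ndarray,
    alignments: pd.DataFrame,
    lattice: LatticeSpec,
    mapp: DensityMap,
    box_px: int | None = None,
    radial_inner_A: float = 0.0,
    radial_outer_A: float | None = None,
    soft_edge_deg: float = 5.0,
) -> ProtofilamentParticleSet:
    """One subtracted, re-centered particle per PF per segment.

    Particle count is exactly n_segments * n_pf. Each particle's initial
    alignment is the MT alignment composed with the j-th PF screw
    transform: rot + j*twist, with the residual sub-pixel re-centering
    stored as the particle shift.
    """
    stack = np.asarray(stack)
    n_seg = stack.shape[0]
    if len(alignments) != n_seg:
        raise ValueError("alignment rows must match the stack")
    n_pf = lattice.n_pf
    params = helical_params_from_spec(lattice)
    vx = mapp.voxel_size_A
    big = mapp.box_px
    if box_px is None:
        box_px = big // 2
    if radial_outer_A is None:
        radial_outer_A = mapp.extent_A / 2.0 - vx
    anchors = _pf_anchor_points(lattice, params)

    from mtrecon.density import euler_matrix

    images, rows = [], []
    for i, (_, row) in enumerate(alignments.iterrows()):
        euler = (float(row["rot_deg"]), float(row["tilt_deg"]), float(row["psi_deg"]))
        shift = (float(row["shift_x_A"]), float(row["shift_y_A"]))
        r = euler_matrix(*euler)
        for j in range(n_pf):
            spec = WedgeMaskSpec(
                n_pf=n_pf,
                pf_index=j,
                radial_inner_A=radial_inner_A,
                radial_outer_A=radial_outer_A,
                soft_edge_deg=soft_edge_deg,
                handedness=lattice.handedness,
            )
            residual = subtract_other_pfs(stack[i], mapp, euler, shift, spec)
            u_A = (r @ anchors[j])[:2] + np.asarray(shift)  # PF center in image, A
            u_px = u_A / vx
            u_int = np.round(u_px).astype(int)
            frac_A = (u_px - u_int) * vx
            # particle center (box-1)/2 lands on residual px (big-1)/2 + u_int
            x0, y0 = (big - box_px) // 2 + u_int[0], (big - box_px) // 2 + u_int[1]
            part = np.zeros((box_px, box_px))
            xs0, ys0 = max(x0, 0), max(y0, 0)
            xs1, ys1 = min(x0 + box_px, big), min(y0 + box_px, big)
            part[xs0 - x0 : xs1 - x0, ys0 - y0 : ys1 - y0] = residual[xs0:xs1, ys0:ys1]
            images.append(part)
            rows.append(
                {
                    "particle_id": i * n_pf + j,
                    "segment_id": int(row["segment_id"]) if "segment_id" in row else i,
                    "pf_index": j,
                    "rot_deg": (euler[0] + j * params.twist_deg) % 360.0,
                    "tilt_deg": euler[1],
                    "psi_deg": euler[2],
                    "shift_x_A": float(frac_A[0]),
                    "shift_y_A": float(frac_A[1]),
                    "cc": np.nan,
                    "class_label": -1,
                }
            )
    return ProtofilamentParticleSet(
        images=np.array(images),
        meta=pd.DataFrame(rows),
        box_px=box_px,
        voxel_size_A=vx,
    )


def single_pf_reference(
    mapp: DensityMap,
    lattice: LatticeSpec,
    radial_inner_A: float = 0.0,
    radial_outer_A: float | None = None,
    soft_edge_deg: float = 5.0,
) -> DensityMap:
    """Wedge-masked single-PF volume re-centered on the PF-0 anchor."""
    from scipy import ndimage

    if radial_outer_A is None:
        radial_outer_A = mapp.extent_A / 2.0 - mapp.voxel_size_A
    spec = WedgeMaskSpec(
        n_pf=lattice.n_pf,
        pf_index=0,
        radial_inner_A=radial_inner_A,
        radial_outer_A=radial_outer_A,
        soft_edge_deg=soft_edge_deg,
        handedness=lattice.handedness,
    )
    mask = make_wedge_mask(mapp, spec)
    vals = mapp.values * mask.values
    params = helical_params_from_spec(lattice)
    q0 = _pf_anchor_points(lattice, params)[0]
    vals = ndimage.shift(vals, -q0 / mapp.voxel_size_A, order=1, mode="constant")
    return DensityMap(vals, mapp.voxel_size_A)


def local_refine_pf(
    particles: ProtofilamentParticleSet,
    single_pf_ref: DensityMap,
    ang_range_deg: float = 4.0,
    shift_range_A: float = 8.0,
    step: tuple[float, float] = (1.0, None),
) -> pd.DataFrame:
    """Constrained local alignment of PF particles about their initials.

    Grid search over rot offsets within +-ang_range_deg (step[0] deg) and
    integer-pixel shifts within +-shift_range_A (step[1] A; default one
    pixel), scored by NCC against projections of the single-PF reference
    cropped to the particle box. Refined values never leave the ranges.
    """
    if ang_range_deg <= 0 or shift_range_A < 0:
        raise ValueError("ranges must be positive")
    vx = particles.voxel_size_A
    if abs(single_pf_ref.voxel_size_A - vx) > 1e-9:
        raise ValueError("reference/particle voxel size mismatch")
    ang_step = step[0]
    shift_step_A = step[1] if step[1] is not None else vx
    # candidates ordered by perturbation size: gains below `min_gain` (NCC
    # interpolation noise) never pull the alignment away from its prior
    min_gain = 1e-4
    dangs = np.arange(-ang_range_deg, ang_range_deg + ang_step / 2, ang_step)
    dangs = dangs[np.argsort(np.abs(dangs), kind="stable")]
    dsh = np.arange(-shift_range_A, shift_range_A + shift_step_A / 2, shift_step_A)
    dsh = dsh[np.argsort(np.abs(dsh), kind="stable")]
    box = particles.box_px
    big = single_pf_ref.box_px
    lo = (big - box) // 2
    proj_cache: dict[tuple, np.ndarray] = {}

    out = particles.meta.copy()
    for pos, (idx, row) in enumerate(particles.meta.iterrows()):
        img = particles.images[pos]
        img = img - img.mean()
        nimg = np.linalg.norm(img)
        if nimg > 0:
            img = img / nimg
        best = (-np.inf, 0.0, 0.0, 0.0)
        for da in dangs:
            key = (round(row["rot_deg"] + da, 3), round(row["tilt_deg"], 3), round(row["psi_deg"], 3))
            if key not in proj_cache:
                p = project(single_pf_ref, key)
                proj_cache[key] = p[lo : lo + box, lo : lo + box]
            ref_img = proj_cache[key]
            for dx in dsh:
                for dy in dsh:
                    from scipy import ndimage

                    shifted = ndimage.shift(
                        ref_img,
                        (
                            (row["shift_x_A"] + dx) / vx,
                            (row["shift_y_A"] + dy) / vx,
                        ),
                        order=1,
                        mode="constant",
                    )
                    score = ncc(img, shifted)
                    if score > best[0] + min_gain:
                        best = (score, da, dx, dy)
        score, da, dx, dy = best
        out.loc[idx, "rot_deg"] = (row["rot_deg"] + da) % 360.0
        out.loc[idx, "shift_x_A"] = row["shift_x_A"] + dx
        out.loc[idx, "shift_y_A"] = row["shift_y_A"] + dy
        out.loc[idx, "cc"] = score
    return out


@dataclass
class ClassifyResult:
    labels: np.ndarray
    class_volumes: list  # DensityMap per class (back-projected class means)
    fractions: np.ndarray
    scores: np.ndarray
    empty_class: bool
    n_iter_run: int


def focused_classify(
    particles: ProtofilamentParticleSet,
    focus_mask: DensityMap,
    k_classes: int = 2,
    n_iter: int = 50,
    seed: int = 0,
    site_ids=None,
    template: DensityMap | None = None,
) -> ClassifyResult:
    """Focused hard classification of PF particles, alignments held fixed.

    Each particle is reduced to a matched-filter statistic: the dot
    product between the particle image and the projection — at that
    particle's own fixed alignment — of the focus-masked consensus
    volume (the back-projection of all particles; pass ``template`` to
    use a model volume instead). Labels then come from alternating hard
    assignment to per-class means of that statistic (1D k-means),
    which is deterministic; ``seed`` is kept for interface stability.
    Class mean volumes are back-projected per class and returned with
    the class fractions.

    The statistic is compared against the *consensus* rather than
    per-class mean volumes because a particle's own noise enters any
    volume its class back-projects, and that self-correlation feeds
    back into the assignment; the consensus shifts every particle's
    score by the same bias and is immune.

    ``site_ids`` (one hashable id per particle) pools scores over
    particles that view the same physical lattice site — different
    segments of a filament see the same dimer from different azimuths,
    so pooling averages away both noise and the residual occupancy
    signal of neighboring sites; the returned labels are still
    per-particle.
    """
    from mtrecon.recon.backproject import backproject

    imgs = np.asarray(particles.images, dtype=float)
    n = imgs.shape[0]
    if k_classes < 1:
        raise ValueError("k_classes must be >= 1")
    if k_classes > n:
        raise ValueError("k_classes exceeds the particle count")
    if focus_mask.box_px != particles.box_px:
        raise ValueError("focus mask must live on the particle-box grid")
    meta = particles.meta
    vx = particles.voxel_size_A

    base = template if template is not None else backproject(imgs, meta, vx)[0]
    tvol = DensityMap(base.values * (focus_mask.values > 0.5), vx)
    scores = np.empty(n)
    eulers, shifts = [], []
    for i, (_, row) in enumerate(meta.iterrows()):
        euler = (float(row["rot_deg"]), float(row["tilt_deg"]), float(row["psi_deg"]))
        shift = (float(row["shift_x_A"]), float(row["shift_y_A"]))
        eulers.append(euler)
        shifts.append(shift)
        scores[i] = float(np.sum(imgs[i] * project(tvol, euler, shift)))

    if site_ids is not None:
        site_ids = np.asarray(site_ids)
        pooled = {s: scores[site_ids == s].mean() for s in np.unique(site_ids)}
        eff_scores = np.array([pooled[s] for s in site_ids])
    else:
        eff_scores = scores

    if k_classes == 1:
        labels = np.zeros(n, dtype=int)
        it = 0
        empty_flag = False
    else:
        centers = np.quantile(eff_scores, np.linspace(0.1, 0.9, k_classes))
        labels = np.zeros(n, dtype=int)
        it = 0
        for it in range(1, n_iter + 1):
            new = np.argmin(np.abs(eff_scores[:, None] - centers[None, :]), axis=1)
            new_centers = centers.copy()
            for k in range(k_classes):
                if np.any(new == k):
                    new_centers[k] = eff_scores[new == k].mean()
            if np.array_equal(new, labels) and np.allclose(new_centers, centers):
                labels = new
                break
            labels, centers = new, new_centers
        empty_flag = any(not np.any(labels == k) for k in range(k_classes))
        # relabel so class order follows ascending score mean
        order = np.argsort(
            [eff_scores[labels == k].mean() if np.any(labels == k) else np.inf
             for k in range(k_classes)]
        )
        remap = np.empty(k_classes, dtype=int)
        remap[order] = np.arange(k_classes)
        labels = remap[labels]

    class_volumes = []
    fractions = np.zeros(k_classes)
    for k in range(k_classes):
        members = labels == k
        fractions[k] = members.sum() / n
        if members.any():
            vol, _ = backproject(imgs[members], meta[members], vx)
            class_volumes.append(vol)
        else:
            class_volumes.append(None)
    return ClassifyResult(labels, class_volumes, fractions, scores, empty_flag, it)
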