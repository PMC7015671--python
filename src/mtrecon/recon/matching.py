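"""Exhaustive projection matching against a reference gallery.

The similarity metric is normalized cross-correlation (NCC), searched
over in-plane shifts on the integer pixel grid by FFT cross-correlation
with parabolic sub-pixel refinement. Filaments lie in the ice plane, so
the gallery covers rot azimuths at tilt ~ 90 deg; a psi (in-plane) list
can widen the search when segment orientations are jittered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from mtrecon.density import DensityMap
from mtrecon.simulate.volume import project

__all__ = ["make_gallery", "projection_match"]


@dataclass
class GalleryEntry:
    rot_deg: float
    tilt_deg: float
    psi_deg: float
    image: np.ndarray  # zero-mean, unit-norm


def make_gallery(
    reference: DensityMap,
    angular_step_deg: float,
    tilt_deg: float = 90.0,
    psi_list=(0.0,),
    rot_max_deg: float = 360.0,
) -> list[GalleryEntry]:
    """Projections of the reference on a rot grid (and optional psi list)."""
    if angular_step_deg <= 0:
        raise ValueError("angular_step_deg must be > 0")
    entries = []
    rots = np.arange(0.0, rot_max_deg, angular_step_deg)
    for rot in rots:
        for psi in psi_list:
            img = project(reference, (float(rot), tilt_deg, float(psi)))
            img = img - img.mean()
            nrm = np.linalg.norm(img)
            if nrm > 0:
                img = img / nrm
            entries.append(GalleryEntry(float(rot), tilt_deg, float(psi), img))
    return entries


def _parabolic_peak(y_m1: float, y_0: float, y_p1: float) -> float:
    denom = y_m1 - 2.0 * y_0 + y_p1
    if denom >= 0 or abs(denom) < 1e-30:
        return 0.0
    d = 0.5 * (y_m1 - y_p1) / denom
    return float(np.clip(d, -0.5, 0.5))


def _best_shift(cc: np.ndarray, max_px: int) -> tuple[float, float, float]:
    """Peak of a cyclic correlation surface within +-max_px, sub-pixel refined."""
    n0, n1 = cc.shape
    sx = np.fft.fftfreq(n0, 1.0 / n0).astype(int)
    sy = np.fft.fftfreq(n1, 1.0 / n1).astype(int)
    ok0 = np.abs(sx) <= max_px
    ok1 = np.abs(sy) <= max_px
    sub = cc[np.ix_(ok0, ok1)]
    i, j = np.unravel_index(np.argmax(sub), sub.shape)
    px, py = int(sx[ok0][i]), int(sy[ok1][j])
    peak = cc[px % n0, py % n1]
    dx = _parabolic_peak(cc[(px - 1) % n0, py % n1], peak, cc[(px + 1) % n0, py % n1])
    dy = _parabolic_peak(cc[px % n0, (py - 1) % n1], peak, cc[px % n0, (py + 1) % n1])
    return px + dx, py + dy, float(peak)


def projection_match(
    stack: np.ndarray,
    reference: DensityMap,
    angular_step_deg: float,
    shift_range_A: float,
    tilt_deg: float = 90.0,
    psi_list=(0.0,),
    meta: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Align every segment to the best gallery orientation and shift.

    Returns an alignment table with one row per segment: euler angles of
    the winning gallery entry (ties go to the lowest gallery index),
    sub-pixel shift in A, and the NCC score.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3 or stack.shape[0] == 0:
        raise ValueError("stack must be a non-empty (n, box, box) array")
    if stack.shape[1] != reference.box_px:
        raise ValueError("reference box does not match segment box")
    gallery = make_gallery(reference, angular_step_deg, tilt_deg, psi_list)
    max_px = max(0, int(np.floor(shift_range_A / reference.voxel_size_A)))
    vx = reference.voxel_size_A

    gallery_ft = [np.fft.fft2(g.image) for g in gallery]
    rows = []
    for i in range(stack.shape[0]):
        img = stack[i] - stack[i].mean()
        nrm = np.linalg.norm(img)
        if nrm > 0:
            img = img / nrm
        img_ft = np.fft.fft2(img)
        best = None
        for gi, gft in enumerate(gallery_ft):
            cc = np.real(np.fft.ifft2(img_ft * np.conj(gft)))
            px, py, score = _best_shift(cc, max_px)
            if best is None or score > best[0] + 1e-12:
                best = (score, gi, px, py)
        score, gi, px, py = best
        g = gallery[gi]
        rows.append(
            {
                "segment_id": i if meta is None else int(meta.iloc[i]["segment_id"]),
                "filament_id": 0 if meta is None else int(meta.iloc[i]["filament_id"]),
                "segment_index": i if meta is None else int(meta.iloc[i]["segment_index"]),
                "axial_position_A": 0.0
                if meta is None
                else float(meta.iloc[i]["axial_position_A"]),
                "rot_deg": g.rot_deg,
                "tilt_deg": g.tilt_deg,
                "psi_deg": g.psi_deg,
                "shift_x_A": px * vx,
                "shift_y_A": py * vx,
                "cc": float(np.clip(score, -1.0, 1.0)),
                "pf_number": pd.NA,
            }
        )
    return pd.DataFrame(rows)
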