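"""Per-filament smoothing of alignment parameters.

Segment alignments along one filament vary smoothly with axial position
(the filament is a continuous polymer), so rot — unwrapped — and the two
shift components are fit per filament with low-degree polynomials;
outliers beyond ``outlier_sigma`` robust standard deviations (MAD-based)
are replaced by the fitted values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["smooth_alignments"]

_SMOOTH_COLS = ("rot_deg", "shift_x_A", "shift_y_A")


def _robust_poly_replace(x: np.ndarray, y: np.ndarray, degree: int, outlier_sigma: float):
    coeff = np.polyfit(x, y, degree)
    resid = y - np.polyval(coeff, x)
    mad = np.median(np.abs(resid - np.median(resid))) * 1.4826
    if mad < 1e-12:
        return y, np.zeros(len(y), dtype=bool)
    bad = np.abs(resid) > outlier_sigma * mad
    if not bad.any():
        return y, bad
    # refit without the outliers, then replace them with the clean fit
    if (~bad).sum() >= degree + 1:
        coeff = np.polyfit(x[~bad], y[~bad], degree)
    out = y.copy()
    out[bad] = np.polyval(coeff, x[bad])
    return out, bad


def smooth_alignments(
    table: pd.DataFrame,
    max_degree: int = 2,
    outlier_sigma: float = 3.0,
) -> pd.DataFrame:
    """Return a smoothed copy of the alignment table.

    Filaments with fewer than ``max_degree + 2`` segments are passed
    through unchanged (a degree-d fit of d+1 points is exact, so nothing
    can be smoothed). An ``is_outlier`` column marks replaced rows.
    """
    out = table.copy()
    out["is_outlier"] = False
    for fid, grp in table.groupby("filament_id"):
        if len(grp) < max_degree + 2:
            continue
        order = grp.sort_values("segment_index").index
        x = table.loc[order, "axial_position_A"].to_numpy(dtype=float)
        if np.allclose(x, x[0]):
            x = table.loc[order, "segment_index"].to_numpy(dtype=float)
        degree = min(max_degree, len(grp) - 2)
        any_bad = np.zeros(len(grp), dtype=bool)
        for col in _SMOOTH_COLS:
            y = table.loc[order, col].to_numpy(dtype=float)
            if col == "rot_deg":
                y = np.rad2deg(np.unwrap(np.deg2rad(y)))
            smoothed, bad = _robust_poly_replace(x, y, degree, outlier_sigma)
            if col == "rot_deg":
                smoothed = smoothed % 360.0
            out.loc[order, col] = smoothed
            any_bad |= bad
        out.loc[order, "is_outlier"] = any_bad
    return out
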