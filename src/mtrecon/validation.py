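"""Resolution estimation and sharpening.

Global resolution is read off the Fourier shell correlation (FSC)
between two independently refined half-maps at the 0.143 criterion;
B-factor sharpening scales Fourier amplitudes by exp(-B s^2 / 4); local
resolution slides a windowed FSC over the box (blocres-style) with a
higher threshold (0.5) appropriate to small-window statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from mtrecon.density import DensityMap

__all__ = [
    "FscCurve",
    "fsc",
    "resolution_at",
    "apply_bfactor",
    "local_resolution",
]


@dataclass
class FscCurve:
    """Per-shell Fourier correlation: frequencies in 1/A, values in [-1, 1]."""

    freq_per_A: np.ndarray
    correlation: np.ndarray
    shell_width_per_A: float
    voxel_size_A: float

    @property
    def nyquist_per_A(self) -> float:
        return 0.5 / self.voxel_size_A


def _freq_grid(n: int, voxel_size_A: float) -> np.ndarray:
    f = np.fft.fftfreq(n, d=voxel_size_A)
    return np.sqrt(f[:, None, None] ** 2 + f[None, :, None] ** 2 + f[None, None, :] ** 2)


def fsc(map_a: DensityMap, map_b: DensityMap, shell_width_px: float = 1.0) -> FscCurve:
    """Fourier shell correlation between two maps on identical grids."""
    if map_a.values.shape != map_b.values.shape or abs(
        map_a.voxel_size_A - map_b.voxel_size_A
    ) > 1e-9:
        raise ValueError("maps must share grid shape and voxel size")
    n = map_a.box_px
    fa = np.fft.fftn(map_a.values)
    fb = np.fft.fftn(map_b.values)
    smag = _freq_grid(n, map_a.voxel_size_A)
    df = shell_width_px / (n * map_a.voxel_size_A)
    nyq = 0.5 / map_a.voxel_size_A
    edges = np.arange(df, nyq + df, df)
    shell_idx = np.minimum((smag / df).astype(int), len(edges) - 1)
    cross = np.real(fa * np.conj(fb))
    pa = np.abs(fa) ** 2
    pb = np.abs(fb) ** 2
    num = np.bincount(shell_idx.ravel(), cross.ravel(), minlength=len(edges))
    da = np.bincount(shell_idx.ravel(), pa.ravel(), minlength=len(edges))
    db = np.bincount(shell_idx.ravel(), pb.ravel(), minlength=len(edges))
    denom = np.sqrt(da * db)
    corr = np.divide(num, denom, out=np.zeros_like(num), where=denom > 0)
    centers = edges - df / 2.0
    return FscCurve(centers, np.clip(corr, -1.0, 1.0), df, map_a.voxel_size_A)


@dataclass
class ResolutionResult:
    resolution_A: float
    saturated: bool = False  # curve never fell below the threshold
    undefined: bool = False  # curve never reached the threshold


def resolution_at(curve: FscCurve, threshold: float = 0.143) -> ResolutionResult:
    """Resolution at the first downward threshold crossing (interpolated).

    A curve that never drops below the threshold reports Nyquist
    (2 * voxel size) with ``saturated``; one that never exceeds it
    reports ``undefined``.
    """
    f = np.asarray(curve.freq_per_A)
    c = np.asarray(curve.correlation)
    if c.size == 0 or np.all(c < threshold):
        return ResolutionResult(np.nan, undefined=True)
    below = np.nonzero(c < threshold)[0]
    start = np.nonzero(c >= threshold)[0][0]
    below = below[below > start]
    if below.size == 0:
        return ResolutionResult(2.0 * curve.voxel_size_A, saturated=True)
    i = below[0]
    f0, f1 = f[i - 1], f[i]
    c0, c1 = c[i - 1], c[i]
    fc = f0 + (f1 - f0) * (c0 - threshold) / (c0 - c1)
    return ResolutionResult(float(1.0 / fc))


def apply_bfactor(mapp: DensityMap, b_A2: float) -> DensityMap:
    """Scale Fourier amplitudes by exp(-B s^2 / 4); negative B sharpens.

    Phases are untouched, so apply(B) then apply(-B) is the identity to
    floating-point precision.
    """
    n = mapp.box_px
    s2 = _freq_grid(n, mapp.voxel_size_A) ** 2
    ft = np.fft.fftn(mapp.values) * np.exp(-b_A2 * s2 / 4.0)
    return DensityMap(np.real(np.fft.ifftn(ft)), mapp.voxel_size_A)


def local_resolution(
    half1: DensityMap,
    half2: DensityMap,
    window_A: float,
    step_px: int = 4,
    threshold: float = 0.5,
) -> DensityMap:
    """Sliding-window FSC local-resolution map (blocres-style).

    Cubic windows of ``window_A`` are Hann-tapered, FSC'ed between the
    half-maps, and the per-window resolution at ``threshold`` is written
    at the window center; values between step positions are linearly
    interpolated. Windows where the FSC never reaches the threshold get
    the worst measurable value (the window size).
    """
    if half1.values.shape != half2.values.shape:
        raise ValueError("half-maps must share grids")
    n = half1.box_px
    vx = half1.voxel_size_A
    w = int(round(window_A / vx))
    w = max(w, 8)
    if w > n:
        raise ValueError("window larger than the box")
    hann = np.hanning(w)
    taper = hann[:, None, None] * hann[None, :, None] * hann[None, None, :]
    centers = np.arange(w // 2, n - w // 2 + 1, step_px)
    res = np.zeros((len(centers),) * 3)
    for a, ci in enumerate(centers):
        for b, cj in enumerate(centers):
            for c_, ck in enumerate(centers):
                sl = (
                    slice(ci - w // 2, ci - w // 2 + w),
                    slice(cj - w // 2, cj - w // 2 + w),
                    slice(ck - w // 2, ck - w // 2 + w),
                )
                w1 = DensityMap(half1.values[sl] * taper, vx)
                w2 = DensityMap(half2.values[sl] * taper, vx)
                r = resolution_at(fsc(w1, w2), threshold)
                res[a, b, c_] = w * vx if r.undefined else r.resolution_A
    # interpolate window-center values onto the full grid
    from scipy.interpolate import RegularGridInterpolator

    interp = RegularGridInterpolator(
        (centers, centers, centers), res, bounds_error=False, fill_value=None, method="linear"
    )
    ax = np.arange(n)
    pts = np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), axis=-1).reshape(-1, 3)
    pts = np.clip(pts, centers[0], centers[-1])
    full = interp(pts).reshape(n, n, n)
    return DensityMap(full, vx)
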