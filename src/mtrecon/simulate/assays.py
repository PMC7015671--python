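"""Synthetic single-molecule and kinetics assay datasets.

Four dataset families mirror the quantitative experiments around the
structural work: steady-state MT-stimulated ATPase curves
(Michaelis-Menten), single-motor velocity/intensity samples (1-2
component Gaussian mixtures) with right-censored exponential run
lengths, optical-trap plateau-force versus MT-overlap-length pairs, and
two-compartment cell images for spindle:cytoplasm intensity ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MMDataset",
    "MotilitySample",
    "ForceDataset",
    "RoiImage",
    "gen_mm_dataset",
    "gen_motility_dataset",
    "gen_force_dataset",
    "gen_roi_image",
]


@dataclass
class MMDataset:
    """Steady-state ATPase rates versus MT concentration."""

    mt_conc_nM: np.ndarray
    rate_per_s: np.ndarray
    kcat_true: float
    km_true: float


@dataclass
class MotilitySample:
    """Single-motor velocities, fluorescence intensities and run lengths."""

    velocities_nm_s: np.ndarray
    intensities_au: np.ndarray
    run_lengths_um: np.ndarray
    censored: np.ndarray  # bool, True where the run hit the observation limit
    censor_limit_um: float


@dataclass
class ForceDataset:
    """Optical-trap plateau force versus MT overlap-zone length."""

    overlap_um: np.ndarray
    plateau_pN: np.ndarray
    slope_true: float


@dataclass
class RoiImage:
    """Two-compartment cell image with spindle/cell/background ROI masks."""

    pixels: np.ndarray
    spindle_mask: np.ndarray
    cell_mask: np.ndarray
    background_rois: np.ndarray
    true_ratio: float


def gen_mm_dataset(
    kcat_per_s: float,
    km_nM: float,
    concs_nM,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> MMDataset:
    """Michaelis-Menten rates v = kcat*S/(Km+S) with multiplicative noise.

    ``noise_cv`` is the coefficient of variation of the multiplicative
    Gaussian error (1 + eps), matching how ATPase replicates scatter.
    """
    concs = np.asarray(concs_nM, dtype=float)
    if concs.size == 0:
        raise ValueError("concs_nM must be non-empty")
    if np.any(concs <= 0):
        raise ValueError("concentrations must be > 0")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    v = kcat_per_s * concs / (km_nM + concs)
    if noise_cv > 0:
        v = v * (1.0 + rng.normal(0.0, noise_cv, size=concs.shape))
    return MMDataset(concs, v, kcat_true=kcat_per_s, km_true=km_nM)


def gen_motility_dataset(
    components,
    n: int,
    runlen_mean_um: float = 8.0,
    censor_limit_um: float = 25.0,
    intensity_components=None,
    seed: int = 0,
) -> MotilitySample:
    """Sample motor velocities from a Gaussian mixture plus censored runs.

    ``components`` is a sequence of (mean, sd, weight) with weights
    summing to 1. Run lengths are exponential with ``runlen_mean_um``,
    right-censored at ``censor_limit_um`` (censored records are recorded
    at the limit with a flag). Intensities default to the velocity
    mixture shape scaled arbitrarily when not given.
    """
    comps = [(float(m), float(s), float(w)) for m, s, w in components]
    ws = np.array([w for _, _, w in comps])
    if abs(ws.sum() - 1.0) > 1e-9:
        raise ValueError(f"component weights must sum to 1, got {ws.sum()}")
    if any(s <= 0 for _, s, _ in comps):
        raise ValueError("component sds must be > 0")
    rng = np.random.default_rng(seed)
    labels = rng.choice(len(comps), size=n, p=ws)
    means = np.array([m for m, _, _ in comps])
    sds = np.array([s for _, s, _ in comps])
    velocities = rng.normal(means[labels], sds[labels])

    if intensity_components is None:
        intensity_components = [(1000.0 * (k + 1), 100.0, w) for k, (_, _, w) in enumerate(comps)]
    iws = np.array([w for _, _, w in intensity_components])
    ilabels = rng.choice(len(intensity_components), size=n, p=iws / iws.sum())
    imeans = np.array([m for m, _, _ in intensity_components])
    isds = np.array([s for _, s, _ in intensity_components])
    intensities = rng.normal(imeans[ilabels], isds[ilabels])

    raw = rng.exponential(runlen_mean_um, size=n)
    censored = raw >= censor_limit_um
    runs = np.where(censored, censor_limit_um, raw)
    return MotilitySample(velocities, intensities, runs, censored, censor_limit_um)


def gen_force_dataset(
    slope_pN_per_um: float,
    n: int,
    overlap_range_um=(1.0, 8.0),
    noise_sd_pN: float = 0.0,
    intercept_pN: float = 0.0,
    seed: int = 0,
) -> ForceDataset:
    """Plateau forces rising linearly with MT overlap length plus noise."""
    if n < 2:
        raise ValueError("n must be >= 2")
    lo, hi = overlap_range_um
    if not (hi > lo):
        raise ValueError("degenerate overlap range")
    rng = np.random.default_rng(seed)
    overlap = rng.uniform(lo, hi, size=n)
    force = intercept_pN + slope_pN_per_um * overlap
    if noise_sd_pN > 0:
        force = force + rng.normal(0.0, noise_sd_pN, size=n)
    return ForceDataset(overlap, force, slope_true=slope_pN_per_um)


def gen_roi_image(
    spindle_mean: float,
    cyto_mean: float,
    bg_mean: float,
    noise_sd: float = 0.0,
    shape=(128, 128),
    seed: int = 0,
) -> RoiImage:
    """Two-compartment cell image: elliptical cell, inner spindle, corner
    background ROIs; pixel = region mean + Gaussian noise.

    The noiseless background-subtracted spindle:cytoplasm ratio equals
    (spindle_mean - bg_mean) / (cyto_mean - bg_mean) by construction.
    """
    ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    cell = ((yy - cy) / (0.38 * ny)) ** 2 + ((xx - cx) / (0.38 * nx)) ** 2 <= 1.0
    spindle = ((yy - cy) / (0.16 * ny)) ** 2 + ((xx - cx) / (0.10 * nx)) ** 2 <= 1.0
    spindle &= cell
    k = max(3, int(0.1 * min(ny, nx)))
    bg = np.zeros(shape, dtype=bool)
    bg[1 : 1 + k, 1 : 1 + k] = True
    bg[-1 - k : -1, -1 - k : -1] = True
    if np.any(bg & cell):
        raise ValueError("background ROIs overlap the cell mask")
    img = np.full(shape, bg_mean, dtype=float)
    img[cell] = cyto_mean
    img[spindle] = spindle_mean
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=shape)
    denom = cyto_mean - bg_mean
    true_ratio = (spindle_mean - bg_mean) / denom if denom != 0 else np.nan
    return RoiImage(img, spindle, cell, bg, true_ratio)
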