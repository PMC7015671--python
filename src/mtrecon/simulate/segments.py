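"""Simulated MT segment stacks with ground-truth alignment metadata.

Filaments lie in the ice plane (tilt ~ 90 deg) and overlapping segments
are extracted every ``spacing_A`` along the filament axis. Because the
monomer lattice is an exact helix (skew 0), translating the viewing
window by dz along the axis is identical to spinning the lattice by
dz / rise * twist about its axis, so each segment is a projection of the
canonical volume at an advanced rot angle. Optional phase-contrast CTF
and Gaussian white noise at a requested footprint SNR complete the
forward model.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from mtrecon.density import DensityMap
from mtrecon.lattice import LatticeSpec, helical_params_from_spec
from mtrecon.simulate.volume import DensitySpec, build_volume, project

__all__ = ["CTFParams", "SegmentSimulation", "simulate_segment_stack", "apply_ctf"]


@dataclass(frozen=True)
class CTFParams:
    """Simple radial CTF: defocus phase term plus amplitude contrast.

    No astigmatism, spherical aberration or envelope — synthetic data
    carries known truth, so the transfer function only needs to be a
    realistic sign-flipping modulation.
    """

    defocus_um: float = 1.5
    voltage_kV: float = 300.0
    amplitude_contrast: float = 0.07

    @property
    def wavelength_A(self) -> float:
        # relativistic electron wavelength
        v = self.voltage_kV * 1e3
        return 12.2639 / np.sqrt(v * (1.0 + 0.97845e-6 * v))


def apply_ctf(image: np.ndarray, voxel_size_A: float, ctf: CTFParams) -> np.ndarray:
    """Multiply the image by the radial CTF in Fourier space."""
    n = image.shape[0]
    f = np.fft.fftfreq(n, d=voxel_size_A)
    s2 = f[:, None] ** 2 + f[None, :] ** 2
    chi = np.pi * ctf.wavelength_A * ctf.defocus_um * 1e4 * s2
    a = ctf.amplitude_contrast
    h = -(np.sqrt(1.0 - a * a) * np.sin(chi) + a * np.cos(chi))
    return np.real(np.fft.ifft2(np.fft.fft2(image) * h))


@dataclass
class SegmentSimulation:
    """A simulated stack plus everything needed to verify it."""

    images: np.ndarray  # (n_segments, box, box)
    meta: pd.DataFrame
    volumes: dict  # filament_id -> DensityMap
    clean_images: np.ndarray
    footprint: np.ndarray  # boolean in-plane MT footprint mask
    voxel_size_A: float


def simulate_segment_stack(
    lattice: LatticeSpec,
    dens: DensitySpec,
    n_filaments: int,
    filament_len_A: float,
    spacing_A: float = 80.0,
    snr: float = np.inf,
    ctf_params: CTFParams | None = None,
    seed: int = 0,
    shift_jitter_A: float = 0.0,
    tilt_jitter_deg: float = 0.0,
    psi_jitter_deg: float = 0.0,
) -> SegmentSimulation:
    """Simulate overlapping segments of in-plane MT filaments.

    Per filament ``floor((filament_len_A - box_extent)/spacing_A) + 1``
    segments are produced; each stores its true Euler angles, shifts, PF
    number, and the seed, so every downstream stage can be scored against
    ground truth. ``snr`` is signal variance over noise variance inside
    the projected MT footprint; ``np.inf`` means noiseless.
    """
    if not (snr > 0):
        raise ValueError("snr must be > 0 (use np.inf for noiseless)")
    box_extent = dens.box_px * dens.voxel_size_A
    if filament_len_A < box_extent:
        raise ValueError("filament_len_A must be at least the box extent")
    n_seg = int(np.floor((filament_len_A - box_extent) / spacing_A)) + 1

    rng = np.random.default_rng(seed)
    hp = helical_params_from_spec(lattice)

    images, clean, rows = [], [], []
    volumes = {}
    footprint = None
    seg_id = 0
    for fid in range(n_filaments):
        vol, _occ = build_volume(lattice, dens, seed=int(rng.integers(2**31)))
        volumes[fid] = vol
        if footprint is None:
            p0 = project(vol, (0.0, 90.0, 0.0))
            footprint = np.abs(p0) > 0.05 * np.abs(p0).max()
        rot0 = float(rng.uniform(0.0, 360.0))
        psi0 = float(rng.normal(0.0, psi_jitter_deg)) if psi_jitter_deg else 0.0
        defocus = ctf_params.defocus_um if ctf_params is not None else np.nan
        for s in range(n_seg):
            z = s * spacing_A
            rot = (rot0 + hp.twist_deg * z / hp.rise_A) % 360.0
            tilt = 90.0 + (float(rng.normal(0.0, tilt_jitter_deg)) if tilt_jitter_deg else 0.0)
            sx, sy = (
                rng.uniform(-shift_jitter_A, shift_jitter_A, size=2)
                if shift_jitter_A
                else (0.0, 0.0)
            )
            img = project(vol, (rot, tilt, psi0), (float(sx), float(sy)))
            if ctf_params is not None:
                img = apply_ctf(img, dens.voxel_size_A, ctf_params)
            clean.append(img)
            if np.isfinite(snr):
                sig_var = img[footprint].var()
                sigma = np.sqrt(sig_var / snr)
                img = img + rng.normal(0.0, sigma, size=img.shape)
            images.append(img)
            rows.append(
                {
                    "segment_id": seg_id,
                    "filament_id": fid,
                    "segment_index": s,
                    "axial_position_A": z,
                    "rot_deg": rot,
                    "tilt_deg": tilt,
                    "psi_deg": psi0,
                    "shift_x_A": float(sx),
                    "shift_y_A": float(sy),
                    "pf_number_true": lattice.n_pf,
                    "defocus_um": defocus,
                    "seed": seed,
                }
            )
            seg_id += 1
    return SegmentSimulation(
        images=np.array(images),
        meta=pd.DataFrame(rows),
        volumes=volumes,
        clean_images=np.array(clean),
        footprint=footprint,
        voxel_size_A=dens.voxel_size_A,
    )
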