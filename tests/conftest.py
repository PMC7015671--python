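"""Shared desk-scale fixtures.

All pipeline tests run on a reduced MT geometry (radius 80 A, 64-96 px
boxes at 4 A/voxel) so the whole suite stays within minutes while every
stage still sees a genuinely helical, decorated lattice.
"""

import numpy as np
import pytest

from mtrecon.lattice import LatticeSpec, helical_params_from_spec
from mtrecon.simulate import DensitySpec, build_volume, simulate_segment_stack


@pytest.fixture(scope="session")
def lattice14():
    return LatticeSpec(n_pf=14, radius_A=80.0)


@pytest.fixture(scope="session")
def dens_plain():
    """Undecorated tubulin-only density spec (64 px box)."""
    return DensitySpec(voxel_size_A=4.0, box_px=64, motor_occupancy=0.0)


@pytest.fixture(scope="session")
def volume14(lattice14, dens_plain):
    vol, occ = build_volume(lattice14, dens_plain, seed=1)
    return vol, occ


@pytest.fixture(scope="session")
def helical14(lattice14):
    return helical_params_from_spec(lattice14)


@pytest.fixture(scope="session")
def noiseless_stack(lattice14, dens_plain):
    """Three noiseless filaments, 7 segments each."""
    return simulate_segment_stack(
        lattice14, dens_plain, n_filaments=3, filament_len_A=880.0,
        spacing_A=80.0, snr=np.inf, seed=2,
    )
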