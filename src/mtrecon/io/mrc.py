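"""Minimal MRC2014 reader/writer (mode 2, little-endian).

Covers exactly what the pipeline produces: cubic float32 volumes and 2D
image stacks with a voxel size, origin at the box center. Arrays are
indexed [ix, iy, iz] in memory (stacks: [section, ix, iy]); on disk the
x axis is fastest as MAPC/MAPR/MAPS = 1/2/3 requires. Round-trips are
bitwise-stable in the data and in every header field we own.
"""

from __future__ import annotations

import struct

import numpy as np

from mtrecon.density import DensityMap

__all__ = ["write_map", "read_map", "write_stack", "read_stack"]

_HEADER_BYTES = 1024
_MODE_FLOAT32 = 2


def _pack_header(nx, ny, nz, voxel_size_A, is_volume, dmin, dmax, dmean, rms):
    h = bytearray(_HEADER_BYTES)
    struct.pack_into("<3i", h, 0, nx, ny, nz)
    struct.pack_into("<i", h, 12, _MODE_FLOAT32)
    struct.pack_into("<3i", h, 16, 0, 0, 0)  # nxstart
    mz = nz if is_volume else 1
    struct.pack_into("<3i", h, 28, nx, ny, mz)  # mx my mz
    struct.pack_into("<3f", h, 40, nx * voxel_size_A, ny * voxel_size_A, mz * voxel_size_A)
    struct.pack_into("<3f", h, 52, 90.0, 90.0, 90.0)
    struct.pack_into("<3i", h, 64, 1, 2, 3)  # mapc mapr maps
    struct.pack_into("<3f", h, 76, dmin, dmax, dmean)
    struct.pack_into("<i", h, 88, 1 if is_volume else 0)  # ispg
    struct.pack_into("<i", h, 92, 0)  # nsymbt
    struct.pack_into("<i", h, 108, 20140)  # nversion
    struct.pack_into("<3f", h, 196, 0.0, 0.0, 0.0)  # origin (box-center convention)
    h[208:212] = b"MAP "
    h[212:216] = bytes([0x44, 0x44, 0x00, 0x00])  # little-endian machine stamp
    struct.pack_into("<f", h, 216, rms)
    struct.pack_into("<i", h, 220, 0)  # nlabl
    return bytes(h)


def write_map(path, mapp: DensityMap) -> None:
    """Write a cubic volume as MRC2014 mode-2."""
    v = np.asarray(mapp.values, dtype=np.float32)
    nx, ny, nz = v.shape
    header = _pack_header(
        nx, ny, nz, mapp.voxel_size_A, True,
        float(v.min()), float(v.max()), float(v.mean()), float(v.std()),
    )
    with open(path, "wb") as f:
        f.write(header)
        # disk order: x fastest -> write the transpose contiguously
        f.write(np.ascontiguousarray(v.T).tobytes())


def _read_header(raw: bytes, path):
    if len(raw) < _HEADER_BYTES:
        raise ValueError(f"{path}: truncated MRC header ({len(raw)} bytes)")
    if raw[208:212] != b"MAP ":
        raise ValueError(f"{path}: missing 'MAP ' signature; not an MRC2014 file")
    nx, ny, nz = struct.unpack_from("<3i", raw, 0)
    (mode,) = struct.unpack_from("<i", raw, 12)
    if mode != _MODE_FLOAT32:
        raise ValueError(f"{path}: unsupported MRC mode {mode} (only mode 2)")
    mx, my, mz = struct.unpack_from("<3i", raw, 28)
    ca, cb, cc = struct.unpack_from("<3f", raw, 40)
    (nsymbt,) = struct.unpack_from("<i", raw, 92)
    voxel = ca / mx if mx > 0 else 1.0
    return nx, ny, nz, nsymbt, voxel


def read_map(path) -> DensityMap:
    with open(path, "rb") as f:
        raw = f.read()
    nx, ny, nz, nsymbt, voxel = _read_header(raw, path)
    need = _HEADER_BYTES + nsymbt + nx * ny * nz * 4
    if len(raw) < need:
        raise ValueError(f"{path}: truncated data ({len(raw)} of {need} bytes)")
    data = np.frombuffer(raw, dtype="<f4", count=nx * ny * nz, offset=_HEADER_BYTES + nsymbt)
    vals = data.reshape(nz, ny, nx).T.astype(np.float64)
    return DensityMap(vals, voxel)


def write_stack(path, images: np.ndarray, voxel_size_A: float) -> None:
    """Write an (n, box, box) image stack as an MRC2014 stack (mz = 1)."""
    imgs = np.asarray(images, dtype=np.float32)
    n, bx, by = imgs.shape
    header = _pack_header(
        bx, by, n, voxel_size_A, False,
        float(imgs.min()), float(imgs.max()), float(imgs.mean()), float(imgs.std()),
    )
    with open(path, "wb") as f:
        f.write(header)
        f.write(np.ascontiguousarray(imgs.transpose(0, 2, 1)).tobytes())


def read_stack(path) -> tuple[np.ndarray, float]:
    with open(path, "rb") as f:
        raw = f.read()
    nx, ny, nz, nsymbt, voxel = _read_header(raw, path)
    need = _HEADER_BYTES + nsymbt + nx * ny * nz * 4
    if len(raw) < need:
        raise ValueError(f"{path}: truncated data ({len(raw)} of {need} bytes)")
    data = np.frombuffer(raw, dtype="<f4", count=nx * ny * nz, offset=_HEADER_BYTES + nsymbt)
    imgs = data.reshape(nz, ny, nx).transpose(0, 2, 1).astype(np.float64)
    return imgs, voxel
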