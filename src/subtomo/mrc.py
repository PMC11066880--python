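"""MRC2014 volume I/O.

Volumes are exchanged as MRC2014 files with mode 0 (signed 8-bit), mode 1
(16-bit integer) or mode 2 (32-bit float); the voxel size is written to the
header.  In memory volumes are numpy arrays indexed (x, y, z); on disk the
x index runs fastest (columns), per the MRC convention.

Integer modes store a linear rescaling of the data; the scale and offset
are chosen to span the dtype range and are recorded in the returned
:class:`MrcScale` so callers can invert the quantization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["read_mrc", "write_mrc", "MrcScale"]

_MODE_DTYPES = {0: np.int8, 1: np.int16, 2: np.float32}
_HEADER_BYTES = 1024


@dataclass
class MrcScale:
    """Linear quantization record: stored = round((data - offset) * scale) + int_min."""

    scale: float = 1.0
    offset: float = 0.0
    int_min: int = 0

    def decode(self, stored: np.ndarray) -> np.ndarray:
        return (stored.astype(np.float64) - self.int_min) / self.scale + self.offset


def _quantize(data: np.ndarray, mode: int):
    dtype = _MODE_DTYPES[mode]
    if mode == 2:
        return data.astype(np.float32), MrcScale()
    info = np.iinfo(dtype)
    lo, hi = float(data.min()), float(data.max())
    if hi <= lo:
        return np.zeros(data.shape, dtype=dtype), MrcScale(1.0, lo, info.min)
    scale = (info.max - info.min) / (hi - lo)
    stored = (np.round((data - lo) * scale) + info.min).astype(dtype)
    return stored, MrcScale(scale, lo, info.min)


def write_mrc(path, data: np.ndarray, voxel_size: float = 1.0, mode: int = 2) -> MrcScale:
    """Write a volume; returns the quantization applied (identity for mode 2)."""
    if mode not in _MODE_DTYPES:
        raise ValueError(f"unsupported MRC mode {mode}; use 0, 1 or 2")
    data = np.asarray(data, dtype=np.float32)
    if data.ndim != 3:
        raise ValueError("expected a 3D volume")
    stored, qscale = _quantize(data, mode)
    nx, ny, nz = data.shape
    header = np.zeros(256, dtype=np.int32)
    fheader = header.view(np.float32)
    header[0:3] = (nx, ny, nz)  # columns, rows, sections with x fastest
    header[3] = mode
    header[7:10] = (nx, ny, nz)  # sampling grid
    fheader[10:13] = (nx * voxel_size, ny * voxel_size, nz * voxel_size)
    fheader[13:16] = (90.0, 90.0, 90.0)
    header[16:19] = (1, 2, 3)  # axis order: x=cols, y=rows, z=sections
    fheader[19] = float(stored.min())
    fheader[20] = float(stored.max())
    fheader[21] = float(stored.mean())
    header[22] = 1  # ISPG: 3D volume
    header[52] = int.from_bytes(b"MAP ", "little")
    header[53] = int.from_bytes(bytes([0x44, 0x44, 0x00, 0x00]), "little")  # little-endian
    fheader[54] = float(stored.astype(np.float64).std())
    with open(path, "wb") as fh:
        fh.write(header.tobytes())
        # disk layout is (z, y, x) C-order == x fastest
        fh.write(np.ascontiguousarray(stored.transpose(2, 1, 0)).tobytes())
    return qscale


def read_mrc(path, dequantize: bool = False):
    """Read a volume; returns ``(data, voxel_size)`` with data indexed (x, y, z).

    Integer modes are returned as stored (``dequantize`` has no effect on the
    values because the quantization offset/scale are not part of the MRC
    header; use the :class:`MrcScale` returned by :func:`write_mrc`).
    """
    with open(path, "rb") as fh:
        raw = fh.read()
    header = np.frombuffer(raw[:_HEADER_BYTES], dtype=np.int32).copy()
    fheader = header.view(np.float32)
    nx, ny, nz = (int(v) for v in header[0:3])
    mode = int(header[3])
    if mode not in _MODE_DTYPES:
        raise ValueError(f"unsupported MRC mode {mode}")
    nsymbt = int(header[23])
    dtype = _MODE_DTYPES[mode]
    count = nx * ny * nz
    data = np.frombuffer(
        raw[_HEADER_BYTES + nsymbt : _HEADER_BYTES + nsymbt + count * dtype().itemsize],
        dtype=dtype,
    ).reshape(nz, ny, nx)
    voxel = float(fheader[10]) / nx if nx else 1.0
    return np.ascontiguousarray(data.transpose(2, 1, 0)), voxel
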