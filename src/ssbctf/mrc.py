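"""Minimal MRC2014 reader/writer (mode 2, float32).

Covers what this package needs: single images, image stacks and volumes
with correct pixel-size (cella) headers, written in little-endian float32.
Reading additionally accepts modes 0 (int8), 1 (int16) and 6 (uint16).
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

_HEADER_SIZE = 1024
_MODE_DTYPES = {0: np.int8, 1: np.int16, 2: np.float32, 6: np.uint16}
# little-endian machine stamp per the MRC2014 spec
_MACHST_LE = b"\x44\x41\x00\x00"


class MrcError(ValueError):
    """Malformed MRC header or unsupported layout."""


def write_mrc(data: np.ndarray, pixel_size: float, path) -> None:
    """Write an image (2D), stack or volume (3D) as MRC2014 mode 2.

    Axis order follows the usual numpy convention: a 3D array is stored as
    ``nz`` sections of ``ny x nx``; a stack is distinguished from a volume
    by ispg (0 vs 1).  2D arrays are written as single images.
    """
    arr = np.asarray(data, dtype=np.float32)
    if arr.ndim == 2:
        arr = arr[None]
        is_volume = False
    elif arr.ndim == 3:
        is_volume = arr.shape[0] == arr.shape[1] == arr.shape[2]
    else:
        raise MrcError(f"can only write 2D or 3D arrays, got ndim={arr.ndim}")
    if pixel_size <= 0:
        raise MrcError("pixel size must be positive")
    nz, ny, nx = arr.shape

    header = bytearray(_HEADER_SIZE)
    struct.pack_into("<3i", header, 0, nx, ny, nz)
    struct.pack_into("<i", header, 12, 2)  # mode
    struct.pack_into("<3i", header, 28, nx, ny, nz)  # mx, my, mz
    struct.pack_into(
        "<3f", header, 40, nx * pixel_size, ny * pixel_size, nz * pixel_size
    )  # cella
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)  # cellb
    struct.pack_into("<3i", header, 64, 1, 2, 3)  # mapc, mapr, maps
    struct.pack_into(
        "<3f", header, 76, float(arr.min()), float(arr.max()), float(arr.mean())
    )
    struct.pack_into("<i", header, 88, 1 if is_volume else 0)  # ispg
    struct.pack_into("<i", header, 92, 0)  # nsymbt
    header[208:212] = b"MAP "
    header[212:216] = _MACHST_LE
    struct.pack_into("<f", header, 216, float(arr.std()))
    struct.pack_into("<i", header, 220, 1)  # nlabl
    label = b"ssbctf"
    header[224 : 224 + len(label)] = label

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(arr.tobytes())


def read_mrc(path):
    """Read an MRC2014 file -> (data, pixel_size).

    Single-section files come back 2D; stacks/volumes 3D (nz, ny, nx).
    Raises :class:`MrcError` naming the offending header field on damage.
    """
    raw = Path(path).read_bytes()
    if len(raw) < _HEADER_SIZE:
        raise MrcError("file shorter than the 1024-byte MRC header")
    if raw[208:212] != b"MAP ":
        raise MrcError(f"bad MAP identifier {raw[208:212]!r} at byte 208")
    machst = raw[212:214]
    if machst == b"\x44\x41" or machst == b"\x44\x44":
        order = "<"
    elif machst == b"\x11\x11":
        order = ">"
    else:
        raise MrcError(f"unrecognised machine stamp {raw[212:216]!r}")
    nx, ny, nz = struct.unpack_from(f"{order}3i", raw, 0)
    (mode,) = struct.unpack_from(f"{order}i", raw, 12)
    if mode not in _MODE_DTYPES:
        raise MrcError(f"unsupported mode {mode}")
    if min(nx, ny, nz) <= 0:
        raise MrcError(f"non-positive dimensions nx,ny,nz = {nx},{ny},{nz}")
    mx, my, mz = struct.unpack_from(f"{order}3i", raw, 28)
    xlen, ylen, zlen = struct.unpack_from(f"{order}3f", raw, 40)
    (nsymbt,) = struct.unpack_from(f"{order}i", raw, 92)
    if mx <= 0 or xlen <= 0:
        pixel_size = 1.0
    else:
        pixel_size = xlen / mx

    dtype = np.dtype(_MODE_DTYPES[mode]).newbyteorder(order)
    offset = _HEADER_SIZE + nsymbt
    count = nx * ny * nz
    if len(raw) < offset + count * dtype.itemsize:
        raise MrcError("file truncated: fewer data bytes than nx*ny*nz")
    data = np.frombuffer(raw, dtype=dtype, count=count, offset=offset)
    data = data.reshape(nz, ny, nx).astype(np.float32)
    if nz == 1:
        data = data[0]
    return data, float(pixel_size)
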