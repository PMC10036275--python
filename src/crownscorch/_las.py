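"""Minimal LAS 1.2 reader/writer for RGB point clouds.

Supports point record formats 2 and 3 (XYZ + RGB), which is all the pipeline
needs. Coordinates are stored with 1-mm scale; colors are stored in the LAS
16-bit RGB fields at their native values (8-bit clouds keep 0-255 values, as
many photogrammetry exporters do), and the bit depth is re-inferred on read
from the value range.
"""

from __future__ import annotations

import struct

import numpy as np

from .cloud import ColoredPointCloud

_HEADER_SIZE = 227
_POINT_DTYPE = np.dtype(
    [
        ("X", "<i4"),
        ("Y", "<i4"),
        ("Z", "<i4"),
        ("intensity", "<u2"),
        ("flags", "u1"),
        ("classification", "u1"),
        ("scan_angle", "i1"),
        ("user_data", "u1"),
        ("point_source", "<u2"),
        ("red", "<u2"),
        ("green", "<u2"),
        ("blue", "<u2"),
    ]
)  # point format 2, 26 bytes


def write_las(cloud: ColoredPointCloud, path) -> None:
    n = len(cloud)
    scale = 0.001
    if n:
        off = np.array([cloud.x.min(), cloud.y.min(), cloud.z.min()])
        mins = np.array([cloud.x.min(), cloud.y.min(), cloud.z.min()])
        maxs = np.array([cloud.x.max(), cloud.y.max(), cloud.z.max()])
    else:
        off = mins = maxs = np.zeros(3)

    header = bytearray(_HEADER_SIZE)
    header[0:4] = b"LASF"
    header[24] = 1  # version major
    header[25] = 2  # version minor
    header[26:26 + 11] = b"crownscorch"
    header[58:58 + 11] = b"crownscorch"
    struct.pack_into("<H", header, 94, _HEADER_SIZE)
    struct.pack_into("<I", header, 96, _HEADER_SIZE)  # offset to point data
    struct.pack_into("<I", header, 100, 0)  # no VLRs
    header[104] = 2  # point data format
    struct.pack_into("<H", header, 105, _POINT_DTYPE.itemsize)
    struct.pack_into("<I", header, 107, n)
    struct.pack_into("<I", header, 111, n)  # points by return, first return
    struct.pack_into("<3d", header, 131, scale, scale, scale)
    struct.pack_into("<3d", header, 155, *off)
    struct.pack_into(
        "<6d", header, 179, maxs[0], mins[0], maxs[1], mins[1], maxs[2], mins[2]
    )

    rec = np.zeros(n, dtype=_POINT_DTYPE)
    rec["X"] = np.rint((cloud.x - off[0]) / scale)
    rec["Y"] = np.rint((cloud.y - off[1]) / scale)
    rec["Z"] = np.rint((cloud.z - off[2]) / scale)
    rec["flags"] = 0b00001001  # return 1 of 1
    rec["red"], rec["green"], rec["blue"] = cloud.r, cloud.g, cloud.b
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(rec.tobytes())


def read_las(path) -> ColoredPointCloud:
    with open(path, "rb") as fh:
        header = fh.read(_HEADER_SIZE)
        if header[:4] != b"LASF":
            raise ValueError(f"{path}: not a LAS file")
        point_format = header[104] & 0x3F
        if point_format not in (2, 3):
            raise ValueError(
                f"{path}: point format {point_format} has no RGB; formats 2/3 required"
            )
        rec_len = struct.unpack_from("<H", header, 105)[0]
        n = struct.unpack_from("<I", header, 107)[0]
        offset_to_points = struct.unpack_from("<I", header, 96)[0]
        scale = struct.unpack_from("<3d", header, 131)
        off = struct.unpack_from("<3d", header, 155)
        fh.seek(offset_to_points)
        raw = fh.read(rec_len * n)

    base = _POINT_DTYPE.itemsize + (8 if point_format == 3 else 0)  # fmt3 adds GPS time
    if rec_len < base:
        raise ValueError(f"{path}: point record length {rec_len} too short")
    arr = np.frombuffer(raw, dtype=np.uint8).reshape(n, rec_len)
    core = arr[:, :20].copy().view(np.dtype(_POINT_DTYPE.descr[:9])).reshape(n)
    rgb_off = 20 + (8 if point_format == 3 else 0)
    rgb = (
        arr[:, rgb_off:rgb_off + 6]
        .copy()
        .view(np.dtype("<u2"))
        .reshape(n, 3)
        .astype(int)
    )
    depth = 8 if (n == 0 or rgb.max() <= 255) else 16
    return ColoredPointCloud(
        core["X"] * scale[0] + off[0],
        core["Y"] * scale[1] + off[1],
        core["Z"] * scale[2] + off[2],
        rgb[:, 0],
        rgb[:, 1],
        rgb[:, 2],
        bit_depth=depth,
    )
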