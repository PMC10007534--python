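"""Minimal C3D motion-capture file codec.

C3D is the biomechanics interchange format: a 512-byte-block binary layout
with a header block, a self-describing parameter section (groups such as
``POINT`` with parameters like ``LABELS``, ``RATE``, ``UNITS``) and a data
section of per-frame marker coordinates plus a residual word.

This codec covers the subset the package needs: 3D point data without
analog channels.  Files are written in the Intel (little-endian,
IEEE-float) dialect with ``POINT:UNITS = "mm"``; reading supports Intel and
SGI/MIPS (big-endian) processor types, both floating-point and scaled
integer storage.  The legacy DEC floating-point dialect is not supported.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass

import numpy as np

__all__ = ["C3DContent", "read_c3d_file", "write_c3d_file"]

_BLOCK = 512
_PROC_INTEL = 84
_PROC_SGI = 86


@dataclass
class C3DContent:
    """Raw decoded content of a C3D file."""

    labels: list[str]
    points: np.ndarray       # frames x markers x 3 (in file units)
    residuals: np.ndarray    # frames x markers; negative = invalid sample
    rate: float
    units: str               # "mm" or "m"


# ---------------------------------------------------------------------------
# writing


def _param_record(name: bytes, group_id: int, dtype: int,
                  dims: bytes, data: bytes) -> bytes:
    rec = struct.pack("bb", len(name), group_id) + name
    body = struct.pack("b", dtype) + struct.pack("B", len(dims)) + dims + data
    body += b"\x00"  # zero-length description
    rec += struct.pack("<h", 2 + len(body)) + body
    return rec


def _group_record(name: bytes, group_id: int) -> bytes:
    rec = struct.pack("bb", len(name), -group_id) + name
    body = b"\x00"  # zero-length description
    rec += struct.pack("<h", 2 + len(body)) + body
    return rec


def write_c3d_file(path, labels: list[str], points: np.ndarray,
                   rate: float = 100.0, units: str = "mm",
                   residuals: np.ndarray | None = None) -> None:
    """Write a float Intel C3D file with the given marker trajectories."""
    points = np.asarray(points, dtype=np.float32)
    if points.ndim != 3 or points.shape[2] != 3:
        raise ValueError(f"points must be frames x markers x 3, got {points.shape}")
    n_frames, n_pts = points.shape[:2]
    if n_frames == 0:
        raise ValueError("cannot write a trial with zero frames")
    if n_pts != len(labels):
        raise ValueError("label count does not match marker axis")
    if residuals is None:
        residuals = np.zeros((n_frames, n_pts), dtype=np.float32)

    label_len = max(4, max(len(l) for l in labels))
    label_blob = b"".join(l.ljust(label_len).encode("ascii") for l in labels)

    params = b"".join([
        _group_record(b"POINT", 1),
        _param_record(b"USED", 1, 2, b"", struct.pack("<h", n_pts)),
        _param_record(b"FRAMES", 1, 2, b"", struct.pack("<h", n_frames)),
        _param_record(b"RATE", 1, 4, b"", struct.pack("<f", rate)),
        _param_record(b"SCALE", 1, 4, b"", struct.pack("<f", -1.0)),
        _param_record(b"UNITS", 1, -1, struct.pack("B", len(units)),
                      units.encode("ascii")),
        _param_record(b"LABELS", 1, -1,
                      struct.pack("BB", label_len, n_pts), label_blob),
        _group_record(b"ANALOG", 2),
        _param_record(b"USED", 2, 2, b"", struct.pack("<h", 0)),
    ])
    # DATA_START is appended once the parameter section size is known; its
    # own record length is fixed, so account for it up front.
    ds_rec_len = len(_param_record(b"DATA_START", 1, 2, b"",
                                   struct.pack("<h", 0)))
    n_param_blocks = -(-(4 + len(params) + ds_rec_len + 4) // _BLOCK)
    data_start_block = 2 + n_param_blocks
    params += _param_record(b"DATA_START", 1, 2, b"",
                            struct.pack("<h", data_start_block))
    params += b"\x00\x00"  # terminating record (name length 0)

    header = bytearray(_BLOCK)
    struct.pack_into("BB", header, 0, 2, 0x50)
    struct.pack_into("<h", header, 2, n_pts)
    struct.pack_into("<h", header, 4, 0)              # analog per frame
    struct.pack_into("<h", header, 6, 1)              # first frame
    struct.pack_into("<h", header, 8, n_frames)       # last frame
    struct.pack_into("<h", header, 10, 10)            # max interpolation gap
    struct.pack_into("<f", header, 12, -1.0)          # scale: float data
    struct.pack_into("<h", header, 16, data_start_block)
    struct.pack_into("<h", header, 18, 0)             # analog samples/frame
    struct.pack_into("<f", header, 20, rate)

    pblock = bytearray(n_param_blocks * _BLOCK)
    struct.pack_into("BBBB", pblock, 0, 1, 0x50, n_param_blocks, _PROC_INTEL)
    pblock[4:4 + len(params)] = params

    frame_data = np.concatenate(
        [points, residuals[:, :, None].astype(np.float32)], axis=2)
    blob = frame_data.astype("<f4").tobytes()
    pad = (-len(blob)) % _BLOCK

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(pblock)
        fh.write(blob)
        fh.write(b"\x00" * pad)


# ---------------------------------------------------------------------------
# reading


def _parse_params(raw: bytes, endian: str):
    """Parse the parameter section into {GROUP: {PARAM: value}}."""
    groups_by_id: dict[int, str] = {}
    values: dict[tuple[int, str], object] = {}
    pos = 4
    while pos < len(raw) - 1:
        nchar = struct.unpack_from("b", raw, pos)[0]
        if nchar == 0:
            break
        group_id = struct.unpack_from("b", raw, pos + 1)[0]
        name = raw[pos + 2:pos + 2 + abs(nchar)].decode("ascii").strip().upper()
        p = pos + 2 + abs(nchar)
        offset = struct.unpack_from(endian + "h", raw, p)[0]
        next_pos = p + offset if offset else len(raw)
        if group_id < 0:
            groups_by_id[-group_id] = name
        else:
            dtype = struct.unpack_from("b", raw, p + 2)[0]
            ndims = raw[p + 3]
            dims = list(raw[p + 4:p + 4 + ndims])
            dp = p + 4 + ndims
            count = int(np.prod(dims)) if dims else 1
            if dtype == -1:
                data = raw[dp:dp + count]
                if len(dims) <= 1:
                    val = data.decode("ascii", "replace").strip()
                else:
                    w = dims[0]
                    n = count // w
                    val = [data[i * w:(i + 1) * w].decode("ascii", "replace").strip()
                           for i in range(n)]
            elif dtype == 1:
                val = np.frombuffer(raw, np.int8, count, dp)
            elif dtype == 2:
                val = np.frombuffer(raw, np.dtype(endian + "i2"), count, dp)
            elif dtype == 4:
                val = np.frombuffer(raw, np.dtype(endian + "f4"), count, dp)
            else:
                raise ValueError(f"unsupported parameter type {dtype} for {name}")
            if isinstance(val, np.ndarray):
                val = val.reshape(dims[::-1]) if len(dims) > 1 else (
                    val[0] if count == 1 else val)
            values[(group_id, name)] = val
        if next_pos <= pos:
            break
        pos = next_pos
    out: dict[str, dict[str, object]] = {}
    for (gid, pname), val in values.items():
        gname = groups_by_id.get(gid, f"GROUP{gid}")
        out.setdefault(gname, {})[pname] = val
    return out


def read_c3d_file(path) -> C3DContent:
    """Read 3D point data from a C3D file."""
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < 2 * _BLOCK:
        raise ValueError(f"{path}: too short to be a C3D file")
    param_block, magic = raw[0], raw[1]
    if magic != 0x50:
        raise ValueError(f"{path}: not a C3D file (magic byte {magic:#x})")
    proc = raw[(param_block - 1) * _BLOCK + 3]
    if proc == _PROC_INTEL:
        endian = "<"
    elif proc == _PROC_SGI:
        endian = ">"
    else:
        raise ValueError(f"{path}: unsupported processor type {proc} "
                         "(DEC floating point is not handled)")

    def h_i16(off):
        return struct.unpack_from(endian + "h", raw, off)[0]

    n_pts = h_i16(2)
    first_frame, last_frame = h_i16(6), h_i16(8)
    scale = struct.unpack_from(endian + "f", raw, 12)[0]
    data_block = h_i16(16)
    rate = float(struct.unpack_from(endian + "f", raw, 20)[0])

    n_param_blocks = raw[(param_block - 1) * _BLOCK + 2]
    pstart = (param_block - 1) * _BLOCK
    params = _parse_params(raw[pstart:pstart + n_param_blocks * _BLOCK], endian)
    point = params.get("POINT", {})

    if "USED" in point:
        n_pts = int(point["USED"])
    n_frames = last_frame - first_frame + 1
    if "FRAMES" in point:
        n_frames = int(point["FRAMES"])
    if n_frames <= 0 or n_pts <= 0:
        raise ValueError(f"{path}: no point data (frames={n_frames}, points={n_pts})")
    if "RATE" in point:
        rate = float(point["RATE"])
    if "SCALE" in point:
        scale = float(point["SCALE"])
    labels = point.get("LABELS", [])
    if isinstance(labels, str):
        labels = [labels]
    labels = list(labels)[:n_pts]
    if len(labels) < n_pts:
        labels += [f"M{i:03d}" for i in range(len(labels), n_pts)]
    units = point.get("UNITS", "mm") or "mm"
    if isinstance(units, list):
        units = units[0] if units else "mm"

    offset = (data_block - 1) * _BLOCK
    words = 4 * n_pts * n_frames
    if scale < 0:  # floating-point storage
        flat = np.frombuffer(raw, np.dtype(endian + "f4"), words, offset)
        frame_data = flat.reshape(n_frames, n_pts, 4).astype(np.float64)
        coords = frame_data[:, :, :3]
        residuals = frame_data[:, :, 3]
    else:  # scaled 16-bit integer storage
        flat = np.frombuffer(raw, np.dtype(endian + "i2"), words, offset)
        frame_data = flat.reshape(n_frames, n_pts, 4).astype(np.float64)
        coords = frame_data[:, :, :3] * scale
        residuals = frame_data[:, :, 3]
    return C3DContent(labels=labels, points=coords.copy(),
                      residuals=residuals.copy(), rate=rate, units=str(units))
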