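"""Minimal DICOM series reader/writer (explicit VR little endian only).

No DICOM library is available in the runtime environment, so this module
implements the small subset of PS3.10 needed to move CT slices in and out
of the pipeline: uncompressed explicit-VR little-endian files carrying
signed 16-bit pixel data plus the geometry and rescale tags.  It is not a
general DICOM implementation; anything outside that subset is rejected
with a hard error naming the offending tag.

DICOM patient coordinates are LPS; the affine returned by
:func:`read_series` is converted to RAS so nibabel's orientation utilities
apply directly.
"""

from __future__ import annotations

import os
import struct
from pathlib import Path

import numpy as np

TRANSFER_SYNTAX_ELE = "1.2.840.10008.1.2.1"  # explicit VR little endian
CT_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.2"

# tags used by the pipeline
TAG_SOP_CLASS = (0x0008, 0x0016)
TAG_SOP_INSTANCE = (0x0008, 0x0018)
TAG_STUDY_UID = (0x0020, 0x000D)
TAG_SERIES_UID = (0x0020, 0x000E)
TAG_POSITION = (0x0020, 0x0032)
TAG_ORIENTATION = (0x0020, 0x0037)
TAG_SAMPLES = (0x0028, 0x0002)
TAG_ROWS = (0x0028, 0x0010)
TAG_COLS = (0x0028, 0x0011)
TAG_PIXEL_SPACING = (0x0028, 0x0030)
TAG_BITS_ALLOC = (0x0028, 0x0100)
TAG_BITS_STORED = (0x0028, 0x0101)
TAG_HIGH_BIT = (0x0028, 0x0102)
TAG_PIXEL_REP = (0x0028, 0x0103)
TAG_INTERCEPT = (0x0028, 0x1052)
TAG_SLOPE = (0x0028, 0x1053)
TAG_PIXEL_DATA = (0x7FE0, 0x0010)

_LONG_VRS = {b"OB", b"OW", b"OF", b"OD", b"OL", b"SQ", b"UC", b"UR", b"UT", b"UN"}


def _encode(tag: tuple[int, int], vr: bytes, value: bytes) -> bytes:
    if len(value) % 2:
        value += b"\x00" if vr in (b"UI", b"OB") else b" "
    head = struct.pack("<HH", *tag) + vr
    if vr in _LONG_VRS:
        return head + b"\x00\x00" + struct.pack("<I", len(value)) + value
    return head + struct.pack("<H", len(value)) + value


def _ds(*values: float) -> bytes:
    return "\\".join(f"{v:.10g}" for v in values).encode()


def write_slice(
    path,
    pixels: np.ndarray,
    *,
    position: tuple[float, float, float],
    orientation: tuple[float, ...],
    pixel_spacing: tuple[float, float],
    slope: float = 1.0,
    intercept: float = -1024.0,
    series_uid: str = "1.2.826.0.1.3680043.9999.1",
    instance_uid: str = "1.2.826.0.1.3680043.9999.1.1",
) -> None:
    """Write one CT slice (raw int16 pixels; HU = raw*slope + intercept).

    ``position`` / ``orientation`` are in the DICOM LPS patient frame;
    ``pixel_spacing`` is (between-rows, between-columns) in mm.
    """
    pixels = np.asarray(pixels)
    if pixels.ndim != 2:
        raise ValueError("slice pixels must be 2-D")
    raw = np.ascontiguousarray(pixels.astype("<i2"))

    meta = b""
    meta += _encode((0x0002, 0x0002), b"UI", CT_SOP_CLASS.encode())
    meta += _encode((0x0002, 0x0003), b"UI", instance_uid.encode())
    meta += _encode((0x0002, 0x0010), b"UI", TRANSFER_SYNTAX_ELE.encode())
    group_len = _encode((0x0002, 0x0000), b"UL", struct.pack("<I", len(meta)))

    body = b""
    body += _encode(TAG_SOP_CLASS, b"UI", CT_SOP_CLASS.encode())
    body += _encode(TAG_SOP_INSTANCE, b"UI", instance_uid.encode())
    body += _encode(TAG_STUDY_UID, b"UI", (series_uid + ".0").encode())
    body += _encode(TAG_SERIES_UID, b"UI", series_uid.encode())
    body += _encode(TAG_POSITION, b"DS", _ds(*position))
    body += _encode(TAG_ORIENTATION, b"DS", _ds(*orientation))
    body += _encode(TAG_SAMPLES, b"US", struct.pack("<H", 1))
    body += _encode(TAG_ROWS, b"US", struct.pack("<H", pixels.shape[0]))
    body += _encode(TAG_COLS, b"US", struct.pack("<H", pixels.shape[1]))
    body += _encode(TAG_PIXEL_SPACING, b"DS", _ds(*pixel_spacing))
    body += _encode(TAG_BITS_ALLOC, b"US", struct.pack("<H", 16))
    body += _encode(TAG_BITS_STORED, b"US", struct.pack("<H", 16))
    body += _encode(TAG_HIGH_BIT, b"US", struct.pack("<H", 15))
    body += _encode(TAG_PIXEL_REP, b"US", struct.pack("<H", 1))
    body += _encode(TAG_INTERCEPT, b"DS", _ds(intercept))
    body += _encode(TAG_SLOPE, b"DS", _ds(slope))
    body += _encode(TAG_PIXEL_DATA, b"OW", raw.tobytes())

    with open(path, "wb") as fh:
        fh.write(b"\x00" * 128 + b"DICM" + group_len + meta + body)


def write_series(
    directory,
    voxels: np.ndarray,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    *,
    slope: float = 1.0,
    intercept: float = -1024.0,
    series_uid: str = "1.2.826.0.1.3680043.9999.1",
    filenames: list[str] | None = None,
) -> list:
    """Write a canonical-frame volume as an axial DICOM series.

    ``voxels`` is (lr, pa, is) with ascending index toward patient
    left / anterior / superior; HU values are stored as raw int16 with the
    given rescale pair, so non-integral HU are rounded.  Returns the
    written paths.  ``filenames`` can scramble the on-disk order to
    exercise position-based sorting.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    nx, ny, nz = voxels.shape
    dx, dy, dz = spacing
    paths = []
    for k in range(nz):
        # rows run anterior -> posterior (LPS +y), columns right -> left (+x)
        pixels = voxels[:, ::-1, k].T
        raw = np.round((pixels - intercept) / slope).astype(np.int16)
        name = filenames[k] if filenames else f"slice_{k:03d}.dcm"
        path = directory / name
        write_slice(
            path, raw,
            position=(0.0, 0.0, k * dz),
            orientation=(1.0, 0.0, 0.0, 0.0, 1.0, 0.0),
            pixel_spacing=(dy, dx),
            slope=slope, intercept=intercept,
            series_uid=series_uid,
            instance_uid=f"{series_uid}.{k + 1}",
        )
        paths.append(path)
    return paths


def _read_elements(buf: bytes, path) -> dict[tuple[int, int], tuple[bytes, bytes]]:
    if buf[128:132] != b"DICM":
        raise ValueError(f"{path}: not a DICOM part-10 file (no DICM magic)")
    elems: dict[tuple[int, int], tuple[bytes, bytes]] = {}
    pos = 132
    while pos + 8 <= len(buf):
        group, elem = struct.unpack_from("<HH", buf, pos)
        vr = buf[pos + 4 : pos + 6]
        if not vr.isalpha() or vr.isupper() is False:
            raise ValueError(f"{path}: tag ({group:04X},{elem:04X}) is not explicit-VR")
        if vr in _LONG_VRS:
            (length,) = struct.unpack_from("<I", buf, pos + 8)
            pos += 12
        else:
            (length,) = struct.unpack_from("<H", buf, pos + 6)
            pos += 8
        if vr == b"SQ":
            raise ValueError(f"{path}: sequences unsupported (tag {group:04X},{elem:04X})")
        elems[(group, elem)] = (vr, buf[pos : pos + length])
        pos += length
    return elems


def _require(elems, tag, path) -> bytes:
    if tag not in elems:
        raise ValueError(f"{path}: missing required tag ({tag[0]:04X},{tag[1]:04X})")
    return elems[tag][1]


def _floats(raw: bytes) -> tuple[float, ...]:
    return tuple(float(x) for x in raw.decode().strip("\x00 ").split("\\"))


def read_slice(path):
    """Parse one slice file -> (HU array, position, orientation, spacing, series uid)."""
    elems = _read_elements(Path(path).read_bytes(), path)
    ts = _require(elems, (0x0002, 0x0010), path).decode().strip("\x00 ")
    if ts != TRANSFER_SYNTAX_ELE:
        raise ValueError(f"{path}: unsupported transfer syntax {ts!r} (tag 0002,0010)")
    if struct.unpack("<H", _require(elems, TAG_BITS_ALLOC, path))[0] != 16:
        raise ValueError(f"{path}: only 16-bit pixel data supported (tag 0028,0100)")
    rows = struct.unpack("<H", _require(elems, TAG_ROWS, path))[0]
    cols = struct.unpack("<H", _require(elems, TAG_COLS, path))[0]
    signed = struct.unpack("<H", _require(elems, TAG_PIXEL_REP, path))[0]
    slope = _floats(_require(elems, TAG_SLOPE, path))[0]
    intercept = _floats(_require(elems, TAG_INTERCEPT, path))[0]
    position = _floats(_require(elems, TAG_POSITION, path))
    orientation = _floats(_require(elems, TAG_ORIENTATION, path))
    if len(orientation) != 6:
        raise ValueError(f"{path}: ImageOrientationPatient (0020,0037) needs 6 values")
    spacing = _floats(_require(elems, TAG_PIXEL_SPACING, path))
    raw = np.frombuffer(
        _require(elems, TAG_PIXEL_DATA, path), dtype="<i2" if signed else "<u2"
    )
    if raw.size != rows * cols:
        raise ValueError(f"{path}: pixel data size mismatch (tag 7FE0,0010)")
    hu = raw.reshape(rows, cols).astype(np.float64) * slope + intercept
    series_uid = _require(elems, TAG_SERIES_UID, path).decode().strip("\x00 ")
    return hu, np.array(position), np.array(orientation), spacing, series_uid


def read_series(directory_path):
    """Read every DICOM file in a directory as one coherent CT series.

    Returns ``(volume, affine_ras, meta)`` with the volume indexed
    (row, column, slice), slices sorted by position along the slice normal.
    """
    directory = Path(directory_path)
    files = sorted(p for p in directory.iterdir() if p.is_file())
    if not files:
        raise ValueError(f"{directory}: no files")
    slices, positions = [], []
    orientation = series_uid = spacing = shape = None
    for p in files:
        hu, pos, ornt, sp, uid = read_slice(p)
        if orientation is None:
            orientation, series_uid, spacing, shape = ornt, uid, sp, hu.shape
        else:
            if not np.allclose(ornt, orientation):
                raise ValueError(
                    f"{p}: ImageOrientationPatient (0020,0037) differs within series"
                )
            if uid != series_uid:
                raise ValueError(f"{p}: mixed SeriesInstanceUID (0020,000E)")
            if hu.shape != shape:
                raise ValueError(f"{p}: slice shape differs within series")
        slices.append(hu)
        positions.append(pos)

    row_cos = orientation[:3]  # direction of increasing column index (LPS)
    col_cos = orientation[3:]  # direction of increasing row index (LPS)
    normal = np.cross(row_cos, col_cos)
    order = np.argsort([float(np.dot(p, normal)) for p in positions], kind="stable")
    slices = [slices[i] for i in order]
    positions = [positions[i] for i in order]

    if len(slices) > 1:
        steps = np.diff([np.dot(p, normal) for p in positions])
        if np.any(steps <= 0):
            raise ValueError(f"{directory}: duplicate slice positions (0020,0032)")
        dz = float(np.mean(steps))
    else:
        dz = 1.0

    vol = np.stack(slices, axis=2)  # (row, col, slice)
    dr, dc = spacing
    affine_lps = np.eye(4)
    affine_lps[:3, 0] = col_cos * dr  # row index step
    affine_lps[:3, 1] = row_cos * dc  # column index step
    affine_lps[:3, 2] = normal * dz
    affine_lps[:3, 3] = positions[0]
    # volume is indexed (row, col, slice) but affine columns above are
    # (row, col, slice) steps already; convert LPS -> RAS for nibabel
    affine_ras = np.diag([-1.0, -1.0, 1.0, 1.0]) @ affine_lps
    meta = {"source": str(directory), "series_uid": series_uid, "n_slices": len(slices)}
    return vol, affine_ras, meta
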