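"""Minimal DICOM support for CT slice series.

This is deliberately a small, constrained implementation — not a general
DICOM toolkit.  It writes single-frame monochrome CT slices as Explicit
VR Little Endian Part-10 files and reads back only that encoding,
validating the transfer syntax and refusing anything else.  Stored pixel
values are signed 16-bit with RescaleSlope/RescaleIntercept mapping to
HU.  UIDs are deterministic (content-derived under the UUID-derived
``2.25`` root) so a regenerated series is byte-identical.
"""

from __future__ import annotations

import hashlib
import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import MissingTagError, ValidationError

EXPLICIT_VR_LE = "1.2.840.10008.1.2.1"
CT_STORAGE = "1.2.840.10008.5.1.4.1.1.2"

# VRs carrying a 2-byte reserved field and 4-byte length
_LONG_VRS = {b"OB", b"OW", b"OF", b"SQ", b"UT", b"UN"}

Tag = tuple[int, int]

TAG_SOP_CLASS = (0x0008, 0x0016)
TAG_SOP_INSTANCE = (0x0008, 0x0018)
TAG_MODALITY = (0x0008, 0x0060)
TAG_SLICE_THICKNESS = (0x0018, 0x0050)
TAG_SERIES_UID = (0x0020, 0x000E)
TAG_INSTANCE_NUMBER = (0x0020, 0x0013)
TAG_IMAGE_POSITION = (0x0020, 0x0032)
TAG_IMAGE_ORIENTATION = (0x0020, 0x0037)
TAG_SAMPLES_PER_PIXEL = (0x0028, 0x0002)
TAG_PHOTOMETRIC = (0x0028, 0x0004)
TAG_ROWS = (0x0028, 0x0010)
TAG_COLUMNS = (0x0028, 0x0011)
TAG_PIXEL_SPACING = (0x0028, 0x0030)
TAG_BITS_ALLOCATED = (0x0028, 0x0100)
TAG_BITS_STORED = (0x0028, 0x0101)
TAG_HIGH_BIT = (0x0028, 0x0102)
TAG_PIXEL_REPRESENTATION = (0x0028, 0x0103)
TAG_RESCALE_INTERCEPT = (0x0028, 0x1052)
TAG_RESCALE_SLOPE = (0x0028, 0x1053)
TAG_PIXEL_DATA = (0x7FE0, 0x0010)


def deterministic_uid(*parts: object) -> str:
    digest = hashlib.sha256("/".join(map(str, parts)).encode()).digest()
    return "2.25." + str(int.from_bytes(digest[:13], "big"))


def _pad(value: bytes, pad_byte: bytes = b"\x00") -> bytes:
    return value + pad_byte if len(value) % 2 else value


def _encode_element(tag: Tag, vr: bytes, value: bytes) -> bytes:
    value = _pad(value, b" " if vr in (b"DS", b"IS", b"LO", b"CS", b"SH") else b"\x00")
    head = struct.pack("<HH", tag[0], tag[1]) + vr
    if vr in _LONG_VRS:
        return head + b"\x00\x00" + struct.pack("<I", len(value)) + value
    if len(value) > 0xFFFF:
        raise ValidationError(f"value too long for short VR at tag {tag}")
    return head + struct.pack("<H", len(value)) + value


def _ds(*numbers: float) -> bytes:
    return "\\".join(format(x, ".10g") for x in numbers).encode()


@dataclass
class SliceInfo:
    """Decoded header fields plus HU pixel array for one slice."""

    series_uid: str
    instance_number: int
    position: tuple[float, float, float]
    pixel_spacing: tuple[float, float]
    slice_thickness: float
    hu: np.ndarray


def write_slice(
    path: Path | str,
    hu_slice: np.ndarray,
    *,
    series_uid: str,
    instance_number: int,
    position: tuple[float, float, float],
    pixel_spacing: tuple[float, float],
    slice_thickness: float,
) -> None:
    """Write one axial HU slice as an Explicit VR Little Endian CT file."""
    hu_slice = np.asarray(hu_slice)
    if hu_slice.ndim != 2:
        raise ValidationError("slice must be 2-D")
    stored = hu_slice.astype("<i2")  # slope 1 intercept 0: stored value == HU
    rows, cols = stored.shape

    sop_uid = deterministic_uid(series_uid, instance_number)
    elements = [
        (TAG_SOP_CLASS, b"UI", CT_STORAGE.encode()),
        (TAG_SOP_INSTANCE, b"UI", sop_uid.encode()),
        (TAG_MODALITY, b"CS", b"CT"),
        (TAG_SLICE_THICKNESS, b"DS", _ds(slice_thickness)),
        (TAG_SERIES_UID, b"UI", series_uid.encode()),
        (TAG_INSTANCE_NUMBER, b"IS", str(instance_number).encode()),
        (TAG_IMAGE_POSITION, b"DS", _ds(*position)),
        (TAG_IMAGE_ORIENTATION, b"DS", _ds(1, 0, 0, 0, 1, 0)),
        (TAG_SAMPLES_PER_PIXEL, b"US", struct.pack("<H", 1)),
        (TAG_PHOTOMETRIC, b"CS", b"MONOCHROME2"),
        (TAG_ROWS, b"US", struct.pack("<H", rows)),
        (TAG_COLUMNS, b"US", struct.pack("<H", cols)),
        (TAG_PIXEL_SPACING, b"DS", _ds(*pixel_spacing)),
        (TAG_BITS_ALLOCATED, b"US", struct.pack("<H", 16)),
        (TAG_BITS_STORED, b"US", struct.pack("<H", 16)),
        (TAG_HIGH_BIT, b"US", struct.pack("<H", 15)),
        (TAG_PIXEL_REPRESENTATION, b"US", struct.pack("<H", 1)),
        (TAG_RESCALE_INTERCEPT, b"DS", _ds(0)),
        (TAG_RESCALE_SLOPE, b"DS", _ds(1)),
        (TAG_PIXEL_DATA, b"OW", stored.tobytes()),
    ]
    body = b"".join(_encode_element(t, vr, v) for t, vr, v in elements)

    meta_elements = [
        ((0x0002, 0x0001), b"OB", b"\x00\x01"),
        ((0x0002, 0x0002), b"UI", CT_STORAGE.encode()),
        ((0x0002, 0x0003), b"UI", sop_uid.encode()),
        ((0x0002, 0x0010), b"UI", EXPLICIT_VR_LE.encode()),
        ((0x0002, 0x0012), b"UI", deterministic_uid("ctild-implementation").encode()),
    ]
    meta_body = b"".join(_encode_element(t, vr, v) for t, vr, v in meta_elements)
    meta = (
        _encode_element((0x0002, 0x0000), b"UL", struct.pack("<I", len(meta_body)))
        + meta_body
    )

    with open(path, "wb") as fh:
        fh.write(b"\x00" * 128 + b"DICM" + meta + body)


def _read_elements(buf: bytes, offset: int, end: int) -> dict[Tag, tuple[bytes, bytes]]:
    elements: dict[Tag, tuple[bytes, bytes]] = {}
    while offset < end:
        group, element = struct.unpack_from("<HH", buf, offset)
        vr = buf[offset + 4 : offset + 6]
        if vr in _LONG_VRS:
            (length,) = struct.unpack_from("<I", buf, offset + 8)
            value_start = offset + 12
        else:
            (length,) = struct.unpack_from("<H", buf, offset + 6)
            value_start = offset + 8
        if length == 0xFFFFFFFF:
            raise ValidationError("undefined-length elements are not supported")
        value = buf[value_start : value_start + length]
        elements[(group, element)] = (vr, value)
        offset = value_start + length
    return elements


def _decode_ds(raw: bytes) -> list[float]:
    return [float(part) for part in raw.decode().strip("\x00 ").split("\\") if part]


def read_slice(path: Path | str) -> SliceInfo:
    """Read one slice written in Explicit VR Little Endian.

    Raises :class:`~ctild.errors.ValidationError` for non-DICOM input or an
    unsupported transfer syntax, and
    :class:`~ctild.errors.MissingTagError` when required tags are absent.
    """
    buf = Path(path).read_bytes()
    if len(buf) < 132 or buf[128:132] != b"DICM":
        raise ValidationError(f"{path}: not a DICOM part-10 file")

    meta_len_elems = _read_elements(buf, 132, 132 + 12)
    vr, raw = meta_len_elems[(0x0002, 0x0000)]
    (meta_len,) = struct.unpack("<I", raw)
    meta_end = 132 + 12 + meta_len
    meta = _read_elements(buf, 144, meta_end)
    ts = meta.get((0x0002, 0x0010))
    if ts is None or ts[1].decode().strip("\x00 ") != EXPLICIT_VR_LE:
        raise ValidationError(
            f"{path}: unsupported transfer syntax (only Explicit VR Little "
            "Endian is handled)"
        )

    data = _read_elements(buf, meta_end, len(buf))

    def require(tag: Tag, name: str) -> tuple[bytes, bytes]:
        if tag not in data:
            raise MissingTagError(
                f"{path}: required tag ({tag[0]:04X},{tag[1]:04X}) {name} is missing"
            )
        return data[tag]

    rows = struct.unpack("<H", require(TAG_ROWS, "Rows")[1])[0]
    cols = struct.unpack("<H", require(TAG_COLUMNS, "Columns")[1])[0]
    slope = _decode_ds(require(TAG_RESCALE_SLOPE, "RescaleSlope")[1])[0]
    intercept = _decode_ds(require(TAG_RESCALE_INTERCEPT, "RescaleIntercept")[1])[0]
    position = _decode_ds(require(TAG_IMAGE_POSITION, "ImagePositionPatient")[1])
    spacing = _decode_ds(require(TAG_PIXEL_SPACING, "PixelSpacing")[1])
    series_uid = require(TAG_SERIES_UID, "SeriesInstanceUID")[1].decode().strip("\x00 ")
    thickness_raw = data.get(TAG_SLICE_THICKNESS)
    thickness = _decode_ds(thickness_raw[1])[0] if thickness_raw else 0.0
    instance_raw = data.get(TAG_INSTANCE_NUMBER)
    instance = int(instance_raw[1].decode().strip("\x00 ")) if instance_raw else 0

    signed = True
    rep = data.get(TAG_PIXEL_REPRESENTATION)
    if rep is not None:
        signed = struct.unpack("<H", rep[1])[0] == 1
    raw_pixels = require(TAG_PIXEL_DATA, "PixelData")[1]
    dtype = "<i2" if signed else "<u2"
    stored = np.frombuffer(raw_pixels, dtype=dtype, count=rows * cols).reshape(rows, cols)
    hu = stored.astype(np.float64) * slope + intercept
    return SliceInfo(
        series_uid=series_uid,
        instance_number=instance,
        position=(position[0], position[1], position[2]),
        pixel_spacing=(spacing[0], spacing[1]),
        slice_thickness=thickness,
        hu=hu,
    )
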