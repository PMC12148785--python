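"""Minimal DICOM reader/writer (Explicit VR Little Endian only).

Supports the subset of Part-10 DICOM needed for the RTDOSE / RTSTRUCT /
RTPLAN objects this package writes and reads: flat data elements, nested
sequences (defined or undefined length), and the VRs used by those IODs.
This is not a general-purpose DICOM implementation; files produced by
other systems are accepted only if they are Explicit VR Little Endian.
"""

from __future__ import annotations

import struct
from typing import Any, Iterator

EXPLICIT_VR_LE = "1.2.840.10008.1.2.1"

#: VRs serialized with a 2-byte reserved field and a 4-byte length.
_LONG_VRS = {"OB", "OW", "OF", "SQ", "UT", "UN"}
_STRING_VRS = {"AE", "AS", "CS", "DA", "DT", "LO", "LT", "PN", "SH", "ST", "TM", "UI", "UT"}

ITEM_TAG = (0xFFFE, 0xE000)
ITEM_DELIM_TAG = (0xFFFE, 0xE00D)
SEQ_DELIM_TAG = (0xFFFE, 0xE0DD)


class DicomError(ValueError):
    """Raised on malformed or unsupported DICOM input."""


class Dataset:
    """An ordered mapping of (group, element) -> (vr, value)."""

    def __init__(self) -> None:
        self._elements: dict[tuple[int, int], tuple[str, Any]] = {}

    def set(self, tag: tuple[int, int], vr: str, value: Any) -> None:
        self._elements[tag] = (vr, value)

    def get(self, tag: tuple[int, int], default: Any = None) -> Any:
        item = self._elements.get(tag)
        return default if item is None else item[1]

    def require(self, tag: tuple[int, int], what: str) -> Any:
        if tag not in self._elements:
            raise DicomError(f"missing required DICOM attribute {what} {_fmt_tag(tag)}")
        return self._elements[tag][1]

    def __contains__(self, tag: tuple[int, int]) -> bool:
        return tag in self._elements

    def items(self) -> Iterator[tuple[tuple[int, int], tuple[str, Any]]]:
        return iter(sorted(self._elements.items()))


def _fmt_tag(tag: tuple[int, int]) -> str:
    return f"({tag[0]:04X},{tag[1]:04X})"


# ---------------------------------------------------------------------------
# encoding

def _encode_value(vr: str, value: Any) -> bytes:
    if vr == "SQ":
        out = b""
        for item in value:
            body = _encode_dataset(item)
            out += struct.pack("<HHI", *ITEM_TAG, len(body)) + body
        return out
    if vr in ("OB", "OW", "UN"):
        data = bytes(value)
        return data + b"\x00" * (len(data) % 2)
    if vr == "US":
        vals = value if isinstance(value, (list, tuple)) else [value]
        return struct.pack(f"<{len(vals)}H", *[int(v) for v in vals])
    if vr == "UL":
        vals = value if isinstance(value, (list, tuple)) else [value]
        return struct.pack(f"<{len(vals)}I", *[int(v) for v in vals])
    if vr == "FL":
        vals = value if isinstance(value, (list, tuple)) else [value]
        return struct.pack(f"<{len(vals)}f", *[float(v) for v in vals])
    if vr == "FD":
        vals = value if isinstance(value, (list, tuple)) else [value]
        return struct.pack(f"<{len(vals)}d", *[float(v) for v in vals])
    if vr == "DS":
        vals = value if isinstance(value, (list, tuple)) else [value]
        text = "\\".join(_format_ds(float(v)) for v in vals)
        return _pad_string(text, pad=b" ")
    if vr == "IS":
        vals = value if isinstance(value, (list, tuple)) else [value]
        text = "\\".join(str(int(v)) for v in vals)
        return _pad_string(text, pad=b" ")
    if vr in _STRING_VRS:
        if isinstance(value, (list, tuple)):
            value = "\\".join(str(v) for v in value)
        pad = b"\x00" if vr == "UI" else b" "
        return _pad_string(str(value), pad=pad)
    raise DicomError(f"cannot encode VR {vr}")


def _format_ds(v: float) -> str:
    # DICOM DS is limited to 16 bytes
    text = repr(v)
    if len(text) > 16:
        text = f"{v:.10g}"
    return text


def _pad_string(text: str, pad: bytes) -> bytes:
    raw = text.encode("ascii")
    if len(raw) % 2:
        raw += pad
    return raw


def _encode_element(tag: tuple[int, int], vr: str, value: Any) -> bytes:
    body = _encode_value(vr, value)
    head = struct.pack("<HH", *tag) + vr.encode("ascii")
    if vr in _LONG_VRS:
        return head + b"\x00\x00" + struct.pack("<I", len(body)) + body
    if len(body) > 0xFFFF:
        raise DicomError(f"value too long for short-form VR {vr} at {_fmt_tag(tag)}")
    return head + struct.pack("<H", len(body)) + body


def _encode_dataset(ds: Dataset) -> bytes:
    return b"".join(_encode_element(tag, vr, value) for tag, (vr, value) in ds.items())


def write_file(path: str, ds: Dataset, sop_class_uid: str, sop_instance_uid: str) -> None:
    """Write *ds* as a Part-10 file with an Explicit VR LE file-meta group."""
    meta = Dataset()
    meta.set((0x0002, 0x0001), "OB", b"\x00\x01")           # FileMetaInformationVersion
    meta.set((0x0002, 0x0002), "UI", sop_class_uid)          # MediaStorageSOPClassUID
    meta.set((0x0002, 0x0003), "UI", sop_instance_uid)       # MediaStorageSOPInstanceUID
    meta.set((0x0002, 0x0010), "UI", EXPLICIT_VR_LE)         # TransferSyntaxUID
    meta.set((0x0002, 0x0012), "UI", "2.25.4242424242")      # ImplementationClassUID
    meta_body = _encode_dataset(meta)
    group_len = _encode_element((0x0002, 0x0000), "UL", len(meta_body))
    with open(path, "wb") as fh:
        fh.write(b"\x00" * 128)
        fh.write(b"DICM")
        fh.write(group_len)
        fh.write(meta_body)
        fh.write(_encode_dataset(ds))


# ---------------------------------------------------------------------------
# decoding

class _Reader:
    def __init__(self, data: bytes, pos: int = 0, end: int | None = None) -> None:
        self.data = data
        self.pos = pos
        self.end = len(data) if end is None else end

    def eof(self) -> bool:
        return self.pos >= self.end

    def read(self, n: int) -> bytes:
        if self.pos + n > self.end:
            raise DicomError("truncated DICOM stream")
        chunk = self.data[self.pos:self.pos + n]
        self.pos += n
        return chunk

    def peek_tag(self) -> tuple[int, int]:
        if self.pos + 4 > self.end:
            raise DicomError("truncated DICOM stream")
        g, e = struct.unpack_from("<HH", self.data, self.pos)
        return (g, e)


def _decode_value(vr: str, raw: bytes) -> Any:
    if vr in ("OB", "OW", "UN", "OF"):
        return raw
    if vr == "US":
        vals = list(struct.unpack(f"<{len(raw) // 2}H", raw))
        return vals[0] if len(vals) == 1 else vals
    if vr == "UL":
        vals = list(struct.unpack(f"<{len(raw) // 4}I", raw))
        return vals[0] if len(vals) == 1 else vals
    if vr == "FL":
        vals = list(struct.unpack(f"<{len(raw) // 4}f", raw))
        return vals[0] if len(vals) == 1 else vals
    if vr == "FD":
        vals = list(struct.unpack(f"<{len(raw) // 8}d", raw))
        return vals[0] if len(vals) == 1 else vals
    text = raw.decode("ascii", errors="replace").rstrip("\x00 ")
    if vr == "DS":
        if not text:
            return []
        vals = [float(p) for p in text.split("\\")]
        return vals[0] if len(vals) == 1 else vals
    if vr == "IS":
        if not text:
            return []
        vals = [int(p) for p in text.split("\\")]
        return vals[0] if len(vals) == 1 else vals
    if "\\" in text:
        return text.split("\\")
    return text


def _parse_sequence(reader: _Reader, length: int) -> list[Dataset]:
    items: list[Dataset] = []
    seq_end = None if length == 0xFFFFFFFF else reader.pos + length
    while True:
        if seq_end is not None and reader.pos >= seq_end:
            break
        tag = struct.unpack("<HH", reader.read(4))
        item_len = struct.unpack("<I", reader.read(4))[0]
        if tag == SEQ_DELIM_TAG:
            break
        if tag != ITEM_TAG:
            raise DicomError(f"unexpected tag {_fmt_tag(tag)} inside sequence")
        if item_len == 0xFFFFFFFF:
            items.append(_parse_dataset(reader, stop_at_item_delim=True))
        else:
            sub = _Reader(reader.data, reader.pos, reader.pos + item_len)
            items.append(_parse_dataset(sub))
            reader.pos = sub.pos
    return items


def _parse_dataset(reader: _Reader, stop_at_item_delim: bool = False) -> Dataset:
    ds = Dataset()
    while not reader.eof():
        tag = struct.unpack("<HH", reader.read(4))
        if stop_at_item_delim and tag == ITEM_DELIM_TAG:
            reader.read(4)
            break
        vr = reader.read(2).decode("ascii")
        if vr in _LONG_VRS:
            reader.read(2)
            length = struct.unpack("<I", reader.read(4))[0]
        else:
            length = struct.unpack("<H", reader.read(2))[0]
        if vr == "SQ":
            ds.set(tag, vr, _parse_sequence(reader, length))
        else:
            if length == 0xFFFFFFFF:
                raise DicomError(f"undefined length outside SQ at {_fmt_tag(tag)}")
            ds.set(tag, vr, _decode_value(vr, reader.read(length)))
    return ds


def read_file(path: str) -> Dataset:
    """Read a Part-10 Explicit VR Little Endian DICOM file."""
    with open(path, "rb") as fh:
        data = fh.read()
    if len(data) < 132 or data[128:132] != b"DICM":
        raise DicomError(f"{path}: not a DICOM Part-10 file (missing DICM marker)")
    reader = _Reader(data, 132)
    # file meta group is always Explicit VR LE
    meta = Dataset()
    while not reader.eof() and reader.peek_tag()[0] == 0x0002:
        tag = struct.unpack("<HH", reader.read(4))
        vr = reader.read(2).decode("ascii")
        if vr in _LONG_VRS:
            reader.read(2)
            length = struct.unpack("<I", reader.read(4))[0]
        else:
            length = struct.unpack("<H", reader.read(2))[0]
        meta.set(tag, vr, _decode_value(vr, reader.read(length)) if vr != "SQ" else None)
    transfer_syntax = meta.get((0x0002, 0x0010))
    if transfer_syntax != EXPLICIT_VR_LE:
        raise DicomError(
            f"unsupported transfer syntax {transfer_syntax!r}; "
            f"only Explicit VR Little Endian ({EXPLICIT_VR_LE}) is supported"
        )
    return _parse_dataset(reader)
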