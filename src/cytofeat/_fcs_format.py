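"""Minimal FCS 3.0/3.1 list-mode binary format support.

Implements the subset of the FCS standard the pipeline needs: list-mode
($MODE L) data segments of type float ($DATATYPE F), double (D) or unsigned
integer (I, byte-aligned widths), little- or big-endian ($BYTEORD). The
writer always emits FCS3.1 float32 little-endian list mode and exists to
produce test fixtures and synthetic experiments, not files for instrument
software.
"""

from __future__ import annotations

import numpy as np

__all__ = ["FcsFormatError", "read_fcs_file", "write_fcs_file"]

HEADER_LEN = 58  # 10-byte version + six 8-byte ASCII offset fields


class FcsFormatError(Exception):
    """The file violates the supported subset of the FCS standard."""


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    if not raw:
        raise FcsFormatError("empty TEXT segment")
    delim = raw[0:1]
    body = raw[1:]
    # A doubled delimiter escapes a literal delimiter inside a value.
    # Split on single delimiters by first protecting doubled ones.
    sentinel = b"\x00\x01\x00"
    parts = body.replace(delim + delim, sentinel).split(delim)
    parts = [p.replace(sentinel, delim) for p in parts]
    if parts and parts[-1] == b"":
        parts = parts[:-1]
    if len(parts) % 2 != 0:
        raise FcsFormatError("TEXT segment has an odd number of tokens")
    text: dict[str, str] = {}
    for key, value in zip(parts[::2], parts[1::2]):
        text[key.decode("ascii", "replace").strip().upper()] = value.decode(
            "ascii", "replace"
        )
    return text


def _data_dtype(text: dict[str, str], n_par: int) -> np.dtype:
    byteord = text.get("$BYTEORD", "1,2,3,4").strip()
    if byteord in ("1,2,3,4", "1,2"):
        endian = "<"
    elif byteord in ("4,3,2,1", "2,1"):
        endian = ">"
    else:
        raise FcsFormatError(f"unsupported $BYTEORD {byteord!r}")
    datatype = text.get("$DATATYPE", "").strip().upper()
    widths = {
        int(text[f"$P{i}B"]) for i in range(1, n_par + 1) if f"$P{i}B" in text
    }
    if datatype == "F":
        if widths - {32}:
            raise FcsFormatError("$DATATYPE F requires 32-bit parameters")
        return np.dtype(f"{endian}f4")
    if datatype == "D":
        if widths - {64}:
            raise FcsFormatError("$DATATYPE D requires 64-bit parameters")
        return np.dtype(f"{endian}f8")
    if datatype == "I":
        if len(widths) != 1:
            raise FcsFormatError("mixed integer widths are not supported")
        width = widths.pop()
        if width not in (8, 16, 32):
            raise FcsFormatError(f"unsupported integer width {width}")
        return np.dtype(f"{endian}u{width // 8}")
    raise FcsFormatError(f"unsupported $DATATYPE {datatype!r}")


def read_fcs_file(path) -> tuple[dict[str, str], list[str], np.ndarray]:
    """Read one FCS data set.

    Returns ``(text_keywords, channel_names, events)`` where *events* is a
    float64 array of shape ``(n_events, n_channels)`` in acquisition order
    and *channel_names* are the $PnN short names in parameter order.
    """
    with open(path, "rb") as fh:
        blob = fh.read()
    if len(blob) < HEADER_LEN:
        raise FcsFormatError(f"{path}: file shorter than an FCS header")
    version = blob[:6].decode("ascii", "replace")
    if version not in ("FCS3.0", "FCS3.1"):
        raise FcsFormatError(f"{path}: unsupported version {version!r}")

    def _offset(lo: int, hi: int, what: str) -> int:
        field = blob[lo:hi].decode("ascii", "replace").strip()
        try:
            return int(field) if field else 0
        except ValueError as exc:
            raise FcsFormatError(
                f"{path}: bad {what} offset {field!r} at byte {lo}"
            ) from exc

    text_begin = _offset(10, 18, "TEXT begin")
    text_end = _offset(18, 26, "TEXT end")
    data_begin = _offset(26, 34, "DATA begin")
    data_end = _offset(34, 42, "DATA end")
    if text_end <= text_begin:
        raise FcsFormatError(f"{path}: invalid TEXT offsets at byte 10")
    text = _parse_text_segment(blob[text_begin : text_end + 1])

    mode = text.get("$MODE", "L").strip().upper()
    if mode != "L":
        raise FcsFormatError(f"{path}: only list mode is supported, got {mode}")
    n_par = int(text["$PAR"])
    n_tot = int(text["$TOT"])
    # FCS3.x: header offsets of 0 defer to $BEGINDATA/$ENDDATA in TEXT.
    if data_begin == 0:
        data_begin = int(text["$BEGINDATA"])
        data_end = int(text["$ENDDATA"])
    dtype = _data_dtype(text, n_par)
    expected = n_tot * n_par * dtype.itemsize
    segment = blob[data_begin : data_begin + expected]
    if len(segment) != expected:
        raise FcsFormatError(
            f"{path}: DATA segment at offset {data_begin} holds "
            f"{len(segment)} bytes, expected {expected}"
        )
    events = (
        np.frombuffer(segment, dtype=dtype).reshape(n_tot, n_par).astype(np.float64)
    )
    names = []
    for i in range(1, n_par + 1):
        names.append(text.get(f"$P{i}N", f"P{i}").strip())
    if data_end and data_end - data_begin + 1 != expected:
        # Tolerate off-by-one $ENDDATA conventions seen in the wild; the
        # $TOT/$PAR/$PnB product is authoritative for the supported subset.
        pass
    return text, names, events


def write_fcs_file(path, channel_names, events, extra_text=None) -> None:
    """Write an FCS3.1 float32 little-endian list-mode file."""
    data = np.ascontiguousarray(events, dtype="<f4")
    if data.ndim != 2:
        raise ValueError("events must be a 2-D array (events x channels)")
    n_tot, n_par = data.shape
    if n_par != len(channel_names):
        raise ValueError("channel_names length must match event columns")
    delim = "/"
    keywords: list[tuple[str, str]] = [
        ("$BEGINANALYSIS", "0"),
        ("$ENDANALYSIS", "0"),
        ("$BEGINSTEXT", "0"),
        ("$ENDSTEXT", "0"),
        ("$BYTEORD", "1,2,3,4"),
        ("$DATATYPE", "F"),
        ("$MODE", "L"),
        ("$NEXTDATA", "0"),
        ("$PAR", str(n_par)),
        ("$TOT", str(n_tot)),
    ]
    for i, name in enumerate(channel_names, start=1):
        if delim in str(name):
            raise ValueError(f"channel name {name!r} contains the delimiter")
        col = data[:, i - 1]
        rng = float(col.max()) if n_tot else 0.0
        keywords += [
            (f"$P{i}N", str(name)),
            (f"$P{i}B", "32"),
            (f"$P{i}E", "0,0"),
            (f"$P{i}R", repr(max(rng, 1.0))),
        ]
    for key, value in (extra_text or {}).items():
        keywords.append((str(key).upper(), str(value)))

    def _render(begin_data: int, end_data: int) -> bytes:
        items = [("$BEGINDATA", str(begin_data)), ("$ENDDATA", str(end_data))]
        items += keywords
        out = delim
        for key, value in items:
            out += f"{key}{delim}{value}{delim}"
        return out.encode("ascii")

    # TEXT length depends on the data offsets it contains; iterate to a
    # fixed point (two passes always suffice for monotone offset widths).
    text_begin = HEADER_LEN
    begin_data, end_data = 0, 0
    for _ in range(4):
        text = _render(begin_data, end_data)
        new_begin = text_begin + len(text)
        new_end = new_begin + data.nbytes - 1 if n_tot else new_begin
        if (new_begin, new_end) == (begin_data, end_data):
            break
        begin_data, end_data = new_begin, new_end
    text = _render(begin_data, end_data)
    text_end = text_begin + len(text) - 1

    def _field(value: int) -> bytes:
        field = str(value)
        if len(field) > 8:
            field = "0"  # too large for the header; TEXT keywords rule
        return field.rjust(8).encode("ascii")

    header = b"FCS3.1    "
    header += _field(text_begin) + _field(text_end)
    if end_data <= 99_999_999:
        header += _field(begin_data) + _field(end_data)
    else:
        header += _field(0) + _field(0)
    header += _field(0) + _field(0)
    assert len(header) == HEADER_LEN
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(data.tobytes())
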