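"""SAS XPORT (transport) version 5 reader/writer.

NHANES raw data tables are published as single-member XPORT v5 files:
80-byte ASCII records, big-endian IBM System/370 double-precision floats
for numeric columns, and space-padded ASCII for character columns.
Missing numeric values are stored as sentinel bytes ('.', '._', '.A'-'.Z')
rather than NaN; this module preserves them as strings so no information
is lost, and :func:`to_dataframe` maps them to NaN for analysis.
"""

from __future__ import annotations

import math
import re
import struct
from dataclasses import dataclass, field
from datetime import datetime
from typing import BinaryIO, Iterable, Union

import numpy as np
import pandas as pd

__all__ = [
    "XptVariable",
    "XptTable",
    "XptError",
    "XptFormatError",
    "XptCorruptionError",
    "XptTruncationError",
    "read_xpt",
    "write_xpt",
    "ibm_to_ieee",
    "ieee_to_ibm",
    "to_dataframe",
    "from_dataframe",
    "MISSING_CODES",
]

Cell = Union[float, str]

#: XPORT missing-value sentinels for numeric cells: '.', '._', '.A' ... '.Z'
MISSING_CODES = (".", "._") + tuple("." + c for c in "ABCDEFGHIJKLMNOPQRSTUVWXYZ")

_SENTINEL_BYTE = {".": 0x2E, "._": 0x5F}
_SENTINEL_BYTE.update({"." + c: ord(c) for c in "ABCDEFGHIJKLMNOPQRSTUVWXYZ"})
_BYTE_SENTINEL = {v: k for k, v in _SENTINEL_BYTE.items()}

_EPOCH = datetime(1960, 1, 1)  # SAS epoch; fixed clock for reproducible fixtures


class XptError(Exception):
    """Base class for transport-file problems."""


class XptFormatError(XptError):
    """The byte stream is not an XPORT v5 library."""


class XptCorruptionError(XptError):
    """Internal structure contradicts the declared counts."""


class XptTruncationError(XptError):
    """The final data record is incomplete."""


@dataclass
class XptVariable:
    """One column of a transport member."""

    name: str
    label: str = ""
    var_type: str = "numeric"  # 'numeric' | 'character'
    storage_length: int = 8
    position: int = 0

    def validate(self) -> None:
        if not self.name or len(self.name) > 8 or not self.name.isascii():
            raise ValueError(f"variable name {self.name!r} must be 1-8 ASCII chars")
        if len(self.label) > 40 or not self.label.isascii():
            raise ValueError(f"label for {self.name} exceeds 40 ASCII chars")
        if self.var_type == "numeric":
            if not 2 <= self.storage_length <= 8:
                raise ValueError(
                    f"numeric {self.name}: storage length {self.storage_length} not in [2, 8]"
                )
        elif self.var_type == "character":
            if not 1 <= self.storage_length <= 200:
                raise ValueError(
                    f"character {self.name}: storage length {self.storage_length} not in [1, 200]"
                )
        else:
            raise ValueError(f"unknown var_type {self.var_type!r}")


@dataclass
class XptTable:
    """Decoded contents and metadata of one transport member."""

    member_name: str
    variables: list[XptVariable]
    rows: list[list[Cell]] = field(default_factory=list)
    created: datetime = _EPOCH

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.variables]

    def validate(self) -> None:
        if not self.member_name or len(self.member_name) > 8:
            raise ValueError("member name must be 1-8 chars")
        seen: set[str] = set()
        for v in self.variables:
            v.validate()
            key = v.name.upper()
            if key in seen:
                raise ValueError(f"duplicate variable name {v.name}")
            seen.add(key)
        width = len(self.variables)
        for i, row in enumerate(self.rows):
            if len(row) != width:
                raise ValueError(f"row {i} has {len(row)} cells, expected {width}")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, XptTable):
            return NotImplemented
        if self.member_name != other.member_name or self.variables != other.variables:
            return False
        if len(self.rows) != len(other.rows):
            return False
        for a, b in zip(self.rows, other.rows):
            for x, y in zip(a, b):
                if isinstance(x, str) or isinstance(y, str):
                    if x != y:
                        return False
                elif x != y:  # exact float equality: IBM<->IEEE is lossless here
                    return False
        return True


# ---------------------------------------------------------------------------
# IBM System/370 double <-> IEEE 754


def ibm_to_ieee(word: bytes) -> Cell:
    """Decode one 8-byte IBM/370 double; sentinel patterns map to missing codes.

    Value is sign * 16**(exponent-64) * fraction/2**56.
    """
    if len(word) != 8:
        raise ValueError("IBM double must be exactly 8 bytes")
    b0 = word[0]
    rest = int.from_bytes(word[1:], "big")
    if rest == 0:
        if b0 == 0:
            return 0.0
        if b0 in _BYTE_SENTINEL:
            return _BYTE_SENTINEL[b0]
    sign = -1.0 if b0 & 0x80 else 1.0
    exponent = b0 & 0x7F
    return sign * math.ldexp(rest, 4 * (exponent - 64) - 56)


def ieee_to_ibm(x: Cell) -> bytes:
    """Encode a finite float (or a missing code) as a normalized IBM/370 double."""
    if isinstance(x, str):
        if x not in _SENTINEL_BYTE:
            raise ValueError(f"unknown missing code {x!r}")
        return bytes([_SENTINEL_BYTE[x]]) + b"\x00" * 7
    x = float(x)
    if math.isnan(x) or math.isinf(x):
        raise ValueError("NaN/Inf have no XPORT representation; use a missing code")
    if x == 0.0:
        return b"\x00" * 8
    sign = 0x80 if x < 0 else 0x00
    m, e = math.frexp(abs(x))  # abs(x) = m * 2**e, m in [0.5, 1)
    hex_exp = -((-e) // 4)  # ceil(e/4)
    shift = 4 * hex_exp - e  # 0..3 leading zero bits in the hex fraction
    mant = int(m * (1 << 53))  # exact: 53-bit significand
    frac = mant << (3 - shift)  # < 2**56, >= 2**52 (normalized)
    biased = hex_exp + 64
    if not 0 <= biased <= 127:
        raise ValueError(f"{x!r} outside IBM/370 double range")
    return bytes([sign | biased]) + frac.to_bytes(7, "big")


# ---------------------------------------------------------------------------
# Reading

_LIB_HEADER = (
    b"HEADER RECORD*******LIBRARY HEADER RECORD!!!!!!!"
    b"000000000000000000000000000000  "
)
_MEMBER_HEADER = (
    b"HEADER RECORD*******MEMBER  HEADER RECORD!!!!!!!"
    b"000000000000000001600000000140  "
)
_DSCRPTR_HEADER = (
    b"HEADER RECORD*******DSCRPTR HEADER RECORD!!!!!!!"
    b"000000000000000000000000000000  "
)
_OBS_HEADER = (
    b"HEADER RECORD*******OBS     HEADER RECORD!!!!!!!"
    b"000000000000000000000000000000  "
)
_NAMESTR_RE = re.compile(
    rb"HEADER RECORD\*{7}NAMESTR HEADER RECORD!{7}0{6}(\d{4})0{20}  "
)

_NAMESTR_FMT = ">hhhh8s40s8shhh2s8shhl52s"
assert struct.calcsize(_NAMESTR_FMT) == 140


def _parse_sas_datetime(text: str) -> datetime:
    try:
        return datetime.strptime(text.strip(), "%d%b%y:%H:%M:%S")
    except ValueError:
        return _EPOCH


def read_xpt(stream: Union[bytes, BinaryIO]) -> XptTable:
    """Decode a single-member XPORT v5 library into an :class:`XptTable`."""
    data = stream if isinstance(stream, (bytes, bytearray)) else stream.read()
    data = bytes(data)
    if len(data) < 80 * 8:
        raise XptFormatError("stream too short to be an XPORT library")
    if len(data) % 80 != 0:
        raise XptTruncationError(
            f"file length {len(data)} is not a multiple of 80 bytes"
        )
    if data[:80] != _LIB_HEADER:
        if b"LIBV8" in data[:80] or b"LIBV9" in data[:80]:
            raise XptFormatError(
                "XPORT v8/v9 transport detected; only v5 (the NHANES format) is supported"
            )
        raise XptFormatError("bad library header magic in first 80-byte record")
    # records 2-3: real header (version/os/dates); record 4: member header
    if data[240:320] != _MEMBER_HEADER:
        raise XptFormatError("missing MEMBER header record (multi-format file?)")
    if data[320:400] != _DSCRPTR_HEADER:
        raise XptFormatError("missing DSCRPTR header record")
    member_rec = data[400:480]
    member_name = member_rec[8:16].decode("ascii", "replace").strip()
    created = _parse_sas_datetime(member_rec[64:80].decode("ascii", "replace"))

    m = _NAMESTR_RE.match(data[560:640])
    if m is None:
        raise XptFormatError("missing NAMESTR header record")
    n_vars = int(m.group(1))
    if n_vars == 0:
        raise XptCorruptionError("NAMESTR header declares zero variables")

    namestr_bytes = n_vars * 140
    namestr_end = 640 + 80 * ((namestr_bytes + 79) // 80)
    if namestr_end + 80 > len(data):
        raise XptCorruptionError(
            f"declared {n_vars} variables but file ends inside NAMESTR section"
        )
    variables: list[XptVariable] = []
    for i in range(n_vars):
        raw = data[640 + i * 140 : 640 + (i + 1) * 140]
        (ntype, _, nlng, _, nname, nlabel, *_rest) = struct.unpack(_NAMESTR_FMT, raw)
        if ntype not in (1, 2):
            raise XptCorruptionError(
                f"NAMESTR {i}: variable type {ntype} is neither numeric nor character"
            )
        variables.append(
            XptVariable(
                name=nname.decode("ascii", "replace").strip(),
                label=nlabel.decode("ascii", "replace").strip(),
                var_type="numeric" if ntype == 1 else "character",
                storage_length=nlng,
                position=i,
            )
        )
    if data[namestr_end : namestr_end + 80] != _OBS_HEADER:
        raise XptCorruptionError(
            "NAMESTR count disagrees with section size: OBS header not found "
            f"at byte {namestr_end}"
        )

    body = data[namestr_end + 80 :]
    rec_len = sum(v.storage_length for v in variables)
    n_rows = len(body) // rec_len
    leftover = body[n_rows * rec_len :]
    if leftover.strip(b" "):
        raise XptTruncationError(
            f"truncated final record: {len(leftover)} stray bytes at offset "
            f"{namestr_end + 80 + n_rows * rec_len}"
        )
    # drop trailing all-blank rows that fit inside the final <80-byte padding
    while n_rows > 0 and len(body) - (n_rows - 1) * rec_len < 80:
        chunk = body[(n_rows - 1) * rec_len : n_rows * rec_len]
        if chunk.strip(b" "):
            break
        n_rows -= 1

    rows: list[list[Cell]] = []
    for r in range(n_rows):
        rec = body[r * rec_len : (r + 1) * rec_len]
        row: list[Cell] = []
        pos = 0
        for v in variables:
            raw = rec[pos : pos + v.storage_length]
            pos += v.storage_length
            if v.var_type == "numeric":
                word = raw + b"\x00" * (8 - len(raw))  # zero-extend short numerics
                row.append(ibm_to_ieee(word))
            else:
                row.append(raw.decode("ascii", "replace").rstrip(" "))
        rows.append(row)
    return XptTable(member_name=member_name, variables=variables, rows=rows, created=created)


# ---------------------------------------------------------------------------
# Writing


def _pad80(chunk: bytes) -> bytes:
    rem = len(chunk) % 80
    return chunk if rem == 0 else chunk + b" " * (80 - rem)


def write_xpt(table: XptTable) -> bytes:
    """Serialize an :class:`XptTable` as a single-member XPORT v5 byte stream.

    Output is deterministic for a fixed table (timestamps come from
    ``table.created``, which defaults to the SAS epoch).
    """
    table.validate()
    stamp = table.created.strftime("%d%b%y:%H:%M:%S").upper().encode("ascii")
    real1 = b"SAS     SAS     SASLIB  6.06    bsd4.2  " + b" " * 24 + stamp
    real2 = stamp + b" " * 64
    member1 = (
        b"SAS     "
        + table.member_name.upper().encode("ascii").ljust(8)
        + b"SASDATA 6.06    bsd4.2  "
        + b" " * 24
        + stamp
    )
    member2 = stamp + b" " * 16 + b" " * 40 + b" " * 8
    namestr_hdr = (
        b"HEADER RECORD*******NAMESTR HEADER RECORD!!!!!!!000000"
        + b"%04d" % len(table.variables)
        + b"0" * 20
        + b"  "
    )
    namestrs = b""
    pos = 0
    for i, v in enumerate(table.variables):
        namestrs += struct.pack(
            _NAMESTR_FMT,
            1 if v.var_type == "numeric" else 2,
            0,
            v.storage_length,
            i + 1,
            v.name.upper().encode("ascii").ljust(8),
            v.label.encode("ascii").ljust(40),
            b"        ",
            0,
            0,
            0,
            b"  ",
            b"        ",
            0,
            0,
            pos,
            b" " * 52,
        )
        pos += v.storage_length

    body = bytearray()
    for row in table.rows:
        for v, cell in zip(table.variables, row):
            if v.var_type == "numeric":
                body += ieee_to_ibm(cell)[: v.storage_length]
            else:
                text = str(cell)
                if len(text) > v.storage_length:
                    raise ValueError(
                        f"value {text!r} exceeds storage length of {v.name}"
                    )
                body += text.encode("ascii").ljust(v.storage_length)

    out = (
        _LIB_HEADER
        + real1
        + real2
        + _MEMBER_HEADER
        + _DSCRPTR_HEADER
        + member1
        + member2
        + namestr_hdr
        + _pad80(namestrs)
        + _OBS_HEADER
        + _pad80(bytes(body))
    )
    assert len(out) % 80 == 0
    return out


# ---------------------------------------------------------------------------
# pandas bridge


def to_dataframe(table: XptTable) -> pd.DataFrame:
    """Convert to a DataFrame; every numeric missing sentinel becomes NaN."""
    cols: dict[str, object] = {}
    for j, v in enumerate(table.variables):
        raw = [row[j] for row in table.rows]
        if v.var_type == "numeric":
            cols[v.name] = np.array(
                [np.nan if isinstance(x, str) else x for x in raw], dtype=float
            )
        else:
            cols[v.name] = pd.array(raw, dtype="string")
    return pd.DataFrame(cols)


def from_dataframe(
    df: pd.DataFrame,
    member_name: str,
    labels: dict[str, str] | None = None,
    char_lengths: dict[str, int] | None = None,
) -> XptTable:
    """Build an :class:`XptTable` from a DataFrame (NaN -> '.' sentinel)."""
    labels = labels or {}
    char_lengths = char_lengths or {}
    variables: list[XptVariable] = []
    for i, name in enumerate(df.columns):
        if pd.api.types.is_numeric_dtype(df[name]):
            variables.append(XptVariable(name, labels.get(name, ""), "numeric", 8, i))
        else:
            width = char_lengths.get(
                name, max(1, int(df[name].astype(str).str.len().max() or 1))
            )
            variables.append(
                XptVariable(name, labels.get(name, ""), "character", width, i)
            )
    rows: list[list[Cell]] = []
    for rec in df.itertuples(index=False):
        row: list[Cell] = []
        for v, cell in zip(variables, rec):
            if v.var_type == "numeric":
                row.append("." if pd.isna(cell) else float(cell))
            else:
                row.append("" if pd.isna(cell) else str(cell))
        rows.append(row)
    return XptTable(member_name=member_name, variables=variables, rows=rows)
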