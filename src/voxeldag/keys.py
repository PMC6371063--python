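"""Storage-key encoding.

Every persisted record uses one flat byte-string key laid out, in order:

    +----------------+---------------------+-------------+-----------+
    | data_id (4 B)  | TKey (class + body) | vid (4 B)   | T (1 B)   |
    | uint32 BE      | type-specific       | uint32 BE   | 00 or FF  |
    +----------------+---------------------+-------------+-----------+

data_id identifies the data instance, the TKey is the datatype-specific
key (first byte = key class, remainder a class-specific body), vid is the
compact version id, and the trailing tombstone byte marks deletion at that
version (0x00 = value, 0xFF = tombstone) without erasing ancestor data.

Because integers are big-endian and TKey bodies are fixed-length or
prefix-free within a class, lexicographic byte order groups all versions
of one TKey contiguously, which is what lets a single range scan gather
every stored version of a key.

Coordinates are stored biased by 2^31 (value + 2^31 as unsigned) so that
negative coordinates sort below positive ones.

Arbitrary string bodies are made prefix-free by escaping: each 0x00 byte
becomes 0x00 0xFE and the body ends with the terminator 0x00 0x00.
"""

from __future__ import annotations

import struct

__all__ = [
    "TOMBSTONE", "VALUE",
    "KeyError_", "encode_storage_key", "decode_storage_key",
    "block_tkey", "decode_block_tkey",
    "label_tkey", "decode_label_tkey",
    "string_tkey", "decode_string_tkey",
    "tkey_class", "next_prefix",
    "MAX_TKEY_BYTES",
]

VALUE = 0x00
TOMBSTONE = 0xFF
MAX_TKEY_BYTES = 4096
_BIAS = 1 << 31


class KeyError_(ValueError):
    """Malformed or oversized storage key component."""


def encode_storage_key(data_id: int, tkey: bytes, vid: int, tombstone: bool = False) -> bytes:
    if len(tkey) > MAX_TKEY_BYTES:
        raise KeyError_(f"TKey of {len(tkey)} bytes exceeds {MAX_TKEY_BYTES}")
    if not tkey:
        raise KeyError_("empty TKey")
    return (struct.pack(">I", data_id) + tkey + struct.pack(">I", vid)
            + (b"\xff" if tombstone else b"\x00"))


def decode_storage_key(key: bytes) -> tuple[int, bytes, int, bool]:
    if len(key) < 10:
        raise KeyError_(f"storage key too short ({len(key)} bytes)")
    data_id = struct.unpack(">I", key[:4])[0]
    vid = struct.unpack(">I", key[-5:-1])[0]
    tomb = key[-1:]
    if tomb not in (b"\x00", b"\xff"):
        raise KeyError_(f"bad tombstone byte {tomb!r}")
    return data_id, key[4:-5], vid, tomb == b"\xff"


def data_tkey_prefix(data_id: int, tkey: bytes) -> bytes:
    return struct.pack(">I", data_id) + tkey


# -- TKey classes ----------------------------------------------------------

def block_tkey(cls: int, bz: int, by: int, bx: int, scale: int = 0) -> bytes:
    """Fixed-length block TKey: class, scale, then biased ZYX coordinates."""
    return struct.pack(">BBIII", cls, scale, bz + _BIAS, by + _BIAS, bx + _BIAS)


def decode_block_tkey(tkey: bytes) -> tuple[int, int, tuple[int, int, int]]:
    """Return (class, scale, (bz, by, bx))."""
    cls, scale, z, y, x = struct.unpack(">BBIII", tkey)
    return cls, scale, (z - _BIAS, y - _BIAS, x - _BIAS)


def label_tkey(cls: int, label: int) -> bytes:
    return struct.pack(">BQ", cls, label)


def decode_label_tkey(tkey: bytes) -> int:
    cls, label = struct.unpack(">BQ", tkey)
    return label


def string_tkey(cls: int, s: str) -> bytes:
    body = s.encode("utf-8").replace(b"\x00", b"\x00\xfe")
    return bytes([cls]) + body + b"\x00\x00"


def decode_string_tkey(tkey: bytes) -> str:
    if len(tkey) < 3 or tkey[-2:] != b"\x00\x00":
        raise KeyError_("string TKey missing terminator")
    body = tkey[1:-2].replace(b"\x00\xfe", b"\x00")
    return body.decode("utf-8")


def tkey_class(tkey: bytes) -> int:
    return tkey[0]


def next_prefix(prefix: bytes) -> bytes:
    """Smallest byte string greater than every string with this prefix.

    Used as the exclusive upper bound of prefix range scans.
    """
    b = bytearray(prefix)
    while b and b[-1] == 0xFF:
        b.pop()
    if not b:
        # all-0xff prefix: no finite bound; callers use open-ended scan
        return b""
    b[-1] += 1
    return bytes(b)
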