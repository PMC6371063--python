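"""Lossless codec for 64³ blocks of 64-bit supervoxel labels.

The scheme follows the sub-block palette idea of Neuroglancer's
compressed-segmentation format with two changes: a block-level label list
shared by all sub-blocks (so per-sub-block palettes store small indices
into that list instead of 64-bit labels), and bit widths that need not be
powers of two.

Wire format (all integers little-endian; bit streams packed LSB-first
within bytes; each of the four sections is padded to a byte boundary):

    Section A  uint32 n_labels, then n_labels × uint64 label list,
               sorted ascending.
    Section B  512 × uint16: number of palette entries n_sub for each of
               the 8³ sub-blocks, in Z-major (Z,Y,X) sub-block order.
    Section C  palette bit stream: for each sub-block in order, n_sub
               indices into the label list, each g = ceil(log2 n_labels)
               bits (0 bits when n_labels == 1), sorted ascending.
    Section D  code bit stream: for each sub-block in order, 512 voxel
               codes (sub-block voxels in Z,Y,X order), each
               b = ceil(log2 n_sub) bits (0 bits when n_sub == 1),
               indexing that sub-block's palette.

A uniform block therefore costs exactly 4 + 8 + 1024 bytes.  The codec is
deterministic: identical voxels yield identical bytes.
"""

from __future__ import annotations

import struct

import numpy as np

__all__ = ["compress_block", "decompress_block", "block_stats", "CodecError",
           "BLOCK_SIDE", "SUB_SIDE"]

BLOCK_SIDE = 64
SUB_SIDE = 8
N_SUB_BLOCKS = (BLOCK_SIDE // SUB_SIDE) ** 3       # 512
SUB_VOXELS = SUB_SIDE ** 3                          # 512


class CodecError(ValueError):
    """Malformed, truncated, or out-of-range compressed stream."""


def _bit_width(n: int) -> int:
    """Minimal bits to address n distinct values (0 when n <= 1)."""
    return (n - 1).bit_length() if n > 1 else 0


def _pack_stream(chunks: list[tuple[np.ndarray, int]]) -> bytes:
    """Pack (values, width) chunks into one LSB-first bit stream."""
    parts = []
    for vals, w in chunks:
        if w == 0 or len(vals) == 0:
            continue
        v = vals.astype(np.uint64)
        bits = ((v[:, None] >> np.arange(w, dtype=np.uint64)) & np.uint64(1))
        parts.append(bits.astype(np.uint8).reshape(-1))
    if not parts:
        return b""
    return np.packbits(np.concatenate(parts), bitorder="little").tobytes()


def _unpack_stream(data: bytes, sizes: list[tuple[int, int]]) -> list[np.ndarray]:
    """Split a bit stream back into chunks of (count, width) values."""
    total_bits = sum(c * w for c, w in sizes)
    need = (total_bits + 7) // 8
    if len(data) < need:
        raise CodecError(f"bit stream truncated: {len(data)} < {need} bytes")
    bits = np.unpackbits(np.frombuffer(data, dtype=np.uint8),
                         bitorder="little")
    out = []
    off = 0
    for count, w in sizes:
        if w == 0 or count == 0:
            out.append(np.zeros(count, dtype=np.uint64))
            continue
        seg = bits[off:off + count * w].reshape(count, w).astype(np.uint64)
        out.append(seg @ (np.uint64(1) << np.arange(w, dtype=np.uint64)))
        off += count * w
    return out


def _to_subblocks(voxels: np.ndarray) -> np.ndarray:
    """(64,64,64) → (512 sub-blocks, 512 voxels), both Z-major."""
    n = BLOCK_SIDE // SUB_SIDE
    v = voxels.reshape(n, SUB_SIDE, n, SUB_SIDE, n, SUB_SIDE)
    return v.transpose(0, 2, 4, 1, 3, 5).reshape(N_SUB_BLOCKS, SUB_VOXELS)


def _from_subblocks(sub: np.ndarray) -> np.ndarray:
    n = BLOCK_SIDE // SUB_SIDE
    v = sub.reshape(n, n, n, SUB_SIDE, SUB_SIDE, SUB_SIDE)
    return v.transpose(0, 3, 1, 4, 2, 5).reshape(BLOCK_SIDE, BLOCK_SIDE, BLOCK_SIDE)


def compress_block(voxels: np.ndarray) -> bytes:
    v = np.asarray(voxels)
    if v.shape != (BLOCK_SIDE,) * 3:
        raise CodecError(f"block must be {BLOCK_SIDE}^3, got {v.shape}")
    v = np.ascontiguousarray(v, dtype=np.uint64)

    labels, inv = np.unique(v, return_inverse=True)
    inv = inv.astype(np.uint32).reshape(v.shape)
    sub = _to_subblocks(inv)

    n_labels = len(labels)
    g = _bit_width(n_labels)

    n_subs = np.empty(N_SUB_BLOCKS, dtype=np.uint16)
    pal_chunks: list[tuple[np.ndarray, int]] = []
    code_chunks: list[tuple[np.ndarray, int]] = []
    for i in range(N_SUB_BLOCKS):
        row = sub[i]
        pal = np.unique(row)                       # sorted ascending
        ns = len(pal)
        n_subs[i] = ns
        pal_chunks.append((pal, g))
        b = _bit_width(ns)
        if b:
            code_chunks.append((np.searchsorted(pal, row), b))

    section_a = struct.pack("<I", n_labels) + labels.astype("<u8").tobytes()
    section_b = n_subs.astype("<u2").tobytes()
    section_c = _pack_stream(pal_chunks)
    section_d = _pack_stream(code_chunks)
    return section_a + section_b + section_c + section_d


def _parse_header(data: bytes):
    if len(data) < 4:
        raise CodecError("stream shorter than header")
    n_labels = struct.unpack_from("<I", data, 0)[0]
    off = 4 + 8 * n_labels
    if len(data) < off + 2 * N_SUB_BLOCKS:
        raise CodecError("stream truncated in label list / sub-block counts")
    labels = np.frombuffer(data, dtype="<u8", count=n_labels, offset=4)
    n_subs = np.frombuffer(data, dtype="<u2", count=N_SUB_BLOCKS, offset=off)
    off += 2 * N_SUB_BLOCKS
    return n_labels, labels, n_subs.astype(np.int64), off


def decompress_block(data: bytes) -> np.ndarray:
    n_labels, labels, n_subs, off = _parse_header(data)
    if n_labels == 0:
        raise CodecError("empty label list")
    if (n_subs < 1).any() or (n_subs > SUB_VOXELS).any():
        raise CodecError("sub-block palette size out of range")
    g = _bit_width(n_labels)

    pal_bits = int(n_subs.sum()) * g
    pal_bytes = (pal_bits + 7) // 8
    palettes = _unpack_stream(data[off:off + pal_bytes],
                              [(int(ns), g) for ns in n_subs])
    off += pal_bytes

    widths = [_bit_width(int(ns)) for ns in n_subs]
    code_bytes = (sum(SUB_VOXELS * b for b in widths) + 7) // 8
    if len(data) < off + code_bytes:
        raise CodecError("code section truncated")
    codes = _unpack_stream(data[off:off + code_bytes],
                           [(SUB_VOXELS if b else 0, b) for b in widths])

    sub = np.empty((N_SUB_BLOCKS, SUB_VOXELS), dtype=np.uint64)
    for i in range(N_SUB_BLOCKS):
        pal = palettes[i]
        if len(pal) and int(pal.max()) >= n_labels:
            raise CodecError("palette index out of range")
        if widths[i] == 0:
            sub[i] = labels[int(pal[0])]
        else:
            c = codes[i]
            if int(c.max()) >= len(pal):
                raise CodecError("voxel code out of range")
            sub[i] = labels[pal[c.astype(np.int64)].astype(np.int64)]
    return _from_subblocks(sub)


def block_stats(data: bytes) -> dict:
    """Size accounting from the stream header, without decoding voxels."""
    n_labels, _, n_subs, off = _parse_header(data)
    g = _bit_width(n_labels)
    pal_bytes = (int(n_subs.sum()) * g + 7) // 8
    code_bytes = (sum(SUB_VOXELS * _bit_width(int(ns)) for ns in n_subs) + 7) // 8
    expect = off + pal_bytes + code_bytes
    if len(data) != expect:
        raise CodecError(f"stream length {len(data)} != expected {expect}")
    return {
        "n_labels": int(n_labels),
        "compressed_size": len(data),
        "bits_per_voxel": 8.0 * len(data) / BLOCK_SIDE ** 3,
    }
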