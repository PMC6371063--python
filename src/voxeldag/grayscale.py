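"""uint8blk: versioned 3D grayscale volumes.

Volumes are stored as raw uint8 blocks (default 64³) under block-coordinate
TKeys with a scale byte, giving arbitrary subvolume and slice access plus a
multiscale pyramid where each scale halves every axis.  Arrays are (z, y, x).
Missing data reads as 0, matching sparse ingestion.
"""

from __future__ import annotations

import numpy as np

from . import keys as K
from .blocks import intersecting_blocks
from .types import BaseInstance, register

__all__ = ["Uint8BlkInstance"]

CLS_BLOCK = 0x01


def _downsample_mean(arr: np.ndarray) -> np.ndarray:
    """2×2×2 mean, rounded half up, for an even-sided uint8 cube."""
    n = arr.shape[0] // 2
    s = arr.reshape(n, 2, n, 2, n, 2).sum(axis=(1, 3, 5), dtype=np.uint32)
    return ((s + 4) // 8).astype(np.uint8)


@register("uint8blk")
class Uint8BlkInstance(BaseInstance):

    @property
    def block_size(self) -> int:
        b = int(self.config.get("block_size", 64))
        if b < 8 or b & (b - 1):
            raise ValueError("block_size must be a power of two ≥ 8")
        return b

    def _tkey(self, bz: int, by: int, bx: int, scale: int = 0) -> bytes:
        return K.block_tkey(CLS_BLOCK, bz, by, bx, scale=scale)

    def _get_block(self, ctx, coord, scale=0) -> np.ndarray | None:
        raw = ctx.vget(self._tkey(*coord, scale=scale))
        if raw is None:
            return None
        b = self.block_size
        return np.frombuffer(raw, dtype=np.uint8).reshape(b, b, b)

    def put_subvolume(self, version: str, offset: tuple[int, int, int],
                      data: np.ndarray, scale: int = 0) -> None:
        """Read-modify-write every intersecting block at ``version``.

        Partially covered blocks inherit untouched voxels from the closest
        stored ancestor before the write.
        """
        data = np.asarray(data)
        if data.dtype != np.uint8:
            raise TypeError("uint8blk payloads must be uint8")
        ctx = self.ctx(version)
        ctx.check_mutable()
        b = self.block_size
        for coord, arr_sl, blk_sl in intersecting_blocks(offset, data.shape, b):
            full = all(sl.stop - sl.start == b for sl in blk_sl)
            if full:
                block = np.ascontiguousarray(data[arr_sl])
            else:
                existing = self._get_block(ctx, coord, scale)
                block = (np.zeros((b, b, b), np.uint8) if existing is None
                         else existing.copy())
                block[blk_sl] = data[arr_sl]
            ctx.vput(self._tkey(*coord, scale=scale), block.tobytes())

    def get_subvolume(self, version: str, offset: tuple[int, int, int],
                      shape: tuple[int, int, int], scale: int = 0) -> np.ndarray:
        if min(shape) <= 0:
            raise ValueError("shape must be positive")
        ctx = self.ctx(version)
        out = np.zeros(shape, dtype=np.uint8)
        for coord, arr_sl, blk_sl in intersecting_blocks(offset, shape,
                                                         self.block_size):
            block = self._get_block(ctx, coord, scale)
            if block is not None:
                out[arr_sl] = block[blk_sl]
        return out

    def get_slice(self, version: str, plane: str, offset: tuple[int, int, int],
                  width: int, height: int, scale: int = 0) -> np.ndarray:
        """2D slice; ``plane`` is "XY", "XZ" or "YZ".

        XY: width along X, height along Y.  XZ: width along X, height
        along Z.  YZ: width along Y, height along Z.  Returns
        (height, width).
        """
        plane = plane.upper()
        if plane == "XY":
            shape = (1, height, width)
        elif plane == "XZ":
            shape = (height, 1, width)
        elif plane == "YZ":
            shape = (height, width, 1)
        else:
            raise ValueError(f"unknown plane {plane!r}")
        vol = self.get_subvolume(version, offset, shape, scale)
        if plane == "XY":
            return vol[0]
        if plane == "XZ":
            return vol[:, 0, :]
        return vol[:, :, 0]

    def _blocks_at_scale(self, ctx, scale: int) -> list[tuple[int, int, int]]:
        prefix = bytes([CLS_BLOCK, scale])
        coords = []
        for tkey, _ in ctx.prefix_scan(prefix):
            _, _, coord = K.decode_block_tkey(tkey)
            coords.append(coord)
        return coords

    def build_pyramid(self, version: str, max_scale: int) -> None:
        """Build scales 1..max_scale; scale k voxels are the 2×2×2 mean
        (rounded half up) of scale k−1.  Blocks absent at the finer scale
        contribute nothing (the parent region stays 0)."""
        ctx = self.ctx(version)
        ctx.check_mutable()
        b = self.block_size
        h = b // 2
        for scale in range(1, max_scale + 1):
            children = self._blocks_at_scale(ctx, scale - 1)
            parents: dict[tuple[int, int, int], list[tuple[int, int, int]]] = {}
            for c in children:
                parents.setdefault(tuple(v // 2 for v in c), []).append(c)
            for pcoord in sorted(parents):
                parent = np.zeros((b, b, b), np.uint8)
                for c in parents[pcoord]:
                    child = self._get_block(ctx, c, scale - 1)
                    if child is None:
                        continue
                    oz, oy, ox = (h * (c[0] % 2), h * (c[1] % 2), h * (c[2] % 2))
                    parent[oz:oz + h, oy:oy + h, ox:ox + h] = _downsample_mean(child)
                ctx.vput(self._tkey(*pcoord, scale=scale), parent.tobytes())
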