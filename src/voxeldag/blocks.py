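"""Block decomposition arithmetic shared by the voxel data types.

Volumes are partitioned into cubic blocks of B voxels per axis; voxel
(z, y, x) belongs to block (floor(z/B), floor(y/B), floor(x/B)).  Arrays
are indexed (z, y, x) throughout.
"""

from __future__ import annotations

from typing import Iterator

__all__ = ["blocks_for_extent", "block_count", "intersecting_blocks"]


def block_count(extent: tuple[int, int, int], block_size: int) -> int:
    nz, ny, nx = extent
    b = block_size
    return ((nz + b - 1) // b) * ((ny + b - 1) // b) * ((nx + b - 1) // b)


def blocks_for_extent(extent: tuple[int, int, int], block_size: int
                      ) -> tuple[int, Iterator[tuple[int, int, int]]]:
    """Count and lazily iterate (Z-major) the blocks covering an extent
    anchored at the origin.  No voxel data is materialized."""
    if min(extent) <= 0:
        raise ValueError("extent must be positive")
    b = block_size
    nz, ny, nx = ((e + b - 1) // b for e in extent)

    def it() -> Iterator[tuple[int, int, int]]:
        for bz in range(nz):
            for by in range(ny):
                for bx in range(nx):
                    yield (bz, by, bx)

    return nz * ny * nx, it()


def intersecting_blocks(offset: tuple[int, int, int],
                        shape: tuple[int, int, int],
                        block_size: int):
    """Yield (block_coord, array_slices, block_slices) for every block a
    subvolume at ``offset`` (z, y, x) with ``shape`` intersects.

    ``array_slices`` index the subvolume array, ``block_slices`` the 64³
    (or B³) block array.
    """
    b = block_size
    z0, y0, x0 = offset
    nz, ny, nx = shape
    for bz in range(z0 // b, -(-(z0 + nz) // b)):
        zs = max(z0, bz * b)
        ze = min(z0 + nz, (bz + 1) * b)
        for by in range(y0 // b, -(-(y0 + ny) // b)):
            ys = max(y0, by * b)
            ye = min(y0 + ny, (by + 1) * b)
            for bx in range(x0 // b, -(-(x0 + nx) // b)):
                xs = max(x0, bx * b)
                xe = min(x0 + nx, (bx + 1) * b)
                arr_sl = (slice(zs - z0, ze - z0),
                          slice(ys - y0, ye - y0),
                          slice(xs - x0, xe - x0))
                blk_sl = (slice(zs - bz * b, ze - bz * b),
                          slice(ys - by * b, ye - by * b),
                          slice(xs - bx * b, xe - bx * b))
                yield (bz, by, bx), arr_sl, blk_sl
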