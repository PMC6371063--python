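"""labelmap: versioned 64-bit segmentation with supervoxel agglomeration.

Voxels store *supervoxel* ids in compressed 64³ blocks.  Agglomerated
neurons ("bodies") are defined by an in-memory supervoxel→body map that is
reconstructed by replaying an append-only mutation log (merges, cleaves,
supervoxel splits) from the root to the queried version.  Merges and
cleaves therefore touch no voxel blocks at all; only supervoxel splits
rewrite blocks.

Persistent key classes:

* 0x01 — compressed supervoxel blocks (scale byte + ZYX block coordinate).
* 0x02 — per-supervoxel indices (uint64 id → JSON {"z,y,x": voxel count}).

A body's index, size, and sparse volume are the union over its member
supervoxels, so no per-body record ever needs rewriting on merge/cleave.
"""

from __future__ import annotations

import json
import struct

import numpy as np

from . import keys as K
from .blockcodec import BLOCK_SIDE, compress_block, decompress_block
from .blocks import intersecting_blocks
from .types import BaseInstance, register

__all__ = ["LabelmapInstance", "SparseVol", "MappingTable", "LabelmapError"]

CLS_BLOCK = 0x01
CLS_INDEX = 0x02


class LabelmapError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Sparse volumes (run-length encoding along X)
# ---------------------------------------------------------------------------

class SparseVol:
    """A label's voxel set as X-runs, sorted by (z, y, x).

    Binary wire format (little-endian): uint8 payload descriptor (0),
    uint32 run count, then runs of 4 × int32 (x, y, z, length).
    """

    def __init__(self, label: int, runs):
        self.label = int(label)
        r = np.asarray(runs, dtype=np.int64).reshape(-1, 4)
        order = np.lexsort((r[:, 0], r[:, 1], r[:, 2]))  # sort by (z, y, x)
        self.runs = r[order]

    @property
    def voxel_count(self) -> int:
        return int(self.runs[:, 3].sum()) if len(self.runs) else 0

    def coords(self) -> np.ndarray:
        """(n, 3) array of (z, y, x) voxel coordinates (oracle helper)."""
        if not len(self.runs):
            return np.empty((0, 3), np.int64)
        parts = []
        for x, y, z, n in self.runs:
            xs = np.arange(x, x + n)
            parts.append(np.stack([np.full(n, z), np.full(n, y), xs], axis=1))
        return np.concatenate(parts)

    def clipped(self, minz=None, maxz=None) -> "SparseVol":
        r = self.runs
        keep = np.ones(len(r), bool)
        if minz is not None:
            keep &= r[:, 2] >= minz
        if maxz is not None:
            keep &= r[:, 2] <= maxz
        return SparseVol(self.label, r[keep])

    @classmethod
    def from_mask(cls, label: int, mask: np.ndarray,
                  origin=(0, 0, 0)) -> "SparseVol":
        """RLE-encode a boolean (z, y, x) mask anchored at ``origin``."""
        oz, oy, ox = origin
        d = np.diff(mask.astype(np.int8), axis=2, prepend=0, append=0)
        starts = np.argwhere(d == 1)
        ends = np.argwhere(d == -1)
        runs = np.empty((len(starts), 4), np.int64)
        runs[:, 0] = starts[:, 2] + ox
        runs[:, 1] = starts[:, 1] + oy
        runs[:, 2] = starts[:, 0] + oz
        runs[:, 3] = ends[:, 2] - starts[:, 2]
        return cls(label, runs)

    def to_binary(self) -> bytes:
        head = struct.pack("<BI", 0, len(self.runs))
        return head + self.runs.astype("<i4").tobytes()

    @classmethod
    def from_binary(cls, data: bytes, label: int = 0) -> "SparseVol":
        desc, n = struct.unpack_from("<BI", data, 0)
        runs = np.frombuffer(data, dtype="<i4", count=4 * n, offset=5)
        return cls(label, runs.reshape(n, 4).astype(np.int64))

    def to_json(self) -> list:
        return [[int(a) for a in run] for run in self.runs]


class MappingTable:
    """Supervoxel → body map for one version (identity where absent)."""

    def __init__(self, version: str):
        self.version = version
        self.forward: dict[int, int] = {}
        self.reverse: dict[int, set[int]] = {}
        self.built_from = 0  # log entries replayed

    def body(self, supervoxel: int) -> int:
        return self.forward.get(supervoxel, supervoxel)

    def members(self, body: int) -> set[int]:
        m = set(self.reverse.get(body, ()))
        if self.forward.get(body, body) == body:
            m.add(body)
        return m

    def _assign(self, sv: int, body: int) -> None:
        old = self.forward.get(sv, sv)
        if old in self.reverse:
            self.reverse[old].discard(sv)
            if not self.reverse[old]:
                del self.reverse[old]
        if sv == body:
            self.forward.pop(sv, None)
        else:
            self.forward[sv] = body
            self.reverse.setdefault(body, set()).add(sv)

    def apply(self, entry) -> None:
        p = entry.payload
        if entry.kind == "merge":
            target = int(p["target"])
            for lab in p["labels"]:
                for sv in self.members(int(lab)):
                    self._assign(sv, target)
        elif entry.kind == "cleave":
            new_body = int(p["new_body"])
            for sv in p["supervoxels"]:
                self._assign(int(sv), new_body)
        elif entry.kind == "split":
            pass  # the new supervoxel is identity-mapped: a fresh body
        else:  # pragma: no cover
            raise LabelmapError(f"unknown mutation kind {entry.kind!r}")
        self.built_from += 1


# ---------------------------------------------------------------------------
# The data type
# ---------------------------------------------------------------------------

@register("labelmap")
class LabelmapInstance(BaseInstance):

    def __init__(self, service, repo, instance):
        super().__init__(service, repo, instance)
        self._map_cache: dict[tuple[str, int], MappingTable] = {}
        self._max_label_seen = 0

    # -- keys & low-level access ------------------------------------------

    def _block_tkey(self, coord, scale=0) -> bytes:
        return K.block_tkey(CLS_BLOCK, *coord, scale=scale)

    def _index_tkey(self, label: int) -> bytes:
        return K.label_tkey(CLS_INDEX, label)

    def _get_block(self, ctx, coord, scale=0) -> np.ndarray | None:
        raw = ctx.vget(self._block_tkey(coord, scale))
        return None if raw is None else decompress_block(raw)

    def _get_index(self, ctx, supervoxel: int) -> dict[tuple[int, int, int], int]:
        raw = ctx.vget(self._index_tkey(supervoxel))
        if raw is None:
            return {}
        d = json.loads(raw)
        return {tuple(int(v) for v in k.split(",")): int(c) for k, c in d.items()}

    def _put_index(self, ctx, supervoxel: int, idx: dict) -> None:
        if not idx:
            ctx.vdelete(self._index_tkey(supervoxel))
            return
        enc = {",".join(map(str, k)): int(v) for k, v in sorted(idx.items())}
        ctx.vput(self._index_tkey(supervoxel), json.dumps(enc).encode())

    # -- mapping -----------------------------------------------------------

    def build_mapping(self, version: str) -> MappingTable:
        """Replay mutation logs along the root→version first-parent path.

        Cached per (version, #entries-on-path); appending a log entry
        naturally invalidates the cache.
        """
        path = self.repo.first_parent_path(version)
        entries = []
        for u in path:
            entries.extend(self.service.mutation_log.entries(self.data_id, u))
        key = (version, len(entries))
        cached = self._map_cache.get(key)
        if cached is not None:
            return cached
        table = MappingTable(version)
        for e in sorted(entries, key=lambda e: e.seq):
            table.apply(e)
        self._map_cache[key] = table
        return table

    # -- allocator ---------------------------------------------------------

    def _note_labels(self, labels) -> None:
        if len(labels):
            self._max_label_seen = max(self._max_label_seen, int(np.max(labels)))

    def _allocate_label(self) -> int:
        """Fresh label: (max label ever seen in the repo) + 1."""
        if self._max_label_seen == 0:
            self._recover_max_label()
        self._max_label_seen += 1
        return self._max_label_seen

    def _recover_max_label(self) -> None:
        # raw scan of all index keys (any version) + log allocations
        prefix = K.data_tkey_prefix(self.data_id, bytes([CLS_INDEX]))
        mx = 0
        for k, _ in self.service.store.scan(prefix, K.next_prefix(prefix)):
            _, tkey, _, _ = K.decode_storage_key(k)
            mx = max(mx, K.decode_label_tkey(tkey))
        for (did, _), es in self.service.mutation_log._entries.items():
            if did != self.data_id:
                continue
            for e in es:
                for f in ("new_body", "new_supervoxel"):
                    if f in e.payload:
                        mx = max(mx, int(e.payload[f]))
        self._max_label_seen = mx

    # -- ingestion ---------------------------------------------------------

    def ingest(self, version: str, offset: tuple[int, int, int],
               labels: np.ndarray) -> None:
        """Store a supervoxel array (z, y, x) and update label indices.

        The mapping is untouched: ingested voxels are supervoxels.
        Background (label 0) is never indexed.
        """
        arr = np.ascontiguousarray(labels, dtype=np.uint64)
        ctx = self.ctx(version)
        ctx.check_mutable()
        self._note_labels(arr)
        b = BLOCK_SIDE
        # per-label index deltas, applied after all blocks are written
        idx_delta: dict[int, dict[tuple[int, int, int], int | None]] = {}
        for coord, arr_sl, blk_sl in intersecting_blocks(offset, arr.shape, b):
            old = self._get_block(ctx, coord)
            full = all(sl.stop - sl.start == b for sl in blk_sl)
            if full:
                new = arr[arr_sl]
            else:
                new = np.zeros((b, b, b), np.uint64) if old is None else old.copy()
                new[blk_sl] = arr[arr_sl]
            ctx.vput(self._block_tkey(coord), compress_block(new))
            old_u, old_c = (np.unique(old, return_counts=True)
                            if old is not None else (np.array([], np.uint64), None))
            new_u, new_c = np.unique(new, return_counts=True)
            new_counts = dict(zip(new_u.tolist(), new_c.tolist()))
            for lab in set(old_u.tolist()) | set(new_u.tolist()):
                if lab == 0:
                    continue
                cnt = new_counts.get(lab)
                idx_delta.setdefault(lab, {})[coord] = cnt  # None = remove
        for lab in sorted(idx_delta):
            idx = self._get_index(ctx, lab)
            for coord, cnt in idx_delta[lab].items():
                if cnt is None:
                    idx.pop(coord, None)
                else:
                    idx[coord] = cnt
            self._put_index(ctx, lab, idx)

    # -- queries -----------------------------------------------------------

    def get_label(self, version: str, point: tuple[int, int, int],
                  supervoxels: bool = False) -> int:
        """Label at voxel point (x, y, z); 0 outside stored data."""
        x, y, z = point
        b = BLOCK_SIDE
        ctx = self.ctx(version)
        block = self._get_block(ctx, (z // b, y // b, x // b))
        if block is None:
            return 0
        sv = int(block[z % b, y % b, x % b])
        if supervoxels or sv == 0:
            return sv
        return self.build_mapping(version).body(sv)

    def _member_svs(self, version: str, label: int, supervoxels: bool) -> set[int]:
        if supervoxels:
            return {label}
        return self.build_mapping(version).members(label)

    def label_size(self, version: str, label: int,
                   supervoxels: bool = False) -> int:
        ctx = self.ctx(version)
        total = 0
        for sv in self._member_svs(version, label, supervoxels):
            total += sum(self._get_index(ctx, sv).values())
        return total

    def sparsevol(self, version: str, label: int, minz=None, maxz=None,
                  supervoxels: bool = False) -> SparseVol:
        ctx = self.ctx(version)
        svs = self._member_svs(version, label, supervoxels)
        blocks: set[tuple[int, int, int]] = set()
        for sv in svs:
            blocks.update(self._get_index(ctx, sv).keys())
        b = BLOCK_SIDE
        sv_arr = np.fromiter(svs, dtype=np.uint64) if svs else np.array([], np.uint64)
        all_runs = []
        for coord in sorted(blocks):
            bz, by, bx = coord
            if minz is not None and (bz + 1) * b <= minz:
                continue
            if maxz is not None and bz * b > maxz:
                continue
            block = self._get_block(ctx, coord)
            if block is None:
                continue
            mask = np.isin(block, sv_arr)
            vol = SparseVol.from_mask(label, mask, origin=(bz * b, by * b, bx * b))
            all_runs.append(vol.runs)
        runs = np.concatenate(all_runs) if all_runs else np.empty((0, 4), np.int64)
        out = SparseVol(label, runs)
        if minz is not None or maxz is not None:
            out = out.clipped(minz, maxz)
        return out

    def get_subvolume(self, version: str, offset: tuple[int, int, int],
                      shape: tuple[int, int, int], scale: int = 0,
                      supervoxels: bool = False) -> np.ndarray:
        """Materialize a (z, y, x) label array; body view unless
        ``supervoxels``.  Missing blocks read as 0."""
        if min(shape) <= 0:
            raise LabelmapError("shape must be positive")
        ctx = self.ctx(version)
        out = np.zeros(shape, dtype=np.uint64)
        for coord, arr_sl, blk_sl in intersecting_blocks(offset, shape,
                                                         BLOCK_SIDE):
            block = self._get_block(ctx, coord, scale)
            if block is not None:
                out[arr_sl] = block[blk_sl]
        if not supervoxels:
            mapping = self.build_mapping(version)
            if mapping.forward:
                u, inv = np.unique(out, return_inverse=True)
                mapped = np.array([mapping.body(int(s)) for s in u],
                                  dtype=np.uint64)
                out = mapped[inv].reshape(shape)
        return out

    def get_specific_blocks(self, version: str, coords, scale: int = 0):
        """Compressed payloads in request order; None marks absent blocks."""
        ctx = self.ctx(version)
        return [(tuple(c), ctx.vget(self._block_tkey(tuple(c), scale)))
                for c in coords]

    def list_indexed_labels(self, version: str) -> list[int]:
        ctx = self.ctx(version)
        return [K.decode_label_tkey(t)
                for t, _ in ctx.prefix_scan(bytes([CLS_INDEX]))]

    def body_exists(self, version: str, label: int) -> bool:
        return self.label_size(version, label) > 0

    # -- mutations ---------------------------------------------------------

    def _log(self, version: str, kind: str, payload: dict):
        entry = self.service.mutation_log.append(self.data_id, version, kind, payload)
        self.service.publish_mutation(self.data_id, version, entry)
        return entry

    def merge(self, version: str, target: int, labels: list[int]) -> None:
        """Fold whole bodies into ``target``.  Mapping-only: no block or
        index key-value is touched."""
        self.repo.check_mutable(version)
        labels = [int(l) for l in labels]
        if target in labels:
            raise LabelmapError("merge target cannot be among merged labels")
        if len(set(labels)) != len(labels):
            raise LabelmapError("duplicate labels in merge list")
        if not self.body_exists(version, target):
            raise LabelmapError(f"unknown merge target {target}")
        for l in labels:
            if not self.body_exists(version, l):
                raise LabelmapError(f"unknown label {l} in merge list")
        self._log(version, "merge", {"target": int(target), "labels": labels})

    def cleave(self, version: str, body: int, supervoxels: list[int]) -> int:
        """Split ``body`` along supervoxel boundaries: the listed
        supervoxels move to a fresh body.  Mapping-only."""
        self.repo.check_mutable(version)
        svs = [int(s) for s in supervoxels]
        if not svs:
            raise LabelmapError("cleave needs at least one supervoxel")
        mapping = self.build_mapping(version)
        members = mapping.members(body)
        # the body must actually exist at this version
        if not self.body_exists(version, body):
            raise LabelmapError(f"unknown body {body}")
        for sv in svs:
            if sv not in members:
                raise LabelmapError(f"supervoxel {sv} is not part of body {body}")
        if set(svs) >= members:
            raise LabelmapError("cannot cleave all supervoxels out of a body")
        new_body = self._allocate_label()
        self._log(version, "cleave",
                  {"body": int(body), "supervoxels": svs, "new_body": new_body})
        return new_body

    def split_supervoxel(self, version: str, label: int,
                         split_rle: SparseVol) -> int:
        """Relabel the RLE voxels of supervoxel ``label`` to a fresh
        supervoxel id, rewriting only the affected blocks and the two
        label indices."""
        self.repo.check_mutable(version)
        ctx = self.ctx(version)
        idx = self._get_index(ctx, label)
        if not idx:
            raise LabelmapError(f"unknown supervoxel {label}")
        b = BLOCK_SIDE
        # group run fragments by block
        by_block: dict[tuple[int, int, int], list[tuple[int, int, int, int]]] = {}
        total = 0
        for x, y, z, n in split_rle.runs:
            x, y, z, n = int(x), int(y), int(z), int(n)
            total += n
            while n > 0:
                coord = (z // b, y // b, x // b)
                take = min(n, (coord[2] + 1) * b - x)
                by_block.setdefault(coord, []).append((x, y, z, take))
                x += take
                n -= take
        if total == 0:
            raise LabelmapError("empty split")
        if total >= sum(idx.values()):
            raise LabelmapError("split would cover the entire supervoxel")
        new_label = self._allocate_label()
        moved: dict[tuple[int, int, int], int] = {}
        for coord in sorted(by_block):
            if coord not in idx:
                raise LabelmapError(
                    f"split voxels touch block {coord} outside supervoxel {label}")
            block = self._get_block(ctx, coord)
            assert block is not None
            oz, oy, ox = coord[0] * b, coord[1] * b, coord[2] * b
            for x, y, z, n in by_block[coord]:
                seg = block[z - oz, y - oy, x - ox:x - ox + n]
                if not (seg == label).all():
                    raise LabelmapError(
                        "split voxels do not all belong to the supervoxel")
                seg[...] = new_label
            ctx.vput(self._block_tkey(coord), compress_block(block))
            moved[coord] = sum(n for _, _, _, n in by_block[coord])
        for coord, n in moved.items():
            idx[coord] -= n
            if idx[coord] <= 0:
                del idx[coord]
        self._put_index(ctx, label, idx)
        self._put_index(ctx, new_label, dict(moved))
        self._log(version, "split",
                  {"supervoxel": int(label), "new_supervoxel": new_label,
                   "runs": split_rle.to_json()})
        return new_label

    # -- multiscale --------------------------------------------------------

    def _blocks_at_scale(self, ctx, scale: int):
        coords = []
        for tkey, _ in ctx.prefix_scan(bytes([CLS_BLOCK, scale])):
            _, _, coord = K.decode_block_tkey(tkey)
            coords.append(coord)
        return coords

    def downsample_labels(self, version: str, max_scale: int) -> None:
        """Build scales 1..max_scale; scale k voxels are the mode of
        their 2×2×2 children, ties broken by the smaller label."""
        ctx = self.ctx(version)
        ctx.check_mutable()
        b = BLOCK_SIDE
        h = b // 2
        for scale in range(1, max_scale + 1):
            children = self._blocks_at_scale(ctx, scale - 1)
            parents: dict[tuple[int, int, int], list] = {}
            for c in children:
                parents.setdefault(tuple(v // 2 for v in c), []).append(c)
            for pcoord in sorted(parents):
                parent = np.zeros((b, b, b), np.uint64)
                for c in parents[pcoord]:
                    child = self._get_block(ctx, c, scale - 1)
                    if child is None:
                        continue
                    oz, oy, ox = (h * (c[0] % 2), h * (c[1] % 2), h * (c[2] % 2))
                    parent[oz:oz + h, oy:oy + h, ox:ox + h] = _mode_downsample(child)
                ctx.vput(self._block_tkey(pcoord, scale), compress_block(parent))

    # -- hooks for annotation sync ----------------------------------------

    def on_segmentation_mutation(self, version, entry):  # pragma: no cover
        raise LabelmapError("labelmap instances cannot subscribe to mutations")


def _mode_downsample(arr: np.ndarray) -> np.ndarray:
    """2×2×2 mode with ties to the smallest label."""
    n = arr.shape[0] // 2
    a = (arr.reshape(n, 2, n, 2, n, 2)
            .transpose(0, 2, 4, 1, 3, 5)
            .reshape(-1, 8))
    s = np.sort(a, axis=1)
    counts = (s[:, :, None] == s[:, None, :]).sum(axis=2)
    # argmax returns the first maximal count; rows are sorted ascending,
    # so ties resolve to the smallest label
    pick = np.argmax(counts, axis=1)
    out = s[np.arange(len(s)), pick]
    return out.reshape(n, n, n)
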