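"""Independent oracles for versioned semantics.

These deliberately avoid the package's storage path: versions hold their
own write records, and resolution is a direct breadth-first walk over the
DAG's parent links.  Label semantics are re-derived from materialized
voxel arrays and a from-scratch mapping replay.
"""

from __future__ import annotations

import numpy as np


class SnapshotOracle:
    """Materialized per-version key→value view of a versioned kv space."""

    def __init__(self, repo):
        self.repo = repo
        self.writes: dict[str, dict[bytes, tuple[bool, bytes]]] = {}

    def put(self, version: str, tkey: bytes, value: bytes) -> None:
        self.writes.setdefault(version, {})[tkey] = (False, value)

    def delete(self, version: str, tkey: bytes) -> None:
        self.writes.setdefault(version, {})[tkey] = (True, b"")

    def _resolve(self, version: str, tkey: bytes):
        # BFS upward, target first, parents in stored order
        queue = [version]
        seen = {version}
        while queue:
            nxt = []
            for u in queue:
                rec = self.writes.get(u, {}).get(tkey)
                if rec is not None:
                    return rec
                for p in self.repo.nodes[u].parents:
                    if p not in seen:
                        seen.add(p)
                        nxt.append(p)
            queue = nxt
        return None

    def get(self, version: str, tkey: bytes):
        rec = self._resolve(version, tkey)
        if rec is None or rec[0]:
            return None
        return rec[1]

    def keys_visible(self, version: str) -> list[bytes]:
        all_keys = {k for w in self.writes.values() for k in w}
        return sorted(k for k in all_keys if self.get(version, k) is not None)

    def distinct_writes(self) -> int:
        """Count of distinct (tkey, version) pairs ever written."""
        return sum(len(w) for w in self.writes.values())


class LabelOracle:
    """Per-version voxel arrays plus a from-scratch supervoxel→body map.

    ``edit`` records mirror the service's mutation kinds; bodies are
    recomputed by replaying records along the first-parent path.
    """

    def __init__(self, repo, extent):
        self.repo = repo
        self.extent = extent
        self.voxels: dict[str, np.ndarray] = {}
        self.edits: dict[str, list[tuple[str, dict]]] = {}

    # voxel (supervoxel) state ------------------------------------------

    def _resolve_voxels(self, version: str) -> np.ndarray | None:
        queue = [version]
        seen = {version}
        while queue:
            nxt = []
            for u in queue:
                if u in self.voxels:
                    return self.voxels[u]
                for p in self.repo.nodes[u].parents:
                    if p not in seen:
                        seen.add(p)
                        nxt.append(p)
            queue = nxt
        return None

    def supervoxels(self, version: str) -> np.ndarray:
        arr = self._resolve_voxels(version)
        return (np.zeros(self.extent, np.uint64) if arr is None
                else arr.copy())

    def write_voxels(self, version: str, arr: np.ndarray) -> None:
        self.voxels[version] = arr.copy()

    # mapping ------------------------------------------------------------

    def record(self, version: str, kind: str, payload: dict) -> None:
        self.edits.setdefault(version, []).append((kind, payload))

    def _first_parent_path(self, version: str) -> list[str]:
        path = []
        u = version
        while True:
            path.append(u)
            parents = self.repo.nodes[u].parents
            if not parents:
                break
            u = parents[0]
        return list(reversed(path))

    def mapping(self, version: str) -> dict[int, int]:
        fwd: dict[int, int] = {}
        for u in self._first_parent_path(version):
            for kind, p in self.edits.get(u, ()):
                if kind == "merge":
                    for lab in p["labels"]:
                        movers = [s for s, b in fwd.items() if b == lab]
                        if fwd.get(lab, lab) == lab:
                            movers.append(lab)
                        for s in movers:
                            fwd[s] = p["target"]
                elif kind == "cleave":
                    for s in p["supervoxels"]:
                        fwd[s] = p["new_body"]
                        if s == p["new_body"]:
                            del fwd[s]
                # splits do not change the mapping
        return fwd

    # derived views ------------------------------------------------------

    def body_view(self, version: str) -> np.ndarray:
        sv = self.supervoxels(version)
        fwd = self.mapping(version)
        if not fwd:
            return sv
        u, inv = np.unique(sv, return_inverse=True)
        mapped = np.array([fwd.get(int(s), int(s)) for s in u], np.uint64)
        return mapped[inv].reshape(sv.shape)

    def body_sizes(self, version: str) -> dict[int, int]:
        view = self.body_view(version)
        u, c = np.unique(view, return_counts=True)
        return {int(l): int(n) for l, n in zip(u, c) if l != 0}

    def body_coords(self, version: str, label: int) -> np.ndarray:
        """Sorted (z, y, x) coordinates of a body's voxels."""
        return np.argwhere(self.body_view(version) == label)

    def annotation_labels(self, version: str, positions) -> dict:
        """position (x, y, z) → body label, by direct voxel lookup."""
        view = self.body_view(version)
        out = {}
        for (x, y, z) in positions:
            out[(x, y, z)] = int(view[z, y, x])
        return out
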