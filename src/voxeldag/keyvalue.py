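"""keyvalue and roi data types.

``keyvalue`` is a pass-through versioned store for arbitrary string keys
(≤ 1 KiB, escape-encoded to keep TKeys prefix-free) — a versioned file
system in miniature.  Because its key space is non-computable, it refuses
non-ordered backends, which cannot enumerate arbitrary keys cheaply.

``roi`` stores a coarse region of interest as sorted, non-overlapping
block-unit X-spans [(bz, by, bx0, bx1), ...] (inclusive bounds, default
block size 32) and answers point-membership queries by bisection.
"""

from __future__ import annotations

import bisect
import json
from typing import Optional

from . import keys as K
from .types import BaseInstance, register

__all__ = ["KeyvalueInstance", "RoiInstance", "KeyvalueError", "RoiError"]

CLS_KV = 0x01
CLS_ROI = 0x01
MAX_KEY_CHARS = 1024


class KeyvalueError(ValueError):
    pass


class RoiError(ValueError):
    pass


@register("keyvalue")
class KeyvalueInstance(BaseInstance):

    def __init__(self, service, repo, instance):
        super().__init__(service, repo, instance)
        if instance.config.get("backend") == "unordered":
            raise KeyvalueError(
                "keyvalue has a non-computable key space and cannot use a "
                "non-ordered backend")

    def _tkey(self, key: str) -> bytes:
        if not key:
            raise KeyvalueError("empty key")
        if len(key) > MAX_KEY_CHARS:
            raise KeyvalueError(f"key longer than {MAX_KEY_CHARS} characters")
        return K.string_tkey(CLS_KV, key)

    def kv_put(self, version: str, key: str, value: bytes) -> None:
        self.ctx(version).vput(self._tkey(key), bytes(value))

    def kv_get(self, version: str, key: str) -> Optional[bytes]:
        return self.ctx(version).vget(self._tkey(key))

    def kv_delete(self, version: str, key: str) -> None:
        self.ctx(version).vdelete(self._tkey(key))

    def kv_keys(self, version: str) -> list[str]:
        ctx = self.ctx(version)
        return sorted(K.decode_string_tkey(t)
                      for t, _ in ctx.prefix_scan(bytes([CLS_KV])))

    def kv_batch_get(self, version: str, keys: list[str]
                     ) -> list[tuple[str, Optional[bytes]]]:
        ctx = self.ctx(version)
        return [(k, ctx.vget(self._tkey(k))) for k in keys]


@register("roi")
class RoiInstance(BaseInstance):

    _SPANS_KEY = "spans"

    @property
    def block_size(self) -> int:
        return int(self.config.get("block_size", 32))

    def _tkey(self) -> bytes:
        return K.string_tkey(CLS_ROI, self._SPANS_KEY)

    @staticmethod
    def _normalize(spans) -> list[tuple[int, int, int, int]]:
        norm = []
        for s in spans:
            if len(s) != 4:
                raise RoiError(f"span must be (bz, by, bx0, bx1): {s!r}")
            bz, by, x0, x1 = (int(v) for v in s)
            if x1 < x0:
                raise RoiError(f"span has bx1 < bx0: {s!r}")
            norm.append((bz, by, x0, x1))
        norm.sort()
        for a, b in zip(norm, norm[1:]):
            if a[0] == b[0] and a[1] == b[1] and b[2] <= a[3]:
                raise RoiError(f"overlapping spans {a} and {b}")
        return norm

    def roi_post(self, version: str, spans) -> None:
        norm = self._normalize(spans)
        self.ctx(version).vput(self._tkey(),
                               json.dumps([list(s) for s in norm]).encode())

    def roi_get(self, version: str) -> list[tuple[int, int, int, int]]:
        raw = self.ctx(version).vget(self._tkey())
        if raw is None:
            return []
        return [tuple(s) for s in json.loads(raw)]

    def roi_ptquery(self, version: str, points) -> list[bool]:
        """Membership per (x, y, z) voxel point, via block bisection."""
        spans = self.roi_get(version)
        b = self.block_size
        out = []
        for x, y, z in points:
            key = (z // b, y // b, x // b)
            i = bisect.bisect_right(spans, (key[0], key[1], key[2], 1 << 62)) - 1
            hit = (i >= 0 and spans[i][0] == key[0] and spans[i][1] == key[1]
                   and spans[i][2] <= key[2] <= spans[i][3])
            out.append(bool(hit))
        return out
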