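"""Storage engines.

Two backend families satisfy the persistence needs of the service:

* Ordered key-value stores with range scans (``OrderedKV``): an in-memory
  sorted map and an embedded on-disk store built on sqlite3.  These back
  the default versioned layout, where a range scan over one TKey prefix
  yields every stored version contiguously.

* Non-ordered object stores with conditional writes (``UnorderedKV``),
  emulating cloud object stores.  Versioning over these uses a single
  "versionless record" per TKey holding the list of stored versions plus
  the highest-priority key-value inline, so that first writes and
  highest-priority reads each touch exactly one stored object.

Priority of a version: a key-value on the master branch outranks any
side-branch one; within the same class, the larger creation sequence
number (more recent version) wins.
"""

from __future__ import annotations

import bisect
import sqlite3
import struct
import threading
from typing import Iterable, Iterator, Optional

from .dag import MASTER, Repo

__all__ = [
    "OrderedKV", "MemoryKV", "SqliteKV",
    "UnorderedKV", "MemoryObjectStore",
    "VersionlessRecord", "priority_greater",
    "u_vput", "u_vget", "WriteConflictError",
]


class WriteConflictError(RuntimeError):
    """Conditional-write retry budget exhausted."""


# ---------------------------------------------------------------------------
# Ordered stores
# ---------------------------------------------------------------------------

class OrderedKV:
    """Ordered key-value store contract.

    ``scan(lo, hi)`` iterates keys in [lo, hi) in strictly increasing
    order; ``hi=None`` means open-ended.  ``reads`` counts stored-object
    fetches (get calls and scan items) for contract tests.
    """

    reads: int = 0

    def get(self, key: bytes) -> Optional[bytes]:
        raise NotImplementedError

    def put(self, key: bytes, value: bytes) -> None:
        raise NotImplementedError

    def delete(self, key: bytes) -> None:
        raise NotImplementedError

    def scan(self, lo: bytes, hi: Optional[bytes]) -> Iterator[tuple[bytes, bytes]]:
        raise NotImplementedError

    def batch_put(self, pairs: Iterable[tuple[bytes, bytes]]) -> None:
        for k, v in pairs:
            self.put(k, v)

    def __len__(self) -> int:
        raise NotImplementedError

    def keys(self) -> list[bytes]:
        return [k for k, _ in self.scan(b"", None)]

    def close(self) -> None:
        pass


class MemoryKV(OrderedKV):
    """In-memory sorted map (dict + bisect-maintained key list)."""

    def __init__(self):
        self._data: dict[bytes, bytes] = {}
        self._keys: list[bytes] = []
        self.reads = 0

    def get(self, key: bytes) -> Optional[bytes]:
        self.reads += 1
        return self._data.get(key)

    def put(self, key: bytes, value: bytes) -> None:
        if key not in self._data:
            bisect.insort(self._keys, key)
        self._data[key] = value

    def delete(self, key: bytes) -> None:
        if key in self._data:
            del self._data[key]
            i = bisect.bisect_left(self._keys, key)
            del self._keys[i]

    def scan(self, lo: bytes, hi: Optional[bytes]) -> Iterator[tuple[bytes, bytes]]:
        i = bisect.bisect_left(self._keys, lo)
        n = len(self._keys)
        while i < n:
            k = self._keys[i]
            if hi is not None and hi != b"" and k >= hi:
                break
            self.reads += 1
            yield k, self._data[k]
            i += 1

    def __len__(self) -> int:
        return len(self._data)


class SqliteKV(OrderedKV):
    """Embedded on-disk ordered store (sqlite3, BLOB primary key)."""

    def __init__(self, path: str = ":memory:"):
        self._conn = sqlite3.connect(path, check_same_thread=False)
        self._lock = threading.Lock()
        self._conn.execute(
            "CREATE TABLE IF NOT EXISTS kv (k BLOB PRIMARY KEY, v BLOB NOT NULL)")
        self._conn.commit()
        self.reads = 0

    def get(self, key: bytes) -> Optional[bytes]:
        self.reads += 1
        with self._lock:
            row = self._conn.execute("SELECT v FROM kv WHERE k = ?", (key,)).fetchone()
        return None if row is None else bytes(row[0])

    def put(self, key: bytes, value: bytes) -> None:
        with self._lock:
            self._conn.execute(
                "INSERT INTO kv (k, v) VALUES (?, ?) "
                "ON CONFLICT(k) DO UPDATE SET v = excluded.v", (key, value))
            self._conn.commit()

    def delete(self, key: bytes) -> None:
        with self._lock:
            self._conn.execute("DELETE FROM kv WHERE k = ?", (key,))
            self._conn.commit()

    def scan(self, lo: bytes, hi: Optional[bytes]) -> Iterator[tuple[bytes, bytes]]:
        with self._lock:
            if hi is None or hi == b"":
                rows = self._conn.execute(
                    "SELECT k, v FROM kv WHERE k >= ? ORDER BY k", (lo,)).fetchall()
            else:
                rows = self._conn.execute(
                    "SELECT k, v FROM kv WHERE k >= ? AND k < ? ORDER BY k",
                    (lo, hi)).fetchall()
        for k, v in rows:
            self.reads += 1
            yield bytes(k), bytes(v)

    def batch_put(self, pairs: Iterable[tuple[bytes, bytes]]) -> None:
        with self._lock:
            self._conn.executemany(
                "INSERT INTO kv (k, v) VALUES (?, ?) "
                "ON CONFLICT(k) DO UPDATE SET v = excluded.v", list(pairs))
            self._conn.commit()

    def __len__(self) -> int:
        with self._lock:
            return self._conn.execute("SELECT COUNT(*) FROM kv").fetchone()[0]

    def close(self) -> None:
        self._conn.close()


# ---------------------------------------------------------------------------
# Non-ordered store with conditional writes
# ---------------------------------------------------------------------------

class UnorderedKV:
    """Object-store contract: no ordering, but generation-checked writes."""

    reads: int = 0

    def get(self, key: bytes) -> tuple[Optional[bytes], int]:
        """Return (value, generation); (None, 0) when absent."""
        raise NotImplementedError

    def put(self, key: bytes, value: bytes) -> None:
        raise NotImplementedError

    def put_if(self, key: bytes, value: bytes, expected_generation: int) -> bool:
        raise NotImplementedError

    def create_if_absent(self, key: bytes, value: bytes) -> bool:
        raise NotImplementedError

    def __len__(self) -> int:
        raise NotImplementedError


class MemoryObjectStore(UnorderedKV):
    """In-process emulation of a cloud object store with conditional writes."""

    def __init__(self):
        self._data: dict[bytes, tuple[bytes, int]] = {}
        self.reads = 0

    def get(self, key: bytes) -> tuple[Optional[bytes], int]:
        self.reads += 1
        v = self._data.get(key)
        return (None, 0) if v is None else v

    def put(self, key: bytes, value: bytes) -> None:
        gen = self._data.get(key, (b"", 0))[1]
        self._data[key] = (value, gen + 1)

    def put_if(self, key: bytes, value: bytes, expected_generation: int) -> bool:
        gen = self._data.get(key, (b"", 0))[1]
        if gen != expected_generation:
            return False
        self._data[key] = (value, gen + 1)
        return True

    def create_if_absent(self, key: bytes, value: bytes) -> bool:
        if key in self._data:
            return False
        self._data[key] = (value, 1)
        return True

    def __len__(self) -> int:
        return len(self._data)


# ---------------------------------------------------------------------------
# Versionless-record protocol
# ---------------------------------------------------------------------------

def priority_greater(a: int, b: int, repo: Repo) -> bool:
    """True iff vid ``a`` outranks vid ``b``.

    Master-branch membership dominates; within the same membership class
    the larger creation sequence number (more recent version) wins.
    Irreflexive: equal vids compare False.
    """
    if a == b:
        return False
    na, nb = repo.node_by_vid(a), repo.node_by_vid(b)
    ka = (na.branch == MASTER, na.seq)
    kb = (nb.branch == MASTER, nb.seq)
    return ka > kb


class VersionlessRecord:
    """The single per-TKey object in a non-ordered store.

    Holds the list of all stored vids plus the highest-priority key-value
    inline.  Lower-priority key-values live under their own versioned
    object keys.
    """

    __slots__ = ("versions", "inline_vid", "inline_tombstone", "inline_value")

    def __init__(self, versions: list[int], inline_vid: int,
                 inline_tombstone: bool, inline_value: bytes):
        self.versions = versions
        self.inline_vid = inline_vid
        self.inline_tombstone = inline_tombstone
        self.inline_value = inline_value

    def to_bytes(self) -> bytes:
        head = struct.pack(">I", len(self.versions))
        head += b"".join(struct.pack(">I", v) for v in self.versions)
        head += struct.pack(">IB", self.inline_vid, 1 if self.inline_tombstone else 0)
        return head + self.inline_value

    @classmethod
    def from_bytes(cls, b: bytes) -> "VersionlessRecord":
        n = struct.unpack(">I", b[:4])[0]
        off = 4
        versions = [struct.unpack(">I", b[off + 4 * i:off + 4 * i + 4])[0]
                    for i in range(n)]
        off += 4 * n
        inline_vid, tomb = struct.unpack(">IB", b[off:off + 5])
        return cls(versions, inline_vid, tomb == 1, b[off + 5:])


def _record_key(data_id: int, tkey: bytes) -> bytes:
    return b"R" + struct.pack(">I", data_id) + tkey


def _versioned_key(data_id: int, tkey: bytes, vid: int) -> bytes:
    return b"V" + struct.pack(">I", data_id) + tkey + struct.pack(">I", vid)


def _pack_versioned(tombstone: bool, value: bytes) -> bytes:
    return (b"\xff" if tombstone else b"\x00") + value


def _unpack_versioned(b: bytes) -> tuple[bool, bytes]:
    return b[:1] == b"\xff", b[1:]


RETRY_BUDGET = 32


def u_vput(store: UnorderedKV, data_id: int, tkey: bytes, vid: int,
           value: bytes, repo: Repo, tombstone: bool = False) -> None:
    """Versioned write into a non-ordered store.

    First write of a TKey is a single conditional create of the versionless
    record.  Later writes either evict the inline key-value (when the new
    one outranks it) or add a versioned object, then commit the updated
    record with a generation-checked write, retrying on contention.
    """
    rkey = _record_key(data_id, tkey)
    fresh = VersionlessRecord([vid], vid, tombstone, value)
    if store.create_if_absent(rkey, fresh.to_bytes()):
        return
    for _ in range(RETRY_BUDGET):
        raw, gen = store.get(rkey)
        if raw is None:  # record deleted concurrently; try create again
            if store.create_if_absent(rkey, fresh.to_bytes()):
                return
            continue
        rec = VersionlessRecord.from_bytes(raw)
        if vid == rec.inline_vid:
            rec.inline_tombstone = tombstone
            rec.inline_value = value
        elif vid in rec.versions:
            store.put(_versioned_key(data_id, tkey, vid),
                      _pack_versioned(tombstone, value))
            return  # record unchanged (version list and inline intact)
        elif priority_greater(vid, rec.inline_vid, repo):
            # evict current inline to its own versioned object first
            store.put(_versioned_key(data_id, tkey, rec.inline_vid),
                      _pack_versioned(rec.inline_tombstone, rec.inline_value))
            rec.versions.append(vid)
            rec.inline_vid = vid
            rec.inline_tombstone = tombstone
            rec.inline_value = value
        else:
            store.put(_versioned_key(data_id, tkey, vid),
                      _pack_versioned(tombstone, value))
            rec.versions.append(vid)
        if store.put_if(rkey, rec.to_bytes(), gen):
            return
    raise WriteConflictError(f"could not commit record for {tkey!r} "
                             f"after {RETRY_BUDGET} attempts")


def u_vget(store: UnorderedKV, data_id: int, tkey: bytes, version: str,
           repo: Repo) -> Optional[bytes]:
    """Versioned read: 1 stored-object read for the highest-priority
    key-value, 2 for any other."""
    raw, _ = store.get(_record_key(data_id, tkey))
    if raw is None:
        return None
    rec = VersionlessRecord.from_bytes(raw)
    best = repo.closest_stored_ancestor(version, rec.versions)
    if best is None:
        return None
    if best == rec.inline_vid:
        return None if rec.inline_tombstone else rec.inline_value
    vraw, _ = store.get(_versioned_key(data_id, tkey, best))
    if vraw is None:
        return None
    tomb, value = _unpack_versioned(vraw)
    return None if tomb else value
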