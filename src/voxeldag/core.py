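"""Service core: repositories over a shared ordered store, plus the
versioned read/write path.

Writes only ever store deltas: a key-value pair is persisted under the
writing version's vid, and reads at any version range-scan the stored
versions of a TKey and pick the closest stored ancestor in the DAG, so
untouched data is inherited rather than copied.
"""

from __future__ import annotations

import json
import threading
from typing import Callable, Iterator, Optional

from . import keys as K
from .backends import MemoryKV, OrderedKV
from .dag import DataInstance, Repo, RepoError, UnknownVersionError

__all__ = ["Service", "VersionedContext", "MutationLogEntry"]


class MutationLogEntry:
    """One labelmap edit (merge / cleave / supervoxel split).

    Replay of a version's entries, root→version, reconstructs the
    in-memory supervoxel→body map.
    """

    __slots__ = ("seq", "kind", "payload", "version")

    def __init__(self, seq: int, kind: str, payload: dict, version: str):
        self.seq = seq
        self.kind = kind
        self.payload = payload
        self.version = version

    def to_json(self) -> dict:
        return {"seq": self.seq, "kind": self.kind,
                "payload": self.payload, "version": self.version}

    @classmethod
    def from_json(cls, d: dict) -> "MutationLogEntry":
        return cls(int(d["seq"]), d["kind"], d["payload"], d["version"])


class MutationLog:
    """Append-only per-(instance, version) edit log, separate from the
    key-value data store (mirrors an append-only log file)."""

    def __init__(self):
        self._entries: dict[tuple[int, str], list[MutationLogEntry]] = {}
        self._next_seq = 0

    def append(self, data_id: int, version: str, kind: str, payload: dict) -> MutationLogEntry:
        e = MutationLogEntry(self._next_seq, kind, payload, version)
        self._next_seq += 1
        self._entries.setdefault((data_id, version), []).append(e)
        return e

    def entries(self, data_id: int, version: str) -> list[MutationLogEntry]:
        return list(self._entries.get((data_id, version), ()))

    def total(self, data_id: int) -> int:
        return sum(len(v) for (d, _), v in self._entries.items() if d == data_id)


class Service:
    """A running dataservice: repos, instances, storage assignment."""

    def __init__(self, store: Optional[OrderedKV] = None,
                 uuid_factory: Optional[Callable[[], str]] = None):
        self.store: OrderedKV = store if store is not None else MemoryKV()
        self.repos: dict[str, Repo] = {}  # root uuid → repo
        self.mutation_log = MutationLog()
        self._uuid_factory = uuid_factory
        self._next_data_id = 0
        self._typed: dict[int, object] = {}  # data_id → typed instance object
        self._subs: dict[int, list[int]] = {}  # labelmap data_id → subscriber data_ids
        self.lock = threading.RLock()

    # -- repo / instance admin --------------------------------------------

    def create_repo(self, alias: str = "") -> Repo:
        repo = Repo(alias=alias, uuid_factory=self._uuid_factory)
        self.repos[repo.root_uuid] = repo
        return repo

    def repo_of(self, uuid: str) -> Repo:
        for repo in self.repos.values():
            if uuid in repo.nodes:
                return repo
        raise UnknownVersionError(uuid)

    def resolve_uuid(self, prefix: str) -> tuple[Repo, str]:
        """Resolve a UUID prefix across all repos."""
        hits = []
        for repo in self.repos.values():
            try:
                hits.append((repo, repo.resolve_uuid(prefix)))
            except UnknownVersionError:
                continue
        if not hits:
            raise UnknownVersionError(f"no version matches prefix {prefix!r}")
        if len(hits) > 1:
            from .dag import AmbiguousUUIDError
            raise AmbiguousUUIDError(f"prefix {prefix!r} matches several versions")
        return hits[0]

    def new_instance(self, repo: Repo, name: str, type_name: str, **config):
        from .types import TYPE_REGISTRY  # late import: types build on core
        if name in repo.instances:
            raise RepoError(f"instance {name!r} already exists in repo")
        if type_name not in TYPE_REGISTRY:
            raise RepoError(f"unknown data type {type_name!r}")
        inst = DataInstance(name=name, type_name=type_name,
                            data_id=self._next_data_id, config=config)
        self._next_data_id += 1
        repo.instances[name] = inst
        typed = TYPE_REGISTRY[type_name](self, repo, inst)
        self._typed[inst.data_id] = typed
        return typed

    def instance(self, repo: Repo, name: str):
        try:
            inst = repo.instances[name]
        except KeyError:
            raise RepoError(f"no instance named {name!r}") from None
        return self._typed[inst.data_id]

    def ctx(self, repo: Repo, name: str, version: str) -> "VersionedContext":
        inst = repo.instances[name]
        repo.node(version)  # validate membership
        return VersionedContext(self, repo, inst, version)

    # -- pub/sub -----------------------------------------------------------

    def register_sync(self, source_data_id: int, subscriber_data_id: int) -> None:
        subs = self._subs.setdefault(source_data_id, [])
        if subscriber_data_id not in subs:
            subs.append(subscriber_data_id)

    def publish_mutation(self, source_data_id: int, version: str,
                         entry: MutationLogEntry) -> None:
        for sid in self._subs.get(source_data_id, ()):
            self._typed[sid].on_segmentation_mutation(version, entry)

    # -- metadata persistence ---------------------------------------------

    def metadata_json(self) -> str:
        return json.dumps({
            "repos": [r.to_json() for r in self.repos.values()],
            "next_data_id": self._next_data_id,
            "mutation_log": {
                "next_seq": self.mutation_log._next_seq,
                "entries": [dict(e.to_json(), data_id=did)
                            for (did, _), es in self.mutation_log._entries.items()
                            for e in es],
            },
            "syncs": {str(k): v for k, v in self._subs.items()},
        }, indent=1)

    def load_metadata(self, text: str) -> None:
        from .types import TYPE_REGISTRY
        d = json.loads(text)
        self.repos = {}
        self._typed = {}
        for rd in d["repos"]:
            repo = Repo.from_json(rd, uuid_factory=self._uuid_factory)
            self.repos[repo.root_uuid] = repo
            for inst in repo.instances.values():
                self._typed[inst.data_id] = TYPE_REGISTRY[inst.type_name](self, repo, inst)
        self._next_data_id = int(d["next_data_id"])
        ml = MutationLog()
        ml._next_seq = int(d["mutation_log"]["next_seq"])
        for ed in sorted(d["mutation_log"]["entries"], key=lambda e: e["seq"]):
            e = MutationLogEntry.from_json(ed)
            ml._entries.setdefault((int(ed["data_id"]), e.version), []).append(e)
        self.mutation_log = ml
        self._subs = {int(k): list(v) for k, v in d.get("syncs", {}).items()}


class VersionedContext:
    """Binding of (service, repo, instance, version) for versioned I/O."""

    __slots__ = ("service", "repo", "instance", "version")

    def __init__(self, service: Service, repo: Repo, instance: DataInstance,
                 version: str):
        self.service = service
        self.repo = repo
        self.instance = instance
        self.version = version

    @property
    def store(self) -> OrderedKV:
        return self.service.store

    @property
    def vid(self) -> int:
        return self.repo.uuid_to_vid[self.version]

    def at(self, version: str) -> "VersionedContext":
        return VersionedContext(self.service, self.repo, self.instance, version)

    def check_mutable(self) -> None:
        self.repo.check_mutable(self.version)

    # -- versioned key-value operations -----------------------------------

    def vput(self, tkey: bytes, value: bytes) -> None:
        self.check_mutable()
        vid = self.vid
        did = self.instance.data_id
        # latest write at a version wins: drop any same-version tombstone
        self.store.delete(K.encode_storage_key(did, tkey, vid, tombstone=True))
        self.store.put(K.encode_storage_key(did, tkey, vid, tombstone=False), value)

    def vdelete(self, tkey: bytes) -> None:
        self.check_mutable()
        vid = self.vid
        did = self.instance.data_id
        self.store.delete(K.encode_storage_key(did, tkey, vid, tombstone=False))
        self.store.put(K.encode_storage_key(did, tkey, vid, tombstone=True), b"")

    def _stored_versions(self, tkey: bytes) -> dict[int, tuple[bool, bytes]]:
        """vid → (tombstoned, value) for every stored version of tkey."""
        prefix = K.data_tkey_prefix(self.instance.data_id, tkey)
        out: dict[int, tuple[bool, bytes]] = {}
        for k, v in self.store.scan(prefix, K.next_prefix(prefix)):
            if len(k) != len(prefix) + 5:
                continue  # foreign key sharing bytes (not possible for
                # prefix-free TKeys; guard for robustness)
            _, _, vid, tomb = K.decode_storage_key(k)
            # tombstone sorts after value for the same vid: later wins
            out[vid] = (tomb, v)
        return out

    def vget(self, tkey: bytes) -> Optional[bytes]:
        stored = self._stored_versions(tkey)
        if not stored:
            return None
        best = self.repo.closest_stored_ancestor(self.version, stored.keys())
        if best is None:
            return None
        tomb, value = stored[best]
        return None if tomb else value

    def vrange(self, tkey_lo: bytes, tkey_hi: bytes) -> Iterator[tuple[bytes, bytes]]:
        """Version-resolved scan over the TKey interval [lo, hi].

        Both bounds must share a key class.  Tombstone-resolved keys are
        omitted; results ascend in TKey order.
        """
        if tkey_lo[0] != tkey_hi[0]:
            raise K.KeyError_("vrange bounds must share a key class")
        did = self.instance.data_id
        lo = K.data_tkey_prefix(did, tkey_lo)
        hi = K.next_prefix(K.data_tkey_prefix(did, tkey_hi))
        groups: dict[bytes, dict[int, tuple[bool, bytes]]] = {}
        for k, v in self.store.scan(lo, hi):
            d, tkey, vid, tomb = K.decode_storage_key(k)
            if d != did:
                continue
            groups.setdefault(tkey, {})[vid] = (tomb, v)
        for tkey in sorted(groups):
            stored = groups[tkey]
            best = self.repo.closest_stored_ancestor(self.version, stored.keys())
            if best is None:
                continue
            tomb, value = stored[best]
            if not tomb:
                yield tkey, value

    def prefix_scan(self, tkey_prefix: bytes) -> Iterator[tuple[bytes, bytes]]:
        """Version-resolved scan of every TKey starting with a prefix."""
        raw_lo = K.data_tkey_prefix(self.instance.data_id, tkey_prefix)
        raw_hi = K.next_prefix(raw_lo)
        groups: dict[bytes, dict[int, tuple[bool, bytes]]] = {}
        for k, v in self.store.scan(raw_lo, raw_hi):
            _, tkey, vid, tomb = K.decode_storage_key(k)
            groups.setdefault(tkey, {})[vid] = (tomb, v)
        for tkey in sorted(groups):
            stored = groups[tkey]
            best = self.repo.closest_stored_ancestor(self.version, stored.keys())
            if best is None:
                continue
            tomb, value = stored[best]
            if not tomb:
                yield tkey, value
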