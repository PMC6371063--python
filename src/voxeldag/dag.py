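"""Version DAG: repositories, version nodes, branches, commit locks.

A repository is a single DAG of versions, each identified by a RFC4122 v4
UUID (32 hex chars).  Committed nodes are immutable data snapshots; only
open (uncommitted) leaf nodes accept writes.  Every branch carries a unique
string name; the root belongs to the "master" branch whose name is the
empty string.  UUIDs are mapped to compact server-local uint32 version ids
(vids) purely to shorten storage keys.
"""

from __future__ import annotations

import datetime
import random
import uuid as _uuidlib
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional

__all__ = [
    "Repo",
    "VersionNode",
    "DataInstance",
    "RepoError",
    "UnknownVersionError",
    "AmbiguousUUIDError",
    "ImmutableVersionError",
    "BranchError",
    "create_repo",
    "seeded_uuid_factory",
]

MASTER = ""  # the master branch is named by the empty string


class RepoError(Exception):
    """Base error for DAG/metadata violations."""


class UnknownVersionError(RepoError, KeyError):
    pass


class AmbiguousUUIDError(RepoError):
    pass


class ImmutableVersionError(RepoError):
    """Raised when a data write targets a committed (locked) version."""


class BranchError(RepoError):
    pass


def seeded_uuid_factory(seed: int) -> Callable[[], str]:
    """Return a deterministic generator of RFC4122-v4-formatted UUIDs.

    Production use draws from ``uuid.uuid4``; tests and fixtures use this
    to make repositories byte-reproducible.
    """
    rng = random.Random(seed)

    def make() -> str:
        bits = rng.getrandbits(128)
        u = _uuidlib.UUID(int=bits, version=4)
        return u.hex

    return make


def _default_uuid() -> str:
    return _uuidlib.uuid4().hex


def _now() -> str:
    return datetime.datetime.now(datetime.timezone.utc).isoformat()


@dataclass
class VersionNode:
    uuid: str
    vid: int
    seq: int
    parents: list[str] = field(default_factory=list)
    children: list[str] = field(default_factory=list)
    branch: str = MASTER
    committed: bool = False
    note: str = ""
    log: list[tuple[str, str]] = field(default_factory=list)

    def to_json(self) -> dict:
        return {
            "uuid": self.uuid,
            "vid": self.vid,
            "seq": self.seq,
            "parents": list(self.parents),
            "children": list(self.children),
            "branch": self.branch,
            "committed": self.committed,
            "note": self.note,
            "log": [list(e) for e in self.log],
        }

    @classmethod
    def from_json(cls, d: dict) -> "VersionNode":
        return cls(
            uuid=d["uuid"],
            vid=int(d["vid"]),
            seq=int(d["seq"]),
            parents=list(d["parents"]),
            children=list(d["children"]),
            branch=d["branch"],
            committed=bool(d["committed"]),
            note=d.get("note", ""),
            log=[tuple(e) for e in d.get("log", [])],
        )


@dataclass
class DataInstance:
    """Descriptor of a typed data instance within a repo."""

    name: str
    type_name: str
    data_id: int
    config: dict = field(default_factory=dict)

    def to_json(self) -> dict:
        return {
            "name": self.name,
            "type_name": self.type_name,
            "data_id": self.data_id,
            "config": dict(self.config),
        }

    @classmethod
    def from_json(cls, d: dict) -> "DataInstance":
        return cls(d["name"], d["type_name"], int(d["data_id"]), dict(d.get("config", {})))


class Repo:
    """A dataset: one version DAG plus its data-instance registry."""

    def __init__(self, alias: str = "", uuid_factory: Optional[Callable[[], str]] = None):
        self.alias = alias
        self._uuid_factory = uuid_factory or _default_uuid
        self.nodes: dict[str, VersionNode] = {}
        self.branch_names: set[str] = set()
        self.uuid_to_vid: dict[str, int] = {}
        self.vid_to_uuid: dict[int, str] = {}
        self.instances: dict[str, DataInstance] = {}
        self._next_vid = 0
        self._next_seq = 0
        root = self._make_node(parents=[], branch=MASTER)
        self.root_uuid = root.uuid

    # -- internals ---------------------------------------------------------

    def _make_node(self, parents: list[str], branch: str) -> VersionNode:
        u = self._uuid_factory()
        while u in self.nodes:  # vanishingly unlikely; keeps injectivity
            u = self._uuid_factory()
        node = VersionNode(uuid=u, vid=self._next_vid, seq=self._next_seq,
                           parents=parents, branch=branch)
        self._next_vid += 1
        self._next_seq += 1
        self.nodes[u] = node
        self.uuid_to_vid[u] = node.vid
        self.vid_to_uuid[node.vid] = u
        self.branch_names.add(branch)
        return node

    def node(self, uuid: str) -> VersionNode:
        try:
            return self.nodes[uuid]
        except KeyError:
            raise UnknownVersionError(uuid) from None

    def node_by_vid(self, vid: int) -> VersionNode:
        try:
            return self.nodes[self.vid_to_uuid[vid]]
        except KeyError:
            raise UnknownVersionError(f"vid {vid}") from None

    # -- operations --------------------------------------------------------

    def commit(self, uuid: str, note: str = "") -> None:
        node = self.node(uuid)
        if node.committed:
            raise RepoError(f"version {uuid} is already committed")
        node.committed = True
        node.note = note

    def check_mutable(self, uuid: str) -> None:
        if self.node(uuid).committed:
            raise ImmutableVersionError(
                f"version {uuid} is committed; writes are rejected")

    def new_version(self, parent: str, branch: str = MASTER) -> str:
        pnode = self.node(parent)
        if not pnode.committed:
            raise RepoError(f"parent {parent} must be committed before branching")
        if branch == MASTER or branch == pnode.branch:
            # extend the parent's branch: at most one same-branch child
            new_branch = pnode.branch
            for c in pnode.children:
                if self.nodes[c].branch == new_branch:
                    raise BranchError(
                        f"parent {parent} already has a child on branch "
                        f"{new_branch!r}")
        else:
            if branch in self.branch_names:
                raise BranchError(f"branch name {branch!r} already in use")
            new_branch = branch
        child = self._make_node(parents=[parent], branch=new_branch)
        pnode.children.append(child.uuid)
        return child.uuid

    def new_merge_version(self, parents: list[str], branch: str = MASTER,
                          note: str = "") -> str:
        """Create a committed merge node over ≥2 ordered parents.

        Ancestor walks visit the first parent first ("node A wins").
        Data-level merge tooling is out of scope, so merge nodes are born
        committed.
        """
        if len(parents) < 2:
            raise RepoError("a merge node needs at least 2 parents")
        pnodes = [self.node(p) for p in parents]
        for pn in pnodes:
            if not pn.committed:
                raise RepoError("all merge parents must be committed")
        first = pnodes[0]
        if branch == MASTER or branch == first.branch:
            new_branch = first.branch
            for c in first.children:
                if self.nodes[c].branch == new_branch:
                    raise BranchError(
                        f"parent {first.uuid} already has a child on branch "
                        f"{new_branch!r}")
        else:
            if branch in self.branch_names:
                raise BranchError(f"branch name {branch!r} already in use")
            new_branch = branch
        node = self._make_node(parents=list(parents), branch=new_branch)
        node.committed = True
        node.note = note
        for pn in pnodes:
            pn.children.append(node.uuid)
        return node.uuid

    def resolve_uuid(self, prefix: str) -> str:
        if not prefix:
            raise UnknownVersionError("empty UUID prefix")
        p = prefix.lower()
        matches = [u for u in self.nodes if u.startswith(p)]
        if not matches:
            raise UnknownVersionError(f"no version matches prefix {prefix!r}")
        if len(matches) > 1:
            raise AmbiguousUUIDError(
                f"prefix {prefix!r} matches {len(matches)} versions")
        return matches[0]

    def closest_stored_ancestor(self, target: str, stored: Iterable[int]) -> Optional[int]:
        """Breadth-first upward walk from ``target`` (itself first), visiting
        each node's parents in stored order; return the first vid found in
        ``stored``, or None."""
        stored = set(stored)
        tnode = self.node(target)
        queue = [tnode]
        seen = {tnode.uuid}
        while queue:
            nxt: list[VersionNode] = []
            for n in queue:
                if n.vid in stored:
                    return n.vid
                for p in n.parents:
                    if p not in seen:
                        seen.add(p)
                        nxt.append(self.nodes[p])
            queue = nxt
        return None

    def first_parent_path(self, target: str) -> list[str]:
        """Root→target path following first parents (for log replay)."""
        path = []
        u = target
        node = self.node(u)
        while True:
            path.append(node.uuid)
            if not node.parents:
                break
            node = self.nodes[node.parents[0]]
        path.reverse()
        return path

    def ancestors(self, target: str) -> set[str]:
        """All ancestors of target including itself (reachability)."""
        out: set[str] = set()
        stack = [target]
        while stack:
            u = stack.pop()
            if u in out:
                continue
            out.add(u)
            stack.extend(self.node(u).parents)
        return out

    def append_node_log(self, uuid: str, message: str) -> None:
        # the node log is metadata, not data: committed nodes accept it
        self.node(uuid).log.append((_now(), message))

    def leaves(self) -> list[str]:
        return [u for u, n in self.nodes.items() if not n.children]

    # -- metadata persistence ---------------------------------------------

    def to_json(self) -> dict:
        return {
            "alias": self.alias,
            "root_uuid": self.root_uuid,
            "nodes": [self.nodes[u].to_json() for u in
                      sorted(self.nodes, key=lambda u: self.nodes[u].seq)],
            "instances": [i.to_json() for i in self.instances.values()],
        }

    @classmethod
    def from_json(cls, d: dict, uuid_factory: Optional[Callable[[], str]] = None) -> "Repo":
        repo = cls.__new__(cls)
        repo.alias = d.get("alias", "")
        repo._uuid_factory = uuid_factory or _default_uuid
        repo.nodes = {}
        repo.branch_names = set()
        repo.uuid_to_vid = {}
        repo.vid_to_uuid = {}
        repo.instances = {}
        for nd in d["nodes"]:
            node = VersionNode.from_json(nd)
            repo.nodes[node.uuid] = node
            repo.uuid_to_vid[node.uuid] = node.vid
            repo.vid_to_uuid[node.vid] = node.uuid
            repo.branch_names.add(node.branch)
        repo.root_uuid = d["root_uuid"]
        repo._next_vid = 1 + max(n.vid for n in repo.nodes.values())
        repo._next_seq = 1 + max(n.seq for n in repo.nodes.values())
        for inst in d.get("instances", []):
            di = DataInstance.from_json(inst)
            repo.instances[di.name] = di
        return repo


def create_repo(alias: str = "", uuid_factory: Optional[Callable[[], str]] = None) -> Repo:
    """Create a repository with a single open root node on master."""
    return Repo(alias=alias, uuid_factory=uuid_factory)
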