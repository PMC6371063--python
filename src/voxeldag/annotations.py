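"""annotation: versioned 3D point annotations (synapses, bookmarks).

Elements are JSON points keyed three ways so that spatial, per-body, and
per-tag queries are each a single key lookup or short range scan:

* 0x01 by block — ZYX block coordinate → JSON element list;
* 0x02 by label — body label (requires a sync to a labelmap instance);
* 0x03 by tag   — arbitrary string tag.

The by-label index is maintained eagerly: segmentation mutations arriving
over the publish/subscribe channel fold or re-resolve the affected lists,
so "all synapses in body X" stays correct after merges, cleaves, and
splits.  At most one element may occupy a voxel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from . import keys as K
from .types import BaseInstance, register

__all__ = ["AnnotationInstance", "Element", "AnnotationError", "NotSyncedError"]

CLS_BLOCK = 0x01
CLS_LABEL = 0x02
CLS_TAG = 0x03


class AnnotationError(ValueError):
    pass


class NotSyncedError(AnnotationError):
    """Label-based query on an instance with no labelmap sync."""


@dataclass(frozen=True)
class Element:
    pos: tuple[int, int, int]           # (x, y, z) voxel
    kind: str                           # e.g. PreSyn, PostSyn, Bookmark
    tags: tuple[str, ...] = ()
    props: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if not self.kind:
            raise AnnotationError("element kind must be non-empty")
        object.__setattr__(self, "pos", tuple(int(v) for v in self.pos))
        object.__setattr__(self, "tags", tuple(self.tags))

    def to_json(self) -> dict:
        return {"Pos": list(self.pos), "Kind": self.kind,
                "Tags": list(self.tags), "Props": dict(self.props)}

    @classmethod
    def from_json(cls, d: dict) -> "Element":
        return cls(pos=tuple(d["Pos"]), kind=d["Kind"],
                   tags=tuple(d.get("Tags", ())), props=dict(d.get("Props", {})))


def _dump(elements: list[Element]) -> bytes:
    elements = sorted(elements, key=lambda e: (e.pos[2], e.pos[1], e.pos[0]))
    return json.dumps([e.to_json() for e in elements]).encode()


def _load(raw: bytes | None) -> list[Element]:
    if raw is None:
        return []
    return [Element.from_json(d) for d in json.loads(raw)]


@register("annotation")
class AnnotationInstance(BaseInstance):

    @property
    def block_size(self) -> int:
        return int(self.config.get("block_size", 64))

    @property
    def sync_target(self) -> str | None:
        return self.config.get("sync")

    def _labelmap(self):
        if self.sync_target is None:
            raise NotSyncedError(
                f"annotation instance {self.name!r} is not synced to a labelmap")
        return self.service.instance(self.repo, self.sync_target)

    def _block_of(self, pos) -> tuple[int, int, int]:
        x, y, z = pos
        b = self.block_size
        return (z // b, y // b, x // b)

    def _block_tkey(self, coord) -> bytes:
        return K.block_tkey(CLS_BLOCK, *coord)

    def _label_tkey(self, label: int) -> bytes:
        return K.label_tkey(CLS_LABEL, label)

    def _tag_tkey(self, tag: str) -> bytes:
        return K.string_tkey(CLS_TAG, tag)

    # -- index list read-modify-write helpers -----------------------------

    def _edit_list(self, ctx, tkey: bytes, remove: list[Element],
                   add: list[Element]) -> None:
        lst = _load(ctx.vget(tkey))
        rm = {e.pos for e in remove}
        lst = [e for e in lst if e.pos not in rm]
        lst.extend(add)
        if lst:
            ctx.vput(tkey, _dump(lst))
        elif remove:
            ctx.vdelete(tkey)

    # -- sync --------------------------------------------------------------

    def register_sync(self, target_instance: str) -> None:
        """Subscribe to a labelmap instance's mutations (idempotent)."""
        from .labels import LabelmapInstance
        target = self.service.instance(self.repo, target_instance)
        if not isinstance(target, LabelmapInstance):
            raise AnnotationError(
                f"sync target {target_instance!r} is not a labelmap")
        if self.config.get("sync") == target_instance:
            return
        self.config["sync"] = target_instance
        self.service.register_sync(target.data_id, self.data_id)

    # -- element ingestion / editing --------------------------------------

    def post_elements(self, version: str, elements: list[Element]) -> None:
        """Upsert elements; an element at an occupied voxel replaces the
        prior one in every index it appears in."""
        ctx = self.ctx(version)
        ctx.check_mutable()
        synced = self.sync_target is not None
        lm = self._labelmap() if synced else None
        by_block: dict[tuple[int, int, int], list[Element]] = {}
        for e in elements:
            by_block.setdefault(self._block_of(e.pos), []).append(e)
        for coord, els in by_block.items():
            old = _load(ctx.vget(self._block_tkey(coord)))
            replaced = [o for o in old if o.pos in {e.pos for e in els}]
            self._edit_list(ctx, self._block_tkey(coord), replaced, els)
            # label index
            if synced:
                touch: dict[int, tuple[list, list]] = {}
                for o in replaced:
                    lab = lm.get_label(version, o.pos)
                    touch.setdefault(lab, ([], []))[0].append(o)
                for e in els:
                    lab = lm.get_label(version, e.pos)
                    touch.setdefault(lab, ([], []))[1].append(e)
                for lab, (rm, addl) in touch.items():
                    self._edit_list(ctx, self._label_tkey(lab), rm, addl)
            # tag index
            tags: dict[str, tuple[list, list]] = {}
            for o in replaced:
                for t in o.tags:
                    tags.setdefault(t, ([], []))[0].append(o)
            for e in els:
                for t in e.tags:
                    tags.setdefault(t, ([], []))[1].append(e)
            for t, (rm, addl) in tags.items():
                self._edit_list(ctx, self._tag_tkey(t), rm, addl)

    def delete_block(self, version: str, coord: tuple[int, int, int]) -> None:
        """Delete all elements in one block (a single tombstone on the
        by-block key, as in the worked deletion example)."""
        ctx = self.ctx(version)
        ctx.check_mutable()
        old = _load(ctx.vget(self._block_tkey(coord)))
        ctx.vdelete(self._block_tkey(coord))
        self._unindex(ctx, version, old)

    def delete_element(self, version: str, pos: tuple[int, int, int]) -> None:
        ctx = self.ctx(version)
        ctx.check_mutable()
        coord = self._block_of(pos)
        old = [e for e in _load(ctx.vget(self._block_tkey(coord)))
               if e.pos == tuple(pos)]
        if not old:
            raise AnnotationError(f"no element at {tuple(pos)}")
        self._edit_list(ctx, self._block_tkey(coord), old, [])
        self._unindex(ctx, version, old)

    def _unindex(self, ctx, version: str, elements: list[Element]) -> None:
        if not elements:
            return
        if self.sync_target is not None:
            lm = self._labelmap()
            by_lab: dict[int, list[Element]] = {}
            for e in elements:
                by_lab.setdefault(lm.get_label(version, e.pos), []).append(e)
            for lab, els in by_lab.items():
                self._edit_list(ctx, self._label_tkey(lab), els, [])
        by_tag: dict[str, list[Element]] = {}
        for e in elements:
            for t in e.tags:
                by_tag.setdefault(t, []).append(e)
        for t, els in by_tag.items():
            self._edit_list(ctx, self._tag_tkey(t), els, [])

    def move_element(self, version: str, frm: tuple[int, int, int],
                     to: tuple[int, int, int]) -> None:
        ctx = self.ctx(version)
        ctx.check_mutable()
        frm, to = tuple(int(v) for v in frm), tuple(int(v) for v in to)
        src = self._block_of(frm)
        old = [e for e in _load(ctx.vget(self._block_tkey(src))) if e.pos == frm]
        if not old:
            raise AnnotationError(f"no element at {frm}")
        dst = self._block_of(to)
        if any(e.pos == to for e in _load(ctx.vget(self._block_tkey(dst)))):
            raise AnnotationError(f"target voxel {to} is occupied")
        el = old[0]
        moved = Element(pos=to, kind=el.kind, tags=el.tags, props=el.props)
        if src == dst:
            self._edit_list(ctx, self._block_tkey(src), [el], [moved])
        else:
            self._edit_list(ctx, self._block_tkey(src), [el], [])
            self._edit_list(ctx, self._block_tkey(dst), [], [moved])
        if self.sync_target is not None:
            lm = self._labelmap()
            old_lab = lm.get_label(version, frm)
            new_lab = lm.get_label(version, to)
            if old_lab == new_lab:
                self._edit_list(ctx, self._label_tkey(old_lab), [el], [moved])
            else:
                self._edit_list(ctx, self._label_tkey(old_lab), [el], [])
                self._edit_list(ctx, self._label_tkey(new_lab), [], [moved])
        for t in el.tags:
            self._edit_list(ctx, self._tag_tkey(t), [el], [moved])

    # -- queries -----------------------------------------------------------

    def get_elements_in_subvolume(self, version: str,
                                  offset: tuple[int, int, int],
                                  shape: tuple[int, int, int]) -> list[Element]:
        """Elements with offset ≤ pos < offset+shape (half-open; both in
        (x, y, z) order)."""
        if min(shape) <= 0:
            raise AnnotationError("shape must be positive")
        ctx = self.ctx(version)
        b = self.block_size
        x0, y0, z0 = offset
        nx, ny, nz = shape
        out: list[Element] = []
        for bz in range(z0 // b, -(-(z0 + nz) // b)):
            for by in range(y0 // b, -(-(y0 + ny) // b)):
                for bx in range(x0 // b, -(-(x0 + nx) // b)):
                    for e in _load(ctx.vget(self._block_tkey((bz, by, bx)))):
                        x, y, z = e.pos
                        if (x0 <= x < x0 + nx and y0 <= y < y0 + ny
                                and z0 <= z < z0 + nz):
                            out.append(e)
        return sorted(out, key=lambda e: (e.pos[2], e.pos[1], e.pos[0]))

    def get_by_label(self, version: str, label: int) -> list[Element]:
        self._labelmap()  # raises NotSyncedError when unsynced
        ctx = self.ctx(version)
        return _load(ctx.vget(self._label_tkey(int(label))))

    def get_by_tag(self, version: str, tag: str) -> list[Element]:
        ctx = self.ctx(version)
        return _load(ctx.vget(self._tag_tkey(tag)))

    def label_counts(self, version: str) -> dict[int, int]:
        ctx = self.ctx(version)
        out = {}
        for tkey, raw in ctx.prefix_scan(bytes([CLS_LABEL])):
            n = len(json.loads(raw))
            if n:
                out[K.decode_label_tkey(tkey)] = n
        return out

    def top_labels_by_count(self, version: str, n: int) -> list[tuple[int, int]]:
        counts = self.label_counts(version)
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        return ranked[:n]

    # -- pub/sub -----------------------------------------------------------

    def on_segmentation_mutation(self, version: str, entry) -> None:
        """Keep the by-label index consistent with a segmentation edit.

        Merges fold absorbed labels' lists into the target; cleaves and
        splits re-resolve the affected elements by position.  Re-applying
        an event is a no-op.
        """
        if self.sync_target is None:
            return
        ctx = self.ctx(version)
        lm = self._labelmap()
        p = entry.payload
        if entry.kind == "merge":
            gathered: list[Element] = []
            for lab in p["labels"]:
                els = _load(ctx.vget(self._label_tkey(int(lab))))
                if els:
                    gathered.extend(els)
                    ctx.vdelete(self._label_tkey(int(lab)))
            if gathered:
                self._edit_list(ctx, self._label_tkey(int(p["target"])),
                                gathered, gathered)
        elif entry.kind == "cleave":
            self._reresolve(ctx, version, lm, [int(p["body"])])
        elif entry.kind == "split":
            body = lm.build_mapping(version).body(int(p["supervoxel"]))
            self._reresolve(ctx, version, lm, [body])

    def _reresolve(self, ctx, version: str, lm, labels: list[int]) -> None:
        for lab in labels:
            els = _load(ctx.vget(self._label_tkey(lab)))
            if not els:
                continue
            regrouped: dict[int, list[Element]] = {}
            for e in els:
                regrouped.setdefault(lm.get_label(version, e.pos), []).append(e)
            for new_lab, group in regrouped.items():
                if new_lab == lab:
                    continue
                self._edit_list(ctx, self._label_tkey(lab), group, [])
                self._edit_list(ctx, self._label_tkey(new_lab), group, group)
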