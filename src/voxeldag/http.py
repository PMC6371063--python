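"""HTTP Science API: a WSGI application over the service core.

Endpoints follow the ``/api/node/<uuid>/<instance>/<command>/...`` shape;
any recognizable UUID prefix resolves to the full version.  Coordinate
path segments are underscore-separated integers in x_y_z order (e.g.
``/label/100_100_47``).  Handlers are thin: every route maps 1:1 onto an
in-process operation, so the HTTP layer adds parsing and status codes
only.

Admin routes live under ``/api/repos``, ``/api/repo/<uuid>`` and
``/api/node/<uuid>``; ``/api/help/<type>`` returns a machine-readable
description of a data type's endpoints.

Status codes: 400 malformed/ambiguous input, 403 write to a committed
version, 404 unknown route/instance/type, 409 state conflicts (e.g.
double commit).
"""

from __future__ import annotations

import base64
import io
import json
import struct
from typing import Optional
from urllib.parse import parse_qs

import numpy as np

from .annotations import AnnotationError, AnnotationInstance, Element, NotSyncedError
from .blockcodec import CodecError
from .core import Service
from .dag import (AmbiguousUUIDError, BranchError, ImmutableVersionError,
                  RepoError, UnknownVersionError)
from .grayscale import Uint8BlkInstance
from .keyvalue import KeyvalueError, KeyvalueInstance, RoiError, RoiInstance
from .labels import LabelmapError, LabelmapInstance, SparseVol

__all__ = ["ScienceAPI", "serve", "HELP"]


class HttpError(Exception):
    def __init__(self, status: int, message: str):
        self.status = status
        self.message = message


HELP = {
    "uint8blk": {
        "description": "3D grayscale volumes stored as uint8 blocks with a "
                       "multiscale pyramid",
        "endpoints": {
            "/raw/0_1_2/<sx_sy_sz>/<ox_oy_oz>[?scale=s]":
                "GET returns / POST stores a raw little-endian uint8 "
                "subvolume",
            "/slice/<xy|xz|yz>/<w_h>/<ox_oy_oz>[?format=png]":
                "GET returns a 2D slice (raw bytes or PNG)",
            "/pyramid/<max_scale>": "POST builds downsampled scales",
        },
    },
    "labelmap": {
        "description": "64-bit segmentation: compressed supervoxel blocks, "
                       "label indices, in-memory supervoxel→body map, "
                       "merge/cleave/split, sparse volumes",
        "endpoints": {
            "/raw/0_1_2/<sx_sy_sz>/<ox_oy_oz>[?supervoxels=true]":
                "GET returns / POST ingests little-endian uint64 labels",
            "/specificblocks?blocks=x,y,z,...":
                "GET returns compressed block payloads",
            "/label/<x_y_z>[?supervoxels=true]": "GET label at a voxel",
            "/size/<label>": "GET voxel count of a body",
            "/sparsevol/<label>[?format=rles|json&minz=&maxz=]":
                "GET run-length encoded voxels of a body",
            "/merge": "POST [target, label1, ...]",
            "/cleave/<body>": "POST [supervoxel, ...]; returns new body",
            "/split/<supervoxel>": "POST sparse volume; returns new label",
            "/maxlabel": "GET highest label in use",
            "/pyramid/<max_scale>": "POST builds downsampled label scales",
        },
    },
    "annotation": {
        "description": "3D point annotations indexed by block, body label, "
                       "and tag; syncable to a labelmap",
        "endpoints": {
            "/elements": "POST JSON element list",
            "/elements/<sx_sy_sz>/<ox_oy_oz>": "GET elements in a subvolume",
            "/element/<x_y_z>": "DELETE one element",
            "/block/<bx_by_bz>": "DELETE all elements in a block",
            "/move/<x_y_z>/<x_y_z>": "POST moves an annotation",
            "/label/<label>": "GET elements on a body (requires sync)",
            "/tag/<tag>": "GET elements carrying a tag",
            "/sync": "POST {\"sync\": \"<labelmap instance>\"}",
            "/top/<n>": "GET labels ranked by element count",
        },
    },
    "keyvalue": {
        "description": "versioned store for arbitrary keys (a versioned "
                       "file system)",
        "endpoints": {
            "/key/<key>": "GET returns, POST stores, DELETE removes a value",
            "/keys": "GET sorted key list",
            "/keyvalues": "POST JSON key array; returns base64 values",
        },
    },
    "roi": {
        "description": "coarse region of interest as block-unit X spans",
        "endpoints": {
            "/roi": "GET returns / POST stores [[bz,by,bx0,bx1], ...]",
            "/ptquery": "POST [[x,y,z], ...]; returns membership flags",
        },
    },
}


def _ints(seg: str, n: Optional[int] = None) -> tuple[int, ...]:
    try:
        vals = tuple(int(v) for v in seg.split("_"))
    except ValueError:
        raise HttpError(400, f"malformed coordinate segment {seg!r}")
    if n is not None and len(vals) != n:
        raise HttpError(400, f"expected {n} integers in {seg!r}")
    return vals


def _json_body(body: bytes):
    try:
        return json.loads(body or b"null")
    except json.JSONDecodeError as e:
        raise HttpError(400, f"malformed JSON body: {e}")


class ScienceAPI:
    """WSGI application exposing the Science API of one service."""

    def __init__(self, service: Service):
        self.service = service

    # -- WSGI plumbing -----------------------------------------------------

    def __call__(self, environ, start_response):
        method = environ["REQUEST_METHOD"].upper()
        path = environ.get("PATH_INFO", "")
        query = {k: v[-1] for k, v in
                 parse_qs(environ.get("QUERY_STRING", "")).items()}
        try:
            length = int(environ.get("CONTENT_LENGTH") or 0)
        except ValueError:
            length = 0
        body = environ["wsgi.input"].read(length) if length else b""
        status, ctype, payload = self.handle(method, path, body, query)
        codes = {200: "200 OK", 400: "400 Bad Request", 403: "403 Forbidden",
                 404: "404 Not Found", 409: "409 Conflict",
                 500: "500 Internal Server Error"}
        start_response(codes.get(status, f"{status} Error"),
                       [("Content-Type", ctype),
                        ("Content-Length", str(len(payload)))])
        return [payload]

    def handle(self, method: str, path: str, body: bytes = b"",
               query: Optional[dict] = None) -> tuple[int, str, bytes]:
        """Dispatch one request; also the in-process test entry point.

        A query string attached to ``path`` is split off and parsed.
        """
        query = dict(query or {})
        if "?" in path:
            path, _, qs = path.partition("?")
            query.update({k: v[-1] for k, v in parse_qs(qs).items()})
        try:
            with self.service.lock:
                result = self._route(method, path, body, query)
            if isinstance(result, bytes):
                return 200, "application/octet-stream", result
            return (200, "application/json",
                    json.dumps(result).encode())
        except HttpError as e:
            return e.status, "application/json", json.dumps(
                {"error": e.message}).encode()
        except ImmutableVersionError as e:
            return 403, "application/json", json.dumps({"error": str(e)}).encode()
        except AmbiguousUUIDError as e:
            return 400, "application/json", json.dumps({"error": str(e)}).encode()
        except (UnknownVersionError, NotSyncedError) as e:
            return 404, "application/json", json.dumps({"error": str(e)}).encode()
        except BranchError as e:
            return 409, "application/json", json.dumps({"error": str(e)}).encode()
        except (LabelmapError, AnnotationError, KeyvalueError, RoiError,
                CodecError, ValueError) as e:
            return 400, "application/json", json.dumps({"error": str(e)}).encode()
        except RepoError as e:
            return 409, "application/json", json.dumps({"error": str(e)}).encode()

    # -- routing -----------------------------------------------------------

    def _route(self, method, path, body, query):
        parts = [p for p in path.split("/") if p]
        if not parts or parts[0] != "api":
            raise HttpError(404, f"unknown path {path!r}")
        parts = parts[1:]
        if not parts:
            raise HttpError(404, "missing API route")

        if parts[0] == "repos":
            return self._repos(method, parts[1:], body)
        if parts[0] == "help":
            if len(parts) != 2:
                raise HttpError(404, "usage: /api/help/<type>")
            if parts[1] not in HELP:
                raise HttpError(404, f"unknown data type {parts[1]!r}")
            return HELP[parts[1]]
        if parts[0] == "repo":
            if len(parts) < 3:
                raise HttpError(404, "usage: /api/repo/<uuid>/<command>")
            repo, _ = self._resolve(parts[1])
            return self._repo_admin(method, repo, parts[2:], body)
        if parts[0] == "node":
            if len(parts) < 3:
                raise HttpError(404, "usage: /api/node/<uuid>/<command>")
            repo, version = self._resolve(parts[1])
            return self._node(method, repo, version, parts[2:], body, query)
        raise HttpError(404, f"unknown route /api/{parts[0]}")

    def _resolve(self, prefix: str):
        return self.service.resolve_uuid(prefix)

    # -- admin -------------------------------------------------------------

    def _repos(self, method, rest, body):
        if method == "POST" and not rest:
            d = _json_body(body) or {}
            repo = self.service.create_repo(alias=d.get("alias", ""))
            return {"root": repo.root_uuid, "alias": repo.alias}
        if method == "GET" and rest == ["info"]:
            return {u: r.to_json() for u, r in self.service.repos.items()}
        raise HttpError(404, "unknown /api/repos route")

    def _repo_admin(self, method, repo, rest, body):
        if method == "GET" and rest == ["info"]:
            return repo.to_json()
        if method == "POST" and rest == ["instance"]:
            d = _json_body(body)
            name, typename = d.get("name"), d.get("typename")
            if not name or not typename:
                raise HttpError(400, "need JSON {name, typename}")
            self.service.new_instance(repo, name, typename,
                                      **d.get("config", {}))
            return {"name": name, "typename": typename}
        raise HttpError(404, "unknown /api/repo route")

    def _node(self, method, repo, version, rest, body, query):
        cmd = rest[0]
        if cmd == "commit" and method == "POST":
            d = _json_body(body) or {}
            repo.commit(version, d.get("note", ""))
            return {"committed": version}
        if cmd == "branch" and method == "POST":
            d = _json_body(body) or {}
            child = repo.new_version(version, d.get("branch", ""))
            return {"child": child}
        if cmd == "log":
            if method == "GET":
                return {"log": [list(e) for e in repo.node(version).log]}
            if method == "POST":
                d = _json_body(body)
                for msg in d.get("log", []):
                    repo.append_node_log(version, msg)
                return {"log entries": len(repo.node(version).log)}
        # instance-typed routes
        if len(rest) < 2:
            raise HttpError(404, f"unknown node command {cmd!r}")
        try:
            inst = self.service.instance(repo, cmd)
        except RepoError:
            raise HttpError(404, f"no data instance named {cmd!r}")
        sub = rest[1:]
        if isinstance(inst, Uint8BlkInstance):
            return self._uint8blk(method, inst, version, sub, body, query)
        if isinstance(inst, LabelmapInstance):
            return self._labelmap(method, inst, version, sub, body, query)
        if isinstance(inst, AnnotationInstance):
            return self._annotation(method, inst, version, sub, body, query)
        if isinstance(inst, KeyvalueInstance):
            return self._keyvalue(method, inst, version, sub, body, query)
        if isinstance(inst, RoiInstance):
            return self._roi(method, inst, version, sub, body)
        raise HttpError(404, f"unroutable instance type for {cmd!r}")

    # -- typed handlers ----------------------------------------------------

    @staticmethod
    def _zyx(xyz: tuple[int, ...]) -> tuple[int, ...]:
        return tuple(reversed(xyz))

    def _uint8blk(self, method, inst, version, sub, body, query):
        scale = int(query.get("scale", 0))
        if sub[0] == "raw" and len(sub) == 4:
            if sub[1] != "0_1_2":
                raise HttpError(400, "only the 0_1_2 dims selector is "
                                     "supported on /raw")
            shape = self._zyx(_ints(sub[2], 3))
            offset = self._zyx(_ints(sub[3], 3))
            if method == "GET":
                return inst.get_subvolume(version, offset, shape, scale).tobytes()
            if method == "POST":
                if len(body) != int(np.prod(shape)):
                    raise HttpError(400, "payload size does not match shape")
                arr = np.frombuffer(body, np.uint8).reshape(shape)
                inst.put_subvolume(version, offset, arr, scale)
                return {"stored": list(shape)}
        if sub[0] == "slice" and len(sub) == 4 and method == "GET":
            plane = sub[1].upper()
            w, h = _ints(sub[2], 2)
            offset = self._zyx(_ints(sub[3], 3))
            img = inst.get_slice(version, plane, offset, w, h, scale)
            if query.get("format") == "png":
                from PIL import Image
                buf = io.BytesIO()
                Image.fromarray(img).save(buf, format="PNG")
                return buf.getvalue()
            return img.tobytes()
        if sub[0] == "pyramid" and len(sub) == 2 and method == "POST":
            inst.build_pyramid(version, int(sub[1]))
            return {"scales": int(sub[1])}
        raise HttpError(404, f"unknown uint8blk route {'/'.join(sub)!r}")

    def _labelmap(self, method, inst, version, sub, body, query):
        supervoxels = query.get("supervoxels", "").lower() == "true"
        if sub[0] == "raw" and len(sub) == 4:
            shape = self._zyx(_ints(sub[2], 3))
            offset = self._zyx(_ints(sub[3], 3))
            if method == "GET":
                arr = inst.get_subvolume(version, offset, shape,
                                         supervoxels=supervoxels)
                return arr.astype("<u8").tobytes()
            if method == "POST":
                if len(body) != 8 * int(np.prod(shape)):
                    raise HttpError(400, "payload size does not match shape")
                arr = np.frombuffer(body, "<u8").reshape(shape)
                inst.ingest(version, offset, arr)
                return {"stored": list(shape)}
        if sub[0] == "specificblocks" and method == "GET":
            try:
                coords = tuple(int(v) for v in
                               query.get("blocks", "").split(","))
            except ValueError:
                raise HttpError(400, "blocks list must be x,y,z triples")
            if len(coords) % 3:
                raise HttpError(400, "blocks list must be x,y,z triples")
            out = bytearray()
            triples = [coords[i:i + 3] for i in range(0, len(coords), 3)]
            got = inst.get_specific_blocks(
                version, [self._zyx(t) for t in triples])
            for (x, y, z), (_, payload) in zip(triples, got):
                out += struct.pack("<iii", x, y, z)
                if payload is None:
                    out += struct.pack("<i", -1)
                else:
                    out += struct.pack("<i", len(payload)) + payload
            return bytes(out)
        if sub[0] == "label" and len(sub) == 2 and method == "GET":
            x, y, z = _ints(sub[1], 3)
            return {"Label": inst.get_label(version, (x, y, z),
                                            supervoxels=supervoxels)}
        if sub[0] == "size" and len(sub) == 2 and method == "GET":
            return {"voxels": inst.label_size(version, int(sub[1]),
                                              supervoxels=supervoxels)}
        if sub[0] == "sparsevol" and len(sub) == 2 and method == "GET":
            minz = int(query["minz"]) if "minz" in query else None
            maxz = int(query["maxz"]) if "maxz" in query else None
            vol = inst.sparsevol(version, int(sub[1]), minz=minz, maxz=maxz,
                                 supervoxels=supervoxels)
            if query.get("format", "rles") == "json":
                return {"label": vol.label, "runs": vol.to_json()}
            return vol.to_binary()
        if sub[0] == "merge" and method == "POST":
            arr = _json_body(body)
            if not isinstance(arr, list) or len(arr) < 2:
                raise HttpError(400, "merge body must be [target, label1, ...]")
            inst.merge(version, int(arr[0]), [int(v) for v in arr[1:]])
            return {"MergedInto": int(arr[0])}
        if sub[0] == "cleave" and len(sub) == 2 and method == "POST":
            svs = _json_body(body)
            new = inst.cleave(version, int(sub[1]), [int(v) for v in svs])
            return {"CleavedLabel": new}
        if sub[0] == "split" and len(sub) == 2 and method == "POST":
            vol = SparseVol.from_binary(body, label=int(sub[1]))
            new = inst.split_supervoxel(version, int(sub[1]), vol)
            return {"label": new}
        if sub[0] == "maxlabel" and method == "GET":
            inst._recover_max_label()
            return {"maxlabel": inst._max_label_seen}
        if sub[0] == "pyramid" and len(sub) == 2 and method == "POST":
            inst.downsample_labels(version, int(sub[1]))
            return {"scales": int(sub[1])}
        raise HttpError(404, f"unknown labelmap route {'/'.join(sub)!r}")

    def _annotation(self, method, inst, version, sub, body, query):
        if sub[0] == "elements" and len(sub) == 1 and method == "POST":
            els = [Element.from_json(d) for d in _json_body(body)]
            inst.post_elements(version, els)
            return {"stored": len(els)}
        if sub[0] == "elements" and len(sub) == 3 and method == "GET":
            shape = _ints(sub[1], 3)
            offset = _ints(sub[2], 3)
            els = inst.get_elements_in_subvolume(version, offset, shape)
            return [e.to_json() for e in els]
        if sub[0] == "element" and len(sub) == 2 and method == "DELETE":
            inst.delete_element(version, _ints(sub[1], 3))
            return {"deleted": sub[1]}
        if sub[0] == "block" and len(sub) == 2 and method == "DELETE":
            bx, by, bz = _ints(sub[1], 3)
            inst.delete_block(version, (bz, by, bx))
            return {"deleted block": sub[1]}
        if sub[0] == "move" and len(sub) == 3 and method == "POST":
            inst.move_element(version, _ints(sub[1], 3), _ints(sub[2], 3))
            return {"moved": [sub[1], sub[2]]}
        if sub[0] == "label" and len(sub) == 2 and method == "GET":
            return [e.to_json()
                    for e in inst.get_by_label(version, int(sub[1]))]
        if sub[0] == "tag" and len(sub) == 2 and method == "GET":
            return [e.to_json() for e in inst.get_by_tag(version, sub[1])]
        if sub[0] == "sync" and method == "POST":
            d = _json_body(body)
            inst.register_sync(d["sync"])
            return {"sync": d["sync"]}
        if sub[0] == "top" and len(sub) == 2 and method == "GET":
            return [[lab, n]
                    for lab, n in inst.top_labels_by_count(version, int(sub[1]))]
        raise HttpError(404, f"unknown annotation route {'/'.join(sub)!r}")

    def _keyvalue(self, method, inst, version, sub, body, query):
        if sub[0] == "key" and len(sub) == 2:
            if method == "GET":
                v = inst.kv_get(version, sub[1])
                if v is None:
                    raise HttpError(404, f"no key {sub[1]!r}")
                return v
            if method == "POST":
                inst.kv_put(version, sub[1], body)
                return {"stored": sub[1]}
            if method == "DELETE":
                inst.kv_delete(version, sub[1])
                return {"deleted": sub[1]}
        if sub[0] == "keys" and method == "GET":
            return inst.kv_keys(version)
        if sub[0] == "keyvalues" and method == "POST":
            keys = _json_body(body)
            return {k: (None if v is None
                        else base64.b64encode(v).decode())
                    for k, v in inst.kv_batch_get(version, keys)}
        raise HttpError(404, f"unknown keyvalue route {'/'.join(sub)!r}")

    def _roi(self, method, inst, version, sub, body):
        if sub[0] == "roi":
            if method == "GET":
                return [list(s) for s in inst.roi_get(version)]
            if method == "POST":
                inst.roi_post(version, _json_body(body))
                return {"spans": len(inst.roi_get(version))}
        if sub[0] == "ptquery" and method == "POST":
            return inst.roi_ptquery(version, _json_body(body))
        raise HttpError(404, f"unknown roi route {'/'.join(sub)!r}")


def serve(service: Service, host: str = "127.0.0.1", port: int = 8000):
    """Run the Science API on a stdlib WSGI server (blocking)."""
    from wsgiref.simple_server import make_server
    app = ScienceAPI(service)
    with make_server(host, port, app) as httpd:
        httpd.serve_forever()
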