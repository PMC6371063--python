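"""Shared randomized edit-script machinery for oracle-equivalence tests.

A script of versioned key-value writes/deletes, segmentation edits
(merge / cleave / supervoxel split), and annotation posts is generated
once and applied through a *driver*; the same script and verification
run either in-process or through the WSGI Science API, so the HTTP layer
can be checked for parity with the library.
"""

from __future__ import annotations

import json
import random

import numpy as np

import voxeldag as V
from voxeldag.labels import SparseVol
from oracles import LabelOracle, SnapshotOracle


class InProcessDriver:
    """Applies operations by direct library calls."""

    def __init__(self, svc, repo):
        self.svc = svc
        self.repo = repo
        self.lm = svc.instance(repo, "segmentation")
        self.ann = svc.instance(repo, "synapses")
        self.kv = svc.instance(repo, "notes")

    def commit(self, u):
        self.repo.commit(u)

    def branch(self, u, name=""):
        return self.repo.new_version(u, name)

    def ingest(self, u, seg):
        self.lm.ingest(u, (0, 0, 0), seg)

    def merge(self, u, target, labels):
        self.lm.merge(u, target, labels)

    def cleave(self, u, body, svs):
        return self.lm.cleave(u, body, svs)

    def split(self, u, sv, runs):
        return self.lm.split_supervoxel(u, sv, SparseVol(sv, runs))

    def post_elements(self, u, positions):
        self.ann.post_elements(
            u, [V.Element(pos=p, kind="PreSyn") for p in positions])

    def kv_put(self, u, key, value):
        self.kv.kv_put(u, key, value)

    def kv_delete(self, u, key):
        self.kv.kv_delete(u, key)

    # reads -------------------------------------------------------------

    def body_view(self, u, shape):
        return self.lm.get_subvolume(u, (0, 0, 0), shape)

    def size(self, u, label):
        return self.lm.label_size(u, label)

    def sparsevol_coords(self, u, label):
        return {tuple(c) for c in self.lm.sparsevol(u, label).coords()}

    def by_label(self, u, label):
        return {e.pos for e in self.ann.get_by_label(u, label)}

    def kv_get(self, u, key):
        return self.kv.kv_get(u, key)


class HttpDriver:
    """Applies the same operations through the WSGI Science API."""

    def __init__(self, client, repo):
        self.c = client
        self.repo = repo

    def commit(self, u):
        self.c.json("POST", f"/api/node/{u[:8]}/commit", {})

    def branch(self, u, name=""):
        st, _, payload = self.c.request("POST", f"/api/node/{u[:8]}/branch",
                                        {"branch": name})
        if st != 200:
            raise V.RepoError(payload.decode())
        return json.loads(payload)["child"]

    def ingest(self, u, seg):
        nz, ny, nx = seg.shape
        self.c.raw("POST", f"/api/node/{u[:8]}/segmentation/raw/0_1_2/"
                           f"{nx}_{ny}_{nz}/0_0_0",
                   seg.astype("<u8").tobytes())

    def merge(self, u, target, labels):
        self.c.json("POST", f"/api/node/{u[:8]}/segmentation/merge",
                    [target] + list(labels))

    def cleave(self, u, body, svs):
        return self.c.json("POST",
                           f"/api/node/{u[:8]}/segmentation/cleave/{body}",
                           list(svs))["CleavedLabel"]

    def split(self, u, sv, runs):
        vol = SparseVol(sv, runs)
        return self.c.json("POST",
                           f"/api/node/{u[:8]}/segmentation/split/{sv}",
                           vol.to_binary())["label"]

    def post_elements(self, u, positions):
        self.c.json("POST", f"/api/node/{u[:8]}/synapses/elements",
                    [{"Pos": list(p), "Kind": "PreSyn"} for p in positions])

    def kv_put(self, u, key, value):
        self.c.json("POST", f"/api/node/{u[:8]}/notes/key/{key}", value)

    def kv_delete(self, u, key):
        self.c.json("DELETE", f"/api/node/{u[:8]}/notes/key/{key}")

    def body_view(self, u, shape):
        nz, ny, nx = shape
        raw = self.c.raw("GET", f"/api/node/{u[:8]}/segmentation/raw/0_1_2/"
                                f"{nx}_{ny}_{nz}/0_0_0")
        return np.frombuffer(raw, "<u8").reshape(shape)

    def size(self, u, label):
        return self.c.json("GET",
                           f"/api/node/{u[:8]}/segmentation/size/{label}")["voxels"]

    def sparsevol_coords(self, u, label):
        d = self.c.json("GET", f"/api/node/{u[:8]}/segmentation/"
                               f"sparsevol/{label}?format=json")
        out = set()
        for x, y, z, n in d["runs"]:
            out.update((z, y, x + i) for i in range(n))
        return out

    def by_label(self, u, label):
        got = self.c.json("GET", f"/api/node/{u[:8]}/synapses/label/{label}")
        return {tuple(e["Pos"]) for e in got}

    def kv_get(self, u, key):
        st, _, payload = self.c.request("GET",
                                        f"/api/node/{u[:8]}/notes/key/{key}")
        return payload if st == 200 else None


def build_world(svc, extent, n_labels, seed):
    repo = svc.create_repo()
    svc.new_instance(repo, "segmentation", "labelmap")
    ann = svc.new_instance(repo, "synapses", "annotation")
    svc.new_instance(repo, "notes", "keyvalue")
    ann.register_sync("segmentation")
    seg, census = V.make_segmentation(
        V.SyntheticSpec(extent=extent, n_labels=n_labels, seed=seed))
    return repo, seg, census


def run_script(driver, repo, seg, rng, n_ops, n_nodes=9, n_branches=3):
    """Random versioned-edit script; returns the oracles and bookkeeping.

    The DAG gets ``n_nodes`` nodes including ``n_branches`` named
    branches; edits hit random open versions.
    """
    root = repo.root_uuid
    oracle = LabelOracle(repo, seg.shape)
    kv_oracle = SnapshotOracle(repo)
    driver.ingest(root, seg)
    oracle.write_voxels(root, seg)
    posted: dict[str, set] = {}
    uuids = [root]
    driver.commit(root)
    branches = 0
    while len(uuids) < n_nodes:
        parent = rng.choice(uuids)
        if not repo.node(parent).committed:
            driver.commit(parent)
        try:
            if branches < n_branches and rng.random() < 0.5:
                branches += 1
                uuids.append(driver.branch(parent, f"branch{branches}"))
            else:
                uuids.append(driver.branch(parent))
        except V.RepoError:
            continue
    open_vs = [u for u in uuids if not repo.node(u).committed]
    kv_keys = [f"doc{i}" for i in range(6)]
    ops = 0
    while ops < n_ops:
        u = rng.choice(open_vs)
        roll = rng.random()
        try:
            if roll < 0.30:  # versioned kv put
                k = rng.choice(kv_keys)
                val = f"val{ops}".encode()
                driver.kv_put(u, k, val)
                kv_oracle.put(u, V.keys.string_tkey(0x01, k), val)
            elif roll < 0.40:  # versioned kv tombstone
                k = rng.choice(kv_keys)
                driver.kv_delete(u, k)
                kv_oracle.delete(u, V.keys.string_tkey(0x01, k))
            elif roll < 0.60:  # merge
                sizes = oracle.body_sizes(u)
                if len(sizes) < 4:
                    continue
                t, m = rng.sample(sorted(sizes), 2)
                driver.merge(u, t, [m])
                oracle.record(u, "merge", {"target": t, "labels": [m]})
            elif roll < 0.75:  # cleave
                fwd = oracle.mapping(u)
                sizes = oracle.body_sizes(u)
                members: dict[int, list[int]] = {}
                sv_present = set(np.unique(oracle.supervoxels(u)).tolist())
                for s in sv_present - {0}:
                    members.setdefault(fwd.get(s, s), []).append(s)
                bodies = [b for b, ms in members.items()
                          if len(ms) > 1 and b in sizes]
                if not bodies:
                    continue
                body = rng.choice(sorted(bodies))
                sv = sorted(members[body])[0]
                new = driver.cleave(u, body, [sv])
                oracle.record(u, "cleave", {"body": body,
                                            "supervoxels": [sv],
                                            "new_body": new})
            elif roll < 0.90:  # supervoxel split
                sv_view = oracle.supervoxels(u)
                svs = [int(s) for s in np.unique(sv_view) if s]
                sv = int(rng.choice(svs))
                vox = np.argwhere(sv_view == sv)
                if len(vox) < 6:
                    continue
                take = vox[rng.randrange(len(vox) - 4):][:3]
                runs = [[int(x), int(y), int(z), 1] for z, y, x in take]
                new = driver.split(u, sv, runs)
                nv = sv_view.copy()
                nv[tuple(take.T)] = new
                oracle.write_voxels(u, nv)
                oracle.record(u, "split", {})
            else:  # annotation posts on foreground voxels
                sv_view = oracle.supervoxels(u)
                fg = np.argwhere(sv_view > 0)
                picks = fg[rng.randrange(len(fg) - 3):][:3]
                positions = [tuple(int(v) for v in reversed(c))
                             for c in picks]
                driver.post_elements(u, positions)
                posted.setdefault(u, set()).update(positions)
        except V.RepoError:
            continue
        ops += 1
    return uuids, oracle, kv_oracle, posted


def verify(driver, repo, uuids, oracle, kv_oracle, posted, rng,
           sparsevol_samples=4):
    """Every version's voxel view, sizes, sparse volumes, annotation
    label queries, and kv reads must equal the oracles."""
    for u in uuids:
        view = driver.body_view(u, oracle.extent)
        assert (view == oracle.body_view(u)).all(), f"voxel view at {u[:8]}"
        sizes = oracle.body_sizes(u)
        for lab in sorted(sizes)[:8]:
            assert driver.size(u, lab) == sizes[lab]
        for lab in rng.sample(sorted(sizes), min(sparsevol_samples, len(sizes))):
            got = driver.sparsevol_coords(u, lab)
            expect = {tuple(c) for c in oracle.body_coords(u, lab)}
            assert got == expect, f"sparsevol {lab} at {u[:8]}"
        # annotations visible at u: everything posted on its ancestor chain
        visible = set()
        for anc in repo.ancestors(u):
            visible |= posted.get(anc, set())
        truth = oracle.annotation_labels(u, visible)
        for lab in set(truth.values()):
            got = driver.by_label(u, lab)
            assert got == {p for p, l in truth.items() if l == lab}, \
                f"annotations for {lab} at {u[:8]}"
        for k in [f"doc{i}" for i in range(6)]:
            assert driver.kv_get(u, k) == kv_oracle.get(
                u, V.keys.string_tkey(0x01, k))
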