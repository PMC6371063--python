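import base64
import json
import random

import numpy as np
import pytest

import voxeldag as V
from voxeldag.labels import SparseVol
from oracles import LabelOracle


@pytest.fixture
def world(client, svc):
    """Repo + segmentation/synapses/keyvalue instances, built over HTTP."""
    root = client.json("POST", "/api/repos", {"alias": "demo"})["root"]
    for name, tname in (("segmentation", "labelmap"),
                        ("synapses", "annotation"),
                        ("grayscale", "uint8blk"),
                        ("notes", "keyvalue"),
                        ("region", "roi")):
        client.json("POST", f"/api/repo/{root[:8]}/instance",
                    {"name": name, "typename": tname})
    client.json("POST", f"/api/node/{root[:8]}/synapses/sync",
                {"sync": "segmentation"})
    seg, census = V.make_segmentation(
        V.SyntheticSpec(extent=(64, 64, 64), n_labels=12, seed=7))
    client.raw("POST", f"/api/node/{root[:8]}/segmentation/raw/0_1_2/"
                       "64_64_64/0_0_0", seg.astype("<u8").tobytes())
    return root, seg, census


def test_uuid_prefix_routing_and_errors(client, world):
    root, seg, _ = world
    ok = client.json("GET", f"/api/node/{root[:5]}/segmentation/size/3")
    full = client.json("GET", f"/api/node/{root}/segmentation/size/3")
    assert ok == full
    st, _, _ = client.request("GET", "/api/node/ffffffff/segmentation/size/3")
    assert st == 404
    st, _, _ = client.request("GET", f"/api/node/{root[:5]}/nosuch/size/3")
    assert st == 404
    st, _, _ = client.request("GET",
                              f"/api/node/{root[:5]}/segmentation/label/1_2")
    assert st == 400


def test_label_and_size_match_in_process(client, svc, world):
    root, seg, census = world
    lm = svc.instance(svc.repos[root], "segmentation")
    for (z, y, x) in [(3, 4, 5), (60, 50, 40)]:
        got = client.json("GET",
                          f"/api/node/{root[:8]}/segmentation/label/{x}_{y}_{z}")
        assert got["Label"] == lm.get_label(root, (x, y, z)) == seg[z, y, x]
    for lab in (1, 5, 12):
        got = client.json("GET", f"/api/node/{root[:8]}/segmentation/size/{lab}")
        assert got["voxels"] == census["counts"][lab]


def test_mutations_on_committed_node_return_403(client, world):
    root, _, _ = world
    client.json("POST", f"/api/node/{root[:8]}/commit", {"note": "freeze"})
    st, _, _ = client.request("POST",
                              f"/api/node/{root[:8]}/segmentation/merge",
                              [5, 6])
    assert st == 403
    st, _, _ = client.request("POST", f"/api/node/{root[:8]}/commit", {})
    assert st == 409


def test_merge_via_http_updates_subsequent_queries(client, world):
    root, seg, census = world
    client.json("POST", f"/api/node/{root[:8]}/segmentation/merge", [9, 5, 6])
    got = client.json("GET", f"/api/node/{root[:8]}/segmentation/size/9")
    assert got["voxels"] == sum(census["counts"][l] for l in (9, 5, 6))


def test_specificblocks_payloads_decompress(client, world):
    root, seg, _ = world
    raw = client.raw("GET", f"/api/node/{root[:8]}/segmentation/"
                            "specificblocks?blocks=0,0,0,9,9,9")
    import struct
    x, y, z, n = struct.unpack_from("<iiii", raw, 0)
    assert (x, y, z) == (0, 0, 0) and n > 0
    block = V.decompress_block(raw[16:16 + n])
    assert (block == seg[:64, :64, :64]).all()
    x2, y2, z2, n2 = struct.unpack_from("<iiii", raw, 16 + n)
    assert (x2, y2, z2, n2) == (9, 9, 9, -1)  # absent marker


def test_sparsevol_binary_equals_in_process(client, svc, world):
    root, _, _ = world
    lm = svc.instance(svc.repos[root], "segmentation")
    raw = client.raw("GET", f"/api/node/{root[:8]}/segmentation/sparsevol/4"
                            "?minz=10&maxz=50")
    got = SparseVol.from_binary(raw, label=4)
    want = lm.sparsevol(root, 4, minz=10, maxz=50)
    assert (got.runs == want.runs).all()


def test_grayscale_slice_and_png(client, world):
    root, _, _ = world
    rng = np.random.default_rng(1)
    vol = rng.integers(0, 256, (32, 32, 32), dtype=np.uint8)
    client.raw("POST", f"/api/node/{root[:8]}/grayscale/raw/0_1_2/"
                       "32_32_32/0_0_0", vol.tobytes())
    sl = client.raw("GET", f"/api/node/{root[:8]}/grayscale/slice/xy/"
                           "16_16/4_4_4")
    got = np.frombuffer(sl, np.uint8).reshape(16, 16)
    assert (got == vol[4, 4:20, 4:20]).all()
    png = client.raw("GET", f"/api/node/{root[:8]}/grayscale/slice/xy/"
                            "16_16/4_4_4?format=png")
    assert png[:8] == b"\x89PNG\r\n\x1a\n"


def test_keyvalue_and_roi_round_trips(client, world):
    root, _, _ = world
    client.json("POST", f"/api/node/{root[:8]}/notes/key/somedata",
                b"\x01\x02payload")
    assert client.raw("GET", f"/api/node/{root[:8]}/notes/key/somedata") == \
        b"\x01\x02payload"
    st, _, _ = client.request("GET", f"/api/node/{root[:8]}/notes/key/miss")
    assert st == 404
    batch = client.json("POST", f"/api/node/{root[:8]}/notes/keyvalues",
                        ["somedata", "miss"])
    assert base64.b64decode(batch["somedata"]) == b"\x01\x02payload"
    assert batch["miss"] is None
    client.json("POST", f"/api/node/{root[:8]}/region/roi",
                [[0, 0, 0, 2]])
    flags = client.json("POST", f"/api/node/{root[:8]}/region/ptquery",
                        [[0, 0, 0], [500, 0, 0]])
    assert flags == [True, False]


def test_help_endpoints(client):
    h = client.json("GET", "/api/help/uint8blk")
    assert any("/raw" in k for k in h["endpoints"])
    h = client.json("GET", "/api/help/labelmap")
    assert any("/sparsevol" in k for k in h["endpoints"])
    st, _, _ = client.request("GET", "/api/help/nosuch")
    assert st == 404


def test_repo_info_reports_dag_state(client, world):
    root, _, _ = world
    client.json("POST", f"/api/node/{root[:8]}/commit", {})
    child = client.json("POST", f"/api/node/{root[:8]}/branch", {})["child"]
    info = client.json("GET", f"/api/repo/{root[:8]}/info")
    assert len(info["nodes"]) == 2
    uuids = {n["uuid"] for n in info["nodes"]}
    assert uuids == {root, child}
    client.json("POST", f"/api/node/{child[:8]}/log", {"log": ["hello"]})
    log = client.json("GET", f"/api/node/{child[:8]}/log")["log"]
    assert [m for _, m in log] == ["hello"]


def test_http_parity_with_oracle_suite(client, svc, world):
    """Drive a randomized merge/cleave/split + annotation script purely
    over HTTP and check every version's views against the independent
    label oracle."""
    root, seg, _ = world
    repo = svc.repos[root]
    rng = random.Random(31)
    oracle = LabelOracle(repo, seg.shape)
    oracle.write_voxels(root, seg)
    client.json("POST", f"/api/node/{root[:8]}/commit", {})
    a = client.json("POST", f"/api/node/{root[:8]}/branch", {})["child"]
    b = client.json("POST", f"/api/node/{root[:8]}/branch",
                    {"branch": "side"})["child"]
    positions = [tuple(int(v) for v in reversed(c))
                 for c in np.argwhere(seg > 0)[::1499]][:10]
    client.json("POST", f"/api/node/{a[:8]}/synapses/elements",
                [{"Pos": list(p), "Kind": "PreSyn"} for p in positions])
    for step in range(10):
        u = rng.choice([a, b])
        sizes = oracle.body_sizes(u)
        labels = sorted(sizes)
        op = rng.random()
        if op < 0.5 and len(labels) > 3:
            t, m = rng.sample(labels, 2)
            st, _, payload = client.request(
                "POST", f"/api/node/{u[:8]}/segmentation/merge", [t, m])
            assert st == 200, payload
            oracle.record(u, "merge", {"target": t, "labels": [m]})
        else:
            sv_view = oracle.supervoxels(u)
            svs = [int(s) for s in np.unique(sv_view) if s]
            sv = rng.choice(svs)
            vox = np.argwhere(sv_view == sv)
            if len(vox) <= 4:
                continue
            take = vox[:2]
            vol = SparseVol(sv, [[int(x), int(y), int(z), 1]
                                 for z, y, x in take])
            resp = client.json("POST",
                               f"/api/node/{u[:8]}/segmentation/split/{sv}",
                               vol.to_binary())
            new = resp["label"]
            nv = sv_view.copy()
            nv[tuple(take.T)] = new
            oracle.write_voxels(u, nv)
            oracle.record(u, "split", {})
    for u in (root, a, b):
        raw = client.raw("GET", f"/api/node/{u[:8]}/segmentation/raw/0_1_2/"
                                "64_64_64/0_0_0")
        got = np.frombuffer(raw, "<u8").reshape(64, 64, 64)
        assert (got == oracle.body_view(u)).all()
        sizes = oracle.body_sizes(u)
        for lab in list(sizes)[:6]:
            resp = client.json("GET",
                               f"/api/node/{u[:8]}/segmentation/size/{lab}")
            assert resp["voxels"] == sizes[lab]
    truth = oracle.annotation_labels(a, positions)
    for lab in set(truth.values()):
        got = client.json("GET", f"/api/node/{a[:8]}/synapses/label/{lab}")
        assert {tuple(e["Pos"]) for e in got} == \
            {p for p, l in truth.items() if l == lab}
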