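import random

import numpy as np
import pytest

import voxeldag as V
from voxeldag.annotations import AnnotationError, Element, NotSyncedError
from voxeldag.labels import SparseVol
from oracles import LabelOracle


@pytest.fixture
def world(svc, repo, small_seg):
    seg, census = small_seg
    lm = svc.new_instance(repo, "segmentation", "labelmap")
    ann = svc.new_instance(repo, "synapses", "annotation")
    lm.ingest(repo.root_uuid, (0, 0, 0), seg)
    ann.register_sync("segmentation")
    return lm, ann, seg, census


def _el(x, y, z, kind="PreSyn", tags=()):
    return Element(pos=(x, y, z), kind=kind, tags=tuple(tags))


def test_post_and_subvolume_query_roundtrip(repo, world):
    lm, ann, seg, _ = world
    els = [_el(i * 5, i * 3, i * 2) for i in range(10)]
    ann.post_elements(repo.root_uuid, els)
    got = ann.get_elements_in_subvolume(repo.root_uuid, (0, 0, 0),
                                        (64, 64, 64))
    assert {e.pos for e in got} == {e.pos for e in els}


def test_subvolume_bounds_are_half_open(repo, world):
    lm, ann, _, _ = world
    root = repo.root_uuid
    ann.post_elements(root, [_el(9, 9, 9), _el(10, 10, 10)])
    got = ann.get_elements_in_subvolume(root, (5, 5, 5), (5, 5, 5))
    assert [e.pos for e in got] == [(9, 9, 9)]  # offset+shape−1 in, +shape out


def test_duplicate_position_upserts(repo, world):
    lm, ann, _, _ = world
    root = repo.root_uuid
    ann.post_elements(root, [_el(4, 4, 4, kind="PreSyn")])
    ann.post_elements(root, [_el(4, 4, 4, kind="PostSyn")])
    got = ann.get_elements_in_subvolume(root, (0, 0, 0), (8, 8, 8))
    assert len(got) == 1 and got[0].kind == "PostSyn"


def test_by_label_lookup_matches_segmentation(repo, world):
    lm, ann, seg, _ = world
    root = repo.root_uuid
    z, y, x = np.argwhere(seg == 7)[0]
    e = _el(int(x), int(y), int(z))
    ann.post_elements(root, [e])
    assert e in ann.get_by_label(root, 7)
    assert ann.get_by_label(root, 6) == []


def test_by_label_requires_sync(svc, repo):
    ann = svc.new_instance(repo, "bookmarks", "annotation")
    ann.post_elements(repo.root_uuid, [_el(1, 1, 1, kind="Bookmark")])
    with pytest.raises(NotSyncedError):
        ann.get_by_label(repo.root_uuid, 1)


def test_double_sync_registration_is_noop(svc, repo, world):
    lm, ann, _, _ = world
    ann.register_sync("segmentation")
    assert ann.config["sync"] == "segmentation"
    with pytest.raises(AnnotationError):
        ann.register_sync("synapses")  # not a labelmap


def test_tag_queries(repo, world):
    lm, ann, _, _ = world
    root = repo.root_uuid
    ann.post_elements(root, [_el(1, 2, 3, tags=("hard", "check")),
                             _el(4, 5, 6, tags=("hard",))])
    assert len(ann.get_by_tag(root, "hard")) == 2
    assert len(ann.get_by_tag(root, "check")) == 1
    assert ann.get_by_tag(root, "nope") == []


def test_move_element_updates_all_indexes(repo, world):
    lm, ann, seg, _ = world
    root = repo.root_uuid
    src = tuple(int(v) for v in reversed(np.argwhere(seg == 3)[0]))
    dst = tuple(int(v) for v in reversed(np.argwhere(seg == 9)[0]))
    ann.post_elements(root, [_el(*src, tags=("t",))])
    ann.move_element(root, src, dst)
    got = ann.get_elements_in_subvolume(root, (0, 0, 0), (64, 64, 64))
    assert [e.pos for e in got] == [dst]
    assert ann.get_by_label(root, 3) == []
    assert [e.pos for e in ann.get_by_label(root, 9)] == [dst]
    assert [e.pos for e in ann.get_by_tag(root, "t")] == [dst]
    with pytest.raises(AnnotationError):
        ann.move_element(root, src, dst)  # nothing left at src
    ann.post_elements(root, [_el(*src)])
    with pytest.raises(AnnotationError):
        ann.move_element(root, src, dst)  # destination occupied


def test_block_deletion_hides_at_child_not_parent(svc, repo, world):
    lm, ann, _, _ = world
    root = repo.root_uuid
    ann.post_elements(root, [_el(2, 2, 2), _el(3, 3, 3)])
    repo.commit(root)
    child = repo.new_version(root)
    ann.delete_block(child, (0, 0, 0))
    assert ann.get_elements_in_subvolume(child, (0, 0, 0), (64,) * 3) == []
    assert len(ann.get_elements_in_subvolume(root, (0, 0, 0), (64,) * 3)) == 2


def test_merge_event_folds_label_lists(repo, world):
    lm, ann, seg, _ = world
    root = repo.root_uuid
    pos5 = tuple(int(v) for v in reversed(np.argwhere(seg == 5)[0]))
    pos9 = tuple(int(v) for v in reversed(np.argwhere(seg == 9)[0]))
    ann.post_elements(root, [_el(*pos5), _el(*pos9)])
    lm.merge(root, 9, [5])
    got = {e.pos for e in ann.get_by_label(root, 9)}
    assert got == {pos5, pos9}
    assert ann.get_by_label(root, 5) == []


def test_merge_event_without_annotations_changes_nothing(svc, repo, world):
    lm, ann, _, _ = world
    before = len(svc.store)
    lm.merge(repo.root_uuid, 1, [2])  # no annotations in either body
    assert len(svc.store) == before


def test_event_replay_is_idempotent(repo, world):
    lm, ann, seg, _ = world
    root = repo.root_uuid
    pos = tuple(int(v) for v in reversed(np.argwhere(seg == 4)[0]))
    ann.post_elements(root, [_el(*pos)])
    lm.merge(root, 8, [4])
    entry = [e for e in lm.service.mutation_log.entries(lm.data_id, root)][-1]
    state = {e.pos for e in ann.get_by_label(root, 8)}
    ann.on_segmentation_mutation(root, entry)  # replay
    assert {e.pos for e in ann.get_by_label(root, 8)} == state


def test_cleave_event_reresolves_by_position(repo, world):
    lm, ann, seg, _ = world
    root = repo.root_uuid
    pos2 = tuple(int(v) for v in reversed(np.argwhere(seg == 2)[0]))
    pos6 = tuple(int(v) for v in reversed(np.argwhere(seg == 6)[0]))
    ann.post_elements(root, [_el(*pos2), _el(*pos6)])
    lm.merge(root, 2, [6])
    assert len(ann.get_by_label(root, 2)) == 2
    new_body = lm.cleave(root, 2, [6])
    assert {e.pos for e in ann.get_by_label(root, 2)} == {pos2}
    assert {e.pos for e in ann.get_by_label(root, new_body)} == {pos6}


def test_top_labels_by_count_ranks_and_breaks_ties(repo, world):
    lm, ann, seg, _ = world
    root = repo.root_uuid
    els = []
    for lab, n in ((3, 3), (5, 2), (7, 2)):
        vox = np.argwhere(seg == lab)[:n]
        els += [_el(int(x), int(y), int(z)) for z, y, x in vox]
    ann.post_elements(root, els)
    top = ann.top_labels_by_count(root, 2)
    assert top == [(3, 3), (5, 2)]  # tie 5-vs-7 → smaller label first
    assert len(ann.top_labels_by_count(root, 50)) == 3
    lm.merge(root, 5, [7])
    assert ann.top_labels_by_count(root, 1) == [(5, 4)]


def test_triple_index_consistency_under_random_interleaving(
        svc, repo, world):
    """Random element edits and segmentation mutations across a small
    DAG: at every version, by-label queries equal the brute-force
    position-lookup oracle and block/tag views agree."""
    lm, ann, seg, census = world
    rng = random.Random(50)
    oracle = LabelOracle(repo, seg.shape)
    oracle.write_voxels(repo.root_uuid, seg)
    root = repo.root_uuid
    repo.commit(root)
    # root edits happened before commit? none: build two open branches
    a = repo.new_version(root)
    b = repo.new_version(root, "side")
    versions = [root, a, b]
    positions = [tuple(int(v) for v in reversed(c))
                 for c in np.argwhere(seg > 0)[::997]]
    posted: dict[str, set] = {a: set(), b: set()}
    for pos in positions[:8]:
        ann.post_elements(a, [_el(*pos)])
        posted[a].add(pos)
    for pos in positions[8:14]:
        ann.post_elements(b, [_el(*pos)])
        posted[b].add(pos)
    for step in range(12):
        u = rng.choice([a, b])
        labels = [l for l, n in oracle.body_sizes(u).items()]
        op = rng.random()
        if op < 0.5 and len(labels) > 3:
            t, m = rng.sample(labels, 2)
            try:
                lm.merge(u, t, [m])
                oracle.record(u, "merge", {"target": t, "labels": [m]})
            except V.RepoError:
                pass
        elif op < 0.8:
            mapping = lm.build_mapping(u)
            bodies = [l for l in labels if len(mapping.members(l)) > 1]
            if bodies:
                body = rng.choice(bodies)
                sv = sorted(mapping.members(body))[0]
                new = lm.cleave(u, body, [sv])
                oracle.record(u, "cleave",
                              {"body": body, "supervoxels": [sv], "new_body": new})
        else:
            sv_view = oracle.supervoxels(u)
            svs = [s for s in np.unique(sv_view) if s != 0]
            sv = int(rng.choice(svs))
            vox = np.argwhere(sv_view == sv)
            if len(vox) > 5:
                take = vox[:3]
                runs = [[int(x), int(y), int(z), 1] for z, y, x in take]
                new = lm.split_supervoxel(u, sv, SparseVol(sv, runs))
                nv = sv_view.copy()
                nv[tuple(take.T)] = new
                oracle.write_voxels(u, nv)
                oracle.record(u, "split", {})
    # final consistency at every version
    for u in versions:
        pts = posted.get(u, set()) | (posted[a] & posted[b] if u == root else set())
        truth = oracle.annotation_labels(u, pts)
        by_label_all = {}
        for lab in set(truth.values()):
            for e in ann.get_by_label(u, lab):
                by_label_all[e.pos] = lab
        assert by_label_all == truth
        got_sub = ann.get_elements_in_subvolume(u, (0, 0, 0), (64, 64, 64))
        assert {e.pos for e in got_sub} == set(pts)
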