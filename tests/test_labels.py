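import hashlib

import numpy as np
import pytest

import voxeldag as V
from voxeldag import keys as K
from voxeldag.labels import CLS_BLOCK, CLS_INDEX, LabelmapError, SparseVol, \
    _mode_downsample


@pytest.fixture
def lm(svc, repo):
    return svc.new_instance(repo, "segmentation", "labelmap")


@pytest.fixture
def seeded(svc, repo, lm, small_seg):
    seg, census = small_seg
    lm.ingest(repo.root_uuid, (0, 0, 0), seg)
    return seg, census


def _store_hash(svc, key_class=None):
    h = hashlib.sha256()
    for k, v in svc.store.scan(b"", None):
        if key_class is not None:
            _, tkey, _, _ = K.decode_storage_key(k)
            if tkey[0] != key_class:
                continue
        h.update(k)
        h.update(v)
    return h.hexdigest()


# -- ingestion & indices ---------------------------------------------------

def test_ingest_creates_one_block_kv_per_block_and_one_index_per_label(
        svc, repo, lm):
    rng = np.random.default_rng(0)
    seg = rng.integers(1, 51, (128, 128, 128)).astype(np.uint64)
    seg[rng.random((128, 128, 128)) < 0.3] = 0
    assert len(np.unique(seg[seg > 0])) == 50
    lm.ingest(repo.root_uuid, (0, 0, 0), seg)
    stored = [K.decode_storage_key(k)[1] for k, _ in svc.store.scan(b"", None)]
    assert sum(1 for t in stored if t[0] == CLS_BLOCK) == 8
    assert sum(1 for t in stored if t[0] == CLS_INDEX) == 50


def test_all_zero_ingest_stores_blocks_but_no_indices(svc, repo, lm):
    lm.ingest(repo.root_uuid, (0, 0, 0), np.zeros((128, 128, 128), np.uint64))
    stored = [K.decode_storage_key(k)[1] for k, _ in svc.store.scan(b"", None)]
    assert sum(1 for t in stored if t[0] == CLS_BLOCK) == 8
    assert sum(1 for t in stored if t[0] == CLS_INDEX) == 0


def test_index_counts_match_brute_force_census(repo, lm, seeded):
    seg, census = seeded
    for label, n in census["counts"].items():
        assert lm.label_size(repo.root_uuid, label) == n
    assert lm.label_size(repo.root_uuid, 0) == 0  # background unindexed
    assert lm.label_size(repo.root_uuid, 424242) == 0


def test_reingest_at_child_preserves_parent_view(svc, repo, lm, seeded):
    seg, _ = seeded
    root = repo.root_uuid
    repo.commit(root)
    child = repo.new_version(root)
    lm.ingest(child, (0, 0, 0), seg)
    assert (lm.get_subvolume(child, (0, 0, 0), seg.shape)
            == lm.get_subvolume(root, (0, 0, 0), seg.shape)).all()


def test_get_label_identity_before_edits(repo, lm, seeded):
    seg, _ = seeded
    for (z, y, x) in [(5, 5, 5), (33, 60, 2), (63, 63, 63)]:
        assert lm.get_label(repo.root_uuid, (x, y, z)) == seg[z, y, x]
    assert lm.get_label(repo.root_uuid, (500, 500, 500)) == 0


# -- merge ----------------------------------------------------------------

def test_merge_sums_sizes_and_retires_labels(svc, repo, lm, seeded):
    seg, census = seeded
    root = repo.root_uuid
    before = _store_hash(svc, CLS_BLOCK)
    lm.merge(root, 3, [5, 7])
    assert _store_hash(svc, CLS_BLOCK) == before  # blocks untouched
    expect = census["counts"][3] + census["counts"][5] + census["counts"][7]
    assert lm.label_size(root, 3) == expect
    assert lm.label_size(root, 5) == 0
    # merged labels' voxels now answer to the target
    zyx = np.argwhere(seg == 5)[0]
    assert lm.get_label(root, (int(zyx[2]), int(zyx[1]), int(zyx[0]))) == 3
    # supervoxel view is unchanged
    assert lm.get_label(root, (int(zyx[2]), int(zyx[1]), int(zyx[0])),
                        supervoxels=True) == 5


def test_merge_validation(repo, lm, seeded):
    root = repo.root_uuid
    with pytest.raises(LabelmapError):
        lm.merge(root, 3, [3])
    with pytest.raises(LabelmapError):
        lm.merge(root, 3, [999])
    with pytest.raises(LabelmapError):
        lm.merge(root, 999, [3])
    repo.commit(root)
    with pytest.raises(V.ImmutableVersionError):
        lm.merge(root, 3, [5])


def test_merge_writes_no_kv_records(svc, repo, lm, seeded):
    n = len(svc.store)
    lm.merge(repo.root_uuid, 1, [2])
    assert len(svc.store) == n  # mapping + log only


# -- cleave ---------------------------------------------------------------

def test_cleave_conserves_sizes_and_blocks(svc, repo, lm, seeded):
    seg, census = seeded
    root = repo.root_uuid
    lm.merge(root, 9, [10, 11])
    size9 = lm.label_size(root, 9)
    before = _store_hash(svc)
    new_body = lm.cleave(root, 9, [10])
    assert _store_hash(svc) == before  # cleave is mapping-only
    assert new_body == 13  # max seen label (12) + 1
    assert lm.label_size(root, new_body) == census["counts"][10]
    assert lm.label_size(root, 9) + lm.label_size(root, new_body) == size9
    # cleave then merge back restores the original size
    lm.merge(root, 9, [new_body])
    assert lm.label_size(root, 9) == size9


def test_cleave_validation(repo, lm, seeded):
    root = repo.root_uuid
    lm.merge(root, 1, [2])
    with pytest.raises(LabelmapError):
        lm.cleave(root, 1, [5])        # not a member
    with pytest.raises(LabelmapError):
        lm.cleave(root, 1, [1, 2])     # would empty the body
    with pytest.raises(LabelmapError):
        lm.cleave(root, 777, [1])      # unknown body


# -- supervoxel split ------------------------------------------------------

def _runs_for_voxels(zyx):
    return [[int(x), int(y), int(z), 1] for z, y, x in zyx]


def test_split_conserves_and_allocates_fresh_label(svc, repo, lm, seeded):
    seg, census = seeded
    root = repo.root_uuid
    target = 4
    vox = np.argwhere(seg == target)[:9]
    vol = SparseVol(target, _runs_for_voxels(vox))
    size_before = lm.label_size(root, target)
    new = lm.split_supervoxel(root, target, vol)
    assert new == 13
    assert lm.label_size(root, new) == 9
    assert lm.label_size(root, target) == size_before - 9
    z, y, x = vox[0]
    assert lm.get_label(root, (int(x), int(y), int(z))) == new


def test_split_rewrites_exactly_touched_blocks_plus_two_indices(
        svc, repo, lm, seeded):
    seg, _ = seeded
    root = repo.root_uuid
    repo.commit(root)
    child = repo.new_version(root)
    vid = repo.uuid_to_vid[child]
    target = 6
    vox = [tuple(v) for v in np.argwhere(seg == target)[:4]]
    lm.split_supervoxel(child, target, SparseVol(target, _runs_for_voxels(vox)))
    blocks = {(z // 64, y // 64, x // 64) for z, y, x in vox}
    delta = [K.decode_storage_key(k) for k, _ in svc.store.scan(b"", None)
             if K.decode_storage_key(k)[2] == vid]
    assert len(delta) == len(blocks) + 2
    # parent view is untouched
    assert (lm.get_subvolume(root, (0, 0, 0), seg.shape) == seg).all()


def test_split_validation(repo, lm, seeded):
    seg, _ = seeded
    root = repo.root_uuid
    vox = np.argwhere(seg == 2)
    with pytest.raises(LabelmapError):  # voxels of the wrong label
        wrong = np.argwhere(seg == 3)[:2]
        lm.split_supervoxel(root, 2, SparseVol(2, _runs_for_voxels(wrong)))
    with pytest.raises(LabelmapError):  # entire supervoxel
        lm.split_supervoxel(root, 2, SparseVol(2, _runs_for_voxels(vox)))
    with pytest.raises(LabelmapError):
        lm.split_supervoxel(root, 31337, SparseVol(31337, [[0, 0, 0, 1]]))


# -- sparse volumes --------------------------------------------------------

def test_sparsevol_matches_per_voxel_oracle(repo, lm, seeded):
    seg, census = seeded
    root = repo.root_uuid
    vol = lm.sparsevol(root, 8)
    assert vol.voxel_count == census["counts"][8]
    got = {tuple(c) for c in vol.coords()}
    expect = {tuple(c) for c in np.argwhere(seg == 8)}
    assert got == expect


def test_sparsevol_z_clip_equals_brute_force_filter(repo, lm, seeded):
    seg, _ = seeded
    root = repo.root_uuid
    vol = lm.sparsevol(root, 8, minz=20, maxz=40)
    expect = {tuple(c) for c in np.argwhere(seg == 8)
              if 20 <= c[0] <= 40}
    assert {tuple(c) for c in vol.coords()} == expect


def test_sparsevol_after_merge_is_union(repo, lm, seeded):
    seg, _ = seeded
    root = repo.root_uuid
    a = {tuple(c) for c in lm.sparsevol(root, 3).coords()}
    b = {tuple(c) for c in lm.sparsevol(root, 4).coords()}
    lm.merge(root, 3, [4])
    merged = {tuple(c) for c in lm.sparsevol(root, 3).coords()}
    assert merged == a | b
    assert lm.sparsevol(root, 4).voxel_count == 0


def test_sparsevol_binary_round_trip(repo, lm, seeded):
    root = repo.root_uuid
    vol = lm.sparsevol(root, 5)
    back = SparseVol.from_binary(vol.to_binary(), label=5)
    assert (back.runs == vol.runs).all()


def test_unknown_label_yields_empty_sparsevol(repo, lm, seeded):
    assert lm.sparsevol(repo.root_uuid, 999999).voxel_count == 0


# -- specific blocks -------------------------------------------------------

def test_specific_blocks_resolve_and_flag_absent(repo, lm, seeded):
    seg, _ = seeded
    root = repo.root_uuid
    got = lm.get_specific_blocks(root, [(0, 0, 0), (9, 9, 9)])
    assert got[0][0] == (0, 0, 0) and got[1][0] == (9, 9, 9)
    assert (V.decompress_block(got[0][1]) == seg[:64, :64, :64]).all()
    assert got[1][1] is None  # absent marker, not a zero block


# -- mapping replay & branches --------------------------------------------

def test_mapping_replay_is_deterministic_and_branch_isolated(
        svc, repo, lm, seeded):
    root = repo.root_uuid
    repo.commit(root)
    a = repo.new_version(root)
    b = repo.new_version(root, "side")
    lm.merge(a, 1, [2])
    ma = lm.build_mapping(a)
    assert ma.body(2) == 1
    assert lm.build_mapping(b).body(2) == 2  # branch B unaffected
    assert lm.build_mapping(root).body(2) == 2
    ma2 = lm.build_mapping(a)
    assert ma2.forward == ma.forward


def test_conservation_of_total_voxels_under_edit_script(repo, lm, seeded):
    seg, census = seeded
    root = repo.root_uuid
    total = sum(census["counts"].values())
    lm.merge(root, 1, [2, 3])
    new = lm.cleave(root, 1, [2])
    vox = np.argwhere(seg == 5)[:3]
    lm.split_supervoxel(root, 5, SparseVol(5, _runs_for_voxels(vox)))
    view = lm.get_subvolume(root, (0, 0, 0), seg.shape)
    assert int((view != 0).sum()) == total


# -- multiscale ------------------------------------------------------------

def test_mode_downsample_majority_and_tie_rules():
    arr = np.zeros((2, 2, 2), np.uint64)
    arr.flat[:] = [7, 7, 7, 7, 7, 7, 7, 1]        # 7-vs-1 majority
    assert _mode_downsample(arr)[0, 0, 0] == 7
    arr.flat[:] = [9, 9, 9, 9, 4, 4, 4, 4]        # 4-vs-4 tie → smaller
    assert _mode_downsample(arr)[0, 0, 0] == 4


def test_downsample_uniform_region_stays_uniform(svc, repo, lm):
    lm.ingest(repo.root_uuid, (0, 0, 0),
              np.full((128, 128, 128), 6, np.uint64))
    lm.downsample_labels(repo.root_uuid, 1)
    s1 = lm.get_subvolume(repo.root_uuid, (0, 0, 0), (64, 64, 64), scale=1)
    assert (s1 == 6).all()


def test_committed_version_rejects_all_mutations(svc, repo, lm, seeded):
    root = repo.root_uuid
    repo.commit(root)
    before = _store_hash(svc)
    for op in (lambda: lm.ingest(root, (0, 0, 0), np.ones((64,) * 3, np.uint64)),
               lambda: lm.merge(root, 1, [2]),
               lambda: lm.cleave(root, 1, [1]),
               lambda: lm.split_supervoxel(root, 1, SparseVol(1, [[0, 0, 0, 1]])),
               lambda: lm.downsample_labels(root, 1)):
        with pytest.raises(V.ImmutableVersionError):
            op()
    assert _store_hash(svc) == before  # byte-identical store
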