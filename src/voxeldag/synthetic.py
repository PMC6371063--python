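"""Deterministic synthetic data and scripted demo scenarios.

The generators emulate the inputs of a connectomics reconstruction at
desk scale: a blob-style over-segmentation (contiguous labeled regions
over background 0), matching grayscale with darkened region boundaries,
and synapse point scatters placed on labeled voxels.  All outputs are
pure functions of a :class:`SyntheticSpec` (NumPy PCG64 generator,
explicit seeding), so fixtures are byte-stable across runs.

Two scripted scenarios build small populated repositories: a delta-
accounting walk-through (ingest at root; tombstone deletion; one-block
and two-block supervoxel splits on descendant versions) and a
proofreader-training layout (per-trainee branches off the root).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .annotations import Element
from .core import Service
from .dag import Repo

__all__ = [
    "SyntheticSpec", "make_segmentation", "make_grayscale", "make_synapses",
    "scenario_delta_accounting", "scenario_training", "ScenarioHandles",
]


@dataclass(frozen=True)
class SyntheticSpec:
    extent: tuple[int, int, int]        # (nz, ny, nx)
    n_labels: int
    seed: int
    style: str = "blobs"                # "blobs" | "voronoi"
    synapse_count: int = 0


def _seed_points(rng: np.random.Generator, extent, n: int) -> np.ndarray:
    """n distinct voxel coordinates, (n, 3) in (z, y, x)."""
    total = int(np.prod(extent))
    if n > total:
        raise ValueError("more labels than voxels")
    flat: set[int] = set()
    while len(flat) < n:
        draw = rng.integers(0, total, size=2 * (n - len(flat)))
        for v in draw.tolist():
            flat.add(v)
            if len(flat) == n:
                break
    idx = np.array(sorted(flat))[rng.permutation(n)]
    return np.stack(np.unravel_index(idx, extent), axis=1)


def make_segmentation(spec: SyntheticSpec):
    """Grow ``n_labels`` contiguous regions; labels are 1..n_labels.

    "blobs": each label is its Voronoi cell intersected with a ball
    around the seed (background 0 elsewhere), covering roughly half the
    volume.  "voronoi": full partition, no background.  Returns
    ``(labels, census)`` where census has per-label voxel ``counts`` and
    per-64³-block label sets ``block_labels`` as ground truth.
    """
    extent = tuple(int(v) for v in spec.extent)
    rng = np.random.default_rng([spec.seed, 0])
    seeds = _seed_points(rng, extent, spec.n_labels)
    tree = cKDTree(seeds.astype(np.float32))
    labels = np.empty(extent, dtype=np.uint64)
    cell_volume = np.prod(extent) / spec.n_labels
    radius = 0.62 * cell_volume ** (1 / 3) if spec.style == "blobs" else None
    ny, nx = extent[1], extent[2]
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    plane = np.stack([yy.ravel(), xx.ravel()], axis=1).astype(np.float32)
    for z in range(extent[0]):  # slab-wise to bound memory
        pts = np.concatenate(
            [np.full((plane.shape[0], 1), z, np.float32), plane], axis=1)
        dist, idx = tree.query(pts)
        lab = (idx + 1).astype(np.uint64)
        if radius is not None:
            lab[dist > radius] = 0
        labels[z] = lab.reshape(ny, nx)
    # seeds always keep their own label
    labels[seeds[:, 0], seeds[:, 1], seeds[:, 2]] = \
        np.arange(1, spec.n_labels + 1, dtype=np.uint64)
    census = _census(labels)
    return labels, census


def _census(labels: np.ndarray, block_size: int = 64) -> dict:
    u, c = np.unique(labels, return_counts=True)
    counts = {int(l): int(n) for l, n in zip(u, c) if l != 0}
    block_labels: dict[tuple[int, int, int], set[int]] = {}
    b = block_size
    nz, ny, nx = labels.shape
    for bz in range(-(-nz // b)):
        for by in range(-(-ny // b)):
            for bx in range(-(-nx // b)):
                blk = labels[bz * b:(bz + 1) * b, by * b:(by + 1) * b,
                             bx * b:(bx + 1) * b]
                present = {int(l) for l in np.unique(blk) if l != 0}
                if present:
                    block_labels[(bz, by, bx)] = present
    return {"counts": counts, "block_labels": block_labels}


def make_grayscale(spec: SyntheticSpec, segmentation: np.ndarray | None = None
                   ) -> np.ndarray:
    """Uniform noise over [0, 255] with darker region boundaries when a
    segmentation is supplied (visual plausibility only)."""
    extent = tuple(int(v) for v in spec.extent)
    rng = np.random.default_rng([spec.seed, 1])
    gray = rng.integers(0, 256, size=extent, dtype=np.int16)
    if segmentation is not None:
        boundary = np.zeros(extent, bool)
        for ax in range(3):
            d = np.diff(segmentation, axis=ax) != 0
            pad = [(0, 0)] * 3
            pad[ax] = (0, 1)
            boundary |= np.pad(d, pad)
            pad[ax] = (1, 0)
            boundary |= np.pad(d, pad)
        gray[boundary] //= 3
    return gray.astype(np.uint8)


def make_synapses(spec: SyntheticSpec, segmentation: np.ndarray
                  ) -> tuple[list[Element], dict[tuple[int, int, int], int]]:
    """Seeded synapse points on non-background voxels.

    Returns the elements (pos in (x, y, z)) and the ground-truth label at
    each position.  Kinds alternate PreSyn/PostSyn.
    """
    rng = np.random.default_rng([spec.seed, 2])
    fg = np.flatnonzero(segmentation.reshape(-1))
    n = min(int(spec.synapse_count), len(fg))
    picks = rng.choice(len(fg), size=n, replace=False)
    coords = np.stack(np.unravel_index(fg[np.sort(picks)],
                                       segmentation.shape), axis=1)
    elements, truth = [], {}
    for i, (z, y, x) in enumerate(coords):
        pos = (int(x), int(y), int(z))
        elements.append(Element(pos=pos,
                                kind="PreSyn" if i % 2 == 0 else "PostSyn"))
        truth[pos] = int(segmentation[z, y, x])
    return elements, truth


# ---------------------------------------------------------------------------
# Scripted scenarios
# ---------------------------------------------------------------------------

@dataclass
class ScenarioHandles:
    service: Service
    repo: Repo
    versions: dict[str, str]
    segmentation_name: str = "segmentation"
    annotation_name: str = "synapses"
    info: dict = field(default_factory=dict)

    @property
    def segmentation(self):
        return self.service.instance(self.repo, self.segmentation_name)

    @property
    def annotations(self):
        return self.service.instance(self.repo, self.annotation_name)

    def kv_delta(self, version: str) -> int:
        """Stored key-value records (data store) written at ``version``."""
        from . import keys as K
        vid = self.repo.uuid_to_vid[version]
        n = 0
        for k, _ in self.service.store.scan(b"", None):
            _, _, kvid, _ = K.decode_storage_key(k)
            if kvid == vid:
                n += 1
        return n


def _styled_uuid_factory(seed: int, prefixes: list[str]):
    """Deterministic UUIDs whose leading hex matches a story line
    (root '8fc4…', etc.), for readable demos and prefix-resolution."""
    from .dag import seeded_uuid_factory
    base = seeded_uuid_factory(seed)
    state = {"i": 0}

    def make() -> str:
        u = base()
        i = state["i"]
        state["i"] += 1
        if i < len(prefixes):
            p = prefixes[i]
            u = p + u[len(p):]
        return u

    return make


def scenario_delta_accounting(scale_divisor: int = 25, seed: int = 8
                       ) -> ScenarioHandles:
    """Delta-accounting walk-through on a 4-node DAG.

    A (6400/scale_divisor)³ segmentation with 1,000 labels plus synapses
    is ingested at the root.  Version 1 tombstones the synapse block
    (1, 2, 3); version 2 splits a one-block fragment off supervoxel 23
    (1 block + 2 index kvs); version 3 splits a two-block fragment off
    supervoxel 23 and adds a synapse there.
    """
    side = 6400 // scale_divisor
    if side > 256:
        raise ValueError("scale_divisor must reduce the extent to ≤ 256³")
    if side < 128:
        raise ValueError("extent too small for the scripted block layout")
    extent = (side, side, side)
    spec = SyntheticSpec(extent=extent, n_labels=1000, seed=seed,
                         synapse_count=200)
    seg, _ = make_segmentation(spec)
    # Carve two label-23 patches at known places: one interior to block
    # (1, 1, 1), one straddling the x=64 block boundary.
    seg[80:83, 80:83, 80:83] = 23
    seg[100:103, 100:103, 62:66] = 23
    census = _census(seg)

    svc = Service(uuid_factory=_styled_uuid_factory(
        seed, ["8fc4", "e14d", "ec80", "d353"]))
    repo = svc.create_repo(alias="fig-delta")
    root = repo.root_uuid
    lm = svc.new_instance(repo, "segmentation", "labelmap")
    ann = svc.new_instance(repo, "synapses", "annotation")

    lm.ingest(root, (0, 0, 0), seg)
    elements, truth = make_synapses(spec, seg)
    # guarantee a synapse inside annotation block (1, 2, 3): voxel
    # (x, y, z) = (200, 150, 70)
    probe = Element(pos=(200, 150, 70), kind="PreSyn")
    elements = [e for e in elements if e.pos != probe.pos] + [probe]
    ann.post_elements(root, elements)
    repo.commit(root, "initial ingest")

    v1 = repo.new_version(root)
    ann.delete_block(v1, (1, 2, 3))
    repo.commit(v1, "remove bad synapse block")

    v2 = repo.new_version(v1)
    from .labels import SparseVol
    frag1 = SparseVol(23, [[80, 80 + dy, 80 + dz, 3]
                           for dz in range(3) for dy in range(3)])
    new1 = lm.split_supervoxel(v2, 23, frag1)
    repo.commit(v2, "one-block split of 23")

    v3 = repo.new_version(v2)
    frag2 = SparseVol(23, [[62, 100 + dy, 100 + dz, 4]
                           for dz in range(3) for dy in range(3)])
    new2 = lm.split_supervoxel(v3, 23, frag2)
    ann.post_elements(v3, [Element(pos=(63, 101, 101), kind="PostSyn")])

    return ScenarioHandles(
        service=svc, repo=repo,
        versions={"root": root, "delete": v1, "split1": v2, "split2": v3},
        info={"census": census, "synapse_truth": truth,
              "deleted_block": (1, 2, 3), "split_labels": (new1, new2),
              "extent": extent})


def scenario_training(n_trainees: int = 2, seed: int = 5) -> ScenarioHandles:
    """Proofreader-training layout: a committed root, one proofread
    master child, and one branch per trainee off the root with isolated
    edits."""
    if n_trainees < 1:
        raise ValueError("need at least one trainee")
    spec = SyntheticSpec(extent=(64, 64, 64), n_labels=20, seed=seed)
    seg, census = make_segmentation(spec)
    svc = Service(uuid_factory=_styled_uuid_factory(seed, ["c78a", "8d65"]))
    repo = svc.create_repo(alias="training")
    root = repo.root_uuid
    lm = svc.new_instance(repo, "segmentation", "labelmap")
    ann = svc.new_instance(repo, "synapses", "annotation")
    lm.ingest(root, (0, 0, 0), seg)
    repo.commit(root, "automated segmentation")

    proofread = repo.new_version(root)  # extends master
    lm.merge(proofread, 1, [2, 3])
    lm.merge(proofread, 4, [5])

    trainees = {}
    rng = np.random.default_rng([seed, 3])
    for t in range(n_trainees):
        branch = repo.new_version(root, f"trainee{t + 1}")
        # each trainee merges a different random pair
        labels = rng.permutation(np.arange(6, 20))[:2] + 0
        lm.merge(branch, int(labels[0]), [int(labels[1])])
        trainees[f"trainee{t + 1}"] = branch

    versions = {"root": root, "proofread": proofread, **trainees}
    return ScenarioHandles(service=svc, repo=repo, versions=versions,
                           info={"census": census, "n_trainees": n_trainees})
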