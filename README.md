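# voxeldag

A branched-versioned, image-oriented dataservice for connectomics, in
Python.  It gives large voxel datasets git-like version control: a DAG
of UUID-identified versions over a key-value storage core, where
committed versions are immutable, open leaves are editable, any version
is instantly readable, and an edit stores only the key-value pairs it
touches.

It is aimed at reconstruction workflows around volume electron
microscopy: ingest grayscale and machine segmentation once, commit,
then branch for proofreading, trainee exercises, or segmentation
experiments without ever copying the bulk data.

## What's inside

* **Version DAG** — repositories, branches (master is the empty-string
  branch), commit locks, node logs, UUID-prefix resolution, and the
  closest-stored-ancestor resolution that makes every read
  version-aware.
* **Versioned key-value core** — keys of the form
  `data_id + TKey + version + tombstone` over ordered backends
  (in-memory; sqlite-embedded on disk), so one range scan gathers all
  versions of a key; tombstones delete in one version without erasing
  ancestors.  A versionless-record protocol supports non-ordered object
  stores with conditional writes.
* **Typed data instances** — `uint8blk` (grayscale volumes with mean
  pyramids), `labelmap` (compressed supervoxel blocks, label indices,
  in-memory supervoxel→body mapping with merge / cleave / supervoxel
  split, run-length-encoded sparse volumes, mode-downsampled scales),
  `annotation` (3D points indexed by block, body label, and tag, kept
  consistent with segmentation edits via publish/subscribe),
  `keyvalue`, and `roi`.
* **Label block codec** — 64³ blocks with a block-level label list and
  per-8³-sub-block palettes using minimal (non-power-of-two) bit
  widths; deterministic and lossless.
* **HTTP Science API** — a WSGI app mirroring the library 1:1
  (`/api/node/<uuid>/<instance>/...`), plus `voxeldag` CLI commands for
  serving and fixture generation.

The central label-editing idea: voxels store *supervoxel* ids; neurons
(bodies) are defined by a supervoxel→body map replayed from an
append-only mutation log.  Merges and cleaves therefore touch no voxel
block at all — for a merge, `size(target)' = size(target) + Σ size(labelᵢ)`
comes entirely from re-pointing map entries — while a supervoxel split
rewrites only the affected blocks plus two small index records.

## Worked example

```python
import numpy as np
import voxeldag as V

svc = V.Service(uuid_factory=V.seeded_uuid_factory(1))
repo = svc.create_repo(alias="demo")
root = repo.root_uuid
lm = svc.new_instance(repo, "segmentation", "labelmap")
syn = svc.new_instance(repo, "synapses", "annotation")
syn.register_sync("segmentation")

seg, census = V.make_segmentation(
    V.SyntheticSpec(extent=(64, 64, 64), n_labels=12, seed=7))
lm.ingest(root, (0, 0, 0), seg)
els, truth = V.make_synapses(
    V.SyntheticSpec((64, 64, 64), 12, 7, synapse_count=40), seg)
syn.post_elements(root, els)

print("size(3) =", lm.label_size(root, 3), "census:", census["counts"][3])
repo.commit(root, "initial ingest")

child = repo.new_version(root)          # proofreading version
lm.merge(child, 3, [5])                 # map edit only; no block rewritten
print("after merge:", lm.label_size(child, 3),
      "=", census["counts"][3] + census["counts"][5])
print("root unchanged:", lm.label_size(root, 3) == census["counts"][3])
print("synapses in body 3 at child:",
      len(syn.get_by_label(child, 3)),
      "vs at root:", len(syn.get_by_label(root, 3)))
```

Output:

```
size(3) = 7332 census: 7332
after merge: 15997 = 15997
root unchanged: True
synapses in body 3 at child: 3 vs at root: 1
```

`size(3)` is body 3's voxel count straight from its label index; after
the merge on the child version the sizes add exactly, the root version
still answers with the pre-merge value (both versions share every
stored block), and the synced annotation instance immediately reports
the merged body's synapses on the child only.

Run `voxeldag serve --port 8000` and the same operations are available
over HTTP, e.g. `GET /api/node/<uuid-prefix>/segmentation/size/3`;
`/api/help/<type>` describes each data type's endpoints.

## Documentation

* `docs/methods.md` — the versioning model, storage engines, label
  semantics, synthetic-data rationale, and limitations.
* `docs/storage_format.md` — byte-level key layout, block codec wire
  format, sparse-volume RLE, and the versionless record.
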