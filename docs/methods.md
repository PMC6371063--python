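# Methods

## The model: branched versioning over key-value storage

The service treats a connectomics dataset as a git-like repository: a
DAG of versions, each a UUID-identified node, where committed nodes are
immutable snapshots and open leaf nodes accept writes.  Every branch has
a unique name; the root sits on the master branch, named by the empty
string.  For a committed node one child may extend its branch, and any
number of children may start newly named branches.

All persisted data reduces to key-value pairs.  A storage key carries
the data-instance id, a datatype-specific key (TKey), a compact version
id, and a tombstone flag, in that order (docs/storage_format.md).  A
write at a version stores only the touched key-value pairs; nothing is
ever copied forward.  A read at any version range-scans the stored
versions of a TKey and selects the *closest stored ancestor*: a
breadth-first upward walk from the queried node (itself first, parents
in stored order) that stops at the first version holding the key.  A
tombstone at that version means "deleted here" without disturbing
ancestors.  This gives O(delta) storage per version and instant reads of
any historical state.

Merge nodes can be created (ordered parents, born committed); ancestor
walks visit the first parent first, so on conflict the first parent
wins.  Data-level merge tooling is out of scope.  Nodes cannot be
deleted.  "Most recent" across branches — needed by the non-ordered
storage protocol — is defined as the larger node-creation sequence
number, a total and reproducible order.

## Storage engines

Two ordered backends implement the same contract (get/put/delete/range
scan): an in-memory sorted map and an embedded on-disk store built on
sqlite3 with a BLOB primary key, which provides ordered scans and
durability in a single file.  Both are exercised by one parametrized
contract suite.

Non-ordered object stores (emulated in-process with per-key write
generations) cannot range-scan, so versioned keys use a *versionless
record* per TKey: it lists all stored vids and holds the
highest-priority key-value inline — master-branch versions outrank
side branches, later creation order breaks ties.  First writes are a
single conditional create; the highest-priority read costs one object
fetch, any other read two.  Writers commit the record with a
generation-checked put and retry on contention (budget: 32 attempts).
Because the first write must be a single object, the inline value lives
only inside the record; evicting it on a higher-priority write adds
exactly one versioned object.  Tombstones are ordinary entries with a
deletion flag, inline or versioned.  The keyvalue data type refuses this
backend family: its key space is not computable, so valid keys could
not be enumerated without scans.

## Label compression

Supervoxel blocks (64³ × uint64) are stored with a sub-block palette
codec: a block-level sorted label list; per-8³-sub-block palettes that
index into that list with the minimal bit width `ceil(log2 n_labels)`;
and per-voxel codes of width `ceil(log2 n_sub)`.  Neither width is
rounded to a power of two, and single-label blocks or sub-blocks cost
zero palette/code bits, so a uniform block is exactly 1036 bytes
(4 + 8 + 512×2).  The codec is deterministic (sorted lists, fixed
section order, LSB-first packing) and lossless by construction; the
worst case (≤ 2¹⁶ distinct labels) stays below the 8 B/voxel raw
encoding.  Edge blocks are zero-padded to 64³ before compression, with
label 0 reserved for background/padding throughout the service.

## Label semantics: supervoxels, bodies, and O(1) edits

Voxels store *supervoxel* ids, which never change except under an
explicit supervoxel split.  Agglomerated neurons ("bodies") exist only
in an in-memory supervoxel→body map, reconstructed on demand by
replaying an append-only mutation log (merge, cleave, split entries)
along the root→version first-parent path; tables are cached per
(version, entries-replayed) so appends invalidate naturally.

The persistent label index is keyed by supervoxel id and records the
per-block voxel counts of that supervoxel.  A body's size, block set, or
sparse volume is the union over its member supervoxels.  Consequently:

* **merge** and **cleave** are log-only edits: no block and no index
  key-value is read or written, which the tests verify by hashing every
  stored byte before and after.
* **supervoxel split** rewrites exactly the blocks the split voxels
  touch, decrements the source supervoxel's index, and writes one new
  index — the classic accounting of 1 block + 2 indices for a
  one-block split.

A split keeps the original id for the remainder and allocates one fresh
id for the split-off voxels, which becomes its own identity-mapped body.
The allocator hands out (highest label ever seen in the repo) + 1,
recovering that maximum from index keys and the log after a restart; it
deliberately stores no counter key-value so edit deltas stay minimal.
Label-keyed queries interpret ids as bodies (post-mapping); a
`supervoxels=true` flag exposes raw ids.

Multiscale: grayscale pyramids average 2×2×2 children with half-up
rounding; label downsampling takes the 2×2×2 mode with ties going to
the smaller label.  Blocks absent at the finer scale contribute nothing
(the parent region stays 0); within a stored block, zeros take part in
the aggregation, since block storage cannot distinguish unwritten from
written-zero voxels.

## Annotations and publish/subscribe

Point annotations are JSON elements (one per voxel) indexed three ways:
by ZYX block, by body label, and by tag.  Spatial queries use half-open
bounds `[offset, offset+shape)`.  The by-label index requires a sync to
a labelmap instance and is maintained eagerly: merge events fold the
absorbed labels' lists into the target; cleave and split events
re-resolve the affected elements by looking their positions up in the
segmentation, which makes event application idempotent.  Block-level
deletion stores a single tombstone on the by-block key; per-element
deletion rewrites the block list.  Label ranking by annotation count is
a scan of the by-label class with ties broken toward the smaller label.

## Synthetic data

The generators emulate desk-scale reconstruction inputs, not EM
realism.  Segmentations are nearest-seed (Voronoi) partitions, either
full ("voronoi") or intersected with a ball around each seed so that
roughly half the volume is background ("blobs", the default); both give
contiguous regions and every label keeps at least its seed voxel.
Grayscale is uniform noise with darkened region boundaries.  Synapses
are uniform draws over foreground voxels with recorded ground-truth
labels.  Everything is a pure function of (extent, label count, seed)
via NumPy's PCG64; fixtures are therefore byte-stable.

What passing tests show, and what they do not: the oracle suites prove
the versioned semantics (inheritance, tombstones, delta-only storage,
mapping replay, index consistency) on volumes up to 320³ with thousands
of keys.  They say nothing about teravoxel-scale throughput, real EM
texture, cloud-store latency, or concurrent multi-writer servers — the
in-process lock serializes HTTP requests.

## Problem sizes and numerical choices

Randomized oracle runs use a 128³ volume (30 supervoxels, 9-node DAG,
3 branches, 220 operations) in-process and a 64³ volume (120
operations) through the HTTP layer; the storage-accounting run ingests
a 320³ / 1,000-label volume, chosen as the smallest extent that keeps
1,000 labels comfortably resolvable (≈ 2,000 foreground voxels per
label).  Coordinates are biased by 2³¹ in keys so negative space sorts
correctly.  Ties and degenerate inputs are pinned down explicitly:
label-mode ties take the smaller label, empty ROIs answer false,
missing voxel data reads as 0, deleting a never-written key still
records a tombstone, and a put after a delete at the same version wins
(the same-version value/tombstone pair can never coexist).

## Known limitations

* Bodies and the reverse map live fully in memory; repositories with
  very large mutation logs would need checkpointing of the map.
* Label indices are rewritten per ingest call; bulk loading many small
  strips touches the same index keys repeatedly.
* The non-ordered backend is an in-process emulation of a cloud object
  store; network drivers, caching tiers, and external event transport
  (e.g. Kafka) are out of scope.
* The HTTP layer serializes requests with one lock — correctness over
  concurrency; it is not a throughput server.
* 2D tile pyramids and transcoding to other compressed-segmentation
  wire formats are not implemented.
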