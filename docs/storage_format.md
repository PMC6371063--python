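# Wire and storage formats

This file freezes the byte layouts the service persists and transports.
They are local conventions of this implementation; changing any of them
is a breaking change to on-disk data.

## Storage key layout

Every record in an ordered backend uses one flat key:

| offset        | size | field     | encoding                              |
|---------------|------|-----------|---------------------------------------|
| 0             | 4    | data_id   | uint32 big-endian (instance id)       |
| 4             | n    | TKey      | class byte + class-specific body      |
| 4+n           | 4    | vid       | uint32 big-endian (version id)        |
| 8+n           | 1    | tombstone | 0x00 = value, 0xFF = deletion marker  |

Big-endian integers make numeric order equal byte order, so a range scan
over one `data_id + TKey` prefix returns every stored version of that
key contiguously, value before tombstone within a vid.  TKeys are capped
at 4 KiB.

### TKey classes

* **Block coordinate** (fixed length 14): class byte, scale (uint8),
  then bz, by, bx each stored biased as `coord + 2³¹` in uint32
  big-endian so negative coordinates sort below positive ones.
  Used by uint8blk and labelmap blocks (class 0x01) and the annotation
  by-block index (class 0x01).
* **uint64 label** (fixed length 9): class byte + label as uint64
  big-endian.  Used by labelmap label indices and the annotation
  by-label index (class 0x02).
* **Escaped string** (variable): class byte, then the UTF-8 body with
  every 0x00 byte rewritten as `0x00 0xFE`, terminated by `0x00 0x00`.
  This keeps arbitrary-string bodies prefix-free.  Used by keyvalue
  keys (class 0x01), the annotation by-tag index (class 0x03), and the
  ROI span record.

## Label block compression

64³ uint64 label blocks are stored compressed; see the module docstring
of `voxeldag.blockcodec` for the full four-section layout (little-endian
integers, LSB-first bit packing, per-section byte alignment):

1. uint32 label count + sorted uint64 label list (block level).
2. 512 × uint16 palette sizes, one per 8³ sub-block in Z,Y,X order.
3. palette bit stream: per sub-block, sorted indices into the label
   list, `ceil(log2 n_labels)` bits each (0 bits when one label).
4. code bit stream: per sub-block, 512 voxel codes of
   `ceil(log2 n_sub)` bits (0 bits when one palette entry).

A uniform block costs exactly 4 + 8 + 1024 = 1036 bytes.

## Sparse volumes (RLE)

Binary transport of a label's voxel set:

| field      | encoding                                   |
|------------|--------------------------------------------|
| descriptor | uint8, currently 0                         |
| run count  | uint32 little-endian                       |
| runs       | run count × 4 × int32 LE: x, y, z, length  |

Runs extend along +x and are sorted by (z, y, x).  A JSON alternative
(`?format=json`) returns `[[x, y, z, length], ...]`.

## Versionless record (non-ordered stores)

For object stores without range scans, each TKey maps to one record
object: uint32 BE version count, that many uint32 BE vids, the inline
vid (uint32 BE), an inline tombstone byte, then the inline value bytes.
Lower-priority key-values live under separate `V + data_id + TKey + vid`
object keys, each prefixed by a tombstone byte.

## Raw voxel transport

HTTP `/raw/0_1_2/<sx_sy_sz>/<ox_oy_oz>` bodies are little-endian voxel
streams in x-fastest (z, y, x array) order: uint8 for grayscale, uint64
for labels.  Sizes and offsets in URLs are x_y_z.
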