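# imp5-lite binary reference format

A compact, indexed container for fully phased biallelic haplotype
panels, designed for fast random access to genomic regions during
imputation. All integers are little-endian.

## Layout

```
offset 0:
  magic      8 bytes   "IMP5LITE"
  version    u8        currently 1
  chrom      str       u16 length + UTF-8 bytes
  N          u32       number of haplotypes
  n_ids      u32       number of haplotype labels (0 allowed)
  ids        n_ids x (u16 length + UTF-8 bytes)
  M          u32       number of markers

records (concatenated, in marker order):
  sparse record:  alt_count x u32     sorted carrier haplotype indices
  bitset record:  ceil(N/8) bytes     haplotype n at byte n>>3, bit n&7
                                      (little-endian bit order)

directory (M entries, in marker order):
  pos        u64       1-based physical position
  cm         f64       genetic position (NaN if unset)
  tag        u8        0 = sparse, 1 = bitset
  alt_count  u32       number of alternate-allele carriers
  offset     u64       absolute file offset of the record
  ref        str       u16 length + UTF-8
  alt        str       u16 length + UTF-8

trailer (last 16 bytes):
  dir_offset u64       absolute offset of the directory
  magic      8 bytes   "IMP5LITE"
```

## Encoding rule

A marker is stored **sparse** iff its alternate-allele frequency is
strictly below 1/256; at exactly 1/256 and above it is a **bitset**.
Record lengths are derivable from the directory (`4 * alt_count` bytes
for sparse, `ceil(N/8)` for bitset), so no per-record length field is
needed.

## Access pattern

A reader parses the fixed header, seeks to the trailer for the
directory offset, and loads the directory (29 bytes + allele strings
per marker). Region queries binary-search the directory's position
column and read only the in-region record byte ranges; the test suite
verifies this I/O bound by counting bytes read.

Missing alleles are unrepresentable by design: panels are validated as
fully phased 0/1 matrices before writing.

The same record structures are used in memory while imputing: rare
untyped markers keep their carrier lists (making the "does any selected
state carry the alternate allele" test an index intersection), common
markers keep packed bitsets.
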