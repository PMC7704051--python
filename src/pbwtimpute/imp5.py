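"""Indexed binary reference-panel container ("imp5-lite").

Each marker is stored independently in one of two encodings chosen by
alternate-allele frequency:

* **sparse** (alt frequency < 1/256): sorted indices of the haplotypes
  carrying the alternate allele, 4-byte little-endian each;
* **bitset** otherwise: ceil(N/8) bytes, haplotype ``n`` at byte
  ``n >> 3``, bit ``n & 7``.

A flat directory (position, alleles, encoding tag, record offset) at the
end of the file is binary-searched for random region access, so a region
read touches only the header, the directory and the in-region records.
The same record layout doubles as the in-memory reference store used
while imputing untyped markers.

File layout (all little-endian)::

    magic "IMP5LITE" | version u8 | chrom (u16 len + utf8)
    N u32 | sample-id block (u32 count, each u16 len + utf8) | M u32
    records ...
    directory: M x (pos u64, cm f64, tag u8, alt_count u32,
                    offset u64, ref str, alt str)
    trailer: directory offset u64 | magic
"""

from __future__ import annotations

import struct
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panels import HaplotypePanel, make_marker_table

MAGIC = b"IMP5LITE"
VERSION = 1
RARE_FREQ_BOUND = 1.0 / 256.0

TAG_SPARSE = 0
TAG_BITSET = 1


class Imp5Error(ValueError):
    """Raised for malformed imp5-lite files."""


@dataclass
class Imp5Record:
    """One marker's allele column in its storage encoding."""

    tag: int
    n: int
    carriers: np.ndarray | None = None  # sorted int32 hap ids (sparse)
    bits: np.ndarray | None = None  # packed uint8 (bitset)
    alt_count: int = 0

    def decode(self) -> np.ndarray:
        """Expand to the full 0/1 allele vector."""
        if self.tag == TAG_SPARSE:
            out = np.zeros(self.n, dtype=np.uint8)
            out[self.carriers] = 1
            return out
        return np.unpackbits(self.bits, count=self.n, bitorder="little")

    def carrier_ids(self) -> np.ndarray:
        if self.tag == TAG_SPARSE:
            return self.carriers
        return np.nonzero(self.decode())[0].astype(np.int32)

    @property
    def alt_frequency(self) -> float:
        return self.alt_count / self.n

    @property
    def is_rare(self) -> bool:
        return self.tag == TAG_SPARSE

    def payload(self) -> bytes:
        if self.tag == TAG_SPARSE:
            return self.carriers.astype("<u4").tobytes()
        return self.bits.tobytes()


def encode_marker(alleles: np.ndarray) -> Imp5Record:
    """Encode one allele column, choosing sparse iff alt freq < 1/256
    (strictly: a frequency of exactly 1/256 is stored as a bitset)."""
    alleles = np.asarray(alleles, dtype=np.uint8)
    if alleles.ndim != 1:
        raise Imp5Error("allele column must be 1-D")
    n = len(alleles)
    alt = int(alleles.sum())
    if alt / n < RARE_FREQ_BOUND:
        carriers = np.nonzero(alleles)[0].astype(np.int32)
        return Imp5Record(TAG_SPARSE, n, carriers=carriers, alt_count=alt)
    bits = np.packbits(alleles, bitorder="little")
    return Imp5Record(TAG_BITSET, n, bits=bits, alt_count=alt)


def carriers_at(record: Imp5Record, state_subset: np.ndarray) -> np.ndarray:
    """Members of ``state_subset`` carrying the alternate allele.

    For sparse records the shorter of (carrier list, state subset) is
    iterated against a hash set built on the longer; for bitsets each
    selected state is a direct bit test.
    """
    states = np.asarray(state_subset, dtype=np.int64)
    if record.tag == TAG_SPARSE:
        carriers = record.carriers
        if len(carriers) <= len(states):
            member = set(states.tolist())
            hit = [int(c) for c in carriers if int(c) in member]
        else:
            member = set(int(c) for c in carriers)
            hit = [int(s) for s in states if int(s) in member]
        return np.asarray(sorted(hit), dtype=np.int64)
    bits = record.bits
    vals = (bits[states >> 3] >> (states & 7).astype(np.uint8)) & 1
    return np.sort(states[vals == 1])


class Imp5Store:
    """In-memory collection of encoded marker records with metadata.

    This is both what :func:`write_imp5` serializes and what the engine
    re-reads untyped markers from during imputation.
    """

    def __init__(self, markers: pd.DataFrame, records: list[Imp5Record], n: int, sample_ids=None):
        if len(markers) != len(records):
            raise Imp5Error("marker table and record list disagree")
        self.markers = markers.reset_index(drop=True)
        self.records = records
        self.n = n
        self.sample_ids = list(sample_ids or [])

    @classmethod
    def from_panel(cls, panel: HaplotypePanel) -> "Imp5Store":
        records = [encode_marker(panel.alleles[:, m]) for m in range(panel.n_markers)]
        return cls(panel.markers.copy(), records, panel.n_haplotypes, panel.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.records)

    @property
    def positions(self) -> np.ndarray:
        return self.markers["pos"].to_numpy()

    def alt_frequency(self) -> np.ndarray:
        return np.array([r.alt_count for r in self.records]) / self.n

    def to_panel(self) -> HaplotypePanel:
        alleles = np.column_stack([r.decode() for r in self.records])
        return HaplotypePanel(alleles, self.markers.copy(), list(self.sample_ids))

    def columnar(self):
        """Cached columnar view for vectorized consumers.

        Returns a dict with ``tags``, and for sparse records the
        concatenated carrier ids + offsets, for bitset records the
        stacked packed-byte matrix + marker indices.
        """
        if getattr(self, "_columnar", None) is not None:
            return self._columnar
        tags = np.array([r.tag for r in self.records], dtype=np.uint8)
        sparse_idx = np.nonzero(tags == TAG_SPARSE)[0]
        lens = np.array(
            [len(self.records[i].carriers) for i in sparse_idx], dtype=np.int64
        )
        carriers_cat = (
            np.concatenate([self.records[i].carriers for i in sparse_idx])
            if len(sparse_idx)
            else np.empty(0, dtype=np.int32)
        )
        offsets = np.concatenate([[0], np.cumsum(lens)])
        bitset_idx = np.nonzero(tags == TAG_BITSET)[0]
        nbytes = (self.n + 7) // 8
        bits_mat = (
            np.stack([self.records[i].bits for i in bitset_idx])
            if len(bitset_idx)
            else np.empty((0, nbytes), dtype=np.uint8)
        )
        self._columnar = {
            "tags": tags,
            "sparse_idx": sparse_idx,
            "carriers_cat": carriers_cat,
            "carrier_offsets": offsets,
            "carrier_lens": lens,
            "bitset_idx": bitset_idx,
            "bits_mat": bits_mat,
        }
        return self._columnar

    def subset(self, idx) -> "Imp5Store":
        idx = np.asarray(idx, dtype=np.intp)
        return Imp5Store(
            self.markers.iloc[idx],
            [self.records[i] for i in idx],
            self.n,
            self.sample_ids,
        )


# --------------------------------------------------------------------------
# serialization


def _pack_str(s: str) -> bytes:
    b = s.encode()
    return struct.pack("<H", len(b)) + b


def _read_str(fh) -> str:
    (ln,) = struct.unpack("<H", fh.read(2))
    return fh.read(ln).decode()


def write_imp5(source, path) -> None:
    """Serialize a panel or store to an imp5-lite file."""
    store = source if isinstance(source, Imp5Store) else Imp5Store.from_panel(source)
    chrom = str(store.markers["chrom"].iloc[0]) if store.n_markers else ""
    with open(path, "wb") as fh:
        fh.write(MAGIC)
        fh.write(struct.pack("<B", VERSION))
        fh.write(_pack_str(chrom))
        fh.write(struct.pack("<I", store.n))
        fh.write(struct.pack("<I", len(store.sample_ids)))
        for sid in store.sample_ids:
            fh.write(_pack_str(sid))
        fh.write(struct.pack("<I", store.n_markers))
        offsets = []
        for rec in store.records:
            offsets.append(fh.tell())
            fh.write(rec.payload())
        dir_offset = fh.tell()
        cms = store.markers["cm"].to_numpy(dtype=float)
        for i, rec in enumerate(store.records):
            row = store.markers.iloc[i]
            fh.write(
                struct.pack(
                    "<QdBIQ",
                    int(row.pos),
                    float(cms[i]) if np.isfinite(cms[i]) else float("nan"),
                    rec.tag,
                    rec.alt_count,
                    offsets[i],
                )
            )
            fh.write(_pack_str(str(row.ref)))
            fh.write(_pack_str(str(row.alt)))
        fh.write(struct.pack("<Q", dir_offset))
        fh.write(MAGIC)


class Imp5File:
    """Random-access reader over an imp5-lite file (or file-like object).

    Only the header and directory are parsed on open; records are read
    on demand by offset, so region extraction is proportional to the
    region, not the file.
    """

    def __init__(self, path_or_file):
        if hasattr(path_or_file, "read"):
            self._fh = path_or_file
            self._own = False
        else:
            self._fh = open(path_or_file, "rb")
            self._own = True
        self._parse()

    def _parse(self):
        fh = self._fh
        fh.seek(0)
        if fh.read(8) != MAGIC:
            raise Imp5Error("bad magic: not an imp5-lite file")
        (version,) = struct.unpack("<B", fh.read(1))
        if version != VERSION:
            raise Imp5Error(f"unsupported imp5-lite version {version}")
        self.chrom = _read_str(fh)
        (self.n,) = struct.unpack("<I", fh.read(4))
        (n_ids,) = struct.unpack("<I", fh.read(4))
        self.sample_ids = [_read_str(fh) for _ in range(n_ids)]
        (self.n_markers,) = struct.unpack("<I", fh.read(4))
        fh.seek(-16, 2)
        dir_offset_raw = fh.read(16)
        if dir_offset_raw[8:] != MAGIC:
            raise Imp5Error("truncated imp5-lite file (bad trailer)")
        (dir_offset,) = struct.unpack("<Q", dir_offset_raw[:8])
        fh.seek(dir_offset)
        pos, cm, tag, alt_count, offset, ref, alt = [], [], [], [], [], [], []
        for _ in range(self.n_markers):
            p, c, t, ac, off = struct.unpack("<QdBIQ", fh.read(29))
            pos.append(p)
            cm.append(c)
            tag.append(t)
            alt_count.append(ac)
            offset.append(off)
            ref.append(_read_str(fh))
            alt.append(_read_str(fh))
        self.pos = np.asarray(pos, dtype=np.int64)
        self.cm = np.asarray(cm, dtype=float)
        self.tag = np.asarray(tag, dtype=np.uint8)
        self.alt_count = np.asarray(alt_count, dtype=np.int64)
        self.offset = np.asarray(offset, dtype=np.int64)
        self.ref = ref
        self.alt = alt
        if np.any(np.diff(self.offset) <= 0) or np.any(np.diff(self.pos) <= 0):
            raise Imp5Error("directory not strictly increasing")

    def close(self):
        if self._own:
            self._fh.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()

    def _read_record(self, i: int) -> Imp5Record:
        fh = self._fh
        fh.seek(int(self.offset[i]))
        ac = int(self.alt_count[i])
        if self.tag[i] == TAG_SPARSE:
            raw = fh.read(4 * ac)
            carriers = np.frombuffer(raw, dtype="<u4").astype(np.int32)
            return Imp5Record(TAG_SPARSE, self.n, carriers=carriers, alt_count=ac)
        nbytes = (self.n + 7) // 8
        raw = fh.read(nbytes)
        return Imp5Record(
            TAG_BITSET, self.n, bits=np.frombuffer(raw, dtype=np.uint8), alt_count=ac
        )

    def _region_slice(self, start: int | None, end: int | None) -> slice:
        lo = 0 if start is None else int(np.searchsorted(self.pos, start, "left"))
        hi = self.n_markers if end is None else int(np.searchsorted(self.pos, end, "right"))
        return slice(lo, hi)

    def read_store(self, start: int | None = None, end: int | None = None) -> Imp5Store:
        sl = self._region_slice(start, end)
        records = [self._read_record(i) for i in range(sl.start, sl.stop)]
        markers = make_marker_table(
            [self.chrom] * (sl.stop - sl.start),
            self.pos[sl],
            self.ref[sl.start : sl.stop],
            self.alt[sl.start : sl.stop],
            self.cm[sl],
        ) if sl.stop > sl.start else pd.DataFrame(
            {"chrom": [], "pos": [], "ref": [], "alt": [], "cm": []}
        )
        return Imp5Store(markers, records, self.n, self.sample_ids)

    def read_region(self, start: int | None = None, end: int | None = None) -> HaplotypePanel | None:
        """Decode the markers with ``start <= pos <= end`` into a panel
        (``None`` when the region is empty)."""
        store = self.read_store(start, end)
        if store.n_markers == 0:
            return None
        return store.to_panel()


def read_region(path, region: str | None = None) -> HaplotypePanel | None:
    """Convenience wrapper: open, slice by ``chrom:start-end``, decode."""
    start = end = None
    if region:
        chrom, _, span = region.partition(":")
        if span:
            s, _, e = span.partition("-")
            start, end = int(s), int(e)
    with Imp5File(path) as f:
        if region and chrom and f.chrom and chrom != f.chrom:
            return None
        return f.read_region(start, end)
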