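"""Phased haplotype panels, markers, genetic maps and their I/O.

A :class:`HaplotypePanel` is the central in-memory container: an N x M
binary allele matrix (haplotype-major) plus a marker table.  Panels are
fully phased by construction -- missing or unphased genotypes are a hard
error at parse time, because the downstream copying model is only defined
for complete phased data.

Marker metadata is kept in a :class:`pandas.DataFrame` with columns
``chrom, pos, ref, alt, cm`` (1-based physical position, centimorgans).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MARKER_COLUMNS = ["chrom", "pos", "ref", "alt", "cm"]


class PanelError(ValueError):
    """Raised for malformed panels or panel files."""


def make_marker_table(chrom, pos, ref, alt, cm=None) -> pd.DataFrame:
    """Assemble a marker table, validating ordering and biallelic alleles."""
    pos = np.asarray(pos, dtype=np.int64)
    if pos.size and pos.min() < 1:
        raise PanelError("marker positions must be >= 1")
    if np.any(np.diff(pos) <= 0):
        raise PanelError("markers must be strictly increasing by position")
    ref = list(map(str, ref))
    alt = list(map(str, alt))
    if any(not a for a in ref) or any(not a for a in alt):
        raise PanelError("alleles must be non-empty")
    if cm is None:
        cm = np.full(pos.shape, np.nan)
    cm = np.asarray(cm, dtype=float)
    if np.any(np.diff(cm[~np.isnan(cm)]) < 0):
        raise PanelError("cm must be non-decreasing along the chromosome")
    chrom = np.broadcast_to(np.asarray(chrom, dtype=object), pos.shape).copy()
    return pd.DataFrame(
        {"chrom": chrom, "pos": pos, "ref": ref, "alt": alt, "cm": cm}
    )


@dataclass
class HaplotypePanel:
    """N phased haplotypes at M biallelic markers.

    Parameters
    ----------
    alleles
        ``(N, M)`` matrix of 0/1 alleles, one row per haplotype.
    markers
        Marker table (``chrom, pos, ref, alt, cm``), one row per column
        of ``alleles``, sorted by position.
    sample_ids
        Haplotype labels; row ``2*i`` and ``2*i + 1`` are the two
        haplotypes of sample ``i`` when the panel is diploid-paired.
    """

    alleles: np.ndarray
    markers: pd.DataFrame
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.alleles = np.ascontiguousarray(self.alleles, dtype=np.uint8)
        if self.alleles.ndim != 2:
            raise PanelError("alleles must be a 2-D matrix")
        n, m = self.alleles.shape
        if n < 1 or m < 1:
            raise PanelError("panel must contain >= 1 haplotype and marker")
        if len(self.markers) != m:
            raise PanelError(
                f"marker table has {len(self.markers)} rows, panel has {m} columns"
            )
        bad = (self.alleles > 1).any()
        if bad:
            raise PanelError("alleles must be 0/1 (biallelic, no missing)")
        if len(self.sample_ids) == 0:
            self.sample_ids = [f"hap{i}" for i in range(n)]
        self.markers = self.markers.reset_index(drop=True)

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_markers(self) -> int:
        return self.alleles.shape[1]

    @property
    def positions(self) -> np.ndarray:
        return self.markers["pos"].to_numpy()

    @property
    def cm(self) -> np.ndarray:
        return self.markers["cm"].to_numpy(dtype=float)

    @property
    def chrom(self) -> str:
        return str(self.markers["chrom"].iloc[0])

    def alt_frequency(self) -> np.ndarray:
        """Alternate-allele frequency per marker."""
        return self.alleles.mean(axis=0)

    def maf(self) -> np.ndarray:
        """Minor-allele frequency per marker."""
        f = self.alt_frequency()
        return np.minimum(f, 1.0 - f)

    def subset_markers(self, idx) -> "HaplotypePanel":
        idx = np.asarray(idx, dtype=np.intp)
        return HaplotypePanel(
            self.alleles[:, idx],
            self.markers.iloc[idx].reset_index(drop=True),
            list(self.sample_ids),
        )

    def restrict_to_region(self, start: int, end: int) -> "HaplotypePanel":
        """Markers with ``start <= pos <= end`` (1-based inclusive)."""
        pos = self.positions
        keep = np.nonzero((pos >= start) & (pos <= end))[0]
        return self.subset_markers(keep)


@dataclass
class MarkerPartition:
    """Split of reference markers into typed (shared) and untyped sets.

    ``typed_idx[j]`` is the reference column matching the j-th retained
    target column ``target_cols[j]``; ``untyped_idx`` are reference-only
    markers.  Matching is exact on (chrom, pos, ref, alt).
    """

    typed_idx: np.ndarray
    untyped_idx: np.ndarray
    target_cols: np.ndarray

    @property
    def n_typed(self) -> int:
        return len(self.typed_idx)


class GeneticMap:
    """Piecewise-linear physical-position -> centimorgan map."""

    def __init__(self, positions, cms):
        self.positions = np.asarray(positions, dtype=np.int64)
        self.cms = np.asarray(cms, dtype=float)
        if self.positions.size == 0:
            raise PanelError("genetic map is empty")
        if np.any(np.diff(self.positions) <= 0):
            raise PanelError("map positions must be strictly increasing")
        if np.any(np.diff(self.cms) < 0):
            raise PanelError("map cM values must be non-decreasing")

    @classmethod
    def constant_rate(cls, start_bp: int, end_bp: int, rate_cm_per_mb: float = 1.0):
        """Uniform-rate map; default 1 cM/Mb (human genome average)."""
        span = (end_bp - start_bp) * 1e-6 * rate_cm_per_mb
        return cls([start_bp, max(end_bp, start_bp + 1)], [0.0, max(span, 1e-12)])

    @classmethod
    def read(cls, path) -> "GeneticMap":
        """Read a genetic map file.

        Accepts the 3-column HapMap format (``position rate cM``, with a
        header line) and the 4-column PLINK format
        (``chrom id cM position``).  Columns are sniffed from the first
        data line.
        """
        df = pd.read_csv(path, sep=r"\s+", header=None, comment="#", dtype=str)
        first = df.iloc[0]
        if not first[0].lstrip("-").replace(".", "", 1).isdigit():
            df = df.iloc[1:].reset_index(drop=True)  # header line
        if df.shape[1] >= 4:
            pos = df[3].astype(np.int64).to_numpy()
            cm = df[2].astype(float).to_numpy()
        elif df.shape[1] == 3:
            pos = df[0].astype(np.int64).to_numpy()
            cm = df[2].astype(float).to_numpy()
        else:
            raise PanelError(f"unrecognized genetic map layout in {path}")
        order = np.argsort(pos, kind="stable")
        return cls(pos[order], cm[order])

    def interpolate(self, positions) -> np.ndarray:
        """cM at ``positions``; extrapolates outside the anchors at the
        nearest interval's recombination rate."""
        positions = np.asarray(positions, dtype=np.int64)
        cm = np.interp(positions, self.positions, self.cms)
        if len(self.positions) >= 2:
            left_rate = (self.cms[1] - self.cms[0]) / max(
                self.positions[1] - self.positions[0], 1
            )
            right_rate = (self.cms[-1] - self.cms[-2]) / max(
                self.positions[-1] - self.positions[-2], 1
            )
            before = positions < self.positions[0]
            after = positions > self.positions[-1]
            cm[before] = self.cms[0] + (positions[before] - self.positions[0]) * left_rate
            cm[after] = self.cms[-1] + (positions[after] - self.positions[-1]) * right_rate
        return cm


def attach_genetic_map(panel: HaplotypePanel, gmap: GeneticMap | None) -> HaplotypePanel:
    """Return a panel with marker cM set from ``gmap``.

    With ``gmap=None`` a constant 1 cM/Mb fallback anchored at the first
    marker of the window is applied (and logged).
    """
    markers = panel.markers.copy()
    if gmap is None:
        pos0 = int(panel.positions[0])
        markers["cm"] = (panel.positions - pos0) * 1e-6
        logger.warning("no genetic map supplied; using constant 1 cM/Mb fallback")
    else:
        markers["cm"] = gmap.interpolate(panel.positions)
    return HaplotypePanel(panel.alleles, markers, list(panel.sample_ids))


def partition_markers(reference: HaplotypePanel, target: HaplotypePanel) -> MarkerPartition:
    """Partition reference markers into typed (shared with the target
    panel) and untyped sets.

    Matching is exact string equality on (chrom, pos, ref, alt); target
    markers with no reference match (including swapped ref/alt) are
    dropped with a logged count.  Raises if no marker is shared, since
    the copying model is undefined without typed markers.
    """
    ref_key = {
        (str(c), int(p), r, a): i
        for i, (c, p, r, a) in enumerate(
            zip(
                reference.markers["chrom"],
                reference.markers["pos"],
                reference.markers["ref"],
                reference.markers["alt"],
            )
        )
    }
    typed, tcols = [], []
    for j, (c, p, r, a) in enumerate(
        zip(
            target.markers["chrom"],
            target.markers["pos"],
            target.markers["ref"],
            target.markers["alt"],
        )
    ):
        i = ref_key.get((str(c), int(p), r, a))
        if i is not None:
            typed.append(i)
            tcols.append(j)
    dropped = target.n_markers - len(tcols)
    if dropped:
        logger.warning("dropped %d target markers absent from the reference", dropped)
    if not typed:
        raise PanelError("no typed markers shared between panels in this window")
    typed_idx = np.asarray(typed, dtype=np.intp)
    untyped_idx = np.setdiff1d(
        np.arange(reference.n_markers, dtype=np.intp), typed_idx
    )
    return MarkerPartition(typed_idx, untyped_idx, np.asarray(tcols, dtype=np.intp))


# --------------------------------------------------------------------------
# VCF I/O


def read_vcf_panel(path, region: str | None = None) -> HaplotypePanel:
    """Read a fully phased biallelic VCF into a :class:`HaplotypePanel`.

    Haplotype order is sample order x {first, second} allele.  Unphased
    or missing genotypes are hard errors naming the offending record;
    multiallelic records are skipped with a warning.  ``region`` is
    ``chrom`` or ``chrom:start-end`` (1-based inclusive).
    """
    from cyvcf2 import VCF

    chrom_f = start = end = None
    if region:
        chrom_f, _, span = region.partition(":")
        if span:
            s, _, e = span.partition("-")
            start, end = int(s), int(e)

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols, chroms, poss, refs, alts = [], [], [], [], []
    for var in vcf:
        if chrom_f is not None and var.CHROM != chrom_f:
            continue
        if start is not None and not (start <= var.POS <= end):
            continue
        if len(var.ALT) != 1:
            logger.warning(
                "skipping multiallelic record %s:%d", var.CHROM, var.POS
            )
            continue
        gts = var.genotype.array()  # (n_samples, ploidy + 1); last col = phased flag
        alleles = gts[:, :-1]
        phased = gts[:, -1]
        if (alleles < 0).any():
            raise PanelError(
                f"missing genotype at {var.CHROM}:{var.POS}; "
                "panels must be phased with no missing alleles"
            )
        if not phased.all():
            raise PanelError(
                f"unphased genotype at {var.CHROM}:{var.POS}; "
                "panels must be fully phased"
            )
        cols.append(alleles.astype(np.uint8).reshape(-1))
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
    vcf.close()
    if not cols:
        raise PanelError(f"no usable records in {path} (region={region!r})")
    alleles = np.column_stack(cols)
    markers = make_marker_table(chroms, poss, refs, alts)
    sample_ids = [f"{s}_{h}" for s in samples for h in (1, 2)]
    return HaplotypePanel(alleles, markers, sample_ids)


def write_vcf_panel(panel: HaplotypePanel, path) -> None:
    """Write a panel as a phased GT-only VCF 4.2 (plain or bgzipped)."""
    import pysam

    n = panel.n_haplotypes
    if n % 2:
        sample_names = [f"HAP{i}" for i in range(n)]
        pair = False
    else:
        sample_names = [f"S{i}" for i in range(n // 2)]
        pair = True
    lines = ["##fileformat=VCFv4.2"]
    lines.append(f"##contig=<ID={panel.chrom}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(sample_names)
    )
    A = panel.alleles
    for m in range(panel.n_markers):
        row = panel.markers.iloc[m]
        col = A[:, m]
        if pair:
            gts = "\t".join(
                f"{col[2 * i]}|{col[2 * i + 1]}" for i in range(n // 2)
            )
        else:
            gts = "\t".join(str(v) for v in col)
        lines.append(
            f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t{gts}"
        )
    text = "\n".join(lines) + "\n"
    path = str(path)
    if path.endswith(".gz"):
        with pysam.BGZFile(path, "w") as fh:
            fh.write(text.encode())
        pysam.tabix_index(path, preset="vcf", force=True)
    else:
        with open(path, "w") as fh:
            fh.write(text)
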