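"""Synthetic study generator and accuracy scoring.

The generator emulates the evaluation design used for imputation
benchmarks: a coalescent panel over a multi-megabase region is split
into a phased reference panel and held-out target samples; the targets
are then masked down to "chip" markers (a random subset of common sites,
reference MAF > 5%, about one marker per 3 kb) and optionally corrupted
with ~2% switch errors to mimic pre-phasing.  Accuracy is the squared
Pearson correlation between true masked alleles and imputed haploid
probabilities, pooled within reference-MAF bins.

Panels are simulated with msprime under a single-population expansion
(ancestral diploid size 10,000 growing exponentially to 1,000,000 in the
recent past), which yields the strongly rare-skewed frequency spectrum
of large sequenced human cohorts.  A dependency-free mosaic fallback
generator (copying-with-mutation from a founder pool) is also provided;
it produces LD-structured binary panels for structural tests but no
coalescent genealogy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .imp5 import Imp5Record, Imp5Store, encode_marker
from .panels import HaplotypePanel, make_marker_table

#: log-spaced minor-allele-frequency bin edges, left-open/right-closed,
#: matching the log-axis the accuracy figures in this field are drawn on
DEFAULT_MAF_BIN_EDGES = (
    0.0, 5e-5, 1e-4, 2e-4, 5e-4, 1e-3, 2e-3, 5e-3, 1e-2, 2e-2, 5e-2, 0.1, 0.2, 0.5,
)

#: the bin conventionally reported as "MAF 1e-4"
RARE_BIN = (5e-5, 2e-4)


@dataclass
class SimConfig:
    """Study conditions for one synthetic imputation experiment.

    Defaults are the desk-scale benchmark design: a 2 Mb region,
    10,000 reference and 100 target samples, chip markers at one per
    3 kb drawn from sites with reference MAF > 5%, and a 2% switch-error
    option for the pre-phasing experiment.
    """

    region_bp: int = 2_000_000
    n_reference: int = 10_000  # diploid samples
    n_target: int = 100
    chip_maf: float = 0.05
    chip_spacing_bp: int = 3_000  # one chip marker per this many bp
    n_chip: int | None = None  # overrides spacing when set
    switch_error_rate: float = 0.02
    seed: int = 1
    mutation_rate: float = 1.25e-8
    recombination_rate: float = 1e-8  # 1 cM/Mb
    ne_ancestral: float = 10_000.0
    ne_present: float = 1_000_000.0
    growth_rate: float = 0.05  # per generation, recent expansion
    chrom: str = "1"

    @property
    def chip_markers(self) -> int:
        if self.n_chip is not None:
            return self.n_chip
        return max(2, round(self.region_bp / self.chip_spacing_bp))


@dataclass
class SimulatedStudy:
    """A simulated reference/target pair split into typed and untyped
    markers, ready for selection + HMM + scoring."""

    chrom: str
    ref_typed: np.ndarray  # (N, T) uint8
    typed_markers: pd.DataFrame
    untyped_store: Imp5Store
    target_typed_truth: np.ndarray  # (K, T) uint8, perfectly phased
    target_untyped_truth: np.ndarray  # (n_untyped, K) uint8
    ref_maf_typed: np.ndarray
    ref_maf_untyped: np.ndarray

    @property
    def n_reference_haplotypes(self) -> int:
        return self.ref_typed.shape[0]


def _demography(cfg: SimConfig):
    import msprime

    demog = msprime.Demography()
    demog.add_population(name="pop", initial_size=cfg.ne_present, growth_rate=cfg.growth_rate)
    t_flat = np.log(cfg.ne_present / cfg.ne_ancestral) / cfg.growth_rate
    demog.add_population_parameters_change(
        time=t_flat, initial_size=cfg.ne_ancestral, growth_rate=0.0, population="pop"
    )
    return demog


def _simulate_ts(cfg: SimConfig):
    import msprime

    ts = msprime.sim_ancestry(
        samples=cfg.n_reference + cfg.n_target,
        demography=_demography(cfg),
        sequence_length=cfg.region_bp,
        recombination_rate=cfg.recombination_rate,
        random_seed=cfg.seed + 1,
    )
    return msprime.sim_mutations(
        ts,
        rate=cfg.mutation_rate,
        model="binary",
        discrete_genome=True,
        random_seed=cfg.seed + 2,
    )


def _variant_stream(ts, n_ref_haps: int):
    """Yield (pos, ref_column, target_column) for biallelic sites that
    are polymorphic in the reference, de-duplicating coincident
    positions (first site at a position wins)."""
    last_pos = -1
    for var in ts.variants():
        if len(var.alleles) != 2:
            continue
        pos = int(var.site.position) + 1  # 1-based
        if pos == last_pos:
            continue
        g = var.genotypes.astype(np.uint8)
        ref_col = g[:n_ref_haps]
        ac = int(ref_col.sum())
        if ac == 0 or ac == n_ref_haps:
            continue  # monomorphic in the reference
        last_pos = pos
        yield pos, ref_col, g[n_ref_haps:]


def simulate_panels(cfg: SimConfig, backend: str = "msprime"):
    """Simulate a (reference, target_truth) pair of dense panels over
    the shared marker list.  Target samples come from the same
    simulation and are removed from the reference; sites monomorphic in
    the reference are dropped.
    """
    if backend == "mosaic":
        return _simulate_panels_mosaic(cfg)
    ts = _simulate_ts(cfg)
    n_ref_haps = 2 * cfg.n_reference
    pos, ref_cols, tgt_cols = [], [], []
    for p, rc, tc in _variant_stream(ts, n_ref_haps):
        pos.append(p)
        ref_cols.append(rc)
        tgt_cols.append(tc)
    cm = (np.asarray(pos) - pos[0]) * cfg.recombination_rate * 1e8 / 1e6
    markers = make_marker_table(cfg.chrom, pos, ["A"] * len(pos), ["C"] * len(pos), cm)
    ref = HaplotypePanel(
        np.column_stack(ref_cols),
        markers,
        [f"R{i}_{h}" for i in range(cfg.n_reference) for h in (1, 2)],
    )
    tgt = HaplotypePanel(
        np.column_stack(tgt_cols),
        markers.copy(),
        [f"T{i}_{h}" for i in range(cfg.n_target) for h in (1, 2)],
    )
    return ref, tgt


def _simulate_panels_mosaic(cfg: SimConfig):
    n_haps = 2 * (cfg.n_reference + cfg.n_target)
    n_markers = max(20, int(cfg.region_bp * cfg.mutation_rate * 4 * cfg.ne_ancestral * 8))
    panel = simulate_mosaic_panel(
        n_haps, n_markers, region_bp=cfg.region_bp, seed=cfg.seed, chrom=cfg.chrom
    )
    nr = 2 * cfg.n_reference
    ref_alleles = panel.alleles[:nr]
    poly = np.nonzero(
        (ref_alleles.sum(0) > 0) & (ref_alleles.sum(0) < nr)
    )[0]
    ref = HaplotypePanel(
        ref_alleles[:, poly],
        panel.markers.iloc[poly],
        [f"R{i}_{h}" for i in range(cfg.n_reference) for h in (1, 2)],
    )
    tgt = HaplotypePanel(
        panel.alleles[nr:, poly],
        panel.markers.iloc[poly].copy(),
        [f"T{i}_{h}" for i in range(cfg.n_target) for h in (1, 2)],
    )
    return ref, tgt


def simulate_mosaic_panel(
    n_haplotypes: int,
    n_markers: int,
    region_bp: int = 1_000_000,
    n_founders: int = 8,
    switch_rate: float = 8.0,  # expected template switches per haplotype
    mutation_prob: float = 0.002,  # per-site private flip
    seed: int = 1,
    chrom: str = "1",
) -> HaplotypePanel:
    """Copying-model panel generator (no coalescent machinery).

    A few founder haplotypes get alleles at log-uniform frequencies (a
    rare-skewed spectrum); every further haplotype is a mosaic of
    segments copied from *previously generated* haplotypes, with
    geometric segment lengths and sparse private mutations.  Sequential
    copying nests the sharing the way a genealogy does, so pairs of
    haplotypes carry long identical stretches and PBWT columns compress
    into runs -- the structural features of real panels this generator
    emulates.  It carries no mutation ages or recombination genealogy.
    """
    rng = np.random.default_rng(seed)
    freq = np.exp(
        rng.uniform(np.log(1.0 / (2 * n_founders)), np.log(0.5), size=n_markers)
    )
    n_founders = min(n_founders, n_haplotypes)
    H = np.empty((n_haplotypes, n_markers), dtype=np.uint8)
    H[:n_founders] = rng.random((n_founders, n_markers)) < freq[None, :]
    p_switch = min(1.0, switch_rate / n_markers)
    cols = np.arange(n_markers)
    for i in range(n_founders, n_haplotypes):
        seg_id = np.concatenate(
            [[0], np.cumsum(rng.random(n_markers - 1) < p_switch)]
        )
        templates = rng.integers(0, i, size=seg_id[-1] + 1)
        hap = H[templates[seg_id], cols]
        H[i] = hap ^ (rng.random(n_markers) < mutation_prob)
    pos = np.sort(rng.choice(np.arange(1, region_bp + 1), size=n_markers, replace=False))
    cm = (pos - pos[0]) * 1e-6
    markers = make_marker_table(chrom, pos, ["A"] * n_markers, ["C"] * n_markers, cm)
    return HaplotypePanel(H, markers)


def choose_chip_markers(ref_maf: np.ndarray, cfg: SimConfig, rng=None) -> np.ndarray:
    """Uniformly sample the chip (typed) marker indices among sites with
    reference MAF above the chip bound."""
    rng = rng or np.random.default_rng(cfg.seed + 3)
    eligible = np.nonzero(ref_maf > cfg.chip_maf)[0]
    want = cfg.chip_markers
    if len(eligible) < want:
        raise ValueError(
            f"only {len(eligible)} markers exceed MAF {cfg.chip_maf}, "
            f"cannot place {want} chip markers"
        )
    return np.sort(rng.choice(eligible, size=want, replace=False))


def mask_to_chip(target_truth: HaplotypePanel, ref_maf: np.ndarray, cfg: SimConfig):
    """Mask the target panel down to chip sites.

    Returns ``(target_observed, typed_idx, untyped_idx)``: the retained
    chip columns and the complementary evaluation mask, both as indices
    into the shared marker list.
    """
    typed_idx = choose_chip_markers(np.asarray(ref_maf), cfg)
    untyped_idx = np.setdiff1d(np.arange(target_truth.n_markers), typed_idx)
    return target_truth.subset_markers(typed_idx), typed_idx, untyped_idx


def inject_switch_errors(panel: HaplotypePanel, rate: float, seed: int):
    """Corrupt phasing: per sample, at each heterozygous site after the
    first, swap the remainder of the two haplotypes with probability
    ``rate``.  Returns the corrupted panel and the realized switch rate.
    """
    if panel.n_haplotypes % 2:
        raise ValueError("switch errors need haplotypes in sample pairs")
    rng = np.random.default_rng(seed)
    alleles = panel.alleles.copy()
    n_events = 0
    n_opportunities = 0
    for i in range(panel.n_haplotypes // 2):
        h1, h2 = alleles[2 * i], alleles[2 * i + 1]
        het = np.nonzero(h1 != h2)[0]
        if len(het) < 2:
            continue
        draws = rng.random(len(het) - 1) < rate
        n_events += int(draws.sum())
        n_opportunities += len(het) - 1
        parity = np.zeros(panel.n_markers, dtype=np.uint8)
        np.add.at(parity, het[1:][draws], 1)
        parity = np.cumsum(parity) & 1
        swap = parity == 1
        h1s = np.where(swap, h2, h1)
        h2s = np.where(swap, h1, h2)
        alleles[2 * i] = h1s
        alleles[2 * i + 1] = h2s
    realized = n_events / n_opportunities if n_opportunities else 0.0
    out = HaplotypePanel(alleles, panel.markers.copy(), list(panel.sample_ids))
    return out, realized


def simulate_study(cfg: SimConfig) -> SimulatedStudy:
    """Full study build with the reference kept in compact encoded form.

    The tree sequence is swept twice: once for reference allele counts
    (to pick chip sites), once to materialise the typed reference
    matrix, the encoded untyped store and the target truth -- the dense
    N x M reference matrix is never built, so panels of tens of
    thousands of haplotypes fit comfortably in memory.
    """
    ts = _simulate_ts(cfg)
    n_ref_haps = 2 * cfg.n_reference
    pos_list, ac_list = [], []
    for p, rc, _ in _variant_stream(ts, n_ref_haps):
        pos_list.append(p)
        ac_list.append(int(rc.sum()))
    pos = np.asarray(pos_list, dtype=np.int64)
    freq = np.asarray(ac_list, dtype=float) / n_ref_haps
    maf = np.minimum(freq, 1.0 - freq)
    typed_idx = choose_chip_markers(maf, cfg)
    typed_set = set(typed_idx.tolist())
    cm = (pos - pos[0]) * cfg.recombination_rate * 1e8 / 1e6

    t = len(typed_idx)
    n_u = len(pos) - t
    k = 2 * cfg.n_target
    ref_typed = np.empty((n_ref_haps, t), dtype=np.uint8)
    target_typed = np.empty((k, t), dtype=np.uint8)
    target_untyped = np.empty((n_u, k), dtype=np.uint8)
    records: list[Imp5Record] = []
    u_rows = []
    ti = ui = 0
    for j, (p, rc, tc) in enumerate(_variant_stream(ts, n_ref_haps)):
        if j in typed_set:
            ref_typed[:, ti] = rc
            target_typed[:, ti] = tc
            ti += 1
        else:
            records.append(encode_marker(rc))
            target_untyped[ui] = tc
            u_rows.append(j)
            ui += 1
    u_rows = np.asarray(u_rows, dtype=np.intp)
    typed_markers = make_marker_table(
        cfg.chrom, pos[typed_idx], ["A"] * t, ["C"] * t, cm[typed_idx]
    )
    untyped_markers = make_marker_table(
        cfg.chrom, pos[u_rows], ["A"] * n_u, ["C"] * n_u, cm[u_rows]
    )
    store = Imp5Store(untyped_markers, records, n_ref_haps)
    return SimulatedStudy(
        chrom=cfg.chrom,
        ref_typed=ref_typed,
        typed_markers=typed_markers,
        untyped_store=store,
        target_typed_truth=target_typed,
        target_untyped_truth=target_untyped,
        ref_maf_typed=maf[typed_idx],
        ref_maf_untyped=maf[u_rows],
    )


def downsample_study(study: SimulatedStudy, n_samples: int) -> SimulatedStudy:
    """Restrict a study's reference panel to its first ``n_samples``
    diploid samples, keeping the marker lists and targets fixed.

    This is the clean panel-size comparison: the same variants are
    imputed for the same targets from nested reference panels, so
    accuracy differences are attributable to panel size alone.  Markers
    monomorphic in the subsample are kept (and impute toward 0), exactly
    as when imputing a fixed site list from a smaller panel.
    """
    n_haps = 2 * n_samples
    if n_haps > study.ref_typed.shape[0]:
        raise ValueError("cannot downsample to more samples than present")
    ref_typed = study.ref_typed[:n_haps]
    records = [
        encode_marker(r.decode()[:n_haps]) for r in study.untyped_store.records
    ]
    store = Imp5Store(
        study.untyped_store.markers.copy(), records, n_haps
    )
    f_typed = ref_typed.mean(axis=0)
    f_untyped = np.array([r.alt_count for r in records]) / n_haps
    return SimulatedStudy(
        chrom=study.chrom,
        ref_typed=ref_typed,
        typed_markers=study.typed_markers.copy(),
        untyped_store=store,
        target_typed_truth=study.target_typed_truth,
        target_untyped_truth=study.target_untyped_truth,
        ref_maf_typed=np.minimum(f_typed, 1 - f_typed),
        ref_maf_untyped=np.minimum(f_untyped, 1 - f_untyped),
    )


@dataclass
class AccuracyTable:
    """Per-MAF-bin squared correlation between truth and dosages."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def pooled_r2(
    truth: np.ndarray, imputed: np.ndarray, ref_maf: np.ndarray, lo: float, hi: float
) -> float:
    """r^2 pooled over the single MAF bin (lo, hi]."""
    tab = score_r2_by_maf(truth, imputed, ref_maf, edges=(lo, hi)).table
    return float(tab["r2"].iloc[0])


def _pearson_r2(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def score_r2_by_maf(
    truth: np.ndarray,
    imputed: np.ndarray,
    ref_maf: np.ndarray,
    edges=DEFAULT_MAF_BIN_EDGES,
) -> AccuracyTable:
    """Bin markers by reference MAF and, within each bin, correlate the
    concatenated (true allele, imputed probability) pairs across all
    markers and target haplotypes.

    ``truth`` and ``imputed`` are ``(n_markers, n_haplotypes)`` (or 1-D
    per-marker vectors); bins with a constant vector are flagged
    undefined (NaN r^2).
    """
    truth = np.atleast_2d(np.asarray(truth, dtype=float).T).T
    imputed = np.atleast_2d(np.asarray(imputed, dtype=float).T).T
    if truth.shape != imputed.shape:
        raise ValueError("truth and imputed shapes differ")
    ref_maf = np.asarray(ref_maf, dtype=float)
    if len(ref_maf) != truth.shape[0]:
        raise ValueError("ref_maf length must match the marker axis")
    edges = np.asarray(edges, dtype=float)
    rows = []
    for b in range(len(edges) - 1):
        lo, hi = edges[b], edges[b + 1]
        in_bin = (ref_maf > lo) & (ref_maf <= hi)
        n_markers = int(in_bin.sum())
        x = truth[in_bin].ravel()
        y = imputed[in_bin].ravel()
        rows.append(
            {
                "bin_low": lo,
                "bin_high": hi,
                "n_markers": n_markers,
                "n_alleles": len(x),
                "r2": _pearson_r2(x, y) if n_markers else float("nan"),
            }
        )
    return AccuracyTable(pd.DataFrame(rows))
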