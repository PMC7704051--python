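"""Orchestration: the per-window imputation pipeline and experiments.

A window is a core region plus a buffer on each side (default 1 Mb).
Typed markers in the whole buffered region drive state selection and
the HMM, so posteriors near the core edges are well conditioned, but
only core-region markers are emitted; adjacent windows therefore
concatenate into exactly the single-run marker inventory.

The pipeline per window: read reference and target panels for the
buffered region -> attach genetic map -> partition markers into typed /
untyped -> PBWT state selection -> per-target forward-backward ->
interpolated (lazy) imputation at untyped markers -> VCF output with
DS/GP.  Everything is deterministic given inputs and flags.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np

from . import imp5, panels
from .hmm import (
    HmmParameters,
    PosteriorSet,
    forward_backward,
    impute_target_untyped,
    lazy_impute_target,
    to_diploid,
)
from .selection import SelectionConfig, StateList, run_selection
from .simulate import (
    SimConfig,
    score_r2_by_maf,
    simulate_study,
    inject_switch_errors,
)

logger = logging.getLogger(__name__)


@dataclass
class WindowPlan:
    """Core imputation region plus flanking buffer (bp, 1-based incl.)."""

    chrom: str
    start: int
    end: int
    buffer_bp: int = 1_000_000

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("window start must be <= end")
        if self.buffer_bp < 0:
            raise ValueError("buffer must be >= 0")

    @property
    def effective_start(self) -> int:
        return max(1, self.start - self.buffer_bp)

    @property
    def effective_end(self) -> int:
        return self.end + self.buffer_bp

    @classmethod
    def parse(cls, region: str, buffer_bp: int = 1_000_000) -> "WindowPlan":
        chrom, _, span = region.partition(":")
        if not chrom or not span or "-" not in span:
            raise ValueError(f"bad region string {region!r}; want chrom:start-end")
        s, _, e = span.partition("-")
        return cls(chrom, int(s), int(e), buffer_bp)


@dataclass
class ImputationResult:
    """Dosages and diagnostics for one window, all targets."""

    typed_markers: "object"  # DataFrame
    untyped_markers: "object"
    dosage_typed: np.ndarray  # (T, K)
    dosage_untyped: np.ndarray  # (n_untyped, K)
    target_typed: np.ndarray  # (K, T) observed alleles
    state_lists: list[StateList] = field(default_factory=list)

    @property
    def mean_states(self) -> float:
        return float(np.mean([len(s) for s in self.state_lists]))


def impute_panels(
    ref_typed: np.ndarray,
    typed_markers,
    untyped_store: imp5.Imp5Store,
    target_typed: np.ndarray,
    sel_cfg: SelectionConfig | None = None,
    params: HmmParameters | None = None,
    sparsify: bool = True,
    lazy: bool = True,
    vectorized: bool = True,
) -> ImputationResult:
    """Core in-memory pipeline over pre-partitioned panels.

    ``ref_typed`` (N x T) and ``target_typed`` (K x T) share the typed
    marker list; ``untyped_store`` holds the reference-only markers in
    encoded form.  ``vectorized`` switches between the batch dosage
    kernel and the per-record streaming path (the latter honours
    ``lazy``; both produce the same dosages).
    """
    sel_cfg = sel_cfg or SelectionConfig()
    params = params or HmmParameters()
    typed_cm = typed_markers["cm"].to_numpy(dtype=float)
    typed_pos = typed_markers["pos"].to_numpy()
    state_lists = run_selection(ref_typed, target_typed, typed_cm, sel_cfg)
    k = target_typed.shape[0]
    t = ref_typed.shape[1]
    n_u = untyped_store.n_markers
    dosage_typed = np.empty((t, k))
    dosage_untyped = np.empty((n_u, k))
    u_pos = untyped_store.positions
    u_cm = untyped_store.markers["cm"].to_numpy(dtype=float)
    n_panel = ref_typed.shape[0]
    for q in range(k):
        states = state_lists[q].states
        state_alleles = ref_typed[states]
        post = forward_backward(
            target_typed[q], state_alleles, typed_cm, params, n_panel=n_panel
        )
        pset = PosteriorSet(
            post, states, typed_pos, typed_cm, sparsify=sparsify
        )
        dosage_typed[:, q] = pset.typed_dosages(state_alleles)
        if n_u == 0:
            continue
        if vectorized:
            dosage_untyped[:, q] = impute_target_untyped(pset, untyped_store)
        else:
            dosage_untyped[:, q] = np.fromiter(
                lazy_impute_target(
                    pset, untyped_store.records, u_pos, u_cm, lazy=lazy
                ),
                dtype=float,
                count=n_u,
            )
    return ImputationResult(
        typed_markers,
        untyped_store.markers,
        dosage_typed,
        dosage_untyped,
        target_typed,
        state_lists,
    )


def _load_reference(path, chrom: str, start: int, end: int) -> panels.HaplotypePanel:
    path = str(path)
    if path.endswith(".imp5"):
        panel = imp5.read_region(path, f"{chrom}:{start}-{end}")
        if panel is None:
            raise panels.PanelError(f"no reference markers in {chrom}:{start}-{end}")
        return panel
    return panels.read_vcf_panel(path, f"{chrom}:{start}-{end}")


def impute_window(
    reference_path,
    target_path,
    plan: WindowPlan,
    out_path,
    map_path=None,
    sel_cfg: SelectionConfig | None = None,
    params: HmmParameters | None = None,
    lazy: bool = True,
    sparsify: bool = True,
) -> dict:
    """File-to-file imputation of one window; returns a run summary.

    Typed markers across the buffered region condition the model; only
    markers inside the core region are written.  Output records carry
    DS (diploid dosage) and GP; typed markers echo the observed GT and
    are flagged TYPED, untyped markers are flagged IMP.
    """
    t0 = time.time()
    ref = _load_reference(reference_path, plan.chrom, plan.effective_start, plan.effective_end)
    tgt = panels.read_vcf_panel(
        target_path, f"{plan.chrom}:{plan.effective_start}-{plan.effective_end}"
    )
    if ref.chrom != tgt.chrom:
        raise panels.PanelError(
            f"chromosome mismatch: reference {ref.chrom}, target {tgt.chrom}"
        )
    gmap = panels.GeneticMap.read(map_path) if map_path else None
    ref = panels.attach_genetic_map(ref, gmap)
    part = panels.partition_markers(ref, tgt)
    ref_typed = ref.alleles[:, part.typed_idx]
    typed_markers = ref.markers.iloc[part.typed_idx].reset_index(drop=True)
    target_typed = tgt.alleles[:, part.target_cols]
    untyped_store = imp5.Imp5Store.from_panel(ref.subset_markers(part.untyped_idx)) \
        if len(part.untyped_idx) else imp5.Imp5Store(
            ref.markers.iloc[:0], [], ref.n_haplotypes
        )
    result = impute_panels(
        ref_typed,
        typed_markers,
        untyped_store,
        target_typed,
        sel_cfg=sel_cfg,
        params=params,
        sparsify=sparsify,
        lazy=lazy,
        vectorized=False,
    )
    n_written = write_imputed_vcf(result, tgt.sample_ids, plan, out_path)
    summary = {
        "n_reference_haplotypes": ref.n_haplotypes,
        "n_target_haplotypes": tgt.n_haplotypes,
        "n_typed": part.n_typed,
        "n_untyped": len(part.untyped_idx),
        "n_written": n_written,
        "mean_selected_states": result.mean_states,
        "seconds": round(time.time() - t0, 3),
    }
    logger.info("window %s:%d-%d done: %s", plan.chrom, plan.start, plan.end, summary)
    return summary


def write_imputed_vcf(
    result: ImputationResult, hap_ids: list[str], plan: WindowPlan, out_path
) -> int:
    """Write core-region markers with GT:DS:GP, sorted by position.

    Formatting is fixed (3 decimals) so repeat runs are byte-identical.
    """
    k = result.dosage_typed.shape[1]
    if k % 2:
        raise ValueError("output requires target haplotypes in sample pairs")
    sample_names = []
    for i in range(0, k, 2):
        name = str(hap_ids[i])
        sample_names.append(name[:-2] if name.endswith("_1") else f"S{i // 2}")

    rows = []  # (pos, ref, alt, imputed, probs (K,), gts or None)
    tm = result.typed_markers
    for j in range(len(tm)):
        rows.append(
            (
                int(tm["pos"].iloc[j]),
                str(tm["ref"].iloc[j]),
                str(tm["alt"].iloc[j]),
                False,
                result.dosage_typed[j],
                result.target_typed[:, j],
            )
        )
    um = result.untyped_markers
    for j in range(len(um)):
        rows.append(
            (
                int(um["pos"].iloc[j]),
                str(um["ref"].iloc[j]),
                str(um["alt"].iloc[j]),
                True,
                result.dosage_untyped[j],
                None,
            )
        )
    rows.sort(key=lambda r: r[0])

    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={plan.chrom}>",
        '##INFO=<ID=IMP,Number=0,Type=Flag,Description="Imputed marker">',
        '##INFO=<ID=TYPED,Number=0,Type=Flag,Description="Genotyped marker">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Diploid dosage">',
        '##FORMAT=<ID=GP,Number=3,Type=Float,Description="Genotype probabilities">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(sample_names),
    ]
    n_written = 0
    for pos, refa, alta, imputed, probs, gts in rows:
        if not (plan.start <= pos <= plan.end):
            continue
        n_written += 1
        p1 = probs[0::2]
        p2 = probs[1::2]
        ds, gp = to_diploid(p1, p2)
        if gts is None:
            g1 = (p1 > 0.5).astype(int)
            g2 = (p2 > 0.5).astype(int)
        else:
            g1, g2 = gts[0::2], gts[1::2]
        fields = [
            f"{g1[i]}|{g2[i]}:{ds[i]:.3f}:{gp[i, 0]:.3f},{gp[i, 1]:.3f},{gp[i, 2]:.3f}"
            for i in range(len(ds))
        ]
        info = "IMP" if imputed else "TYPED"
        lines.append(
            f"{plan.chrom}\t{pos}\t.\t{refa}\t{alta}\t.\tPASS\t{info}\tGT:DS:GP\t"
            + "\t".join(fields)
        )
    text = "\n".join(lines) + "\n"
    out_path = str(out_path)
    if out_path.endswith(".gz"):
        import pysam

        with pysam.BGZFile(out_path, "w") as fh:
            fh.write(text.encode())
    else:
        with open(out_path, "w") as fh:
            fh.write(text)
    return n_written


def run_simulated_experiment(
    cfg: SimConfig,
    sel_cfg: SelectionConfig | None = None,
    params: HmmParameters | None = None,
    with_switch_errors: bool = False,
) -> dict:
    """Simulate a study, impute it, and score accuracy by MAF bin.

    Returns the accuracy table plus diagnostics (mean selected states,
    realized switch-error rate).  This is the quantitative-benchmark
    driver: chip-masked targets imputed back from the same simulation's
    reference panel, scored as r^2 against the masked truth.
    """
    sel_cfg = sel_cfg or SelectionConfig(interval_cm=0.002)
    study = simulate_study(cfg)
    target_typed = study.target_typed_truth
    realized_switch = 0.0
    if with_switch_errors:
        tpanel = panels.HaplotypePanel(
            target_typed, study.typed_markers.copy(),
            [f"T{i}_{h}" for i in range(cfg.n_target) for h in (1, 2)],
        )
        tpanel, realized_switch = inject_switch_errors(
            tpanel, cfg.switch_error_rate, cfg.seed + 4
        )
        target_typed = tpanel.alleles
    result = impute_panels(
        study.ref_typed,
        study.typed_markers,
        study.untyped_store,
        target_typed,
        sel_cfg=sel_cfg,
        params=params,
    )
    table = score_r2_by_maf(
        study.target_untyped_truth.astype(float),
        result.dosage_untyped,
        study.ref_maf_untyped,
    )
    return {
        "accuracy": table,
        "truth_untyped": study.target_untyped_truth,
        "dosage_untyped": result.dosage_untyped,
        "ref_maf_untyped": study.ref_maf_untyped,
        "mean_selected_states": result.mean_states,
        "realized_switch_rate": realized_switch,
        "n_typed": study.ref_typed.shape[1],
        "n_untyped": study.untyped_store.n_markers,
    }
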