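import numpy as np
import pytest

from pbwtimpute.panels import HaplotypePanel, make_marker_table


def make_panel(alleles, pos=None, chrom="1", cm=None, sample_ids=None):
    """Build a small panel from a raw 0/1 matrix."""
    alleles = np.asarray(alleles, dtype=np.uint8)
    m = alleles.shape[1]
    if pos is None:
        pos = np.arange(1, m + 1) * 100
    if cm is None:
        cm = (np.asarray(pos) - pos[0]) * 1e-6
    markers = make_marker_table(chrom, pos, ["A"] * m, ["C"] * m, cm)
    return HaplotypePanel(alleles, markers, sample_ids or [])


def write_vcf_text(path, records, samples=("S0", "S1"), chrom="1"):
    """Write a minimal phased VCF; records are (pos, ref, alt, gt_fields)."""
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={chrom}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    for pos, ref, alt, gts in records:
        lines.append(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t" + "\t".join(gts))
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def mosaic_panel():
    """LD-structured panel shared by PBWT/selection statistical tests."""
    from pbwtimpute.simulate import simulate_mosaic_panel

    return simulate_mosaic_panel(64, 160, seed=3)
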