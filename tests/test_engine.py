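import numpy as np
import pytest
from click.testing import CliRunner

from pbwtimpute.cli import main as cli_main
from pbwtimpute.engine import WindowPlan, impute_window
from pbwtimpute.panels import PanelError, write_vcf_panel
from pbwtimpute.selection import SelectionConfig
from pbwtimpute.simulate import SimConfig, mask_to_chip, simulate_panels


@pytest.fixture(scope="module")
def study_files(tmp_path_factory):
    """Reference/target VCFs for a small simulated window."""
    d = tmp_path_factory.mktemp("win")
    cfg = SimConfig(
        region_bp=400_000, n_reference=150, n_target=6,
        chip_spacing_bp=8_000, seed=21,
    )
    ref, tgt_truth = simulate_panels(cfg)
    observed, typed_idx, untyped_idx = mask_to_chip(tgt_truth, ref.maf(), cfg)
    ref_path = d / "ref.vcf"
    tgt_path = d / "tgt.vcf"
    write_vcf_panel(ref, ref_path)
    write_vcf_panel(observed, tgt_path)
    return {
        "dir": d, "ref": ref_path, "tgt": tgt_path,
        "ref_panel": ref, "chrom": ref.chrom,
        "span": (int(ref.positions[0]), int(ref.positions[-1])),
    }


def _markers_of(vcf_path):
    out = []
    for line in open(vcf_path):
        if line.startswith("#"):
            continue
        f = line.split("\t", 3)
        out.append(int(f[1]))
    return out


class TestWindowPlan:
    def test_parse_and_buffer(self):
        p = WindowPlan.parse("7:1000-2000", buffer_bp=500)
        assert (p.chrom, p.start, p.end) == ("7", 1000, 2000)
        assert p.effective_start == 500
        assert p.effective_end == 2500

    def test_effective_start_clipped_to_one(self):
        assert WindowPlan("1", 100, 900).effective_start == 1

    @pytest.mark.parametrize("bad", ["chr1", "1:50", "1:9-1"])
    def test_bad_region_strings(self, bad):
        with pytest.raises(ValueError):
            WindowPlan.parse(bad)


class TestImputeWindow:
    def test_windows_concatenate_to_whole_region(self, study_files, tmp_path):
        lo, hi = study_files["span"]
        mid = (lo + hi) // 2
        whole = tmp_path / "whole.vcf"
        impute_window(
            study_files["ref"], study_files["tgt"],
            WindowPlan(study_files["chrom"], lo, hi, 0), whole,
        )
        parts = []
        for i, (a, b) in enumerate([(lo, mid), (mid + 1, hi)]):
            out = tmp_path / f"part{i}.vcf"
            impute_window(
                study_files["ref"], study_files["tgt"],
                WindowPlan(study_files["chrom"], a, b, 100_000), out,
            )
            parts.extend(_markers_of(out))
        assert parts == _markers_of(whole)

    def test_byte_identical_across_runs(self, study_files, tmp_path):
        lo, hi = study_files["span"]
        plan = WindowPlan(study_files["chrom"], lo, lo + 150_000, 50_000)
        out1, out2 = tmp_path / "a.vcf", tmp_path / "b.vcf"
        for out in (out1, out2):
            impute_window(study_files["ref"], study_files["tgt"], plan, out)
        assert out1.read_bytes() == out2.read_bytes()

    def test_buffer_makes_core_dosages_match_whole_run(self, study_files, tmp_path):
        lo, hi = study_files["span"]
        core = (lo + 150_000, lo + 250_000)
        whole = tmp_path / "whole.vcf"
        impute_window(
            study_files["ref"], study_files["tgt"],
            WindowPlan(study_files["chrom"], lo, hi, 0), whole,
        )
        win = tmp_path / "win.vcf"
        impute_window(
            study_files["ref"], study_files["tgt"],
            WindowPlan(study_files["chrom"], core[0], core[1], 150_000), win,
        )

        def dosages(path, sel):
            out = {}
            for line in open(path):
                if line.startswith("#"):
                    continue
                f = line.rstrip("\n").split("\t")
                pos = int(f[1])
                if sel[0] <= pos <= sel[1]:
                    out[pos] = [x.split(":")[1] for x in f[9:]]
            return out

        dw = dosages(whole, core)
        dv = dosages(win, core)
        assert dw.keys() == dv.keys()
        diffs = [
            abs(float(a) - float(b))
            for p in dw
            for a, b in zip(dw[p], dv[p])
        ]
        assert max(diffs) < 1e-3

    def test_lazy_on_off_identical_output(self, study_files, tmp_path):
        lo, hi = study_files["span"]
        plan = WindowPlan(study_files["chrom"], lo, hi, 0)
        on, off = tmp_path / "on.vcf", tmp_path / "off.vcf"
        impute_window(study_files["ref"], study_files["tgt"], plan, on, lazy=True)
        impute_window(study_files["ref"], study_files["tgt"], plan, off, lazy=False)
        assert on.read_bytes() == off.read_bytes()

    def test_imp5_reference_gives_same_output(self, study_files, tmp_path):
        from pbwtimpute.imp5 import write_imp5

        lo, hi = study_files["span"]
        plan = WindowPlan(study_files["chrom"], lo, lo + 200_000, 0)
        imp5_path = tmp_path / "ref.imp5"
        write_imp5(study_files["ref_panel"], imp5_path)
        out_vcf = tmp_path / "from_vcf.vcf"
        out_imp5 = tmp_path / "from_imp5.vcf"
        impute_window(study_files["ref"], study_files["tgt"], plan, out_vcf)
        impute_window(imp5_path, study_files["tgt"], plan, out_imp5)
        assert out_vcf.read_bytes() == out_imp5.read_bytes()

    def test_region_without_typed_markers_is_error(self, study_files, tmp_path):
        lo, hi = study_files["span"]
        with pytest.raises(PanelError):
            impute_window(
                study_files["ref"], study_files["tgt"],
                WindowPlan("2", lo, hi, 0), tmp_path / "x.vcf",
            )

    def test_typed_markers_echo_observed_genotypes(self, study_files, tmp_path):
        lo, hi = study_files["span"]
        out = tmp_path / "o.vcf"
        impute_window(
            study_files["ref"], study_files["tgt"],
            WindowPlan(study_files["chrom"], lo, hi, 0), out,
        )
        tgt_gts = {}
        for line in open(study_files["tgt"]):
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            tgt_gts[int(f[1])] = [x.split(":")[0] for x in f[9:]]
        n_typed = n_imp = 0
        for line in open(out):
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            pos, info = int(f[1]), f[7]
            gts = [x.split(":")[0] for x in f[9:]]
            if info == "TYPED":
                n_typed += 1
                assert gts == tgt_gts[pos]
            else:
                assert info == "IMP"
                n_imp += 1
        assert n_typed > 0 and n_imp > 0


class TestCli:
    def test_impute_and_score_round(self, study_files, tmp_path):
        runner = CliRunner()
        lo, hi = study_files["span"]
        out = tmp_path / "imputed.vcf"
        r = runner.invoke(
            cli_main,
            ["impute", "--h", str(study_files["ref"]), "--g", str(study_files["tgt"]),
             "--r", f"{study_files['chrom']}:{lo}-{hi}", "--o", str(out),
             "--pbwt-depth", "4", "--pbwt-cm", "0.002", "--selection", "neighbour"],
        )
        assert r.exit_code == 0, r.output
        assert out.exists()

    def test_convert_round_trip(self, study_files, tmp_path):
        runner = CliRunner()
        imp5 = tmp_path / "ref.imp5"
        back = tmp_path / "back.vcf"
        assert runner.invoke(
            cli_main, ["convert", str(study_files["ref"]), str(imp5)]
        ).exit_code == 0
        assert runner.invoke(
            cli_main, ["convert", str(imp5), str(back)]
        ).exit_code == 0
        from pbwtimpute.panels import read_vcf_panel

        a = read_vcf_panel(study_files["ref"])
        b = read_vcf_panel(back)
        assert np.array_equal(a.alleles, b.alleles)

    def test_simulate_subcommand(self, tmp_path):
        runner = CliRunner()
        r = runner.invoke(
            cli_main,
            ["simulate", "--region-bp", "120000", "--n-reference", "40",
             "--n-target", "4", "--chip-spacing-bp", "20000",
             "--seed", "3", "--out-prefix", str(tmp_path / "sim")],
        )
        assert r.exit_code == 0, r.output
        assert (tmp_path / "sim.reference.vcf").exists()
        assert (tmp_path / "sim.targets.vcf").exists()

    def test_score_on_perfect_dosages(self, tmp_path, rng):
        """Scoring an output whose probabilities equal the truth yields
        an all-ones table in populated bins."""
        from pbwtimpute.simulate import score_r2_by_maf

        truth = rng.integers(0, 2, (40, 6)).astype(float)
        maf = rng.uniform(0.01, 0.5, 40)
        tab = score_r2_by_maf(truth, truth, maf).table
        assert np.allclose(tab[tab.n_markers > 0]["r2"], 1.0)

    def test_unknown_region_flag_errors(self, study_files, tmp_path):
        runner = CliRunner()
        r = runner.invoke(
            cli_main,
            ["impute", "--h", str(study_files["ref"]), "--g", str(study_files["tgt"]),
             "--r", "nonsense", "--o", str(tmp_path / "x.vcf")],
        )
        assert r.exit_code != 0
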