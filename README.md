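# pbwtimpute

PBWT-accelerated haploid genotype imputation: impute the markers a
study cohort was never genotyped at from a large phased reference
panel, scaling to big panels by conditioning each study haplotype on a
small, locally chosen subset of reference haplotypes.

**Who it is for.** Statistical-genetics pipelines that have pre-phased
chip data (a few hundred thousand typed markers) and a sequenced
reference panel (millions of markers) and want per-marker posterior
allele probabilities for downstream GWAS or scoring.

## Method in brief

Each target haplotype *t* is modelled as an imperfect mosaic of
reference haplotypes (the haploid Li & Stephens model). With copying
labels *Z_m* over a state set of reference haplotypes,

- switches: Pr(Z_{m+1}=i | Z_m=j) = (1−ρ_m)·1[i=j] + ρ_m/S, with
  ρ_m = 1 − exp(−4·Ne·g_m/N), g_m the genetic gap in Morgans and N the
  reference panel size;
- emissions: Pr(t_m = a | Z_m = n) = 0.9999 if the copied haplotype
  carries *a*, else 0.0001.

Posterior copying probabilities at typed markers come from a
forward–backward pass; at untyped markers they are linearly
interpolated in genetic distance and summed over the states carrying
the alternate allele.

The state set is chosen with the positional Burrows–Wheeler transform
(PBWT): sweeping the typed markers once, each target is tracked in the
reference's reverse-prefix order with an O(1) FM-index update per
marker, and every ~0.02 cM the *L* (default 4) reference haplotypes
adjacent to the target's insertion point — its locally longest
reverse-prefix matches — are added to its copying list. Selection cost
per target is independent of panel size, and the merged lists shrink
as panels grow, which is what makes the method scale sub-linearly.

Reference panels can be stored in an indexed binary container
(`.imp5`, see `docs/imp5lite_format.md`): rare markers as carrier-index
lists, common markers as bitsets, with random region access. Rare
untyped markers whose carriers miss every stored state are emitted as
monomorphic without any interpolation work ("delayed lazy
imputation"), which is exact, not approximate.

See `docs/methods.md` for assumptions, parameters, and limitations.

## Worked example

Simulate a 500 kb study (400 reference / 10 target samples, one chip
marker per 5 kb), impute, and score:

```
$ pbwtimpute simulate --region-bp 500000 --n-reference 400 --n-target 10 \
      --chip-spacing-bp 5000 --seed 11 --out-prefix demo
{"n_markers": 2164, "n_typed": 100, "n_untyped": 2064, "realized_switch_rate": 0.0, "seed": 11}

$ pbwtimpute impute --h demo.reference.vcf --g demo.targets.vcf \
      --r 1:1-500000 --pbwt-cm 0.002 --o demo.imputed.vcf
{"n_reference_haplotypes": 800, "n_target_haplotypes": 20, "n_typed": 100,
 "n_untyped": 2064, "n_written": 2164, "mean_selected_states": 29.55, "seconds": 0.841}

$ pbwtimpute score --truth demo.truth.vcf --imputed demo.imputed.vcf \
      --reference demo.reference.vcf --out demo.accuracy.tsv
```

The impute step reports that each of the 20 target haplotypes
conditioned on ~30 reference haplotypes (out of 800) merged from its
selection events, and wrote all 2,164 reference markers with dosages:

```
1  7  .  A  C  .  PASS  IMP  GT:DS:GP  0|0:0.000:1.000,0.000,0.000 ...
```

`TYPED` records echo the observed genotypes with their model dosage;
`IMP` records are imputed. `DS` is the diploid dosage (sum of the two
haploid alternate-allele probabilities), `GP` the genotype
probabilities. The accuracy table pools (truth, probability) pairs per
reference-MAF bin:

```
bin_low  bin_high  n_markers  n_alleles  r2
0.005    0.01      158        3160       0.763147
0.01     0.02      179        3580       0.953695
0.05     0.1       242        4840       0.991739
0.2      0.5       393        7860       0.977061
```

r² rises with minor-allele frequency, and grows at every frequency as
the reference panel gets larger — the central accuracy behaviour of
panel-based imputation.

The same pipeline is available as a library (`pbwtimpute.impute_panels`
for in-memory panels, `pbwtimpute.impute_window` for files), and
`pbwtimpute convert` moves reference panels between VCF and `.imp5`.

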