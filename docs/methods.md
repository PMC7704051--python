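# Methods

## Problem and model

Genotype imputation predicts the alleles a study ("target") haplotype
carries at markers typed only in a reference panel. Both panels are
assumed phased with no missing alleles. Each target haplotype is
modelled as an imperfect mosaic of reference haplotypes — the haploid
Li & Stephens copying model — and untyped alleles are read off the
posterior distribution over which reference haplotype is being copied.

The pipeline has three stages per window:

1. **State selection (PBWT).** The reference panel, restricted to the
   typed markers, is swept left to right building the positional
   Burrows-Wheeler transform: at marker *m* the haplotypes are ordered
   by their reverse prefix (alleles from *m* back to the window start).
   Each target is located in this order with an O(1) FM-index update
   per marker, independent of panel size. At *selection markers*
   (every `I` cM, default 0.02; 0.002 recommended and used for
   simulated constant-rate maps) the `L` reference haplotypes nearest
   the target's insertion slot are harvested — either plain neighbours
   (ceil(L/2) above, floor(L/2) below; fewer near the ends of the
   array) or by divergence-guided two-pointer expansion that always
   takes the side with the older running match start. Events are
   unioned into one copying-state list per target for the window.
2. **HMM at typed markers.** A forward-backward pass over the selected
   states with uniform initialisation, emission 0.9999/0.0001 for
   match/mismatch, and per-interval switch probability
   `rho = max(min_rho, 1 - exp(-4 Ne g / N))`, `g` the genetic gap in
   Morgans. Rescaled per marker; posteriors normalized per marker.
3. **Imputation at untyped markers.** State posteriors are thresholded
   at 1/S (S = state-list size): a state is stored across a
   typed-marker interval if it exceeds the threshold at either flank.
   Stored flank posteriors are renormalized, interpolated linearly in
   genetic distance, and summed over the states carrying the alternate
   allele. Untyped markers outside the typed span use the nearest
   typed marker's posteriors. Rare markers (alternate frequency
   < 1/256, i.e. exactly the sparse-encoded records of the reference
   container) first check whether any stored flank state carries the
   alternate allele; if none does the marker is emitted with
   probability exactly 0 and no interpolation ("delayed lazy
   imputation") — bit-identical to the full computation, since
   unstored states carry zero renormalized mass.

## The switch-rate denominator

The classical copying model over N haplotypes uses switch intensity
`4 Ne g / N`: the more haplotypes, the longer the shared segments, the
less switching. When the HMM runs on a PBWT-selected *subset* of S
states there are two candidate denominators. This package uses the
**full reference panel size**, not S: the subset is a computational
restriction of the full-panel model, and the restricted chain should
keep the full model's switch intensity (the uniform `rho/S` landing
mixture still runs over the subset). The subset-size alternative was
implemented and measured during development and behaves pathologically
at desk scale: because selected lists shrink as panels grow, it makes
the switch rate *rise* with panel size and MAF-bin accuracy *fall* with
a 10x larger reference panel — the opposite of both coalescent
intuition and the well-established empirical behaviour of this model
family. `forward_backward` exposes the denominator (`n_panel`) so the
self-contained S-state model remains available; with all states
selected the two coincide, which is how the dense-oracle equivalence
tests pin correctness.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `L` | 4 | states harvested per selection event; accuracy saturates near 4 |
| `I` | 0.02 cM | selection interval (0.002 for simulated maps) |
| `Ne` | 20,000 | effective diploid population size in the switch rate (conventional human value) |
| emission | 0.9999 / 0.0001 | match / mismatch probability, absorbing mutation and genotype error |
| `min_rho` | 1e-9 | switch-probability floor so co-sited markers never freeze the chain |
| buffer | 1 Mb | flank added to each window so posteriors are conditioned near core edges |
| rarity bound | 1/256 | alt-frequency threshold shared by the sparse file encoding and the lazy-imputation test |

Mismatch guard (neighbour selection, on by default): after the
counting sort the prefix array splits into a 0-block and a 1-block at
the current marker, so on each side of the target's slot the
mismatching neighbours are exactly those beyond its own allele block.
The guard skips them and extends the matching side instead (never
discarding a longer match); quota the matching block cannot absorb
falls back to the nearest mismatching neighbours so border behaviour
(`L >= 2N` returns the whole panel; fewer states near array ends) is
preserved.

## Numerical choices

* Rank convention is inclusive (`rank(b, n)` counts positions 0..n), so
  `rank(0,n) + rank(1,n) = n + 1` holds exactly; insertion slots use
  exclusive prefix counts of the same array.
* Divergence arrays follow the canonical one-pass construction
  (running maxima per symbol class, vectorized with segmented
  `maximum.reduceat`); the sentinel at rank 0 is `m + 1`.
* Forward-backward uses per-marker rescaling, not log space; the test
  suite compares it to an extended-precision unscaled dense
  implementation to 1e-10.
* If thresholding would empty a marker's stored set (an exact tie at
  1/S, e.g. identical states), the whole row is kept.
* Interpolated dosages are clamped to [0, 1]; weights use genetic
  distance, falling back to weight 0 across zero-cM intervals.
* Allele matching between panels is exact string equality on
  (chrom, pos, ref, alt); no strand flipping (silent flipping is a
  correctness hazard), mismatches are dropped with a logged count.
* Without a genetic map, a constant 1 cM/Mb rate (the human average)
  is applied from the window start and logged.

## Synthetic data

`simulate_study` draws a coalescent sample with msprime under a
single-population exponential expansion (ancestral diploid size 10,000
growing at 5%/generation to 1,000,000, mutation rate 1.25e-8,
recombination 1e-8 = 1 cM/Mb), which gives the strongly rare-skewed
site-frequency spectrum of large sequenced human cohorts. Targets are
drawn from the same simulation and removed from the reference;
reference-monomorphic sites are dropped; chip sites are a uniform
random subset (default one per 3 kb) of markers with reference
MAF > 5%; optional switch errors swap the remainder of a sample's two
haplotypes at heterozygous typed sites with probability 2%. The
default study conditions are a 2 Mb region with 10,000 reference and
100 target samples — a desk-scale version of the published benchmark
design (10 Mb, 3,333 chip markers, panels of 10K-1M samples).

What the generator does *not* emulate: genotyping error on chip sites,
strand/allele-coding ambiguity, population structure and admixture,
variable recombination maps, and real-chip site ascertainment. Passing
tests therefore demonstrate correctness of the machinery and the
model's behaviour under clean, well-specified conditions, not
performance on real cohort data.

A mosaic fallback generator (`simulate_mosaic_panel`, sequential
copying from previously generated haplotypes with private mutations)
provides LD-structured panels without coalescent machinery; it
reproduces the haplotype-sharing structure the PBWT exploits but
carries no mutation ages, so it is used for structural tests only.

## Evaluation

Accuracy is the squared Pearson correlation between true (masked)
alleles and imputed haploid probabilities, pooled over all
(marker, haplotype) pairs within reference-MAF bins. Bin edges are
log-spaced ({5e-5, 1e-4, 2e-4, 5e-4, ..., 0.2, 0.5}, left-open /
right-closed); "the MAF 1e-4 bin" in summaries means the pooled bin
(5e-5, 2e-4]. Bins with a constant vector are reported undefined.
Panel-size comparisons use nested references (the larger panel
downsampled with markers and targets fixed), which isolates panel size
from simulation noise; independent per-size simulations at desk scale
are noise-dominated in the shared bins.

## Problem sizes used by the test suite and acceptance script

The oracle suites run hundreds of random panels up to 64 x 200 and
HMM instances up to 16 states x 50 markers (exact / 1e-8 agreement).
Behavioural trends use a 1 Mb region with 5,000 reference samples
(nested 500-sample subset) and 40 targets. The quantitative benchmark
uses the default 2 Mb / 10,000-sample / 100-target study; at those
conditions the MAF-1e-4-bin r^2 is ~0.31 (seed 1). This sits below the
~0.4 of the full 10 Mb design because rare-variant accuracy grows with
window span — a longer window harvests a rare carrier's haplotype at
more selection events (a 10 Mb run recovers ~0.53); the per-seed spread
of the scaled benchmark is also substantial (~±0.1 and more), since the
bin holds only AC 2-4 variants with a handful of target carriers.

## Known limitations

* Haploid model only: target phase is taken as given, and diploid
  output (DS/GP) assumes independence of a sample's two haplotypes.
* Biallelic markers only; multiallelic records are skipped, not split.
* No estimation of recombination or error parameters from data; the
  genetic map and `Ne` are inputs.
* Parallelism is by independent window invocations (the windows
  concatenate exactly); there is no in-process threading.
* The file-based window pipeline uses the streaming per-record dosage
  path; the in-memory experiment API uses a vectorized kernel that
  agrees to numerical round-off but is not byte-reproducible against
  the streamed path (summation order differs).
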