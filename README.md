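# clarecomb

Population-genomic analysis of how a species-specific transposable element
relates to the recombination landscape and haplotype-block structure of
*Chironomus riparius* populations.

The non-biting midge *C. riparius* carries the *Cla*-element, a
minisatellite-like TE (120 bp consensus unit) that occurs as monomeric
repeats and as tandem-repetitive clusters, with many population-specific
insertions. A central question is whether such TEs accumulate in regions
of low recombination (insertion bias plus selection against ectopic
recombination), or whether TE activity itself reshapes the local
recombination landscape. `clarecomb` implements the statistical pipeline
for asking that question from three data layers:

* **phased diploid genotypes** (VCF) from several populations,
* **per-individual recombination maps** — piecewise-constant
  population-scaled recombination rates ρ, as produced by SMC-based
  inference, delivered as chrom/start/end/ρ tracks,
* **TE insertion cluster intervals** (BED) per population.

It is aimed at population geneticists working on non-model systems who
have these tracks and want the complete battery of downstream statistics
with a tested, seedable implementation.

## What it computes

* **Haplotype blocks** — the confidence-interval (Gabriel) method on the
  normalized gametic disequilibrium D′ = |D|/D_max. For each SNP pair the
  multinomial likelihood of the gamete counts is evaluated on a D′ grid,
  giving a 90% CI [c_L, c_U]; a pair is *strong LD* if c_L ≥ 0.65 and
  c_U ≥ 0.97, *strong recombination* if c_U < 0.90. A block is a SNP run
  whose outermost pair is strong LD and in which strong-LD pairs make up
  ≥ 90% of informative pairs (PLINK `--blocks` parameterization, with
  MAF ≥ 0.10 and missingness ≤ 0.05 site filters and a ≥ 50 bp block
  length filter).
* **Recombination windows** — coverage-weighted mean ρ in complete fixed
  windows (1 kb / 10 kb / 100 kb / 1 Mb), per-chromosome and
  per-population mean/median/±SE summary tables, and hotspot windows
  (ρ > chromosome mean + 2·SD for at least one individual).
* **Distance decay** — Pearson (TE clusters, split at 500 bp into size
  classes) and Spearman (haplotype blocks) correlation of window ρ with
  the gap to the nearest feature, per chromosome arm / centromere part,
  with bootstrap envelopes of the binned mean curve.
* **Inside/outside statistics** — overlap classification of clusters
  against blocks, the exact binomial test, Wilcoxon rank-sum
  comparisons, and a constrained region-permutation test: each
  permutation re-places every cluster uniformly on its own chromosome,
  preserving lengths and forbidding mutual overlap, and the overlap
  statistic is recomputed against the fixed blocks
  (p = (k+1)/(n_perm+1), with a z-score against the permuted mean).
* **Sharing classes** — clusters present in one population (*unique*),
  several (*shared*), or all, tallied by genomic compartment
  (centromere ± flanks, arms, short chromosomes analysed whole,
  unplaced scaffolds).

A synthetic-data generator (`clarecomb.synthdata`) emulates all three
data layers with known ground truth — centromere-depressed ρ landscapes
with hotspot spikes, block-structured phased haplotypes from an
ancestral-haplotype-pool model, and population-structured TE insertions
with configurable placement bias — so every stage is testable without
sequencing data.

## Worked example

Run the whole pipeline on a synthetic dataset mirroring the emulated
study design (5 populations × 4 diploid individuals, 4 chromosomes with
centromeres, 441 ancestral insertion loci of which 14 are shared by all
populations and 139 by several):

```python
from pathlib import Path
from clarecomb import PipelineConfig, SimConfig, run_pipeline

cfg = PipelineConfig(
    output_dir=Path("demo"),
    sim=SimConfig(seed=1),
    n_perm=1000, perm_seed=1,
    whole_chromosomes=("chr4",),   # no arm split for the short chromosome
)
report = run_pipeline(cfg)
print(report["stages"]["sharing"]["percentages"])
print(report["stages"]["overlap"]["permutation"]["z_score"])
```

With seed 1 this prints (numbers produced by the code above):

```
{'shared_all': 3.2, 'shared_partial': 31.5, 'unique': 65.3, 'shared_any': 34.7}
1.2774268392574126
```

and reports 523 detected haplotype blocks (510 after the 50 bp filter),
290 ten-kb ρ windows with 17 hotspot windows, and 332 of 441 clusters
overlapping blocks. The sharing percentages recover the configured
generator fractions exactly. Note that the haplotype-pool LD model makes
detected blocks *dense* (≈ 68% of the synthetic genome), so most
clusters fall inside blocks here — the opposite of sparse-block real
data, where the same machinery reports the outside excess; the
permutation z-score above is correspondingly small, as uniform placement
should give. The same stages are available as shell commands
(`clarecomb simulate | blocks | windows | hotspots | decay |
overlap-test | sharing | run-all`).

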