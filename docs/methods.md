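# Methods

This note documents the models, conventions and numerical choices behind
`clarecomb`, in the spirit of the methods documentation of statistical
genetics packages.

## Coordinates and interval arithmetic

All intervals are 0-based half-open (BED convention); VCF positions are
converted at the I/O boundary. Nearest-feature distances follow the
bedtools-closest workflow: the distance is 0 when two intervals share at
least one bp, otherwise the number of bp strictly between the nearest
edges, computed in half-open arithmetic. Under this convention
book-ended intervals (query end == feature start) are at distance 0,
whereas bedtools `-d` reports 1 for that single configuration; the decay
analyses are invariant to this constant offset, and the half-open rule
keeps every distance consistent with the overlap predicate. Ties between
equidistant features are broken toward the feature with the smaller
start (then smaller end) so results are deterministic. Windows tile each
chromosome from 0 in fixed widths and only complete windows are kept;
the trailing remainder is dropped.

## Haplotype blocks (confidence-interval method)

Site filters retain biallelic SNPs with minor allele frequency ≥ 0.10
and per-site missingness ≤ 0.05 (the PLINK `--maf/--geno` step). For a
pair of sites the four gamete frequencies are obtained by direct
counting when both genotypes are phased; for unphased data only the
double heterozygote is phase-ambiguous and its cis/trans resolution is
apportioned by EM from an equal-split initialisation (tolerance 1e-10,
≤ 1000 iterations). The equal split makes the symmetric fixed point of a
pure double-heterozygote sample reproducible. On fully phased data the
EM path reduces to exact counting (this identity is asserted in the
tests at machine precision).

The D′ confidence interval follows the Haploview convention: alleles are
oriented so D ≥ 0, the multinomial log-likelihood of the gamete counts
is evaluated on a D′ grid of step 0.001, normalised to a unit mass, and
the 90% interval is read off at cumulative mass 0.05 and 0.95. Pairs are
*strong LD* when ci_low ≥ 0.65 and ci_high ≥ 0.97, *strong
recombination* when ci_high < 0.90, otherwise uninformative; monomorphic
pairs are uninformative with an explicit undefined flag. Note that with
very few chromosomes the equal-counts configuration (D′ = 0) still
yields ci_high < 0.9 — small-sample pairs are not automatically
uninformative; the wide-CI regime arises for small samples with
positive D′.

Blocks are assembled PLINK-style: a candidate is a consecutive SNP run
whose outermost pair is strong LD and whose span is ≤ `max_kb`
(default 1000); it is accepted when strong-LD pairs are ≥ 90% of the
informative (strong LD + strong recombination) pairs in the span —
uninformative pairs are excluded from the denominator. Overlapping
candidates are resolved greedily, longest bp span first, ties to the
leftmost. `no_small_max_span` (default on, matching the emulated
parameterization) disables the Haploview-style extra caps of 20 kb
(2-SNP) and 30 kb (3–4-SNP) candidates. Block length is BP2 − BP1 (the
outermost SNP positions, half-open), and the census filter keeps blocks
≥ 50 bp. Exact PLINK bit-compatibility is not promised; the `.det`
output schema (CHR, BP1, BP2, KB, NSNPS, SNPS) is matched so downstream
tooling is drop-in.

Pair classification depends on the data only through the gamete counts,
so classifications are memoised on the count tuple; for n haplotypes
there are O(n³) distinct tuples, which turns the all-pairs scan from
millions of likelihood-grid evaluations into a few thousand.

## Recombination windows, summaries, hotspots

A window's value for one individual is the coverage-weighted mean of the
piecewise-constant ρ segments inside it; segments straddling a border
contribute only their in-window bp, and windows with zero covered bp are
missing (excluded from N, not zero-filled). Summary tables report mean,
median and mean ± SE over all (window × individual) values in scope,
with SE = sample SD/√N (n−1 denominator, the convention of the R tools
this emulates). Hotspots are computed per individual — windows with
ρ > that individual's chromosome mean + 2·SD — and the reported set is
the union across individuals. Both mean and SD scale linearly with the
track, so hotspot calls are invariant under rescaling an individual's
map.

## Distance decay

Correlations are computed on raw (distance, ρ) pairs, unbinned: the
published workflow correlates window ρ with the bedtools-closest
distance, and any binning choice would be an extra free parameter.
Binning (20 equal-count distance bins by default) is used only for the
bootstrap visualisation, in which each of 100 replicates resamples the
pairs with replacement at the original n and re-averages ρ per bin. TE
decay uses 100 kb windows and splits clusters at 500 bp; haplotype-block
decay uses 1 kb windows and Spearman rank correlation. Per-population
decay pairs the population's own insertion track with the population
mean ρ per window (individuals averaged before pairing). Stars follow
the usual convention (* < 0.05, ** < 0.01, *** < 0.001).

## Overlap and permutation statistics

A cluster is *inside* when it shares ≥ 1 bp with any block; half-open
abutment is outside. The exact binomial test defaults to p₀ = 0.5
(configurable), and two Wilcoxon rank-sum comparisons are exposed:
cluster size inside vs outside blocks, and block length with vs without
clusters — the two concrete readings of the ambiguous published pairing.
The rank-sum test uses the exact null for ≤ 50 tie-free observations and
the tie-corrected normal approximation otherwise.

The permutation test re-places every query uniformly at random on its
original chromosome (integer start positions in [0, L − len]),
preserving its length, rejecting and redrawing placements that overlap
an already-placed permuted query (budget 10 000 attempts per element,
then an infeasibility error naming the chromosome). Permuted queries may
overlap the fixed references — forbidding that would make the statistic
degenerate. The p-value uses the add-one rule (k+1)/(n_perm+1), so it is
never 0 and never below 1/(n_perm+1); the z-score is
(observed − permuted mean)/permuted SD, undefined (NaN, flagged) when
the permuted SD is 0. `alternative` can fix a tail, request a two-sided
p (2·min(tails), capped at 1), or pick the tail of the observed
deviation (`auto`, the default reporting mode). By default only the
queries are randomized against fixed references, the reading consistent
with reporting a permuted mean of elements outside blocks.

## Synthetic data

The generator defines the study conditions for all calibration and
recovery experiments. Defaults mirror the emulated design: 5 populations
× 4 diploid individuals; 4 chromosomes with centromere ranges; 441
ancestral TE insertion loci with 14 shared by all populations, 139
shared by several (each in a uniform subset of 2–4 populations) and 288
unique; TE lengths from a lognormal law (meanlog 5.5, sdlog 0.6 — free
parameters chosen to give a mean near 300 bp, not estimates) truncated
to the observed 73–1802 bp range. Chromosome lengths default to a
desk-scale genome (1.0/0.9/0.7/0.3 Mb); the real assembly is two orders
of magnitude larger, and all rate parameters are per-bp so the scaling
changes only the number of windows and SNPs.

ρ maps: the expected profile is baseline 0.0127 (the 10 kb global mean
scale of the emulated system) times a smooth (cosine-ramp) multiplicative
centromere depression to 0.1× over the centromere ± a 10%-of-chromosome
flank, times a telomeric elevation to 2× at chromosome ends; hotspot
spikes arrive as a Poisson process (5/Mb, 2 kb wide, 10×) on the shared
profile, and each individual multiplies the shared profile by
independent per-segment gamma noise with unit mean (shape 10, ≈ 32% CV).
At the centromere midpoint the noiseless profile equals baseline ×
centromere factor exactly, which the tests use as a closed form.

Haplotypes: LD is induced by an ancestral-haplotype-pool model rather
than a coalescent simulation — the genome is partitioned into latent
blocks with exponential lengths (mean 10 kb), each haploid genome copies
one of K = 4 (default) pool haplotypes per block with Dirichlet-drawn
frequencies, independently across blocks. This gives direct control over
true block boundaries at negligible cost; with K = 2 every polymorphic
intra-block pair has |D′| = 1. What it does *not* emulate: recombination
within blocks, mutation, relatedness structure, or realistic site
frequency spectra — so passing tests demonstrate correctness of the
machinery, not calibration on real LD decay. Note also that detected
blocks are dense under this model (most of the genome), unlike the
sparse block coverage typical of real data.

Insertions: sharing classes are assigned to ancestral loci first
(deterministic counts round(fraction × total)), and populations inherit
coordinates exactly, mirroring how group-level insertion genotyping
names shared sites. Placement is uniform; or rho-coupled with density
∝ exp(−β·ρ(x)) (β default 200 — on a ρ range of ~0.001–0.05 this gives a
strong low-recombination bias; β is an artifact knob, not a biological
estimate); or block-avoiding, where a uniform draw overlapping a
reference block is rejected with probability q. Ancestral loci never
overlap one another. In end-to-end runs the avoided reference set is a
sparse subsample (10%) of latent blocks, because the full latent
partition tiles the genome and would make avoidance vacuous. Partial
sharing requires ≥ 3 populations (a partial subset must contain ≥ 2 and
exclude ≥ 1); the generator validates this.

Each generator draws from a fixed-offset child stream of the master
seed, so regenerating one layer never perturbs another and a fixed seed
reproduces every file byte for byte.

## Calibration and recovery experiments

The acceptance experiments run at desk scale, sizes chosen as the
package's own test conditions:

* *Permutation oracle*: a 4 bp toy chromosome where the overlap
  probability is exactly 0.5 by enumeration; the permuted mean must
  agree within 3 standard errors at 5000 permutations.
* *Type-I error*: 200 replicates of uniform TE placement (400 clusters,
  two chromosomes of 400/300 kb, ~90 reference blocks of 2 kb per
  chromosome, 500 permutations each), tested one-sided in the depletion
  direction — the direction the pipeline's question targets. The
  add-one permutation p on a tied integer statistic is conservative;
  the dense configuration keeps the statistic's spread large enough
  that the realised rate (~3%) sits inside the nominal 2–8% band.
* *Power*: with block-avoiding placement the depletion signal (z < 0,
  p < 0.05) must be detected in ≥ 90% of 20 replicates at q = 0.9, and
  the rejection rate must be non-decreasing over q ∈ {0, 0.5, 0.9}.
* *LD-block recovery*: with pool size 2 and 10 kb latent blocks, ≥ 80%
  of detected block bp must lie within a single latent block (latent
  blocks tile the genome, so the measure is the best-single-block
  containment, i.e. boundary crossing).
* *Decay recovery*: rho-coupled placement (β = 200) must yield a
  positive Pearson distance correlation in ≥ 90% of 20 replicates.
* *Conservation*: Σ(window mean × covered bp) equals Σ(segment ρ × bp)
  over complete windows to 1e-9 relative tolerance.

## Degenerate inputs and tie-breaks

Empty reference sets give a flagged degenerate permutation result
(z undefined, p = 1). A single summary value yields SE = 0 with a
warning. Zero-variance margins give flagged undefined correlations,
excluded from heatmaps as NA rows. Chromosomes without a centromere are
analysed whole. Merging population calls at tolerance 0 unifies only
genuine overlaps (abutting calls stay separate); the merge is
idempotent. Compartment assignment gives the centromere ± flank (default
5% of chromosome length per side; the flank width is a free parameter —
published tallies depend on it and are validated only against synthetic
ground truth) precedence over arms, and scaffolds absent from the layout
count as unplaced.

## Known limitations

* SMC-based inference of ρ maps is out of scope; maps are inputs.
* No coalescent realism in the haplotype model; block detection is
  validated against latent truth, not against an external phasing/LD
  toolchain.
* The binomial null p₀ = 0.5 treats inside/outside as a fair coin; the
  genome-fraction null is available via the `p0` argument.
* Wilcoxon pairing of the published comparison is ambiguous; both
  concrete variants are reported.
* No plotting: tables are emitted for external visualisation.
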