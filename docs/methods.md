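# Methods

## Domain model and caller

A chromosome of `n` fixed-size bins (default 5000 bp) carries a
symmetric contact-count matrix `C`. The caller scores a candidate
domain `[k, l]` (inclusive bin indices, length `d = l − k + 1` bins) by

```
q(k, l) = W(k, l) / d^γ − μ(d),        W(k, l) = Σ_{k ≤ i < j ≤ l} C[i, j]
```

with `μ(d)` the mean of `W/d^γ` over every start position at that
length on the same chromosome. The diagonal is excluded from `W` (self
contacts carry no interaction information), `d` is the bin count, and
the scaled-density exponent uses `d` directly. These conventions are
internal choices — published scaled-density callers differ in off-by-one
details — and are certified by an independent brute-force enumerator
(`tadvar.validation`): on random matrices the dynamic program's total
score equals the exhaustive optimum exactly.

The objective is the sum of `q` over a set of disjoint windows,
counting only windows with `q > 0`; bins in no window are inter-domain.
The DP runs over prefix ends with all candidate lengths vectorised
(`O(n · d_max)` time). Ties are broken toward fewer domains, then
toward the leftmost domain start, making output deterministic.

Parameters: `γ` (default 0.4) trades domain size against density —
larger values favour smaller, denser domains; `min_bins = 2` because a
single-bin window has an empty upper triangle; `max_bins` defaults to
the chromosome. Only the single-γ optimal segmentation is produced (no
multi-γ consensus, no near-optimal alternatives, no nesting).

**Recovery metric.** Caller benchmarks use domain-level F1: a true
domain counts as recovered when a called domain matches *both* its
edges within a tolerance (default ±1 bin); precision is the analogous
fraction over called domains. Per-edge any-match scoring was rejected
because on a 400-bin chromosome with ~66 true edges a random caller
already places ~half of its boundaries within ±1 bin of some true edge,
so it cannot distinguish signal from a structureless null; domain-level
matching scores the structural null near zero while exact recovery
scores 1.

## Interval conventions

All coordinates are 0-based half-open. BED is consumed natively, GFF3
shifted from 1-based closed, VCF positions shifted by −1. Merging joins
overlapping *and* adjacent intervals. Complements and the
exon/intron/intergenic partition conserve total genome length exactly
(integer arithmetic, asserted as invariants). Where gene models
overlap, exon takes precedence over intron and intron over intergenic.
Genes are assigned to TAD or inter-TAD by majority overlap, ties to the
first class listed. Strand is carried but ignored throughout.

## Two-group statistics

The statistical units are the individual TAD and inter-TAD intervals
(thousands of regions), not pooled compartments. Densities are events
per kb of region (or stratum-intersected region); signal comparisons
use length-weighted means; tests are two-tailed Wilcoxon rank-sum on
untransformed values — exact enumeration when the pooled sample is ≤ 20
without ties, otherwise the normal approximation with tie and
continuity corrections (scipy's `mannwhitneyu` is the engine; the exact
small-sample values are independently verified by enumeration in the
test suite). The C→T fraction is strand-literal (ref C → alt T) by
default; a flag collapses G→A onto it. MAF filtering takes `INFO/AF`
when present, else computes frequency from genotypes.

## Permutation enrichment

The observed statistic is the number of query intervals overlapping the
fixed set by ≥ 1 bp (base-pair overlap is available as an option and is
preferable when the query regions are themselves domain-sized — the
interval count then saturates). The null re-places each query interval
uniformly at random: a chromosome is drawn with probability
proportional to its number of valid start positions for that interval's
length, then a uniform valid start. Placements may overlap each other
(flag to forbid); an exclude set is honoured by rejection sampling.
Query intervals are deliberately *not* merged — the null re-places
exactly the intervals that were counted, which keeps the test calibrated
for dense query sets. `p = (#{null ⋄ obs} + 1)/(N + 1)` (never zero),
`z = (obs − mean)/sd`, `sd = 0` yields `z = NaN` with a valid p. The
reported significance threshold is the `(1 − α)` null quantile.

The empirical p is discrete (it inherits the ties of the overlap
count), hence slightly conservative; with a few hundred
variable-length query regions the count spreads over enough values
that the null p is indistinguishable from uniform (KS), which is the
regime the calibration checks use.

## Boundary relative abundance

Boundaries are the deduplicated domain edges (both edges by default;
orientation is not inferred). For offsets `o ∈ {−flank, …, flank − bin}`
the observed value is the mean over boundaries of the feature density
in `[pos + o, pos + o + bin)` — events per kb for point tracks, mean
signal for interval tracks. Boundaries whose full window leaves the
chromosome are dropped, keeping the per-offset sample size constant.
The expectation is a single scalar: the mean over R rounds (default
1000) of the average density of `n_boundaries` windows of width `bin`
re-distributed uniformly across the genome; the rounds' 2.5/97.5
percentiles give the null band. Relative abundance is observed over
expected, so it is invariant under global rescaling of the track.
Defaults: flank 20 kb (rice scale; ~500 kb suits mammal-scale domains),
bin 1 kb — fine enough to resolve kb-scale dips near boundaries.
A stratified mode (`restrict=`) computes both numerator and denominator
per bp of a given stratum (e.g. intergenic sequence), which is what
makes gene-density-driven artefacts vanish; windows without stratum
coverage drop out of the means.

## Binned correlation

The genome is tiled into fixed windows (default 40 kb); trailing
partial bins are kept with their true length (dropping them would bias
telomeric features). Point and interval features become counts
overlapping the bin per kb (an interval spanning two bins counts once
in each); signal tracks become length-weighted means, NaN where
uncovered. Correlation methods: Pearson on `log2(x + pseudo)` with
pseudo 0.1 (or the median of all cells), Pearson raw, Spearman raw
(= Pearson on ranks, asserted to 1e−12). Significance per cell from
`t = r·sqrt((n−2)/(1−r²))` with `n − 2` df, two-sided; the mask flags
`p < α` (default 0.05) with no multiple-testing correction (raw
per-cell masking is the convention this report follows; correction is
left to the caller). NaN bins are dropped pairwise; constant columns
give NaN with a warning.

## Synthetic data: what it emulates, and what it does not

The generator tiles one chromosome (default 2 Mb; analyses here use
10 Mb, power studies 90 Mb) with alternating TAD/inter-TAD segments,
log-normal with medians 35 kb and 25 kb (the size scale of rice domains
at 5 kb resolution) and σ = 0.25. Contacts are independent Poisson
draws with `λ = depth · |i−j|^−α`, doubled (enrichment 2.0) when both
bins sit in the same planted TAD; `α = 1` is a typical Hi-C decay,
depth 50 gives realistic counts at 5 kb. Point features are
class-homogeneous Poisson processes: SNPs 2.6/2.0 per kb (TAD/inter,
ratio 1.3), deletion breakpoints 0.65/0.5, insertion breakpoints
0.26/0.2, crossovers 0.05/kb base with TAD weight 2.0. SNP alleles are
C→T with probability 0.24 (TAD) / 0.23 (inter), other substitutions
uniform. Active marks are a base level plus Gaussian bumps (height 2.0,
sd 800 bp) at every boundary; methylation-like marks get a +0.5 class
offset inside TADs; both carry Gaussian noise (σ 0.1) and are clipped
at zero. The recombination track is the realised crossover count per
10 kb window in events/Mb — windows finer than the domain scale, so the
class contrast survives. Genes are placed left-to-right with
exponential gaps (mean 6 kb), log-normal lengths (medians 2 kb in TADs,
3 kb in inter-TADs), 1–5 exons, and log2-normal expression one unit
lower in TADs. Deletion records are planted at half the breakpoint
rate with 50–500 bp lengths so that start+end breakpoints realise the
configured rate.

Randomness is one named substream per track derived from the single
spec seed, so adding a track never perturbs another, and every output
(including the written VCF/GFF3/bedGraph files) is bit-reproducible.

What the generator does **not** emulate: sequence context (no FASTA, no
mutational signatures beyond the C→T label), linkage disequilibrium or
population structure, read-level Hi-C noise (coverage bias, so ICE
balancing is a no-op on simulated maps), hierarchical/nested domains,
chromosome-scale compartments, TE sequence evolution, and expression
measurement noise. Passing tests therefore certify the *statistical
machinery* — that each stage recovers exactly the effect planted at the
published parameter scales and stays calibrated under the null — not
that real rice data would yield any particular estimate.

## Numerical and design choices

- Matrices are dense per chromosome (desk-scale genomes); window sums
  via a 2-D integral image, O(1) per window.
- ICE balancing (optional, off by default: the caller consumes whatever
  normalisation it is given): iterative marginal equalisation to
  tolerance 1e−6, zero-marginal bins masked with bias 0, warning plus
  best iterate on non-convergence.
- DP score ties resolved (fewer domains, then leftmost start) with
  exact float comparison — deterministic, and exercised only on
  degenerate matrices.
- Permutation and profile expectations draw integer starts as
  `floor(u · n_valid)` from one `numpy` Generator; all public entry
  points accept either a seed or a Generator.
- Pipeline outputs are plain TSV/BED/JSON; a manifest records the
  package version, seed and full config echo, and identical
  config+seed reruns are byte-identical.
- Problem sizes in the acceptance checks: 200 random matrices (n ≤ 12)
  for the DP oracle; 10 seeds × 400 bins for recovery; a 90 Mb
  chromosome (~3000 regions) × 100/500 runs for density power and
  type-I; 500 replicates × 1000 permutations (300 variable-length query
  regions) for calibration; 500-bin tables × 20 seeds for correlation.

## Known limitations

- The caller's scaled-density conventions are internally consistent and
  oracle-verified but are not guaranteed to bit-match any specific
  published implementation's output on the same matrix.
- The empirical permutation p is conservative for small or homogeneous
  query sets (heavy ties in the overlap count).
- Under equal event rates the TAD and inter-TAD density samples are
  still not identically distributed — the classes have different
  region-length distributions, so the Poisson densities differ in
  variance — and the rank-sum test's rejection rate at α = 0.05 runs
  slightly hot (~0.07 rather than 0.05) on such nulls. This is a
  property of using per-region densities as statistical units, not of
  the test implementation.
- `μ(d)` at lengths near the chromosome size is estimated from very few
  windows; with `max_bins = n` the full-chromosome window always has
  `q = 0` and is never called.
- Boundary profiles drop near-telomeric boundaries rather than
  truncating windows; with large flanks on short chromosomes this can
  discard many boundaries (an error is raised if none remain).
- The bp-overlap permutation mode is a per-permutation loop and is an
  order of magnitude slower than interval counting.
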