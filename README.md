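# tadvar

**TAD calling and TAD/inter-TAD genome-variation statistics for plant Hi-C data.**

Topologically associating domains (TADs) — contiguous regions whose loci
contact each other in 3D far more often than they contact flanking
sequence — partition plant genomes into a dense-domain compartment and
its complement (inter-TADs). In rice, the two compartments differ
systematically in sequence variation, epigenetic state, transposon
content and meiotic recombination. `tadvar` implements the full analysis
chain needed to quantify those differences, for anyone with a binned
Hi-C contact map and standard feature tracks (VCF, BED, bedGraph, GFF3):

1. **Domain calling** (`tadvar.tad_caller`) — Armatus-style dynamic
   programming. A window of bins `[k, l]` (length `d = l − k + 1`) is
   scored by its scaled density minus a length-matched expectation,

   `q(k, l) = W(k, l) / d^γ − μ(d)`,

   where `W` sums contact counts over the strict upper triangle of the
   window and `μ(d)` is the mean of `W/d^γ` over all windows of length
   `d`. The optimal set of disjoint positive-quality windows is found
   exactly in `O(n · d_max)`; bins in no window form the inter-TAD
   complement. Default `γ = 0.4` at 5 kb bins.
2. **Genome partitioning** (`tadvar.genome_intervals`) — exact interval
   algebra (0-based half-open): TAD/inter-TAD and exon/intron/intergenic
   partitions with strict length conservation.
3. **Per-region statistics** (`tadvar.region_stats`) — SNP and
   structural-variant breakpoint densities per region and stratum,
   two-tailed Wilcoxon rank-sum tests, C→T substitution fractions,
   length-weighted signal means (recombination rate, methylation), gene
   length/expression comparisons.
4. **Permutation enrichment** (`tadvar.enrichment_permutation`) —
   regioneR-style overlap tests: the null re-distributes the query
   regions uniformly across the genome N times (default 1000), with
   `p = (#{null ⋄ obs} + 1)/(N + 1)` and a z-score.
5. **Boundary profiles** (`tadvar.boundary_profile`) — relative
   abundance: observed mean feature density in offset bins around
   boundaries divided by the expectation from randomly re-distributed
   windows of the same width, with a Monte-Carlo confidence band.
6. **Binned correlation** (`tadvar.feature_correlation`) — 40 kb
   genome-wide feature table; Pearson on `log2(x + 0.1)` (or raw /
   Spearman) with per-cell t-test significance masking.
7. **Synthetic data** (`tadvar.synthetic_data`) — a generator that
   plants all of the above: alternating TAD/inter-TAD segments
   (log-normal medians 35/25 kb), a distance-decay Poisson contact
   matrix with intra-TAD enrichment, class-dependent Poisson point
   features, boundary-peaked / class-shifted signal tracks, and gene
   models — so every stage can be validated against known truth.

## Worked example

The `analysis/` scripts run the whole study on a 10 Mb planted
chromosome (seed 0):

```bash
python analysis/01_simulate.py
python analysis/02_call_tads.py
python analysis/03_variant_density.py
python analysis/04_boundary_profiles.py
python analysis/05_enrichment.py
python analysis/06_correlation.py
```

Output (abridged):

```
called 165 TADs covering 58.1% of the genome
median TAD size 35 kb, median inter-TAD size 25 kb
domain-level recovery F1 vs planted truth (±1 bin): 1.000

    snp density: TAD median 2.600/kb vs inter 2.000/kb, Wilcoxon p = 2.22e-40
 del_bp density: TAD median 0.600/kb vs inter 0.500/kb, Wilcoxon p = 2.59e-08
 ins_bp density: TAD median 0.267/kb vs inter 0.200/kb, Wilcoxon p = 8.70e-10
C->T fraction: TAD median 0.2381 vs inter 0.2237, p = 0.00764

   H3K4me3: RA range 0.88-1.56, max at offset +0 bp

true_tads vs called TADs: observed 5588749, null 3364865.0±108701.7, z = 20.5, p = 0.0010
crossovers vs called TADs: observed 595, null 480.0±14.2, z = 8.1, p = 0.0010
recombination rate: TAD median 100.0 vs inter 50.0 events/Mb, Wilcoxon p = 2.34e-12
```

Reading the numbers: the caller reproduces the planted domain map
exactly (F1 = 1.0 at ±1 bin); the planted 1.3× SNP/SV rate ratio, the
higher C→T fraction in TADs, the boundary-centred H3K4me3 peak (relative
abundance 1.56 at offset 0), and the 2× crossover intensity in TADs are
all recovered with the expected directions and magnitudes. Tables and
BED files land under `results/`.

The same pipeline runs on real data through the CLI (`tadvar simulate |
call-tads | compare | enrich | profile | correlate | run`), e.g.

```bash
tadvar call-tads --matrix contacts.matrix --bins contacts_abs.bed \
    --chrom-sizes chrom.sizes --gamma 0.4 --out-prefix rice
tadvar run --config pipeline.yaml   # full configured analysis
```

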