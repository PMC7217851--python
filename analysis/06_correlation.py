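#!/usr/bin/env python
"""Genome-wide 40 kb binned feature correlation matrix.

Bins every simulated track — SNPs, deletion/insertion breakpoints,
crossovers, gene density, H3K4me3, CG methylation, recombination rate —
into 40 kb windows and reports pairwise Pearson correlations on
log2(x + 0.1)-transformed values with the p < 0.05 significance mask.
"""

from pathlib import Path

from tadvar.feature_correlation import bin_features, correlate
from tadvar.genome_intervals import (
    RegionSet,
    read_chrom_sizes,
    read_gff3_genes,
)
from tadvar.region_stats import extract_breakpoints, filter_snps, read_sv_vcf
from tadvar.tracks import PointTrack, SignalTrack, read_bed_points

DATA = Path("results/data")
OUT = Path("results")

layout = read_chrom_sizes(DATA / "chrom.sizes")
bps = extract_breakpoints(read_sv_vcf(DATA / "svs.vcf"))
genes = read_gff3_genes(DATA / "genes.gff3")
features = {
    "snp": PointTrack.from_points(filter_snps(DATA / "snps.vcf")),
    "del_bp": PointTrack.from_points(b for b in bps if b.kind == "del_bp"),
    "ins_bp": PointTrack.from_points(b for b in bps if b.kind == "ins_bp"),
    "crossover": read_bed_points(DATA / "crossovers.bed"),
    "gene": RegionSet([g.interval() for g in genes], "gene"),
    "H3K4me3": SignalTrack.read_bedgraph(DATA / "H3K4me3.bedgraph"),
    "CG": SignalTrack.read_bedgraph(DATA / "CG.bedgraph"),
    "recombination": SignalTrack.read_bedgraph(DATA / "recombination.bedgraph"),
}

table = bin_features(layout, features, bin_bp=40_000)
table.to_csv(OUT / "binned_features.tsv", sep="\t", index=False, float_format="%.6g")
report = correlate(table, method="pearson_log2", alpha=0.05)
report.write_tsv(OUT / "feature_correlations.tsv")

long = report.to_long()
sig = long[long.significant].sort_values("r")
print(f"{len(table)} bins x {len(report.r)} features; "
      f"{len(sig)}/{len(long)} pairs significant at p < 0.05")
print("strongest correlations:")
show = sig.iloc[[0, 1, -2, -1]] if len(sig) >= 4 else sig
for _, row in show.iterrows():
    print(f"  {row.feature_a:>13} ~ {row.feature_b:<13} r = {row.r:+.2f}")
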