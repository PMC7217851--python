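"""Synthetic genomes with planted TAD structure and downstream tracks.

Every analysis stage in :mod:`tadvar` can be exercised against ground
truth generated here: a chromosome tiled by alternating TAD and
inter-TAD segments with log-normal sizes (medians 35 kb and 25 kb, the
scale observed for rice domains at 5-kb Hi-C resolution); a
distance-decay Poisson contact matrix with multiplicative intra-domain
enrichment; region-class-dependent Poisson point processes for SNPs, SV
breakpoints and meiotic crossovers; boundary-peaked or class-shifted
signal tracks for chromatin marks and DNA methylation; and
non-overlapping gene models with class-dependent length and expression.

Randomness is organised as one named substream per track, all derived
from the single ``SimulationSpec.seed``, so adding a track never
perturbs the others and every output is bit-reproducible.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .contact_matrix import ContactMatrix, write_hicpro
from .genome_intervals import (
    GeneModel,
    GenomeLayout,
    GenomicInterval,
    RegionSet,
    write_bed,
)
from .region_stats import PointFeature, SVRecord
from .tracks import PointTrack, SignalTrack, write_bed_points

__all__ = ["SimulationSpec", "GroundTruth", "plant_domain_map", "simulate_contacts",
           "simulate_point_features", "simulate_signal", "simulate_crossovers",
           "simulate_genes", "simulate_svs", "simulate_all"]

_BASES = ("A", "C", "G", "T")
_ALLELE_PAIRS = [(r, a) for r in _BASES for a in _BASES if r != a]
_NON_CT = [p for p in _ALLELE_PAIRS if p != ("C", "T")]

#: marks simulated as boundary-peaked (active) vs class-shifted (repressive)
MARK_MODES = {
    "H3K4me3": "peaked",
    "H3K9ac": "peaked",
    "H4K12ac": "peaked",
    "CG": "tad_shifted",
    "CHG": "tad_shifted",
    "H3K9me2": "tad_shifted",
}


@dataclass
class SimulationSpec:
    """All generator knobs with their study-condition defaults.

    Rates are events per kb.  ``enrichment >= 1`` plants domains in the
    contact matrix; ``enrichment = 1`` is the structural null.  The SNP
    and SV rate ratios between TADs and inter-TADs default to 1.3, the
    crossover intensity ratio to 2.0.
    """

    chrom_name: str = "chr1"
    chrom_length: int = 2_000_000
    resolution: int = 5_000
    # planted segment sizes (log-normal, bp)
    tad_median_bp: float = 35_000.0
    tad_sigma: float = 0.25
    inter_median_bp: float = 25_000.0
    inter_sigma: float = 0.25
    # Hi-C model
    decay_alpha: float = 1.0
    depth: float = 50.0
    enrichment: float = 2.0
    # point-feature rates (events / kb)
    rate_snp_tad: float = 2.6
    rate_snp_inter: float = 2.0
    rate_del_tad: float = 0.65
    rate_del_inter: float = 0.5
    rate_ins_tad: float = 0.26
    rate_ins_inter: float = 0.2
    ct_fraction_tad: float = 0.24
    ct_fraction_inter: float = 0.23
    crossover_base_rate: float = 0.05
    crossover_weight_tad: float = 2.0
    # signal tracks
    signal_base: float = 1.0
    signal_noise: float = 0.1
    signal_step_bp: int = 1_000
    boundary_peak_height: float = 2.0
    boundary_peak_sd_bp: float = 800.0
    class_shift: float = 0.5
    # genes
    gene_length_median_tad: float = 2_000.0
    gene_length_median_inter: float = 3_000.0
    gene_sigma: float = 0.4
    gene_spacing_bp: float = 6_000.0  # mean intergenic gap
    expr_log2_mean_tad: float = 3.0
    expr_log2_mean_inter: float = 4.0
    expr_log2_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        for name, v in asdict(self).items():
            if name.startswith(("rate_", "crossover_")) and v < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.enrichment < 1:
            raise ValueError("enrichment must be >= 1 (1 plants the null)")
        min_len = min(self.gene_length_median_tad, self.gene_length_median_inter)
        if min_len / self.gene_spacing_bp > 0.9:
            raise ValueError("gene placement infeasible at configured density")

    @property
    def layout(self) -> GenomeLayout:
        return GenomeLayout([(self.chrom_name, self.chrom_length)])

    def rng(self, name: str) -> np.random.Generator:
        """Named substream, stable under addition of other streams."""
        return np.random.default_rng(
            np.random.SeedSequence([self.seed & 0x7FFFFFFF, zlib.crc32(name.encode())])
        )


@dataclass
class GroundTruth:
    """Planted domain map plus the generating spec."""

    tads: RegionSet
    inters: RegionSet
    spec: SimulationSpec
    seed: int

    @property
    def layout(self) -> GenomeLayout:
        return self.spec.layout

    def class_regions(self) -> list[RegionSet]:
        return [self.tads, self.inters]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "spec": asdict(self.spec),
            "tads": [[iv.chrom, iv.start, iv.end] for iv in self.tads],
            "inters": [[iv.chrom, iv.start, iv.end] for iv in self.inters],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        spec = SimulationSpec(**payload["spec"])
        return cls(
            tads=RegionSet(
                [GenomicInterval(c, s, e) for c, s, e in payload["tads"]], "TAD"
            ),
            inters=RegionSet(
                [GenomicInterval(c, s, e) for c, s, e in payload["inters"]],
                "inter-TAD",
            ),
            spec=spec,
            seed=payload["seed"],
        )


def plant_domain_map(
    spec: SimulationSpec, rng: np.random.Generator | None = None
) -> GroundTruth:
    """Tile the chromosome with alternating TAD / inter-TAD segments.

    Segment lengths are log-normal with the configured medians; the
    first segment's class is a fair coin flip and the last segment is
    truncated at the chromosome end, so the map covers the chromosome
    exactly with no gaps.
    """
    rng = rng if rng is not None else spec.rng("domain_map")
    tads, inters = [], []
    pos = 0
    is_tad = bool(rng.random() < 0.5)
    while pos < spec.chrom_length:
        if is_tad:
            length = rng.lognormal(np.log(spec.tad_median_bp), spec.tad_sigma)
        else:
            length = rng.lognormal(np.log(spec.inter_median_bp), spec.inter_sigma)
        end = min(pos + max(int(round(length)), 1), spec.chrom_length)
        iv = GenomicInterval(spec.chrom_name, pos, end)
        (tads if is_tad else inters).append(iv)
        pos = end
        is_tad = not is_tad
    return GroundTruth(
        tads=RegionSet(tads, "TAD"),
        inters=RegionSet(inters, "inter-TAD"),
        spec=spec,
        seed=spec.seed,
    )


def _bin_domain_ids(truth: GroundTruth, n_bins: int) -> np.ndarray:
    """Planted domain index of each bin by midpoint (−1 = inter)."""
    spec = truth.spec
    mids = (np.arange(n_bins) + 0.5) * spec.resolution
    arr = truth.tads.by_chrom().get(spec.chrom_name)
    ids = np.full(n_bins, -1, dtype=np.int64)
    if arr is not None and len(arr):
        idx = np.searchsorted(arr[:, 0], mids, "right") - 1
        ok = (idx >= 0) & (mids < arr[np.clip(idx, 0, None), 1])
        ids[ok] = idx[ok]
    return ids


def simulate_contacts(
    truth: GroundTruth, rng: np.random.Generator | None = None
) -> ContactMatrix:
    """Distance-decay block contact matrix with planted enrichment.

    ``counts[i][j] ~ Poisson(depth * |i-j|**(-alpha) * enr)`` where
    ``enr`` is the enrichment factor when bins i and j fall in the same
    planted TAD and 1 otherwise; symmetric with a zero diagonal.
    """
    spec = truth.spec
    rng = rng if rng is not None else spec.rng("contacts")
    n = int(np.ceil(spec.chrom_length / spec.resolution))
    ids = _bin_domain_ids(truth, n)
    d = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :]).astype(float)
    with np.errstate(divide="ignore"):
        lam = spec.depth * d ** (-spec.decay_alpha)
    np.fill_diagonal(lam, 0.0)
    same = (ids[:, None] == ids[None, :]) & (ids[:, None] >= 0)
    lam = np.where(same, lam * spec.enrichment, lam)
    upper = np.triu(rng.poisson(lam).astype(float), k=1)
    counts = upper + upper.T
    return ContactMatrix(spec.chrom_name, spec.resolution, counts)


def _class_rates(spec: SimulationSpec, kind: str) -> tuple[float, float]:
    table = {
        "snp": (spec.rate_snp_tad, spec.rate_snp_inter),
        "del_bp": (spec.rate_del_tad, spec.rate_del_inter),
        "ins_bp": (spec.rate_ins_tad, spec.rate_ins_inter),
        "crossover": (
            spec.crossover_base_rate * spec.crossover_weight_tad,
            spec.crossover_base_rate,
        ),
    }
    if kind not in table:
        raise ValueError(f"unknown point-feature kind {kind!r}")
    return table[kind]


def _draw_alleles(rng: np.random.Generator, n: int, ct_prob: float):
    is_ct = rng.random(n) < ct_prob
    other = rng.integers(0, len(_NON_CT), size=n)
    return [
        ("C", "T") if ct else _NON_CT[o] for ct, o in zip(is_ct, other)
    ]


def simulate_point_features(
    truth: GroundTruth, kind: str, rng: np.random.Generator | None = None
) -> list[PointFeature]:
    """Homogeneous Poisson events per region class at the configured rates."""
    spec = truth.spec
    rng = rng if rng is not None else spec.rng(f"points:{kind}")
    rate_tad, rate_inter = _class_rates(spec, kind)
    out: list[PointFeature] = []
    for regions, rate in ((truth.tads, rate_tad), (truth.inters, rate_inter)):
        ct = spec.ct_fraction_tad if regions is truth.tads else spec.ct_fraction_inter
        for iv in regions:
            n = rng.poisson(rate * iv.length / 1000.0)
            if n == 0:
                continue
            pos = np.sort(rng.integers(iv.start, iv.end, size=n))
            if kind == "snp":
                alleles = _draw_alleles(rng, n, ct)
                out.extend(
                    PointFeature(iv.chrom, int(p), "snp", r, a)
                    for p, (r, a) in zip(pos, alleles)
                )
            else:
                out.extend(PointFeature(iv.chrom, int(p), kind) for p in pos)
    out.sort(key=lambda p: (p.chrom, p.pos))
    return out


def simulate_svs(
    truth: GroundTruth, rng: np.random.Generator | None = None
) -> list[SVRecord]:
    """DEL and INS records whose breakpoints realise the configured rates.

    Deletion *records* are planted at half the breakpoint rate (each
    contributes two breakpoints) with lengths uniform in 50–500 bp;
    insertions at the full insertion-breakpoint rate.
    """
    spec = truth.spec
    rng = rng if rng is not None else spec.rng("svs")
    out: list[SVRecord] = []
    for regions, r_del, r_ins in (
        (truth.tads, spec.rate_del_tad, spec.rate_ins_tad),
        (truth.inters, spec.rate_del_inter, spec.rate_ins_inter),
    ):
        for iv in regions:
            kb = iv.length / 1000.0
            for _ in range(rng.poisson(r_del / 2.0 * kb)):
                start = int(rng.integers(iv.start, iv.end))
                length = int(rng.integers(50, 501))
                end = min(start + length, spec.chrom_length - 1)
                if end > start:
                    out.append(SVRecord(iv.chrom, start, end, "DEL"))
            for _ in range(rng.poisson(r_ins * kb)):
                out.append(
                    SVRecord(iv.chrom, int(rng.integers(iv.start, iv.end)), 0, "INS")
                )
    out = [
        r if r.svtype == "DEL" else SVRecord(r.chrom, r.start, r.start + 1, "INS")
        for r in out
    ]
    out.sort(key=lambda r: (r.chrom, r.start))
    return out


def simulate_signal(
    truth: GroundTruth,
    mark: str,
    rng: np.random.Generator | None = None,
    mode: str | None = None,
) -> SignalTrack:
    """Piecewise-constant signal: base + boundary peaks or class shift + noise.

    ``mode`` is looked up in :data:`MARK_MODES` when not given:
    ``peaked`` adds Gaussian bumps centred on every planted boundary
    (active marks), ``tad_shifted`` / ``inter_shifted`` add the class
    offset inside the respective regions (methylation contexts,
    H3K9me2).  Values are clipped at zero.
    """
    spec = truth.spec
    rng = rng if rng is not None else spec.rng(f"signal:{mark}")
    mode = mode or MARK_MODES.get(mark)
    if mode not in ("peaked", "tad_shifted", "inter_shifted"):
        raise ValueError(f"no mode configured for mark {mark!r}")
    step = spec.signal_step_bp
    starts = np.arange(0, spec.chrom_length, step, dtype=np.int64)
    ends = np.minimum(starts + step, spec.chrom_length)
    mids = (starts + ends) / 2.0
    values = np.full(len(starts), spec.signal_base)
    if mode == "peaked":
        bounds = np.unique(
            np.concatenate(
                [[iv.start, iv.end] for iv in truth.tads]
                if len(truth.tads)
                else [np.empty(0, dtype=np.int64)]
            )
        )
        for b in bounds:
            values += spec.boundary_peak_height * np.exp(
                -((mids - b) ** 2) / (2 * spec.boundary_peak_sd_bp**2)
            )
    else:
        target = truth.tads if mode == "tad_shifted" else truth.inters
        arr = target.by_chrom().get(spec.chrom_name)
        if arr is not None and len(arr):
            idx = np.searchsorted(arr[:, 0], mids, "right") - 1
            inside = (idx >= 0) & (mids < arr[np.clip(idx, 0, None), 1])
            values = values + np.where(inside, spec.class_shift, 0.0)
    if spec.signal_noise > 0:
        values = values + rng.normal(0.0, spec.signal_noise, size=len(values))
    values = np.clip(values, 0.0, None)
    return SignalTrack({spec.chrom_name: (starts, ends, values)})


def simulate_crossovers(
    truth: GroundTruth,
    rng: np.random.Generator | None = None,
    rate_window_bp: int = 10_000,
) -> tuple[list[PointFeature], SignalTrack]:
    """Crossover points plus the realised recombination-rate track.

    Points follow the class-weighted intensity; the rate track reports
    the realised crossover count per fixed window in events per Mb
    (cM/Mb-like units, one event ≙ one centimorgan-scale unit).
    """
    spec = truth.spec
    rng = rng if rng is not None else spec.rng("crossovers")
    points = simulate_point_features(truth, "crossover", rng=rng)
    track = PointTrack.from_points(points)
    starts = np.arange(0, spec.chrom_length, rate_window_bp, dtype=np.int64)
    ends = np.minimum(starts + rate_window_bp, spec.chrom_length)
    counts = track.counts_in_many(spec.chrom_name, starts, ends)
    rate = counts / ((ends - starts) / 1e6)
    return points, SignalTrack({spec.chrom_name: (starts, ends, rate)})


def simulate_genes(
    truth: GroundTruth, rng: np.random.Generator | None = None
) -> tuple[list[GeneModel], pd.Series]:
    """Non-overlapping gene models with class-dependent length/expression.

    Genes are laid left-to-right within each planted region with
    exponential gaps; lengths are log-normal with the per-class median;
    each gene gets 1–5 exons; expression (TPM-like) is log2-normal per
    class, lower inside TADs.
    """
    spec = truth.spec
    rng = rng if rng is not None else spec.rng("genes")
    genes: list[GeneModel] = []
    expr: dict[str, float] = {}
    counter = 0
    for regions in (truth.tads, truth.inters):
        in_tad = regions is truth.tads
        med = spec.gene_length_median_tad if in_tad else spec.gene_length_median_inter
        mu_expr = spec.expr_log2_mean_tad if in_tad else spec.expr_log2_mean_inter
        for iv in regions:
            pos = iv.start + int(rng.exponential(spec.gene_spacing_bp / 2.0))
            while True:
                length = int(round(rng.lognormal(np.log(med), spec.gene_sigma)))
                length = max(length, 200)
                if pos + length > iv.end:
                    break
                gid = f"gene{counter:05d}"
                counter += 1
                genes.append(
                    _make_gene(gid, iv.chrom, pos, pos + length, rng)
                )
                expr[gid] = float(2.0 ** rng.normal(mu_expr, spec.expr_log2_sd))
                pos += length + int(rng.exponential(spec.gene_spacing_bp)) + 1
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes, pd.Series(expr, name="tpm")


def _make_gene(gid, chrom, start, end, rng) -> GeneModel:
    length = end - start
    n_ex = int(rng.integers(1, 6))
    n_ex = min(n_ex, max(1, length // 100))
    # cut the gene into 2*n_ex - 1 parts; odd parts are exons
    n_parts = 2 * n_ex - 1
    if n_parts == 1:
        exons = ((start, end),)
    else:
        cuts = np.sort(rng.choice(np.arange(1, length), size=n_parts - 1, replace=False))
        edges = np.concatenate([[0], cuts, [length]])
        exons = tuple(
            (start + int(edges[i]), start + int(edges[i + 1]))
            for i in range(0, n_parts, 2)
        )
    strand = "+" if rng.random() < 0.5 else "-"
    return GeneModel(gid, chrom, start, end, strand, exons)


# ---------------------------------------------------------------------------
# File writers / one-shot dataset
# ---------------------------------------------------------------------------

def write_snp_vcf(
    points: list[PointFeature],
    layout: GenomeLayout,
    path: str | Path,
    rng: np.random.Generator,
    maf_low: float = 0.05,
    maf_high: float = 0.5,
) -> None:
    """Sites-only VCF with INFO/AF drawn uniformly in [maf_low, maf_high)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in layout.chroms:
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Allele Frequency">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for p in points:
            af = rng.uniform(maf_low, maf_high)
            fh.write(
                f"{p.chrom}\t{p.pos + 1}\t.\t{p.ref}\t{p.alt}\t.\tPASS\tAF={af:.4f}\n"
            )


def write_sv_vcf(records: list[SVRecord], layout: GenomeLayout, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in layout.chroms:
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="SV end">\n')
        fh.write('##ALT=<ID=DEL,Description="Deletion">\n')
        fh.write('##ALT=<ID=INS,Description="Insertion">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in records:
            fh.write(
                f"{r.chrom}\t{r.start + 1}\t.\tN\t<{r.svtype}>\t.\tPASS\t"
                f"SVTYPE={r.svtype};END={r.end}\n"
            )


def write_gff3(genes: list[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\ttadvar\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            mid = f"{g.gene_id}.1"
            fh.write(
                f"{g.chrom}\ttadvar\tmRNA\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={mid};Parent={g.gene_id}\n"
            )
            for k, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.chrom}\ttadvar\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={mid}.exon{k};Parent={mid}\n"
                )


def simulate_all(spec: SimulationSpec, outdir: str | Path) -> dict:
    """Generate the full planted dataset and write every standard file.

    Writes Hi-C-Pro matrix + bins, SNP and SV VCFs, crossover BED,
    recombination bedGraph, one peaked and one shifted mark bedGraph,
    GFF3 gene models, expression TSV, chrom.sizes, and the ground-truth
    JSON.  Returns the in-memory objects keyed by name.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = plant_domain_map(spec)
    contacts = simulate_contacts(truth)
    snps = simulate_point_features(truth, "snp")
    svs = simulate_svs(truth)
    crossovers, recomb = simulate_crossovers(truth)
    marks = {m: simulate_signal(truth, m) for m in ("H3K4me3", "CG")}
    genes, expression = simulate_genes(truth)

    from .genome_intervals import write_chrom_sizes

    write_chrom_sizes(spec.layout, outdir / "chrom.sizes")
    write_hicpro(
        {spec.chrom_name: contacts},
        outdir / "contacts.matrix",
        outdir / "contacts_abs.bed",
        layout=spec.layout,
    )
    write_snp_vcf(snps, spec.layout, outdir / "snps.vcf", spec.rng("snp_af"))
    write_sv_vcf(svs, spec.layout, outdir / "svs.vcf")
    write_bed_points(
        PointTrack.from_points(crossovers), outdir / "crossovers.bed"
    )
    recomb.write_bedgraph(outdir / "recombination.bedgraph")
    for mark, track in marks.items():
        track.write_bedgraph(outdir / f"{mark}.bedgraph")
    write_gff3(genes, outdir / "genes.gff3")
    expression.rename_axis("gene_id").to_csv(outdir / "expression.tsv", sep="\t")
    write_bed(truth.tads, outdir / "true_tads.bed")
    truth.to_json(outdir / "truth.json")
    return {
        "truth": truth,
        "contacts": contacts,
        "snps": snps,
        "svs": svs,
        "crossovers": crossovers,
        "recombination": recomb,
        "marks": marks,
        "genes": genes,
        "expression": expression,
    }
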