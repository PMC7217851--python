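"""Configuration-driven orchestration of the full analysis.

A :class:`PipelineConfig` (flat-key YAML) names the input files and the
analysis parameters; :func:`run` executes whichever stages the inputs
allow — TAD calling, genome partitioning, per-region densities and
rank-sum tests, permutation enrichment, boundary relative-abundance
profiles and binned feature correlation — writing TSV/BED/JSON outputs
plus a run manifest that suffices to reproduce every output.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .boundary_profile import extract_boundaries, relative_abundance
from .contact_matrix import read_hicpro
from .enrichment_permutation import perm_test
from .feature_correlation import bin_features, correlate
from .genome_intervals import (
    read_bed,
    read_chrom_sizes,
    read_gff3_genes,
    partition_strata,
    write_bed,
)
from .region_stats import (
    ct_fraction,
    density_per_region,
    extract_breakpoints,
    filter_snps,
    gene_metrics,
    lengthweighted_signal,
    read_sv_vcf,
    wilcoxon_rank_sum,
)
from .tad_caller import DomainParams, call_tads
from .tracks import PointTrack, SignalTrack, read_bed_points

__all__ = ["PipelineConfig", "run"]


@dataclass
class PipelineConfig:
    """Flat-key pipeline configuration; paths may be None to skip stages."""

    chrom_sizes: str
    hicpro_matrix: str
    hicpro_bins: str
    outdir: str
    snp_vcf: str | None = None
    sv_vcf: str | None = None
    genes_gff: str | None = None
    expression_tsv: str | None = None
    crossover_bed: str | None = None
    recombination_bedgraph: str | None = None
    signal_bedgraphs: dict = field(default_factory=dict)  # name -> path
    resolution: int = 5000
    gamma: float = 0.4
    min_bins: int = 2
    flank_bp: int = 20000
    profile_bin_bp: int = 1000
    corr_bin_bp: int = 40000
    n_perm: int = 1000
    n_rand: int = 1000
    maf_min: float = 0.01
    alpha: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for name in (
            "chrom_sizes",
            "hicpro_matrix",
            "hicpro_bins",
            "snp_vcf",
            "sv_vcf",
            "genes_gff",
            "expression_tsv",
            "crossover_bed",
            "recombination_bedgraph",
        ):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p}")
        for name, p in self.signal_bedgraphs.items():
            if not Path(p).exists():
                raise FileNotFoundError(f"signal_bedgraphs[{name}]: {p}")


def _test_row(name: str, stratum: str, res) -> dict:
    return {
        "comparison": name,
        "stratum": stratum,
        "statistic": res.statistic,
        "p_value": res.p_value,
        "n_tad": res.n1,
        "n_inter": res.n2,
        "median_tad": res.median1,
        "median_inter": res.median2,
    }


def run(config: PipelineConfig) -> dict[str, str]:
    """Execute the configured stages; returns a name → path map.

    Fails fast on a missing input; partially written outputs are
    removed before the error propagates.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def out(name: str) -> Path:
        p = outdir / name
        written.append(p)
        return p

    try:
        return _run_stages(config, out)
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise


def _run_stages(config: PipelineConfig, out) -> dict[str, str]:
    layout = read_chrom_sizes(config.chrom_sizes)
    rng = np.random.default_rng(config.seed)
    outputs: dict[str, str] = {}

    # --- TAD calling ------------------------------------------------------
    matrices = read_hicpro(config.hicpro_matrix, config.hicpro_bins, layout)
    params = DomainParams(gamma=config.gamma, min_bins=config.min_bins)
    domains = call_tads(matrices, params, layout)
    tads = domains.tad_regions()
    inter = domains.inter
    p = out("tads.bed")
    write_bed(
        tads,
        p,
        names=[f"TAD_{i}" for i in range(len(tads))],
        scores=[d.quality for d in domains.domains],
    )
    outputs["tads"] = str(p)
    p = out("inter_tads.bed")
    write_bed(inter, p)
    outputs["inter_tads"] = str(p)
    boundaries = extract_boundaries(domains)
    p = out("boundaries.bed")
    with open(p, "w") as fh:
        for chrom, pos in boundaries.pairs():
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\n")
    outputs["boundaries"] = str(p)

    strata = None
    genes = None
    if config.genes_gff:
        genes = read_gff3_genes(config.genes_gff)
        strata = partition_strata(genes, layout)

    test_rows = []
    density_tables = []
    corr_features: dict[str, object] = {}

    # --- variant densities ------------------------------------------------
    point_sets: dict[str, list] = {}
    if config.snp_vcf:
        point_sets["snp"] = filter_snps(config.snp_vcf, maf_min=config.maf_min)
    if config.sv_vcf:
        bps = extract_breakpoints(read_sv_vcf(config.sv_vcf))
        point_sets["del_bp"] = [b for b in bps if b.kind == "del_bp"]
        point_sets["ins_bp"] = [b for b in bps if b.kind == "ins_bp"]
    for name, points in point_sets.items():
        track = PointTrack.from_points(points)
        corr_features[name] = track
        for regions, stratified in ((tads, strata), (inter, strata)):
            density_tables.append(
                density_per_region(track, regions, strata=stratified).assign(
                    feature=name
                )
            )
        d_tad = density_per_region(track, tads)["density_per_kb"]
        d_int = density_per_region(track, inter)["density_per_kb"]
        test_rows.append(
            _test_row(f"{name}_density", "all", wilcoxon_rank_sum(d_tad, d_int))
        )
        if strata is not None:
            dt = density_per_region(track, tads, strata=strata)
            di = density_per_region(track, inter, strata=strata)
            for sname in ("exon", "intron", "intergenic"):
                xt = dt[dt.stratum == sname]["density_per_kb"]
                xi = di[di.stratum == sname]["density_per_kb"]
                if len(xt) and len(xi):
                    test_rows.append(
                        _test_row(
                            f"{name}_density", sname, wilcoxon_rank_sum(xt, xi)
                        )
                    )

    if "snp" in point_sets:
        ct_tad = ct_fraction(point_sets["snp"], tads).dropna()
        ct_int = ct_fraction(point_sets["snp"], inter).dropna()
        if len(ct_tad) and len(ct_int):
            test_rows.append(
                _test_row("ct_fraction", "all", wilcoxon_rank_sum(ct_tad, ct_int))
            )

    # --- signal comparisons ----------------------------------------------
    signal_tracks = {
        name: SignalTrack.read_bedgraph(path)
        for name, path in (config.signal_bedgraphs or {}).items()
    }
    if config.recombination_bedgraph:
        signal_tracks["recombination_rate"] = SignalTrack.read_bedgraph(
            config.recombination_bedgraph
        )
    for name, track in signal_tracks.items():
        corr_features[name] = track
        v_tad = lengthweighted_signal(track, tads)
        v_int = lengthweighted_signal(track, inter)
        v_tad = v_tad[np.isfinite(v_tad)]
        v_int = v_int[np.isfinite(v_int)]
        if len(v_tad) and len(v_int):
            test_rows.append(
                _test_row(f"{name}_signal", "all", wilcoxon_rank_sum(v_tad, v_int))
            )

    # --- genes -------------------------------------------------------------
    if genes:
        expression = None
        if config.expression_tsv:
            expression = pd.read_csv(
                config.expression_tsv, sep="\t", index_col=0
            ).iloc[:, 0]
        metrics = gene_metrics(genes, expression, [tads, inter])
        gl_t = metrics["TAD"]["length"]
        gl_i = metrics["inter-TAD"]["length"]
        test_rows.append(_test_row("gene_length", "all", wilcoxon_rank_sum(gl_t, gl_i)))
        if expression is not None:
            ex_t = metrics["TAD"]["expression"].dropna()
            ex_i = metrics["inter-TAD"]["expression"].dropna()
            if len(ex_t) and len(ex_i):
                test_rows.append(
                    _test_row("gene_expression", "all", wilcoxon_rank_sum(ex_t, ex_i))
                )

    # --- permutation enrichment --------------------------------------------
    perm_rows = []
    if config.crossover_bed:
        crossovers = read_bed(config.crossover_bed, label="crossover")
        res = perm_test(
            crossovers,
            tads,
            layout,
            n_perm=config.n_perm,
            alternative="greater",
            seed=config.seed,
            alpha=config.alpha,
        )
        perm_rows.append(
            {
                "query": "crossovers",
                "fixed": "TADs",
                "observed": res.observed,
                "null_mean": res.null_mean,
                "null_sd": res.null_sd,
                "threshold": res.significance_threshold,
                "p": res.p_empirical,
                "z": res.z_score,
                "n_perm": res.n_perm,
                "seed": config.seed,
            }
        )
        corr_features["crossover"] = PointTrack.from_points(
            (iv.chrom, iv.start) for iv in crossovers
        )

    # --- boundary profiles ---------------------------------------------------
    profile_paths = {}
    profile_targets: dict[str, object] = {}
    if "snp" in point_sets:
        profile_targets["snp"] = PointTrack.from_points(point_sets["snp"])
    for name, track in signal_tracks.items():
        profile_targets[name] = track
    for name, track in profile_targets.items():
        try:
            prof = relative_abundance(
                boundaries,
                track,
                layout,
                flank_bp=config.flank_bp,
                bin_bp=config.profile_bin_bp,
                R=config.n_rand,
                seed=config.seed,
            )
        except ValueError:
            continue
        p = out(f"profile_{name}.tsv")
        prof.write_tsv(p)
        profile_paths[name] = str(p)
    outputs.update({f"profile_{k}": v for k, v in profile_paths.items()})

    # --- correlation ---------------------------------------------------------
    if genes:
        from .genome_intervals import RegionSet

        corr_features["gene"] = RegionSet(
            [g.interval() for g in genes], label="gene"
        )
    if len(corr_features) >= 2:
        table = bin_features(layout, corr_features, bin_bp=config.corr_bin_bp)
        p = out("binned_features.tsv")
        table.to_csv(p, sep="\t", index=False, float_format="%.6g")
        outputs["binned_features"] = str(p)
        report = correlate(table, method="pearson_log2", alpha=config.alpha)
        p = out("correlations.tsv")
        report.write_tsv(p)
        outputs["correlations"] = str(p)

    # --- tables and manifest -------------------------------------------------
    if density_tables:
        p = out("region_densities.tsv")
        pd.concat(density_tables, ignore_index=True).to_csv(
            p, sep="\t", index=False, float_format="%.6g"
        )
        outputs["region_densities"] = str(p)
    if test_rows:
        p = out("tests.tsv")
        pd.DataFrame(test_rows).to_csv(p, sep="\t", index=False, float_format="%.6g")
        outputs["tests"] = str(p)
    if perm_rows:
        p = out("permutation_tests.tsv")
        pd.DataFrame(perm_rows).to_csv(p, sep="\t", index=False, float_format="%.6g")
        outputs["permutation_tests"] = str(p)

    manifest = {
        "tadvar_version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "outputs": outputs,
        "n_tads": len(tads),
        "n_inter": len(inter),
        "tad_coverage": tads.total_length / layout.total_length,
    }
    p = out("manifest.json")
    p.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    outputs["manifest"] = str(p)
    return outputs
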