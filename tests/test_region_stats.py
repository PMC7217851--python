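"""Region densities, rank-sum tests, C→T fractions, weighted signal, genes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tadvar.genome_intervals import GeneModel, GenomicInterval, RegionSet, StrataPartition
from tadvar.region_stats import (
    PointFeature,
    SVRecord,
    ct_fraction,
    density_per_region,
    extract_breakpoints,
    filter_snps,
    gene_metrics,
    lengthweighted_signal,
    read_sv_vcf,
    wilcoxon_rank_sum,
)
from tadvar.tracks import SignalTrack

from conftest import make_regions

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "##contig=<ID=chr1,length=100000>\n"
    '##INFO=<ID=AF,Number=A,Type=Float,Description="AF">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
)


class TestBreakpoints:
    def test_del_and_ins(self):
        recs = [SVRecord("chr1", 100, 200, "DEL"), SVRecord("chr1", 150, 151, "INS")]
        bps = extract_breakpoints(recs)
        assert [(b.pos, b.kind) for b in bps] == [
            (100, "del_bp"),
            (200, "del_bp"),
            (150, "ins_bp"),
        ]

    def test_unknown_type_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="unknown SV type"):
            out = extract_breakpoints([SVRecord("chr1", 1, 2, "INV")])
        assert out == []

    def test_empty(self):
        assert extract_breakpoints([]) == []


class TestFilterSnps:
    def test_maf_threshold(self, tmp_path):
        vcf = tmp_path / "a.vcf"
        vcf.write_text(
            VCF_HEADER
            + "chr1\t100\t.\tC\tT\t.\tPASS\tAF=0.005\n"
            + "chr1\t200\t.\tA\tG\t.\tPASS\tAF=0.5\n"
            + "chr1\t300\t.\tG\tA\t.\tPASS\tAF=0.995\n"  # MAF 0.005: dropped
        )
        snps = filter_snps(vcf, maf_min=0.01)
        assert [(s.pos, s.ref, s.alt) for s in snps] == [(199, "A", "G")]

    def test_af_from_genotypes(self, tmp_path):
        header = (
            "##fileformat=VCFv4.2\n##contig=<ID=chr1,length=1000>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(f"s{i}" for i in range(5))
            + "\n"
        )
        # 1 alt allele among 10 -> AF 0.1, kept at 0.01
        vcf = tmp_path / "b.vcf"
        vcf.write_text(
            header + "chr1\t50\t.\tC\tT\t.\tPASS\t.\tGT\t0/1\t0/0\t0/0\t0/0\t0/0\n"
        )
        snps = filter_snps(vcf, maf_min=0.01)
        assert len(snps) == 1 and snps[0].pos == 49

    def test_sv_vcf_reader(self, tmp_path):
        vcf = tmp_path / "sv.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=chr1,length=100000>\n"
            '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="t">\n'
            '##INFO=<ID=END,Number=1,Type=Integer,Description="e">\n'
            '##ALT=<ID=DEL,Description="d">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr1\t101\t.\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;END=200\n"
        )
        recs = read_sv_vcf(vcf)
        assert recs == [SVRecord("chr1", 100, 200, "DEL")]


class TestDensity:
    def test_basic_density(self):
        pts = [PointFeature("chr1", p) for p in range(0, 10000, 2000)]
        table = density_per_region(pts, make_regions([(0, 10000)], label="TAD"))
        assert table.iloc[0]["count"] == 5
        assert table.iloc[0]["density_per_kb"] == 0.5

    def test_point_at_region_end_not_counted(self):
        pts = [PointFeature("chr1", 10000)]
        table = density_per_region(pts, make_regions([(0, 10000)]))
        assert table.iloc[0]["count"] == 0

    def test_stratified_density(self):
        pts = [PointFeature("chr1", 100), PointFeature("chr1", 3000)]
        region = make_regions([(0, 10000)], label="TAD")
        strata = StrataPartition(
            exon=make_regions([(0, 4000)], label="exon"),
            intron=make_regions([], label="intron"),
            intergenic=make_regions([(4000, 10000)], label="intergenic"),
        )
        table = density_per_region(pts, region, strata=strata)
        exon_row = table[table.stratum == "exon"].iloc[0]
        assert exon_row["density_per_kb"] == pytest.approx(0.5)
        assert "intron" not in set(table.stratum)  # zero-length rows dropped

    def test_counts_conserved_over_partition(self, rng):
        pts = [PointFeature("chr1", int(p)) for p in rng.integers(0, 1000, 200)]
        a = make_regions([(0, 300), (600, 1000)], label="a")
        b = make_regions([(300, 600)], label="b")
        total = (
            density_per_region(pts, a)["count"].sum()
            + density_per_region(pts, b)["count"].sum()
        )
        assert total == 200


class TestWilcoxon:
    def test_exact_examples(self):
        assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]).p_value == pytest.approx(0.1)
        assert wilcoxon_rank_sum([1, 2], [3, 4]).p_value == pytest.approx(1 / 3)

    def test_identical_samples_p_one(self):
        res = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == pytest.approx(1.0)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        x=st.lists(st.integers(-500, 500), min_size=2, max_size=30),
        y=st.lists(st.integers(-500, 500), min_size=2, max_size=30),
    )
    def test_symmetry_and_monotone_invariance(self, x, y):
        p_xy = wilcoxon_rank_sum(x, y).p_value
        p_yx = wilcoxon_rank_sum(y, x).p_value
        assert p_xy == pytest.approx(p_yx)
        # strictly monotone transform of the pooled data: identical p
        fx = [float(v) ** 3 for v in x]
        fy = [float(v) ** 3 for v in y]
        assert wilcoxon_rank_sum(fx, fy).p_value == pytest.approx(p_xy, rel=1e-9)


class TestCtFraction:
    def make_snps(self, specs):
        return [
            PointFeature("chr1", pos, "snp", ref, alt) for pos, ref, alt in specs
        ]

    def test_fraction(self):
        snps = self.make_snps(
            [(i * 10, "C", "T") for i in range(2)]
            + [(100 + i * 10, "A", "G") for i in range(6)]
        )
        out = ct_fraction(snps, make_regions([(0, 1000)]))
        assert out.iloc[0] == pytest.approx(0.25)

    def test_all_ct(self):
        snps = self.make_snps([(10, "C", "T"), (20, "C", "T")])
        assert ct_fraction(snps, make_regions([(0, 100)])).iloc[0] == 1.0

    def test_empty_region_nan(self):
        snps = self.make_snps([(10, "C", "T")])
        out = ct_fraction(snps, make_regions([(500, 600)]))
        assert np.isnan(out.iloc[0])

    def test_strand_collapse_flag(self):
        snps = self.make_snps([(10, "G", "A"), (20, "A", "C")])
        regions = make_regions([(0, 100)])
        assert ct_fraction(snps, regions).iloc[0] == 0.0
        assert ct_fraction(snps, regions, collapse_strands=True).iloc[0] == 0.5


class TestLengthweightedSignal:
    def test_weighted_mean(self):
        track = SignalTrack({"chr1": ([0, 3000], [3000, 4000], [4.0, 1.0])})
        out = lengthweighted_signal(track, make_regions([(0, 4000)]))
        assert out[0] == pytest.approx(3.25)

    def test_uniform_track(self):
        track = SignalTrack({"chr1": ([0], [10_000], [2.5])})
        out = lengthweighted_signal(track, make_regions([(2000, 7000)]))
        assert out[0] == pytest.approx(2.5)

    def test_region_outside_track_nan(self):
        track = SignalTrack({"chr1": ([0], [1000], [1.0])})
        out = lengthweighted_signal(track, make_regions([(5000, 6000)]))
        assert np.isnan(out[0])

    def test_overlapping_track_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            SignalTrack({"chr1": ([0, 500], [1000, 1500], [1.0, 2.0])})


class TestGeneMetrics:
    def test_length_and_assignment(self):
        genes = [
            GeneModel("a", "chr1", 100, 400, "+", ((100, 400),)),
            GeneModel("b", "chr1", 600, 700, "+", ((600, 700),)),
        ]
        tad = make_regions([(0, 500)], label="TAD")
        inter = make_regions([(500, 1000)], label="inter-TAD")
        out = gene_metrics(genes, {"a": 5.0, "b": 7.0}, [tad, inter])
        assert out["TAD"].iloc[0]["length"] == 300
        assert out["inter-TAD"].iloc[0]["expression"] == 7.0

    def test_missing_expression_excluded_not_fatal(self):
        genes = [
            GeneModel("a", "chr1", 0, 100, "+", ((0, 100),)),
            GeneModel("b", "chr1", 600, 700, "+", ((600, 700),)),
        ]
        tad = make_regions([(0, 500)], label="TAD")
        inter = make_regions([(500, 1000)], label="inter-TAD")
        out = gene_metrics(genes, {"a": 5.0}, [tad, inter])
        assert np.isnan(out["inter-TAD"].iloc[0]["expression"])

    def test_empty_class_raises(self):
        genes = [GeneModel("a", "chr1", 0, 100, "+", ((0, 100),))]
        tad = make_regions([(0, 500)], label="TAD")
        inter = make_regions([(500, 1000)], label="inter-TAD")
        with pytest.raises(ValueError, match="no genes"):
            gene_metrics(genes, None, [tad, inter])

    def test_planted_length_contrast_detected(self):
        from tadvar.synthetic_data import SimulationSpec, plant_domain_map, simulate_genes

        spec = SimulationSpec(seed=5, chrom_length=10_000_000)
        truth = plant_domain_map(spec)
        genes, expr = simulate_genes(truth)
        out = gene_metrics(genes, expr, [truth.tads, truth.inters])
        res = wilcoxon_rank_sum(out["TAD"]["length"], out["inter-TAD"]["length"])
        assert res.p_value < 0.01
        assert res.median1 < res.median2  # TAD genes shorter by construction
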