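"""Planted-truth generator: determinism, conservation, calibrated rates."""

import numpy as np
import pytest

from tadvar.genome_intervals import read_gff3_genes
from tadvar.region_stats import extract_breakpoints, filter_snps, read_sv_vcf
from tadvar.synthetic_data import (
    GroundTruth,
    SimulationSpec,
    plant_domain_map,
    simulate_contacts,
    simulate_crossovers,
    simulate_genes,
    simulate_point_features,
    simulate_signal,
    simulate_svs,
    simulate_all,
)
from tadvar.tracks import PointTrack


class TestPlantDomainMap:
    def test_same_seed_identical(self):
        spec = SimulationSpec(seed=4)
        a = plant_domain_map(spec)
        b = plant_domain_map(spec)
        assert [(iv.start, iv.end) for iv in a.tads] == [
            (iv.start, iv.end) for iv in b.tads
        ]

    def test_exact_cover_no_gaps(self):
        truth = plant_domain_map(SimulationSpec(seed=1))
        total = truth.tads.total_length + truth.inters.total_length
        assert total == truth.spec.chrom_length
        # alternating segments: sorted union must be contiguous
        all_ivs = sorted(
            [(iv.start, iv.end) for iv in truth.tads]
            + [(iv.start, iv.end) for iv in truth.inters]
        )
        cursor = 0
        for s, e in all_ivs:
            assert s == cursor
            cursor = e
        assert cursor == truth.spec.chrom_length

    def test_median_sizes_near_configured(self):
        # large genome -> many segments; sample medians near 35/25 kb
        spec = SimulationSpec(seed=2, chrom_length=200_000_000)
        truth = plant_domain_map(spec)
        med_tad = np.median([iv.length for iv in truth.tads])
        med_int = np.median([iv.length for iv in truth.inters])
        assert abs(med_tad - spec.tad_median_bp) / spec.tad_median_bp < 0.1
        assert abs(med_int - spec.inter_median_bp) / spec.inter_median_bp < 0.1


class TestSimulateContacts:
    def test_poisson_mean_with_enrichment(self):
        # pairs at distance 4 inside one planted TAD: lambda = depth/4 * 2
        spec = SimulationSpec(seed=3, depth=100.0, enrichment=2.0)
        truth = plant_domain_map(spec)
        m = simulate_contacts(truth)
        from tadvar.synthetic_data import _bin_domain_ids

        ids = _bin_domain_ids(truth, m.n_bins)
        vals = []
        for i in range(m.n_bins - 4):
            if ids[i] >= 0 and ids[i] == ids[i + 4]:
                vals.append(m.counts[i, i + 4])
        lam = 100.0 / 4 * 2
        se = np.sqrt(lam / len(vals))
        assert abs(np.mean(vals) - lam) < 3 * se

    def test_symmetric_zero_diagonal(self):
        truth = plant_domain_map(SimulationSpec(seed=5))
        m = simulate_contacts(truth)
        assert np.all(np.diag(m.counts) == 0)
        np.testing.assert_array_equal(m.counts, m.counts.T)

    def test_seed_reproducibility(self):
        spec = SimulationSpec(seed=6)
        truth = plant_domain_map(spec)
        np.testing.assert_array_equal(
            simulate_contacts(truth).counts, simulate_contacts(truth).counts
        )


class TestPointFeatures:
    def test_poisson_mean_per_class(self):
        spec = SimulationSpec(seed=7, chrom_length=20_000_000)
        truth = plant_domain_map(spec)
        snps = simulate_point_features(truth, "snp")
        track = PointTrack.from_points(snps)
        in_tad = sum(track.count_in(iv.chrom, iv.start, iv.end) for iv in truth.tads)
        kb_tad = truth.tads.total_length / 1000
        rate = in_tad / kb_tad
        se = np.sqrt(spec.rate_snp_tad / kb_tad)
        assert abs(rate - spec.rate_snp_tad) < 4 * se

    def test_snp_alleles_follow_ct_proportion(self):
        spec = SimulationSpec(
            seed=8, chrom_length=20_000_000, ct_fraction_tad=0.4, ct_fraction_inter=0.1
        )
        truth = plant_domain_map(spec)
        snps = simulate_point_features(truth, "snp")
        tad_arr = truth.tads.by_chrom()["chr1"]
        idx = np.array([p.pos for p in snps])
        j = np.searchsorted(tad_arr[:, 0], idx, "right") - 1
        in_tad = (j >= 0) & (idx < tad_arr[np.clip(j, 0, None), 1])
        is_ct = np.array([(p.ref, p.alt) == ("C", "T") for p in snps])
        assert abs(is_ct[in_tad].mean() - 0.4) < 0.02
        assert abs(is_ct[~in_tad].mean() - 0.1) < 0.02

    def test_crossover_class_share(self):
        spec = SimulationSpec(seed=9, chrom_length=30_000_000)
        truth = plant_domain_map(spec)
        points, rate_track = simulate_crossovers(truth)
        track = PointTrack.from_points(points)
        in_tad = sum(track.count_in(iv.chrom, iv.start, iv.end) for iv in truth.tads)
        cov = truth.tads.total_length / spec.chrom_length
        expect = 2 * cov / (2 * cov + (1 - cov))
        assert abs(in_tad / track.total - expect) < 0.04
        # rate track integrates to the realised number of events
        s, e, v = rate_track.data["chr1"]
        assert np.dot(v, (e - s) / 1e6) == pytest.approx(track.total)

    def test_unknown_kind_rejected(self):
        truth = plant_domain_map(SimulationSpec(seed=0))
        with pytest.raises(ValueError):
            simulate_point_features(truth, "inversion")


class TestSignalAndGenes:
    def test_constant_track_without_noise_or_peak(self):
        spec = SimulationSpec(seed=1, signal_noise=0.0, boundary_peak_height=0.0)
        truth = plant_domain_map(spec)
        sig = simulate_signal(truth, "H3K4me3")
        _, _, v = sig.data["chr1"]
        np.testing.assert_allclose(v, spec.signal_base)

    def test_shifted_mark_higher_in_tads(self):
        from tadvar.region_stats import lengthweighted_signal, wilcoxon_rank_sum

        spec = SimulationSpec(seed=2, chrom_length=5_000_000)
        truth = plant_domain_map(spec)
        sig = simulate_signal(truth, "CG")
        v_tad = lengthweighted_signal(sig, truth.tads)
        v_int = lengthweighted_signal(sig, truth.inters)
        res = wilcoxon_rank_sum(v_tad[np.isfinite(v_tad)], v_int[np.isfinite(v_int)])
        assert res.p_value < 1e-6 and res.median1 > res.median2

    def test_genes_non_overlapping_and_within_chromosome(self):
        spec = SimulationSpec(seed=3, chrom_length=5_000_000)
        truth = plant_domain_map(spec)
        genes, expr = simulate_genes(truth)
        assert len(genes) > 50
        spans = sorted((g.start, g.end) for g in genes)
        for (s1, e1), (s2, _) in zip(spans, spans[1:]):
            assert s2 >= e1
        assert set(expr.index) == {g.gene_id for g in genes}

    def test_infeasible_gene_density_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            SimulationSpec(gene_length_median_tad=50_000, gene_spacing_bp=1000)


class TestWriters:
    def test_simulate_all_roundtrips(self, tmp_path):
        spec = SimulationSpec(seed=11, chrom_length=500_000)
        objs = simulate_all(spec, tmp_path)
        # truth JSON round trip
        truth2 = GroundTruth.from_json(tmp_path / "truth.json")
        assert truth2.tads.total_length == objs["truth"].tads.total_length
        # SNP VCF: all simulated SNPs survive the default MAF filter
        snps = filter_snps(tmp_path / "snps.vcf", maf_min=0.01)
        assert len(snps) == len(objs["snps"])
        assert [s.pos for s in snps[:5]] == [p.pos for p in objs["snps"][:5]]
        # SV VCF: DEL -> 2 breakpoints, INS -> 1
        recs = read_sv_vcf(tmp_path / "svs.vcf")
        bps = extract_breakpoints(recs)
        n_del = sum(r.svtype == "DEL" for r in recs)
        n_ins = sum(r.svtype == "INS" for r in recs)
        assert len(bps) == 2 * n_del + n_ins
        # GFF3 round trip
        genes = read_gff3_genes(tmp_path / "genes.gff3")
        assert len(genes) == len(objs["genes"])
        g0, s0 = genes[0], objs["genes"][0]
        assert (g0.start, g0.end, g0.exons) == (s0.start, s0.end, s0.exons)

    def test_bit_reproducible_outputs(self, tmp_path):
        spec = SimulationSpec(seed=12, chrom_length=300_000)
        simulate_all(spec, tmp_path / "a")
        simulate_all(spec, tmp_path / "b")
        for name in ("snps.vcf", "contacts.matrix", "genes.gff3", "truth.json"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()
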