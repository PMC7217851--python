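"""Boundary extraction and relative-abundance profiles."""

import numpy as np
import pytest

from tadvar.boundary_profile import (
    expected_density,
    extract_boundaries,
    observed_profile,
    relative_abundance,
)
from tadvar.genome_intervals import GenomeLayout, GenomicInterval, RegionSet
from tadvar.tracks import PointTrack, SignalTrack

from conftest import make_regions


class TestExtractBoundaries:
    def test_both_edges(self):
        b = extract_boundaries(make_regions([(10_000, 45_000)]))
        assert list(b.positions["chr1"]) == [10_000, 45_000]

    def test_shared_edge_deduplicated(self):
        b = extract_boundaries(make_regions([(0, 10_000), (10_000, 20_000)]))
        assert list(b.positions["chr1"]) == [0, 10_000, 20_000]

    def test_empty(self):
        assert extract_boundaries(make_regions([])).total == 0

    def test_edge_modes(self):
        regions = make_regions([(100, 200)])
        assert list(extract_boundaries(regions, "start").positions["chr1"]) == [100]
        assert list(extract_boundaries(regions, "end").positions["chr1"]) == [200]


class TestObservedProfile:
    def test_uniform_point_track(self):
        layout = GenomeLayout([("chr1", 100_000)])
        pts = PointTrack({"chr1": np.arange(0, 100_000, 1000)})  # exactly 1 per kb
        b = extract_boundaries(make_regions([(30_000, 60_000)]))
        offsets, dens, n = observed_profile(b, pts, layout, 10_000, 1000)
        assert n == 2
        np.testing.assert_allclose(dens, 1.0)

    def test_boundary_near_chrom_end_excluded(self):
        layout = GenomeLayout([("chr1", 50_000)])
        pts = PointTrack({"chr1": np.arange(0, 50_000, 500)})
        b = extract_boundaries(make_regions([(5_000, 30_000)]))
        _, _, n = observed_profile(b, pts, layout, 10_000, 1000)
        assert n == 1  # the 5 kb boundary's window exits the chromosome
        with pytest.raises(ValueError, match="excluded"):
            observed_profile(
                extract_boundaries(make_regions([(1000, 49_500)])),
                pts,
                layout,
                10_000,
                1000,
            )

    def test_single_boundary_manual(self):
        layout = GenomeLayout([("chr1", 100_000)])
        pts = PointTrack({"chr1": np.array([48_000, 49_000, 49_500, 51_000])})
        b = extract_boundaries(make_regions([(50_000, 90_000)]), "start")
        offsets, dens, _ = observed_profile(b, pts, layout, 2000, 2000)
        # window [-2000, 0): 3 events in 2 kb; [0, 2000): 1 event
        assert list(offsets) == [-2000, 0]
        np.testing.assert_allclose(dens, [1.5, 0.5])

    def test_flank_not_divisible_rejected(self):
        layout = GenomeLayout([("chr1", 100_000)])
        b = extract_boundaries(make_regions([(30_000, 60_000)]))
        with pytest.raises(ValueError, match="divisible"):
            observed_profile(b, PointTrack({}), layout, 1500, 1000)


class TestExpectedDensity:
    def test_uniform_rate_recovered(self):
        layout = GenomeLayout([("chr1", 100_000)])
        pts = PointTrack({"chr1": np.arange(0, 100_000, 1000)})
        exp, (lo, hi), _ = expected_density(
            pts, layout, 50, 1000, R=200, rng=np.random.default_rng(0)
        )
        assert exp == pytest.approx(1.0, rel=0.05)
        assert lo <= 1.0 <= hi

    def test_same_seed_identical(self):
        layout = GenomeLayout([("chr1", 100_000)])
        pts = PointTrack({"chr1": np.arange(0, 100_000, 700)})
        a = expected_density(pts, layout, 20, 1000, R=150, rng=np.random.default_rng(5))
        b = expected_density(pts, layout, 20, 1000, R=150, rng=np.random.default_rng(5))
        assert a[0] == b[0]
        np.testing.assert_array_equal(a[2], b[2])

    def test_half_genome_concentration_averages_out(self):
        # all events in the first half at 2/kb -> genome-wide expectation 1/kb
        layout = GenomeLayout([("chr1", 200_000)])
        pts = PointTrack({"chr1": np.arange(0, 100_000, 500)})
        exp, _, _ = expected_density(
            pts, layout, 100, 1000, R=300, rng=np.random.default_rng(1)
        )
        assert exp == pytest.approx(1.0, rel=0.1)


class TestRelativeAbundance:
    def _truth(self, seed=3, length=5_000_000):
        from tadvar.synthetic_data import SimulationSpec, plant_domain_map

        spec = SimulationSpec(seed=seed, chrom_length=length)
        return spec, plant_domain_map(spec)

    def test_uniform_track_ra_near_one(self):
        spec, truth = self._truth()
        rng = np.random.default_rng(8)
        n = rng.poisson(spec.chrom_length / 1000)
        pts = PointTrack({"chr1": np.sort(rng.integers(0, spec.chrom_length, n))})
        prof = relative_abundance(
            extract_boundaries(truth.tads), pts, spec.layout, R=300, seed=4
        )
        assert np.abs(prof.relative_abundance - 1.0).max() < 0.5
        assert np.abs(np.median(prof.relative_abundance) - 1.0) < 0.1

    def test_ra_invariant_under_track_rescaling(self):
        # doubling every event (two events at each position) leaves RA unchanged
        spec, truth = self._truth()
        rng = np.random.default_rng(9)
        pos = np.sort(rng.integers(0, spec.chrom_length, 3000))
        b = extract_boundaries(truth.tads)
        p1 = relative_abundance(b, PointTrack({"chr1": pos}), spec.layout, R=200, seed=2)
        doubled = np.sort(np.concatenate([pos, pos]))
        p2 = relative_abundance(
            b, PointTrack({"chr1": doubled}), spec.layout, R=200, seed=2
        )
        np.testing.assert_allclose(
            p1.relative_abundance, p2.relative_abundance, rtol=1e-9
        )

    def test_planted_peak_maximum_at_boundary(self):
        spec, truth = self._truth(seed=11)
        rng = np.random.default_rng(12)
        base = rng.integers(0, spec.chrom_length, rng.poisson(spec.chrom_length / 1000))
        extra = []
        b = extract_boundaries(truth.tads)
        for chrom, p in b.pairs():
            extra.extend(rng.normal(p, 600, size=rng.poisson(4.0)))
        extra = np.array(extra)
        extra = extra[(extra >= 0) & (extra < spec.chrom_length)].astype(np.int64)
        pts = PointTrack({"chr1": np.sort(np.concatenate([base, extra]))})
        prof = relative_abundance(b, pts, spec.layout, R=200, seed=3)
        peak = prof.offsets[np.argmax(prof.relative_abundance)]
        assert peak in (-1000, 0)
        # decays back to ~1 at the flank ends
        assert abs(prof.relative_abundance[0] - 1) < 0.3
        assert abs(prof.relative_abundance[-1] - 1) < 0.3

    def test_planted_depletion_below_one(self):
        spec, truth = self._truth(seed=13)
        rng = np.random.default_rng(14)
        pos = np.sort(rng.integers(0, spec.chrom_length, 10_000))
        b = extract_boundaries(truth.tads)
        near = np.zeros(len(pos), dtype=bool)
        for chrom, p in b.pairs():
            near |= np.abs(pos - p) < 2000
        prof = relative_abundance(
            b, PointTrack({"chr1": pos[~near]}), spec.layout, R=200, seed=5
        )
        sel = (prof.offsets >= -2000) & (prof.offsets < 2000)
        assert np.all(prof.relative_abundance[sel] < 0.5)

    def test_gene_density_dip_disappears_after_stratification(self):
        """A boundary gene-density gradient carves a dip in the total variant
        profile that vanishes when only intergenic variants are profiled."""
        spec, truth = self._truth(seed=15, length=8_000_000)
        rng = np.random.default_rng(16)
        b = extract_boundaries(truth.tads)
        # gene density elevated near boundaries (~50% coverage) over a ~10%
        # background; variants are depleted inside genes
        from tadvar.genome_intervals import complement, normalize

        genic = []
        bg_starts = rng.integers(0, spec.chrom_length - 800, 1000)
        genic.extend(GenomicInterval("chr1", int(s), int(s) + 800) for s in bg_starts)
        for chrom, p in b.pairs():
            for s in rng.integers(p - 3000, p + 2200, 4):
                s = int(np.clip(s, 0, spec.chrom_length - 800))
                genic.append(GenomicInterval("chr1", s, s + 800))
        genic_set = normalize(RegionSet(genic, "genic"), spec.layout)
        pos = np.sort(rng.integers(0, spec.chrom_length, 16_000))
        arrs = genic_set.by_chrom()["chr1"]
        idx = np.searchsorted(arrs[:, 0], pos, "right") - 1
        in_gene = (idx >= 0) & (pos < arrs[np.clip(idx, 0, None), 1])
        keep_genic = rng.random(len(pos)) < 0.3  # 70% depletion inside genes
        kept = pos[~in_gene | keep_genic]
        track = PointTrack({"chr1": kept})
        all_prof = relative_abundance(b, track, spec.layout, R=200, seed=6)
        # stratified profile: densities per intergenic bp only
        intergenic = complement(genic_set, spec.layout)
        strat_prof = relative_abundance(
            b, track, spec.layout, R=200, seed=7, restrict=intergenic
        )
        centre = np.abs(all_prof.offsets + 500) <= 2000
        dip_all = all_prof.relative_abundance[centre].mean()
        assert dip_all < 0.85  # visible dip from the gene gradient
        dip_strat = strat_prof.relative_abundance[centre].mean()
        assert abs(dip_strat - 1.0) < 0.15  # the dip disappears under stratification
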