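"""Per-region feature densities and two-group comparisons.

Implements the statistics comparing TAD and inter-TAD regions: variant
(SNP / SV-breakpoint) densities per region, optionally stratified by
exon / intron / intergenic sequence; the two-tailed Wilcoxon rank-sum
test on per-region values (individual TAD and inter-TAD intervals are
the statistical units, and tests run on non-log-transformed densities);
the C→T substitution fraction per region; length-weighted signal means
(recombination rate, methylation); and gene length / expression samples
per region class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_intervals import (
    GeneModel,
    GenomicInterval,
    RegionSet,
    StrataPartition,
    assign_region_class,
    intersect,
)
from .tracks import PointTrack, SignalTrack

__all__ = [
    "PointFeature",
    "SVRecord",
    "TestResult",
    "extract_breakpoints",
    "filter_snps",
    "read_sv_vcf",
    "density_per_region",
    "wilcoxon_rank_sum",
    "ct_fraction",
    "lengthweighted_signal",
    "gene_metrics",
]


@dataclass(frozen=True)
class PointFeature:
    """A point genomic event: SNP, SV breakpoint, or crossover."""

    chrom: str
    pos: int
    kind: str = "snp"  # snp | del_bp | ins_bp | crossover
    ref: str | None = None
    alt: str | None = None


@dataclass(frozen=True)
class SVRecord:
    """Minimal structural-variant record (coordinates 0-based half-open)."""

    chrom: str
    start: int
    end: int
    svtype: str  # DEL | INS


@dataclass
class TestResult:
    """Two-sample rank-sum test outcome."""

    statistic: float
    p_value: float
    n1: int
    n2: int
    median1: float
    median2: float
    method: str = "wilcoxon_rank_sum"


def extract_breakpoints(sv_records: Iterable[SVRecord]) -> list[PointFeature]:
    """SV records → breakpoint point features.

    Deletions contribute two breakpoints (start and end coordinates);
    insertions contribute one (the start coordinate).  Records of any
    other type are skipped with a warning.
    """
    out: list[PointFeature] = []
    for rec in sv_records:
        if rec.svtype.upper() == "DEL":
            out.append(PointFeature(rec.chrom, rec.start, "del_bp"))
            out.append(PointFeature(rec.chrom, rec.end, "del_bp"))
        elif rec.svtype.upper() == "INS":
            out.append(PointFeature(rec.chrom, rec.start, "ins_bp"))
        else:
            warnings.warn(f"unknown SV type {rec.svtype!r}; record skipped")
    return out


def _maf_of(variant, populations: Sequence[int] | None) -> float | None:
    af = variant.INFO.get("AF")
    if af is not None and populations is None:
        if isinstance(af, (tuple, list)):
            af = af[0]
        return min(float(af), 1.0 - float(af))
    gts = variant.gt_types  # 0 hom-ref, 1 het, 3 hom-alt, 2 unknown
    if gts is None or len(gts) == 0:
        return None
    if populations is not None:
        gts = gts[np.asarray(populations, dtype=int)]
    called = gts != 2
    if not np.any(called):
        return None
    alt = (gts[called] == 1).sum() + 2 * (gts[called] == 3).sum()
    freq = alt / (2 * called.sum())
    return min(freq, 1.0 - freq)


def filter_snps(
    vcf_path: str | Path,
    maf_min: float = 0.01,
    populations: Sequence[int] | None = None,
) -> list[PointFeature]:
    """Read biallelic SNPs from VCF keeping those with MAF >= *maf_min*.

    Allele frequency comes from ``INFO/AF`` when present, else from the
    genotypes of the selected samples (*populations* gives sample
    indices).  Records with neither are skipped with a warning.
    Positions are converted to the internal 0-based convention.
    """
    from cyvcf2 import VCF

    out: list[PointFeature] = []
    for v in VCF(str(vcf_path)):
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            continue  # not a biallelic SNV
        maf = _maf_of(v, populations)
        if maf is None:
            warnings.warn(f"no AF and no genotypes at {v.CHROM}:{v.POS}; skipped")
            continue
        if maf >= maf_min:
            out.append(PointFeature(v.CHROM, v.start, "snp", v.REF, v.ALT[0]))
    return out


def read_sv_vcf(vcf_path: str | Path) -> list[SVRecord]:
    """Read SV records (SVTYPE DEL/INS) from VCF."""
    from cyvcf2 import VCF

    out: list[SVRecord] = []
    for v in VCF(str(vcf_path)):
        svtype = v.INFO.get("SVTYPE")
        if svtype is None:
            alt = v.ALT[0] if v.ALT else ""
            svtype = alt.strip("<>") if alt.startswith("<") else ""
        end = v.INFO.get("END")
        end = int(end) if end is not None else v.start + max(len(v.REF), 1)
        out.append(SVRecord(v.CHROM, v.start, end, str(svtype)))
    return out


def density_per_region(
    points: Iterable[PointFeature] | PointTrack,
    regions: RegionSet,
    strata: StrataPartition | None = None,
) -> pd.DataFrame:
    """Per-region event counts and densities (events per kb).

    One row per region; with *strata* given each region is first
    intersected with each stratum and one row is emitted per region ×
    stratum (zero-length intersections are dropped).  Counting uses the
    half-open convention: a point at the region end is not counted.
    """
    track = points if isinstance(points, PointTrack) else PointTrack.from_points(points)
    rows = []
    strata_map = strata.as_dict() if strata is not None else {None: None}
    for i, iv in enumerate(regions):
        for stratum_name, stratum in strata_map.items():
            if stratum is None:
                pieces = [(iv.start, iv.end)]
            else:
                pieces = intersect(iv, stratum)
            length = sum(e - s for s, e in pieces)
            if length == 0:
                continue
            count = sum(track.count_in(iv.chrom, s, e) for s, e in pieces)
            rows.append(
                {
                    "label": regions.label,
                    "stratum": stratum_name if stratum_name else "all",
                    "chrom": iv.chrom,
                    "start": iv.start,
                    "end": iv.end,
                    "length_bp": length,
                    "count": count,
                    "density_per_kb": count / (length / 1000.0),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "label",
            "stratum",
            "chrom",
            "start",
            "end",
            "length_bp",
            "count",
            "density_per_kb",
        ],
    )


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-tailed Wilcoxon rank-sum (Mann-Whitney U) test.

    Uses exact enumeration when the pooled sample has at most 20 values
    and no ties, and the normal approximation with tie and continuity
    corrections otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= 20 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        n1=int(x.size),
        n2=int(y.size),
        median1=float(np.median(x)),
        median2=float(np.median(y)),
    )


def ct_fraction(
    snps: Iterable[PointFeature],
    regions: RegionSet,
    collapse_strands: bool = False,
) -> pd.Series:
    """Per-region fraction of SNPs that are C→T substitutions.

    Strand-literal by default (ref C, alt T only); with
    ``collapse_strands`` G→A counts as well.  Regions with no SNPs get
    NaN; non-SNV allele pairs are skipped.
    """
    by_chrom: dict[str, list[tuple[int, bool]]] = {}
    for p in snps:
        if p.ref is None or p.alt is None or len(p.ref) != 1 or len(p.alt) != 1:
            continue
        is_ct = (p.ref, p.alt) == ("C", "T") or (
            collapse_strands and (p.ref, p.alt) == ("G", "A")
        )
        by_chrom.setdefault(p.chrom, []).append((p.pos, is_ct))
    pos_arr = {}
    ct_arr = {}
    for c, lst in by_chrom.items():
        lst.sort()
        pos_arr[c] = np.array([p for p, _ in lst], dtype=np.int64)
        ct_arr[c] = np.cumsum([0] + [int(f) for _, f in lst])
    vals = []
    for iv in regions:
        if iv.chrom not in pos_arr:
            vals.append(np.nan)
            continue
        p = pos_arr[iv.chrom]
        i0 = int(np.searchsorted(p, iv.start, "left"))
        i1 = int(np.searchsorted(p, iv.end, "left"))
        n = i1 - i0
        vals.append((ct_arr[iv.chrom][i1] - ct_arr[iv.chrom][i0]) / n if n else np.nan)
    return pd.Series(vals, name="ct_fraction")


def lengthweighted_signal(track: SignalTrack, regions: RegionSet) -> np.ndarray:
    """Length-weighted mean signal per region; NaN where the track has
    no coverage.  Overlapping track intervals are rejected by the
    :class:`~tadvar.tracks.SignalTrack` constructor."""
    out = np.empty(len(regions))
    for i, iv in enumerate(regions):
        out[i] = track.mean_in(iv.chrom, iv.start, iv.end)
    return out


def gene_metrics(
    genes: Sequence[GeneModel],
    expression: Mapping[str, float] | pd.Series | None,
    classes: Sequence[RegionSet],
) -> dict[str, pd.DataFrame]:
    """Per-class gene length and expression samples.

    Genes are assigned to the class with the largest overlap (ties to
    the first class listed).  Genes missing from the expression table
    are excluded from the expression sample only (NaN length stays).
    Raises if any class ends up empty.
    """
    if expression is not None and not isinstance(expression, pd.Series):
        expression = pd.Series(dict(expression))
    acc: dict[str, list[dict]] = {c.label: [] for c in classes}
    for g in genes:
        label = assign_region_class(g.interval(), classes)
        expr = np.nan
        if expression is not None and g.gene_id in expression.index:
            expr = float(expression[g.gene_id])
        acc[label].append(
            {"gene_id": g.gene_id, "length": g.length, "expression": expr}
        )
    out = {}
    for label, rows in acc.items():
        if not rows:
            raise ValueError(f"no genes assigned to class {label!r}")
        out[label] = pd.DataFrame(rows)
    return out
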