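"""Coordinate conventions, interval algebra, and genome partitioning.

Everything in :mod:`tadvar` lives in a single internal coordinate system:
0-based, half-open ``[start, end)`` intervals, the BED convention.  GFF3
input (1-based, closed) is shifted on read; VCF positions are shifted by
−1.  Strand is carried on intervals but ignored by all arithmetic — none
of the analyses here are strand-specific.

The partitioning operations implement the two genome decompositions the
downstream statistics depend on: TAD / inter-TAD (a region set and its
complement) and exon / intron / intergenic, with exon taking precedence
over intron and intron over intergenic when gene models overlap.  Both
decompositions conserve total genome length exactly, which the test suite
asserts as an invariant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "GenomeLayout",
    "GenomicInterval",
    "RegionSet",
    "GeneModel",
    "StrataPartition",
    "normalize",
    "complement",
    "intersect",
    "coverage_fraction",
    "partition_strata",
    "assign_region_class",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_bed",
    "write_bed",
    "read_gff3_genes",
]


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names and lengths; the coordinate universe.

    Parameters
    ----------
    chroms
        Sequence of ``(name, length_bp)`` pairs in genome order.
    """

    chroms: tuple[tuple[str, int], ...]

    def __init__(self, chroms: Iterable[tuple[str, int]]):
        chroms = tuple((str(n), int(l)) for n, l in chroms)
        names = [n for n, _ in chroms]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        if any(l < 1 for _, l in chroms):
            raise ValueError("chromosome lengths must be >= 1")
        object.__setattr__(self, "chroms", chroms)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.chroms)

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chroms)

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chroms)

    def length_of(self, chrom: str) -> int:
        try:
            return self.lengths[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


class RegionSet:
    """A labelled collection of genomic intervals (e.g. ``"TAD"``).

    The constructor accepts intervals in any order and does not merge
    them; call :func:`normalize` to obtain the sorted, non-overlapping
    canonical form required by most downstream operations.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = (), label: str = ""):
        self.intervals: list[GenomicInterval] = list(intervals)
        self.label = label
        self._by_chrom_cache: dict[str, np.ndarray] | None = None

    @classmethod
    def from_arrays(
        cls, chrom_arrays: dict[str, np.ndarray], label: str = ""
    ) -> "RegionSet":
        """Build from ``{chrom: (k, 2) array of [start, end)}``."""
        ivs = [
            GenomicInterval(c, int(s), int(e))
            for c, arr in chrom_arrays.items()
            for s, e in np.asarray(arr).reshape(-1, 2)
        ]
        return cls(ivs, label=label)

    def by_chrom(self) -> dict[str, np.ndarray]:
        """Per-chromosome ``(k, 2)`` int arrays, sorted by start.

        The result is cached; a :class:`RegionSet` is treated as
        immutable once handed to any operation.
        """
        if self._by_chrom_cache is None or (
            sum(len(a) for a in self._by_chrom_cache.values()) != len(self.intervals)
        ):
            out: dict[str, list[tuple[int, int]]] = {}
            for iv in self.intervals:
                out.setdefault(iv.chrom, []).append((iv.start, iv.end))
            self._by_chrom_cache = {
                c: np.array(sorted(pairs), dtype=np.int64).reshape(-1, 2)
                for c, pairs in out.items()
            }
        return self._by_chrom_cache

    @property
    def total_length(self) -> int:
        return sum(iv.length for iv in self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __repr__(self) -> str:
        return f"RegionSet({self.label!r}, n={len(self)}, bp={self.total_length})"


def _check_bounds(regions: RegionSet, layout: GenomeLayout) -> None:
    for iv in regions:
        if iv.chrom not in layout:
            raise ValueError(f"interval on unknown chromosome {iv.chrom!r}")
        if iv.end > layout.length_of(iv.chrom):
            raise ValueError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome "
                f"length {layout.length_of(iv.chrom)}"
            )


def normalize(regions: RegionSet, layout: GenomeLayout | None = None) -> RegionSet:
    """Sort intervals and merge any that overlap or are adjacent.

    If *layout* is given, intervals outside chromosome bounds raise a
    ``ValueError``.  The merged set covers at most the nominal input
    length (duplicates and overlaps collapse).
    """
    if layout is not None:
        _check_bounds(regions, layout)
    merged: dict[str, list[list[int]]] = {}
    for chrom, arr in regions.by_chrom().items():
        out: list[list[int]] = []
        for s, e in arr:
            if out and s <= out[-1][1]:  # overlap or adjacency: merge
                out[-1][1] = max(out[-1][1], int(e))
            else:
                out.append([int(s), int(e)])
        merged[chrom] = out
    order = layout.names if layout is not None else sorted(merged)
    ivs = [
        GenomicInterval(c, s, e)
        for c in order
        if c in merged
        for s, e in merged[c]
    ]
    return RegionSet(ivs, label=regions.label)


def complement(regions: RegionSet, layout: GenomeLayout) -> RegionSet:
    """The genome-wide complement of a (normalized) region set.

    Input and output are disjoint and together tile every chromosome
    exactly once; ``complement(complement(r)) == r`` on normalized *r*.
    """
    norm = normalize(regions, layout).by_chrom()
    ivs: list[GenomicInterval] = []
    for chrom, length in layout.chroms:
        cursor = 0
        for s, e in norm.get(chrom, np.empty((0, 2), dtype=np.int64)):
            if s > cursor:
                ivs.append(GenomicInterval(chrom, cursor, int(s)))
            cursor = int(e)
        if cursor < length:
            ivs.append(GenomicInterval(chrom, cursor, length))
    label = f"non-{regions.label}" if regions.label else ""
    return RegionSet(ivs, label=label)


def intersect(interval: GenomicInterval, regions: RegionSet) -> list[tuple[int, int]]:
    """Pieces of *interval* covered by *regions* (assumed normalized)."""
    arr = regions.by_chrom().get(interval.chrom)
    if arr is None or len(arr) == 0:
        return []
    starts, ends = arr[:, 0], arr[:, 1]
    i0 = int(np.searchsorted(ends, interval.start, side="right"))
    i1 = int(np.searchsorted(starts, interval.end, side="left"))
    out = []
    for s, e in arr[i0:i1]:
        lo, hi = max(int(s), interval.start), min(int(e), interval.end)
        if lo < hi:
            out.append((lo, hi))
    return out


def coverage_fraction(regions: RegionSet, layout: GenomeLayout) -> float:
    """Fraction of the genome covered after merging, in ``[0, 1]``."""
    return normalize(regions, layout).total_length / layout.total_length


@dataclass(frozen=True)
class GeneModel:
    """A gene with its exon structure (coordinates 0-based half-open)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self):
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValueError(
                    f"exon [{s},{e}) outside gene {self.gene_id} "
                    f"[{self.start},{self.end})"
                )

    @property
    def length(self) -> int:
        return self.end - self.start

    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)


@dataclass
class StrataPartition:
    """Mutually exclusive exon / intron / intergenic genome partition."""

    exon: RegionSet
    intron: RegionSet
    intergenic: RegionSet

    def as_dict(self) -> dict[str, RegionSet]:
        return {"exon": self.exon, "intron": self.intron, "intergenic": self.intergenic}


def partition_strata(genes: Sequence[GeneModel], layout: GenomeLayout) -> StrataPartition:
    """Split the genome into exon, intron and intergenic sequence.

    Exon takes precedence over intron (an exon of one gene inside the
    intron of an overlapping gene counts as exon), and intron over
    intergenic.  The three strata are disjoint and their lengths sum to
    the genome length exactly.
    """
    exon_ivs = [
        GenomicInterval(g.chrom, s, e) for g in genes for s, e in g.exons
    ]
    body_ivs = [g.interval() for g in genes]
    exon = normalize(RegionSet(exon_ivs, "exon"), layout)
    bodies = normalize(RegionSet(body_ivs, "gene"), layout)
    # intron = gene bodies minus exons
    intron_ivs: list[GenomicInterval] = []
    exon_by_chrom = exon.by_chrom()
    for iv in bodies:
        cursor = iv.start
        for s, e in intersect(iv, exon):
            if s > cursor:
                intron_ivs.append(GenomicInterval(iv.chrom, cursor, s))
            cursor = e
        if cursor < iv.end:
            intron_ivs.append(GenomicInterval(iv.chrom, cursor, iv.end))
    intron = normalize(RegionSet(intron_ivs, "intron"), layout)
    intergenic = complement(bodies, layout)
    intergenic.label = "intergenic"
    return StrataPartition(exon=exon, intron=intron, intergenic=intergenic)


def assign_region_class(item: GenomicInterval, classes: Sequence[RegionSet]) -> str:
    """Label of the class overlapping *item* the most; ties → first listed.

    Raises ``ValueError`` when no class overlaps the item at all (the
    classes are expected to jointly cover the genome).
    """
    overlaps = []
    for cls in classes:
        ov = sum(e - s for s, e in intersect(item, cls))
        overlaps.append(ov)
    best = int(np.argmax(overlaps))  # argmax takes the first maximum: tie rule
    if overlaps[best] == 0:
        raise ValueError(
            f"interval {item.chrom}:{item.start}-{item.end} overlaps no class"
        )
    return classes[best].label


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

def read_chrom_sizes(path: str | Path) -> GenomeLayout:
    """Two-column TSV: chromosome name, length."""
    chroms = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        name, length = line.split("\t")[:2]
        chroms.append((name, int(length)))
    return GenomeLayout(chroms)


def write_chrom_sizes(layout: GenomeLayout, path: str | Path) -> None:
    Path(path).write_text(
        "".join(f"{n}\t{l}\n" for n, l in layout.chroms)
    )


def read_bed(path: str | Path, label: str = "") -> RegionSet:
    """Read BED3+ (0-based half-open; strand from column 6 if present)."""
    ivs = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.rstrip("\n").split("\t")
        strand = f[5] if len(f) > 5 and f[5] in "+-" else "."
        ivs.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand))
    return RegionSet(ivs, label=label)


def write_bed(
    regions: RegionSet,
    path: str | Path,
    names: Sequence[str] | None = None,
    scores: Sequence[float] | None = None,
) -> None:
    """Write BED3 (or BED5 when names/scores are given)."""
    with open(path, "w") as fh:
        for i, iv in enumerate(regions):
            row = [iv.chrom, str(iv.start), str(iv.end)]
            if names is not None or scores is not None:
                row.append(names[i] if names is not None else f"{regions.label}_{i}")
                row.append(f"{scores[i]:.6g}" if scores is not None else "0")
            fh.write("\t".join(row) + "\n")


def read_gff3_genes(path: str | Path) -> list[GeneModel]:
    """Read gene models (gene → mRNA → exon lineage) from GFF3.

    Only the gene/mRNA/exon feature lineage is resolved; exons of all
    transcripts of a gene are pooled (the union is taken downstream by
    :func:`partition_strata`).
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        exons = []
        for ex in db.children(g, featuretype="exon"):
            exons.append((ex.start - 1, ex.end))  # GFF3 1-based closed -> half-open
        if not exons:
            warnings.warn(f"gene {g.id} has no exon children; using its full span")
            exons = [(g.start - 1, g.end)]
        genes.append(
            GeneModel(
                gene_id=g.id,
                chrom=g.seqid,
                start=g.start - 1,
                end=g.end,
                strand=g.strand if g.strand in "+-" else ".",
                exons=tuple(sorted(exons)),
            )
        )
    return genes
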