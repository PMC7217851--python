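"""Point and signal feature tracks.

Two in-memory track flavours cover every feature the analyses consume:

* :class:`PointTrack` — point events (SNPs, SV breakpoints, crossovers)
  held as sorted position arrays per chromosome; counting events in a
  window is a pair of binary searches.
* :class:`SignalTrack` — piecewise-constant interval signal (ChIP
  coverage, DNA methylation, recombination rate in cM/Mb) in bedGraph
  dialect; queries return length-weighted means.

Interval features (genes, TEs) are represented by
:class:`~tadvar.genome_intervals.RegionSet`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

from .genome_intervals import GenomicInterval, RegionSet

__all__ = ["PointTrack", "SignalTrack", "read_bed_points", "write_bed_points"]


class PointTrack:
    """Sorted point events per chromosome."""

    def __init__(self, positions: dict[str, np.ndarray]):
        self.positions = {
            c: np.sort(np.asarray(p, dtype=np.int64)) for c, p in positions.items()
        }

    @classmethod
    def from_points(cls, points: Iterable) -> "PointTrack":
        """Build from objects with ``.chrom``/``.pos`` or ``(chrom, pos)``."""
        acc: dict[str, list[int]] = {}
        for p in points:
            chrom, pos = (p.chrom, p.pos) if hasattr(p, "chrom") else (p[0], p[1])
            acc.setdefault(chrom, []).append(int(pos))
        return cls({c: np.array(v, dtype=np.int64) for c, v in acc.items()})

    @property
    def total(self) -> int:
        return sum(len(p) for p in self.positions.values())

    def count_in(self, chrom: str, start: int, end: int) -> int:
        p = self.positions.get(chrom)
        if p is None:
            return 0
        return int(np.searchsorted(p, end, "left") - np.searchsorted(p, start, "left"))

    def counts_in_many(
        self, chrom: str, starts: np.ndarray, ends: np.ndarray
    ) -> np.ndarray:
        """Vectorised :meth:`count_in` over parallel start/end arrays."""
        p = self.positions.get(chrom)
        if p is None:
            return np.zeros(len(starts), dtype=np.int64)
        return np.searchsorted(p, ends, "left") - np.searchsorted(p, starts, "left")


@dataclass
class SignalTrack:
    """Non-overlapping interval signal; ``data[chrom] = (starts, ends, values)``."""

    data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]

    def __init__(self, data):
        clean = {}
        for chrom, (s, e, v) in data.items():
            s = np.asarray(s, dtype=np.int64)
            e = np.asarray(e, dtype=np.int64)
            v = np.asarray(v, dtype=float)
            order = np.argsort(s, kind="stable")
            s, e, v = s[order], e[order], v[order]
            if np.any(e[:-1] > s[1:]):
                raise ValueError(f"overlapping signal intervals on {chrom}")
            if np.any(s >= e):
                raise ValueError(f"empty signal interval on {chrom}")
            clean[chrom] = (s, e, v)
        self.data = clean

    def weighted_sum(self, chrom: str, start: int, end: int) -> tuple[float, int]:
        """(sum of value × overlap bp, covered bp) within ``[start, end)``."""
        entry = self.data.get(chrom)
        if entry is None:
            return 0.0, 0
        s, e, v = entry
        i0 = int(np.searchsorted(e, start, "right"))
        i1 = int(np.searchsorted(s, end, "left"))
        if i1 <= i0:
            return 0.0, 0
        ov = np.minimum(e[i0:i1], end) - np.maximum(s[i0:i1], start)
        ov = np.clip(ov, 0, None)
        return float(np.dot(v[i0:i1], ov)), int(ov.sum())

    def mean_in(self, chrom: str, start: int, end: int) -> float:
        """Length-weighted mean over the covered part; NaN if uncovered."""
        total, covered = self.weighted_sum(chrom, start, end)
        return total / covered if covered > 0 else float("nan")

    # -- bedGraph IO --------------------------------------------------------

    @classmethod
    def read_bedgraph(cls, path: str | Path) -> "SignalTrack":
        acc: dict[str, list[tuple[int, int, float]]] = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            c, s, e, v = line.rstrip("\n").split("\t")[:4]
            acc.setdefault(c, []).append((int(s), int(e), float(v)))
        return cls(
            {
                c: tuple(np.array(col) for col in zip(*sorted(rows)))
                for c, rows in acc.items()
            }
        )

    def write_bedgraph(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.data):
                s, e, v = self.data[chrom]
                for si, ei, vi in zip(s, e, v):
                    fh.write(f"{chrom}\t{si}\t{ei}\t{vi:.6g}\n")


def read_bed_points(path: str | Path) -> PointTrack:
    """Read point events from BED (the interval start is the event position)."""
    acc: dict[str, list[int]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        acc.setdefault(f[0], []).append(int(f[1]))
    return PointTrack({c: np.array(v, dtype=np.int64) for c, v in acc.items()})


def write_bed_points(track: PointTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(track.positions):
            for pos in track.positions[chrom]:
                fh.write(f"{chrom}\t{pos}\t{pos + 1}\n")


def regions_to_track(regions: RegionSet) -> PointTrack:
    """Interval starts as a point track (occasionally useful for profiles)."""
    return PointTrack.from_points((iv.chrom, iv.start) for iv in regions)
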