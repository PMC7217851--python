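"""Relative feature abundance around TAD boundaries.

For each offset bin around the set of boundary positions we compute the
mean feature density (events per kb for point tracks, mean signal for
interval tracks) across boundaries, and divide it by an expectation
obtained by re-distributing windows of the same width uniformly across
the genome.  Operating on densities and using randomized windows (not
the genome-wide abundance) for the denominator removes the bias that
fixed-width genomic windows would otherwise introduce; the randomized
rounds also provide a Monte-Carlo confidence band for the null ratio
of 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genome_intervals import GenomeLayout, GenomicInterval, RegionSet, intersect
from .tad_caller import DomainSet
from .tracks import PointTrack, SignalTrack

__all__ = [
    "BoundarySet",
    "ProfileResult",
    "extract_boundaries",
    "observed_profile",
    "expected_density",
    "relative_abundance",
]

DEFAULT_FLANK_BP = 20_000  # rice-scale flank; use ~500 kb for human-scale TADs
DEFAULT_BIN_BP = 1_000


@dataclass
class BoundarySet:
    """Deduplicated boundary positions per chromosome."""

    positions: dict[str, np.ndarray]
    source: str = "both"

    @property
    def total(self) -> int:
        return sum(len(p) for p in self.positions.values())

    def pairs(self) -> list[tuple[str, int]]:
        return [
            (c, int(p)) for c in sorted(self.positions) for p in self.positions[c]
        ]


@dataclass
class ProfileResult:
    """Observed, expected and relative abundance per offset bin."""

    offsets: np.ndarray  # bin left edges, bp; negative = upstream
    observed_density: np.ndarray
    expected: float
    expected_ci: tuple[float, float]
    relative_abundance: np.ndarray
    n_boundaries: int
    n_rounds: int
    seed: int | None = None

    def to_dataframe(self) -> pd.DataFrame:
        lo, hi = self.expected_ci
        return pd.DataFrame(
            {
                "offset_bp": self.offsets,
                "observed": self.observed_density,
                "expected": self.expected,
                "ci_low": lo,
                "ci_high": hi,
                "relative_abundance": self.relative_abundance,
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.6g")


def extract_boundaries(
    domains: DomainSet | RegionSet, edge_mode: str = "both"
) -> BoundarySet:
    """Boundary positions from domain edges.

    ``edge_mode`` selects ``start``, ``end`` or ``both`` edges; adjacent
    domains sharing an edge contribute that position once.
    """
    regions = domains.tad_regions() if isinstance(domains, DomainSet) else domains
    if edge_mode not in ("start", "end", "both"):
        raise ValueError(f"unknown edge_mode {edge_mode!r}")
    acc: dict[str, set[int]] = {}
    for iv in regions:
        s = acc.setdefault(iv.chrom, set())
        if edge_mode in ("start", "both"):
            s.add(iv.start)
        if edge_mode in ("end", "both"):
            s.add(iv.end)
    return BoundarySet(
        {c: np.array(sorted(v), dtype=np.int64) for c, v in acc.items()},
        source=edge_mode,
    )


def _window_density(
    track: PointTrack | SignalTrack,
    chrom: str,
    start: int,
    end: int,
    restrict: RegionSet | None = None,
) -> float:
    """Density of *track* in a window, optionally per *restrict*-stratum bp.

    With a restriction (e.g. the intergenic stratum) both the event count
    and the length denominator use only the window's intersection with
    the stratum; a window with no stratum coverage has undefined (NaN)
    density and drops out of the means.
    """
    if restrict is not None:
        pieces = intersect(GenomicInterval(chrom, start, end), restrict)
        covered = sum(e - s for s, e in pieces)
        if covered == 0:
            return float("nan")
        if isinstance(track, PointTrack):
            n = sum(track.count_in(chrom, s, e) for s, e in pieces)
            return n / (covered / 1000.0)
        tot = 0.0
        cov = 0
        for s, e in pieces:
            t, c = track.weighted_sum(chrom, s, e)
            tot += t
            cov += c
        return tot / cov if cov else float("nan")
    if isinstance(track, PointTrack):
        return track.count_in(chrom, start, end) / ((end - start) / 1000.0)
    return track.mean_in(chrom, start, end)


def observed_profile(
    boundaries: BoundarySet,
    track: PointTrack | SignalTrack,
    layout: GenomeLayout,
    flank_bp: int = DEFAULT_FLANK_BP,
    bin_bp: int = DEFAULT_BIN_BP,
    restrict: RegionSet | None = None,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Mean per-offset density across boundaries.

    Boundaries whose full window ``[pos - flank, pos + flank)`` leaves
    the chromosome are dropped (keeping per-offset sample size
    constant).  With *restrict* (a stratum such as intergenic sequence)
    densities are computed per stratum bp inside each window.  Returns
    ``(offsets, densities, n_boundaries_used)``.
    """
    if flank_bp % bin_bp != 0:
        raise ValueError("flank_bp must be divisible by bin_bp")
    offsets = np.arange(-flank_bp, flank_bp, bin_bp)
    sums = np.zeros(len(offsets))
    counts = np.zeros(len(offsets))
    n_used = 0
    for chrom, positions in boundaries.positions.items():
        if chrom not in layout:
            continue
        length = layout.length_of(chrom)
        keep = positions[(positions - flank_bp >= 0) & (positions + flank_bp <= length)]
        if keep.size == 0:
            continue
        n_used += keep.size
        if isinstance(track, PointTrack) and restrict is None:
            starts = keep[:, None] + offsets[None, :]
            c = track.counts_in_many(
                chrom, starts.ravel(), (starts + bin_bp).ravel()
            ).reshape(starts.shape)
            sums += c.sum(axis=0) / (bin_bp / 1000.0)
            counts += keep.size
        else:
            for pos in keep:
                for j, o in enumerate(offsets):
                    v = _window_density(
                        track, chrom, int(pos + o), int(pos + o + bin_bp), restrict
                    )
                    if np.isfinite(v):
                        sums[j] += v
                        counts[j] += 1
    if n_used == 0:
        raise ValueError("all boundaries excluded by the flank window")
    with np.errstate(invalid="ignore"):
        dens = np.where(counts > 0, sums / counts, np.nan)
    return offsets, dens, n_used


def expected_density(
    track: PointTrack | SignalTrack,
    layout: GenomeLayout,
    n_windows: int,
    bin_bp: int,
    R: int = 1000,
    rng: np.random.Generator | None = None,
    restrict: RegionSet | None = None,
) -> tuple[float, tuple[float, float], np.ndarray]:
    """Expected window density from R rounds of random window placement.

    Each round places *n_windows* windows of width *bin_bp* uniformly
    across the genome and takes their mean density; the expectation is
    the mean over rounds and the CI the empirical 2.5/97.5 percentiles.
    Returns ``(expected, (lo, hi), per-round means)``.
    """
    if R < 100:
        raise ValueError("R must be >= 100")
    rng = rng if rng is not None else np.random.default_rng()
    chrom_lengths = np.array([l for _, l in layout.chroms], dtype=np.int64)
    valid = np.clip(chrom_lengths - bin_bp + 1, 0, None).astype(float)
    if valid.sum() == 0:
        raise ValueError("bin wider than every chromosome")
    probs = valid / valid.sum()
    names = layout.names
    rounds = np.empty(R)
    for r in range(R):
        ci = rng.choice(len(names), size=n_windows, p=probs)
        starts = np.floor(rng.random(n_windows) * valid[ci]).astype(np.int64)
        if isinstance(track, PointTrack) and restrict is None:
            dens = np.empty(n_windows)
            for c in np.unique(ci):
                sel = ci == c
                dens[sel] = track.counts_in_many(
                    names[c], starts[sel], starts[sel] + bin_bp
                ) / (bin_bp / 1000.0)
        else:
            dens = np.array(
                [
                    _window_density(
                        track, names[ci[i]], int(starts[i]), int(starts[i]) + bin_bp,
                        restrict,
                    )
                    for i in range(n_windows)
                ]
            )
        with np.errstate(invalid="ignore"):
            rounds[r] = np.nanmean(dens)
    expected = float(np.mean(rounds))
    ci_lo, ci_hi = np.percentile(rounds, [2.5, 97.5])
    return expected, (float(ci_lo), float(ci_hi)), rounds


def relative_abundance(
    boundaries: BoundarySet,
    track: PointTrack | SignalTrack,
    layout: GenomeLayout,
    flank_bp: int = DEFAULT_FLANK_BP,
    bin_bp: int = DEFAULT_BIN_BP,
    R: int = 1000,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    restrict: RegionSet | None = None,
) -> ProfileResult:
    """Observed-over-expected density profile around boundaries.

    *restrict* computes a stratified profile: both the observed and the
    expected densities are taken per bp of the given stratum only.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    offsets, obs, n_used = observed_profile(
        boundaries, track, layout, flank_bp=flank_bp, bin_bp=bin_bp, restrict=restrict
    )
    expected, ci, _ = expected_density(
        track, layout, n_windows=n_used, bin_bp=bin_bp, R=R, rng=rng, restrict=restrict
    )
    if expected == 0:
        raise ValueError("expected density is zero; relative abundance undefined")
    return ProfileResult(
        offsets=offsets,
        observed_density=obs,
        expected=expected,
        expected_ci=ci,
        relative_abundance=obs / expected,
        n_boundaries=n_used,
        n_rounds=R,
        seed=seed,
    )
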