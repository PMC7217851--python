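"""Permutation-null region-overlap enrichment tests.

The regioneR-style scheme: keep a fixed region set (e.g. TADs), count
how many query regions (e.g. crossovers, TEs, a second TAD set) overlap
it, then rebuild the null by randomly re-distributing the query regions
across the genome N times with their lengths preserved.  The empirical
p-value uses the +1 correction ``p = (#{null >= obs} + 1) / (N + 1)``
(for the ``greater`` alternative), so p can never be exactly zero, and
the z-score is the observed count standardised by the null sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome_intervals import GenomeLayout, GenomicInterval, RegionSet, normalize

__all__ = ["PermutationResult", "randomize_regions", "overlap_count", "perm_test"]


@dataclass
class PermutationResult:
    observed: float
    null_sample: np.ndarray
    p_empirical: float
    z_score: float
    alternative: str
    n_perm: int
    seed: int | None = None
    alpha: float = 0.05

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_sample))

    @property
    def null_sd(self) -> float:
        return float(np.std(self.null_sample, ddof=1))

    @property
    def significance_threshold(self) -> float:
        """The (1 − α) null quantile (α quantile for alternative='less')."""
        q = 1.0 - self.alpha if self.alternative == "greater" else self.alpha
        return float(np.quantile(self.null_sample, q))


def _valid_starts(lengths: np.ndarray, layout: GenomeLayout) -> np.ndarray:
    """(m, n_chrom) matrix of valid start counts per region per chromosome."""
    chrom_lengths = np.array([l for _, l in layout.chroms], dtype=np.int64)
    v = chrom_lengths[None, :] - lengths[:, None] + 1
    return np.clip(v, 0, None)


def _sample_placements(
    lengths: np.ndarray,
    layout: GenomeLayout,
    rng: np.random.Generator,
    size: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw uniform placements for each region, *size* independent times.

    Each region goes to a chromosome with probability proportional to
    its number of valid start positions there, then to a uniform valid
    start.  Returns ``(chrom_idx, starts)`` of shape ``(size, m)``.
    """
    m = len(lengths)
    v = _valid_starts(lengths, layout).astype(float)  # (m, n_chrom)
    totals = v.sum(axis=1)
    if np.any(totals == 0):
        bad = lengths[totals == 0].max()
        raise ValueError(f"region of length {bad} fits on no chromosome")
    cum = np.cumsum(v, axis=1)  # (m, n_chrom)
    u = rng.random((size, m)) * totals[None, :]
    chrom_idx = (u[:, :, None] >= cum[None, :, :]).sum(axis=2)
    prev = np.concatenate([np.zeros((m, 1)), cum[:, :-1]], axis=1)
    offset = u - np.take_along_axis(
        np.broadcast_to(prev, (size, m, prev.shape[1])), chrom_idx[:, :, None], axis=2
    )[:, :, 0]
    starts = np.floor(offset).astype(np.int64)
    return chrom_idx, starts


def randomize_regions(
    regions: RegionSet,
    layout: GenomeLayout,
    rng: np.random.Generator,
    non_overlapping: bool = False,
    exclude: RegionSet | None = None,
    max_tries: int = 1000,
) -> RegionSet:
    """Uniformly re-distribute regions across the genome, lengths preserved.

    By default placements may overlap each other; with
    ``non_overlapping`` the whole set is rejection-sampled until
    disjoint.  An *exclude* set removes placements touching it (also by
    rejection).  Raises after *max_tries* failed attempts.
    """
    lengths = np.array([iv.length for iv in regions], dtype=np.int64)
    names = layout.names
    excl = normalize(exclude, layout).by_chrom() if exclude is not None else None

    def attempt() -> list[GenomicInterval] | None:
        chrom_idx, starts = _sample_placements(lengths, layout, rng, size=1)
        ivs = [
            GenomicInterval(names[c], int(s), int(s) + int(l))
            for c, s, l in zip(chrom_idx[0], starts[0], lengths)
        ]
        if excl is not None:
            for iv in ivs:
                arr = excl.get(iv.chrom)
                if arr is not None and len(arr):
                    i0 = np.searchsorted(arr[:, 1], iv.start, "right")
                    i1 = np.searchsorted(arr[:, 0], iv.end, "left")
                    if i1 > i0:
                        return None
        if non_overlapping:
            seen: dict[str, list[tuple[int, int]]] = {}
            for iv in ivs:
                seen.setdefault(iv.chrom, []).append((iv.start, iv.end))
            for pairs in seen.values():
                pairs.sort()
                for (s1, e1), (s2, _) in zip(pairs, pairs[1:]):
                    if s2 < e1:
                        return None
        return ivs

    for _ in range(max_tries):
        ivs = attempt()
        if ivs is not None:
            return RegionSet(ivs, label=regions.label)
    raise RuntimeError(f"no valid placement found in {max_tries} tries")


def overlap_count(query: RegionSet, fixed: RegionSet, mode: str = "intervals") -> int:
    """Overlap statistic between two normalized region sets.

    ``mode='intervals'`` (default, matching regioneR's numOverlaps):
    number of query intervals overlapping >= 1 bp of *fixed*;
    ``mode='bp'``: total base pairs of intersection.  *fixed* must be
    normalized; query intervals are counted as given (not merged).
    """
    fixed_arr = fixed.by_chrom()
    total = 0
    for chrom, q in query.by_chrom().items():
        f = fixed_arr.get(chrom)
        if f is None or len(f) == 0:
            continue
        if mode == "intervals":
            hit = np.searchsorted(f[:, 0], q[:, 1], "left") > np.searchsorted(
                f[:, 1], q[:, 0], "right"
            )
            total += int(hit.sum())
        elif mode == "bp":
            for s, e in q:
                i0 = int(np.searchsorted(f[:, 1], s, "right"))
                i1 = int(np.searchsorted(f[:, 0], e, "left"))
                if i1 > i0:
                    ov = np.minimum(f[i0:i1, 1], e) - np.maximum(f[i0:i1, 0], s)
                    total += int(np.clip(ov, 0, None).sum())
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return total


def perm_test(
    query: RegionSet,
    fixed: RegionSet,
    layout: GenomeLayout,
    n_perm: int = 1000,
    alternative: str = "greater",
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    mode: str = "intervals",
    alpha: float = 0.05,
) -> PermutationResult:
    """Permutation overlap test of *query* against *fixed*.

    The null sample holds the overlap count of each of *n_perm*
    uniform re-distributions of the query regions (lengths preserved,
    overlaps among the randomized regions allowed, as in regioneR's
    default).  A degenerate null (sd = 0) yields ``z = nan`` while the
    empirical p stays valid.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    if rng is None:
        rng = np.random.default_rng(seed)
    # the query is NOT merged: the statistic counts query intervals as given,
    # and the null re-places exactly those intervals (regioneR semantics)
    fnorm = normalize(fixed, layout)
    observed = overlap_count(query, fnorm, mode=mode)

    lengths = np.array([iv.length for iv in query], dtype=np.int64)
    names = layout.names
    chrom_idx, starts = _sample_placements(lengths, layout, rng, size=n_perm)
    ends = starts + lengths[None, :]
    fixed_arr = fnorm.by_chrom()
    if mode == "intervals":
        null = np.zeros(n_perm, dtype=np.int64)
        for ci, chrom in enumerate(names):
            f = fixed_arr.get(chrom)
            sel = chrom_idx == ci
            if f is None or len(f) == 0 or not sel.any():
                continue
            hit = np.searchsorted(f[:, 0], ends, "left") > np.searchsorted(
                f[:, 1], starts, "right"
            )
            null += (hit & sel).sum(axis=1)
        null = null.astype(float)
    else:
        null = np.array(
            [
                overlap_count(
                    RegionSet.from_arrays(
                        {
                            chrom: np.stack(
                                [starts[i][chrom_idx[i] == ci], ends[i][chrom_idx[i] == ci]],
                                axis=1,
                            )
                            for ci, chrom in enumerate(names)
                        }
                    ),
                    fnorm,
                    mode="bp",
                )
                for i in range(n_perm)
            ],
            dtype=float,
        )

    if alternative == "greater":
        extreme = int(np.sum(null >= observed))
    else:
        extreme = int(np.sum(null <= observed))
    p = (extreme + 1) / (n_perm + 1)
    sd = float(np.std(null, ddof=1))
    z = (observed - float(np.mean(null))) / sd if sd > 0 else float("nan")
    return PermutationResult(
        observed=float(observed),
        null_sample=null,
        p_empirical=float(p),
        z_score=z,
        alternative=alternative,
        n_perm=n_perm,
        seed=seed,
        alpha=alpha,
    )
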