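"""Densely-interacting-domain (TAD) calling by dynamic programming.

The caller follows the Armatus scheme: score every candidate bin window
``[k, l]`` by its *scaled density* — the sum of contact counts over the
strict upper triangle of the window, divided by ``d**gamma`` where
``d = l - k + 1`` is the window length in bins — minus the mean scaled
density ``mu[d]`` of all windows of the same length on that chromosome.
A window whose scaled density exceeds the length-matched expectation
has positive quality; the optimal segmentation is the set of disjoint
windows maximising total quality, found exactly by dynamic programming
in ``O(n * max_bins)``.

``gamma`` trades domain size against density: larger values favour
smaller, denser domains.  The default 0.4 at 5-kb bins reproduces the
regime in which rice chromatin domains have a ~35-kb median size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .contact_matrix import ContactMatrix, DEFAULT_RESOLUTION
from .genome_intervals import GenomeLayout, GenomicInterval, RegionSet, complement

__all__ = [
    "DomainParams",
    "Domain",
    "DomainSet",
    "window_sum",
    "mu_profile",
    "quality",
    "optimal_segmentation",
    "call_tads",
    "domain_recovery_f1",
]

DEFAULT_GAMMA = 0.4


@dataclass
class DomainParams:
    """Parameters of the quality function and the segmentation."""

    gamma: float = DEFAULT_GAMMA
    min_bins: int = 2
    max_bins: int | None = None  # None -> chromosome length in bins

    def __post_init__(self):
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")
        if self.min_bins < 2:
            raise ValueError("min_bins must be >= 2 (1-bin windows have no pairs)")
        if self.max_bins is not None and self.max_bins < self.min_bins:
            raise ValueError("max_bins must be >= min_bins")


@dataclass
class Domain:
    chrom: str
    bin_start: int  # inclusive
    bin_end: int  # inclusive
    quality: float
    interval: GenomicInterval


@dataclass
class DomainSet:
    """Disjoint domains per chromosome plus the inter-domain complement."""

    domains: list[Domain]
    inter: RegionSet
    total_score: float
    resolution: int = DEFAULT_RESOLUTION

    def tad_regions(self, label: str = "TAD") -> RegionSet:
        return RegionSet([d.interval for d in self.domains], label=label)

    def domains_on(self, chrom: str) -> list[Domain]:
        return [d for d in self.domains if d.chrom == chrom]


class _WindowSums:
    """O(1) strict-upper-triangle window sums via a 2-D integral image."""

    def __init__(self, counts: np.ndarray):
        n = counts.shape[0]
        I = np.zeros((n + 1, n + 1))
        I[1:, 1:] = counts.cumsum(axis=0).cumsum(axis=1)
        self.I = I
        self.diag = np.concatenate([[0.0], np.cumsum(np.diag(counts))])
        self.n = n

    def __call__(self, k, l):
        """Sum of counts[i][j] over k <= i < j <= l (vectorised in k, l)."""
        I, diag = self.I, self.diag
        block = I[l + 1, l + 1] - I[k, l + 1] - I[l + 1, k] + I[k, k]
        return (block - (diag[l + 1] - diag[k])) / 2.0


def window_sum(m: ContactMatrix, k: int, l: int) -> float:
    """Sum of contacts over the strict upper triangle of bins ``[k, l]``."""
    n = m.n_bins
    if not (0 <= k <= l < n):
        raise IndexError(f"window [{k},{l}] out of range for {n} bins")
    return float(_WindowSums(m.counts)(k, l))


def mu_profile(m: ContactMatrix, gamma: float, max_bins: int | None = None) -> np.ndarray:
    """Mean scaled density per window length.

    Returns an array ``mu`` indexed by window length ``d`` (entries 0 and
    1 are zero) where ``mu[d]`` is the mean over all start positions of
    ``window_sum(k, k+d-1) / d**gamma``.
    """
    n = m.n_bins
    dmax = n if max_bins is None else min(max_bins, n)
    ws = _WindowSums(m.counts)
    mu = np.zeros(dmax + 1)
    for d in range(2, dmax + 1):
        k = np.arange(0, n - d + 1)
        mu[d] = float(np.mean(ws(k, k + d - 1))) / d**gamma
    return mu


def quality(
    m: ContactMatrix, k: int, l: int, gamma: float, mu: np.ndarray
) -> float:
    """Scaled density of window ``[k, l]`` minus its length-matched mean."""
    d = l - k + 1
    if d >= len(mu):
        raise ValueError(f"window length {d} exceeds mu profile ({len(mu) - 1})")
    return window_sum(m, k, l) / d**gamma - mu[d]


def _segment(
    m: ContactMatrix, params: DomainParams
) -> tuple[list[tuple[int, int, float]], float]:
    """DP core: returns [(bin_start, bin_end, quality), ...] and total score.

    Only windows with strictly positive quality enter the objective; bins
    covered by no chosen window are inter-domain.  Ties in score are broken
    toward fewer domains, then toward the leftmost domain start.
    """
    n = m.n_bins
    dmax = n if params.max_bins is None else min(params.max_bins, n)
    ws = _WindowSums(m.counts)
    mu = mu_profile(m, params.gamma, dmax)
    ds = np.arange(params.min_bins, dmax + 1)
    scale = ds.astype(float) ** params.gamma

    best = np.zeros(n + 1)  # best[i]: optimum over the first i bins
    ndom = np.zeros(n + 1, dtype=np.int64)
    choice = np.zeros(n + 1, dtype=np.int64)  # 0 = skip; d = domain length d
    for i in range(1, n + 1):
        best[i], ndom[i], choice[i] = best[i - 1], ndom[i - 1], 0
        usable = ds[ds <= i]
        if usable.size == 0:
            continue
        ks = i - usable
        q = ws(ks, i - 1) / scale[: usable.size] - mu[usable]
        pos = q > 0
        if not np.any(pos):
            continue
        cand = best[ks[pos]] + q[pos]
        cand_nd = ndom[ks[pos]] + 1
        cand_d = usable[pos]
        # lexicographic: max score, then fewer domains, then larger d
        # (larger d = leftmost start of the final domain)
        order = np.lexsort((-cand_d, cand_nd, -cand))
        j = order[0]
        if cand[j] > best[i] or (cand[j] == best[i] and cand_nd[j] < ndom[i]):
            best[i] = cand[j]
            ndom[i] = cand_nd[j]
            choice[i] = cand_d[j]

    doms: list[tuple[int, int, float]] = []
    i = n
    while i > 0:
        d = int(choice[i])
        if d == 0:
            i -= 1
        else:
            k, l = i - d, i - 1
            doms.append((k, l, float(ws(np.int64(k), np.int64(l)) / d**params.gamma - mu[d])))
            i -= d
    doms.reverse()
    return doms, float(best[n])


def optimal_segmentation(
    m: ContactMatrix,
    params: DomainParams | None = None,
    chrom_length: int | None = None,
) -> DomainSet:
    """Globally optimal disjoint-domain segmentation of one chromosome."""
    params = params or DomainParams()
    length = chrom_length if chrom_length is not None else m.n_bins * m.resolution
    doms, total = _segment(m, params)
    domains = [
        Domain(
            chrom=m.chrom,
            bin_start=k,
            bin_end=l,
            quality=q,
            interval=GenomicInterval(
                m.chrom, k * m.resolution, min((l + 1) * m.resolution, length)
            ),
        )
        for k, l, q in doms
    ]
    layout = GenomeLayout([(m.chrom, length)])
    inter = complement(RegionSet([d.interval for d in domains], "TAD"), layout)
    inter.label = "inter-TAD"
    return DomainSet(domains, inter, total, resolution=m.resolution)


def call_tads(
    matrices: dict[str, ContactMatrix],
    params: DomainParams | None = None,
    layout: GenomeLayout | None = None,
) -> DomainSet:
    """Per-chromosome segmentation in bp coordinates.

    Domain ``[bin_start, bin_end]`` maps to
    ``[bin_start * res, (bin_end + 1) * res)`` clipped to the chromosome
    length; bins in no domain form the inter-TAD complement.
    """
    params = params or DomainParams()
    if layout is None:
        layout = GenomeLayout(
            [(c, m.n_bins * m.resolution) for c, m in matrices.items()]
        )
    all_domains: list[Domain] = []
    total = 0.0
    resolution = DEFAULT_RESOLUTION
    for chrom in layout.names:
        if chrom not in matrices:
            continue
        m = matrices[chrom]
        resolution = m.resolution
        ds = optimal_segmentation(m, params, chrom_length=layout.length_of(chrom))
        all_domains.extend(ds.domains)
        total += ds.total_score
    tads = RegionSet([d.interval for d in all_domains], "TAD")
    inter = complement(tads, layout)
    inter.label = "inter-TAD"
    return DomainSet(all_domains, inter, total, resolution=resolution)


def domain_recovery_f1(
    called: list[tuple[int, int]],
    truth: list[tuple[int, int]],
    tol_bins: int = 1,
) -> float:
    """Domain-level recovery F1 between called and true bin-domains.

    A true domain is recovered when some called domain matches *both* its
    start and end bin within ``tol_bins``; precision is the analogous
    fraction over called domains.  Inputs are ``(bin_start, bin_end)``
    inclusive pairs.  Returns 0 when either side is empty.
    """
    if not called or not truth:
        return 0.0

    def matches(a, b):
        return abs(a[0] - b[0]) <= tol_bins and abs(a[1] - b[1]) <= tol_bins

    recalled = sum(any(matches(t, c) for c in called) for t in truth)
    precise = sum(any(matches(c, t) for t in truth) for c in called)
    recall = recalled / len(truth)
    precision = precise / len(called)
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def domains_to_bins(regions: RegionSet, resolution: int) -> list[tuple[int, int]]:
    """bp intervals -> inclusive ``(bin_start, bin_end)`` pairs by rounding."""
    out = []
    for iv in regions:
        b0 = int(round(iv.start / resolution))
        b1 = int(round(iv.end / resolution)) - 1
        if b1 >= b0:
            out.append((b0, b1))
    return out
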