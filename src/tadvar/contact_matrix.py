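"""Binned Hi-C contact matrices in the Hi-C-Pro sparse dialect.

Hi-C-Pro emits a bins BED (``chrom  start  end  bin_id``, ids global and
1-based by convention) plus a triplet matrix file (``bin_i  bin_j
count``) holding the upper triangle of the genome-wide matrix.  We read
that pair of files into dense per-chromosome symmetric matrices —
domains are intra-chromosomal, so inter-chromosomal entries are dropped
— and optionally ICE-balance them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .genome_intervals import GenomeLayout

__all__ = ["ContactMatrix", "read_hicpro", "write_hicpro", "ice_balance"]

DEFAULT_RESOLUTION = 5000  # bp per bin


@dataclass
class ContactMatrix:
    """Symmetric binned interaction counts for one chromosome."""

    chrom: str
    resolution: int
    counts: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=float)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("counts must be a square matrix")
        if not np.all(np.isfinite(c)) or np.any(c < 0):
            raise ValueError("counts must be finite and non-negative")
        if not np.allclose(c, c.T):
            raise ValueError("counts must be symmetric")
        self.counts = c

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]


def _read_bins_bed(bins_bed_path: str | Path):
    """bin_id -> (chrom, start, end); also per-chrom bin index and count."""
    bins: dict[int, tuple[str, int, int]] = {}
    for line in Path(bins_bed_path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        chrom, start, end, bin_id = line.rstrip("\n").split("\t")[:4]
        bins[int(bin_id)] = (chrom, int(start), int(end))
    return bins


def read_hicpro(
    matrix_path: str | Path,
    bins_bed_path: str | Path,
    layout: GenomeLayout | None = None,
) -> dict[str, ContactMatrix]:
    """Read a Hi-C-Pro matrix into per-chromosome dense matrices.

    Absent pairs are zero; entries are placed symmetrically; pairs of
    bins on different chromosomes are ignored.  Unknown bin ids and
    conflicting duplicate entries raise ``ValueError``.
    """
    bins = _read_bins_bed(bins_bed_path)
    # per-chromosome local index of each global bin id
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for bid, (chrom, start, end) in bins.items():
        by_chrom.setdefault(chrom, []).append((start, end, bid))
    local: dict[int, tuple[str, int]] = {}
    sizes: dict[str, int] = {}
    resolutions: dict[str, int] = {}
    for chrom, rows in by_chrom.items():
        rows.sort()
        sizes[chrom] = len(rows)
        widths = [e - s for s, e, _ in rows]
        resolutions[chrom] = int(max(widths))  # trailing bin may be shorter
        for idx, (_, _, bid) in enumerate(rows):
            local[bid] = (chrom, idx)

    mats = {
        chrom: np.zeros((n, n), dtype=float) for chrom, n in sizes.items()
    }
    seen: dict[tuple[int, int], float] = {}
    for line in Path(matrix_path).read_text().splitlines():
        if not line.strip():
            continue
        a, b, c = line.split()[:3]
        i, j, count = int(a), int(b), float(c)
        for bid in (i, j):
            if bid not in local:
                raise ValueError(f"bin id {bid} not present in bins BED")
        key = (min(i, j), max(i, j))
        if key in seen:
            if seen[key] != count:
                raise ValueError(f"conflicting duplicate entry for bins {key}")
            continue
        seen[key] = count
        ci, li = local[i]
        cj, lj = local[j]
        if ci != cj:
            continue  # inter-chromosomal: dropped
        mats[ci][li, lj] = count
        mats[ci][lj, li] = count

    if layout is not None:
        order = [c for c in layout.names if c in mats]
    else:
        order = sorted(mats)
    return {
        chrom: ContactMatrix(chrom, resolutions[chrom], mats[chrom])
        for chrom in order
    }


def write_hicpro(
    matrices: dict[str, ContactMatrix],
    matrix_path: str | Path,
    bins_bed_path: str | Path,
    layout: GenomeLayout | None = None,
) -> None:
    """Write per-chromosome matrices back to the Hi-C-Pro pair of files.

    Bin ids are global, 1-based, in layout order; only the upper
    triangle (including diagonal) of nonzero entries is emitted.
    """
    order = (
        [c for c in layout.names if c in matrices] if layout else sorted(matrices)
    )
    offset = 0
    offsets: dict[str, int] = {}
    with open(bins_bed_path, "w") as fh:
        for chrom in order:
            m = matrices[chrom]
            offsets[chrom] = offset
            length = layout.length_of(chrom) if layout else m.n_bins * m.resolution
            for b in range(m.n_bins):
                start = b * m.resolution
                end = min(start + m.resolution, length)
                fh.write(f"{chrom}\t{start}\t{end}\t{offset + b + 1}\n")
            offset += m.n_bins
    with open(matrix_path, "w") as fh:
        for chrom in order:
            m = matrices[chrom]
            off = offsets[chrom]
            ii, jj = np.nonzero(np.triu(m.counts))
            for i, j in zip(ii, jj):
                v = m.counts[i, j]
                txt = f"{v:.10g}"
                fh.write(f"{off + i + 1}\t{off + j + 1}\t{txt}\n")


def ice_balance(
    m: ContactMatrix, max_iter: int = 200, tol: float = 1e-6
) -> tuple[ContactMatrix, np.ndarray]:
    """Iterative correction: equalise marginals of non-empty bins.

    Bins whose raw marginal is zero are masked (bias 0, row untouched).
    Returns the balanced matrix and the per-bin bias vector such that
    ``balanced = counts / outer(bias, bias)`` on unmasked bins.  If the
    iteration does not converge within *max_iter*, a warning is issued
    and the best iterate returned.
    """
    W = m.counts.copy()
    marginal = W.sum(axis=0)
    mask = marginal == 0
    bias = np.ones(m.n_bins)
    converged = False
    for _ in range(max_iter):
        s = W.sum(axis=0)
        active = s[~mask]
        if active.size == 0:
            break
        db = s / active.mean()
        db[mask] = 1.0
        W = W / np.outer(db, db)
        bias *= db
        if np.abs(db - 1.0).max() < tol:
            converged = True
            break
    if not converged and not np.all(mask):
        warnings.warn(f"ICE did not converge within {max_iter} iterations")
    bias[mask] = 0.0
    W[mask, :] = m.counts[mask, :]
    W[:, mask] = m.counts[:, mask]
    return ContactMatrix(m.chrom, m.resolution, W), bias


def write_dense_tsv(m: ContactMatrix, path: str | Path) -> None:
    """Dense matrix TSV, for debugging."""
    np.savetxt(path, m.counts, delimiter="\t", fmt="%.6g")
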