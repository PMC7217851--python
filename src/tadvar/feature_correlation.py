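"""Genome-binned feature table and correlation matrix.

The genome is tiled into fixed, non-overlapping windows (40 kb by
default; the trailing partial bin of each chromosome is kept with its
true length).  Point and interval features become densities per kb in
each bin; signal tracks become length-weighted means.  Pairwise
correlations are computed as Pearson on log2-transformed values
(``log2(x + 0.1)``), Pearson on raw values, or Spearman on raw values,
with per-cell significance from the t statistic
``t = r * sqrt((n - 2) / (1 - r^2))`` with ``n − 2`` degrees of freedom
(the cor.mtest construction) and a mask at ``p < alpha``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .genome_intervals import GenomeLayout, RegionSet
from .tracks import PointTrack, SignalTrack

__all__ = ["bin_features", "log2_shift", "correlate", "CorrelationReport"]

DEFAULT_BIN_BP = 40_000
COORD_COLUMNS = ("chrom", "start", "end")


def _tile(layout: GenomeLayout, bin_bp: int) -> pd.DataFrame:
    rows = []
    for chrom, length in layout.chroms:
        edges = list(range(0, length, bin_bp)) + [length]
        for s, e in zip(edges[:-1], edges[1:]):
            rows.append((chrom, s, e))
    return pd.DataFrame(rows, columns=list(COORD_COLUMNS))


def bin_features(
    layout: GenomeLayout,
    features: Mapping[str, PointTrack | SignalTrack | RegionSet],
    bin_bp: int = DEFAULT_BIN_BP,
) -> pd.DataFrame:
    """Tile the genome and compute one column per feature.

    Point tracks → events per kb; interval features (RegionSet) → number
    of intervals overlapping the bin per kb (an interval spanning two
    bins counts once in each); signal tracks → length-weighted mean
    (NaN where the bin has no signal coverage).
    """
    table = _tile(layout, bin_bp)
    starts = table["start"].to_numpy()
    ends = table["end"].to_numpy()
    chroms = table["chrom"].to_numpy()
    kb = (ends - starts) / 1000.0
    for name, feat in features.items():
        col = np.full(len(table), np.nan)
        for chrom in layout.names:
            sel = chroms == chrom
            if not sel.any():
                continue
            s, e = starts[sel], ends[sel]
            if isinstance(feat, PointTrack):
                col[sel] = feat.counts_in_many(chrom, s, e) / kb[sel]
            elif isinstance(feat, RegionSet):
                arr = feat.by_chrom().get(chrom)
                if arr is None or len(arr) == 0:
                    col[sel] = 0.0
                else:
                    n = np.searchsorted(arr[:, 0], e, "left") - np.searchsorted(
                        arr[:, 1], s, "right"
                    )
                    col[sel] = n / kb[sel]
            elif isinstance(feat, SignalTrack):
                col[sel] = [
                    feat.mean_in(chrom, int(si), int(ei)) for si, ei in zip(s, e)
                ]
            else:
                raise TypeError(f"unsupported feature type for {name!r}")
        table[name] = col
    return table


def log2_shift(table: pd.DataFrame, pseudo: float | str = 0.1) -> pd.DataFrame:
    """``x -> log2(x + pseudo)`` on all feature columns.

    ``pseudo='median'`` resolves to the median over all feature cells of
    the table (the convention used to avoid log2(0)); an explicit pseudo
    must be positive.
    """
    cols = [c for c in table.columns if c not in COORD_COLUMNS]
    values = table[cols].to_numpy(dtype=float)
    if np.nanmin(values) < 0:
        raise ValueError("log2_shift requires all values >= 0")
    if pseudo == "median":
        pseudo = float(np.nanmedian(values))
    pseudo = float(pseudo)
    if pseudo <= 0:
        raise ValueError("pseudo-count must be positive")
    out = table.copy()
    out[cols] = np.log2(values + pseudo)
    return out


@dataclass
class CorrelationReport:
    method: str
    r: pd.DataFrame
    p: pd.DataFrame
    mask: pd.DataFrame  # True where p < alpha
    alpha: float
    n: pd.DataFrame  # pairwise-complete sample sizes

    def to_long(self) -> pd.DataFrame:
        rows = []
        feats = list(self.r.columns)
        for i, a in enumerate(feats):
            for b in feats[i + 1 :]:
                rows.append(
                    {
                        "feature_a": a,
                        "feature_b": b,
                        "method": self.method,
                        "r": self.r.loc[a, b],
                        "p": self.p.loc[a, b],
                        "n": self.n.loc[a, b],
                        "significant": bool(self.mask.loc[a, b]),
                    }
                )
        return pd.DataFrame(rows)

    def write_tsv(self, path: str | Path) -> None:
        self.to_long().to_csv(path, sep="\t", index=False, float_format="%.6g")


def _pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < 3:
        return np.nan, np.nan, n
    x, y = x[ok], y[ok]
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("constant column in correlation; r undefined")
        return np.nan, np.nan, n
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(min(r, 1.0), -1.0)
    if abs(r) == 1.0:
        return r, 0.0, n
    t = r * np.sqrt((n - 2) / (1 - r * r))
    p = 2 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p), n


def correlate(
    table: pd.DataFrame,
    method: str = "pearson_log2",
    alpha: float = 0.05,
    pseudo: float | str = 0.1,
) -> CorrelationReport:
    """Pairwise feature correlations with significance masking.

    Methods: ``pearson_log2`` (Pearson after ``log2(x + pseudo)``),
    ``pearson_raw``, ``spearman_raw`` (Pearson on ranks).  NaN cells are
    dropped pairwise.  Constant columns yield NaN with a warning.
    """
    if method not in ("pearson_log2", "pearson_raw", "spearman_raw"):
        raise ValueError(f"unknown method {method!r}")
    if method == "pearson_log2":
        table = log2_shift(table, pseudo=pseudo)
    cols = [c for c in table.columns if c not in COORD_COLUMNS]
    if len(table) < 3:
        raise ValueError("need at least 3 bins")
    data = {c: table[c].to_numpy(dtype=float) for c in cols}
    k = len(cols)
    r = np.eye(k)
    p = np.zeros((k, k))
    n = np.full((k, k), len(table), dtype=int)
    for i in range(k):
        for j in range(i + 1, k):
            x, y = data[cols[i]], data[cols[j]]
            if method == "spearman_raw":
                ok = np.isfinite(x) & np.isfinite(y)
                xr = np.full_like(x, np.nan)
                yr = np.full_like(y, np.nan)
                xr[ok] = stats.rankdata(x[ok])
                yr[ok] = stats.rankdata(y[ok])
                rij, pij, nij = _pearson_with_p(xr, yr)
            else:
                rij, pij, nij = _pearson_with_p(x, y)
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij
            n[i, j] = n[j, i] = nij
    rdf = pd.DataFrame(r, index=cols, columns=cols)
    pdf = pd.DataFrame(p, index=cols, columns=cols)
    ndf = pd.DataFrame(n, index=cols, columns=cols)
    mask = pdf < alpha
    np.fill_diagonal(mask.values, False)
    return CorrelationReport(method=method, r=rdf, p=pdf, mask=mask, alpha=alpha, n=ndf)
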