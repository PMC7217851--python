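"""Reference implementations used to validate the fast paths.

These are deliberately naive and kept independent of the production
algorithms: the exhaustive segmentation enumerator recomputes window
qualities from first principles and explores every set of disjoint bin
intervals, so agreement with the dynamic program certifies the DP's
optimality on small inputs.
"""

from __future__ import annotations

import numpy as np

from .contact_matrix import ContactMatrix
from .tad_caller import DomainParams

__all__ = ["exhaustive_segmentation_score"]


def _naive_window_sum(counts: np.ndarray, k: int, l: int) -> float:
    total = 0.0
    for i in range(k, l + 1):
        for j in range(i + 1, l + 1):
            total += counts[i, j]
    return total


def exhaustive_segmentation_score(m: ContactMatrix, params: DomainParams) -> float:
    """Best total quality over all sets of disjoint bin intervals.

    Brute-force enumeration (only feasible for small matrices): window
    sums, the mu profile and qualities are all recomputed naively, and
    every segmentation is explored recursively.  Only windows with
    strictly positive quality contribute, matching the caller's
    objective.
    """
    n = m.n_bins
    dmax = n if params.max_bins is None else min(params.max_bins, n)
    counts = m.counts
    mu = np.zeros(dmax + 1)
    for d in range(2, dmax + 1):
        vals = [
            _naive_window_sum(counts, k, k + d - 1) / d**params.gamma
            for k in range(0, n - d + 1)
        ]
        mu[d] = float(np.mean(vals))

    q = {
        (k, k + d - 1): _naive_window_sum(counts, k, k + d - 1) / d**params.gamma
        - mu[d]
        for d in range(params.min_bins, dmax + 1)
        for k in range(0, n - d + 1)
    }

    def best_from(i: int) -> float:
        if i >= n:
            return 0.0
        # either bin i is in no domain ...
        best = best_from(i + 1)
        # ... or a domain of length d starts at i
        for d in range(params.min_bins, min(dmax, n - i) + 1):
            qi = q[(i, i + d - 1)]
            if qi > 0:
                best = max(best, qi + best_from(i + d))
        return best

    return best_from(0)
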