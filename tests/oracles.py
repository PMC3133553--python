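"""Independent brute-force oracle for the gated local alignment score.

The oracle enumerates every pair of contiguous sub-lists of the two peak
sequences and, for each pair, the best fully gapped global alignment by
depth-first recursion over the three moves (match/mismatch, gap, gap) using
the same pair scores w and gap penalty d. No zero clamp, no score matrix, no
traceback — an entirely separate formulation of the same optimum.
"""

from functools import lru_cache

import numpy as np


def gated_weights(sim: np.ndarray, u: float, v: float, rho: float) -> np.ndarray:
    return np.where(sim >= rho, u * sim, -v)


def brute_force_best_local_score(sim, u, v, rho, d) -> float:
    W = gated_weights(np.asarray(sim, float), u, v, rho)
    m, n = W.shape

    @lru_cache(maxsize=None)
    def best_global(h, i, k, j):
        # optimal gapped alignment of X[h..i) against Y[k..j), depth-first
        if h == i:
            return -d * (j - k)
        if k == j:
            return -d * (i - h)
        return max(
            W[h, k] + best_global(h + 1, i, k + 1, j),
            -d + best_global(h + 1, i, k, j),
            -d + best_global(h, i, k + 1, j),
        )

    best = 0.0
    for h in range(m):
        for i in range(h + 1, m + 1):
            for k in range(n):
                for j in range(k + 1, n + 1):
                    best = max(best, best_global(h, i, k, j))
    return best


def segment_score(segment, sim, u, v, rho, d) -> float:
    """Score of one traceback segment under the same w and d."""
    W = gated_weights(np.asarray(sim, float), u, v, rho)
    total = 0.0
    for st in segment:
        total += W[st.i, st.j] if st.kind == "match" else -d
    return total
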