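"""Similarity-gated Smith-Waterman scoring for ordered peak lists.

Peaks take the place of sequence residues: the match/mismatch score for the
cell (i, j) is gated by the mass-spectral similarity S(x_i, y_j) against the
user cut-off rho,

    w(i, j) = u * S(x_i, y_j)   if S(x_i, y_j) >= rho
            = -v                otherwise,

and this w replaces the usual m(i,j) in the local-alignment recurrence

    H(i, j) = max{0, H(i-1, j-1) + w(i, j), H(i-1, j) - d, H(i, j-1) - d}

with zero initialization along row 0 and column 0 and a linear gap penalty d.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .peaks import PeakList

__all__ = ["SWParams", "ScoreMatrix", "pair_score_w", "build_score_matrix", "METHOD_NAMES"]

#: method index -> traceback variant name
METHOD_NAMES = {1: "SWRM", 2: "SWRE", 3: "SWRME"}
METHOD_INDEX = {v.lower(): k for k, v in METHOD_NAMES.items()}


@dataclass(frozen=True)
class SWParams:
    """Scoring constants for the gated Smith-Waterman alignment.

    u : match weight (reward is u * similarity)
    v : mismatch penalty magnitude (applied when similarity < rho)
    d : linear gap penalty
    rho : spectral-similarity cut-off in [0, 1]; gates both the match reward
        and the post-alignment pair filter (boundary S == rho counts as match)
    q : traceback variant, 1 = SWRM, 2 = SWRE, 3 = SWRME
    """

    u: float = 1.0
    v: float = 1.0
    d: float = 0.5
    rho: float = 0.8
    q: int = 1

    def __post_init__(self) -> None:
        if self.u < 0 or self.v < 0 or self.d < 0:
            raise ValueError("u, v, d must be non-negative")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError(f"rho must lie in [0, 1], got {self.rho}")
        if self.q not in METHOD_NAMES:
            raise ValueError(f"method index q must be in {{1,2,3}}, got {self.q}")

    @property
    def method_name(self) -> str:
        return METHOD_NAMES[self.q]


@dataclass(frozen=True)
class ScoreMatrix:
    """Bordered (m+1) x (n+1) score matrix H with its parameter provenance."""

    H: np.ndarray
    params: SWParams

    @property
    def m(self) -> int:
        return self.H.shape[0] - 1

    @property
    def n(self) -> int:
        return self.H.shape[1] - 1


def pair_score_w(S_ij: float, p: SWParams) -> float:
    """Gated pair score w(i, j): u*S if S >= rho, else -v."""
    return p.u * S_ij if S_ij >= p.rho else -p.v


def build_score_matrix(
    X: PeakList | None, Y: PeakList | None, sim: np.ndarray, p: SWParams
) -> ScoreMatrix:
    """Fill the local-alignment score matrix from a precomputed similarity matrix.

    ``X``/``Y`` are accepted for dimension checking and may be None when the
    caller works from the similarity matrix alone.
    """
    sim = np.asarray(sim, dtype=float)
    if sim.ndim != 2:
        raise ValueError("similarity matrix must be 2-D")
    m, n = sim.shape
    if X is not None and len(X) != m:
        raise ValueError(f"similarity matrix has {m} rows but reference has {len(X)} peaks")
    if Y is not None and len(Y) != n:
        raise ValueError(f"similarity matrix has {n} cols but target has {len(Y)} peaks")

    W = np.where(sim >= p.rho, p.u * sim, -p.v)
    H = np.zeros((m + 1, n + 1))
    for i in range(1, m + 1):
        Hi, Hprev, Wrow = H[i], H[i - 1], W[i - 1]
        for j in range(1, n + 1):
            Hi[j] = max(
                0.0, Hprev[j - 1] + Wrow[j - 1], Hprev[j] - p.d, Hi[j - 1] - p.d
            )
    return ScoreMatrix(H=H, params=p)


def dump_matrix_tsv(sm: ScoreMatrix, path) -> None:
    """Write the bordered score matrix as TSV with 6-decimal entries."""
    np.savetxt(path, sm.H, fmt="%.6f", delimiter="\t")
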