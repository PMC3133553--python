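"""Repeat-traceback local alignment of two peak lists.

The classic Smith-Waterman traceback yields a single local alignment; peak
lists from two chromatographic runs typically share several conserved
stretches separated by unmatched peaks, so three modified tracebacks emit
*repeated* local alignments from one score matrix:

SWRM  (repeat alignment, maximum scores)
    start at the global maximum of H, trace back to a zero cell (s, t), then
    repeat inside the sub-matrix rows 1..s, columns 1..t, until the start of
    the matrix is reached or the remaining region is all zero.

SWRE  (repeat alignment, ending scores)
    start at the corner cell (m, n); on hitting a zero-valued cell the walk
    slides (emitting nothing) to the predecessor with maximal H and resumes
    normal traceback at the next positive cell, terminating at the border.

SWRME (repeat alignment, maximum of ending scores)
    scan column n (then n-1, ...) for its maximal entry until a non-zero one
    is found, trace back from it, then repeat the column scan in the
    remaining sub-matrix.

After traceback, matched pairs whose spectral similarity falls below the
cut-off rho are discarded (the post-filter); the retained pairs are the
alignment. All indices in steps and pairs are 0-based positions into the
*ordered* peak lists.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

from .peaks import PeakList, order_peaklist
from .similarity import similarity_matrix
from .sw import ScoreMatrix, SWParams, build_score_matrix

__all__ = [
    "AlignmentStep",
    "AlignmentResult",
    "traceback_single",
    "traceback_swrm",
    "traceback_swre",
    "traceback_swrme",
    "postfilter_pairs",
    "align_peaklists",
]


@dataclass(frozen=True)
class AlignmentStep:
    """One traceback step: a matched pair or a gap in either list (0-based)."""

    kind: Literal["match", "gap_in_X", "gap_in_Y"]
    i: Optional[int] = None  # reference index (absent for gap_in_X)
    j: Optional[int] = None  # target index (absent for gap_in_Y)

    def __post_init__(self) -> None:
        if self.kind == "match" and (self.i is None or self.j is None):
            raise ValueError("match step needs both indices")
        if self.kind == "gap_in_X" and (self.i is not None or self.j is None):
            raise ValueError("gap_in_X consumes a target peak only")
        if self.kind == "gap_in_Y" and (self.i is None or self.j is not None):
            raise ValueError("gap_in_Y consumes a reference peak only")


@dataclass
class AlignmentResult:
    """Outcome of aligning reference X (length m) against target Y (length n).

    ``segments`` holds the raw traceback runs in discovery order;
    ``pairs`` the k retained (i, j, similarity) matches after the rho
    post-filter, sorted by ascending index.
    """

    segments: list[list[AlignmentStep]]
    pairs: list[tuple[int, int, float]]
    params: SWParams
    m: int
    n: int
    ref_name: str = ""
    target_name: str = ""

    @property
    def k(self) -> int:
        return len(self.pairs)

    def matched_index_pairs(self) -> set[tuple[int, int]]:
        return {(i, j) for i, j, _ in self.pairs}


def _weights(sim: np.ndarray, p: SWParams) -> np.ndarray:
    return np.where(np.asarray(sim, float) >= p.rho, p.u * np.asarray(sim, float), -p.v)


def _argmax_cell(H: np.ndarray, s: int, t: int) -> tuple[float, int, int]:
    """Max of H over rows 1..s, cols 1..t with deterministic tie-break.

    Ties resolve to the smallest i+j, then the smallest i.
    """
    sub = H[1 : s + 1, 1 : t + 1]
    best = sub.max()
    rows, cols = np.nonzero(sub == best)
    order = np.lexsort((rows, rows + cols))
    q, r = int(rows[order[0]]) + 1, int(cols[order[0]]) + 1
    return float(best), q, r


def _walk(
    H: np.ndarray, W: np.ndarray, d: float, i: int, j: int
) -> tuple[list[AlignmentStep], int, int]:
    """Classic traceback from cell (i, j) until a zero cell or the border.

    Predecessor ties break diagonal first, then vertical (consume x_i), then
    horizontal; diagonal preference maximizes matched pairs. Returns the
    forward-ordered steps and the cell at which the walk stopped.
    """
    steps: list[AlignmentStep] = []
    while i > 0 and j > 0 and H[i, j] > 0:
        h = H[i, j]
        if h == H[i - 1, j - 1] + W[i - 1, j - 1]:
            steps.append(AlignmentStep("match", i - 1, j - 1))
            i, j = i - 1, j - 1
        elif h == H[i - 1, j] - d:
            steps.append(AlignmentStep("gap_in_Y", i=i - 1))
            i -= 1
        else:
            steps.append(AlignmentStep("gap_in_X", j=j - 1))
            j -= 1
    steps.reverse()
    return steps, i, j


def traceback_single(sm: ScoreMatrix, sim: np.ndarray) -> list[AlignmentStep]:
    """Unmodified Smith-Waterman traceback: the best single local alignment."""
    H = sm.H
    W = _weights(sim, sm.params)
    best, q, r = _argmax_cell(H, sm.m, sm.n)
    if best <= 0:
        return []
    steps, _, _ = _walk(H, W, sm.params.d, q, r)
    return steps


def traceback_swrm(sm: ScoreMatrix, sim: np.ndarray) -> list[list[AlignmentStep]]:
    """Repeat traceback from successive sub-matrix maxima (SWRM)."""
    H = sm.H
    W = _weights(sim, sm.params)
    s, t = sm.m, sm.n
    segments: list[list[AlignmentStep]] = []
    while s >= 1 and t >= 1:
        best, q, r = _argmax_cell(H, s, t)
        if best <= 0:
            break
        steps, ei, ej = _walk(H, W, sm.params.d, q, r)
        if steps:
            segments.append(steps)
        if ei > 1 and ej > 1:
            s, t = ei, ej
        else:
            break
    return segments


def traceback_swre(sm: ScoreMatrix, sim: np.ndarray) -> list[list[AlignmentStep]]:
    """Repeat traceback walked from the corner cell (m, n) (SWRE).

    Zero-valued cells emit no steps; the walk moves to the predecessor with
    maximal H (ties diagonal, vertical, horizontal) and normal traceback
    resumes at the next positive cell.
    """
    H = sm.H
    W = _weights(sim, sm.params)
    d = sm.params.d
    i, j = sm.m, sm.n
    segments: list[list[AlignmentStep]] = []
    while i > 0 and j > 0:
        if H[i, j] > 0:
            steps, i, j = _walk(H, W, d, i, j)
            if steps:
                segments.append(steps)
        else:
            cand = ((H[i - 1, j - 1], i - 1, j - 1), (H[i - 1, j], i - 1, j), (H[i, j - 1], i, j - 1))
            best = max(c[0] for c in cand)
            for h, ci, cj in cand:  # tuple order encodes the tie-break
                if h == best:
                    i, j = ci, cj
                    break
    return segments


def traceback_swrme(sm: ScoreMatrix, sim: np.ndarray) -> list[list[AlignmentStep]]:
    """Repeat traceback from per-column ending maxima (SWRME).

    Columns are scanned right to left for the first non-zero column maximum;
    traceback runs from it, and the scan repeats in the remaining sub-matrix.
    """
    H = sm.H
    W = _weights(sim, sm.params)
    s, t = sm.m, sm.n
    segments: list[list[AlignmentStep]] = []
    while s >= 1 and t >= 1:
        start = None
        for j in range(t, 0, -1):
            col = H[1 : s + 1, j]
            best = col.max()
            if best > 0:
                start = (int(np.nonzero(col == best)[0][0]) + 1, j)
                break
        if start is None:
            break
        steps, ei, ej = _walk(H, W, sm.params.d, *start)
        if steps:
            segments.append(steps)
        if ei > 1 and ej > 1:
            s, t = ei, ej
        else:
            break
    return segments


_TRACEBACKS = {1: traceback_swrm, 2: traceback_swre, 3: traceback_swrme}


def postfilter_pairs(
    segments: Sequence[Sequence[AlignmentStep]], sim: np.ndarray, rho: float
) -> list[tuple[int, int, float]]:
    """Retain matched pairs with similarity >= rho; drop gaps and the rest.

    Returns (i, j, S_ij) triples sorted by ascending reference index; sorting
    restores elution order since segments are discovered corner-inward.
    """
    retained = [
        (st.i, st.j, float(sim[st.i, st.j]))
        for seg in segments
        for st in seg
        if st.kind == "match" and sim[st.i, st.j] >= rho
    ]
    retained.sort()
    return retained


def align_peaklists(
    X: PeakList,
    Y: PeakList,
    p: SWParams,
    *,
    assume_ordered: bool = False,
    sim: np.ndarray | None = None,
) -> AlignmentResult:
    """Full alignment pipeline: order, score, trace back (variant p.q), filter.

    ``assume_ordered``/``sim`` let a caller sweeping the (rho, q) grid reuse
    the elution ordering and the similarity matrix, which do not depend on
    the scoring parameters.
    """
    if not assume_ordered:
        X = order_peaklist(X)
        Y = order_peaklist(Y)
    if sim is None:
        sim = similarity_matrix(X, Y)
    sm = build_score_matrix(X, Y, sim, p)
    segments = _TRACEBACKS[p.q](sm, sim)
    pairs = postfilter_pairs(segments, sim, p.rho)
    return AlignmentResult(
        segments=segments,
        pairs=pairs,
        params=p,
        m=len(X),
        n=len(Y),
        ref_name=X.name,
        target_name=Y.name,
    )


def write_alignment_tsv(result: AlignmentResult, X: PeakList, Y: PeakList, path) -> None:
    """Write retained pairs as TSV (indices are 0-based into the ordered lists)."""
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(
            [
                "ref_index", "target_index", "ref_name", "target_name",
                "ref_rt1", "ref_rt2", "target_rt1", "target_rt2",
                "similarity", "segment",
            ]
        )
        seg_of = {}
        for si, seg in enumerate(result.segments):
            for st in seg:
                if st.kind == "match":
                    seg_of[(st.i, st.j)] = si
        for i, j, s in result.pairs:
            xp, yp = X[i], Y[j]
            w.writerow(
                [
                    i, j, xp.label or "", yp.label or "",
                    f"{xp.rt1:.6f}", f"{xp.rt2:.6f}", f"{yp.rt1:.6f}", f"{yp.rt2:.6f}",
                    f"{s:.6f}", seg_of.get((i, j), -1),
                ]
            )
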