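"""Mass-spectral similarity: Pearson correlation over a union m/z support.

Two fragment spectra rarely share exactly the same m/z bins, so the two
intensity vectors are first expanded onto the sorted union of their bins,
filling absent bins with zero (absent ions are evidence of difference, so
they are kept rather than intersected away). The similarity S(x_i, y_j) is
the sample Pearson correlation of the two union-support vectors.
"""

from __future__ import annotations

import warnings

import numpy as np

from .peaks import MassSpectrum, PeakList

__all__ = ["union_support", "pearson_similarity", "similarity_matrix"]


def union_support(a: MassSpectrum, b: MassSpectrum) -> tuple[np.ndarray, np.ndarray]:
    """Intensity vectors of ``a`` and ``b`` over the sorted union of m/z bins."""
    bins = np.union1d(np.asarray(a.mz, dtype=np.int64), np.asarray(b.mz, dtype=np.int64))
    va = np.zeros(bins.shape[0])
    vb = np.zeros(bins.shape[0])
    va[np.searchsorted(bins, a.mz)] = a.intensity
    vb[np.searchsorted(bins, b.mz)] = b.intensity
    return va, vb


def pearson_similarity(a: MassSpectrum, b: MassSpectrum) -> float:
    """Pearson correlation of two spectra on their union support, in [-1, 1].

    Symmetric and invariant to positive rescaling of either spectrum. A
    zero-variance (flat) vector leaves the correlation undefined; it is
    reported as 0.0 — "no evidence of identity" — with a warning, so one
    pathological peak cannot abort a whole alignment.
    """
    va, vb = union_support(a, b)
    if va.shape[0] < 2:
        raise ValueError("union m/z support has fewer than 2 bins")
    ca = va - va.mean()
    cb = vb - vb.mean()
    ssa = float(ca @ ca)
    ssb = float(cb @ cb)
    if ssa == 0.0 or ssb == 0.0:
        warnings.warn("zero-variance spectrum vector; similarity set to 0", stacklevel=2)
        return 0.0
    # num and den are symmetric in (a, b) operation order, so S(a,b) == S(b,a)
    # bit-exactly; guard against sqrt rounding pushing |r| past 1
    r = float(ca @ cb) / np.sqrt(ssa * ssb)
    return float(min(1.0, max(-1.0, r)))


def similarity_matrix(X: PeakList, Y: PeakList) -> np.ndarray:
    """m x n matrix of pairwise spectral similarities between two peak lists."""
    m, n = len(X), len(Y)
    S = np.empty((m, n))
    for i, xp in enumerate(X):
        for j, yp in enumerate(Y):
            S[i, j] = pearson_similarity(xp.spectrum, yp.spectrum)
    return S
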