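"""Likelihood functions over retained pairs and automatic (rho, method) choice.

Choosing the similarity cut-off rho by hand is data-specific; the automatic
variant sweeps a grid of cut-offs crossed with the three traceback methods
and keeps the configuration maximizing the likelihood

    LS(rho, q) = sum of the spectral similarities of the k retained pairs,

a surrogate for the (unobservable, truth-requiring) F1 score. The product
likelihood LP is computed and reported alongside but never used to select —
it rewards *fewer* retained pairs and anti-tracks alignment quality.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .align import AlignmentResult, align_peaklists
from .peaks import PeakList, order_peaklist
from .similarity import similarity_matrix
from .sw import METHOD_NAMES, SWParams

__all__ = [
    "DEFAULT_RHO_GRID",
    "OptimizationGrid",
    "OptimizationResult",
    "likelihood_sum",
    "likelihood_product",
    "select_optimal",
]

logger = logging.getLogger(__name__)

#: 13-point cut-off grid used throughout: dense to 0.9, fine steps near 1.
DEFAULT_RHO_GRID: tuple[float, ...] = (
    0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 0.93, 0.95, 0.97, 0.99,
)


@dataclass(frozen=True)
class OptimizationGrid:
    """Search grid: cut-off values x traceback method indices."""

    rho_values: tuple[float, ...] = DEFAULT_RHO_GRID
    methods: tuple[int, ...] = (1, 2, 3)

    def __post_init__(self) -> None:
        if not self.rho_values or not self.methods:
            raise ValueError("grid must have at least one rho and one method")
        if any(not 0.0 <= r <= 1.0 for r in self.rho_values):
            raise ValueError("all rho values must lie in [0, 1]")
        if any(q not in METHOD_NAMES for q in self.methods):
            raise ValueError("method indices must be in {1, 2, 3}")


@dataclass
class OptimizationResult:
    """Argmax configuration plus the full (rho, q, LS, LP, k) sweep trace."""

    rho_star: float
    q_star: int
    ls_star: float
    alignment: AlignmentResult
    trace: pd.DataFrame

    @property
    def method_name(self) -> str:
        return METHOD_NAMES[self.q_star]


def likelihood_sum(a: AlignmentResult) -> float:
    """LS: sum of retained-pair similarities; 0 for an empty alignment."""
    return float(sum(s for _, _, s in a.pairs))


def likelihood_product(a: AlignmentResult) -> float:
    """LP: product of retained-pair similarities; 0 for an empty alignment.

    The empty product is defined as 0 rather than 1 so an empty alignment can
    never be the most likely configuration.
    """
    if not a.pairs:
        return 0.0
    return float(math.prod(s for _, _, s in a.pairs))


def select_optimal(
    X: PeakList,
    Y: PeakList,
    grid: OptimizationGrid | None = None,
    p0: SWParams | None = None,
) -> OptimizationResult:
    """Run the alignment at every grid point and keep the LS maximizer.

    The elution ordering and the similarity matrix are shared across the
    sweep (they do not depend on rho or q). Argmax ties resolve toward the
    larger (more conservative) rho, then the smaller method index.
    """
    grid = grid or OptimizationGrid()
    p0 = p0 or SWParams()
    X = order_peaklist(X)
    Y = order_peaklist(Y)
    sim = similarity_matrix(X, Y)

    rows = []
    best: tuple[float, float, int] | None = None  # (LS, rho, -q) maximized
    best_alignment: AlignmentResult | None = None
    for rho in grid.rho_values:
        for q in grid.methods:
            p = SWParams(u=p0.u, v=p0.v, d=p0.d, rho=rho, q=q)
            a = align_peaklists(X, Y, p, assume_ordered=True, sim=sim)
            ls = likelihood_sum(a)
            rows.append(
                {"rho": rho, "method": q, "LS": ls, "LP": likelihood_product(a), "k": a.k}
            )
            key = (ls, rho, -q)
            if best is None or key > best:
                best, best_alignment = key, a
    trace = pd.DataFrame(rows)
    assert best is not None and best_alignment is not None
    ls_star, rho_star, neg_q = best
    if ls_star == 0.0:
        logger.warning("LS is zero over the whole grid; returning an empty alignment")
    return OptimizationResult(
        rho_star=rho_star,
        q_star=-neg_q,
        ls_star=ls_star,
        alignment=best_alignment,
        trace=trace,
    )
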