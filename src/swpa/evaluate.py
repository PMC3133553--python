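"""Truth construction and alignment scoring: TPR, PPV, F1 and batch summaries.

Ground truth comes from compound labels: a (reference, target) peak pair
carrying the same label is a positive pair, and the r positive pairs live in
a universe of m*n candidate pairs. An alignment retaining t pairs is scored
by

    TP = retained positives          FP = t - TP
    FN = r - TP                      TN = m*n - r - FP
    TPR = TP / r (recall)            PPV = TP / t (precision)
    F1  = harmonic mean of TPR and PPV.

Degenerate denominators (r = 0, t = 0, TPR = PPV = 0) yield 0 by the usual
information-retrieval conventions, keeping batch summaries total.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

from .align import AlignmentResult
from .peaks import PeakList

__all__ = [
    "TruthSet",
    "EvaluationResult",
    "BatchSummary",
    "build_truth",
    "evaluate_alignment",
    "summarize_batch",
    "make_pair_plan",
]


@dataclass(frozen=True)
class TruthSet:
    """Positive (reference index, target index) pairs sharing a label."""

    positive_pairs: frozenset[tuple[int, int]]

    @property
    def r(self) -> int:
        return len(self.positive_pairs)


@dataclass(frozen=True)
class EvaluationResult:
    TP: int
    FP: int
    FN: int
    TN: int
    t: int
    TPR: float
    PPV: float
    F1: float


@dataclass(frozen=True)
class BatchSummary:
    """Per-metric mean and standard error (sample SD / sqrt(N)) over a batch."""

    n: int
    mean: Mapping[str, float]
    se: Mapping[str, float]


def build_truth(X: PeakList, Y: PeakList) -> TruthSet:
    """Positive pairs from label equality between two deduplicated lists.

    Unlabeled peaks contribute no positives. Duplicate labels within one list
    are an error: truth requires the one-peak-per-compound invariant that
    deduplication establishes.
    """
    pos: set[tuple[int, int]] = set()
    for name, pl in (("reference", X), ("target", Y)):
        labels = [p.label for p in pl if p.label is not None]
        if len(labels) != len(set(labels)):
            dup = next(l for l in labels if labels.count(l) > 1)
            raise ValueError(f"duplicate label {dup!r} in {name} list; dedupe first")
    y_index = {p.label: j for j, p in enumerate(Y) if p.label is not None}
    for i, p in enumerate(X):
        if p.label is not None and p.label in y_index:
            pos.add((i, y_index[p.label]))
    return TruthSet(positive_pairs=frozenset(pos))


def evaluate_alignment(
    a: AlignmentResult, truth: TruthSet, m: int | None = None, n: int | None = None
) -> EvaluationResult:
    """Confusion counts and TPR/PPV/F1 of an alignment against a truth set."""
    m = a.m if m is None else m
    n = a.n if n is None else n
    retained = a.matched_index_pairs()
    r, t = truth.r, len(retained)
    TP = len(retained & truth.positive_pairs)
    FP = t - TP
    FN = r - TP
    TN = m * n - r - FP
    # counting identities, asserted on every evaluation
    assert TP + FN == r and TP + FP == t and TP <= min(r, t) and TN >= 0
    TPR = TP / r if r else 0.0
    PPV = TP / t if t else 0.0
    F1 = 2 * TPR * PPV / (TPR + PPV) if (TPR + PPV) else 0.0
    return EvaluationResult(TP=TP, FP=FP, FN=FN, TN=TN, t=t, TPR=TPR, PPV=PPV, F1=F1)


_METRICS = ("TPR", "PPV", "F1")


def summarize_batch(results: Sequence[EvaluationResult]) -> BatchSummary:
    """Mean and standard error of TPR, PPV, F1 over a batch of evaluations.

    SE uses the sample standard deviation over sqrt(N); a single result gets
    SE = 0 by convention.
    """
    if not results:
        raise ValueError("summarize_batch needs at least one result")
    n = len(results)
    mean, se = {}, {}
    for metric in _METRICS:
        vals = np.array([getattr(rr, metric) for rr in results], dtype=float)
        mean[metric] = float(vals.mean())
        se[metric] = float(vals.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return BatchSummary(n=n, mean=mean, se=se)


def make_pair_plan(
    groups: Mapping[str, Sequence], mode: Literal["homogeneous", "heterogeneous"]
) -> list[tuple[object, object]]:
    """Enumerate (reference, target) run pairs for a pairwise alignment study.

    homogeneous: all unordered within-group pairs, C(g, 2) per group;
    heterogeneous: all cross-group pairs for every couple of groups.
    """
    names = list(groups)
    if mode == "homogeneous":
        plan = []
        for name in names:
            members = list(groups[name])
            if len(members) < 2:
                raise ValueError(f"homogeneous group {name!r} needs >= 2 runs")
            plan.extend(itertools.combinations(members, 2))
        return plan
    if mode == "heterogeneous":
        if len(names) < 2:
            raise ValueError("heterogeneous mode needs >= 2 groups")
        plan = []
        for ga, gb in itertools.combinations(names, 2):
            plan.extend(itertools.product(groups[ga], groups[gb]))
        return plan
    raise ValueError(f"unknown pair-plan mode {mode!r}")
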