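"""Inter-rater agreement tools: Cohen's kappa, the confidence-threshold
sweep with kappa-based selection, and the 2x2 chi-square accuracy test.

The threshold sweep mirrors the model-selection experiment behind the
engine's default 0.80 confidence threshold: candidate thresholds from 0.50
to 0.95 in steps of 0.05 are evaluated by turning sub-threshold predictions
into abstentions (excluded from the agreement table, with the retained
fraction recorded), computing Cohen's kappa against the reference rater on
what remains, and selecting the kappa-maximizing threshold — ties broken by
the higher F1 of retained predictions, then by the smaller threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Hashable, Mapping, Sequence

import numpy as np
from scipy import stats as _stats

__all__ = [
    "RatingSeries",
    "SweepResult",
    "cohen_kappa",
    "default_grid",
    "sweep_thresholds",
    "chi_square_2x2",
]


@dataclass(frozen=True)
class RatingSeries:
    """One rater's labels over a shared item set, optionally with confidences."""

    items: tuple[Hashable, ...]
    labels: tuple[str, ...]
    confidence: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.items) != len(self.labels):
            raise ValueError("items and labels must have equal length")
        if len(set(self.items)) != len(self.items):
            raise ValueError("duplicate item ids")
        if self.confidence is not None and len(self.confidence) != len(self.items):
            raise ValueError("confidence must align with items")

    def __len__(self) -> int:
        return len(self.items)

    @classmethod
    def from_mapping(cls, labels: Mapping[Hashable, str]) -> "RatingSeries":
        keys = tuple(labels)
        return cls(keys, tuple(labels[k] for k in keys))


def _aligned_labels(a: RatingSeries, b: RatingSeries) -> tuple[list[str], list[str]]:
    if set(a.items) != set(b.items):
        raise ValueError("rating series rate different item sets")
    pos_b = {item: i for i, item in enumerate(b.items)}
    la = list(a.labels)
    lb = [b.labels[pos_b[item]] for item in a.items]
    return la, lb


def cohen_kappa(a: RatingSeries, b: RatingSeries) -> float:
    """Chance-corrected agreement kappa = (p_o - p_e) / (1 - p_e).

    p_o is the observed agreement fraction; p_e the chance agreement from
    the product of the two raters' marginal label frequencies.  When p_e = 1
    both marginals are degenerate on the same label, so the series agree
    everywhere and kappa is 1 by convention.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty rating series")
    if len(a) < 2:
        raise ValueError("kappa needs at least 2 items")
    la, lb = _aligned_labels(a, b)
    n = len(la)
    p_o = sum(x == y for x, y in zip(la, lb)) / n
    cats = set(la) | set(lb)
    p_e = sum((la.count(c) / n) * (lb.count(c) / n) for c in cats)
    if p_e >= 1.0 - 1e-12:
        return 1.0
    return (p_o - p_e) / (1.0 - p_e)


def default_grid(start: float = 0.50, stop: float = 0.95,
                 step: float = 0.05) -> tuple[float, ...]:
    """The sweep grid: 0.50, 0.55, ..., 0.95."""
    n = int(round((stop - start) / step)) + 1
    return tuple(round(start + i * step, 10) for i in range(n))


@dataclass(frozen=True)
class SweepResult:
    grid: tuple[float, ...]
    kappa: tuple[float, ...]            # NaN where undefined (all abstained)
    precision: tuple[float, ...]        # correct / retained
    recall: tuple[float, ...]           # correct / all items
    f1: tuple[float, ...]
    retained_fraction: tuple[float, ...]
    selected: float

    def as_dict(self) -> dict:
        return {
            "grid": list(self.grid),
            "kappa": list(self.kappa),
            "precision": list(self.precision),
            "recall": list(self.recall),
            "f1": list(self.f1),
            "retained_fraction": list(self.retained_fraction),
            "selected": self.selected,
        }


def sweep_thresholds(
    pred: RatingSeries,
    reference: RatingSeries,
    grid: Sequence[float] | None = None,
) -> SweepResult:
    """Evaluate kappa across confidence thresholds and select the best.

    At each threshold t, predictions with confidence < t abstain and are
    excluded from the agreement table; kappa is computed on the retained
    items.  Precision is correct/retained, recall correct/total — the
    selective-prediction trade-off the F1 tie-break summarizes.
    """
    if pred.confidence is None:
        raise ValueError("pred series carries no confidences")
    grid = default_grid() if grid is None else tuple(sorted(grid))
    if len(grid) == 0:
        raise ValueError("empty threshold grid")
    if any(b - a <= 0 for a, b in zip(grid, grid[1:])):
        raise ValueError("grid must be strictly increasing")
    la, lref = _aligned_labels(pred, reference)
    conf = np.asarray(pred.confidence, dtype=float)
    n = len(la)

    kappas, precs, recs, f1s, retained = [], [], [], [], []
    for t in grid:
        keep = conf >= t
        idx = np.flatnonzero(keep)
        retained.append(len(idx) / n)
        correct = sum(la[i] == lref[i] for i in idx)
        prec = correct / len(idx) if len(idx) else 0.0
        rec = correct / n
        f1 = 2 * prec * rec / (prec + rec) if (prec + rec) > 0 else 0.0
        precs.append(prec)
        recs.append(rec)
        f1s.append(f1)
        if len(idx) < 2:
            kappas.append(math.nan)  # flagged undefined, skipped in argmax
            continue
        sub_a = RatingSeries(tuple(int(i) for i in idx),
                             tuple(la[i] for i in idx))
        sub_b = RatingSeries(tuple(int(i) for i in idx),
                             tuple(lref[i] for i in idx))
        kappas.append(cohen_kappa(sub_a, sub_b))

    candidates = [i for i, k in enumerate(kappas) if not math.isnan(k)]
    if not candidates:
        raise ValueError("kappa undefined at every threshold (all abstain)")
    # max kappa; ties -> higher F1 of retained predictions; ties -> smaller t
    best = min(candidates, key=lambda i: (-kappas[i], -f1s[i], grid[i]))
    return SweepResult(
        grid=tuple(grid),
        kappa=tuple(kappas),
        precision=tuple(precs),
        recall=tuple(recs),
        f1=tuple(f1s),
        retained_fraction=tuple(retained),
        selected=grid[best],
    )


def chi_square_2x2(
    correct_a: int, total_a: int, correct_b: int, total_b: int,
    continuity_correction: bool = False,
) -> tuple[float, float]:
    """Pearson chi-square (1 df) comparing two correct/incorrect proportions.

    No Yates continuity correction by default.  Returns (statistic, p-value).
    """
    if total_a <= 0 or total_b <= 0:
        raise ValueError("totals must be positive")
    if not (0 <= correct_a <= total_a and 0 <= correct_b <= total_b):
        raise ValueError("correct counts must lie within their totals")
    table = np.array(
        [[correct_a, total_a - correct_a],
         [correct_b, total_b - correct_b]], dtype=float)
    n = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    if (expected == 0).any():
        raise ValueError("chi-square undefined: an expected count is zero")
    diff = np.abs(table - expected)
    if continuity_correction:
        diff = np.maximum(diff - 0.5, 0.0)
    stat = float((diff ** 2 / expected).sum())
    p = float(_stats.chi2.sf(stat, df=1))
    return stat, p
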