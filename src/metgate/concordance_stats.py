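"""Agreement statistics between FISH and NGS MET-status calls.

Axes of the 3x3 confusion matrix are ordered (AMPLIFICATION, POLYSOMY,
NEGATIVE); rows are FISH (the reference assay), columns are NGS. One-vs-rest
sensitivity is per-class recall against FISH; specificity is the fraction of
FISH non-class samples that NGS also calls non-class. The overall agreement
carries an exact (Clopper-Pearson) binomial 95% confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, List, Sequence, Tuple

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .core_types import STATUS_ORDER, MetStatus
from .errors import MetgateError, UndefinedMetric


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (2.5 -> 3), used for reported percentages."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionSummary:
    """3x3 contingency of FISH (rows) vs NGS (columns) calls."""

    matrix: np.ndarray
    n: int

    @property
    def labels(self) -> Tuple[MetStatus, ...]:
        return STATUS_ORDER

    def row_sum(self, cls: MetStatus) -> int:
        return int(self.matrix[STATUS_ORDER.index(cls)].sum())

    def col_sum(self, cls: MetStatus) -> int:
        return int(self.matrix[:, STATUS_ORDER.index(cls)].sum())

    @property
    def trace(self) -> int:
        return int(np.trace(self.matrix))


def from_matrix(matrix) -> ConfusionSummary:
    """Build a summary from an explicit 3x3 count matrix (FISH rows, NGS cols)."""
    m = np.asarray(matrix, dtype=np.int64)
    if m.shape != (3, 3) or (m < 0).any():
        raise MetgateError("expected a 3x3 matrix of nonnegative counts")
    return ConfusionSummary(matrix=m, n=int(m.sum()))


def confusion(
    fish_labels: Sequence[MetStatus], ngs_labels: Sequence[MetStatus]
) -> ConfusionSummary:
    if len(fish_labels) != len(ngs_labels):
        raise MetgateError(
            f"label lists differ in length ({len(fish_labels)} vs {len(ngs_labels)})"
        )
    idx = {s: i for i, s in enumerate(STATUS_ORDER)}
    m = np.zeros((3, 3), dtype=np.int64)
    for f, g in zip(fish_labels, ngs_labels):
        try:
            m[idx[f], idx[g]] += 1
        except (KeyError, TypeError):
            raise MetgateError(f"unknown label in input: {f!r} / {g!r}") from None
    return ConfusionSummary(matrix=m, n=len(fish_labels))


def one_vs_rest(summary: ConfusionSummary, cls: MetStatus) -> Tuple[float, float]:
    """(sensitivity, specificity) of the NGS call for one class vs the rest.

    A zero denominator yields an UndefinedMetric (NaN sentinel), not a crash.
    """
    i = STATUS_ORDER.index(cls)
    m = summary.matrix
    row = int(m[i].sum())
    rest = summary.n - row
    sens = m[i, i] / row if row > 0 else UndefinedMetric()
    if rest > 0:
        # FISH non-cls samples that NGS also calls non-cls: each non-cls row
        # minus its column-i (false positive) cell
        not_cls_called_not_cls = int(sum(m[j].sum() - m[j, i] for j in range(3) if j != i))
        spec = not_cls_called_not_cls / rest
    else:
        spec = UndefinedMetric()
    return sens, spec


def overall_agreement(summary: ConfusionSummary) -> Tuple[float, float, float]:
    """(proportion, ci_low, ci_high): trace/n with exact 95% binomial CI."""
    if summary.n == 0:
        raise MetgateError("cannot compute agreement on an empty summary")
    k, n = summary.trace, summary.n
    lo, hi = proportion_confint(k, n, alpha=0.05, method="beta")  # Clopper-Pearson
    return k / n, float(lo), float(hi)


def collapse_to_binary(
    summary: ConfusionSummary, positive_class: MetStatus = MetStatus.AMPLIFICATION
) -> Tuple[np.ndarray, int]:
    """Merge the two non-positive classes; returns (2x2 matrix, n).

    Axes ordered (positive, rest); counts are conserved.
    """
    i = STATUS_ORDER.index(positive_class)
    m = summary.matrix
    others = [j for j in range(3) if j != i]
    out = np.array(
        [
            [m[i, i], int(m[i, others].sum())],
            [int(m[others, i].sum()), int(m[np.ix_(others, others)].sum())],
        ],
        dtype=np.int64,
    )
    return out, summary.n


def agreement_by_gcn(
    met_gcn: Sequence[float],
    fish_labels: Sequence[MetStatus],
    ngs_labels: Sequence[MetStatus],
    bin_edges: Sequence[float] = (2.0, 5.0),
) -> List[Dict]:
    """Per-stratum agreement over MET-GCN bins.

    Samples fall in half-open bins [e_i, e_{i+1}) plus a leading (-inf, e_0)
    bin and a terminal [e_last, inf) bin. Empty bins report an
    UndefinedMetric agreement.
    """
    edges = [float(e) for e in bin_edges]
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise MetgateError("bin_edges must be strictly increasing")
    if not (len(met_gcn) == len(fish_labels) == len(ngs_labels)):
        raise MetgateError("met_gcn and label lists must have equal length")
    bounds = [-np.inf] + edges + [np.inf]
    out = []
    for lo, hi in zip(bounds, bounds[1:]):
        members = [
            (f, g)
            for v, f, g in zip(met_gcn, fish_labels, ngs_labels)
            if lo <= v < hi
        ]
        n = len(members)
        agree = sum(f is g for f, g in members) / n if n else UndefinedMetric()
        out.append({"lo": lo, "hi": hi, "n": n, "agreement": agree})
    return out
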