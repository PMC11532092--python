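"""Re-derivation of a ratio-gate model from a paired NGS + FISH cohort.

The procedure has three stages, mirroring how the published model was built:

1. For every candidate denominator gene, a ROC-style sweep over the observed
   MET/gene ratios finds the threshold maximising Youden's J
   (sensitivity + specificity - 1) for separating FISH amplification from the
   pooled polysomy/negative rest, with ``score >= t`` semantics.
2. An exhaustive enumeration over all 63 nonempty subsets of the six
   candidate genes combines per-gene thresholds conjunctively and scores each
   candidate by full three-class agreement with FISH.
3. Inside each candidate, the MET-GCN polysomy cutoff is refitted by the same
   ROC rule on the samples the candidate's gates call non-amplified,
   restricted to FISH polysomy/negative members.

Ties between candidates are broken by (1) highest overall agreement,
(2) highest amplification sensitivity, (3) fewest gates,
(4) lexicographically smallest gene subset. The search is deterministic.

Agreement is in-sample (fit and evaluated on the same cohort); a warning is
emitted to that effect.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

from .core_types import DENOMINATOR_GENES, GCNProfile, MetStatus, RatioGateModel
from .errors import DegenerateLabelsError
from .ngs_classifier import classify_ngs, met_ratio


@dataclass(frozen=True)
class CandidateRecord:
    """One evaluated gate-gene subset with its fitted thresholds and score."""

    genes: Tuple[str, ...]
    gates: Dict[str, float]
    polysomy_gcn_threshold: float
    agreement: float
    amp_sensitivity: float


@dataclass(frozen=True)
class TrainingResult:
    model: RatioGateModel
    agreement: float
    per_candidate_log: Tuple[CandidateRecord, ...]


def roc_cutoff(values: Sequence[float], positives: Sequence[bool]) -> float:
    """Youden-optimal threshold for the decision rule ``value >= t``.

    Candidate thresholds are the observed values; among thresholds tied on
    Youden's J, the smallest is returned so the rule is maximally sensitive.
    """
    values = [float(v) for v in values]
    positives = [bool(p) for p in positives]
    if len(values) != len(positives):
        raise ValueError("values and positives must have equal length")
    n_pos = sum(positives)
    n_neg = len(positives) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise DegenerateLabelsError(
            "threshold fitting needs both a positive and a negative example "
            f"(got {n_pos} positives, {n_neg} negatives)"
        )
    best_t = None
    best_j = -2.0
    for t in sorted(set(values)):
        tp = sum(1 for v, p in zip(values, positives) if p and v >= t)
        tn = sum(1 for v, p in zip(values, positives) if not p and v < t)
        j = tp / n_pos + tn / n_neg - 1.0
        if j > best_j:  # sorted ascending, so first maximiser is the smallest
            best_j = j
            best_t = t
    return best_t


def fit_amp_gates(
    profiles: Sequence[GCNProfile],
    fish_labels: Sequence[MetStatus],
    genes: Sequence[str],
) -> Dict[str, float]:
    """Independent per-gene ROC thresholds for amplification vs the rest."""
    positives = [lab is MetStatus.AMPLIFICATION for lab in fish_labels]
    gates = {}
    for gene in genes:
        ratios = [met_ratio(p, gene) for p in profiles]
        gates[gene] = roc_cutoff(ratios, positives)
    return gates


def fit_polysomy_cutoff(
    profiles: Sequence[GCNProfile], fish_labels: Sequence[MetStatus]
) -> float:
    """ROC threshold on MET GCN separating FISH polysomy from negative."""
    pairs = [
        (p.met_gcn, lab is MetStatus.POLYSOMY)
        for p, lab in zip(profiles, fish_labels)
        if lab in (MetStatus.POLYSOMY, MetStatus.NEGATIVE)
    ]
    if not pairs:
        raise DegenerateLabelsError("no POLYSOMY/NEGATIVE samples to fit the GCN cutoff on")
    values, positives = zip(*pairs)
    return roc_cutoff(values, positives)


def _evaluate_candidate(
    profiles: Sequence[GCNProfile],
    fish_labels: Sequence[MetStatus],
    genes: Tuple[str, ...],
) -> CandidateRecord:
    gates = fit_amp_gates(profiles, fish_labels, genes)
    amp_called = [
        all(met_ratio(p, g) >= thr for g, thr in gates.items()) for p in profiles
    ]
    # Refit the GCN cutoff on samples the gates leave non-amplified, among
    # FISH polysomy/negative members; if the gates swallow a whole class,
    # fall back to the full polysomy/negative subcohort so the search stays
    # total.
    sub = [
        (p, lab)
        for p, lab, amp in zip(profiles, fish_labels, amp_called)
        if not amp and lab in (MetStatus.POLYSOMY, MetStatus.NEGATIVE)
    ]
    sub_labels = {lab for _, lab in sub}
    if sub_labels >= {MetStatus.POLYSOMY, MetStatus.NEGATIVE}:
        gcn_thr = fit_polysomy_cutoff([p for p, _ in sub], [lab for _, lab in sub])
    else:
        gcn_thr = fit_polysomy_cutoff(profiles, fish_labels)

    model = RatioGateModel(gates=gates, polysomy_gcn_threshold=gcn_thr)
    calls = [classify_ngs(p, model) for p in profiles]
    agree = sum(c is lab for c, lab in zip(calls, fish_labels)) / len(profiles)
    n_amp = sum(lab is MetStatus.AMPLIFICATION for lab in fish_labels)
    amp_sens = (
        sum(
            c is MetStatus.AMPLIFICATION and lab is MetStatus.AMPLIFICATION
            for c, lab in zip(calls, fish_labels)
        )
        / n_amp
    )
    return CandidateRecord(
        genes=genes,
        gates=gates,
        polysomy_gcn_threshold=gcn_thr,
        agreement=agree,
        amp_sensitivity=amp_sens,
    )


def train(
    profiles: Sequence[GCNProfile],
    fish_labels: Sequence[MetStatus],
    candidate_genes: Sequence[str] = DENOMINATOR_GENES,
) -> TrainingResult:
    """Exhaustive gate-subset search returning the best candidate model."""
    if len(profiles) != len(fish_labels):
        raise ValueError("profiles and fish_labels must have equal length")
    present = set(fish_labels)
    missing = [s.value for s in MetStatus if s not in present]
    if missing:
        raise DegenerateLabelsError(
            f"training cohort is missing FISH class(es): {', '.join(missing)}"
        )
    warnings.warn(
        "agreement is in-sample: the model is fitted and scored on the same cohort",
        stacklevel=2,
    )

    candidates: List[CandidateRecord] = []
    genes_sorted = sorted(candidate_genes)
    for r in range(1, len(genes_sorted) + 1):
        for subset in itertools.combinations(genes_sorted, r):
            candidates.append(_evaluate_candidate(profiles, fish_labels, subset))

    best = min(
        candidates,
        key=lambda c: (-c.agreement, -c.amp_sensitivity, len(c.genes), c.genes),
    )
    model = RatioGateModel(
        gates=best.gates, polysomy_gcn_threshold=best.polysomy_gcn_threshold
    )
    return TrainingResult(
        model=model, agreement=best.agreement, per_candidate_log=tuple(candidates)
    )
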