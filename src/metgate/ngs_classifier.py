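"""NGS-side MET status call: a ratio-gate model applied to a copy-number profile.

The call is a pure conjunction: a sample is AMPLIFICATION only if every
MET/denominator ratio meets its threshold (all comparisons inclusive, >=).
Failing that, MET GCN >= the polysomy threshold calls POLYSOMY, else NEGATIVE.
A profile missing any gate gene is a hard error — silently defaulting to
NEGATIVE would corrupt downstream concordance statistics.
"""

from __future__ import annotations

import math

from .core_types import GCNProfile, MetStatus, RatioGateModel
from .errors import MissingGeneError, UndefinedRatioError


def _ge(value: float, threshold: float) -> bool:
    """Inclusive >= that absorbs float representation error at the boundary.

    Ratios like 3.36/3.0 land one ulp below the printed threshold 1.12; a
    relative tolerance of 1e-9 keeps the printed boundary semantics exact
    without affecting any realistic measurement.
    """
    return value >= threshold or math.isclose(value, threshold, rel_tol=1e-9)


def met_ratio(profile: GCNProfile, denom_gene: str) -> float:
    """CN(MET) / CN(denom_gene) for one profile."""
    denom_gene = denom_gene.strip().upper()
    missing = [g for g in ("MET", denom_gene) if g not in profile.gcn]
    if missing:
        raise MissingGeneError(missing)
    denom = profile.gcn[denom_gene]
    if denom <= 0:
        raise UndefinedRatioError(
            f"sample {profile.sample_id!r}: CN({denom_gene}) = {denom} is not a valid denominator"
        )
    return profile.gcn["MET"] / denom


def classify_ngs(profile: GCNProfile, model: RatioGateModel) -> MetStatus:
    """Three-class MET status from gene copy numbers under a gate model."""
    absent = [g for g in model.gates if g not in profile.gcn]
    if absent:
        raise MissingGeneError(sorted(absent))
    if all(_ge(met_ratio(profile, gene), thr) for gene, thr in model.gates.items()):
        return MetStatus.AMPLIFICATION
    if _ge(profile.met_gcn, model.polysomy_gcn_threshold):
        return MetStatus.POLYSOMY
    return MetStatus.NEGATIVE
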