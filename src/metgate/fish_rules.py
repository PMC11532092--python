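"""Gold-standard FISH classification of MET status.

Scoring convention: mean MET and CEP7 signals per nucleus over >= 50
non-overlapping tumour-cell nuclei. Amplification is a MET/CEP7 ratio >= 2
(focal gain outpaces the centromere); polysomy is a mean MET count >= 5 with
ratio < 2 (whole chromosome 7 gained, so MET and CEP7 rise together);
everything else is negative. Both cutoffs are inclusive.
"""

from __future__ import annotations

from .core_types import FISHObservation, MetStatus
from .errors import UndefinedRatioError

RATIO_CUTOFF = 2.0
POLYSOMY_MEAN_GCN_CUTOFF = 5.0


def fish_ratio(obs: FISHObservation) -> float:
    """MET/CEP7 signal ratio for one sample."""
    if obs.mean_cep7 <= 0:
        raise UndefinedRatioError(
            f"sample {obs.sample_id!r}: MET/CEP7 ratio undefined (mean CEP7 = {obs.mean_cep7})"
        )
    return obs.mean_met / obs.mean_cep7


def classify_fish(obs: FISHObservation) -> MetStatus:
    """Apply the FISH decision rules; total and deterministic."""
    if fish_ratio(obs) >= RATIO_CUTOFF:
        return MetStatus.AMPLIFICATION
    if obs.mean_met >= POLYSOMY_MEAN_GCN_CUTOFF:
        return MetStatus.POLYSOMY
    return MetStatus.NEGATIVE
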