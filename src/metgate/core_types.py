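"""Shared domain types for MET copy-number status calling.

The panel covers seven chromosome-7 genes. MET is the gene of interest; the
other six (EGFR, BRAF, CDK6, PMS2, ABCB1, CYP3A4) serve as intra-chromosomal
denominators that distinguish a focal MET gain (MET rises, denominators stay
near diploid) from whole-chromosome-7 polysomy (everything rises together).
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping, Optional, Sequence, Tuple

from .errors import SchemaError

#: The seven chromosome-7 genes on the panel, MET first.
PANEL_GENES: Tuple[str, ...] = ("MET", "EGFR", "BRAF", "CDK6", "PMS2", "ABCB1", "CYP3A4")

#: Genes eligible as ratio denominators (everything on the panel except MET).
DENOMINATOR_GENES: Tuple[str, ...] = ("EGFR", "BRAF", "CDK6", "PMS2", "ABCB1", "CYP3A4")


@enum.unique
class MetStatus(enum.Enum):
    """Three-level MET copy-number status.

    A total order NEGATIVE < POLYSOMY < AMPLIFICATION reflects increasing
    MET dosage and is used by monotonicity checks.
    """

    NEGATIVE = "NEGATIVE"
    POLYSOMY = "POLYSOMY"
    AMPLIFICATION = "AMPLIFICATION"

    @property
    def rank(self) -> int:
        return _STATUS_RANK[self]

    def __lt__(self, other: "MetStatus") -> bool:
        if not isinstance(other, MetStatus):
            return NotImplemented
        return self.rank < other.rank

    def __le__(self, other: "MetStatus") -> bool:
        if not isinstance(other, MetStatus):
            return NotImplemented
        return self.rank <= other.rank


_STATUS_RANK = {MetStatus.NEGATIVE: 0, MetStatus.POLYSOMY: 1, MetStatus.AMPLIFICATION: 2}

#: Canonical display/report order (matches confusion-matrix axes).
STATUS_ORDER: Tuple[MetStatus, ...] = (
    MetStatus.AMPLIFICATION,
    MetStatus.POLYSOMY,
    MetStatus.NEGATIVE,
)


def _normalize_gcn(gcn: Mapping[str, float]) -> Mapping[str, float]:
    out = {}
    for gene, value in gcn.items():
        symbol = str(gene).strip().upper()
        if symbol not in PANEL_GENES:
            warnings.warn(f"ignoring unknown gene column {symbol!r}", stacklevel=3)
            continue
        if value is None or (isinstance(value, float) and math.isnan(value)):
            continue  # blank cell -> missing gene
        value = float(value)
        if not math.isfinite(value) or value <= 0:
            raise SchemaError(f"copy number for {symbol} must be finite and > 0, got {value!r}")
        out[symbol] = value
    return MappingProxyType(out)


@dataclass(frozen=True)
class GCNProfile:
    """One sample's NGS gene copy numbers (diploid baseline 2.0).

    MET must be present; other panel genes may be individually missing, in
    which case gates using them as denominators cannot be evaluated for this
    profile.
    """

    sample_id: str
    gcn: Mapping[str, float]

    def __post_init__(self):
        object.__setattr__(self, "gcn", _normalize_gcn(self.gcn))
        if "MET" not in self.gcn:
            raise SchemaError(f"sample {self.sample_id!r}: MET copy number is required")

    @property
    def met_gcn(self) -> float:
        return self.gcn["MET"]

    def has_genes(self, genes: Sequence[str]) -> bool:
        return all(g in self.gcn for g in genes)


@dataclass(frozen=True)
class FISHObservation:
    """Per-sample FISH signal counts: mean MET and mean CEP7 per nucleus.

    When per-nucleus counts are supplied (at least 50 nuclei, mirroring
    standard scoring practice) the means are recomputed from them and any
    stored means are ignored — the raw counts are the single source of truth.
    """

    sample_id: str
    mean_met: float
    mean_cep7: float
    nuclei: Optional[Tuple[Tuple[int, int], ...]] = None

    def __post_init__(self):
        if self.nuclei is not None:
            nuclei = tuple((int(m), int(c)) for m, c in self.nuclei)
            if len(nuclei) < 50:
                raise SchemaError(
                    f"sample {self.sample_id!r}: {len(nuclei)} nuclei given, "
                    "at least 50 non-overlapping nuclei are required"
                )
            for i, (m, c) in enumerate(nuclei):
                if m < 0:
                    raise SchemaError(f"sample {self.sample_id!r}, nucleus {i}: MET count < 0")
                if c <= 0:
                    raise SchemaError(f"sample {self.sample_id!r}, nucleus {i}: CEP7 count must be > 0")
            object.__setattr__(self, "nuclei", nuclei)
            object.__setattr__(self, "mean_met", sum(m for m, _ in nuclei) / len(nuclei))
            object.__setattr__(self, "mean_cep7", sum(c for _, c in nuclei) / len(nuclei))
        else:
            object.__setattr__(self, "mean_met", float(self.mean_met))
            object.__setattr__(self, "mean_cep7", float(self.mean_cep7))
        if not math.isfinite(self.mean_met) or self.mean_met < 0:
            raise SchemaError(f"sample {self.sample_id!r}: mean MET count must be finite and >= 0")
        if not math.isfinite(self.mean_cep7) or self.mean_cep7 <= 0:
            raise SchemaError(f"sample {self.sample_id!r}: mean CEP7 count must be > 0")


@dataclass(frozen=True)
class RatioGateModel:
    """A conjunction of MET/denominator ratio gates plus a MET-GCN cutoff.

    A sample passes the amplification call only if every gate
    ``MET/gene >= threshold`` holds; among the remaining samples, those with
    MET GCN at or above ``polysomy_gcn_threshold`` are called polysomy.
    """

    gates: Mapping[str, float]
    polysomy_gcn_threshold: float

    def __post_init__(self):
        gates = {}
        for gene, thr in self.gates.items():
            symbol = str(gene).strip().upper()
            if symbol == "MET":
                raise SchemaError("MET cannot be a gate denominator")
            if symbol not in DENOMINATOR_GENES:
                raise SchemaError(f"unknown gate denominator gene {symbol!r}")
            thr = float(thr)
            if not math.isfinite(thr) or thr <= 0:
                raise SchemaError(f"gate threshold for {symbol} must be finite and > 0")
            gates[symbol] = thr
        if not gates:
            raise SchemaError("a gate model needs at least one ratio gate")
        object.__setattr__(self, "gates", MappingProxyType(gates))
        thr = float(self.polysomy_gcn_threshold)
        if not math.isfinite(thr) or thr <= 0:
            raise SchemaError("polysomy GCN threshold must be finite and > 0")
        object.__setattr__(self, "polysomy_gcn_threshold", thr)

    @property
    def gate_genes(self) -> Tuple[str, ...]:
        return tuple(sorted(self.gates))


_PUBLISHED = None


def published_model() -> RatioGateModel:
    """The published gate model.

    Amplification requires MET/CYP3A4 >= 1.12 AND MET/CDK6 >= 1.20 AND
    MET/BRAF >= 1.53; otherwise MET GCN >= 2.8 calls polysomy, else negative.
    """
    global _PUBLISHED
    if _PUBLISHED is None:
        _PUBLISHED = RatioGateModel(
            gates={"CYP3A4": 1.12, "CDK6": 1.20, "BRAF": 1.53},
            polysomy_gcn_threshold=2.8,
        )
    return _PUBLISHED
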