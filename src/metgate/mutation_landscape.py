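"""Somatic-variant filtering and mutation-landscape summaries.

Filtering applies, in order: (1) a germline cut on annotated population
allele frequency (> 0.1%), (2) a low-VAF cut (< 1%), (3) an in-silico
benign cut that removes a variant only when BOTH predictors agree it is
harmless (SIFT > 0.05 AND PolyPhen2 <= 0.446); a variant with either score
missing survives rule 3 as "unknown significance". The rules are pure
predicates, so the retained set is order-independent, but the per-rule
removal counts follow the stated order.

Association tests between mutation carriage and MET status use Pearson
chi-squared (Yates-corrected for 2x2, matching R's chisq.test default) when
every expected cell count is >= 5, and Fisher's exact test otherwise
(Freeman-Halton enumeration for three groups).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .errors import MetgateError, SchemaError

GERMLINE_POP_FREQ = 0.001
MIN_VAF = 0.01
SIFT_BENIGN_GT = 0.05
POLYPHEN2_BENIGN_LE = 0.446

MUTATION_FORMS = ("missense", "nonsense", "nonstop", "frameshift_inframe", "splicing")

#: The six pyrimidine-reference substitution classes.
SUBSTITUTION_CLASSES = ("C>T", "C>A", "C>G", "T>C", "T>A", "T>G")

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class VariantRecord:
    """One annotated somatic variant call for one patient."""

    patient_id: str
    gene: str
    site: str
    form: str
    vaf: float
    ref_base: Optional[str] = None
    alt_base: Optional[str] = None
    pop_freq: Optional[float] = None
    sift: Optional[float] = None
    polyphen2: Optional[float] = None

    def __post_init__(self):
        object.__setattr__(self, "gene", self.gene.strip().upper())
        if self.form not in MUTATION_FORMS:
            raise SchemaError(
                f"patient {self.patient_id!r}: unknown mutation form {self.form!r}"
            )
        for name in ("vaf", "pop_freq", "sift", "polyphen2"):
            v = getattr(self, name)
            if v is None:
                continue
            v = float(v)
            if not (0.0 <= v <= 1.0):
                raise SchemaError(
                    f"patient {self.patient_id!r}: {name} = {v} outside [0, 1]"
                )
            object.__setattr__(self, name, v)
        for name in ("ref_base", "alt_base"):
            b = getattr(self, name)
            if b is not None:
                b = str(b).strip().upper()
                if b not in _COMPLEMENT:
                    raise SchemaError(
                        f"patient {self.patient_id!r}: invalid base {b!r} for {name}"
                    )
                object.__setattr__(self, name, b)
        if self.ref_base is not None and self.ref_base == self.alt_base:
            raise SchemaError(
                f"patient {self.patient_id!r}: ref and alt bases are identical"
            )


def filter_variants(
    records: Sequence[VariantRecord],
) -> Tuple[List[VariantRecord], Dict[str, int]]:
    """Apply the three filtering rules; returns (retained, per-rule counts)."""
    counts = {"germline_pop_freq": 0, "low_vaf": 0, "predicted_benign": 0}
    retained = []
    for rec in records:
        if rec.pop_freq is not None and rec.pop_freq > GERMLINE_POP_FREQ:
            counts["germline_pop_freq"] += 1
            continue
        if rec.vaf < MIN_VAF:
            counts["low_vaf"] += 1
            continue
        if (
            rec.sift is not None
            and rec.polyphen2 is not None
            and rec.sift > SIFT_BENIGN_GT
            and rec.polyphen2 <= POLYPHEN2_BENIGN_LE
        ):
            counts["predicted_benign"] += 1
            continue
        retained.append(rec)
    return retained, counts


def gene_frequencies(
    records: Sequence[VariantRecord], cohort_size: int
) -> Dict[str, float]:
    """Per-gene percentage of patients carrying >= 1 retained variant.

    Includes an ``ANY`` entry for patients with at least one variant in any
    gene. Percentages are half-up rounded to 2 decimals.
    """
    if cohort_size <= 0:
        raise MetgateError("cohort_size must be > 0")
    patients_by_gene: Dict[str, set] = {}
    any_patients = set()
    for rec in records:
        patients_by_gene.setdefault(rec.gene, set()).add(rec.patient_id)
        any_patients.add(rec.patient_id)
    out = {
        gene: _pct2(len(pats) / cohort_size)
        for gene, pats in sorted(patients_by_gene.items())
    }
    out["ANY"] = _pct2(len(any_patients) / cohort_size)
    return out


def _pct2(fraction: float) -> float:
    return float(
        Decimal(repr(fraction * 100.0)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)
    )


def classify_substitution(ref_base: str, alt_base: str) -> str:
    """Collapse a single-base substitution to its pyrimidine-reference class."""
    ref = str(ref_base).strip().upper()
    alt = str(alt_base).strip().upper()
    if ref not in _COMPLEMENT or alt not in _COMPLEMENT:
        raise SchemaError(f"invalid base pair ({ref_base!r}, {alt_base!r})")
    if ref == alt:
        raise SchemaError("ref and alt bases must differ")
    if ref in ("A", "G"):  # purine reference: use the reverse complement
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return f"{ref}>{alt}"


def substitution_counts(records: Sequence[VariantRecord]) -> Dict[str, int]:
    """Counts per substitution class over records that carry ref/alt bases."""
    counts = {cls: 0 for cls in SUBSTITUTION_CLASSES}
    for rec in records:
        if rec.ref_base is not None and rec.alt_base is not None:
            counts[classify_substitution(rec.ref_base, rec.alt_base)] += 1
    return counts


def form_counts(records: Sequence[VariantRecord]) -> Dict[str, int]:
    counts = {form: 0 for form in MUTATION_FORMS}
    for rec in records:
        counts[rec.form] += 1
    return counts


def egfr_site_summary(records: Sequence[VariantRecord]) -> Dict:
    """EGFR hotspot-site fractions and per-patient site-count distribution.

    Site fractions use EGFR-mutant patients as denominator; the site-count
    distribution is bucketed {1, 2, >2}.
    """
    sites_by_patient: Dict[str, set] = {}
    for rec in records:
        if rec.gene == "EGFR":
            sites_by_patient.setdefault(rec.patient_id, set()).add(rec.site)
    n_mut = len(sites_by_patient)
    site_fractions: Dict[str, float] = {}
    if n_mut:
        site_patients: Dict[str, int] = {}
        for sites in sites_by_patient.values():
            for s in sites:
                site_patients[s] = site_patients.get(s, 0) + 1
        site_fractions = {
            s: _pct2(c / n_mut) for s, c in sorted(site_patients.items())
        }
    buckets = {"1": 0, "2": 0, ">2": 0}
    for sites in sites_by_patient.values():
        k = len(sites)
        buckets["1" if k == 1 else "2" if k == 2 else ">2"] += 1
    bucket_fractions = {
        b: (_pct2(c / n_mut) if n_mut else 0.0) for b, c in buckets.items()
    }
    return {
        "n_egfr_mutant": n_mut,
        "site_fractions_pct": site_fractions,
        "site_count_buckets": buckets,
        "site_count_fractions_pct": bucket_fractions,
    }


# --- association testing -----------------------------------------------------


def _freeman_halton(table: np.ndarray) -> float:
    """Exact conditional test for a K x 2 table by full enumeration.

    Sums, over all tables with the observed margins, the probabilities of
    tables no more probable than the observed one under the multivariate
    hypergeometric null.
    """
    row_sums = table.sum(axis=1)
    col_sums = table.sum(axis=0)
    n = int(table.sum())

    def log_fact(k):
        return math.lgamma(k + 1)

    log_const = (
        sum(log_fact(r) for r in row_sums)
        + sum(log_fact(c) for c in col_sums)
        - log_fact(n)
    )

    def table_logp(first_col: Sequence[int]) -> float:
        lp = log_const
        for a, r in zip(first_col, row_sums):
            lp -= log_fact(a) + log_fact(r - a)
        return lp

    obs_logp = table_logp(table[:, 0])
    total = 0.0
    c0 = int(col_sums[0])
    ranges = [range(0, int(r) + 1) for r in row_sums]
    for first_col in itertools.product(*ranges[:-1]):
        last = c0 - sum(first_col)
        if 0 <= last <= row_sums[-1]:
            lp = table_logp(list(first_col) + [last])
            if lp <= obs_logp + 1e-10:  # tolerance for fp ties
                total += math.exp(lp)
    return min(total, 1.0)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table (probability-mass definition)."""
    t = np.asarray(table, dtype=np.int64)
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def association_test(table, method: str = "auto") -> Tuple[float, str]:
    """Test association in a K x 2 mutated/unmutated contingency table.

    Returns (two-sided p-value, method tag). With method="auto", Fisher's
    exact test is used when any expected cell count is < 5, Pearson
    chi-squared otherwise (Yates-corrected for 2x2).
    """
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2 or t.shape[1] != 2 or t.shape[0] not in (2, 3):
        raise MetgateError("expected a Kx2 table with K in {2, 3}")
    if (t < 0).any():
        raise MetgateError("table counts must be nonnegative")
    if t.sum() == 0:
        raise MetgateError("empty contingency table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        # a zero margin carries no information about association
        return 1.0, "degenerate-margin"

    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    if method == "auto":
        method = "fisher" if (expected < 5).any() else "chi2"
    if method == "chi2":
        res = stats.chi2_contingency(t, correction=(t.shape[0] == 2))
        return float(res.pvalue), "chi2"
    if method == "fisher":
        if t.shape[0] == 2:
            return fisher_exact_2x2(t), "fisher"
        return _freeman_halton(t), "fisher-freeman-halton"
    raise MetgateError(f"unknown method {method!r}")


def pairwise_comparisons(table) -> Dict[Tuple[int, int], Dict]:
    """Pairwise group-vs-group tests for a 3x2 mutated/unmutated table.

    P-values are reported raw; no multiplicity adjustment is applied (the
    result dict carries an explicit ``adjustment: none`` flag).
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (3, 2):
        raise MetgateError("pairwise comparisons need a 3x2 table")
    out = {}
    for i, j in itertools.combinations(range(3), 2):
        p, tag = association_test(t[[i, j], :])
        out[(i, j)] = {"p": p, "method": tag, "adjustment": "none"}
    return out
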