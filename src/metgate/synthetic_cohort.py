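"""Synthetic paired NGS + FISH cohorts with known MET-status truth.

The generator emulates the biology the classifier must separate:

* NEGATIVE — diploid chromosome 7: all panel genes and the centromere at 2
  copies per tumour cell.
* POLYSOMY — whole-chromosome gain: every chromosome-7 gene AND the CEP7
  centromere at k copies (k drawn from ``polysomy_range``), so MET/gene and
  MET/CEP7 ratios stay near 1 while absolute copy number rises.
* AMPLIFICATION — focal MET gain: MET at m copies (``focal_met_range``) on a
  background of 2 or 3 chromosome-7 copies carried by the other genes and
  CEP7, so ratios rise to roughly m/background.

Bulk NGS copy number mixes tumour and normal cells at purity rho:
rho * tumour_copies + (1 - rho) * 2, plus additive Gaussian noise. FISH
observes 50 nuclei; each is a tumour nucleus with probability rho (counts
Poisson around the tumour copy numbers, floored at 1 signal) and a normal
nucleus otherwise (Poisson around 2). When ``gcn_noise_sd`` is 0 the
generator is fully noise-free: bulk values and nucleus counts equal the
latent copy numbers exactly, which makes the closure properties (FISH
reproduces truth; training recovers perfect agreement) analytic rather than
approximate.

All randomness flows from one integer seed through per-sample child streams
(numpy SeedSequence spawning), so cohorts sharing a seed agree on their
common prefix regardless of n.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core_types import PANEL_GENES, FISHObservation, GCNProfile, MetStatus
from .errors import MetgateError
from .mutation_landscape import MUTATION_FORMS, VariantRecord


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition knobs for the paired-cohort generator.

    Defaults follow the observed three-class mix (14.6% amplification,
    16.7% polysomy, 68.8% negative) of the reference FISH cohort.
    """

    n: int = 96
    class_probs: Tuple[float, float, float] = (14 / 96, 16 / 96, 66 / 96)  # (amp, poly, neg)
    purity_range: Tuple[float, float] = (0.2, 0.9)
    focal_met_range: Tuple[int, int] = (6, 30)
    polysomy_range: Tuple[int, int] = (3, 6)
    background_copies: Tuple[int, ...] = (2, 3)
    gcn_noise_sd: float = 0.15
    nuclei_per_sample: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.n <= 0:
            raise MetgateError("cohort size must be > 0")
        if abs(sum(self.class_probs) - 1.0) > 1e-9 or any(p < 0 for p in self.class_probs):
            raise MetgateError("class_probs must be nonnegative and sum to 1")
        for name in ("purity_range", "focal_met_range", "polysomy_range"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise MetgateError(f"{name} is empty: ({lo}, {hi})")
        if not (0 < self.purity_range[0] and self.purity_range[1] <= 1):
            raise MetgateError("purity_range must lie in (0, 1]")
        if self.gcn_noise_sd < 0:
            raise MetgateError("gcn_noise_sd must be >= 0")
        if self.nuclei_per_sample < 50:
            raise MetgateError("at least 50 nuclei per sample are required")


@dataclass(frozen=True)
class SimulatedSample:
    profile: GCNProfile
    fish: FISHObservation
    truth: MetStatus


def _tumor_genotype(cls: MetStatus, rng: np.random.Generator, config: CohortConfig):
    """Latent per-tumour-cell copy numbers: ({gene: copies}, cep7_copies)."""
    if cls is MetStatus.NEGATIVE:
        return {g: 2 for g in PANEL_GENES}, 2
    if cls is MetStatus.POLYSOMY:
        k = int(rng.integers(config.polysomy_range[0], config.polysomy_range[1] + 1))
        return {g: k for g in PANEL_GENES}, k
    m = int(rng.integers(config.focal_met_range[0], config.focal_met_range[1] + 1))
    b = int(rng.choice(config.background_copies))
    genotype = {g: b for g in PANEL_GENES}
    genotype["MET"] = m
    return genotype, b


def _nucleus_counts(mean: float, rng: np.random.Generator, noisy: bool) -> int:
    if not noisy:
        return max(1, int(round(mean)))
    return max(1, int(rng.poisson(mean)))


def simulate_cohort(config: CohortConfig) -> List[SimulatedSample]:
    """Draw a paired (GCN profile, FISH observation, truth label) cohort."""
    children = np.random.SeedSequence(config.seed).spawn(config.n)
    noisy = config.gcn_noise_sd > 0
    classes = (MetStatus.AMPLIFICATION, MetStatus.POLYSOMY, MetStatus.NEGATIVE)
    samples = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        cls = classes[rng.choice(3, p=config.class_probs)]
        rho = float(rng.uniform(*config.purity_range))
        genotype, cep7 = _tumor_genotype(cls, rng, config)

        gcn = {}
        for gene in PANEL_GENES:
            bulk = rho * genotype[gene] + (1 - rho) * 2.0
            if noisy:
                bulk += rng.normal(0.0, config.gcn_noise_sd)
            gcn[gene] = max(0.1, bulk)
        profile = GCNProfile(sample_id=f"S{i:04d}", gcn=gcn)

        nuclei = []
        for _ in range(config.nuclei_per_sample):
            tumor = rng.random() < rho
            met_mean = genotype["MET"] if tumor else 2
            cep_mean = cep7 if tumor else 2
            nuclei.append(
                (
                    _nucleus_counts(met_mean, rng, noisy),
                    _nucleus_counts(cep_mean, rng, noisy),
                )
            )
        fish = FISHObservation(
            sample_id=profile.sample_id, mean_met=0.0, mean_cep7=1.0, nuclei=tuple(nuclei)
        )
        samples.append(SimulatedSample(profile=profile, fish=fish, truth=cls))
    return samples


def simulate_discordance_zone(config: Optional[CohortConfig] = None) -> List[SimulatedSample]:
    """A cohort whose bulk MET GCN concentrates in the ambiguous [2, 5) zone.

    Low purity plus modest copy gains put the NGS signal where focal gain and
    polysomy are hardest to separate; diploid negatives are excluded because
    their bulk MET GCN straddles 2 symmetrically.
    """
    base = config if config is not None else CohortConfig()
    zone = replace(
        base,
        class_probs=(0.5, 0.5, 0.0),
        purity_range=(0.2, 0.4),
        focal_met_range=(6, 8),
        polysomy_range=(3, 4),
    )
    return simulate_cohort(zone)


# Default per-gene mutation probabilities mirror the observed landscape of
# the osimertinib-resistant cohort (fractions of patients mutated).
DEFAULT_GENE_PROBS: Dict[str, float] = {
    "EGFR": 0.5994,
    "TP53": 0.4385,
    "NRG1": 0.0946,
    "PIK3CA": 0.0631,
    "ATM": 0.0536,
    "APC": 0.0442,
    "ARID1A": 0.0442,
    "BRAF": 0.0410,
    "NTRK1": 0.0410,
    "POLE": 0.0410,
    "KRAS": 0.0379,
}

#: EGFR hotspot sites with conditional draw weights (given EGFR-mutant).
DEFAULT_EGFR_SITE_WEIGHTS: Dict[str, float] = {
    "del19": 0.4842,
    "L858R": 0.4684,
    "T790M": 0.1789,
    "A750P": 0.0263,
    "C797S": 0.0211,
    "E709K": 0.0105,
}

#: Distribution of the number of distinct EGFR sites per EGFR-mutant patient.
DEFAULT_EGFR_SITE_COUNT_PROBS: Tuple[float, float, float] = (0.658, 0.263, 0.079)

#: Substitution-class draw weights (pyrimidine-reference classes).
DEFAULT_SUBSTITUTION_PROBS: Dict[str, float] = {
    "C>T": 0.411,
    "C>A": 0.17,
    "C>G": 0.12,
    "T>C": 0.13,
    "T>A": 0.08,
    "T>G": 0.089,
}

_CLASS_TO_PAIRS = {
    "C>T": (("C", "T"), ("G", "A")),
    "C>A": (("C", "A"), ("G", "T")),
    "C>G": (("C", "G"), ("G", "C")),
    "T>C": (("T", "C"), ("A", "G")),
    "T>A": (("T", "A"), ("A", "T")),
    "T>G": (("T", "G"), ("A", "C")),
}

_FORM_PROBS = (0.62, 0.10, 0.02, 0.16, 0.10)  # over MUTATION_FORMS


def _clean_annotations(rng: np.random.Generator) -> Dict[str, Optional[float]]:
    """Annotation values for a true somatic variant (always survives filters)."""
    vaf = float(rng.uniform(0.01, 0.6))
    pop_freq = None if rng.random() < 0.5 else float(rng.uniform(0.0, 0.001))
    if rng.random() < 0.3:  # unknown significance: a score is missing
        sift = None if rng.random() < 0.5 else float(rng.uniform(0.0, 1.0))
        polyphen2 = None
    elif rng.random() < 0.5:  # deleterious by SIFT
        sift = float(rng.uniform(0.0, 0.05))
        polyphen2 = float(rng.uniform(0.0, 1.0))
    else:  # damaging by PolyPhen2
        sift = float(rng.uniform(0.0, 1.0))
        polyphen2 = float(rng.uniform(0.4461, 1.0))
    return {"vaf": vaf, "pop_freq": pop_freq, "sift": sift, "polyphen2": polyphen2}


def simulate_variant_table(
    cohort_size: int,
    gene_probs: Optional[Dict[str, float]] = None,
    seed: int = 0,
    germline_rate: float = 0.1,
    low_vaf_rate: float = 0.1,
    benign_rate: float = 0.1,
    egfr_site_weights: Optional[Dict[str, float]] = None,
    egfr_site_count_probs: Sequence[float] = DEFAULT_EGFR_SITE_COUNT_PROBS,
    substitution_probs: Optional[Dict[str, float]] = None,
) -> List[VariantRecord]:
    """Simulate an annotated variant table for ``cohort_size`` patients.

    ``germline_rate`` / ``low_vaf_rate`` / ``benign_rate`` are the expected
    numbers of rule-violating artifact records per patient (each drawn
    Poisson); at rate 0 every generated record survives filtering.
    """
    if cohort_size <= 0:
        raise MetgateError("cohort_size must be > 0")
    gene_probs = dict(DEFAULT_GENE_PROBS if gene_probs is None else gene_probs)
    site_weights = dict(
        DEFAULT_EGFR_SITE_WEIGHTS if egfr_site_weights is None else egfr_site_weights
    )
    sub_probs = dict(
        DEFAULT_SUBSTITUTION_PROBS if substitution_probs is None else substitution_probs
    )
    for name, probs in (
        ("gene_probs", gene_probs.values()),
        ("egfr_site_count_probs", egfr_site_count_probs),
        ("substitution_probs", sub_probs.values()),
    ):
        if any(not (0 <= p <= 1) for p in probs):
            raise MetgateError(f"{name} must lie in [0, 1]")
    for name, rate in (
        ("germline_rate", germline_rate),
        ("low_vaf_rate", low_vaf_rate),
        ("benign_rate", benign_rate),
    ):
        if rate < 0:
            raise MetgateError(f"{name} must be >= 0")

    sub_classes = list(sub_probs)
    sub_w = np.asarray([sub_probs[c] for c in sub_classes], dtype=float)
    sub_w /= sub_w.sum()
    site_names = list(site_weights)
    site_w = np.asarray([site_weights[s] for s in site_names], dtype=float)
    site_w /= site_w.sum()
    count_p = np.asarray(egfr_site_count_probs, dtype=float)
    count_p /= count_p.sum()

    children = np.random.SeedSequence(seed).spawn(cohort_size)
    records: List[VariantRecord] = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        pid = f"P{i:05d}"

        def make_record(gene: str, site: str, **overrides) -> VariantRecord:
            form = MUTATION_FORMS[rng.choice(len(MUTATION_FORMS), p=_FORM_PROBS)]
            ref = alt = None
            if form in ("missense", "nonsense", "nonstop"):
                cls = sub_classes[rng.choice(len(sub_classes), p=sub_w)]
                ref, alt = _CLASS_TO_PAIRS[cls][int(rng.integers(2))]
            ann = _clean_annotations(rng)
            ann.update(overrides)
            return VariantRecord(
                patient_id=pid, gene=gene, site=site, form=form,
                ref_base=ref, alt_base=alt, **ann,
            )

        for gene, p in gene_probs.items():
            if rng.random() >= p:
                continue
            if gene == "EGFR":
                n_sites = (1, 2, 3)[rng.choice(3, p=count_p)]
                if n_sites == 3 and rng.random() < 0.3:
                    n_sites = 4  # ">2" bucket occasionally exceeds three
                n_sites = min(n_sites, len(site_names))
                chosen = rng.choice(len(site_names), size=n_sites, replace=False, p=site_w)
                for idx in chosen:
                    records.append(make_record("EGFR", site_names[idx]))
            else:
                records.append(make_record(gene, f"{gene}_site1"))

        # artifact records that the filters should remove
        for _ in range(rng.poisson(germline_rate)):
            records.append(
                make_record("TP53", "germline_artifact", pop_freq=float(rng.uniform(0.002, 0.05)))
            )
        for _ in range(rng.poisson(low_vaf_rate)):
            records.append(
                make_record("TP53", "lowvaf_artifact", vaf=float(rng.uniform(0.0001, 0.009)),
                            pop_freq=None)
            )
        for _ in range(rng.poisson(benign_rate)):
            records.append(
                make_record(
                    "TP53", "benign_artifact",
                    sift=float(rng.uniform(0.051, 1.0)),
                    polyphen2=float(rng.uniform(0.0, 0.446)),
                    pop_freq=None,
                )
            )
    return records
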