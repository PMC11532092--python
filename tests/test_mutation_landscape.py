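"""Variant filtering, landscape summaries, and association tests.

The exact-test oracles are written from first principles here: the 2x2
Fisher p is rebuilt by direct hypergeometric enumeration, and the 3x2
Freeman-Halton p by iterating over every integer table with the observed
margins via nested loops.
"""

import itertools
import math

import numpy as np
import pytest

from metgate import (
    MetgateError,
    SchemaError,
    VariantRecord,
    association_test,
    classify_substitution,
    egfr_site_summary,
    filter_variants,
    fisher_exact_2x2,
    gene_frequencies,
    pairwise_comparisons,
    simulate_variant_table,
)

COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def rec(patient="p1", gene="TP53", site="X1", form="missense", vaf=0.2, **kw):
    return VariantRecord(patient_id=patient, gene=gene, site=site, form=form, vaf=vaf, **kw)


class TestFilterVariants:
    def test_germline_population_frequency_cut(self):
        retained, counts = filter_variants([rec(pop_freq=0.002)])
        assert retained == [] and counts["germline_pop_freq"] == 1

    def test_low_vaf_cut(self):
        retained, counts = filter_variants([rec(vaf=0.005)])
        assert retained == [] and counts["low_vaf"] == 1

    def test_benign_requires_both_scores_agreeing(self):
        both = rec(sift=0.30, polyphen2=0.20)
        missing_pp = rec(sift=0.30)
        deleterious_sift = rec(sift=0.01, polyphen2=0.20)
        damaging_pp = rec(sift=0.30, polyphen2=0.80)
        retained, counts = filter_variants([both, missing_pp, deleterious_sift, damaging_pp])
        assert counts["predicted_benign"] == 1
        assert retained == [missing_pp, deleterious_sift, damaging_pp]

    def test_boundaries_are_exclusive_of_retention_thresholds(self):
        # pop_freq exactly 0.1% and vaf exactly 1% are retained;
        # sift exactly 0.05 is not "benign"; polyphen2 exactly 0.446 is
        at_edges = rec(pop_freq=0.001, vaf=0.01, sift=0.05, polyphen2=0.446)
        over = rec(sift=0.051, polyphen2=0.446)
        retained, counts = filter_variants([at_edges, over])
        assert retained == [at_edges] and counts["predicted_benign"] == 1

    def test_rule_order_fixes_attribution(self):
        # violates rules 1 and 2; removal is charged to rule 1
        _, counts = filter_variants([rec(pop_freq=0.01, vaf=0.001)])
        assert counts == {"germline_pop_freq": 1, "low_vaf": 0, "predicted_benign": 0}

    def test_idempotent(self):
        records = [rec(), rec(pop_freq=0.002), rec(vaf=0.001), rec(sift=0.3, polyphen2=0.1)]
        retained, _ = filter_variants(records)
        again, counts = filter_variants(retained)
        assert again == retained and sum(counts.values()) == 0

    def test_out_of_range_scores_rejected(self):
        with pytest.raises(SchemaError, match="vaf"):
            rec(vaf=1.5)


class TestGeneFrequencies:
    def test_any_gene_fraction_on_study_scale(self):
        # 261 of 317 patients carry >= 1 retained variant
        records = [rec(patient=f"p{i}", gene="EGFR") for i in range(261)]
        freqs = gene_frequencies(records, cohort_size=317)
        assert freqs["ANY"] == 82.33

    def test_multiple_variants_per_patient_deduplicated(self):
        records = [rec(site=f"s{i}", gene="EGFR") for i in range(3)]
        assert gene_frequencies(records, cohort_size=10)["EGFR"] == 10.0

    def test_empty_table(self):
        assert gene_frequencies([], cohort_size=5) == {"ANY": 0.0}


class TestClassifySubstitution:
    def test_pyrimidine_reference_kept(self):
        assert classify_substitution("C", "T") == "C>T"

    def test_purine_reference_collapsed(self):
        assert classify_substitution("G", "A") == "C>T"

    def test_enumeration_of_all_twelve_ordered_pairs(self):
        """Exactly two ordered base pairs map to each of the six classes."""
        hits = {}
        for ref, alt in itertools.permutations("ACGT", 2):
            hits.setdefault(classify_substitution(ref, alt), []).append((ref, alt))
        assert len(hits) == 6
        assert all(len(pairs) == 2 for pairs in hits.values())
        assert all(cls[0] in "CT" for cls in hits)

    def test_reverse_complement_invariant(self):
        for ref, alt in itertools.permutations("ACGT", 2):
            assert classify_substitution(ref, alt) == classify_substitution(
                COMP[ref], COMP[alt]
            )

    def test_invalid_base_rejected(self):
        with pytest.raises(SchemaError):
            classify_substitution("N", "A")


class TestEgfrSiteSummary:
    def test_bucket_distribution(self):
        records = [
            rec(patient="p1", gene="EGFR", site="L858R"),
            rec(patient="p2", gene="EGFR", site="L858R"),
            rec(patient="p2", gene="EGFR", site="T790M"),
            rec(patient="p3", gene="EGFR", site="del19"),
            rec(patient="p3", gene="EGFR", site="T790M"),
            rec(patient="p3", gene="EGFR", site="C797S"),
            rec(patient="p3", gene="EGFR", site="L718Q"),
        ]
        out = egfr_site_summary(records)
        assert out["site_count_buckets"] == {"1": 1, "2": 1, ">2": 1}
        assert out["site_fractions_pct"]["T790M"] == pytest.approx(66.67)

    def test_all_single_site(self):
        records = [rec(patient=f"p{i}", gene="EGFR", site="L858R") for i in range(4)]
        out = egfr_site_summary(records)
        assert out["site_count_fractions_pct"] == {"1": 100.0, "2": 0.0, ">2": 0.0}

    def test_planted_bucket_probabilities_recovered(self):
        """Generator round-trip at n=500 recovers the bucket mix within noise."""
        records = simulate_variant_table(500, seed=42)
        retained, _ = filter_variants(records)
        out = egfr_site_summary(retained)
        fr = out["site_count_fractions_pct"]
        # binomial 3-sigma at n≈300 EGFR-mutant patients is ~8 points
        assert abs(fr["1"] - 65.8) < 9
        assert abs(fr["2"] - 26.3) < 9
        assert abs(fr[">2"] - 7.9) < 6


def _fisher_2x2_oracle(a, b, c, d):
    """Two-sided Fisher by direct hypergeometric enumeration."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def pmf(x):
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    p_obs = pmf(a)
    return sum(
        pmf(x)
        for x in range(max(0, c1 - r2), min(r1, c1) + 1)
        if pmf(x) <= p_obs * (1 + 1e-12)
    )


def _freeman_halton_oracle(table):
    """3x2 exact p by nested-loop enumeration over all margin-preserving tables."""
    t = np.asarray(table)
    r = t.sum(axis=1)
    c0 = t[:, 0].sum()
    n = t.sum()

    def logp(col):
        lp = sum(math.lgamma(x + 1) for x in r)
        lp += math.lgamma(c0 + 1) + math.lgamma(n - c0 + 1) - math.lgamma(n + 1)
        for a, rr in zip(col, r):
            lp -= math.lgamma(a + 1) + math.lgamma(rr - a + 1)
        return lp

    obs = logp(t[:, 0])
    total = 0.0
    for a0 in range(r[0] + 1):
        for a1 in range(r[1] + 1):
            a2 = c0 - a0 - a1
            if 0 <= a2 <= r[2]:
                lp = logp((a0, a1, a2))
                if lp <= obs + 1e-10:
                    total += math.exp(lp)
    return min(total, 1.0)


class TestAssociationTest:
    def test_gender_table_reproduces_reported_p(self):
        p, method = association_test([[7, 7], [43, 39]])
        assert method == "chi2"
        assert round(p, 3) == 1.000

    def test_symmetric_table(self):
        p, _ = association_test([[5, 5], [5, 5]])
        assert p == pytest.approx(1.0)

    def test_fisher_dispatch_on_small_expected_counts(self):
        p, method = association_test([[1, 9], [8, 2]])
        assert method == "fisher"
        assert p == pytest.approx(_fisher_2x2_oracle(1, 9, 8, 2), abs=1e-9)

    def test_2x2_fisher_matches_enumeration_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(60):
            a, b, c, d = rng.integers(0, 10, size=4)
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            assert fisher_exact_2x2([[a, b], [c, d]]) == pytest.approx(
                _fisher_2x2_oracle(a, b, c, d), abs=1e-9
            )

    def test_3x2_freeman_halton_matches_enumeration_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            t = rng.integers(0, 7, size=(3, 2))
            if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
                continue
            p, method = association_test(t, method="fisher")
            assert method == "fisher-freeman-halton"
            assert p == pytest.approx(_freeman_halton_oracle(t), abs=1e-9)

    def test_l858r_omnibus_significant(self):
        # mutated/unmutated by MET status group, reconstructed from the
        # reported group frequencies (50.0% of 14, 68.8% of 16, 25.8% of 66)
        p, method = association_test([[7, 7], [11, 5], [17, 49]])
        assert method == "chi2"
        assert p < 0.01

    def test_empty_table_rejected(self):
        with pytest.raises(MetgateError):
            association_test([[0, 0], [0, 0]])


class TestPairwiseComparisons:
    def test_identical_proportions_give_p_near_one(self):
        out = pairwise_comparisons([[5, 5], [5, 5], [5, 5]])
        assert all(v["p"] > 0.9 for v in out.values())
        assert all(v["adjustment"] == "none" for v in out.values())

    def test_one_divergent_group_flags_its_pairs(self):
        out = pairwise_comparisons([[6, 0], [0, 6], [0, 6]])
        assert out[(0, 1)]["p"] < 0.05
        assert out[(0, 2)]["p"] < 0.05
        assert out[(1, 2)]["p"] == pytest.approx(1.0)
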