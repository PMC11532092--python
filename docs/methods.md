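# Methods

## The classification model

A sample's MET status is called from seven chromosome-7 gene copy numbers
(GCN; diploid baseline 2.0). The call is a two-stage rule:

1. **Amplification gate (conjunction).** For each denominator gene g in the
   model, compute CN(MET)/CN(g). The sample is AMPLIFICATION iff *every*
   ratio meets its threshold. Because the denominators share chromosome 7
   with MET, whole-chromosome gains cancel in the ratio; only focal MET
   gains pass.
2. **Polysomy gate.** Among non-amplified samples, MET GCN >= the polysomy
   threshold calls POLYSOMY, otherwise NEGATIVE. Absolute GCN (not a ratio)
   is what distinguishes a global chromosome-7 gain from a diploid sample.

The published instance is MET/CYP3A4 >= 1.12, MET/CDK6 >= 1.20,
MET/BRAF >= 1.53, polysomy GCN >= 2.8. All comparisons are inclusive.

The FISH reference rules are: MET/CEP7 signal ratio >= 2 is amplification;
otherwise mean MET signals per nucleus >= 5 is polysomy; otherwise negative.
"Mean GCN" in the polysomy rule is taken as the mean MET signal count.
Means are computed over at least 50 nuclei; when per-nucleus counts are
supplied they override any stored means (single source of truth). Missing
FISH is treated as absent, never as NEGATIVE.

## Training procedure

Given paired profiles and FISH labels containing all three classes:

* **Per-gene ROC cutoff.** For each candidate denominator, the threshold is
  the observed ratio value maximising Youden's J = sensitivity +
  specificity − 1 for the rule `ratio >= t`, positives being FISH
  amplification vs the pooled polysomy/negative rest. Restricting candidates
  to observed values keeps thresholds exactly reproducible; among J ties the
  smallest value is chosen (maximal sensitivity). Fitting amplification
  against the pooled rest (rather than against negatives only) follows the
  two-subtype framing of the cutoff-selection step.
* **Subset enumeration.** All 63 nonempty subsets of the six candidate
  genes are evaluated. Per-gene thresholds are fitted independently and
  combined conjunctively; the enumerated dimension is the subset choice, not
  joint threshold optimisation.
* **Polysomy cutoff refit.** Inside each candidate, the MET-GCN cutoff is
  refitted by the same ROC rule on samples the candidate's gates call
  non-amplified, restricted to FISH polysomy/negative members — mirroring
  the "among the other cases" structure of the final model. If a candidate's
  gates swallow one of those classes entirely, the cutoff falls back to the
  full polysomy/negative subcohort so the enumeration stays total.
* **Selection.** Candidates are ranked by (1) three-class agreement with
  FISH, (2) amplification sensitivity, (3) fewer gates, (4) lexicographically
  smaller gene subset. The tie-break order is a package convention; nothing
  in the procedure itself distinguishes tied candidates.

There is no cross-validation: the model is fitted and scored on the same
cohort (as the reference study did with its 96 paired samples), and
`train()` warns that agreement is in-sample.

## Concordance statistics

* One-vs-rest sensitivity is the per-class recall against FISH; specificity
  is the fraction of FISH non-class samples NGS also calls non-class.
  Overall agreement (trace/n) is algebraically the prevalence-weighted mean
  of the three sensitivities — a property test asserts this on random
  matrices.
* The 95% CI for overall agreement is the exact Clopper–Pearson interval
  (beta quantiles via statsmodels). It was chosen because, for 71/96
  concordant samples, it reproduces the reported interval 64.0%–82.4% where
  Wilson and Wald do not.
* GCN stratification defaults to edges (2, 5) with open outer bins, the
  zone where the two assays disagree most; empty bins report an undefined
  metric (NaN sentinel), not zero.
* Binary collapse (amplification vs rest) merges the non-positive rows and
  columns, conserving counts. Computed from the matrix implied by the
  reported per-class metrics it gives 92.7%, slightly below the reported
  combined figure of 93.9%; the package always computes from the matrix.
* Reported percentages use half-up rounding to 1 decimal (2 decimals in the
  mutation summaries, which are conventionally printed that way).

## Variant filtering and association tests

Filtering removes, in order: population allele frequency > 0.1% (germline);
VAF < 1%; and variants both predictors call harmless (SIFT > 0.05 AND
PolyPhen2 <= 0.446). A variant missing either score survives rule 3 as
"unknown significance" — the only reading under which retained variants can
be deleterious, likely deleterious *or* of unknown significance. The rules
are pure predicates, so the retained set is order-free; per-rule removal
counts are attributed in the stated order. The PolyPhen2 column is treated
as the HDIV score.

Substitutions are collapsed to the six pyrimidine-reference classes
(C>T, C>A, C>G, T>C, T>A, T>G) by reverse-complementing purine-reference
pairs.

Association between mutation carriage and MET-status groups uses Pearson
chi-squared when every expected cell count is >= 5 and Fisher's exact test
otherwise (the classic rule; the 2×2 chi-squared applies Yates continuity
correction, matching R's `chisq.test` default, which is what reproduces the
reported clinical-table p-values). For three groups the Fisher branch is a
Freeman–Halton test by full enumeration of margin-preserving tables, summing
probabilities no greater than the observed table's (with a 1e-10 log-scale
tolerance for floating-point ties). Pairwise group comparisons report raw
p-values with an explicit "no adjustment" flag; the reported pairwise values
are consistent with unadjusted testing.

## Synthetic cohort generator

Per sample: a class is drawn from (14/96, 16/96, 66/96) — the exact
three-class mix of the reference FISH cohort — then purity ρ ~ U(0.2, 0.9)
and a tumour genotype:

* NEGATIVE: all seven genes and CEP7 at 2 copies;
* POLYSOMY: all genes and CEP7 at k copies, k ~ U{3..6};
* AMPLIFICATION: MET at m ~ U{6..30} on a background of 2 or 3 copies
  carried by the other genes and CEP7.

Bulk NGS GCN per gene is ρ·copies + (1−ρ)·2 + N(0, sd), floored at 0.1,
with sd defaulting to 0.15 — chosen so that low-purity samples place their
discordance in the ambiguous GCN 2–5 zone. FISH draws 50 nuclei; each is a
tumour nucleus with probability ρ, with MET/CEP7 counts Poisson around the
tumour copy numbers (floored at one signal), normal nuclei around 2. CEP7 in
amplification cases follows the chromosome background, which is exactly why
FISH separates focal gain (ratio ≈ m/background) from polysomy (ratio ≈ 1).

**Noise-free mode.** `gcn_noise_sd = 0` switches off *all* measurement
noise: bulk values and nucleus counts equal the latent mixture means
exactly. This makes the generator/classifier closure analytic — FISH labels
equal truth whenever m/background >= 2 and k >= 5, and training reaches
agreement 1.0 — rather than holding only up to Poisson wobble, which would
fail with probability ~1/2 for amplifications sitting exactly at ratio 2.
The end-to-end recovery checks therefore use noise 0, purity 1 and
polysomy_range (5, 6); with k ∈ {3, 4} a polysomy case is, by the FISH
definition itself, indistinguishable from negative.

**Discordance-zone mode** draws only amplification/polysomy classes (1:1) at
purity 0.2–0.4 with m ∈ {6..8}, k ∈ {3, 4}, concentrating bulk MET GCN in
[2, 5). Diploid negatives are excluded because their bulk GCN straddles 2
symmetrically under noise. This mode exists to exercise the stratified
agreement statistics, not to mimic a clinical population.

Randomness flows from a single integer seed through per-sample child
streams (numpy `SeedSequence.spawn`), so cohorts sharing a seed agree on
common sample indices regardless of cohort size.

The variant-table generator plants per-gene Bernoulli mutation probabilities
taken from the observed resistance-cohort landscape (EGFR 0.5994, TP53
0.4385, …), EGFR site identities from hotspot weights, EGFR site counts
from the observed (0.658, 0.263, 0.079) bucket mix, substitution classes
with C>T at 0.411, and appends Poisson-rate artifact records violating each
filter rule (default 0.1 per patient per rule; at rate 0 every record
survives filtering by construction).

## What the synthetic data does and does not show

The generator reproduces the *structure* the method assumes — focal vs
whole-chromosome geometry, purity dilution, independent per-gene noise,
nucleus-count sampling — but not real-panel artefacts: GC/coverage bias
correlated across genes, subclonal heterogeneity, copy-neutral LOH, FISH
scoring ambiguity, or inter-gene noise correlation. Passing the closure and
recovery tests shows the pipeline is internally consistent and the search is
exhaustive; it does not certify the published thresholds on real cohorts,
and the specific fitted values (1.12/1.20/1.53/2.8) are reproducible only
from the original patient data, which is not publicly deposited.

## Numerical choices

* Gate comparisons use an inclusive `>=` with relative tolerance 1e-9 so
  that printed-precision boundaries behave exactly (3.36/3.0 is one ulp
  below 1.12 in binary floating point). No rounding is applied to copy
  numbers before comparison.
* ROC thresholds are always observed data values; determinism everywhere —
  `train()` involves no randomness and returns identical results on
  identical cohorts.
* Degenerate inputs raise typed errors: missing gate genes are a hard error
  (never silently NEGATIVE), single-class label vectors raise a
  degenerate-labels error, zero denominators an undefined-ratio error.
  Metrics with empty denominators return a NaN sentinel rather than raising.
* Report JSON wraps results in metadata (tool version, seed, config hash,
  timestamp); only the timestamp varies between identical runs — the
  results payload is a pure function of inputs and seed.

## Problem sizes

Default test/verification scales: training-recovery cohorts of n = 300
(noise-free) and n = 30–40 (optimality oracle, 50 cohorts); coverage checks
with 2,000 binomial draws at n = 96; variant-recovery tables of 317–5,000
patients; the exact-test oracle enumerates all 2×2 tables with margins
<= 12. These sizes make every property analytic or statistically decisive
while keeping the full suite under a minute of compute.

## Known limitations

* The polysomy/negative boundary is intrinsically weak at low purity; the
  reference comparison itself shows 37.5% polysomy sensitivity, and the
  synthetic discordance zone reproduces that behaviour.
* Per-gene ROC fitting followed by subset enumeration is not joint threshold
  optimisation; the optimality guarantee is exhaustiveness over the defined
  search space, not global optimality over all conceivable gate models.
* Association tests assume independent patients and fixed margins;
  pairwise p-values are unadjusted by design and flagged as such.
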