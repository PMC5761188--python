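# Methods

## Analysis model

The unit of analysis is the carrier, not the variant. For a scope S (one
gene, a gene set, or a prediction stratum) and a consequence class
(loss-of-function or missense), a subject is a carrier if they hold at
least one qualifying variant of that class in S; a subject with several
qualifying variants, or variants in several genes of a set, counts once.
Every comparison uses the full cohort sizes as denominators — per-gene
sequencing coverage does not change the population at risk.

A variant qualifies when it passes three independent filters:

* **Consensus QC** — caller support ≥ 2, total depth ≥ 10, alternate-read
  fraction ≥ 0.20. All boundaries are inclusive, matching "at least"/"≥"
  semantics; the test suite probes each threshold at the value and ±ε.
* **Rarity** — every non-null reference-database frequency (ExAC
  overall/NFE, EVS overall/European) ≤ 0.001. A null field means the
  variant was never observed in that database and is treated as frequency
  0; readers therefore never coerce a blank cell to 0.0, keeping "absent"
  and "observed at 0 in this sample" distinguishable.
* **Consequence** — classified on the canonical transcript by the ordered
  preference (1) longest CCDS translation without internal stop codons,
  (2) longest Ensembl/Havana-merged translation, (3) longest translation,
  (4) longest non-coding transcript. Length ties break to the
  lexicographically smallest transcript id purely for determinism.
  Loss-of-function means stop-gained, frameshift, or essential splice site
  (the two intronic bases at the donor/acceptor); `splice_region_variant`
  is *not* loss-of-function. Stop-gains annotated on insertions are
  classified by their annotated term, never re-derived from the HGVS
  string. An unknown term maps to OTHER with a logged warning rather than
  an error, so one bad annotation cannot abort a cohort run.

Missense variants carry a five-tool profile. A tool flags a variant when
Condel = deleterious, PolyPhen-2 ∈ {probably, possibly damaging},
SIFT = deleterious, CADD ≥ 15, or REVEL ≥ 0.5 (both score thresholds
inclusive). A missing call or score never flags, so `all_five` requires
five affirmative, present calls.

## Exact inference

Conditional on both margins, the case-carrier count follows Fisher's
noncentral hypergeometric distribution with odds-ratio parameter ψ,
P(k) ∝ C(n₁,k)·C(n₂,K−k)·ψᵏ over k ∈ [max(0, K−n₂), min(K, n₁)]. All
probabilities are computed as log-weights (via `gammaln`) normalised by
log-sum-exp and summed exhaustively over the support, which for carrier
data never exceeds the total carrier count — exact and fast.

* **Two-sided p** uses the minimum-likelihood rule at ψ = 1: sum P(k) over
  outcomes with P(k) ≤ P(a)·(1 + 10⁻⁷). The relative tolerance protects
  probability ties against floating-point rounding; without the tie rule a
  3-vs-0 table would lose its opposite-tail point mass.
* **Point estimate** is the unconditional cross-product a·d/(b·c). Kinds:
  FINITE; ZERO (a = 0, c > 0, rendered "0"); UNDEFINED (c = 0 with a > 0,
  or a = c = 0, rendered "Und"). The conditional MLE (the ψ solving
  E[X | ψ] = a, found by Brent's method on log ψ in [−70, 70]) is exposed
  for cross-checks and invariants only — the two estimators differ in the
  third decimal on this package's typical tables.
* **Confidence intervals** invert the one-sided conditional tail tests:
  low solves P_ψ(X ≥ a) = (1−level)/2, high solves P_ψ(X ≤ a) = (1−level)/2,
  each by root finding on log ψ (xtol 10⁻¹⁰). At the support boundary the
  corresponding bound is exact: low = 0 when a is minimal, high = ∞ when a
  is maximal, so zero-cell tables yield one-sided intervals such as
  (0.37, ∞) or (0, 35.30). A fully determined table (degenerate support)
  returns (0, ∞).
* **Yates chi-square** floors the continuity correction at zero
  (|ad − bc| < N/2 gives statistic 0, p = 1) and returns p = 1 on any zero
  margin. It is used for the large missense aggregates and the prediction
  strata, where the exact test's discreteness no longer matters; Fisher is
  used per gene and for the sparse loss-of-function aggregates. The
  assignment is configuration, not a cell-count heuristic, so reports are
  reproducible from the config alone.

No multiplicity correction is applied to the burden report by default (the
rows are descriptive); a Bonferroni factor can be recorded via
`AnalysisConfig(bonferroni=True)`.

## Synthetic cohorts

The generator reproduces the statistical structure the analysis assumes
and nothing below it: no reads, no genotype likelihoods, no linkage
disequilibrium. Carrier status per (subject, gene, class) is Bernoulli,
with the case-arm probability derived from the control rate through the
odds transform odds_case = OR·odds_control, so the true carrier odds ratio
equals the configured effect. Each carrier receives one qualifying record
(optionally more, to exercise collapsing); annotations are drawn to pass
the filters: depth ~ Poisson(170) floored at 10 (matching typical panel
coverage), alt fraction uniform on [0.35, 0.65], support 2–3 callers.

Defaults emulate the study conditions: 1043 cases vs 944 controls over the
packaged 56-gene panel; per-gene control carrier rates calibrated to the
printed control-arm totals (LoF 13/(56·944) ≈ 2.5×10⁻⁴, missense
≈ 7.4×10⁻³) with pooled odds ratios 1.83 (LoF) and 1.07 (missense). These
calibrated defaults are working values consistent with the printed counts,
not estimates of the study's true per-gene rates. The MAF model mixes a
point mass at "absent from the reference databases" (weight 0.65, the
fraction of packaged LoF rows unobserved in both databases) with a
log-uniform frequency on [10⁻⁵, 10⁻³]. The five prediction tools share a
latent truly-pathogenic indicator (fraction 0.25, per-tool sensitivity
0.8, false-positive rate 0.25, 2% missingness), which induces the
between-tool correlation real ensembles show — independent per-tool draws
would make the "all five" stratum vanish.

Decoy records exercise the filters: QC artifacts each violate exactly one
criterion (support 1, depth 9, or fraction 0.19) and rarity decoys carry
database frequencies well above 0.001. Every record's intended fate is
labelled in the `SimulationTruth`, so leakage of excluded records into
carrier counts is a detectable bug, not a silent bias. The packaged
loss-of-function variant list can be spiked into any sufficiently large
cohort, assigning each printed carrier to a distinct subject; spiking
twice is refused.

What passing tests on these cohorts do **not** show: robustness to
population stratification, relatedness, somatic contamination (low-VAF
artifacts beyond the 20% cut), per-gene coverage differences, or
correlated errors between callers — none of which the generator models.

## SNP co-occurrence scan

For each gene–SNP pair the scan cross-classifies subjects by risk-allele
carriage (dominant coding, dosage ≥ 1; an additive allele-count coding is
available) and rare-variant carriage, separately within cases and
controls, and applies the two-sided Fisher test. Subjects without a dosage
record are excluded and counted in a log line. "Adjusted for multiple
testing" is implemented as Bonferroni across every test the scan emits;
since no published procedure is specified for this analysis, the raw p
values are always reported alongside and the adjustment is labelled a
reconstruction in the scan metadata.

## Problem sizes in the test suite

Stochastic invariants run at sizes chosen to keep the default suite brisk
while leaving comfortable statistical margins: Fisher-p oracle equivalence
exhaustively for arm sizes ≤ 12 plus seeded random tables to 30; CI
coverage at ψ = 2 over 800 simulated tables (threshold ≥ 93% at nominal
95%); parameter recovery for OR ∈ {1, 2, 4} at 5000/5000 subjects × 200
replicates (median within 10%, type-I ≤ 0.055); interaction family-wise
error over 300 null scans of the 56-gene panel (≤ 0.07 at nominal 0.05);
independence calibration over 1000 gene-level tests at 1000 subjects per
stratum. All seeds are fixed.

## Known limitations

* Homozygous carriers and multi-allelic sites are not modelled; the data
  model stores per-subject presence and counts a homozygote once. The
  packaged carrier counts are per-subject, so this cannot be resolved from
  them.
* The rarity rule applies "every available frequency column ≤ threshold";
  whether the original per-database filters were joint or per-column is
  not recoverable from the published tables, and the packaged LoF rows
  satisfy either reading.
* The conditional exact CI is conservative (coverage ≥ nominal), inherited
  from the discreteness of the hypergeometric; no mid-p variants are
  offered.
* The co-occurrence scan's statistic and adjustment are a defensible
  reconstruction, not a replication of an exactly specified procedure.
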