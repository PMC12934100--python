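# Methods

## The dormancy–proliferation model

The package assumes a two-state transcriptional model of melanoma: a
proliferative, melanocytic program and a dormant, mesenchymal/EMT-like
program marked by reduced mitotic activity. The analysis treats the states
as a per-sample axis rather than a hard partition: the composite score
S = (U − D)/(|U| + |D|) contrasts the summed per-gene z-scores of four
up-regulated (TACSTD2, EREG, SOX9, LPPR4) and four down-regulated (LAMA1,
TMEM27, AMIGO2, MGAT5B) signature genes. Gene identifiers are opaque
strings; no symbol remapping is attempted (LPPR4's current symbol is
PLPPR4, but the packaged signature keeps the name used with the cohort).

### Normalization of the score

Among per-sample normalizations of U − D, dividing by |U| + |D| is the one
that guarantees S ∈ [−1, 1] with equality exactly when U and D have opposite
signs, and places the boundary S = 0 at U = D. Two conventions are fixed and
documented rather than configurable:

* **Boundary tie**: S = 0 (including the degenerate U = D = 0 case) is
  classified *proliferative*, so "dormant" always means strictly positive
  evidence.
* **z-scores** use log2(TPM+1), per gene, across the cohort being scored
  (cohort-relative scoring), with the sample standard deviation (n−1).
  Constant genes get z = 0 and are reported, not errored: FFPE cohorts
  routinely contain non-expressed genes and silently dropping or failing on
  them would be worse.

A consequence worth knowing: whenever a sample's up-sum is positive while
its down-sum is negative, S is exactly ±1. Strongly separated cohorts
therefore produce score distributions concentrated at the extremes; the
score's value is in ranking and classifying, not in resolving gradations
near the extremes.

### Classifier evaluation

ROC curves are built by a full threshold sweep (no interpolation dropping)
and integrated by the trapezoid rule, which makes the AUC identical to the
Mann–Whitney U statistic scaled by 1/(n₁n₂) with ties credited ½. The test
suite checks this equality against a brute-force concordant-pair count on
instances up to 50 samples. Whether a published AUC of this kind is
resubstitution or cross-validated is often ambiguous; this package computes
resubstitution AUC when given truth labels and reports it as such.

## Signature re-derivation

1. Per-gene two-sided Wilcoxon rank-sum on log2(TPM+1) between phenotypes.
   The exact null distribution is used whenever a gene has no ties and the
   smaller group has ≤ 25 samples; otherwise the normal approximation with
   continuity correction. Exactness is not cosmetic: with 11 + 11 samples
   the normal approximation cannot produce a two-sided p below 8.1 × 10⁻⁵,
   which sits only ~3× below a Bonferroni threshold of 0.05/219, so the
   approximation would randomly drop truly separated genes.
2. Bonferroni adjustment over all tested genes (α = 0.05), the stated
   multiple-testing convention for this analysis.
3. Genes passing the filter are z-scored; a PCA over samples is computed and
   the component whose sample scores correlate most strongly (in absolute
   value) with the phenotype label ranks genes by absolute loading.
4. The top-k genes (default k = 8) are assigned up/down by the sign of their
   dormant-minus-proliferative median difference. Ties break by larger
   absolute loading, then lexicographic gene id. Fewer than k passing genes
   is an error naming the shortfall, not a silent shrink.

## Co-expression network stage

Unsigned weighted network: a_ij = |cor(g_i, g_j)|^β with β = 6 (the common
unsigned soft-threshold default; no scale-free fit routine is included).
Topological overlap is the standard form

TOM_ij = (Σ_{u≠i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij),

with unit diagonal; for two genes it reduces exactly to the adjacency, which
the tests exploit as a closed-form oracle. Modules come from average-linkage
hierarchical clustering of 1 − TOM with a **static** height cut — chosen for
determinism over dynamic tree cutting — discarding clusters below
min_module_size = 5.

The cut height default is 0.985. A note on magnitudes: TOM values scale with
shared-neighbor mass, so small modules in small cohorts live at overlaps of
only 0.05–0.5, i.e. dissimilarities 0.5–0.95, while uncorrelated background
pairs sit at ≈ 0.999. Cuts far below ~0.95 dissolve genuinely correlated
blocks into singletons (a block of ten genes with within-correlation 0.9 and
β = 6 has within-block TOM ≈ 0.53). The default separates planted structure
from background across the generator's operating range; it is a parameter,
and real large cohorts may warrant lower cuts.

Eigengenes are first right-singular vectors of the module's z-score
submatrix (unit norm), sign-oriented to correlate non-negatively with the
module's mean profile. Module–trait association is a Pearson correlation
with the two-sided p from the t-transform t = r√((n−2)/(1−r²)). The hub is
the gene with maximal intramodular connectivity k_i = Σ_{j∈module} a_ij
("central degree" of the module graph), ties broken lexicographically —
deliberately connectivity-based rather than eigengene-membership-based.

## Variant concordance

Protein-level variant labels ("BRAF p.V600E", "NRAS Q61K", bare "V600E")
are normalized by stripping the optional `p.` prefix and upper-casing; `WT`
is an explicit wild-type call; `na`, `-` and empty cells are missing.
Classification per sample: same gene + change at DNA and RNA level →
confirmed_same_site (with rna_higher/rna_lower/rna_equal by strict
comparison when both VAF percentages are present); same gene, different
change → different_site; RNA wild type → not_detected_rna; missing RNA, or
missing/wild-type DNA → not_evaluable. Summaries partition records per gene
and the invariants (total = sum of categories; higher+lower+equal = pairs
with both VAFs) are property-tested on random tables. Gene symbols are not
validated against any registry; the packaged cohort table intentionally
preserves its printed `BRAV` typo, and an alias map can fold it at load time.

## Outcome analysis

Kaplan–Meier product-limit estimation and the two-sample log-rank test
(statistic (ΣO − ΣE)²/ΣV, hypergeometric expectations and variances per
distinct event time, p from χ²₁) are delegated to `lifelines`; the test
suite pins the conventions against fully hand-worked ≤ 4-subject examples,
including events-before-censorings at tied times. Therapy response uses the
Pearson χ² statistic with expected counts from the margins and
df = (r−1)(c−1); no continuity correction by default (a documented switch
enables Yates on 2×2). Cohort dichotomization for outcome analysis is always
score > 0 → dormant — the score's own boundary, never a median split.
Cox proportional-hazards modeling is out of scope.

## The synthetic-cohort generator

The generator emulates the study conditions the analysis assumes; its
defaults are the fixed conditions under which the pipeline's recovery
properties are stated, not tuning knobs.

* **Cohort**: 11 dormant + 11 proliferative samples — the 22-cell-line
  discovery setting.
* **Expression**: Gaussian on the log2 scale (baseline per-gene means
  uniform on [3, 8]), exponentiated to TPM-like values via 2^x − 1. The
  pipeline consumes TPM and z-scores log values, so a count model would add
  nothing the tests could see.
* **Signature effect**: ±effect_size/2 (default effect_size = 2 on the log2
  scale) for the 8 planted signature genes; residual SD 0.5.
* **Planted module**: 12 genes (hub = TACSTD2, which is also an up-gene)
  driven by a single latent factor with per-gene loadings calibrated so
  plain members correlate pairwise at 0.7 and the hub at 0.9
  (module_correlation + hub_boost), guaranteeing the hub the largest
  expected intramodular connectivity. The factor's *realized* sample
  correlation with the standardized phenotype indicator is fixed exactly at
  module_trait_r = 0.6 by Gram–Schmidt construction, so the planted
  module–trait correlation is a condition of the simulation rather than a
  random variable with ±0.15 sampling noise at n = 18. Defaults were fixed
  once from the expected-adjacency calculation (a weaker module lets the
  phenotype-driven |r| ≈ 0.8 among signature genes, amplified by β = 6,
  rival the hub's module links).
* **Background**: 200 independent genes.
* **Survival**: exponential event times, baseline median 24 months, dormant
  hazard = 3 × baseline; independent censoring flags at rate 0.2 with
  censoring times uniform before the latent event. Response is Bernoulli
  (0.15 dormant vs 0.50 proliferative responder probability).
* **Variant pairs**: one BRAF/NRAS driver per sample; RNA confirms the same
  site unless it comes back WT (p = 0.1) or at a different site (p = 0.08);
  among comparable pairs RNA VAF exceeds DNA VAF with probability 12/14,
  the rate observed in the cohort table.
* **Single cell**: 200 cells per sample; the hub gene is expressed in a
  uniform (2 %, 20 %] fraction of cells per sample, other signature genes in
  30–90 %.
* **Seeding**: one integer seed; every generator draws from its own
  hierarchically spawned stream, so outputs are bit-identical across runs
  and independent across stages.

What the generator does **not** emulate: library-size or GC artefacts,
count-level noise (negative binomial dispersion), batch effects,
tumor-microenvironment admixture, correlated censoring, or RECIST's ordinal
response scale (response is binary). Passing the planted-truth tests shows
the estimators recover the structures they target under the stated model —
it does not certify performance on real FFPE cohorts.

## Numerical and procedural choices

* Wilcoxon with all-tied values returns p = 1 (no separation) rather than a
  0/0 variance failure; direction is "none".
* Degenerate genes: zero rows in z-scores, zero off-diagonal adjacency.
* Eigengene sign: non-negative correlation with the module mean; trait
  correlations therefore have interpretable signs.
* Log-rank calibration is measured on 10,000 null cohorts (30 + 30
  exponential samples, no censoring). The asymptotic test's true level at
  this sample size is slightly above nominal (~0.054), so the rejection-rate
  estimate needs that many replicates for its own noise (SD ≈ 0.002) to be
  small against the documented 0.04–0.06 acceptance band.
* Problem sizes in the test suite (cohorts of 18–100 samples, 50–100 seed
  replicates for recovery rates, 200 replicates for power) were chosen as
  the smallest sizes at which the binomial noise of the measured rates is
  comfortably below the margins being asserted.

## Known limitations

* The static tree cut is a deliberate simplification of dynamic tree
  cutting; very unbalanced module sizes on real data may need per-dataset
  cut heights.
* The score saturates at ±1 for any sample whose up- and down-sums disagree
  in sign, limiting within-class resolution.
* The exact Wilcoxon path is quadratic-ish in group size and is therefore
  capped at min-group ≤ 25; larger cohorts fall back to the asymptotic test,
  whose tail resolution is limited.
* Variant parsing targets simple protein-change notation (as printed in
  cohort tables); genomic coordinates, indel normalization and VCF semantics
  are out of scope.
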