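# Methods

This note documents the statistical model behind `virowas`, the defaults
that matter, the design choices made where the procedure was genuinely
open, and what the synthetic-data experiments do and do not demonstrate.

## Triage decision rules

Contigs are triaged strictly in this order: length screen → host-like
exclusion → candidate-viral criteria → BUSCO removal → completeness
filter. Each contig receives exactly one verdict.

* The length screen keeps contigs **strictly longer** than 2000 bp.
* The host-like exclusion is read as a **conjunction**: a contig is
  excluded iff it has more than 10 host genes **and** more than five
  times as many host as viral genes. The sentence describing this rule
  admits a two-independent-rules reading; the conjunction matches
  CheckV-based prescreens in common use and is the permissive
  interpretation. The alternative can be composed from
  `hostlike_exclusion` by callers that want it.
* Candidate criteria (any-of): viral genes strictly greater than host
  genes; detector score strictly > 0.90 with p < 0.01; annotated viral by
  the secondary tool. `fired_rules` records all criteria that held.
* The BUSCO ratio (bacterial universal single-copy orthologs over total
  genes) removes a candidate at **≥ 5%**, evaluated as an exact rational
  comparison (`Fraction(busco, total) >= 1/20`), so 1 BUSCO in 20 genes
  is removed. Contigs with zero predicted genes skip this rule.
* Completeness must strictly exceed 50%.

## vOTU clustering

Dereplication at species level uses greedy longest-first centroid
clustering: sequences are visited by descending length (ties broken by
id); each joins the first centroid with identity ≥ 95% and coverage
≥ 0.70, else founds a new cluster. Because centroids are visited in
founding order and a sequence is only ever attached to a centroid, the
representative (the centroid) is the longest member by construction.

Open choices and how they were fixed:

* **Coverage denominator** — the aligned fraction is computed on the
  *shorter* sequence of the pair (union of aligned intervals ÷ shorter
  length). This is the permissive convention standard in viral
  dereplication; the identity of a pair is the alignment-length-weighted
  mean of segment identities.
* **Threshold strictness** — thresholds are inclusive (≥ 95, ≥ 0.70); a
  strict variant (`strict=True`) is available because ">" phrasing also
  appears in descriptions of this criterion.
* Clusters whose members are all external-catalog genomes are dropped, so
  the catalog remains anchored to sequences observed in the study itself.

Quality tiers follow CheckV conventions: complete (= 100% completeness),
high (≥ 90%), medium (≥ 50%), low otherwise, with a separate
low-contamination flag at < 10%.

## Abundance model

For one sample and one vOTU, with per-base depths d₁…d_L (zeros included):

1. **Trimmed depth** — sort depths ascending and drop ⌊0.1·L⌋ positions
   from each end, then average. The floor convention never removes more
   than 10% per side and removes nothing for L < 10; ranking is a stable
   sort, so ties break by position and the result is permutation-
   invariant and deterministic.
2. **Confirmation** — the depth is set to 0 when an independent read
   classifier assigned no reads to the vOTU (guards against spurious
   coverage from shared or repetitive regions).
3. **Closure** — depths are divided by the per-sample total. All-zero
   samples are retained as all-zero rows (flagged with a warning) so the
   sample sets of the two modalities stay aligned.

Family-level profiles sum the relative abundances of member vOTUs; row
sums are preserved exactly. The virus-to-bacterium ratio divides each
entity's mapped reads by its genome length ("cell count") and takes the
ratio of the viral to bacterial totals; an absent bacterial fraction
yields +inf with a warning rather than an exception.

## Annotation

Protein hits are first filtered at identity ≥ 30%, query and subject
coverage ≥ 50%, bit score ≥ 50 (all inclusive, matching the semantics of
the homology-search thresholds they emulate). Family votes count
**distinct proteins** per family — a protein hitting the same family
repeatedly votes once; a protein hitting two families votes once in each.
Genomes with fewer than 30 genes are assigned to the top family iff its
vote count strictly exceeds one-fifth of the gene total; genomes with 30
or more genes need at least 10 votes. A tie for the best family yields
`unclassified` (conservative). Votes are computed over *filtered* hits.

Kingdom (eukaryotic/prokaryotic) derives from the family via a fixed
shipped lookup covering the families the diversity analyses track;
unknown families map to `unknown`, never an error.

## Diversity statistics

* **Alpha** — observed richness counts vOTUs with nonzero relative
  abundance; the Shannon index uses natural logarithms. On a kingdom
  subset the profile is restricted and renormalized within the subset
  before the index is computed, matching the proportion handling of the
  standard community-ecology routines.
* **Beta** — profiles are square-root transformed, then Bray–Curtis
  distances computed. Distances between all-zero rows are defined as 0
  with a warning.
* **PCoA** — Gower centering of −D²/2 followed by symmetric
  eigendecomposition; coordinates are eigenvectors scaled by √λ for
  eigenvalues above a relative tolerance of 1e−10; explained variance is
  λᵢ over the sum of positive eigenvalues. Negative eigenvalues (from
  non-Euclidean distances) are excluded rather than corrected.
* **PERMANOVA** — the one-way adonis decomposition:
  SS_total = Σ_{i<j} d²ᵢⱼ/N over all pairs, SS_within the analogous
  per-group sum, R² = 1 − SS_within/SS_total, and
  pseudo-F = (SS_between/(k−1))/(SS_within/(N−k)). The permutation
  p-value is (1 + #{F_perm ≥ F_obs})/(1 + n_perm) with a default of 999
  permutations; the permutation stream is seeded and keyed to the sorted
  sample ids, so the result is invariant to input row order. Note that a
  permutation reproducing the observed partition ties F_obs, so the
  minimal attainable p is only reached when no permutation recreates the
  grouping — with ≥ 12 samples per group this is essentially certain.

## Signature calling

Per modality, a vOTU is tested only if it is nonzero in at least 10% of
that modality's samples (configurable); untested vOTUs are reported
`not_tested`, never silently `not_significant`. The test is the two-sided
Wilcoxon rank-sum: exact by enumeration for tie-free samples with
n₁+n₂ ≤ 12, otherwise the normal approximation with tie and continuity
corrections. p-values are Benjamini–Hochberg adjusted **within each
modality across all tested vOTUs** (the natural reading of requiring
significance "in both datasets"; a joint adjustment across modalities
would couple the two error rates).

A vOTU is `case_enriched` iff q < α in both modalities and the mean
case−control difference is positive in both (mirrored for
`control_enriched`); α defaults to 0.05. Direction uses the difference of
group means to match fold-change semantics; fold changes are reported
with a pseudocount of 1e−9 applied only at reporting time.

Cross-modality concordance is Fisher's exact test on the 2×2 table
cross-classifying {differential in VLP} × {differential in bulk} over
vOTUs tested in both modalities. The two-sided p sums hypergeometric
probabilities of all tables (margins fixed) at most as probable as the
observed one, with 1e−12 relative slack for floating-point ties; the
reported odds ratio is the sample cross-product (a·d)/(b·c) — a closed
form that an enumeration oracle can check — **not** the conditional
maximum-likelihood estimate some statistical environments report, which
differs for extreme tables. Functional enrichment applies the same test
per function to (possessing vs not) × (signature group) tables, with BH
adjustment across functions and a q < 0.05 flag.

## Random-forest validation

Forests use 500 trees and √p feature subsampling (the canonical defaults
of the reference R implementation) with no class weights. Intra-dataset
performance is five repeats of stratified five-fold cross-validation; AUC
is computed from out-of-fold case probabilities with the Mann–Whitney
formulation (ties count ½). Feature importance is mean decrease in
accuracy (MDA): on each held-out fold, each feature column is permuted
(five repeats, batched into a single stacked prediction for speed) and
the accuracy drop recorded; MDA is averaged over all 25 folds and
features ranked by it, ties broken by feature id. Feature selection takes
the union of each dataset's top-k (default 5) features. Cross-dataset
AUC trains on one full dataset and scores another; LODO trains on the
concatenation of all datasets but one and scores the held-out one
(requiring at least three datasets). All fits and fold assignments derive
their random state from one seed via stable hashing, so every report is
bit-reproducible.

## Synthetic-study generator

The generator emulates the statistical structure the analysis assumes,
not sequence-level realism (genomes are random nucleotide strings):

* Per-vOTU base abundances are log-normal(0, 1) — the standard
  heavy-tailed community model, which also motivates rank-based testing.
  Each subject carries one latent abundance vector (per-vOTU lognormal
  subject noise, σ = 1) shared by that subject's VLP and bulk samples.
* Planted vOTUs are multiplied by `effect_fold` (default 4) in the
  favored group; compositions are then closed per sample, so the realized
  group-mean abundance ratio is pulled toward but stays near the planted
  fold when planted mass is balanced between groups.
* VLP samples multiply family-specific capture factors before closure.
  The defaults ({Microviridae: 10×, Myoviridae: 0.23×}) mirror the
  strongest family-level VLP-vs-bulk shifts reported for paired human
  gut viromes (13.5% vs 1.4% and 1.8% vs 7.8% mean relative abundance);
  there is no quantitative model of the real capture bias, so these are
  free parameters of the simulation, not estimates.
* Each vOTU is present in a subject with probability 0.9; an absent vOTU
  acquires spurious low depth (0.5 reads/bp) with probability
  `dropout_rate` (default 0.05) and is never confirmed by the read
  classifier — exercising the confirmation-zeroing step. Present vOTUs
  get a confirmation count of 1 + Poisson(depth × 20), so genuine signal
  is never erased by confirmation noise.
* Per-base depths are i.i.d. Poisson with mean proportional to closed
  abundance × mean depth (default 10 reads/bp) on genomes of 2.5–5 kb.
  A fast path (`simulate_depth=False`) draws a single Poisson total per
  (sample, vOTU) instead; it is used for calibration sweeps over many
  seeds where the per-base layer only adds runtime.
* Cohort sizes default to 30 cases + 30 controls, 50 vOTUs with 10
  case-enriched and 10 control-enriched — the parameter-recovery
  conditions exercised by the acceptance suite. Family composition is
  drawn as 39.5% prokaryotic / 4.9% eukaryotic / 55.6% unclassified, the
  proportions reported for large human gut virus catalogs.
* One global seed fans out to per-entity generators by stable hashing of
  (seed, cohort, entity id), making regeneration byte-identical and
  independent of iteration order; distinct `cohort_id`s under one seed
  share the planted truth and base abundances but draw fresh subjects,
  which is how multi-cohort transfer (cross-dataset, LODO) experiments
  are constructed.
* `effect_fold` may be set to exactly 1 to generate null cohorts in which
  truth still labels the planted vOTUs (for false-positive calibration);
  values below 1 are rejected.

What passing tests on these data show: the pipeline's decision rules,
statistics, and machine-learning workflow are internally correct,
calibrated under the stated null, and able to recover planted signals of
realistic effect size under compositional noise, modality bias, and
spurious-coverage contamination. What they do not show: performance on
real viromes, where depth is not Poisson (GC and mappability bias,
uneven coverage), abundances are zero-inflated beyond simple occupancy,
vOTU catalogs are incomplete, and batch effects correlate with cohort.

## Numerical and engineering choices

* Exact Wilcoxon enumeration switches to the tie-corrected normal
  approximation above n₁+n₂ = 12 or in the presence of ties.
* Fisher p-values treat probabilities within 1e−12 relative slack as
  tied; if every table qualifies, p is exactly 1.
* All-zero abundance rows, degenerate 2×2 margins, constant Spearman
  inputs, and missing bacterial fractions produce warnings and defined
  values rather than exceptions, so cohort-scale sweeps do not abort on
  degenerate samples.
* TSV files use '.' for missing values and are read with default NA
  parsing disabled (the status value "null" is data, not missingness).
  Alignment coordinates are 1-based inclusive on disk, 0-based half-open
  in memory.
* The demo pipeline configuration uses a scaled-down cohort (12+12
  subjects, 30 vOTUs, 2.1–3.2 kb genomes, 199 permutations) — the same
  model at a size convenient for smoke tests and determinism checks; the
  acceptance quantities are computed at the full default sizes above.

## Known limitations

* The greedy clustering consumes precomputed pairwise similarities; it
  does not compute alignments from sequence.
* PERMANOVA is one-way only (no covariates or strata).
* The conditional-MLE odds ratio is not implemented; the sample odds
  ratio is reported (documented divergence for extreme tables).
* LODO requires ≥ 3 datasets and is skipped (with a note in the run
  report) for the single-cohort pipeline.
* No plotting: outputs are tables and JSON intended for downstream
  figure tooling.
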