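# Methods

## The problem and the model

Single-variant association studies of folate-pathway genes have been
inconsistent for neural tube defects, plausibly because risk arises from
the joint effect of many variants — most of them rare — distributed
across an interconnected metabolic pathway.  `miscore` implements two
per-individual aggregation statistics over a case-control genotype
matrix:

* the **unweighted minor-allele burden**, `B_i = Σ_j g_ij`, where
  `g_ij ∈ {0,1,2}` counts the minor alleles of individual *i* at variant
  *j* of a chosen subset (1 per heterozygote, 2 per minor-allele
  homozygote); and
* the **Metabolic Index Score (MIS)**,
  `MIS_i = Σ_j s(gene_j) · g_ij`, where each gene carries a sign
  `s ∈ {+1, −1}` for a given metabolic output.  Genes whose activity
  pushes the output up (e.g. supply one-carbon units toward cytoplasmic
  10-formyl-THF for purine synthesis) are `+`; genes that compete with
  or drain the output are `−`.  Genes unsigned for a metabolite
  contribute nothing.  Every gene and every variant within a gene has
  identical weight: the score is a deliberately simple flux heuristic,
  not a kinetic model.

The shipped pathway model covers three metabolic compartments of
folate/one-carbon metabolism — purine synthesis, thymidylate (dTMP)
synthesis, and homocysteine abundance — over 23 signed genes with
cytoplasmic/mitochondrial tags.  Genes shared between the purine and
homocysteine sets carry opposite signs (reduced flux toward methionine
regeneration lowers purine precursor supply but raises homocysteine).
MAT1A/MAT2A are excluded from the homocysteine set because AdoMet
synthesis does not materially move homocysteine levels.  Users can
replace the model wholesale via YAML/TSV.

## Inference

Case-control differences in a score vector are tested with a Welch
(unequal-variance) t statistic when the score distribution is roughly
normal (common-variant sums) and with the Mann-Whitney U statistic for
rare-variant sums, whose distributions are right-skewed; a
Kolmogorov-Smirnov sup-distance statistic is available for
distribution-shape comparisons.  All p-values come from permuting the
case-control labels:

* when the number of distinct label arrangements is at most 10⁶ the
  null is enumerated exhaustively and the p-value is exact (`b/B`,
  observed arrangement included);
* otherwise `B` Monte-Carlo shuffles are drawn and the add-one
  estimator `p = (b+1)/(B+1)` is used, which cannot return zero and is
  valid (conservative by at most 1/(B+1)).

Tests are two-sided by default, on the centered statistic (`t` as-is,
`U − n₁n₂/2`, KS distance).  In pooled ("all-strata") analyses,
permutations are stratified within race-ethnicity so each stratum's
case/control ratio is preserved — a pooled shuffle would confound
stratum frequency differences with case status.

Family-wise error over the metabolite × subset grid is controlled by
single-step max(T): one shared permutation stream, and the adjusted
p-value of hypothesis *h* is the exceedance fraction of the
per-permutation maximum |statistic| over the observed |statistic_h|.
Because the maximum dominates each per-hypothesis statistic pointwise,
adjusted ≥ raw always holds within one stream.  Two deliberate choices:

* the family is formed **within each analysis stratum** (metabolite ×
  subset, 12 hypotheses with the default grid).  max(T) requires every
  hypothesis to be computed on the same individuals under the same
  permutations, which is impossible across strata containing different
  people; the reports state the family used.
* inside max(T) all hypotheses use the Welch t statistic, even for
  rare subsets, so the maxima compare statistics on one scale; the raw
  p-value column keeps each subset's own statistic.  Mixing t and U
  inside a single maximum would let the statistic with the larger
  numeric range dominate.

Single-variant association is a log-additive (per-allele) logistic
regression of status on dosage with optional stratum indicator
adjustment.  Rare variants frequently separate the data (e.g. a lone
carrier who is a case); on a non-converged or diverging ML fit the
model is refit with Firth's Jeffreys-prior penalty (Newton iterations
with a step cap of 5 and step-halving on the penalized log-likelihood)
and flagged.  Dichotomized odds ratios use 2×2 tables with Woolf log
confidence intervals and the Haldane-Anscombe 0.5-per-cell correction
when a cell is empty (flagged).  Cut rules: control median (ties to the
below arm), fixed cut (ties excluded by default — relevant for the
natural MIS < 0 vs > 0 split, where MIS = 0 belongs to neither side),
and distribution extremes (scores strictly between the two bounds are
dropped).

## Preprocessing

* **Orientation.**  Dosages are loaded as raw alt-allele counts and
  flipped per variant (`g → 2−g`) wherever the counted allele's
  frequency exceeds 0.5 among the non-missing genotypes of the analysis
  stratum, cases and controls pooled.  Orientation is per-stratum by
  default because the minor allele's identity can differ between
  race-ethnicity groups (the MTHFD1 R653Q minor allele, for instance,
  is the major allele in Mexican-American populations); a tie at 0.5
  keeps the alt allele as minor.  Orientation is idempotent and caps
  the MAF at 0.5.
* **QC.**  Samples with strictly more than 25% missing genotypes are
  dropped first, then variants by the same rule recomputed on retained
  samples ("more than", so exactly 25% survives).  The order is
  configurable; sample-first is the default.
* **Imputation.**  Each missing cell is drawn once from the variant's
  empirical genotype distribution within the sample's stratum (falling
  back to the cohort-wide distribution when the stratum has no call),
  seeded for reproducibility.  This preserves stratum allele
  frequencies in expectation but ignores haplotype structure — it is a
  frequency-based imputer, not a haplotype-model one, and slightly
  attenuates LD relative to true genotypes.  Scoring requires a
  complete matrix by default; a `complete_case` mode (missing counts 0)
  exists for diagnostics.
* **LD pruning.**  LD is genotypic: squared Pearson correlation of
  dosage vectors over complete-case pairs, which requires no phasing.
  Grouping is greedy single-linkage in variant-coordinate order: each
  unassigned variant seeds a group and absorbs every later unassigned
  variant with seed-R² > 0.8; the seed is retained as the group's
  representative.  The procedure is deterministic given column order;
  a variant monomorphic over complete cases has undefined R² and never
  joins a group.  Pruning runs cohort-wide on the imputed matrix before
  subsetting; this keeps one variant set across strata.

## The synthetic cohort generator

`simulate_cohort` emulates the structure of the motivating study design
so every downstream stage is testable without access to individual-level
genotypes (which are not publicly deposited for such cohorts):

* 240 cases + 240 controls; race-ethnicity strata at 65% Hispanic,
  21% non-Hispanic white, 14% other;
* 31 folate-pathway genes carrying 1,441 variants, with functional
  classes drawn at the catalogue proportions 1050:211:171:4:5
  (non-coding : nonsynonymous : synonymous : truncation : frameshift);
* a rarity spectrum with 614/1441 singleton mass, a Beta(0.8, 80) tail
  for rare non-singleton MAFs below 2.5%, and a Beta(1.2, 5) body for
  common MAFs on [0.025, 0.45].  Singletons are placed exactly (one
  heterozygous carrier at a random individual);
* stratum-specific allele frequencies via a Balding-Nichols
  perturbation with Fst = 0.01 — a conventional magnitude for closely
  related continental-admixture strata;
* LD via allele copying: within blocks of up to 4 consecutive
  non-singleton variants of a gene, each allele slot of a member copies
  the block seed's allele with probability ρ = 0.3, else draws fresh.
  The marginal MAF of a member is then the blend
  `ρ·p_seed + (1−ρ)·p_member`, which the generator records as that
  variant's target so realized-vs-target checks compare against the
  true marginal;
* 6% missingness, completely at random.  Real missingness is not MCAR
  (it tracks assay quality and GC content), so QC/imputation behaviour
  under informative missingness is not covered by these simulations.

`plant_effect` inverts the analysis: it computes the MIS for a chosen
metabolite/subset (missing genotypes contributing 0) and redraws case
status per individual from `Bernoulli(expit(α + β·MIS_i))`, with α
solved by Brent's method so the marginal prevalence matches the
requested baseline (default 0.5, matching a balanced case-control
draw).  β is the planted log-odds per MIS unit; β < 0 produces cohorts
where cases have the *lower* mean score, the direction the purine-risk
signature takes.  The generator does not attempt coalescent realism,
real haplotype structure, or genotyping-error models; passing tests
demonstrate correctness of the statistical machinery under the stated
generative model, not robustness to real-data artefacts.

## Numerical and design notes

* Dosage matrices are floats with NaN as the missing state; validation
  rejects any non-missing entry outside {0, 1, 2}.
* Exceedance counts use a 1e-12 tolerance so exact ties in permuted
  statistics (common with integer scores) count as exceedances rather
  than falling to float jitter.
* Degenerate score vectors: permutation p = 1 by convention; inside
  max(T) a constant hypothesis row carries statistic 0.
* The boundary MAF = 2.5% is classed common (the threshold is
  inclusive).
* The `variant_id` convention is `GENE_coordinate`, with coordinate 1
  placed 1 kb upstream of the transcription start; internally the id is
  an opaque key and no liftover is attempted.
* Multi-allelic VCF records are split into one biallelic dosage column
  per alt allele; genotypes with any uncalled allele are missing.
* Problem sizes in the test suite: the permutation-validity study uses
  1,000 null cohorts of n = 100 at B = 200; family-wise error uses 500
  all-null simulations of 3 hypotheses × 30 individuals; planted-effect
  recovery uses 200 replicates of n = 2,000 over a 4-gene mixed-sign
  set (one competing, three beneficial genes — the shape of the
  cytoplasmic purine module); the full-pipeline check runs 480 × 1,441
  at B = 10,000.  These sizes give binomial error bands tight enough to
  detect miscalibration of a few percentage points while keeping the
  suite quick on a laptop.

## Known limitations

* The imputer is marginal-frequency based; downstream LD estimates on
  imputed cells are attenuated.
* Exact conditional logistic inference is not implemented; the Firth
  fallback handles separation but small-sample ORs remain approximate.
* max(T) is single-step, not step-down; step-down Westfall-Young would
  be slightly more powerful under strong dependence.
* The MIS treats every variant as equally deleterious; weighting
  schemes (e.g. frequency-based) are deliberately out of scope.
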