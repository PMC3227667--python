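# miscore

Pathway-informed variant collapsing for case-control genotype cohorts:
unweighted minor-allele burden sums and the signed **Metabolic Index
Score (MIS)** over folate/one-carbon pathway gene sets, with
label-permutation inference, single-step max(T) family-wise adjustment,
LD pruning, missingness QC and imputation, single-variant log-additive
association, and dichotomized odds ratios.  A synthetic cohort
generator reproduces the structure of a ~480-member, 31-gene,
~1,400-variant sequencing study so the whole analysis can be exercised
and validated end to end without any external data.

## Who this is for

Statistical geneticists and epidemiologists analyzing targeted
sequencing of a metabolic pathway in a case-control design, where most
variants are rare and the unit of risk is plausibly a pathway output
rather than any single allele.

## The statistics

For individual *i* over a variant subset *S* (a functional class ×
within-stratum MAF bin, after LD pruning at R² > 0.8):

* burden: `B_i = Σ_{j∈S} g_ij`, with dosage `g_ij ∈ {0,1,2}` counting
  stratum-minor alleles — 1 per heterozygote, 2 per homozygote;
* Metabolic Index Score: `MIS_i = Σ_{j∈S} s(gene_j) · g_ij`, where
  `s = +1` for genes beneficial to a metabolic output (purine
  synthesis, thymidylate synthesis, or homocysteine abundance) and
  `s = −1` for genes competing with it.  A minor-allele homozygote in a
  beneficial gene contributes +2; a heterozygote in a competing gene
  contributes −1.

Case-control differences are tested by permuting case-control labels
(Welch t for common-variant sums, Mann-Whitney U for skewed rare-variant
sums, exhaustive enumeration when feasible, otherwise
`p = (b+1)/(B+1)`), and the metabolite × subset grid is adjusted by
max(T) permutation.  See `docs/methods.md` for the model, its
assumptions, and all numerical conventions.

## Worked example

Simulate a study-sized cohort, plant a protective purine-pathway effect
(β = −0.5 log-odds per MIS unit on the common nonsynonymous subset),
and run the full pipeline:

```python
from miscore import (AnalysisConfig, CohortSpec, EffectSpec,
                     default_pathway_model, plant_effect, run_pipeline,
                     simulate_cohort)

spec = CohortSpec(rng_seed=1)            # 480 individuals, 31 genes, 1,441 variants
matrix, variants, samples = simulate_cohort(spec)
planted = plant_effect(
    matrix, variants, samples, default_pathway_model(),
    EffectSpec(metabolite="purine", class_filter="nonsynonymous",
               maf_bin="common", beta=-0.5),
    rng_seed=2,
)
config = AnalysisConfig(n_permutations=10_000, rng_seed=3)
results = run_pipeline(matrix, variants, planted[["status", "stratum"]],
                       config=config)
print(results["mis_grid"].sort_values("raw_p").head(3)
      [["stratum", "metabolite", "subset", "n_variants", "raw_p",
        "maxt_adjusted_p"]].to_string(index=False))
```

prints

```
 stratum   metabolite               subset  n_variants  raw_p  maxt_adjusted_p
Hispanic       purine nonsynonymous:common          58 0.0001           0.0001
Hispanic homocysteine nonsynonymous:common          58 0.0001           0.0001
   White       purine nonsynonymous:common          63 0.0001           0.0001
```

The planted signal is recovered exactly where it was planted — the
common nonsynonymous purine cell — and survives max(T) adjustment.
(The homocysteine cell mirrors it because the two gene sets carry
opposite signs over shared genes, which a two-sided test cannot
distinguish.)  The corresponding dichotomized odds ratio at the
Hispanic control median (MIS = 1) is 0.38 (95% CI 0.23–0.65): higher
scores are protective, i.e. cases sit lower on the purine MIS, matching
the planted β < 0.

The same pipeline runs from the shell:

```sh
miscore simulate --seed 1 --effect-metabolite purine --effect-beta -0.5 --out cohort/
miscore run --dosages cohort/dosages.tsv --annotations cohort/variants.tsv \
            --samples cohort/samples.tsv --permutations 10000 --seed 3 --out report/
```

## Layout

| module | contents |
| --- | --- |
| `miscore.datatypes` | domain containers, validation, `PathwayModel`, `AnalysisConfig` |
| `miscore.io` | VCF/TSV readers and writers, minor-allele orientation, stratified MAF |
| `miscore.simulate` | synthetic cohort generator and effect planting |
| `miscore.preprocess` | missingness QC, frequency imputation, dosage-R² LD pruning |
| `miscore.scoring` | variant subsetting, burden sums, the MIS, genotype combinations |
| `miscore.stats` | permutation tests, max(T), logistic association, 2×2 odds ratios |
| `miscore.pipeline` / `miscore.cli` | end-to-end orchestration and the `miscore` command |
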