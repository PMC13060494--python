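# radvar

Rare-variant gene-discovery toolkit: Sequence Ontology consequence masking,
covariate-adjusted gene-based aggregation tests (burden, SKAT, SKAT-O,
ACAT-V, ACAT-O), carrier-based odds-ratio and trait-shift profiling,
ancestry-concentration classification of rare variants, and allele-age
summary comparisons — exercised end-to-end on a seeded synthetic
multi-ancestry cohort generator.

## Modules

| Module | Purpose |
|---|---|
| `radvar.synthetic_cohort` | Seeded cohort generator: genotypes (heavy rare tail with a controlled singleton fraction, ancestry-concentrated carriers, planted risk/protective genes), covariates, traits, allele-age tables. |
| `radvar.consequence_masks` | Severity ranking of SO consequence terms, multi-allelic decomposition, M1/M2/M3 mask assignment, per-(gene, mask) qualifying sets under a MAF cutoff. |
| `radvar.aggregation_tests` | Null-model fitting (logistic IRLS / least squares) and score-based burden, SKAT (Davies chi-square-mixture tails with Liu fallback), SKAT-O (minimum-p over a rho grid with the one-dimensional integration adjustment), ACAT-V/ACAT-O Cauchy combinations, Bonferroni threshold. |
| `radvar.carrier_analysis` | Carrier status, ancestry-stratified + pooled Wald odds ratios with Haldane-Anscombe correction, Wilcoxon/Hodges-Lehmann and Fisher trait comparisons with direction-standardized signed scores. |
| `radvar.ancestry_concentration` | Per-variant carrier profiles, AD-enriched / AD-skew classification, dominant-ancestry proportion, single-ancestry-like calls, Gini-Simpson diversity, group comparisons. |
| `radvar.allele_age_summary` | Allele-age quality filtering (CI-ratio and age caps) and rank-sum group comparisons. |
| `radvar.pipeline` | End-to-end orchestration with a JSON run manifest and deterministic TSV outputs. |

## CLI

```bash
# generate a synthetic cohort (VCF + annotation/phenotype/age TSVs)
radvar simulate --config cohort.yaml --out DIR --seed 7

# build qualifying sets, run association tests, trait cells, concentration, ages
radvar mask --vcf DIR/genotypes.vcf --anno DIR/annotations.tsv --maf 0.01 --out sets.tsv
radvar test --vcf DIR/genotypes.vcf --anno DIR/annotations.tsv \
    --pheno DIR/phenotypes.tsv --trait AD --out results.tsv
radvar traits --vcf DIR/genotypes.vcf --anno DIR/annotations.tsv \
    --pheno DIR/phenotypes.tsv --out cells.tsv
radvar concentration --vcf DIR/genotypes.vcf --anno DIR/annotations.tsv \
    --pheno DIR/phenotypes.tsv --min-carriers 2 --out profiles.tsv
radvar ages --ages DIR/ages.tsv --max-ci-ratio 10 --max-age 500000 --out summary.tsv

# or everything at once from one YAML config
radvar run --config run.yaml
```

A minimal cohort YAML:

```yaml
n_per_ancestry: {EUR: 2000, AFR: 1000}
case_fraction_per_ancestry: {EUR: 0.3, AFR: 0.25}
n_genes: 100
variants_per_gene_mean: 8
singleton_fraction_target: 0.51
ancestry_concentration: 0.5
planted_genes:
  - {gene: G0000, mask: M2, effect: 1.1, direction: risk}
trait_specs:
  - {name: MEM, kind: quantitative, case_shift: -0.5}
seed: 1
```

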