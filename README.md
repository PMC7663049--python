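# omnileaf

A tested, reusable implementation of an analysis chain for characterizing a
highly polygenic quantitative trait: clonal quantitative genetics, mixed-model
GWAS, SNP-to-gene set enrichment with a permutation null, extreme-group
differential expression with a centrality randomization scheme, aggregated
co-expression network inference, and selection-signature comparisons —
exercised end-to-end on synthetic cohorts with known ground truth.

## Modules

| Module | What it does |
| --- | --- |
| `omnileaf.synthdata` | Synthetic cohorts: Balding–Nichols structured genotypes on a toy annotated genome, clonal phenotypes with configurable variance components and genetic correlations, NB expression with modular co-expression and phenotype-linked DE genes. Writes VCF/GFF3/CSV/TSV/GMT/JSON bundles. |
| `omnileaf.quantgen` | REML variance components (profile likelihood for the one-way case, EM through Henderson's equations otherwise), broad-sense heritability `H² = V_G/(V_G+V_E)` with F-bound/bootstrap CIs, `Q_ST = V_pop/(V_pop+2·V_geno)` with genotype bootstrap, genetic correlations via the variance-of-a-sum identity, BLUPs, and a range-normalized two-way GxE ANOVA. |
| `omnileaf.gwas` | Centered kinship matrix, exact one-eigendecomposition univariate LMM with likelihood-ratio p-values and BH adjustment, genomic-control λ, and a REML-based PVE (a labelled substitute for an MCMC sparse-model PVE). |
| `omnileaf.annotate` | SNP→gene mapping within a 2 kb window, top-k candidate-gene walk down the p-value ranking, genomic-context classification (UTR/exon/intron/flanks/conflict) and length-normalized context density tests. |
| `omnileaf.gsea` | Weighted running-sum gene-set enrichment on any gene ranking, gene-ranking permutation null with empirical p-values, leading-edge extraction, and Storey q-values. |
| `omnileaf.degx` | Extreme-quartile DE: BLUP quartile groups, median-of-ratios size factors, NB dispersions estimated on all samples, Wald tests on the extremes only, the n-shuffle centrality randomization, and expression–phenotype correlation contrasts. |
| `omnileaf.netinfer` | Pearson/Spearman/CLR/partial-correlation edge scores, inverse-rank-product aggregation, noise-corrected backbone at σ = 2.32, greedy-modularity partitioning, centralities (PageRank, betweenness, eigenvector, Katz, HITS), and network summary statistics. |
| `omnileaf.popgen` | Per-gene Tajima's D from unphased dosages, Wilcoxon gene-set contrasts, and MAF spectrum comparisons. |
| `omnileaf.pipeline` | One-config orchestration of the full chain with a markdown report. |

## CLI

All stages are exposed under one entry point:

```bash
omnileaf simulate --out sim/ --seed 1
omnileaf quantgen --pheno sim/phenotypes.csv --traits area,circularity,indent_depth
omnileaf gwas --vcf sim/genotypes.vcf --pheno blups.csv --trait circularity --out assoc.tsv
omnileaf annotate --assoc assoc.tsv --gff sim/genes.gff3 --window 2000 --topk 1000
omnileaf gsea --ranking ranking.tsv --gmt sim/gene_sets.gmt --nperm 10000 --seed 1
omnileaf degx --counts sim/counts.tsv --samples sim/samples.csv --blups blups.tsv --trait circularity
omnileaf network --expr sim/counts.tsv --methods pearson,spearman,clr,pcor --sigma 2.32
omnileaf popgen --vcf sim/genotypes.vcf --gff sim/genes.gff3
omnileaf run --config cfg.yaml --out run/   # full pipeline from one YAML
```

## Notes on scope and substitutions

- The MCMC sparse-mixed-model PVE is replaced by a REML kinship-variance PVE
  (flagged as a substitute in its output).
- The NB differential-expression engine is a documented simplification
  (method-of-moments dispersions shrunk toward a robust trend + Wald tests);
  the scientific design — extreme-group contrast with full-data dispersion
  estimation — is preserved exactly.
- Graph partitioning uses greedy modularity maximisation in place of a
  map-equation optimizer; cluster ids are formatted `component:cluster`.
- The backbone z statistic is weight-unit dependent; aggregate weights are
  expressed in a count-like unit (weakest edge = 1) before thresholding
  (see `netinfer.backbone`).
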