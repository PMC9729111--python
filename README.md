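# gwaspost

A post-GWAS analysis toolkit for case-control meta-analyses: fixed-effect
inverse-variance pooling with locus definition and novelty annotation,
approximate conditional/joint selection from summary statistics, functionally
informed fine-mapping with annotation-enriched priors, liability-scale
heritability explained, an eight-predictor consensus causal-gene
prioritization framework, and polygenic-score stratification — together with
a synthetic-data generator that produces every input the pipeline consumes,
so the whole chain is testable end to end without any external download.

## Modules

| module | what it does |
| --- | --- |
| `gwaspost.simulate` | synthetic LD panels (block AR(1)), per-study summary statistics under a polygenic case-control model, annotation tracks enriched at causal variants, two ancestries with a configured effect correlation, locus x gene x predictor evidence matrices, prospective cohorts for score evaluation |
| `gwaspost.meta` | allele alignment, IVW meta-analysis (log-space p-values), study/case-count filters, 500-kb transitive clumping, novelty vs. known variants (r² rule), Storey q-values, sex-heterogeneity screen, cross-ancestry correlations |
| `gwaspost.cojo` | summary-statistic joint effects via an LD reference and greedy stepwise selection with backward elimination |
| `gwaspost.finemap` | Wakefield log-ABFs, per-tissue enrichment coefficients across regions, region selection by BF increment, annotation-reweighted PPAs, 95% credible sets |
| `gwaspost.heritability` | logit-to-liability transformation at population risk K and percent of twin heritability explained |
| `gwaspost.genes` | consensus gene nomination (unweighted 8-predictor vote, tiers at ≥2/≥3), agreement/concordance metrics, positive-control evaluation, risk-factor consistency classifier |
| `gwaspost.prs` | dosage scoring with allele alignment, decile stratification, Cox per-SD association (lifelines) |

## CLI

Each pipeline stage is a subcommand of `gwaspost`:

```sh
gwaspost simulate --config config.yaml --seed 7 --out data/          # all inputs
gwaspost meta data/study*.tsv --out meta.tsv --min-studies 2 --min-cases 30000
gwaspost clump meta.tsv --out loci.tsv --known known.tsv --panel data/panel
gwaspost fdr meta.tsv --out fdr.tsv --target 0.01
gwaspost sexhet males.tsv females.tsv --out sexhet.tsv
gwaspost crossanc meta_eur.tsv meta_eas.tsv --sentinels sentinels.txt
gwaspost cojo meta.tsv --panel data/panel --out signals.tsv
gwaspost finemap meta.tsv --panel data/panel --bed data/tissue01.bed \
    --out-regions regions.tsv --out-variants ppa.tsv
gwaspost h2 signals.tsv --out h2.tsv --k 0.0719 --h2-twin 0.4
gwaspost prioritize evidence.tsv --out nominees.tsv --controls controls.tsv
gwaspost prs --cohort data/cohort --weights data/weights.tsv --out scores.tsv
```

Thresholds default to the conventional values (genome-wide significance
5e-8, 500-kb clumping, novelty r² 0.2, 1% FDR).

## File formats

Summary statistics are tab-delimited with columns `CHR POS RSID EA NEA EAF
BETA SE P N_CASES N_CONTROLS INFO` (1-based positions). Annotation tracks
are BED (0-based half-open, converted on read). LD panels are a variant
index TSV plus a dense correlation-matrix TSV. Evidence matrices are
`LOCUS_ID GENE DISTANCE_BP` followed by the eight binary predictor columns
(`clinvar_monogenic drug_or_mr pops_top2 eqtl_highld mouse_ko
protein_altering_highld rare_variant_assoc nearest_gene`). PRS weight files
are `RSID EA WEIGHT`.
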