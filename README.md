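# asmpath

Pathway enrichment analysis of GWAS summary statistics that incorporates
allele-specific methylation (ASM) information through a subset-weighting
scheme.

Given per-SNP association p-values (PLINK `.assoc` dialect), gene
coordinates (BED4), a SNP–CpG ASM pair list (TSV, cis/trans with
association p-values) and pathway gene sets (GMT), the pipeline:

1. maps SNPs to genes within a 5 kb window of both gene ends;
2. partitions mapped genes into ASM / non-ASM sets (a gene is ASM if it
   contains an ASM-list SNP or is the CpG target of one);
3. represents each gene by its min-p (ASM genes: minimum over their ASM
   SNPs only), normalized for gene size against a resampled null and
   converted to a 1-df chi-square–scale gene score;
4. weights each pathway's ASM and non-ASM subsets from their
   informative-gene proportions via the harmonic-average rule
   (`R_n/H`, `R_m/H`; integer 1–6 bins when the non-ASM subset has no
   informative gene; equal weights otherwise);
5. tests each pathway (mapped size 10–380) with three statistics —
   GSEA-style enrichment score, sum-statistic and sum-square-statistic —
   with and without weights, using gene-label permutations for add-one
   empirical p-values and Benjamini–Hochberg FDR (threshold 0.01);
6. reports GO-term over-representation of genes from enriched non-GO
   pathways (one-sided hypergeometric over the mapped-gene universe) and
   the genes over-represented across enriched pathways.

A synthetic-study generator produces complete, seeded input bundles with
controllable null/alternative structure plus a truth table, so the whole
pipeline is testable without controlled-access GWA data.

## CLI

```sh
# generate a synthetic study bundle
asmpath simulate --config sim.yaml --seed 1 --out study/

# run the full pipeline
asmpath run --config run.yaml [--perms N --seed S --weighting on|off|both --out DIR]

# standalone GO over-representation
asmpath annotate --genes query.txt --gmt go.gmt --universe genes.txt --out go.tsv
```

`run.yaml` keys mirror `asmpath.pipeline.RunConfig`
(`assoc_path`, `genes_path`, `asm_path`, `gmt_path`, optional
`go_gmt_path`, `out_dir`, `window_bp`, `cis_alpha`, `trans_alpha`,
`snp_alpha`, `gene_stat: adjusted|raw_chisq`, `score_perms`,
`pathway_perms`, `min_size`, `max_size`, `fdr_threshold`, `weighting`,
`seed`). Outputs: `gene_table.tsv`, `weights.tsv`, `results.tsv`,
`gene_report.tsv`, `go_terms.tsv` (when `go_gmt_path` is set) and a
`manifest.json` recording the config, input checksums and stage counts.
Identical config and inputs give bit-identical outputs. Exit codes:
0 ok, 1 usage error, 2 data error.

`sim.yaml` keys mirror `asmpath.synthetic_data.SyntheticStudyConfig`,
e.g.:

```yaml
n_genes: 2000
snps_per_gene: {min: 2, max: 30, mean: 10.0}
n_pathways: 60
pathway_size: [10, 50]
asm_gene_fraction: 0.13
enriched_pathways:
  - {pathway_index: 0, noncentrality: 8.0, asm_concentration: 0.9}
seed: 1
```

## Package layout

```
src/asmpath/
  io_formats.py      readers/writers (.assoc, BED4, ASM TSV, GMT, results TSV)
  synthetic_data.py  seeded synthetic study bundles + truth tables
  gene_scoring.py    SNP→gene mapping, ASM partition, min-p, size-adjusted scores
  asm_weighting.py   harmonic-average subset weights (exact fractions)
  enrichment.py      ES / sum / sum-square statistics, permutations, BH
  postprocess.py     GO over-representation, over-represented-gene report
  pipeline.py, cli.py  orchestration, YAML config, manifest, CLI verbs
```
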