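# rnadriver

Driver-gene discovery from tumor RNA-seq cohorts, packaged as a tested,
reusable pipeline and exercised end-to-end on a synthetic cohort
generator. The stages mirror a leukemia RNA-seq analysis workflow:

- **`rnadriver.simulate`** — synthetic cohorts: gene models (GTF), exome
  and RNA variant tables (VCF) with planted recurrent driver mutations,
  germline SNPs and allelic-imbalance structure, negative-binomial count
  matrices with GC/length bias, collection-center batch shifts and
  TF-defined subtype programs, fusion candidates (true classes plus
  read-through/ribosomal/chrM/low-support decoys) and junction tables
  with planted exon skipping — each bundled with a machine-readable
  truth record.
- **`rnadriver.variants`** — SNV/INDEL filter cascade (read-position,
  depth ≥ 20, VAF ≥ 0.20, population databases with COSMIC rescue,
  repeats, normal panel/thymus, homopolymer context for INDELs) and
  protein-altering consequence selection, with telescoping filter traces.
- **`rnadriver.concordance`** — RNA vs exome callset comparison at ≥ 20×
  in both assays, VAF scatter data, and the RNA-genotype breakdown of
  DNA-heterozygous sites (het / hom-ref / hom-var).
- **`rnadriver.recurrence`** — recurrence-based driver selection
  (≥ 2 distinct patient samples; cell lines annotated, not counted) and
  Mann-Whitney mutation-burden comparison.
- **`rnadriver.normalize`** — log2 counts, within-sample GC/length trend
  removal, upper-quartile / full-quantile between-sample normalization,
  least-squares batch-effect removal, classical MDS diagnostics, and
  Ward clustering of samples on subtype-defining TFs.
- **`rnadriver.coexpr`** — template-matching co-expression (Pearson r
  with parametric p-values), marker-defined log-fold-change rankings and
  weighted-KS gene-set enrichment with a permutation null.
- **`rnadriver.fusions`** — fusion-candidate triage (spanning ≥ 8 AND
  split ≥ 5, ribosomal/mitochondrial partners, adjacent-gene
  read-throughs) and consequence classification into chimeric protein /
  partner over-expression / partner inactivation using frame status,
  tumor-suppressor flags and flanking-gene expression evidence.
- **`rnadriver.splicing`** — exon-skipping ratio C/(A+B+C), Fisher exact
  tumor-vs-control testing and a BH-corrected cohort scan.

## Test

```sh
python -m pytest -q tests/
```

One acceptance test (`TestCriterion2BurdenComparison`) requires an
external supplementary per-sample burden table and is expected to fail
when that file is absent; everything else is self-contained.

## CLI

Every stage is a subcommand of the `rnadriver` entry point:

```sh
rnadriver simulate --config cfg.yaml --seed 1 --outdir out/
rnadriver filter-variants --vcf out/rna.vcf --out retained.tsv --trace trace.json
rnadriver concordance --exome out/exome.vcf --rna out/rna.vcf --out report.json
rnadriver recurrence --calls retained.tsv --meta out/samples.tsv --out genes.tsv
rnadriver normalize --counts out/counts.tsv --genes out/genes.gtf \
    --meta out/samples.tsv --out normalized.tsv
rnadriver coexpr --expr normalized.tsv --template TAL1 --out neighbors.tsv
rnadriver gsea --expr normalized.tsv --marker TAL1 --gmt sets.gmt --out gsea.json
rnadriver fusions --candidates out/fusion_candidates.tsv --expr normalized.tsv \
    --genes out/genes.gtf --meta out/samples.tsv --out calls.tsv
rnadriver splice --junctions out/junctions.tsv --out events.tsv
rnadriver run-all --config cfg.yaml --seed 1 --outdir run/
```

`run-all` executes the whole chain (simulate → filter → concordance →
recurrence → normalize → co-expression/GSEA → fusions → splice scan) and
writes a JSON run manifest; a single seed fans out deterministically to
per-stage child seeds, so identical (config, seed) runs reproduce every
output byte for byte.

The config file is a YAML mapping of `SimulationConfig` fields, e.g.

```yaml
n_patients: 20
n_celllines: 8
n_genes: 400
batch_effect_sd: 0.7
```

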