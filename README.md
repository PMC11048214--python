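# mitocohort

Post-variant-calling analysis of mitochondrial (mtDNA) and nuclear-encoded
mitochondrial-gene (nDNA) variants in case/control cohorts: variant
retention rules and heteroplasmy classification, circular rCRS region
annotation, rare-variant prioritisation, pathogenicity-predictor
concordance scoring, region-wise enrichment statistics, and mtDNA
copy-number estimation — plus a fully parameterised synthetic-cohort
generator so every stage is testable without any sequencing download.

## Modules

| module | what it does |
| --- | --- |
| `mitocohort.mito_map` | Circular rCRS (16,569 bp) interval atlas: genes, control-region (CR) sub-regions (HV1–3), functional domains (ETAS/CSB/LSP/central domain), secondary-structure elements, homopolymer tracts. Bundled editable default atlas; BED or native TSV input. |
| `mitocohort.variant_filter` | mtDNA call retention: depth ≥ 5, mapping quality ≥ 25, no homopolymer tract, both-strand support, heteroplasmy fraction (HF) ≥ 0.01; homoplasmic iff HF ≥ 0.95; dedupe and observation/site counting. |
| `mitocohort.prioritize` | Rare-variant cascades: nuclear (drop LOW impact → drop control-shared sites → MAF < 0.01 or absent → CADD ≥ 10 → caller PASS) and mitochondrial (first three stages); ±10 kb gene windows; per-gene case burden. |
| `mitocohort.concordance` | Simplifies heterogeneous categorical predictor labels to D/B/NA via editable lexicons and condenses them to a −2…+2 concordance score. |
| `mitocohort.enrichment_stats` | Stratified case/control contingency tables (ploidy, CR/coding, HV, functional domains, genes, substitution spectrum) with two-sided Fisher exact (2-row) or uncorrected chi-square (3+-row) tests, and pooled-variance t-tests from group summaries. |
| `mitocohort.mtdna_cn` | Copy number = 2 × (mean mtDNA depth / length-weighted mean autosomal depth); group comparison by pooled t-test. |
| `mitocohort.synthetic_data` | Deterministic synthetic cohorts: mtDNA calls with a binomial heteroplasmy observation model and planted filter-rule violations, annotated nuclear calls with known cascade outcomes, and depth tables with planted copy numbers, each with a truth ledger. |
| `mitocohort.pipeline` / `mitocohort.cli` | Orchestration, `n/N (%)` summary rendering, run manifests, CLI. |

## CLI

```bash
# simulate a cohort bundle (per-sample VCFs, design, depth table, truth ledger)
mitocohort simulate --seed 11 --out scratch/sim

# full pipeline: filter -> tables -> tests -> copy number
mitocohort run-all --bundle scratch/sim --out scratch/report

# individual stages
mitocohort filter scratch/sim/mt/*.vcf --out scratch/flt
mitocohort enrich scratch/sim/mt/*.vcf --design scratch/sim/design.tsv --out scratch/enr
mitocohort cn scratch/sim/depth.tsv --design scratch/sim/design.tsv --out scratch/cn.json
mitocohort prioritize nuclear/*.vcf --design design.tsv --windows genes.tsv --out scratch/prio
mitocohort score labels.tsv --out scratch/scored.tsv
```

Thresholds (`--min-depth`, `--min-quality`, `--min-hf`,
`--hf-hom-threshold`, `--min-strand-reads`, `--maf-max`, `--cadd-min`)
default to the published values shown above. Exit codes: 0 ok,
1 validation error, 2 internal error.

## Notes on bundled defaults

The default atlas ships MITOMAP-convention coordinates for the CR
(16024–16569 ∪ 1–576) and HV1–3, and literature-reconstruction defaults
for CR functional domains and secondary-structure elements; only spans
with published coordinates (e.g. ETAS2 16294–16357, structure elements
J 116–149 and K 181–226) should be treated as authoritative. Everything
is overridable via `--atlas` / `load_atlas(path)`.
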