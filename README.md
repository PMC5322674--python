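# famvar

Pedigree-aware WGS analysis toolkit: read-depth deletion calling with
multi-segment size/gap arithmetic, parent-of-origin inference from
Mendelian-inconsistency informative sites, inheritance-model variant
filtering with a frequency/evidence/clinical-significance cascade, and
phenotype-driven candidate prioritization with confidence tiers and a
term-subset robustness analysis. A first-class simulation module generates
every input the pipeline consumes (multi-sample VCF, PED, bedgraph depth
tracks, annotation fields, HPO term sets and a toy gene–disease–phenotype
knowledge base), so the whole analysis is testable offline.

## Layout

| module | what it does |
| --- | --- |
| `famvar.io_formats` | core data model (pedigree, variant sites, CNV calls, depth tracks) and VCF/PED/BED/bedgraph/TSV readers & writers; 1-based inclusive coordinates internally |
| `famvar.synthetic_data` | seeded simulation: founder haplotypes from a Beta AF law, whole-haplotype transmission, logged genotype errors, planted hemizygous deletions, Poisson depth, annotations, knowledge-base generation |
| `famvar.cnv_depth` | deletion calling from binned depth, segment/gap arithmetic, depth-ratio confirmation, per-caller post-call filter rules |
| `famvar.parental_origin` | informative-site classification (parent homozygous + sibling heterozygous), origin calling, Mendelian violation scan |
| `famvar.inheritance_filter` | dominant/recessive/de novo/compound-het/X-linked partitioning, AF + evidence stages with a conserving `FilterTrace`, clinical-significance rescue report, INDEL QC rule |
| `famvar.pheno_prioritize` | knowledge-base scoring, `[0,1]` normalization, high/medium/low tiers, per-term importance, exact-combination downsampling |
| `famvar.cli_pipeline` | `famvar` CLI and three reproducible end-to-end demo scenarios |

## CLI

```bash
# end-to-end demo: plant a 3-segment paternal de novo deletion, call it from
# depth, infer the deleted parental allele, prioritize the interval
famvar run-scenario pws_demo --seed 1 --out out/pws

# stage-by-stage on the files the demo wrote
famvar call-cnv --depth out/pws/depth.bedgraph --out-bed out/calls.bed --report out/calls.tsv
famvar origin --vcf out/pws/genotypes.vcf --ped out/pws/pedigree.ped \
    --region chr15:300,001-820,000 --father 10231 --sibling 10233 --proband 10232 \
    --out out/origin.tsv
famvar filter --vcf out/pws/genotypes.vcf --ped out/pws/pedigree.ped \
    --phenotype pws --out-dir out/filtered
famvar prioritize --terms out/pws/terms.tsv --individual 10232 --kb out/pws/kb \
    --out out/prioritized.tsv
famvar combo-analysis --terms out/pws/terms.tsv --individual 10232 \
    --kb out/pws/kb --target GENE0001 --k-min 1 --k-max 6 --out out/combo.tsv
famvar report --bundle out/pws
```

Other subcommands: `simulate` (YAML spec → VCF/PED/bedgraph/truth bundle),
`filter-sv` (post-call CNV/SV rules with per-rule removal reasons),
`run-scenario hh_demo` (recessive track recovery) and
`run-scenario dysautonomia_demo` (dominant cascade with a fixed survivor
count). Exit codes: 0 success, 2 validation error, 3 stage failure.

## Conventions & limitations

- All internal coordinates are 1-based inclusive; BED stays 0-based
  half-open on disk and is converted bijectively on read/write.
- Missing annotation values are `None`, never silently 0.
- Sex chromosomes: `X`/`chrX` are recognized for the X-linked model; no
  pseudo-autosomal-region handling.
- One chromosome per simulation spec; multi-chromosome studies are a loop
  over independent specs.
- No read-level simulation, alignment, or primary variant calling; the
  package operates on call records and their annotations.
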