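# ponsub

Panel-of-normals SNP database construction and allele-aware tumor-VCF
subtraction.

## The problem

A somatic mutation call in a tumor sample is only believable once germline
variation has been removed — both the individual's own (via a matched
normal) and the population's (via public catalogs such as dbSNP). Public
catalogs under-represent many non-European populations, so population-
specific germline variants routinely survive catalog depletion and
masquerade as somatic events. The remedy is a *panel of normals* (PoN): a
database of germline variants built from unrelated normal samples of the
study population, used as one more subtraction layer after the public
catalogs.

`ponsub` is a toolkit for exactly that workflow, aimed at cancer-genomics
analysts post-processing VCFs:

1. **build** — merge normal-sample VCFs into a cohort table, apply quality
   filters, deplete against known-SNP and known-somatic catalogs, persist
   the survivors as a single-file SQLite database;
2. **subtract** — remove database variants from tumor VCFs;
3. **summarize** — funnel percentages, the cohort minor-allele-frequency
   spectrum, per-chromosome novelty, annotation summaries;
4. **simulate** — synthetic cohorts with planted ground truth for testing.

## The model

Every variant is identified by the allele-aware key
*(chrom, pos, ref, alt)* — never by position alone — with chromosome labels
normalized (`chr7 → 7`, `chrM → MT`) and multi-allelic records split into
biallelic keys first. A cohort variant enters the database iff

```
max alt-read depth over carriers >= 5    (AD FORMAT field)
    OR  recurrence >= 4 distinct normal samples
```

and its key is in neither the known-SNP catalog nor the known-somatic
catalog. The recurrence clause rescues shallowly covered but independently
recurrent germline variants; the somatic-catalog depletion removes
catalogued cancer hotspots that would otherwise cause true somatic calls to
be subtracted from tumors. Subtraction removes a tumor record iff its key
is in the database; of a multi-allelic record only the matching alt alleles
are removed. The cohort allele frequency of a database entry is
`alt_allele_count / 2N` (diploid, non-carriers counted as hom-ref), folded
to a minor allele frequency in [0, 0.5].

## Worked example

```
$ ponsub simulate --out-dir demo --n-samples 4 --n-sites 120 --seed 5
demo: 4 normal VCFs, 120 sites, 46 expected database members (seed 5); tumor.vcf with 10 database members planted

$ ponsub build --normals demo/NORMAL_001.vcf --normals demo/NORMAL_002.vcf \
    --normals demo/NORMAL_003.vcf --normals demo/NORMAL_004.vcf \
    --snp-catalog demo/snp_catalog.tsv --somatic-catalog demo/somatic_catalog.tsv \
    --out demo/pon.db
INFO ponsub: build: 4 normal VCFs, min_alt_depth=5, min_recurrence=4
INFO ponsub: funnel: raw=216 unique=120 quality=118 -SNPcat=70 -somcat=2 final=46
demo/pon.db: 46 variants from 4 normals

$ ponsub subtract --tumor demo/tumor.vcf --db demo/pon.db \
    --out demo/tumor.subtracted.vcf --summary demo/summary.tsv
INFO ponsub: subtract: database demo/pon.db (46 variants, 4 normals)
INFO ponsub: tumor.vcf: input=40 removed=10 retained=30 (25.0%)
removed 10 panel-of-normals variants across 1 tumor VCF(s)
```

Reading the numbers: the 4-sample cohort restated 120 unique variant keys
in 216 observations; 118 passed the depth/recurrence filter; 70 were
already in the SNP catalog and 2 in the somatic catalog, leaving a
46-variant panel. The tumor VCF carried 40 variant keys of which the 10
planted database members were removed, retaining 30 candidate somatic
variants (a 25% reduction).

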