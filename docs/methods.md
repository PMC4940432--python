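# Methods

## The procedure

`ponsub` implements a panel-of-normals (PoN) workflow for post-processing
variant calls from tumor exomes. The pipeline has a fixed stage order:

1. **Merge.** Normal-sample VCFs are decomposed into per-(sample, allele)
   observations keyed by the allele-aware variant key
   *(chrom, pos, ref, alt)* and aggregated into one cohort entry per key.
   Recurrence counts *distinct samples* (a duplicated VCF line contributes
   nothing extra); the alt-allele count sums genotype dosages (het = 1,
   hom-alt = 2); the alt depth retained is the maximum AD entry over
   carriers.
2. **Quality filter.** An entry passes iff its maximum known alt depth is
   ≥ `min_alt_depth` (default 5) **or** its recurrence is ≥
   `min_recurrence` (default 4). The two clauses overlap at depth exactly
   5; the predicate is a plain OR, so an entry at the boundary passes by
   the depth clause alone. Entries whose carriers all lack AD have unknown
   depth and can pass only through the recurrence clause — a shallow or
   depthless observation is never assumed deep.
3. **Catalog depletion.** Survivors are removed if their key appears in
   the known-SNP catalog, then the remainder against the known-somatic
   catalog. Depletion is membership-only, so the retained set is the same
   in either order; the funnel accounting attributes each removal to the
   fixed SNP-then-somatic stage order.
4. **Persistence.** The final entries form the PoN database, stored as a
   single SQLite file with a `variants` table (chrom, pos, ref, alt,
   recurrence, alt_allele_count, max_alt_depth) and a `meta` table
   (cohort size, filter thresholds, catalog labels). Per-sample carrier
   identities are not persisted; reloaded entries carry
   `carrier_ids=None`.

**Subtraction** removes a tumor record iff its normalized key is in the
database. Multi-allelic tumor records lose only their matched alt alleles:
the record is dropped only when every alt matched, otherwise it is
rewritten with the surviving alts. Counting is per biallelic key, so
`n_input = n_removed + n_retained` holds exactly. Subtraction is
idempotent and monotone: re-subtracting removes nothing, and growing the
database can only shrink the retained set.

## Key and coordinate conventions

* Coordinates are 1-based throughout (VCF convention); no conversion
  anywhere.
* Chromosome labels are normalized by stripping a leading `chr`
  (case-insensitive) and mapping `M`/`chrM` to `MT`, so databases and
  tumor VCFs from different callers interoperate. Normalization is applied
  on both sides of every match.
* Multi-allelic sites are split into biallelic keys before any matching;
  the key has exactly one ref and one alt.
* Indel alleles are matched as exact strings after splitting. No
  left-alignment or parsimony trimming is performed: trimming would change
  matching semantics invisibly, and both sides of every comparison pass
  through the same normalization, so representation is consistent within a
  run. Inputs mixing indel representations from different callers should
  be normalized upstream (e.g. `bcftools norm`) before building.
* Symbolic alleles (`<DEL>`, breakends, `*`) are never matched: they are
  skipped with a warning during cohort building and retained with a
  warning during subtraction.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `min_alt_depth` | 5 reads | depth clause of the quality filter (alt-supporting reads, AD) |
| `min_recurrence` | 4 samples | recurrence rescue threshold |
| MAF bin edges | 0, .01, .02, .03, .04, .05, .10, .25, .5 | half-open bins of the cohort MAF spectrum; top bin closed at 0.5 |

The depth threshold is interpreted against the *cohort maximum* alt depth:
one confidently observed carrier suffices to trust the site. The stricter
per-carrier alternative (require ≥ 5 in every carrier) would discard
legitimately polymorphic sites whose additional carriers happen to be
shallow.

## Cohort allele frequencies

The alt allele frequency of a database entry is
`alt_allele_count / (2 * cohort_size)`: diploid genotypes, with samples
lacking a call at the site counted as homozygous reference. The minor
allele frequency is `min(f, 1 − f)`. Sex-chromosome ploidy is **not**
special-cased: X/Y frequencies use the same 2N denominator and are
therefore biased low for male-hemizygous sites; reports flag this rather
than correct it. Per-chromosome novelty against a reference catalog is
`100 · n_new / (n_new + n_reference)` — the share of the combined
known-plus-new pool on that chromosome contributed by the database.

Annotation summaries consume a pre-computed tab-delimited table
(chrom, pos, ref, alt, variant_class, region); this package never
annotates. Non-synonymous classes are missense, nonsense, splice-site,
frameshift/in-frame indels and start-codon changes; synonymous is
silent/synonymous. Reporting rounds percentages to 1 decimal, ratios to 2
decimals, and headline depletion percentages to the nearest integer.

## Synthetic cohorts

The generator emulates GATK-UnifiedGenotyper-style single-sample VCFs
(GT:AD:DP) for a cohort of normals, with planted per-site carrier counts,
alt depths and catalog memberships, and a truth table recording each
site's expected fate (the filter predicate and catalog flags applied to
the planted values). Defaults model a 62-normal exome cohort:

* carrier counts follow a truncated geometric law (P(k) ∝ 0.55^k), which
  puts the bulk of sites at minor allele frequencies ≤ 5%, the regime a
  cohort-private germline database actually occupies;
* alt depths are Poisson with mean 10 — a typical heterozygous alt depth
  at exome coverage;
* 60% of sites are planted into the SNP catalog and 2% into the somatic
  catalog (disjointly), echoing a funnel in which the large majority of
  quality variants are already publicly known;
* positions are drawn without replacement on contigs 1–22, X, Y; an
  optional indel fraction exercises exact-string indel matching.

Truth generation uses integer arithmetic and fixed formatting only, so a
given seed reproduces byte-identical files across platforms. What the
generator does **not** emulate: linkage between sites, mutational
signatures, strand/mapping artifacts, multi-sample joint calling, or any
read-level error process. Passing the planted-truth tests therefore
demonstrates the bookkeeping (merging, filtering, depletion, subtraction)
is exact, not that the filter thresholds are optimal for real exomes.

## Numerical and degenerate-input choices

* Percentages with a zero denominator are reported as not-applicable
  (`None`/`NA`), never as 0.
* A cohort producing zero usable observations raises an explicit
  empty-cohort error; a cohort whose variants all fail the filter yields a
  valid empty database.
* Build output is sorted by key, making rebuilds byte-identical and
  independent of input file order.
* MAF binning uses half-open `[lo, hi)` intervals with the top bin closed
  at 0.5, so every frequency lands in exactly one bin and the spectrum
  sums to 100%.
* The funnel statistics object validates its own conservation identities
  (`n_quality = n_post_snp + n_removed_snp`, `n_final = n_post_snp −
  n_removed_somatic`, monotone non-increasing stages) before any
  percentage is derived from it.

## Scale of the shipped checks

The acceptance checks run the published-count parity arithmetic (instant)
and synthetic end-to-end builds at 62 samples × 5000 sites, plus 100
random 10-sample × 500-site cohorts for planted-truth recovery — sizes
chosen to exercise every code path with distinct per-stage counts while
keeping a full run under a minute on one CPU. Rebuilding the original
database content itself is out of scope: it requires cluster-scale
alignment and variant calling of the raw cohort reads.

## Known limitations

* When a multi-allelic tumor record is rewritten with surviving alts, the
  FORMAT/sample columns (AD ordering, PL shape) still refer to the
  original allele list; downstream consumers re-parsing genotype fields of
  rewritten records must account for this. Whole-record removal and
  biallelic inputs (the common case after `bcftools norm`) are unaffected.
* Catalog matching is exact-key; a catalog using a different indel
  representation will not match without upstream normalization.
* gVCF blocks, structural variants and phasing are out of scope; GT is
  required for an observation to count.
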