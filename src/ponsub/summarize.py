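"""Descriptive statistics for the panel-of-normals and the subtraction funnel.

Covers four families of summaries:

* funnel and depletion percentages (what fraction each stage removed, and
  the additional reduction a PoN buys on top of a public SNP catalog);
* the cohort minor-allele-frequency (MAF) spectrum of the database;
* per-chromosome novelty relative to a reference catalog — the share of
  all known-plus-new variants on a chromosome that the database contributes;
* annotation summaries (non-synonymous/synonymous ratio, variant-class and
  genomic-region breakdowns) consumed from a pre-computed annotation table.

Every reported percentage is recomputable from the counts it accompanies;
no percentage is stored without its numerator and denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .pon import CohortEntry, FunnelStats, PoNDatabase

__all__ = [
    "MafSpectrum",
    "ChromNovelty",
    "AnnotationSummary",
    "DEFAULT_MAF_BIN_EDGES",
    "funnel_percentages",
    "depletion_percentages",
    "cohort_allele_frequency",
    "maf_spectrum",
    "maf_fraction_at_or_below",
    "chromosome_novelty",
    "annotation_summary",
    "read_annotation_table",
]

# Half-open bins [lo, hi); the last bin includes 0.5. Fine-grained below 5%
# where a cohort-private germline database concentrates its mass.
DEFAULT_MAF_BIN_EDGES: tuple[float, ...] = (
    0.0, 0.01, 0.02, 0.03, 0.04, 0.05, 0.10, 0.25, 0.5,
)


def _pct(numerator: int, denominator: int) -> Optional[float]:
    """Percentage, or None (reported as not-applicable) on a zero denominator."""
    if denominator == 0:
        return None
    return 100.0 * numerator / denominator


def funnel_percentages(stats: FunnelStats) -> dict[str, Optional[float]]:
    """Per-stage percentages of the build funnel.

    percent depleted at a stage = 100 * removed / entering that stage;
    percent remaining overall = 100 * final / unique.
    """
    stats.validate()
    return {
        "quality_removed_percent": _pct(
            stats.n_unique - stats.n_quality, stats.n_unique
        ),
        "snp_catalog_depleted_percent": _pct(
            stats.n_removed_snp_catalog, stats.n_quality
        ),
        "somatic_catalog_depleted_percent": _pct(
            stats.n_removed_somatic_catalog, stats.n_post_snp_catalog
        ),
        "final_remaining_percent": _pct(stats.n_final, stats.n_unique),
    }


def depletion_percentages(
    total: int, post_catalog: int, post_pon: int
) -> dict[str, Optional[float]]:
    """Tumor-side reduction summary for one sample set.

    ``total``: variants entering; ``post_catalog``: remaining after public
    SNP-catalog depletion; ``post_pon``: remaining after additional PoN
    subtraction. ``additional_reduction_percent`` is the share of
    post-catalog variants that the PoN further removed:
    100 * (post_catalog - post_pon) / post_catalog.
    """
    if not (total >= post_catalog >= post_pon >= 0):
        raise ValueError("stage counts must be non-negative and non-increasing")
    return {
        "post_catalog_percent": _pct(post_catalog, total),
        "post_pon_percent": _pct(post_pon, total),
        "catalog_depleted_percent": _pct(total - post_catalog, total),
        "additional_reduction_percent": _pct(
            post_catalog - post_pon, post_catalog
        ),
    }


def cohort_allele_frequency(
    entry: CohortEntry, cohort_size: int
) -> tuple[float, float]:
    """(alt allele frequency, minor allele frequency) for one entry.

    Assumes diploid genotypes and counts non-carriers as homozygous
    reference, so f_alt = alt_allele_count / (2 * cohort_size) and
    MAF = min(f_alt, 1 - f_alt).
    """
    if cohort_size < 1:
        raise ValueError("cohort_size must be >= 1")
    if entry.recurrence > cohort_size:
        raise ValueError("entry recurrence exceeds cohort size")
    f_alt = entry.alt_allele_count / (2 * cohort_size)
    return f_alt, min(f_alt, 1.0 - f_alt)


@dataclass
class MafSpectrum:
    """Binned minor-allele-frequency distribution of the database."""

    bin_edges: tuple[float, ...]
    bin_counts: list[int]
    n_total: int

    @property
    def bin_percents(self) -> list[float]:
        return [100.0 * c / self.n_total for c in self.bin_counts]

    def labels(self) -> list[str]:
        edges = self.bin_edges
        return [f"[{lo:g},{hi:g})" for lo, hi in zip(edges, edges[1:])]


def maf_spectrum(
    db: PoNDatabase,
    bin_edges: Sequence[float] = DEFAULT_MAF_BIN_EDGES,
) -> MafSpectrum:
    """Bin each database variant's MAF into half-open intervals [lo, hi)
    (the top bin is closed at 0.5). Percentages are over database size and
    sum to 100."""
    if len(db) == 0:
        raise ValueError("nothing to summarize: database is empty")
    edges = tuple(bin_edges)
    if list(edges) != sorted(edges) or edges[0] != 0.0 or edges[-1] != 0.5:
        raise ValueError("bin edges must ascend from 0.0 to 0.5")
    counts = [0] * (len(edges) - 1)
    for entry in db.entries:
        _, maf = cohort_allele_frequency(entry, db.cohort_size)
        for i, (lo, hi) in enumerate(zip(edges, edges[1:])):
            last = i == len(counts) - 1
            if lo <= maf < hi or (last and maf == hi):
                counts[i] += 1
                break
    return MafSpectrum(bin_edges=edges, bin_counts=counts, n_total=len(db))


def maf_fraction_at_or_below(db: PoNDatabase, threshold: float) -> float:
    """Percent of database variants with MAF <= threshold."""
    if len(db) == 0:
        raise ValueError("nothing to summarize: database is empty")
    n = sum(
        1
        for e in db.entries
        if cohort_allele_frequency(e, db.cohort_size)[1] <= threshold
    )
    return 100.0 * n / len(db)


@dataclass
class ChromNovelty:
    """Per-chromosome share of variants that are new relative to a catalog.

    percent_new(chrom) = 100 * n_new / (n_new + n_reference): the fraction
    of the combined known-plus-new pool on that chromosome contributed by
    the database. None where the combined pool is empty.
    """

    n_new: dict[str, int]
    n_reference: dict[str, int]

    @property
    def percent_new(self) -> dict[str, Optional[float]]:
        chroms = set(self.n_new) | set(self.n_reference)
        return {
            c: _pct(
                self.n_new.get(c, 0),
                self.n_new.get(c, 0) + self.n_reference.get(c, 0),
            )
            for c in chroms
        }

    @property
    def total_new(self) -> int:
        return sum(self.n_new.values())


def chromosome_novelty(
    db: PoNDatabase, reference_counts: Mapping[str, int]
) -> ChromNovelty:
    """Count database variants per chromosome and pair them with reference
    catalog counts. Chromosomes absent from the database report 0 new."""
    n_new: dict[str, int] = {}
    for entry in db.entries:
        n_new[entry.key.chrom] = n_new.get(entry.key.chrom, 0) + 1
    return ChromNovelty(n_new=n_new, n_reference=dict(reference_counts))


# Variant-class vocabulary: which classes count as protein-changing
# (non-synonymous) versus synonymous in the NS/S ratio.
NONSYNONYMOUS_CLASSES = frozenset(
    {
        "non-synonymous", "nonsynonymous", "missense", "missense_mutation",
        "nonsense", "nonsense_mutation", "splice-site", "splice_site",
        "nonstop", "frame_shift_ins", "frame_shift_del",
        "in_frame_ins", "in_frame_del", "indel", "start_codon_snp",
    }
)
SYNONYMOUS_CLASSES = frozenset({"synonymous", "silent"})


@dataclass
class AnnotationSummary:
    """Counts of variants by functional class and genomic region."""

    class_counts: dict[str, int]
    region_counts: dict[str, int]
    n_total: int

    @property
    def n_nonsynonymous(self) -> int:
        return sum(
            c for k, c in self.class_counts.items()
            if k.lower() in NONSYNONYMOUS_CLASSES
        )

    @property
    def n_synonymous(self) -> int:
        return sum(
            c for k, c in self.class_counts.items()
            if k.lower() in SYNONYMOUS_CLASSES
        )

    @property
    def ns_s_ratio(self) -> Optional[float]:
        s = self.n_synonymous
        if s == 0:
            return None
        return self.n_nonsynonymous / s

    def region_percent(self, region: str) -> Optional[float]:
        return _pct(self.region_counts.get(region, 0), self.n_total)

    def class_percent(self, cls: str) -> Optional[float]:
        return _pct(self.class_counts.get(cls, 0), self.n_total)


def annotation_summary(
    annotations: Union[pd.DataFrame, Iterable[tuple[str, str]]],
) -> AnnotationSummary:
    """Summarize a pre-computed annotation table.

    Accepts a DataFrame with ``variant_class`` and ``region`` columns, or an
    iterable of (variant_class, region) pairs. Unknown labels are counted
    as-is (they fall under neither NS nor S).
    """
    if isinstance(annotations, pd.DataFrame):
        pairs = list(
            zip(annotations["variant_class"].astype(str), annotations["region"].astype(str))
        )
    else:
        pairs = list(annotations)
    if not pairs:
        raise ValueError("nothing to summarize: annotation table is empty")
    class_counts: dict[str, int] = {}
    region_counts: dict[str, int] = {}
    for cls, region in pairs:
        class_counts[cls] = class_counts.get(cls, 0) + 1
        region_counts[region] = region_counts.get(region, 0) + 1
    return AnnotationSummary(
        class_counts=class_counts,
        region_counts=region_counts,
        n_total=len(pairs),
    )


def read_annotation_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read a tab-delimited annotation table with columns
    (chrom, pos, ref, alt, variant_class, region)."""
    df = pd.read_csv(path, sep="\t", comment=None)
    required = {"chrom", "pos", "ref", "alt", "variant_class", "region"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    return df
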