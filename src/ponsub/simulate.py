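"""Synthetic normal cohorts, catalogs and tumor VCFs with planted truth.

The generator emulates the kind of input the builder sees in practice: a
cohort of normal-sample VCFs in GATK UnifiedGenotyper style (GT:AD:DP
FORMAT columns), with controlled per-site carrier counts, controlled alt
depths, and a controlled fraction of sites planted into a known-SNP catalog
and a known-somatic catalog. Every site's expected fate through the build
funnel is recorded in a truth table computed from the planted values by the
documented filter predicate, so end-to-end tests can compare the pipeline's
output against an independent expectation.

Defaults mirror a 62-normal exome cohort: carrier counts are skewed low
(most variants are singletons, putting >90% of sites at cohort MAF <= 5%),
alt depths are Poisson with mean 10, and a majority of sites (60%) are
already known to the SNP catalog. Truth generation uses integer arithmetic
and fixed formatting only, so a seed reproduces byte-identical files on any
platform.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .pon import Catalog, FilterParams
from .vcf_io import VariantKey, VcfDocument, VcfRecord, make_document

__all__ = [
    "CohortSpec",
    "SiteTruth",
    "TruthTable",
    "CohortData",
    "generate_cohort",
    "generate_tumor",
    "write_truth_table",
    "write_catalog_tsv",
]

CONTIGS: tuple[str, ...] = tuple(str(i) for i in range(1, 23)) + ("X", "Y")
_BASES = ("A", "C", "G", "T")

# Carrier-count law emulating a low-frequency-dominated germline pool:
# P(k carriers) ~ 0.55^k, truncated at the cohort size.
_RECURRENCE_DECAY = 0.55


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic normal cohort.

    recurrence_distribution: "skewed" (geometric-like, low-frequency
    dominated), "uniform" (1..n_samples), or an explicit per-site carrier
    count list of length n_sites. depth_distribution: "poisson" (mean
    depth_mean) or an explicit per-site depth list applied to every carrier.
    Planted catalog fractions must not overlap (sum <= 1).
    """

    n_samples: int = 62
    n_sites: int = 5000
    recurrence_distribution: Union[str, Sequence[int]] = "skewed"
    depth_distribution: Union[str, Sequence[int]] = "poisson"
    depth_mean: float = 10.0
    frac_in_snp_catalog: float = 0.60
    frac_in_somatic_catalog: float = 0.02
    indel_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_sites < 1:
            raise ValueError("n_samples and n_sites must be >= 1")
        for f in (self.frac_in_snp_catalog, self.frac_in_somatic_catalog):
            if not 0.0 <= f <= 1.0:
                raise ValueError("catalog fractions must lie in [0, 1]")
        if self.frac_in_snp_catalog + self.frac_in_somatic_catalog > 1.0:
            raise ValueError(
                "catalog plant fractions overlap: their sum exceeds 1"
            )


@dataclass
class SiteTruth:
    """Planted values and expected outcomes for one site."""

    key: VariantKey
    carrier_samples: list[int]          # sample indices carrying the alt
    carrier_depths: list[int]           # alt depth per carrier, same order
    carrier_dosages: list[int]          # 1 het / 2 hom-alt per carrier
    in_snp_catalog: bool
    in_somatic_catalog: bool
    expected_pass_filter: bool
    expected_in_db: bool

    @property
    def recurrence(self) -> int:
        return len(self.carrier_samples)

    @property
    def alt_allele_count(self) -> int:
        return sum(self.carrier_dosages)

    @property
    def max_alt_depth(self) -> int:
        return max(self.carrier_depths)


@dataclass
class TruthTable:
    sites: list[SiteTruth]
    spec: CohortSpec

    @property
    def expected_db_keys(self) -> frozenset[VariantKey]:
        return frozenset(s.key for s in self.sites if s.expected_in_db)

    @property
    def expected_pass_keys(self) -> frozenset[VariantKey]:
        return frozenset(s.key for s in self.sites if s.expected_pass_filter)


@dataclass
class CohortData:
    """In-memory output of :func:`generate_cohort`."""

    normals: list[VcfDocument]
    sample_names: list[str]
    snp_catalog: Catalog
    somatic_catalog: Catalog
    truth: TruthTable


def _draw_recurrence(rng: np.random.Generator, spec: CohortSpec) -> list[int]:
    if isinstance(spec.recurrence_distribution, str):
        if spec.recurrence_distribution == "uniform":
            return [
                int(rng.integers(1, spec.n_samples + 1))
                for _ in range(spec.n_sites)
            ]
        if spec.recurrence_distribution == "skewed":
            ks = np.arange(1, spec.n_samples + 1)
            weights = _RECURRENCE_DECAY ** ks
            probs = weights / weights.sum()
            return [int(k) for k in rng.choice(ks, size=spec.n_sites, p=probs)]
        raise ValueError(
            f"unknown recurrence_distribution {spec.recurrence_distribution!r}"
        )
    values = list(spec.recurrence_distribution)
    if len(values) != spec.n_sites:
        raise ValueError("explicit recurrence list must have n_sites entries")
    if any(not 1 <= v <= spec.n_samples for v in values):
        raise ValueError("recurrence values must lie in 1..n_samples")
    return [int(v) for v in values]


def _draw_depth(rng: np.random.Generator, spec: CohortSpec, site: int) -> Optional[int]:
    if isinstance(spec.depth_distribution, str):
        if spec.depth_distribution == "poisson":
            return int(rng.poisson(spec.depth_mean))
        raise ValueError(
            f"unknown depth_distribution {spec.depth_distribution!r}"
        )
    values = spec.depth_distribution
    if len(values) != spec.n_sites:
        raise ValueError("explicit depth list must have n_sites entries")
    return int(values[site])


def _draw_keys(rng: np.random.Generator, spec: CohortSpec) -> list[VariantKey]:
    """Distinct keys spread over synthetic contigs, positions drawn without
    replacement per contig, sorted by (chrom, pos)."""
    contig_of_site = rng.integers(0, len(CONTIGS), size=spec.n_sites)
    used: dict[str, set[int]] = {c: set() for c in CONTIGS}
    keys: list[VariantKey] = []
    for site in range(spec.n_sites):
        chrom = CONTIGS[int(contig_of_site[site])]
        while True:
            pos = int(rng.integers(1, 50_000_000))
            if pos not in used[chrom]:
                used[chrom].add(pos)
                break
        ref = _BASES[int(rng.integers(0, 4))]
        if spec.indel_fraction > 0 and rng.random() < spec.indel_fraction:
            if rng.random() < 0.5:  # insertion
                ins = "".join(_BASES[int(rng.integers(0, 4))] for _ in range(2))
                alt = ref + ins
            else:  # deletion: multi-base ref
                tail = "".join(_BASES[int(rng.integers(0, 4))] for _ in range(2))
                ref, alt = ref + tail, ref
        else:
            alt = _BASES[int(rng.integers(0, 4))]
            while alt == ref:
                alt = _BASES[int(rng.integers(0, 4))]
        keys.append(VariantKey(chrom, pos, ref, alt))
    keys.sort()
    return keys


def generate_cohort(
    spec: CohortSpec,
    out_dir: Optional[Union[str, Path]] = None,
    filter_params: FilterParams = FilterParams(),
) -> CohortData:
    """Generate a synthetic normal cohort with planted truth.

    Returns in-memory documents, catalogs and the truth table; when
    ``out_dir`` is given, also writes one VCF per normal sample, the two
    catalogs as TSV, and the truth table as TSV. Reproducible: the same
    spec (including seed) yields byte-identical outputs.
    """
    rng = np.random.default_rng(spec.seed)
    keys = _draw_keys(rng, spec)
    recurrences = _draw_recurrence(rng, spec)

    n_snp = int(round(spec.frac_in_snp_catalog * spec.n_sites))
    n_som = int(round(spec.frac_in_somatic_catalog * spec.n_sites))
    planted = rng.permutation(spec.n_sites)
    snp_sites = set(int(i) for i in planted[:n_snp])
    som_sites = set(int(i) for i in planted[n_snp:n_snp + n_som])

    sites: list[SiteTruth] = []
    for i, (key, rec) in enumerate(zip(keys, recurrences)):
        carriers = sorted(
            int(s) for s in rng.choice(spec.n_samples, size=rec, replace=False)
        )
        depths = [int(_draw_depth(rng, spec, i)) for _ in carriers]
        dosages = [2 if rng.random() < 0.05 else 1 for _ in carriers]
        in_snp = i in snp_sites
        in_som = i in som_sites
        passes = max(depths) >= filter_params.min_alt_depth or (
            rec >= filter_params.min_recurrence
        )
        sites.append(
            SiteTruth(
                key=key,
                carrier_samples=carriers,
                carrier_depths=depths,
                carrier_dosages=dosages,
                in_snp_catalog=in_snp,
                in_somatic_catalog=in_som,
                expected_pass_filter=passes,
                expected_in_db=passes and not in_snp and not in_som,
            )
        )

    sample_names = [f"NORMAL_{i + 1:03d}" for i in range(spec.n_samples)]
    normals = []
    for s in range(spec.n_samples):
        records = []
        for site in sites:
            if s not in site.carrier_samples:
                continue
            idx = site.carrier_samples.index(s)
            depth = site.carrier_depths[idx]
            dosage = site.carrier_dosages[idx]
            gt = "1/1" if dosage == 2 else "0/1"
            ref_depth = int(depth) if dosage == 1 else 0
            dp = ref_depth + depth
            records.append(
                VcfRecord(
                    [
                        site.key.chrom, str(site.key.pos), ".",
                        site.key.ref, site.key.alt, "100", "PASS", ".",
                        "GT:AD:DP", f"{gt}:{ref_depth},{depth}:{dp}",
                    ]
                )
            )
        normals.append(
            make_document([sample_names[s]], records, source="ponsub-simulate")
        )

    snp_catalog = Catalog(
        name="snp-catalog",
        keys=frozenset(sites[i].key for i in snp_sites),
        version_label="synthetic-snp",
    )
    somatic_catalog = Catalog(
        name="somatic-catalog",
        keys=frozenset(sites[i].key for i in som_sites),
        version_label="synthetic-somatic",
    )
    truth = TruthTable(sites=sites, spec=spec)
    data = CohortData(
        normals=normals,
        sample_names=sample_names,
        snp_catalog=snp_catalog,
        somatic_catalog=somatic_catalog,
        truth=truth,
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        from .vcf_io import write_vcf

        for name, doc in zip(sample_names, normals):
            write_vcf(doc, out_dir / f"{name}.vcf")
        write_catalog_tsv(snp_catalog, out_dir / "snp_catalog.tsv")
        write_catalog_tsv(somatic_catalog, out_dir / "somatic_catalog.tsv")
        write_truth_table(truth, out_dir / "truth.tsv")
    return data


def generate_tumor(
    truth: TruthTable,
    n_private_somatic: int,
    n_db_overlap: int,
    seed: int,
    sample_name: str = "TUMOR",
) -> tuple[VcfDocument, int]:
    """Generate a tumor VCF containing exactly ``n_db_overlap`` keys from
    the truth table's expected database plus ``n_private_somatic`` novel
    keys absent from the cohort. Returns (document, expected removal count
    under subtraction against the built database)."""
    rng = np.random.default_rng(seed)
    db_keys = sorted(truth.expected_db_keys)
    if n_db_overlap > len(db_keys):
        raise ValueError(
            f"requested overlap {n_db_overlap} exceeds database size {len(db_keys)}"
        )
    picked = [
        db_keys[int(i)]
        for i in rng.choice(len(db_keys), size=n_db_overlap, replace=False)
    ] if n_db_overlap else []

    cohort_keys = {s.key for s in truth.sites}
    used_pos = {(k.chrom, k.pos) for k in cohort_keys}
    private: list[VariantKey] = []
    while len(private) < n_private_somatic:
        chrom = CONTIGS[int(rng.integers(0, len(CONTIGS)))]
        pos = int(rng.integers(50_000_001, 100_000_000))
        if (chrom, pos) in used_pos:
            continue
        used_pos.add((chrom, pos))
        ref = _BASES[int(rng.integers(0, 4))]
        alt = _BASES[int(rng.integers(0, 4))]
        while alt == ref:
            alt = _BASES[int(rng.integers(0, 4))]
        private.append(VariantKey(chrom, pos, ref, alt))

    records = []
    for key in sorted(picked + private):
        depth = max(1, int(rng.poisson(20)))
        records.append(
            VcfRecord(
                [
                    key.chrom, str(key.pos), ".", key.ref, key.alt,
                    "100", "PASS", ".",
                    "GT:AD:DP", f"0/1:{depth},{depth}:{2 * depth}",
                ]
            )
        )
    doc = make_document([sample_name], records, source="ponsub-simulate")
    return doc, n_db_overlap


def write_catalog_tsv(catalog: Catalog, path: Union[str, Path]) -> None:
    lines = ["#chrom\tpos\tref\talt"]
    for key in sorted(catalog.keys):
        lines.append(f"{key.chrom}\t{key.pos}\t{key.ref}\t{key.alt}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_truth_table(truth: TruthTable, path: Union[str, Path]) -> None:
    lines = [
        "#chrom\tpos\tref\talt\trecurrence\tmax_alt_depth\talt_allele_count"
        "\tin_snp_catalog\tin_somatic_catalog\tpass_filter\tin_db"
    ]
    for s in truth.sites:
        lines.append(
            f"{s.key.chrom}\t{s.key.pos}\t{s.key.ref}\t{s.key.alt}"
            f"\t{s.recurrence}\t{s.max_alt_depth}\t{s.alt_allele_count}"
            f"\t{int(s.in_snp_catalog)}\t{int(s.in_somatic_catalog)}"
            f"\t{int(s.expected_pass_filter)}\t{int(s.expected_in_db)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
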