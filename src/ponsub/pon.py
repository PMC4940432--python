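"""Panel-of-normals database construction.

The pipeline merges per-sample normal VCFs into a cohort table keyed by
(chrom, pos, ref, alt), applies a two-clause quality filter — an alt-allele
read depth of at least 5 in some carrier, or recurrence in at least 4
distinct normal samples — then depletes the survivors against a known-SNP
catalog (dbSNP-style) and a known-somatic catalog (COSMIC-style). What
remains is the panel-of-normals (PoN) database of cohort-private germline
variants, persisted as a single SQLite file.

The recurrence rescue exists because a variant seen independently in many
unrelated normals is almost certainly a real germline polymorphism even
when each individual observation is shallow; the somatic-catalog depletion
exists because a catalogued somatic hotspot showing up in normal tissue is
more plausibly a false somatic event than a population polymorphism, and
keeping it in the PoN would subtract true somatic calls from tumors.
"""

from __future__ import annotations

import sqlite3
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

from .vcf_io import (
    VariantKey,
    VcfDocument,
    normalize_chrom,
    read_vcf,
)

__all__ = [
    "CohortEntry",
    "FilterParams",
    "Catalog",
    "PoNDatabase",
    "FunnelStats",
    "EmptyCohortError",
    "DatabaseFormatError",
    "merge_cohort",
    "apply_quality_filter",
    "deplete_catalog",
    "build_database",
    "save_database",
    "load_database",
    "read_catalog",
]


class EmptyCohortError(ValueError):
    """No usable variant observations across the normal cohort."""


class DatabaseFormatError(ValueError):
    """A file is not a PoN database (missing or malformed tables)."""


@dataclass
class CohortEntry:
    """One variant aggregated across the normal cohort.

    recurrence counts *distinct samples* carrying the allele (a duplicated
    VCF line adds nothing); alt_allele_count counts allele copies (het=1,
    hom_alt=2 per carrier); max_alt_depth is the maximum known alt-supporting
    read depth over carriers, None when no carrier reported AD.
    carrier_ids is None for entries reloaded from disk (per-sample identity
    is not persisted).
    """

    key: VariantKey
    recurrence: int
    max_alt_depth: Optional[int]
    alt_allele_count: int
    carrier_ids: Optional[frozenset[str]] = None

    def __post_init__(self) -> None:
        if self.recurrence < 1:
            raise ValueError("recurrence must be >= 1")
        if not (self.recurrence <= self.alt_allele_count <= 2 * self.recurrence):
            raise ValueError(
                f"alt_allele_count {self.alt_allele_count} inconsistent with "
                f"recurrence {self.recurrence}"
            )
        if self.carrier_ids is not None and len(self.carrier_ids) != self.recurrence:
            raise ValueError("recurrence must equal |carrier_ids|")


@dataclass(frozen=True)
class FilterParams:
    """Quality-filter thresholds.

    min_alt_depth: minimum alt-supporting read depth for the depth clause
    (default 5). min_recurrence: minimum number of distinct carrier samples
    for the recurrence rescue (default 4).
    """

    min_alt_depth: int = 5
    min_recurrence: int = 4

    def __post_init__(self) -> None:
        if self.min_alt_depth < 1 or self.min_recurrence < 1:
            raise ValueError("filter thresholds must be >= 1")

    def passes(self, entry: CohortEntry) -> bool:
        """True iff the entry survives: known depth >= min_alt_depth, OR
        recurrence >= min_recurrence. Unknown depth never satisfies the
        depth clause."""
        deep = entry.max_alt_depth is not None and entry.max_alt_depth >= self.min_alt_depth
        return deep or entry.recurrence >= self.min_recurrence


@dataclass
class Catalog:
    """A set of known variant keys (e.g. a dbSNP- or COSMIC-style list)."""

    name: str
    keys: frozenset[VariantKey]
    version_label: str = ""

    def __len__(self) -> int:
        return len(self.keys)

    @classmethod
    def empty(cls, name: str) -> "Catalog":
        return cls(name=name, keys=frozenset())


@dataclass
class FunnelStats:
    """Counts at each stage of the build funnel.

    Invariants: n_quality = n_post_snp_catalog + n_removed_snp_catalog and
    n_final = n_post_snp_catalog - n_removed_somatic_catalog; all stages
    after n_unique are monotone non-increasing.
    """

    n_raw: int
    n_unique: int
    n_quality: int
    n_removed_snp_catalog: int
    n_post_snp_catalog: int
    n_removed_somatic_catalog: int
    n_final: int

    def validate(self) -> None:
        counts = [
            self.n_raw, self.n_unique, self.n_quality,
            self.n_removed_snp_catalog, self.n_post_snp_catalog,
            self.n_removed_somatic_catalog, self.n_final,
        ]
        if any(c < 0 for c in counts):
            raise ValueError("funnel counts must be non-negative")
        if self.n_quality != self.n_post_snp_catalog + self.n_removed_snp_catalog:
            raise ValueError("funnel conservation violated at SNP-catalog stage")
        if self.n_final != self.n_post_snp_catalog - self.n_removed_somatic_catalog:
            raise ValueError("funnel conservation violated at somatic-catalog stage")
        if not (self.n_unique >= self.n_quality >= self.n_post_snp_catalog >= self.n_final):
            raise ValueError("funnel must be monotone non-increasing")


@dataclass
class PoNDatabase:
    """The panel-of-normals: retained cohort entries plus provenance."""

    entries: list[CohortEntry]
    cohort_size: int
    provenance: dict[str, str] = field(default_factory=dict)

    @property
    def keys(self) -> frozenset[VariantKey]:
        return frozenset(e.key for e in self.entries)

    def __len__(self) -> int:
        return len(self.entries)


def merge_cohort(
    normals: Sequence[VcfDocument],
) -> dict[VariantKey, CohortEntry]:
    """Merge normal-sample VCF documents into one cohort table.

    Sample identity comes from the VCF sample columns; a sample id appearing
    in more than one document (or twice in one) is a fatal configuration
    error. A sample contributes at most once to a key's recurrence no matter
    how many VCF lines restate it; for restated lines the deepest AD and the
    highest allele dosage win.
    """
    seen_samples: set[str] = set()
    for doc in normals:
        for name in doc.sample_names:
            if name in seen_samples:
                raise ValueError(f"duplicate sample id across cohort: {name!r}")
            seen_samples.add(name)
    if not seen_samples:
        raise ValueError("cohort documents declare no samples")

    # per key: sample -> (best depth, best dosage)
    acc: dict[VariantKey, dict[str, tuple[Optional[int], int]]] = {}
    for doc in normals:
        for obs in doc.iter_observations():
            per_sample = acc.setdefault(obs.key, {})
            prev = per_sample.get(obs.sample_id)
            depth, dosage = obs.alt_depth, obs.allele_dosage
            if prev is not None:
                prev_depth, prev_dosage = prev
                if depth is None or (prev_depth is not None and prev_depth > depth):
                    depth = prev_depth
                dosage = max(dosage, prev_dosage)
            per_sample[obs.sample_id] = (depth, dosage)

    cohort: dict[VariantKey, CohortEntry] = {}
    for key, per_sample in acc.items():
        depths = [d for d, _ in per_sample.values() if d is not None]
        cohort[key] = CohortEntry(
            key=key,
            recurrence=len(per_sample),
            max_alt_depth=max(depths) if depths else None,
            alt_allele_count=sum(dos for _, dos in per_sample.values()),
            carrier_ids=frozenset(per_sample),
        )
    return cohort


def apply_quality_filter(
    cohort: Mapping[VariantKey, CohortEntry] | Iterable[CohortEntry],
    params: FilterParams = FilterParams(),
) -> tuple[list[CohortEntry], list[CohortEntry]]:
    """Partition cohort entries into (passed, failed) by the quality predicate."""
    entries = cohort.values() if isinstance(cohort, Mapping) else cohort
    passed, failed = [], []
    for entry in entries:
        (passed if params.passes(entry) else failed).append(entry)
    return passed, failed


def deplete_catalog(
    variants: Iterable[CohortEntry], catalog: Catalog
) -> tuple[list[CohortEntry], list[CohortEntry]]:
    """Partition entries into (retained, removed) by exact-key catalog
    membership. Matching is allele-aware on the full (chrom, pos, ref, alt)
    key, never position-only."""
    retained, removed = [], []
    for entry in variants:
        (removed if entry.key in catalog.keys else retained).append(entry)
    return retained, removed


def _sorted_entries(entries: Iterable[CohortEntry]) -> list[CohortEntry]:
    return sorted(entries, key=lambda e: e.key)


def build_database(
    normals: Sequence[VcfDocument],
    snp_catalog: Catalog,
    somatic_catalog: Catalog,
    params: FilterParams = FilterParams(),
) -> tuple[PoNDatabase, FunnelStats]:
    """Run the full build funnel: merge -> quality filter -> SNP-catalog
    depletion -> somatic-catalog depletion.

    Raises :class:`EmptyCohortError` when the cohort yields zero usable
    variant observations (an all-reference cohort is a configuration
    problem, not an empty database). The result is deterministic and
    independent of input document ordering: entries are sorted by key.
    """
    n_raw = sum(
        len(list(doc.iter_observations())) for doc in normals
    )
    cohort = merge_cohort(normals)
    if not cohort:
        raise EmptyCohortError(
            "no usable variant observations in the normal cohort"
        )
    passed, _failed = apply_quality_filter(cohort, params)
    post_snp, removed_snp = deplete_catalog(passed, snp_catalog)
    final, removed_somatic = deplete_catalog(post_snp, somatic_catalog)

    stats = FunnelStats(
        n_raw=n_raw,
        n_unique=len(cohort),
        n_quality=len(passed),
        n_removed_snp_catalog=len(removed_snp),
        n_post_snp_catalog=len(post_snp),
        n_removed_somatic_catalog=len(removed_somatic),
        n_final=len(final),
    )
    stats.validate()

    cohort_size = sum(len(doc.sample_names) for doc in normals)
    db = PoNDatabase(
        entries=_sorted_entries(final),
        cohort_size=cohort_size,
        provenance={
            "min_alt_depth": str(params.min_alt_depth),
            "min_recurrence": str(params.min_recurrence),
            "snp_catalog": snp_catalog.version_label or snp_catalog.name,
            "somatic_catalog": somatic_catalog.version_label or somatic_catalog.name,
        },
    )
    return db, stats


# ---------------------------------------------------------------------------
# persistence: single-file SQLite with tables `variants` and `meta`

_SCHEMA = """
CREATE TABLE variants (
    chrom TEXT NOT NULL,
    pos INTEGER NOT NULL,
    ref TEXT NOT NULL,
    alt TEXT NOT NULL,
    recurrence INTEGER NOT NULL,
    alt_allele_count INTEGER NOT NULL,
    max_alt_depth INTEGER,
    PRIMARY KEY (chrom, pos, ref, alt)
);
CREATE TABLE meta (key TEXT PRIMARY KEY, value TEXT);
"""


def save_database(db: PoNDatabase, path: Union[str, Path]) -> None:
    """Persist a PoN database to a SQLite file (overwrites)."""
    path = Path(path)
    if path.exists():
        path.unlink()
    con = sqlite3.connect(path)
    try:
        con.executescript(_SCHEMA)
        con.executemany(
            "INSERT INTO variants VALUES (?,?,?,?,?,?,?)",
            [
                (
                    e.key.chrom, e.key.pos, e.key.ref, e.key.alt,
                    e.recurrence, e.alt_allele_count, e.max_alt_depth,
                )
                for e in db.entries
            ],
        )
        meta = {"cohort_size": str(db.cohort_size), **db.provenance}
        con.executemany("INSERT INTO meta VALUES (?,?)", sorted(meta.items()))
        con.commit()
    finally:
        con.close()


def load_database(path: Union[str, Path]) -> PoNDatabase:
    """Load a PoN database saved by :func:`save_database`.

    Raises :class:`DatabaseFormatError` for files that are not SQLite or
    lack the ``variants`` table.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    con = sqlite3.connect(path)
    try:
        try:
            tables = {
                row[0]
                for row in con.execute(
                    "SELECT name FROM sqlite_master WHERE type='table'"
                )
            }
        except sqlite3.DatabaseError as exc:
            raise DatabaseFormatError(f"{path}: not a SQLite database") from exc
        if "variants" not in tables:
            raise DatabaseFormatError(f"{path}: missing table 'variants'")
        entries = [
            CohortEntry(
                key=VariantKey(chrom, pos, ref, alt),
                recurrence=rec,
                alt_allele_count=aac,
                max_alt_depth=mad,
                carrier_ids=None,
            )
            for chrom, pos, ref, alt, rec, aac, mad in con.execute(
                "SELECT chrom,pos,ref,alt,recurrence,alt_allele_count,max_alt_depth"
                " FROM variants ORDER BY chrom,pos,ref,alt"
            )
        ]
        meta = dict(con.execute("SELECT key, value FROM meta")) if "meta" in tables else {}
    finally:
        con.close()
    cohort_size = int(meta.pop("cohort_size", "0"))
    return PoNDatabase(
        entries=_sorted_entries(entries),
        cohort_size=cohort_size,
        provenance=meta,
    )


def read_catalog(path: Union[str, Path], name: str, version_label: str = "") -> Catalog:
    """Read a known-variant catalog from VCF or 4-column TSV.

    The TSV form is (chrom, pos, ref, alt), tab-delimited, ``#`` comment
    lines ignored. A file starting with ``##fileformat=`` is parsed as VCF;
    multi-allelic ALT fields are split into one key per allele.
    """
    path = Path(path)
    with open(path, "rt") as fh:
        first = fh.readline()
    keys: set[VariantKey] = set()
    if first.startswith("##fileformat="):
        doc = read_vcf(path)
        for rec in doc.records:
            for alt in rec.alts:
                if alt.startswith("<") or alt in (".", "*"):
                    continue
                keys.add(VariantKey.make(rec.chrom, rec.pos, rec.ref, alt))
    else:
        with open(path, "rt") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                cols = line.split("\t")
                if len(cols) < 4:
                    raise ValueError(
                        f"{path}: line {lineno}: catalog rows need 4 columns "
                        "(chrom, pos, ref, alt)"
                    )
                keys.add(
                    VariantKey.make(cols[0], int(cols[1]), cols[2], cols[3])
                )
    return Catalog(name=name, keys=frozenset(keys), version_label=version_label)


def write_funnel_report(stats: FunnelStats, path: Union[str, Path]) -> None:
    """Plain-text funnel report with counts and per-stage percentages."""
    from .summarize import funnel_percentages

    pct = funnel_percentages(stats)
    lines = [
        "panel-of-normals build funnel",
        f"raw observations\t{stats.n_raw}",
        f"unique keys\t{stats.n_unique}",
        f"pass quality filter\t{stats.n_quality}",
        f"removed by SNP catalog\t{stats.n_removed_snp_catalog}"
        f"\t({_fmt(pct['snp_catalog_depleted_percent'])}%)",
        f"after SNP catalog\t{stats.n_post_snp_catalog}",
        f"removed by somatic catalog\t{stats.n_removed_somatic_catalog}"
        f"\t({_fmt(pct['somatic_catalog_depleted_percent'])}%)",
        f"final database size\t{stats.n_final}",
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def _fmt(value: Optional[float]) -> str:
    return "NA" if value is None else f"{value:.1f}"
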