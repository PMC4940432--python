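"""Text-level VCF 4.x reading/writing and allele-aware record normalization.

The central identity used throughout the package is the :class:`VariantKey`:
the tuple (chromosome, position, reference allele, alternate allele). All
matching — panel-of-normals membership, catalog depletion, tumor
subtraction — is exact on this key, never on position alone, so a novel
allele at a known polymorphic position is never swallowed by a catalog hit.

Records are kept column-verbatim: a document read from disk and written
back reproduces its data lines byte for byte. That property is load-bearing
for the subtraction tool, whose contract is to filter records, not to
re-serialize or re-annotate them.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, Union

logger = logging.getLogger(__name__)

__all__ = [
    "VariantKey",
    "Genotype",
    "SampleObservation",
    "VcfRecord",
    "VcfDocument",
    "VcfFormatError",
    "normalize_chrom",
    "read_vcf",
    "write_vcf",
    "normalize_record",
]


class VcfFormatError(ValueError):
    """Raised when a file is not parseable as VCF."""


def normalize_chrom(label: str) -> str:
    """Normalize a chromosome label: strip a leading ``chr`` (any case),
    map mitochondrial aliases (``M``, ``chrM``) to ``MT``.

    Idempotent: normalizing an already-normalized label is a no-op.
    """
    out = label
    if out[:3].lower() == "chr":
        out = out[3:]
    if out in ("M", "m"):
        out = "MT"
    return out


@dataclass(frozen=True, order=True)
class VariantKey:
    """Allele-aware variant identity (chrom, pos, ref, alt).

    ``pos`` is 1-based (VCF convention). ``alt`` is always a single allele:
    multi-allelic records are split into one key per alternate allele before
    any matching. Indels are carried as literal multi-base strings; no
    left-alignment or parsimony trimming is performed, so matching semantics
    are exactly those of the literal VCF fields.
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) is not a variant")
        if "," in self.alt:
            raise ValueError("alt must be a single allele, not comma-joined")

    @classmethod
    def make(cls, chrom: str, pos: int, ref: str, alt: str) -> "VariantKey":
        """Build a key with chromosome normalization applied."""
        return cls(normalize_chrom(chrom), pos, ref.upper(), alt.upper())


class Genotype(str, Enum):
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"


@dataclass(frozen=True)
class SampleObservation:
    """One sample carrying one alternate allele at one site.

    ``alt_depth`` is the read count supporting this alt allele (the AD
    FORMAT entry for the allele); ``None`` when the source record lacks
    per-allele depths.
    """

    key: VariantKey
    sample_id: str
    alt_depth: Optional[int]
    genotype: Genotype

    def __post_init__(self) -> None:
        if self.alt_depth is not None and self.alt_depth < 0:
            raise ValueError("alt_depth must be non-negative when known")

    @property
    def allele_dosage(self) -> int:
        """Copies of the alt allele implied by the genotype (het=1, hom=2)."""
        return 2 if self.genotype is Genotype.HOM_ALT else 1


@dataclass
class VcfRecord:
    """A raw VCF data line, split on tabs but otherwise verbatim.

    ``fields[0..7]`` are CHROM POS ID REF ALT QUAL FILTER INFO; ``fields[8]``
    (if present) is FORMAT and the rest are sample columns.
    """

    fields: list[str]

    @property
    def chrom(self) -> str:
        return self.fields[0]

    @property
    def pos(self) -> int:
        return int(self.fields[1])

    @property
    def ref(self) -> str:
        return self.fields[3]

    @property
    def alt_field(self) -> str:
        return self.fields[4]

    @property
    def alts(self) -> list[str]:
        return self.fields[4].split(",")

    @property
    def format_keys(self) -> list[str]:
        return self.fields[8].split(":") if len(self.fields) > 8 else []

    @property
    def sample_fields(self) -> list[str]:
        return self.fields[9:]

    def to_line(self) -> str:
        return "\t".join(self.fields)


@dataclass
class VcfDocument:
    """An ordered VCF: header lines plus raw records.

    Writing then re-reading yields identical keys, FORMAT fields and record
    order (byte-identical data lines).
    """

    header_lines: list[str]
    records: list[VcfRecord] = field(default_factory=list)

    @property
    def column_header(self) -> str:
        return self.header_lines[-1]

    @property
    def sample_names(self) -> list[str]:
        cols = self.column_header.lstrip("#").split("\t")
        return cols[9:] if len(cols) > 9 else []

    @property
    def n_records(self) -> int:
        return len(self.records)

    def with_header_line(self, line: str) -> "VcfDocument":
        """Copy of this document with ``line`` inserted before #CHROM."""
        return VcfDocument(
            header_lines=self.header_lines[:-1] + [line, self.header_lines[-1]],
            records=list(self.records),
        )

    def iter_observations(self) -> Iterator[SampleObservation]:
        for rec in self.records:
            yield from normalize_record(rec, self.sample_names)


_MANDATORY_COLUMNS = 8


def _open_text(path: Union[str, Path]):
    """Open plain or (b)gzipped text transparently."""
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_vcf(path: Union[str, Path]) -> VcfDocument:
    """Parse a VCF 4.x file into a :class:`VcfDocument`.

    Raises :class:`VcfFormatError` if the file does not start with a
    ``##fileformat=`` line, lacks a ``#CHROM`` column header, or contains a
    data line with fewer than the 8 mandatory columns or a non-integer POS
    (the error message names the offending line number).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    header_lines: list[str] = []
    records: list[VcfRecord] = []
    saw_column_header = False
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if lineno == 1 and not line.startswith("##fileformat="):
                raise VcfFormatError(
                    f"{path}: not a VCF file (first line must begin "
                    f"'##fileformat=', got {line[:40]!r})"
                )
            if line.startswith("##"):
                header_lines.append(line)
                continue
            if line.startswith("#"):
                header_lines.append(line)
                saw_column_header = True
                continue
            if not line:
                continue
            if not saw_column_header:
                raise VcfFormatError(f"{path}: data line {lineno} before #CHROM header")
            cols = line.split("\t")
            if len(cols) < _MANDATORY_COLUMNS:
                raise VcfFormatError(
                    f"{path}: line {lineno}: expected >= {_MANDATORY_COLUMNS} "
                    f"tab-separated columns, got {len(cols)}"
                )
            try:
                int(cols[1])
            except ValueError:
                raise VcfFormatError(
                    f"{path}: line {lineno}: POS is not an integer: {cols[1]!r}"
                ) from None
            records.append(VcfRecord(cols))
    if not saw_column_header:
        raise VcfFormatError(f"{path}: missing #CHROM column header line")
    return VcfDocument(header_lines=header_lines, records=records)


def write_vcf(doc: VcfDocument, path: Union[str, Path]) -> None:
    """Write a document as VCF text. Data lines are emitted verbatim."""
    if not doc.header_lines or not doc.header_lines[0].startswith("##fileformat="):
        raise VcfFormatError("document header must begin with ##fileformat=")
    path = Path(path)
    with open(path, "wt") as fh:
        for line in doc.header_lines:
            fh.write(line + "\n")
        for rec in doc.records:
            fh.write(rec.to_line() + "\n")


def _is_symbolic(alt: str) -> bool:
    return alt.startswith("<") or "[" in alt or "]" in alt or alt in (".", "*")


def _parse_gt_indices(gt: str) -> Optional[list[int]]:
    """Allele indices from a GT string; None when the call is missing."""
    if gt in (".", "./.", ".|."):
        return None
    out = []
    for tok in gt.replace("|", "/").split("/"):
        if tok == ".":
            continue
        try:
            out.append(int(tok))
        except ValueError:
            return None
    return out or None


def normalize_record(
    record: VcfRecord, sample_names: Sequence[str]
) -> list[SampleObservation]:
    """Decompose a raw record into per-(sample, alt-allele) observations.

    Multi-allelic ALT fields are split into biallelic keys; the chromosome
    label is normalized; each sample whose GT carries alt allele *i*
    contributes one observation for that allele, with ``alt_depth`` taken
    from its AD entry when AD is present (else unknown). Reference-only and
    missing genotypes contribute nothing. Symbolic alts (``<DEL>``,
    breakends, spanning deletions) are skipped with a logged warning.
    """
    observations: list[SampleObservation] = []
    alts = record.alts
    fmt = record.format_keys
    gt_idx = fmt.index("GT") if "GT" in fmt else None
    ad_idx = fmt.index("AD") if "AD" in fmt else None

    keys: dict[int, Optional[VariantKey]] = {}
    for i, alt in enumerate(alts, start=1):
        if _is_symbolic(alt) or _is_symbolic(record.ref):
            logger.warning(
                "skipping symbolic allele %s at %s:%s", alt, record.chrom, record.pos
            )
            keys[i] = None
            continue
        try:
            keys[i] = VariantKey.make(record.chrom, record.pos, record.ref, alt)
        except ValueError as exc:
            logger.warning(
                "skipping unnormalizable allele at %s:%s: %s",
                record.chrom, record.pos, exc,
            )
            keys[i] = None

    if gt_idx is None:
        return observations

    for sample_id, sample_field in zip(sample_names, record.sample_fields):
        parts = sample_field.split(":")
        if gt_idx >= len(parts):
            continue
        indices = _parse_gt_indices(parts[gt_idx])
        if indices is None:
            continue
        carried = sorted({i for i in indices if i >= 1})
        for i in carried:
            key = keys.get(i)
            if key is None:
                continue
            alt_depth: Optional[int] = None
            if ad_idx is not None and ad_idx < len(parts):
                ad_entries = parts[ad_idx].split(",")
                if i < len(ad_entries):
                    try:
                        alt_depth = int(ad_entries[i])
                    except ValueError:
                        alt_depth = None
            n_copies = sum(1 for j in indices if j == i)
            genotype = Genotype.HOM_ALT if n_copies >= 2 else Genotype.HET
            observations.append(
                SampleObservation(
                    key=key, sample_id=sample_id,
                    alt_depth=alt_depth, genotype=genotype,
                )
            )
    return observations


def make_document(
    sample_names: Sequence[str],
    records: Iterable[VcfRecord] = (),
    extra_header: Sequence[str] = (),
    source: str = "ponsub",
) -> VcfDocument:
    """Construct a minimal valid single- or multi-sample document."""
    columns = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
    if sample_names:
        columns += ["FORMAT", *sample_names]
    header = [
        "##fileformat=VCFv4.2",
        f"##source={source}",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        *extra_header,
        "\t".join(columns),
    ]
    return VcfDocument(header_lines=header, records=list(records))
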