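"""Allele-aware subtraction of panel-of-normals variants from tumor VCFs.

A tumor record is removed when its normalized (chrom, pos, ref, alt) key is
in the database. Multi-allelic records are handled per alt allele: only
matched alts are dropped, and the record itself is dropped only when every
alt matched — removing the whole record on a single-alt hit would
over-subtract genuine somatic alleles sharing a position with a germline
one. Retained records pass through with INFO/FILTER/FORMAT untouched; the
tool filters, it does not re-annotate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

from .pon import PoNDatabase
from .vcf_io import (
    VariantKey,
    VcfDocument,
    VcfRecord,
    read_vcf,
)

logger = logging.getLogger(__name__)

__all__ = ["SubtractionResult", "subtract", "batch_subtract", "write_summary_table"]

_PROVENANCE_PREFIX = "##ponsub_subtraction="


@dataclass
class SubtractionResult:
    """Outcome of subtracting one tumor VCF against the database.

    Counts are over biallelic keys (one per alt allele of each record), so
    a multi-allelic record contributes one unit per alt.
    Invariant: n_input = n_removed + n_retained.
    """

    retained: VcfDocument
    sample_label: str
    n_input: int
    n_removed: int
    n_retained: int
    removed_keys: frozenset[VariantKey] = frozenset()
    removed_records: list[VcfRecord] = field(default_factory=list)

    @property
    def percent_removed(self) -> float | None:
        if self.n_input == 0:
            return None
        return 100.0 * self.n_removed / self.n_input


def _record_keys(rec: VcfRecord) -> list[VariantKey | None]:
    """Normalized key per alt allele; None for unnormalizable alleles."""
    out: list[VariantKey | None] = []
    for alt in rec.alts:
        if alt.startswith("<") or "[" in alt or "]" in alt or alt in (".", "*"):
            out.append(None)
            continue
        try:
            out.append(VariantKey.make(rec.chrom, rec.pos, rec.ref, alt))
        except ValueError:
            out.append(None)
    return out


def subtract(
    tumor: VcfDocument,
    db: PoNDatabase,
    sample_label: str = "tumor",
    keep_removed: bool = False,
) -> SubtractionResult:
    """Remove database variants from a tumor document.

    Unnormalizable records (symbolic alleles and the like) are retained with
    a warning and excluded from key accounting. The output header carries
    one added provenance line recording the database size and cohort.
    Applying subtract twice with the same database removes nothing the
    second time.
    """
    db_keys = db.keys
    kept_records: list[VcfRecord] = []
    removed_records: list[VcfRecord] = []
    removed_keys: set[VariantKey] = set()
    n_input = n_removed = n_retained = 0

    for rec in tumor.records:
        keys = _record_keys(rec)
        real = [k for k in keys if k is not None]
        if not real:
            logger.warning(
                "retaining unnormalizable record at %s:%s",
                rec.chrom, rec.fields[1],
            )
            kept_records.append(rec)
            continue
        n_input += len(real)
        hits = [k for k in real if k in db_keys]
        misses = [k for k in real if k not in db_keys]
        n_removed += len(hits)
        n_retained += len(misses)
        removed_keys.update(hits)
        if not hits:
            kept_records.append(rec)
        elif not misses and len(real) == len(keys):
            removed_records.append(rec)
        else:
            # partial match: rewrite ALT with surviving alleles only
            surviving = [
                alt
                for alt, key in zip(rec.alts, keys)
                if key is None or key not in db_keys
            ]
            new_fields = list(rec.fields)
            new_fields[4] = ",".join(surviving)
            kept_records.append(VcfRecord(new_fields))

    provenance = (
        f"{_PROVENANCE_PREFIX}database_size={len(db)};"
        f"cohort_size={db.cohort_size};removed={n_removed}"
    )
    retained_doc = VcfDocument(
        header_lines=tumor.header_lines[:-1]
        + [provenance, tumor.header_lines[-1]],
        records=kept_records,
    )
    return SubtractionResult(
        retained=retained_doc,
        sample_label=sample_label,
        n_input=n_input,
        n_removed=n_removed,
        n_retained=n_retained,
        removed_keys=frozenset(removed_keys),
        removed_records=removed_records if keep_removed else [],
    )


def batch_subtract(
    tumors: Sequence[Union[VcfDocument, str, Path]],
    db: PoNDatabase,
) -> list[SubtractionResult]:
    """Subtract each tumor independently; unreadable files are reported and
    skipped, never aborting the batch."""
    results: list[SubtractionResult] = []
    for i, item in enumerate(tumors):
        if isinstance(item, (str, Path)):
            label = Path(item).name
            try:
                doc = read_vcf(item)
            except Exception as exc:  # report & continue per batch contract
                logger.error("skipping unreadable tumor %s: %s", item, exc)
                continue
        else:
            label, doc = f"tumor_{i + 1}", item
        results.append(subtract(doc, db, sample_label=label))
    return results


def write_summary_table(
    results: Iterable[SubtractionResult], path: Union[str, Path]
) -> None:
    """Tab-delimited per-sample summary plus a TOTAL row."""
    rows = ["sample\tn_input\tn_removed\tn_retained\tpercent_removed"]
    tot_in = tot_rm = tot_kept = 0
    for r in results:
        pct = "NA" if r.percent_removed is None else f"{r.percent_removed:.1f}"
        rows.append(
            f"{r.sample_label}\t{r.n_input}\t{r.n_removed}\t{r.n_retained}\t{pct}"
        )
        tot_in += r.n_input
        tot_rm += r.n_removed
        tot_kept += r.n_retained
    tot_pct = "NA" if tot_in == 0 else f"{100.0 * tot_rm / tot_in:.1f}"
    rows.append(f"TOTAL\t{tot_in}\t{tot_rm}\t{tot_kept}\t{tot_pct}")
    Path(path).write_text("\n".join(rows) + "\n")
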