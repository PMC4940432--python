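import pytest
from hypothesis import settings

from ponsub.vcf_io import VcfDocument, VcfRecord, make_document

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def record(chrom, pos, ref, alt, fmt="GT:AD", *samples):
    return VcfRecord(
        [chrom, str(pos), ".", ref, alt, "100", "PASS", ".", fmt, *samples]
    )


def single_sample_doc(sample_name, rows):
    """rows: iterable of (chrom, pos, ref, alt, gt, ad) with ad like '10,6' or None."""
    records = []
    for chrom, pos, ref, alt, gt, ad in rows:
        if ad is None:
            records.append(
                VcfRecord([chrom, str(pos), ".", ref, alt, "100", "PASS", ".",
                           "GT", gt])
            )
        else:
            records.append(record(chrom, pos, ref, alt, "GT:AD", f"{gt}:{ad}"))
    return make_document([sample_name], records)


@pytest.fixture
def three_record_vcf(tmp_path):
    doc = single_sample_doc(
        "S1",
        [
            ("1", 100, "A", "T", "0/1", "8,6"),
            ("chr2", 200, "G", "C", "1/1", "0,12"),
            ("chrM", 300, "T", "A", "0/1", "4,3"),
        ],
    )
    path = tmp_path / "three.vcf"
    from ponsub.vcf_io import write_vcf

    write_vcf(doc, path)
    return path
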