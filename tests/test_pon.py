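"""Cohort merge, quality filter, catalog depletion and persistence."""

import pytest

from ponsub.pon import (
    Catalog,
    CohortEntry,
    DatabaseFormatError,
    EmptyCohortError,
    FilterParams,
    PoNDatabase,
    apply_quality_filter,
    build_database,
    deplete_catalog,
    load_database,
    merge_cohort,
    read_catalog,
    save_database,
)
from ponsub.vcf_io import VariantKey

from conftest import single_sample_doc


def entry(chrom="1", pos=100, ref="A", alt="T", recurrence=1,
          max_alt_depth=None, alt_allele_count=None, carriers=None):
    if alt_allele_count is None:
        alt_allele_count = recurrence
    if carriers is None:
        carriers = frozenset(f"S{i}" for i in range(recurrence))
    return CohortEntry(
        key=VariantKey(chrom, pos, ref, alt),
        recurrence=recurrence,
        max_alt_depth=max_alt_depth,
        alt_allele_count=alt_allele_count,
        carrier_ids=frozenset(carriers),
    )


class TestMergeCohort:
    def test_recurrence_counts_distinct_samples(self):
        rows = [("1", 100, "A", "T", "0/1", "5,5")]
        docs = [single_sample_doc(f"S{i}", rows) for i in range(3)]
        docs += [single_sample_doc(f"S{i}", []) for i in range(3, 5)]
        cohort = merge_cohort(docs)
        e = cohort[VariantKey("1", 100, "A", "T")]
        assert e.recurrence == 3
        assert e.alt_allele_count == 3
        assert e.carrier_ids == frozenset({"S0", "S1", "S2"})

    def test_duplicate_line_counts_sample_once(self):
        rows = [("1", 100, "A", "T", "0/1", "5,3"),
                ("1", 100, "A", "T", "0/1", "5,7")]
        cohort = merge_cohort([single_sample_doc("S1", rows)])
        e = cohort[VariantKey("1", 100, "A", "T")]
        assert e.recurrence == 1
        assert e.max_alt_depth == 7  # deepest restatement wins

    def test_duplicate_sample_id_is_fatal(self):
        docs = [single_sample_doc("S1", []), single_sample_doc("S1", [])]
        with pytest.raises(ValueError, match="duplicate sample id"):
            merge_cohort(docs)

    def test_max_depth_over_carriers_and_unknowns(self):
        docs = [
            single_sample_doc("S1", [("1", 100, "A", "T", "0/1", "9,2")]),
            single_sample_doc("S2", [("1", 100, "A", "T", "0/1", None)]),
            single_sample_doc("S3", [("1", 100, "A", "T", "1/1", "0,6")]),
        ]
        e = merge_cohort(docs)[VariantKey("1", 100, "A", "T")]
        assert e.max_alt_depth == 6
        assert e.alt_allele_count == 1 + 1 + 2

    def test_all_unknown_depths(self):
        docs = [single_sample_doc("S1", [("1", 100, "A", "T", "0/1", None)])]
        e = merge_cohort(docs)[VariantKey("1", 100, "A", "T")]
        assert e.max_alt_depth is None

    def test_chrom_label_normalization_unifies_callers(self):
        docs = [
            single_sample_doc("S1", [("chr7", 100, "A", "T", "0/1", "5,5")]),
            single_sample_doc("S2", [("7", 100, "A", "T", "0/1", "5,5")]),
        ]
        cohort = merge_cohort(docs)
        assert len(cohort) == 1
        assert cohort[VariantKey("7", 100, "A", "T")].recurrence == 2

    def test_generated_cohort_matches_truth_table(self):
        from ponsub.simulate import CohortSpec, generate_cohort

        data = generate_cohort(CohortSpec(n_samples=10, n_sites=500, seed=7))
        cohort = merge_cohort(data.normals)
        assert len(cohort) == 500
        for site in data.truth.sites:
            e = cohort[site.key]
            assert e.recurrence == site.recurrence
            assert e.max_alt_depth == site.max_alt_depth
            assert e.alt_allele_count == site.alt_allele_count


class TestQualityFilter:
    @pytest.mark.parametrize(
        "depth,rec,expected",
        [
            (5, 1, True),    # depth clause alone
            (2, 4, True),    # recurrence rescue alone
            (4, 3, False),   # below both thresholds
            (5, 4, True),    # boundary overlap of the two clauses
            (None, 4, True), # unknown depth rescued by recurrence
            (None, 3, False),# unknown depth never satisfies depth clause
        ],
    )
    def test_predicate_boundaries(self, depth, rec, expected):
        e = entry(recurrence=rec, max_alt_depth=depth)
        passed, failed = apply_quality_filter({e.key: e})
        assert (e in passed) is expected
        assert (e in failed) is (not expected)

    def test_partition_is_exact(self):
        entries = [entry(pos=100 + i, recurrence=1 + i % 5,
                         max_alt_depth=i % 11) for i in range(50)]
        passed, failed = apply_quality_filter(entries)
        assert len(passed) + len(failed) == len(entries)
        assert not (set(id(e) for e in passed) & set(id(e) for e in failed))

    def test_matches_brute_force_oracle_on_grid(self):
        """Exhaustive (depth 0..10) x (recurrence 1..10) grid incl. 4 and 5."""
        params = FilterParams()
        for depth in list(range(11)) + [None]:
            for rec in range(1, 11):
                e = entry(pos=1000, recurrence=rec, max_alt_depth=depth,
                          alt_allele_count=rec)
                oracle = (depth is not None and depth >= 5) or rec >= 4
                passed, _ = apply_quality_filter([e], params)
                assert (len(passed) == 1) is oracle, (depth, rec)

    def test_custom_thresholds(self):
        params = FilterParams(min_alt_depth=3, min_recurrence=2)
        assert params.passes(entry(recurrence=1, max_alt_depth=3))
        assert params.passes(entry(recurrence=2, max_alt_depth=0))
        assert not params.passes(entry(recurrence=1, max_alt_depth=2))


class TestDepleteCatalog:
    def test_empty_catalog_is_identity(self):
        entries = [entry(pos=p) for p in (1, 2, 3)]
        retained, removed = deplete_catalog(entries, Catalog.empty("snp"))
        assert retained == entries and removed == []

    def test_matching_is_allele_aware(self):
        catalog = Catalog("snp", frozenset({VariantKey("5", 100, "A", "T")}))
        variant = entry(chrom="5", pos=100, ref="A", alt="G")
        retained, removed = deplete_catalog([variant], catalog)
        assert retained == [variant] and removed == []

    def test_planted_members_all_removed(self):
        from ponsub.simulate import CohortSpec, generate_cohort

        data = generate_cohort(
            CohortSpec(n_samples=5, n_sites=1000, seed=13,
                       frac_in_snp_catalog=0.3, frac_in_somatic_catalog=0.0)
        )
        cohort = merge_cohort(data.normals)
        retained, removed = deplete_catalog(cohort.values(), data.snp_catalog)
        assert len(removed) == 300
        assert {e.key for e in removed} == data.snp_catalog.keys

    def test_order_insensitive_membership(self):
        entries = [entry(pos=p) for p in range(1, 21)]
        cat_a = Catalog("a", frozenset(e.key for e in entries[:8]))
        cat_b = Catalog("b", frozenset(e.key for e in entries[5:12]))
        ab, _ = deplete_catalog(deplete_catalog(entries, cat_a)[0], cat_b)
        ba, _ = deplete_catalog(deplete_catalog(entries, cat_b)[0], cat_a)
        assert {e.key for e in ab} == {e.key for e in ba}


class TestBuildDatabase:
    def _planted_cohort(self):
        """20 pass-filter sites; 8 in SNP catalog, 2 of the rest somatic."""
        rows = [("1", 1000 + i, "A", "T", "0/1", "5,9") for i in range(20)]
        docs = [single_sample_doc("S1", rows)] + [
            single_sample_doc(f"S{i}", []) for i in range(2, 6)
        ]
        keys = [VariantKey("1", 1000 + i, "A", "T") for i in range(20)]
        snp = Catalog("snp", frozenset(keys[:8]), "snp-v1")
        som = Catalog("som", frozenset(keys[8:10]), "som-v1")
        return docs, snp, som

    def test_planted_funnel_arithmetic(self):
        docs, snp, som = self._planted_cohort()
        db, stats = build_database(docs, snp, som)
        assert stats.n_quality == 20
        assert stats.n_removed_snp_catalog == 8
        assert stats.n_removed_somatic_catalog == 2
        assert stats.n_final == len(db) == 10

    def test_empty_catalogs_keep_all_quality_variants(self):
        docs, _, _ = self._planted_cohort()
        db, stats = build_database(
            docs, Catalog.empty("snp"), Catalog.empty("som")
        )
        assert stats.n_final == stats.n_quality == len(db)

    def test_empty_cohort_is_an_error(self):
        docs = [single_sample_doc("S1", []), single_sample_doc("S2", [])]
        with pytest.raises(EmptyCohortError):
            build_database(docs, Catalog.empty("snp"), Catalog.empty("som"))

    def test_all_fail_filter_gives_empty_database(self):
        docs = [single_sample_doc("S1", [("1", 100, "A", "T", "0/1", "9,1")])]
        db, stats = build_database(
            docs, Catalog.empty("snp"), Catalog.empty("som")
        )
        assert len(db) == 0 and stats.n_unique == 1

    def test_determinism_and_input_order_independence(self):
        docs, snp, som = self._planted_cohort()
        db1, _ = build_database(docs, snp, som)
        db2, _ = build_database(list(reversed(docs)), snp, som)
        assert [e.key for e in db1.entries] == [e.key for e in db2.entries]
        assert db1.cohort_size == db2.cohort_size

    def test_provenance_records_params_and_catalogs(self):
        docs, snp, som = self._planted_cohort()
        db, _ = build_database(docs, snp, som,
                               FilterParams(min_alt_depth=6, min_recurrence=3))
        assert db.provenance["min_alt_depth"] == "6"
        assert db.provenance["snp_catalog"] == "snp-v1"


class TestPersistence:
    def _db(self, n=50):
        entries = sorted(
            (entry(chrom=str(1 + i % 22), pos=100 + i, recurrence=1 + i % 4,
                   max_alt_depth=(None if i % 7 == 0 else 5 + i % 9),
                   alt_allele_count=(1 + i % 4) + (i % 2 if i % 4 else 0))
             for i in range(n)),
            key=lambda e: e.key,
        )
        return PoNDatabase(entries=entries, cohort_size=62,
                           provenance={"min_alt_depth": "5"})

    def test_round_trip(self, tmp_path):
        db = self._db()
        path = tmp_path / "pon.db"
        save_database(db, path)
        loaded = load_database(path)
        assert loaded.cohort_size == db.cohort_size
        assert loaded.provenance == db.provenance
        assert [e.key for e in loaded.entries] == [e.key for e in db.entries]
        for a, b in zip(loaded.entries, db.entries):
            assert (a.recurrence, a.alt_allele_count, a.max_alt_depth) == (
                b.recurrence, b.alt_allele_count, b.max_alt_depth
            )
            assert a.carrier_ids is None  # identity not persisted

    def test_empty_database_round_trip(self, tmp_path):
        db = PoNDatabase(entries=[], cohort_size=5, provenance={})
        path = tmp_path / "empty.db"
        save_database(db, path)
        loaded = load_database(path)
        assert len(loaded) == 0 and loaded.cohort_size == 5

    def test_text_file_rejected(self, tmp_path):
        path = tmp_path / "not_a_db.txt"
        path.write_text("this is not a database\n")
        with pytest.raises(DatabaseFormatError):
            load_database(path)

    def test_sqlite_without_variants_table_rejected(self, tmp_path):
        import sqlite3

        path = tmp_path / "foreign.db"
        con = sqlite3.connect(path)
        con.execute("CREATE TABLE other (x)")
        con.commit()
        con.close()
        with pytest.raises(DatabaseFormatError, match="variants"):
            load_database(path)


class TestReadCatalog:
    def test_tsv_catalog(self, tmp_path):
        path = tmp_path / "cat.tsv"
        path.write_text("#chrom\tpos\tref\talt\nchr1\t100\tA\tT\n2\t200\tG\tC\n")
        cat = read_catalog(path, "snp")
        assert cat.keys == {VariantKey("1", 100, "A", "T"),
                            VariantKey("2", 200, "G", "C")}

    def test_vcf_catalog_splits_multiallelics(self, tmp_path):
        path = tmp_path / "cat.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "1\t100\trs1\tA\tT,G\t.\t.\t.\n"
        )
        cat = read_catalog(path, "snp")
        assert cat.keys == {VariantKey("1", 100, "A", "T"),
                            VariantKey("1", 100, "A", "G")}

    def test_short_row_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("1\t100\tA\n")
        with pytest.raises(ValueError, match="4 columns"):
            read_catalog(path, "snp")
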