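"""Count-table/FASTA/label I/O and the packaged 26-ASV signature table."""

import pytest

from refsig import (
    AsvTable,
    SyntheticConfig,
    generate_discovery,
    load_asd_signature,
    read_asv_table,
    read_signature_table,
    summarize_taxonomy,
    write_asv_table,
    write_signature_table,
)
from refsig.core_io import TAXONOMY_RANKS, TableValidationError

from conftest import write_cohort


class TestAsvTableIO:
    def test_round_trip_identity(self, toy_table, tmp_path):
        paths = write_cohort(toy_table, tmp_path)
        again = read_asv_table(*paths)
        assert again.equals(toy_table)
        assert again.counts.shape == (3, 4)
        # file order preserved
        assert again.sample_ids == ["s1", "s2", "s3"]
        assert again.asv_ids == toy_table.asv_ids

    def test_synthetic_cohort_round_trip(self, tmp_path):
        cfg = SyntheticConfig(n_case=20, n_control=20, n_asv=100, seed=1)
        table, _ = generate_discovery(cfg)
        paths = write_cohort(table, tmp_path, "synth")
        assert read_asv_table(*paths).equals(table)

    def test_negative_count_names_cell(self, toy_table, tmp_path):
        counts, fasta, labels = write_cohort(toy_table, tmp_path)
        text = counts.read_text().replace("\t3\t", "\t-1\t")
        counts.write_text(text)
        with pytest.raises(TableValidationError, match="s2.*asv1|asv1.*s2"):
            read_asv_table(counts, fasta, labels)

    def test_non_integer_count_rejected(self, toy_table, tmp_path):
        counts, fasta, labels = write_cohort(toy_table, tmp_path)
        counts.write_text(counts.read_text().replace("\t7\t", "\t7.5\t"))
        with pytest.raises(TableValidationError, match="non-integer"):
            read_asv_table(counts, fasta, labels)

    def test_missing_sequence_names_asv(self, toy_table, tmp_path):
        counts, fasta, labels = write_cohort(toy_table, tmp_path)
        records = fasta.read_text().split(">")
        fasta.write_text(">" + ">".join(r for r in records if r and not r.startswith("asv2")))
        with pytest.raises(TableValidationError, match="asv2"):
            read_asv_table(counts, fasta, labels)

    def test_label_aliases_case_insensitive(self, toy_table, tmp_path):
        counts, fasta, labels = write_cohort(toy_table, tmp_path)
        labels.write_text("sample_id\tlabel\ns1\tASD\ns2\tNT\ns3\t1\n")
        table = read_asv_table(counts, fasta, labels)
        assert table.labels == {"s1": "case", "s2": "control", "s3": "case"}

    def test_unknown_label_fatal(self, toy_table, tmp_path):
        counts, fasta, labels = write_cohort(toy_table, tmp_path)
        labels.write_text("sample_id\tlabel\ns1\tcase\ns2\tmaybe\ns3\tcase\n")
        with pytest.raises(TableValidationError, match="maybe"):
            read_asv_table(counts, fasta, labels)

    def test_transpose_dialect(self, toy_table, tmp_path):
        counts, fasta, labels = write_cohort(toy_table, tmp_path)
        frame = toy_table.counts_frame().T
        tcounts = tmp_path / "transposed.tsv"
        frame.to_csv(tcounts, sep="\t", index_label="asv_id")
        assert read_asv_table(tcounts, fasta, labels, transpose=True).equals(toy_table)

    def test_short_sequence_rejected(self, toy_table):
        seqs = dict(toy_table.sequences)
        seqs[toy_table.asv_ids[0]] = "ACGT" * 5  # 20 nt
        with pytest.raises(TableValidationError, match="minimum"):
            AsvTable(
                sample_ids=toy_table.sample_ids,
                asv_ids=toy_table.asv_ids,
                counts=toy_table.counts,
                sequences=seqs,
                labels=toy_table.labels,
            )


class TestSignatureTable:
    def test_packaged_signature_has_26_records(self):
        sig = load_asd_signature()
        assert len(sig) == 26
        assert [r.index for r in sig.records] == list(range(1, 27))
        assert all(r.sequence is None for r in sig.records)

    def test_fully_unassigned_and_domain_only_rows(self):
        sig = load_asd_signature()
        row21 = sig.records[20]
        assert all(row21.taxonomy[r] is None for r in TAXONOMY_RANKS)
        assert row21.direction == "ASD increased"
        row25 = sig.records[24]
        assert row25.taxonomy["domain"] == "Bacteria"
        assert all(row25.taxonomy[r] is None for r in TAXONOMY_RANKS[1:])

    def test_presence_totals_per_cohort(self):
        counts = load_asd_signature().presence_counts()
        assert counts == {"PRJNA578223": 20, "PRJNA589343": 22}

    def test_signature_round_trip(self, tmp_path):
        sig = load_asd_signature()
        path = tmp_path / "sig.tsv"
        write_signature_table(sig, path)
        again = read_signature_table(path)
        assert len(again) == 26
        for a, b in zip(sig.records, again.records):
            assert (a.index, a.taxonomy, a.direction, a.presence) == (
                b.index,
                b.taxonomy,
                b.direction,
                b.presence,
            )

    def test_empty_file_is_no_records(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        with pytest.raises(TableValidationError, match="no records"):
            read_signature_table(path)

    def test_duplicate_index_fatal(self, tmp_path):
        sig = load_asd_signature()
        path = tmp_path / "sig.tsv"
        write_signature_table(sig, path)
        lines = path.read_text().splitlines()
        lines[2] = "1" + lines[2][len("2"):]
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(TableValidationError, match="duplicate|consecutive"):
            read_signature_table(path)

    def test_unknown_direction_fatal(self, tmp_path):
        sig = load_asd_signature()
        path = tmp_path / "sig.tsv"
        write_signature_table(sig, path)
        path.write_text(path.read_text().replace("ASD increased", "sideways", 1))
        with pytest.raises(TableValidationError, match="direction"):
            read_signature_table(path)

    def test_taxonomy_prefix_consistency_enforced(self, tmp_path):
        sig = load_asd_signature()
        path = tmp_path / "sig.tsv"
        write_signature_table(sig, path)
        # name a genus below an unassigned family on row 1
        lines = path.read_text().splitlines()
        parts = lines[1].split("\t")
        genus_col = lines[0].split("\t").index("genus")
        family_col = lines[0].split("\t").index("family")
        parts[family_col], parts[genus_col] = "NA", "Escherichia"
        lines[1] = "\t".join(parts)
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(TableValidationError, match="unassigned"):
            read_signature_table(path)


class TestSummarizeTaxonomy:
    def test_phylum_counts_match_published_signature(self):
        counts = summarize_taxonomy(load_asd_signature(), "phylum")
        assert counts == {
            "Firmicutes": 17,
            "Proteobacteria": 3,
            "Bacteroidota": 2,
            "Actinobacteria": 2,
            "unassigned": 2,
        }

    def test_family_counts_match_published_signature(self):
        counts = summarize_taxonomy(load_asd_signature(), "family")
        assert counts["Lachnospiraceae"] == 7
        assert counts["Clostridiaceae"] == 6
        assert counts["Enterobacteriaceae"] == 3
        assert counts["Erysipelatoclostridiaceae"] == 2
        assert counts["unassigned"] == 2
        singletons = [k for k, v in counts.items() if v == 1]
        assert len(singletons) == 6

    @pytest.mark.parametrize("rank", TAXONOMY_RANKS)
    def test_counts_conserve_record_total(self, rank):
        sig = load_asd_signature()
        assert sum(summarize_taxonomy(sig, rank).values()) == len(sig)

    def test_single_record_table(self):
        sig = load_asd_signature()
        from refsig.core_io import SignatureRecord, SignatureTable

        rec = sig.records[0]
        one = SignatureTable(records=[SignatureRecord(1, rec.taxonomy, rec.direction, {})])
        for rank in TAXONOMY_RANKS:
            assert sum(summarize_taxonomy(one, rank).values()) == 1

    def test_bad_rank_rejected(self):
        with pytest.raises(ValueError, match="rank"):
            summarize_taxonomy(load_asd_signature(), "kingdom")
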