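"""Library assembly: merge, dereplication, species filter, trimming, length filter."""

import datetime as dt
import random

import pytest

from barcodeqc.builder import (
    dereplicate_by_accession,
    filter_min_length,
    filter_species_level,
    is_species_level,
    merge_sources,
    trim_to_reference,
)
from barcodeqc.records import BarcodeRecord, ReferenceLibrary


def rec(rid, label="Longitarsus pratensis", seq="ACGT" * 100, acc=None, date=None,
        source="genbank"):
    return BarcodeRecord(
        record_id=rid, species_label=label, sequence=seq, accession=acc,
        updated_date=date, source=source,
    )


class TestMerge:
    def test_concatenation_preserves_counts_and_sources(self):
        a = ReferenceLibrary([rec(f"a{i}", source="genbank") for i in range(3)])
        b = ReferenceLibrary([rec(f"b{i}", source="bold") for i in range(2)])
        merged = merge_sources([a, b])
        assert len(merged) == 5
        assert [r.source for r in merged] == ["genbank"] * 3 + ["bold"] * 2

    def test_single_library_identity(self):
        a = ReferenceLibrary([rec("a1"), rec("a2")])
        merged = merge_sources([a])
        assert merged.ids == a.ids

    def test_clashing_record_id_names_the_clash(self):
        a = ReferenceLibrary([rec("dup")])
        b = ReferenceLibrary([rec("dup")])
        with pytest.raises(ValueError, match="dup"):
            merge_sources([a, b])


class TestDereplication:
    def test_same_accession_same_label_collapses(self):
        lib = ReferenceLibrary([rec("r1", acc="MK1"), rec("r2", acc="MK1")])
        out, conflicts = dereplicate_by_accession(lib)
        assert len(out) == 1 and not conflicts
        assert out.filter_log[-1] == ("dereplicate_by_accession", 1)

    def test_conflicting_labels_keep_more_recent_name(self):
        lib = ReferenceLibrary(
            [
                rec("r1", label="Longitarsus x", acc="MK1", date=dt.date(2018, 1, 1)),
                rec("r2", label="Longitarsus y", acc="MK1", date=dt.date(2019, 6, 1)),
            ]
        )
        out, conflicts = dereplicate_by_accession(lib)
        assert len(out) == 1 and not conflicts
        assert out.records[0].species_label == "Longitarsus y"

    def test_undated_conflict_is_flagged_first_label_kept(self):
        lib = ReferenceLibrary(
            [rec("r1", label="Longitarsus x", acc="MK1"),
             rec("r2", label="Longitarsus y", acc="MK1")]
        )
        out, conflicts = dereplicate_by_accession(lib)
        assert out.records[0].species_label == "Longitarsus x"
        assert conflicts and conflicts[0]["accession"] == "MK1"

    def test_distinct_accessions_identity(self):
        lib = ReferenceLibrary([rec("r1", acc="A1"), rec("r2", acc="A2"), rec("r3")])
        out, _ = dereplicate_by_accession(lib)
        assert out.ids == lib.ids

    def test_order_independent_result_set_with_unique_dates(self):
        records = [
            rec("r1", label="Longitarsus x", acc="MK1", date=dt.date(2018, 1, 1)),
            rec("r2", label="Longitarsus y", acc="MK1", date=dt.date(2019, 1, 1)),
            rec("r3", label="Longitarsus z", acc="MK2", date=dt.date(2017, 1, 1)),
        ]
        baseline = None
        for perm_seed in range(4):
            shuffled = records.copy()
            random.Random(perm_seed).shuffle(shuffled)
            out, _ = dereplicate_by_accession(ReferenceLibrary(shuffled))
            got = {(r.accession, r.species_label) for r in out}
            baseline = baseline or got
            assert got == baseline


class TestSpeciesFilter:
    @pytest.mark.parametrize(
        "label,kept",
        [
            ("Longitarsus sp.", False),
            ("Longitarsus sp", False),
            ("Longitarsus cf. pratensis", False),
            ("Longitarsus aff. anchusae", False),
            ("Longitarsus nr. echii", False),
            ("Longitarsus", False),  # bare genus
            ("Longitarsus pratensis", True),
            ("Longitarsus ochroleucus lindbergi", True),  # subspecies retained
        ],
    )
    def test_open_nomenclature_patterns(self, label, kept):
        assert is_species_level(label) is kept
        lib = ReferenceLibrary([rec("r1", label=label)])
        assert len(filter_species_level(lib)) == (1 if kept else 0)

    def test_idempotent(self):
        lib = ReferenceLibrary([rec("r1"), rec("r2", label="Longitarsus sp.")])
        once = filter_species_level(lib)
        twice = filter_species_level(once)
        assert len(twice) == len(once) == 1
        assert twice.filter_log[-1] == ("filter_species_level", 0)


class TestTrim:
    REF = ("ATGGCACTTAGCCTTAATCGAGCTGAATTAGGAACTCCAGGATCATTAATTGGTGATGATCAAATTTATA"
           "ATGTAATTGTTACTGCCCATGCTTTTATTATAATTTTCTTTATAGTTATACCTATTATAATTGGAGGATT"
           "TGGAAATTGATTAGTTCCTTTAATATTAGGAGCCCC")  # 176 bp

    def test_flanks_removed(self):
        flank = "GGGGGTTTTTCCCCCAAAAA"
        lib = ReferenceLibrary([rec("r1", seq=flank + self.REF + flank)])
        result = trim_to_reference(lib, rec("ref", seq=self.REF))
        assert result.library.alignment_length == len(self.REF)
        assert result.library.records[0].sequence == self.REF

    def test_partial_coverage_is_padded(self):
        lib = ReferenceLibrary([rec("r1", seq=self.REF[50:150])])
        result = trim_to_reference(lib, rec("ref", seq=self.REF))
        out = result.library.records[0].sequence
        assert len(out) == len(self.REF)
        assert out[:50] == "-" * 50
        assert out[50:150] == self.REF[50:150]
        assert out[150:] == "-" * (len(self.REF) - 150)

    def test_insertion_relative_to_reference_dropped(self):
        with_insert = self.REF[:80] + "AAAAAAAA" + self.REF[80:]
        lib = ReferenceLibrary([rec("r1", seq=with_insert)])
        result = trim_to_reference(lib, rec("ref", seq=self.REF))
        assert result.library.records[0].sequence == self.REF

    def test_shuffled_sequence_is_unmappable(self):
        shuffled = list(self.REF)
        random.Random(0).shuffle(shuffled)
        lib = ReferenceLibrary([rec("r1", seq="".join(shuffled)), rec("r2", seq=self.REF)])
        result = trim_to_reference(lib, rec("ref", seq=self.REF))
        assert result.unmappable == ["r1"]
        assert result.library.ids == ["r2"]

    def test_gapped_reference_rejected(self):
        lib = ReferenceLibrary([rec("r1", seq=self.REF)])
        with pytest.raises(ValueError):
            trim_to_reference(lib, rec("ref", seq=self.REF[:10] + "-" + self.REF[10:]))


class TestLengthFilter:
    def seq_with_informative(self, n):
        return "A" * n + "N" * 10 + "-" * 40

    def test_strict_boundary_at_300(self):
        lib = ReferenceLibrary(
            [rec("short", seq=self.seq_with_informative(299)),
             rec("exact", seq=self.seq_with_informative(300))]
        )
        out = filter_min_length(lib, 300)
        assert out.ids == ["exact"]

    def test_empty_library(self):
        out = filter_min_length(ReferenceLibrary([]), 300)
        assert len(out) == 0

    def test_idempotent(self):
        lib = ReferenceLibrary([rec("r1", seq=self.seq_with_informative(350))])
        once = filter_min_length(lib, 300)
        twice = filter_min_length(once, 300)
        assert twice.filter_log[-1][1] == 0


def test_count_conservation_across_full_build():
    records = [
        rec("r1", acc="A1"),
        rec("r2", acc="A1"),  # duplicate accession
        rec("r3", label="Longitarsus sp."),  # not species level
        rec("r4", seq="A" * 200 + "N" * 200),  # too short after filter
        rec("r5"),
    ]
    lib = ReferenceLibrary(records)
    lib, _ = dereplicate_by_accession(lib)
    lib = filter_species_level(lib)
    lib = filter_min_length(lib, 300)
    removed = sum(n for _, n in lib.filter_log)
    assert len(records) == len(lib) + removed
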