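"""Type registry loading, listing, export, and round-tripping."""

import io

import pytest

from bmctyper import (default_registry, export_type, list_types, load_registry,
                      read_multifasta, save_registry)
from bmctyper.errors import FormatError, RegistryError
from bmctyper.registry import profile_stats
from bmctyper.simulate import make_registry


class TestDefaultRegistry:
    def test_enumerates_68_distinct_types(self):
        reg = default_registry()
        assert len(reg) == 68
        assert len(set(reg.entries)) == 68

    def test_every_entry_has_example_fingerprint(self):
        reg = default_registry()
        for entry in reg.entries.values():
            assert entry.example_fingerprints

    def test_known_type_ids_present(self):
        reg = default_registry()
        for tid in ("SPU1", "SPU4", "SPU5", "SPU6", "ACI", "EUT2D",
                    "GRM4", "PDU1A", "PDU1B"):
            assert tid in reg


class TestListTypes:
    def test_substring_filter_case_insensitive(self):
        reg = default_registry()
        spu = list_types(reg, "spu")
        assert [e.type_id for e in spu] == [f"SPU{i}" for i in range(1, 8)]

    def test_empty_filter_returns_all_sorted(self):
        reg = default_registry()
        ids = [e.type_id for e in list_types(reg)]
        assert len(ids) == 68
        assert ids == sorted(ids)

    def test_no_match_is_empty(self):
        assert list_types(default_registry(), "zzz") == []


class TestLoadSave:
    def test_minimal_registry(self):
        text = ("# bmctyper type registry v1\n"
                "T1\tdesc\tH_a,P_b\tH_a,P_b\t\n")
        reg = load_registry(text)
        assert len(reg) == 1
        assert reg.entries["T1"].component_inventory == ["H_a", "P_b"]

    def test_duplicate_type_rejected(self):
        text = ("# bmctyper type registry v1\n"
                "SPU1\td\tH_a\tH_a\t\n"
                "SPU1\td\tH_a\tH_a\t\n")
        with pytest.raises(RegistryError, match="duplicate"):
            load_registry(text)

    def test_entry_without_fingerprint_rejected(self):
        text = "# bmctyper type registry v1\nT1\td\tH_a\t\t\n"
        with pytest.raises(RegistryError, match="no example fingerprint"):
            load_registry(text)

    def test_bad_magic_rejected(self):
        with pytest.raises(FormatError, match="magic"):
            load_registry("T1\td\tH_a\tH_a\t\n")

    def test_round_trip_identity(self, small_world):
        reg = make_registry(small_world, include_sequences=True)
        buf = io.StringIO()
        save_registry(reg, buf)
        reg2 = load_registry(buf.getvalue())
        assert set(reg2.entries) == set(reg.entries)
        for tid, e in reg.entries.items():
            e2 = reg2.entries[tid]
            assert [f.labels for f in e2.example_fingerprints] == \
                [f.labels for f in e.example_fingerprints]
            assert e2.sequences == e.sequences
            assert e2.component_inventory == e.component_inventory


class TestExportType:
    def test_export_round_trips_through_fasta(self, small_world):
        reg = make_registry(small_world, include_sequences=True)
        tid = small_world.types[0]
        fasta, fp_text = export_type(reg, tid)
        records = read_multifasta(fasta)
        assert len(records) == len(reg.entries[tid].sequences)
        for rec in records:
            assert rec.seq == reg.entries[tid].sequences[rec.id]
        assert fp_text.strip()

    def test_unknown_type_rejected(self, small_world):
        reg = make_registry(small_world)
        with pytest.raises(RegistryError, match="unknown"):
            export_type(reg, "NOPE")

    def test_type_without_sequences_rejected(self, small_world):
        reg = make_registry(small_world, include_sequences=False)
        with pytest.raises(RegistryError, match="no sequences"):
            export_type(reg, small_world.types[0])


def test_profile_stats_summary():
    stats = profile_stats({"a": "MKDEEDK", "b": "MKRRKRK"})
    assert stats["count"] == 2
    assert stats["length_min"] == stats["length_max"] == 7
    # acidic sequence has lower pI than basic one
    assert stats["pi_min"] < 7 < stats["pi_max"]
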