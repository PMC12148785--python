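import pytest

from planwatch import planlib, synthgen
from planwatch.exceptions import VersioningError
from planwatch.planlib import (
    LibraryFilter, PlanRecord, Privilege, append_record, filter_similar,
    latest_only, load_library, parse_preferences, pseudonymize, write_library,
)


def record(user="userA", plan_id="p1", ts="2024-01-01T08:00:00", protocol="FAST_FORWARD",
           laterality="RIGHT", technique="VMAT", boost=False, mods=frozenset(),
           metrics=None):
    return PlanRecord(
        timestamp=ts, user=user, patient_key=pseudonymize(plan_id), plan_id=plan_id,
        protocol=protocol, laterality=laterality, has_boost=boost, has_nodes=False,
        breast_modifier="NONE", technique=technique, technique_modifiers=mods,
        bolus="NONE", mu_sum=400.0, bw_score=90,
        metrics=metrics if metrics is not None else {"LUNG_IPSI:V16Gy[%]": 12.5},
    )


class TestAppendLoad:
    def test_append_to_empty(self, tmp_path):
        path = str(tmp_path / "lib.csv")
        assert append_record(path, record()) == (1, 1)

    def test_second_user_counts(self, tmp_path):
        path = str(tmp_path / "lib.csv")
        append_record(path, record(user="userA"))
        own, total = append_record(path, record(user="userB", plan_id="p2",
                                                ts="2024-01-01T09:00:00"))
        assert (own, total) == (1, 2)

    def test_header_mismatch_is_versioning_error(self, tmp_path):
        path = str(tmp_path / "lib.csv")
        append_record(path, record())
        bad = record(metrics={"LUNG_IPSI:V16Gy[%]": 12.5, "NEW:V1Gy[%]": 1.0})
        with pytest.raises(VersioningError, match="header mismatch"):
            append_record(path, bad)

    def test_roundtrip_field_equality(self, tmp_path):
        path = str(tmp_path / "lib.csv")
        original = record(mods=frozenset({"BH", "TANG"}),
                          metrics={"LUNG_IPSI:V16Gy[%]": 12.5, "HEART:Dmean[Gy]": None})
        append_record(path, original)
        back = load_library(path)[0]
        assert back == original

    def test_privilege_scoping(self, tmp_path):
        path = str(tmp_path / "lib.csv")
        records = [
            record(user="userA" if i < 4 else "userB", plan_id=f"p{i}",
                   ts=f"2024-01-01T0{i}:00:00")
            for i in range(10)
        ]
        write_library(path, records)
        assert len(load_library(path, Privilege.OWN_ONLY, "userA")) == 4
        assert len(load_library(path, Privilege.ALL)) == 10

    def test_header_only_file(self, tmp_path):
        path = str(tmp_path / "lib.csv")
        write_library(path, [record()])
        lines = open(path).readlines()
        open(path, "w").writelines(lines[:2])
        assert load_library(path) == []

    def test_missing_schema_line(self, tmp_path):
        path = tmp_path / "lib.csv"
        path.write_text("timestamp,user\n")
        with pytest.raises(VersioningError, match="schema"):
            load_library(str(path))

    def test_malformed_rows_skipped(self, tmp_path, caplog):
        path = str(tmp_path / "lib.csv")
        append_record(path, record())
        with open(path, "a") as fh:
            fh.write("garbage,row\n")
        with caplog.at_level("WARNING"):
            records = load_library(path)
        assert len(records) == 1
        assert any("malformed" in m for m in caplog.messages)


class TestFilterSimilar:
    def build(self):
        return [
            record(plan_id="a", ts="2024-01-01T08:00:00"),
            record(plan_id="b", ts="2024-01-01T07:00:00", boost=True),
            record(plan_id="c", ts="2024-01-01T09:00:00", mods=frozenset({"BH"})),
            record(plan_id="d", ts="2024-01-01T06:00:00", laterality="LEFT"),
            record(plan_id="e", ts="2024-01-01T05:00:00", technique="3DCRT"),
            record(plan_id="f", ts="2024-01-01T04:00:00", protocol="FAST"),
        ]

    def test_cohort_filter(self):
        # right-sided VMAT, boost or not, no breath-hold
        f = LibraryFilter(
            protocol="FAST_FORWARD", laterality="RIGHT", technique="VMAT",
            forbid_modifiers=frozenset({"BH"}),
        )
        got = filter_similar(self.build(), f)
        assert [r.plan_id for r in got] == ["b", "a"]  # timestamp ascending

    def test_protocol_only(self):
        got = filter_similar(self.build(), LibraryFilter(protocol="FAST_FORWARD"))
        assert len(got) == 5

    def test_contradictory_filter_empty(self):
        f = LibraryFilter(
            protocol="FAST_FORWARD",
            require_modifiers=frozenset({"BH"}), forbid_modifiers=frozenset({"BH"}),
        )
        assert filter_similar(self.build(), f) == []

    def test_subset_property(self):
        base = LibraryFilter(protocol="FAST_FORWARD", laterality="RIGHT")
        narrower = LibraryFilter(protocol="FAST_FORWARD", laterality="RIGHT",
                                 technique="VMAT")
        records = self.build()
        wide = {r.plan_id for r in filter_similar(records, base)}
        narrow = {r.plan_id for r in filter_similar(records, narrower)}
        assert narrow <= wide


class TestHelpers:
    def test_latest_only(self):
        records = [
            record(plan_id="a", ts="2024-01-01T08:00:00"),
            record(plan_id="a", ts="2024-01-02T08:00:00"),
            record(plan_id="b", ts="2024-01-01T09:00:00"),
        ]
        got = latest_only(records)
        assert len(got) == 2
        assert {r.timestamp for r in got if r.plan_id == "a"} == {"2024-01-02T08:00:00"}

    def test_pseudonymize_is_stable_and_opaque(self):
        assert pseudonymize("PAT123") == pseudonymize("PAT123")
        assert "PAT123" not in pseudonymize("PAT123")

    def test_parse_preferences(self):
        text = """
        export_drawer = /data/exports   # drawer
        privilege = OWN_ONLY
        user = alice
        [sanity]
        max_isocenters = 2
        """
        prefs = parse_preferences(text)
        assert prefs["privilege"] == "OWN_ONLY"
        assert prefs["user"] == "alice"
        assert "max_isocenters" not in prefs


def test_make_library_roundtrips(tmp_path):
    spec = synthgen.LibrarySpec(
        n=30, seed=5, users=[("a", 0.4), ("b", 0.6)],
        metrics={"LUNG_IPSI:V16Gy[%]": synthgen.MetricDist("normal", mu=12, sigma=3)},
    )
    path = synthgen.make_library(spec, str(tmp_path / "lib.csv"))
    records = load_library(path)
    assert len(records) == 30
    assert all(r.metrics["LUNG_IPSI:V16Gy[%]"] is not None for r in records)
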