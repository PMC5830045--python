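"""Container bookkeeping: creation, insertion, removal, metadata, summaries."""

import random

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ammlib import (
    AmLibrary,
    DuplicateKeyError,
    DuplicateNameError,
    InvalidSelectorError,
    MetadataMap,
    NotFoundError,
    OpaquePayload,
    create_library,
    describe,
    edit_info,
    get_record,
    insert_records,
    list_names,
    make_record,
    record_meta,
    remove_record,
    sanitize_name,
    summarize,
)

pytestmark = pytest.mark.filterwarnings("error")


def _plant_frame():
    return pd.DataFrame({"weight": [4.17, 5.58], "group": ["Ctl", "Ctl"]})


class TestCreateAndDescribe:
    def test_fresh_library_layout(self):
        lib = create_library(
            "This AM Model Library stores models and data.",
            {"owner": "me", "email": "me@somewhere.com"})
        assert describe(lib) == "This AM Model Library stores models and data."
        assert list(lib.info.keys()) == ["owner", "email", "date.created"]
        assert list_names(lib, "model") == []
        assert list_names(lib, "data") == []
        text = str(lib)
        assert "There are no models" in text
        assert "There are no datasets" in text

    def test_empty_creation_has_only_timestamp(self):
        lib = create_library("", {})
        assert describe(lib) == ""
        assert list(lib.info.keys()) == ["date.created"]

    def test_duplicate_info_keys_rejected(self):
        with pytest.raises(DuplicateKeyError):
            create_library("x", [("owner", "a"), ("owner", "b")])

    def test_description_write_read_identity(self):
        lib = create_library("initial")
        assert describe(lib, "updated text") == "updated text"
        assert describe(lib) == "updated text"
        assert describe(lib, "") == ""  # empty string, not a null

    @given(st.text(max_size=50),
           st.dictionaries(st.text(min_size=1, max_size=10).filter(
               lambda k: k != "date.created"),
               st.text(max_size=30), max_size=5))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_summary_reflects_creation_arguments(self, desc, info):
        lib = create_library(desc, info)
        summary = summarize(lib)
        assert summary.description == desc
        for key, value in info.items():
            assert summary.info[key] == value


class TestInfo:
    @pytest.fixture
    def lib(self):
        return create_library("d", {"owner": "me", "email": "me@somewhere.com"})

    def test_select_single_key(self, lib):
        assert edit_info(lib, select_key="owner").to_dict() == {"owner": "me"}

    def test_upsert_and_null_delete(self, lib):
        result = edit_info(lib, {"date.created": None, "owner": "Me",
                                 "organization": "My Organization"})
        assert result.to_dict() == {"owner": "Me", "email": "me@somewhere.com",
                                    "organization": "My Organization"}
        assert "date.created" not in lib.info

    def test_empty_update_is_noop(self, lib):
        before = lib.info.to_dict()
        assert edit_info(lib, {}).to_dict() == before

    def test_missing_select_key_names_it(self, lib):
        with pytest.raises(NotFoundError, match="nothere"):
            edit_info(lib, select_key="nothere")


class TestMakeRecord:
    def test_tabular_detection_and_timestamp(self):
        rec = make_record("data", _plant_frame(),
                          {"comment": "Plant dataset from the lm helpfile.",
                           "taxa": "plants"})
        assert rec.payload_class == "DataFrame"
        assert rec.origin_package is None
        assert rec.shape() == (2, 2)
        assert list(rec.metadata.keys()) == ["comment", "taxa", "date"]

    def test_minimal_record_gets_timestamp_only(self):
        rec = make_record("model", object(), {})
        assert list(rec.metadata.keys()) == ["date"]

    def test_user_supplied_date_wins(self):
        rec = make_record("data", {}, {"date": "2001-01-01 00:00:00"})
        assert rec.metadata["date"] == "2001-01-01 00:00:00"

    def test_metadata_copy_workflow(self):
        src = make_record("data", _plant_frame(), {"comment": "c", "taxa": "t"})
        dup = make_record("data", _plant_frame(), src.metadata)
        assert dup.metadata == src.metadata

    def test_payload_isolated_from_caller(self):
        frame = _plant_frame()
        rec = make_record("data", frame, {})
        frame.loc[0, "weight"] = 99.0
        assert rec.payload.loc[0, "weight"] == 4.17

    def test_self_declared_origin(self):
        payload = OpaquePayload.build("unmarkedFrameOccu", "unmarked")
        rec = make_record("data", payload, {})
        assert rec.payload_class == "unmarkedFrameOccu"
        assert rec.origin_package == "unmarked"
        assert rec.shape() is None

    def test_bad_role_rejected(self):
        with pytest.raises(ValueError):
            make_record("dataset", {}, {})


class TestInsertRemoveList:
    def test_insert_and_listing(self):
        lib = create_library()
        insert_records(lib, data={"plant.data": make_record(
            "data", pd.concat([_plant_frame()] * 10, ignore_index=True), {})})
        summary = summarize(lib)
        assert summary.data_rows == [{
            "index": 1, "name": "plant.data", "payload_class": "DataFrame",
            "nrows": 20, "ncols": 2, "origin_package": None}]

    def test_duplicate_name_rejected(self):
        lib = create_library()
        insert_records(lib, data={"d": make_record("data", {}, {})})
        with pytest.raises(DuplicateNameError):
            insert_records(lib, data={"d": make_record("data", {}, {})})

    def test_unnamed_record_rejected(self):
        with pytest.raises(InvalidSelectorError):
            create_library().insert(data={"": make_record("data", {}, {})})

    def test_empty_insert_is_noop(self):
        lib = create_library()
        insert_records(lib)
        assert list_names(lib, "data") == []

    def test_name_sanitization(self):
        lib = create_library()
        lib.insert(data={"2 bad name!": make_record("data", {}, {})})
        assert list_names(lib, "data") == ["X2.bad.name."]

    def test_remove_by_index_shifts_indices(self):
        lib = create_library()
        for name in ["plant.data", "updated.plant.data", "apple.data",
                     "sim.data", "frog.data"]:
            lib.insert(data={name: make_record("data", {}, {})})
        remove_record(lib, "data", 4)
        assert list_names(lib, "data") == [
            "plant.data", "updated.plant.data", "apple.data", "frog.data"]
        remove_record(lib, "data", "updated.plant.data")
        assert list_names(lib, "data") == ["plant.data", "apple.data",
                                           "frog.data"]

    def test_remove_model_keeps_indices_contiguous(self):
        lib = create_library()
        names = ["plant.model", "frog.model1", "frog.model2", "apple.m1",
                 "apple.m2"]
        for name in names:
            lib.insert(models={name: make_record("model", {}, {})})
        remove_record(lib, "model", "apple.m2")
        summary = summarize(lib)
        assert [r["index"] for r in summary.model_rows] == [1, 2, 3, 4]
        assert list_names(lib, "model") == names[:-1]

    @pytest.mark.parametrize("selector,exc", [
        (0, InvalidSelectorError), (-1, InvalidSelectorError),
        (99, NotFoundError), ("ghost", NotFoundError)])
    def test_bad_selectors(self, selector, exc):
        lib = create_library()
        lib.insert(data={"d": make_record("data", {}, {})})
        with pytest.raises(exc):
            remove_record(lib, "data", selector)

    def test_random_scripts_match_list_oracle(self):
        rng = random.Random(42)
        for _ in range(30):
            lib = create_library()
            oracle: list[str] = []
            for step in range(20):
                if oracle and rng.random() < 0.4:
                    idx = rng.randint(1, len(oracle))
                    remove_record(lib, "data", idx)
                    del oracle[idx - 1]
                else:
                    name = f"rec{step}"
                    lib.insert(data={name: make_record("data", {}, {})})
                    oracle.append(name)
                assert list_names(lib, "data") == oracle


class TestGetRecord:
    @pytest.fixture
    def lib(self):
        lib = create_library()
        lib.insert(data={"plant.data": make_record(
            "data", _plant_frame(), {"comment": "c"})})
        return lib

    def test_payload_returned_in_original_class(self, lib):
        payload = get_record(lib, "data", "plant.data")
        assert type(payload).__name__ == lib.data["plant.data"].payload_class

    def test_with_metadata_two_part_result(self, lib):
        result = get_record(lib, "data", "plant.data", with_metadata=True)
        assert set(result) == {"data", "metadata"}
        assert result["metadata"]["comment"] == "c"

    def test_checkout_does_not_mutate(self, lib):
        first = get_record(lib, "data", "plant.data")
        lib.insert(models={"m": make_record("model", {}, {})})
        second = get_record(lib, "data", "plant.data")
        pd.testing.assert_frame_equal(first, second)

    def test_caller_edits_do_not_reach_the_library(self, lib):
        checked_out = get_record(lib, "data", "plant.data")
        checked_out.loc[0, "weight"] = 0.0
        assert get_record(lib, "data", "plant.data").loc[0, "weight"] == 4.17


class TestRecordMeta:
    @pytest.fixture
    def lib(self):
        lib = create_library()
        lib.insert(data={"plant.data": make_record(
            "data", _plant_frame(),
            {"comment": "Plant dataset from the lm helpfile.",
             "taxa": "plants"})})
        return lib

    def test_whole_collection_view(self, lib):
        allmeta = record_meta(lib, "data")
        assert set(allmeta) == {"plant.data"}
        assert list(allmeta["plant.data"].keys()) == ["comment", "taxa", "date"]

    def test_upsert_grows_metadata(self, lib):
        record_meta(lib, "data", "plant.data",
                    {"url": "u", "group": "g", "weight": "w"})
        assert len(record_meta(lib, "data", "plant.data")) == 6

    def test_set_then_delete_is_identity(self, lib):
        before = record_meta(lib, "data", "plant.data").to_dict()
        record_meta(lib, "data", "plant.data", {"k": "v"})
        record_meta(lib, "data", "plant.data", {"k": None})
        assert record_meta(lib, "data", "plant.data").to_dict() == before

    def test_updates_without_name_rejected(self, lib):
        with pytest.raises(InvalidSelectorError):
            record_meta(lib, "data", updates={"k": "v"})


class TestSummaries:
    def test_truncation_marks_summary_only(self):
        lib = create_library()
        long = "x" * 200
        lib.insert(data={"d": make_record("data", {}, {"comment": long})})
        shown = summarize(lib, truncation_width=60).data_meta["d"]["comment"]
        assert len(shown) == 60 and shown.endswith("…")
        assert record_meta(lib, "data", "d")["comment"] == long

    def test_non_tabular_rows_are_na(self, demo_library):
        rows = {r["name"]: r for r in summarize(demo_library).data_rows}
        frog = rows["frog.data"]
        assert frog["nrows"] is None and frog["ncols"] is None
        assert frog["origin_package"] == "unmarked"
        assert rows["plant.data"]["nrows"] == 20

    def test_indices_match_positions(self, demo_library):
        summary = summarize(demo_library)
        for role, rows in (("model", summary.model_rows),
                           ("data", summary.data_rows)):
            names = demo_library.names(role)
            for row in rows:
                assert names[row["index"] - 1] == row["name"]


@given(st.text(min_size=1, max_size=20))
@settings(max_examples=100, deadline=None, derandomize=True)
def test_sanitized_names_are_valid_identifiers(raw):
    clean = sanitize_name(raw)
    assert clean
    assert not clean[0].isdigit()
    assert all(c.isalnum() or c in "._" for c in clean)
    # idempotent: sanitizing a sanitized name changes nothing
    assert sanitize_name(clean) == clean


class TestMetadataMap:
    def test_values_coerced_to_text(self):
        meta = MetadataMap({"n": 100, "rate": 0.25})
        assert meta.to_dict() == {"n": "100", "rate": "0.25"}

    def test_null_sentinel_deletes(self):
        meta = MetadataMap({"a": "1", "b": "2"})
        meta.update({"a": None})
        assert "a" not in meta and list(meta.keys()) == ["b"]

    def test_keys_are_case_sensitive(self):
        meta = MetadataMap({"Key": "1", "key": "2"})
        assert meta["Key"] == "1" and meta["key"] == "2"

    def test_empty_key_rejected(self):
        with pytest.raises(DuplicateKeyError):
            MetadataMap({"": "v"})
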