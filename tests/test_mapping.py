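"""Transformation algebra: step semantics, oracles, map versioning."""

import random

import pytest

from latebind import (
    AmbiguousJoinError,
    MapDefinitionError,
    MapRegistry,
    MapStep,
    OutputDomain,
    PipelineRunner,
    PivotCollisionError,
    RetiredMapError,
    UserContext,
    apply_blinding,
    apply_depivot,
    apply_dict,
    apply_join,
    apply_pipeline,
    apply_pivot,
)
from latebind.functions import iso_date, study_day, upper_case_trim


def od(*steps, name="OUT", input_domain="IN"):
    return OutputDomain(name, input_domain, list(steps))


SEV_TABLE = {1: "mild", 2: "moderate", 3: "severe", 4: "life-threatening", 5: "death"}


class TestRowLocalSteps:
    def test_empty_pipeline_is_identity(self):
        rows = [{"a": "1"}, {"a": "2"}]
        assert apply_pipeline(rows, od()) == rows

    def test_rename_composition(self):
        rows = [{"a": "1", "z": "9"}]
        two_step = apply_pipeline(rows, od(
            MapStep("rename", {"src": "a", "dst": "b"}),
            MapStep("rename", {"src": "b", "dst": "c"})))
        one_step = apply_pipeline(rows, od(MapStep("rename", {"src": "a", "dst": "c"})))
        assert two_step == one_step == [{"z": "9", "c": "1"}]

    def test_copy_keeps_source(self):
        out = apply_pipeline([{"TERM": " ha "}], od(
            MapStep("copy", {"src": "TERM", "dst": "TERM_FOR_JOIN"})))
        assert out == [{"TERM": " ha ", "TERM_FOR_JOIN": " ha "}]

    def test_filter_drops_rows_without_term(self):
        rows = [{"TERM": "HEADACHE"}, {"OTHER": "x"}]
        out = apply_pipeline(rows, od(MapStep("filter", {"predicate": "r.TERM != null"})))
        assert out == [{"TERM": "HEADACHE"}]

    @pytest.mark.parametrize("value,expected", [("2", "moderate"), ("5", "death"),
                                                ("1", "mild"), ("99", "99")])
    def test_dict_code_list(self, value, expected):
        # unmapped values pass through unchanged
        assert apply_dict("SEV", SEV_TABLE, {"SEV": value})["SEV"] == expected

    def test_functional_error_flags_row_and_continues(self):
        runner = PipelineRunner()
        runner.functions.register("boom", lambda row, args, ctx: 1 / 0)
        out = runner.apply_pipeline([{"a": "1"}, {"a": "2"}],
                                    od(MapStep("functional", {"function": "boom"})))
        assert len(out) == 2
        assert all("_map_error" in r for r in out)

    def test_unregistered_function_rejected_before_any_row(self):
        with pytest.raises(MapDefinitionError):
            apply_pipeline([{"a": "1"}], od(MapStep("functional", {"function": "nope"})))

    def test_streaming_equals_batch_for_row_local_steps(self):
        """Row-local steps give identical results row-at-a-time or in bulk."""
        steps = [
            MapStep("rename", {"src": "a", "dst": "b"}),
            MapStep("filter", {"predicate": "r.b != null && r.b > 1"}),
            MapStep("dict", {"column": "b", "table": {"2": "two", "3": "three"}}),
            MapStep("copy", {"src": "b", "dst": "c"}),
        ]
        rows = [{"a": str(i)} for i in range(6)] + [{"x": "nope"}]
        batch = apply_pipeline(rows, od(*steps))
        streamed = []
        for row in rows:
            streamed.extend(apply_pipeline([row], od(*steps)))
        assert batch == streamed

    def test_nested_step_lists_flatten_in_depth_first_order(self):
        shared = [MapStep("rename", {"src": "a", "dst": "b"}),
                  [MapStep("copy", {"src": "b", "dst": "c"})]]
        domain = od(shared, MapStep("rename", {"src": "c", "dst": "d"}))
        assert [s.step_kind for s in domain.steps] == ["rename", "copy", "rename"]
        assert apply_pipeline([{"a": "1"}], domain) == [{"b": "1", "d": "1"}]

    def test_step_params_validated_at_creation(self):
        with pytest.raises(MapDefinitionError):
            MapStep("rename", {"src": "a"})
        with pytest.raises(MapDefinitionError):
            MapStep("join", {"selectedDomain": "X", "joinCols": ["k"],
                             "colNameTranslations": {}, "selectedColumn": ["a"],
                             "outputColumn": ["b"]})
        with pytest.raises(MapDefinitionError):
            MapStep("wibble", {})


class TestFunctionals:
    def test_iso_date_conversion(self):
        assert iso_date("10/07/2017") == "2017-10-07"
        assert iso_date("2017-10-05") == "2017-10-05"
        assert iso_date("not a date") == "not a date"

    def test_upper_case_trim_trims_then_uppercases(self):
        assert upper_case_trim("  headache ") == "HEADACHE"

    def test_study_day_has_no_day_zero(self):
        assert study_day("2017-10-05", "2017-10-07") == "3"
        assert study_day("2017-10-05", "2017-10-05") == "1"
        assert study_day("2017-10-05", "2017-10-04") == "-1"


class TestJoin:
    SPEC = {"selectedDomain": "AECoding", "joinCols": ["AETERM"],
            "colNameTranslations": {"AETERM": "TERM_FOR_JOIN"},
            "selectedColumn": ["I_AETERM_PT", "I_AETERM_SOC"],
            "outputColumn": ["DECOD", "BODSYS"]}
    CODING = [{"AETERM": "HEADACHE", "I_AETERM_PT": "Headache",
               "I_AETERM_SOC": "Nervous system disorders"}]

    def test_matching_row_gains_coded_columns(self):
        [row] = apply_join([{"TERM_FOR_JOIN": "HEADACHE"}], self.SPEC, self.CODING)
        assert row["DECOD"] == "Headache"
        assert row["BODSYS"] == "Nervous system disorders"

    def test_no_match_yields_nulls(self):
        [row] = apply_join([{"TERM_FOR_JOIN": "NAUSEA"}], self.SPEC, self.CODING)
        assert row["DECOD"] is None and row["BODSYS"] is None

    def test_null_key_yields_nulls(self):
        [row] = apply_join([{"OTHER": "x"}], self.SPEC, self.CODING)
        assert row["DECOD"] is None

    def test_ambiguous_match_raises_by_default(self):
        coding = self.CODING + [dict(self.CODING[0], I_AETERM_PT="Other")]
        with pytest.raises(AmbiguousJoinError):
            apply_join([{"TERM_FOR_JOIN": "HEADACHE"}], self.SPEC, coding)
        # configurable first-match fallback
        [row] = apply_join([{"TERM_FOR_JOIN": "HEADACHE"}], self.SPEC, coding,
                           first_match=True)
        assert row["DECOD"] == "Headache"

    def test_random_tables_match_nested_loop_oracle(self):
        rng = random.Random(777)
        spec = {"selectedDomain": "R", "joinCols": ["k1", "k2"],
                "colNameTranslations": {"k1": "a1", "k2": "a2"},
                "selectedColumn": ["v"], "outputColumn": ["out"]}
        for _ in range(20):
            left = [{"a1": str(rng.randrange(6)), "a2": str(rng.randrange(3)),
                     "payload": str(rng.random())} for _ in range(rng.randrange(1, 60))]
            # unique right-hand keys (ambiguity handled in its own test)
            keys = {(str(rng.randrange(6)), str(rng.randrange(3)))
                    for _ in range(rng.randrange(1, 15))}
            right = [{"k1": k1, "k2": k2, "v": f"{k1}-{k2}"} for k1, k2 in keys]
            got = apply_join(left, spec, right)
            # oracle: nested loops over both tables
            expected = []
            for lrow in left:
                matches = [r for r in right
                           if r["k1"] == lrow["a1"] and r["k2"] == lrow["a2"]]
                new = dict(lrow)
                new["out"] = matches[0]["v"] if matches else None
                expected.append(new)
            assert got == expected


class TestPivot:
    def test_worked_example_lb_pivot(self):
        rows = [
            {"subject": "0001", "site": "1", "visit": "1", "testcd": "AST",
             "value": "5", "dat": "10/07/2017"},
            {"subject": "0001", "site": "1", "visit": "1", "testcd": "ALT",
             "value": "6", "dat": "10/07/2017"},
        ]
        out = apply_pivot(rows, ["subject", "site", "visit", "dat"], "testcd", "value")
        assert out == [{"subject": "0001", "site": "1", "visit": "1",
                        "dat": "10/07/2017", "AST": "5", "ALT": "6"}]

    def test_collision_names_key_and_attribute(self):
        rows = [{"k": "1", "attr": "A", "v": "x"}, {"k": "1", "attr": "A", "v": "y"}]
        with pytest.raises(PivotCollisionError) as exc:
            apply_pivot(rows, ["k"], "attr", "v")
        assert exc.value.attribute == "A"

    def test_depivot_single_row_single_measure(self):
        out = apply_depivot([{"k": "1", "HR": "60"}], ["k"], ["HR"], "attr", "val")
        assert out == [{"k": "1", "attr": "HR", "val": "60"}]

    def test_depivot_pivot_round_trip_random_tables(self):
        rng = random.Random(42)
        for _ in range(20):
            n_keys = rng.randrange(1, 10)
            measures = [f"M{i}" for i in range(rng.randrange(1, 5))]
            wide = [{"k": str(i), **{m: str(rng.randrange(100)) for m in measures}}
                    for i in range(n_keys)]
            eav = apply_depivot(wide, ["k"], measures, "attr", "val")
            assert len(eav) == n_keys * len(measures)
            back = apply_pivot(eav, ["k"], "attr", "val")
            assert sorted(back, key=lambda r: r["k"]) == sorted(wide, key=lambda r: r["k"])

    def test_pivot_matches_group_by_oracle_random(self):
        rng = random.Random(99)
        for _ in range(20):
            rows = []
            seen = set()
            for _ in range(rng.randrange(1, 50)):
                k, a = str(rng.randrange(8)), f"A{rng.randrange(4)}"
                if (k, a) in seen:
                    continue
                seen.add((k, a))
                rows.append({"k": k, "attr": a, "v": str(rng.randrange(100))})
            got = {r["k"]: r for r in apply_pivot(rows, ["k"], "attr", "v")}
            # oracle: dict-of-dicts group-by
            expected = {}
            for r in rows:
                expected.setdefault(r["k"], {"k": r["k"]})[r["attr"]] = r["v"]
            assert got == expected


class TestBlinding:
    RULE = {"role": "Blinded", "end_date": "2019-01-01", "salt": "s1"}

    def test_blinded_before_end_date_fuzzes_into_range(self):
        ctx = UserContext(role="Blinded", now=1527811200000)  # 2018-06-01
        row = {"_record_id": "abc", "DOSE": "80"}
        out = apply_blinding("DOSE", self.RULE, row, ctx)
        assert out["DOSE"] in {"0", "1", "2"}

    def test_fuzz_stable_across_repeated_queries(self):
        ctx = UserContext(role="Blinded", now=1527811200000)
        row = {"_record_id": "abc", "DOSE": "80"}
        first = apply_blinding("DOSE", self.RULE, row, ctx)
        for _ in range(5):
            assert apply_blinding("DOSE", self.RULE, dict(row), ctx) == first

    def test_unblinded_role_unchanged(self):
        ctx = UserContext(role="Unblinded", now=1527811200000)
        row = {"_record_id": "abc", "DOSE": "80"}
        assert apply_blinding("DOSE", self.RULE, row, ctx)["DOSE"] == "80"

    def test_automatic_unblinding_after_end_date(self):
        ctx = UserContext(role="Blinded", now=1559347200000)  # 2019-06-01
        row = {"_record_id": "abc", "DOSE": "80"}
        assert apply_blinding("DOSE", self.RULE, row, ctx)["DOSE"] == "80"

    def test_different_records_fuzz_independently(self):
        ctx = UserContext(role="Blinded", now=1527811200000)
        values = {apply_blinding("DOSE", self.RULE,
                                 {"_record_id": f"r{i}", "DOSE": "80"}, ctx)["DOSE"]
                  for i in range(30)}
        assert values == {"0", "1", "2"}  # all three fuzz values occur


class TestMapRegistry:
    def d(self, tag):
        return od(MapStep("rename", {"src": "a", "dst": tag}))

    def test_edit_closes_interval_and_versions(self):
        reg = MapRegistry()
        reg.create_map("LB", self.d("v1"), t=100)
        reg.edit_map("LB", self.d("v2"), t=200)
        assert reg.active_maps_asof(150)["LB"].version == 1
        assert reg.active_maps_asof(200)["LB"].version == 2
        assert reg.active_maps_asof(50) == {}

    def test_retired_map_rejects_edits(self):
        reg = MapRegistry()
        reg.create_map("LB", self.d("v1"), t=100)
        reg.retire_map("LB", t=200)
        with pytest.raises(RetiredMapError):
            reg.edit_map("LB", self.d("v2"), t=300)
        assert reg.active_maps_asof(250) == {}
        assert reg.active_maps_asof(150)["LB"].version == 1

    def test_validity_intervals_disjoint_and_contiguous(self):
        reg = MapRegistry()
        reg.create_map("LB", self.d("v1"), t=100)
        for i, t in enumerate((200, 300, 400), start=2):
            reg.edit_map("LB", self.d(f"v{i}"), t=t)
        history = reg.history("LB")
        for prev, nxt in zip(history, history[1:]):
            assert prev.invalidated_at == nxt.created_at
        assert history[-1].invalidated_at is None

    def test_random_edit_sequences_match_replay_oracle(self):
        rng = random.Random(2024)
        for trial in range(30):
            reg = MapRegistry()
            events = []  # (t, map_id, version)
            t = 0
            known = []
            for _ in range(rng.randrange(1, 30)):
                t += rng.randrange(1, 10)
                if known and rng.random() < 0.7:
                    map_id = rng.choice(known)
                    mv = reg.edit_map(map_id, self.d(f"{map_id}@{t}"), t)
                else:
                    map_id = f"m{len(known)}"
                    known.append(map_id)
                    mv = reg.create_map(map_id, self.d(f"{map_id}@{t}"), t)
                events.append((t, map_id, mv.version))
            for _ in range(20):
                q = rng.randrange(0, t + 5)
                # oracle: replay events up to q; latest event per map wins
                expected = {}
                for ev_t, map_id, version in events:
                    if ev_t <= q:
                        expected[map_id] = version
                got = {m: mv.version for m, mv in reg.active_maps_asof(q).items()}
                assert got == expected

    def test_serialization_round_trip(self):
        reg = MapRegistry()
        reg.create_map("LB", self.d("v1"), t=100)
        reg.edit_map("LB", self.d("v2"), t=200)
        clone = MapRegistry.from_json_obj(reg.to_json_obj())
        for t in (50, 150, 250):
            assert ({m: v.version for m, v in reg.active_maps_asof(t).items()}
                    == {m: v.version for m, v in clone.active_maps_asof(t).items()})
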