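"""Graph store: constraints, merge semantics, matching, lineage, snapshots."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from conftest import brute_force_match, random_pattern, random_store, rows_to_multiset
from pergola.graphstore import (AmbiguousMergeError, Cmp, Const, ConstraintViolation,
                                GraphError, GraphStore, N, PatternError, Prop,
                                Query, R, Ref, UnknownNodeError)


@pytest.fixture
def store() -> GraphStore:
    s = GraphStore()
    s.register_unique("Blob", ["bucket", "path"])
    s.register_unique("Sample", ["sample_id"])
    return s


class TestCreateAndConstraints:
    def test_multi_label_node(self, store):
        rec = store.create_node({"Blob", "Fastq"}, {"bucket": "b", "path": "p", "crc32c": "x"})
        assert rec.labels == {"Blob", "Fastq"}
        assert store.node(rec.id).properties["path"] == "p"

    def test_empty_label_set_rejected(self, store):
        with pytest.raises(GraphError):
            store.create_node(set(), {})

    def test_uniqueness_violation_is_an_error_not_overwrite(self, store):
        store.create_node({"Blob"}, {"bucket": "b", "path": "p"})
        with pytest.raises(ConstraintViolation):
            store.create_node({"Blob"}, {"bucket": "b", "path": "p", "size": 2})
        assert len(store) == 1

    def test_constraint_only_applies_with_full_key(self, store):
        store.create_node({"Blob"}, {"bucket": "b"})  # no path: key not engaged
        store.create_node({"Blob"}, {"bucket": "b"})
        assert len(store) == 2


class TestMerge:
    def test_created_flag_then_idempotent(self, store):
        first = store.merge_node({"Sample"}, {"sample_id": "S1"}, on_create={"plate_id": "P"})
        again = store.merge_node({"Sample"}, {"sample_id": "S1"}, on_create={"plate_id": "Q"})
        assert first.created and not again.created
        assert first.node_id == again.node_id
        assert store.node(first.node_id).properties["plate_id"] == "P"  # on_create once

    def test_merge_after_create_applies_on_match(self, store):
        rec = store.create_node({"Sample"}, {"sample_id": "S1"})
        res = store.merge_node({"Sample"}, {"sample_id": "S1"}, on_match={"seen": True})
        assert not res.created and res.node_id == rec.id
        assert store.node(rec.id).properties["seen"] is True

    def test_ambiguous_merge_raises(self):
        s = GraphStore()  # no constraint registered, duplicates possible
        s.create_node({"JobRequest"}, {"task": "t", "input_key": "k"})
        s.create_node({"JobRequest"}, {"task": "t", "input_key": "k"})
        with pytest.raises(AmbiguousMergeError):
            s.merge_node({"JobRequest"}, {"task": "t", "input_key": "k"})

    def test_empty_key_rejected(self, store):
        with pytest.raises(GraphError):
            store.merge_node({"Sample"}, {})

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(ops=st.lists(st.tuples(st.sampled_from(["A", "B"]),
                                  st.integers(0, 4),
                                  st.integers(0, 3)), max_size=20))
    def test_replaying_merge_log_is_idempotent(self, ops):
        """Applying any merge sequence twice is isomorphic to applying it once."""
        def apply(s: GraphStore, times: int):
            for _ in range(times):
                ids = {}
                for label, key, extra in ops:
                    res = s.merge_node({label}, {"k": key}, on_create={"extra": extra})
                    ids[(label, key)] = res.node_id
                pairs = list(ids.values())
                for a, b in zip(pairs, pairs[1:]):
                    s.merge_relationship(a, "GENERATED", b)
            return s
        once, twice = apply(GraphStore(), 1), apply(GraphStore(), 2)
        assert once.fingerprint() == twice.fingerprint()


class TestRelationships:
    def test_merge_relationship_deduplicates(self, store):
        a = store.create_node({"Blob"}, {"bucket": "b", "path": "1"}).id
        b = store.create_node({"Job"}, {"job_id": "j"}).id
        store.merge_relationship(a, "WAS_USED_BY", b)
        store.merge_relationship(a, "WAS_USED_BY", b)
        assert store.relationship_count == 1

    def test_provenance_edge_queryable_from_either_end(self, store):
        j = store.create_node({"Job"}, {"job_id": "j"}).id
        b = store.create_node({"Blob"}, {"bucket": "b", "path": "1"}).id
        store.merge_relationship(j, "GENERATED", b)
        fwd = store.match(N("j", {"Job"}), R("GENERATED"), N("b", {"Blob"}))
        rev = store.match(N("b", {"Blob"}), R("GENERATED", "in"), N("j", {"Job"}))
        assert fwd[0]["b"] == b and rev[0]["j"] == j

    def test_missing_endpoint_is_error(self, store):
        a = store.create_node({"Blob"}, {"bucket": "b", "path": "1"}).id
        with pytest.raises(UnknownNodeError):
            store.merge_relationship(a, "GENERATED", 999)


class TestMatch:
    def test_single_hop(self, store):
        b = store.create_node({"Blob"}, {"bucket": "x", "path": "p"}).id
        j = store.create_node({"Job"}, {"job_id": "j"}).id
        store.merge_relationship(b, "WAS_USED_BY", j)
        rows = store.match(N("b", {"Blob"}), R("WAS_USED_BY"), N("j", {"Job"}))
        assert rows == [{"b": b, "j": j}]

    def test_malformed_pattern_rejected(self, store):
        with pytest.raises(PatternError):
            store.match(N("a"), N("b"))  # node-node without relationship

    def test_count_aggregate_of_read_group_ubams(self, store):
        """A sample with four read-group uBAMs aggregates to count 4."""
        for rg in range(4):
            store.create_node({"Blob", "Ubam"},
                              {"bucket": "b", "path": f"u{rg}", "sample_id": "S", "read_group": rg})
        store.create_node({"Blob", "Ubam"}, {"bucket": "b", "path": "other", "sample_id": "T",
                                             "read_group": 0})
        q = (Query().match(N("u", {"Ubam"}, {"sample_id": "S"}))
             .aggregate(aggs={"n": ("count_distinct", Prop("u", "read_group"))})
             .returns(n=Ref("n")))
        assert store.run(q) == [{"n": 4}]

    @pytest.mark.parametrize("seed", range(12))
    def test_agrees_with_brute_force_on_random_graphs(self, seed):
        store = random_store(seed)
        rng = random.Random(seed + 1000)
        for _ in range(8):
            elements = random_pattern(rng)
            rows = store.match(*elements)
            node_vars = [e.var for e in elements[0::2]]
            assert rows_to_multiset(rows, node_vars) == brute_force_match(store, elements)


class TestSoftDelete:
    def _pipeline(self, store):
        blobs = [store.create_node({"Blob"}, {"bucket": "b", "path": f"p{i}"}).id
                 for i in range(4)]
        return blobs

    def test_flagged_excluded_from_matches_but_lineage_reachable(self, store):
        blobs = self._pipeline(store)
        job = store.create_node({"Job"}, {"job_id": "j"}).id
        store.merge_relationship(job, "GENERATED", blobs[0])
        assert store.mark_deleted(blobs[:3]) == 3
        assert len(store.match(N("b", {"Blob"}))) == 1
        assert len(store.match(N("b", {"Blob"}), include_deleted=True)) == 4
        paths = store.traverse_lineage(job, ["GENERATED"], "downstream", include_deleted=True)
        assert any(blobs[0] in p.node_ids for p in paths)

    def test_double_delete_not_recounted(self, store):
        blobs = self._pipeline(store)
        assert store.mark_deleted(blobs[:2]) == 2
        assert store.mark_deleted(blobs[:3]) == 1  # only the third is new

    def test_unknown_id_is_error(self, store):
        with pytest.raises(UnknownNodeError):
            store.mark_deleted([12345])

    def test_relationships_survive_deletion(self, store):
        a = store.create_node({"Blob"}, {"bucket": "b", "path": "a"}).id
        b = store.create_node({"Blob"}, {"bucket": "b", "path": "b"}).id
        store.merge_relationship(a, "GENERATED", b)
        store.mark_deleted([a, b])
        assert store.relationship_count == 1


class TestLineage:
    def test_three_step_linear_pipeline_matches_adjacency_oracle(self, store):
        """fastq -> job1 -> ubam -> job2 -> bam -> job3 -> vcf, upstream from vcf."""
        chain = ["fastq", "job1", "ubam", "job2", "bam", "job3", "vcf"]
        ids = {}
        for i, name in enumerate(chain):
            labels = {"Job"} if name.startswith("job") else {"Blob"}
            props = ({"job_id": name} if "Job" in labels
                     else {"bucket": "b", "path": name})
            ids[name] = store.create_node(labels, props).id
        for src, dst in zip(chain, chain[1:]):
            rtype = "WAS_USED_BY" if src in ("fastq", "ubam", "bam") else "GENERATED"
            store.merge_relationship(ids[src], rtype, ids[dst])
        paths = store.traverse_lineage(ids["vcf"], ["GENERATED", "WAS_USED_BY"], "upstream")
        assert len(paths) == 1
        assert list(paths[0].node_ids) == [ids[n] for n in reversed(chain)]
        assert len(paths[0]) == 6

    def test_isolated_node_yields_zero_length_path(self, store):
        nid = store.create_node({"Sample"}, {"sample_id": "S"}).id
        paths = store.traverse_lineage(nid, ["GENERATED"], "upstream")
        assert paths == [type(paths[0])((nid,), ())]

    def test_unknown_node_is_error(self, store):
        with pytest.raises(UnknownNodeError):
            store.traverse_lineage(999, ["GENERATED"])


class TestQueryPipeline:
    def test_absent_guard_blocks_when_node_exists(self, store):
        store.create_node({"JobRequest"}, {"task": "t", "input_key": "k"})
        q = (Query().match(N("x", {"JobRequest"}, {"task": "t", "input_key": "k"}),
                           absent=True)
             .returns(ok=Const(True)))
        assert store.run(q) == []
        q2 = (Query().match(N("x", {"JobRequest"}, {"task": "t", "input_key": "other"}),
                            absent=True)
              .returns(ok=Const(True)))
        assert store.run(q2) == [{"ok": True}]

    def test_merge_semaphore_gates_second_run(self, store):
        def launch_query():
            return (Query()
                    .merge_node("req", {"JobRequest"}, key={"task": "t", "input_key": "k"})
                    .filter_created("req")
                    .returns(launch=Const(True)))
        assert store.run(launch_query()) == [{"launch": True}]
        assert store.run(launch_query()) == []

    def test_unbound_reference_is_error(self, store):
        q = Query().returns(x=Ref("nope"))
        with pytest.raises(PatternError):
            store.run(q)

    def test_where_compares_aggregate_to_other_node_property(self, store):
        for rg in range(3):
            store.create_node({"Ubam"}, {"sample_id": "S", "read_group": rg, "path": f"u{rg}"})
        m = store.create_node({"Checksum"}, {"sample_id": "S", "expected_read_groups": 3}).id
        q = (Query().match(N("u", {"Ubam"}, {"sample_id": "S"}))
             .aggregate(aggs={"rgs": ("count_distinct", Prop("u", "read_group"))})
             .match(N("m", {"Checksum"}, {"sample_id": "S"}))
             .where(Cmp("eq", Ref("rgs"), Prop("m", "expected_read_groups")))
             .returns(rgs=Ref("rgs")))
        assert store.run(q) == [{"rgs": 3}]
        store.set_properties(m, {"expected_read_groups": 4})
        assert store.run(q) == []


class TestSerialization:
    def test_jsonl_round_trip_preserves_fingerprint(self, store, tmp_path):
        a = store.create_node({"Blob", "Fastq"},
                              {"bucket": "b", "path": "p", "mate_pair": 1, "tags": ["x", "y"]}).id
        b = store.create_node({"Job"}, {"job_id": "j"}).id
        store.merge_relationship(a, "WAS_USED_BY", b, {"weight": 2})
        store.mark_deleted([a])
        path = tmp_path / "snap.jsonl"
        store.to_jsonl(path)
        restored = GraphStore.from_jsonl(path)
        assert restored.fingerprint() == store.fingerprint()
        assert restored.node(a).deleted
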